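"""Delimited-text and JSON I/O.

All tables are tab-separated UTF-8 with a header row and "." decimals, so
round trips are bit-exact for tests; structured reports are JSON with
sorted keys. Phylotype tables are stored samples-as-rows with the sample id
as the first column; BIOM input is accepted through an optional lazy
import.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phylotype_table(table: pd.DataFrame, path: str | Path) -> None:
    write_table(table, path, index=True)


def read_phylotype_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x phylotypes relative-abundance table (TSV or BIOM)."""
    p = Path(path)
    if p.suffix == ".biom":
        try:
            import biom  # optional; TSV is the primary interchange format
        except ImportError as exc:
            raise ImportError(
                "BIOM input requires the biom-format package; "
                "convert the table to TSV instead"
            ) from exc
        t = biom.load_table(str(p))
        df = t.to_dataframe(dense=True).T  # biom stores observations x samples
        df.index.name = "site_id"
        return df
    return pd.read_csv(p, sep="\t", index_col=0)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return None if np.isnan(o) else float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
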