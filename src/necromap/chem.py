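"""Necromass chemistry: amino-sugar biomarkers and qPCR relative quantification.

Soil microbial necromass carbon (MNC) is estimated from amino-sugar
biomarkers. Muramic acid (MurA) occurs only in bacterial cell walls, while
glucosamine (GluN) is predominantly fungal, so the two can be combined into
separate bacterial and fungal necromass-C pools:

    fungal C    = (GluN/179.17 - 2 * MurA/251.23) * 179.17 * 9
    bacterial C = MurA * 45
    total C     = fungal C + bacterial C

with concentrations in mg per g dry soil, 179.17 and 251.23 the molar masses
of GluN and MurA, 9 the fungal GluN->C conversion factor and 45 the
MurA->bacterial-C factor. On strongly bacteria-dominated samples the fungal
term can go negative; it is clamped to zero and flagged.

Functional-gene abundance from high-throughput qPCR is expressed as a
relative quantity 10**((31 - Ct) / (10/3)); a gene is called positive in a
sample only when all three technical replicates amplified, in which case the
per-replicate relative quantities are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConversionCoefficients",
    "MncEstimate",
    "CtRecord",
    "mnc_from_amino_sugars",
    "mnc_table",
    "qpcr_relative_quant",
    "qpcr_call",
]

#: Required columns of an amino-sugar profile table (mg per g dry soil).
AMINO_SUGAR_COLUMNS = ("GluN", "GalN", "MurA", "ManN")


@dataclass(frozen=True)
class ConversionCoefficients:
    """Literature conversion constants for amino sugar -> necromass C.

    Alternates can be supplied wherever a ``ConversionCoefficients`` is
    accepted; these defaults are the standard values.
    """

    glun_molar_mass: float = 179.17  # g/mol glucosamine
    mura_molar_mass: float = 251.23  # g/mol muramic acid
    fungal_factor: float = 9.0       # fungal GluN -> C
    bacterial_factor: float = 45.0   # MurA -> bacterial C


@dataclass(frozen=True)
class MncEstimate:
    """Fungal, bacterial and total necromass C (mg C per g dry soil)."""

    fungal_C: float
    bacterial_C: float
    total_C: float
    clamped: bool = False


@dataclass(frozen=True)
class CtRecord:
    """One gene x sample qPCR measurement with three technical replicates.

    Missing replicates are ``None`` (or NaN).
    """

    gene_id: str
    sample_id: str
    ct_replicates: tuple = field(default=(None, None, None))


def mnc_from_amino_sugars(
    glun: float,
    mura: float,
    coefficients: ConversionCoefficients | None = None,
) -> MncEstimate:
    """Convert GluN and MurA concentrations (mg/g) to an :class:`MncEstimate`.

    The fungal pool subtracts the bacterial share of glucosamine (two moles
    of GluN per mole of MurA); if that difference is negative the fungal pool
    is clamped to zero and ``clamped`` is set.

    Raises
    ------
    ValueError
        If either concentration is negative.
    """
    c = coefficients or ConversionCoefficients()
    if glun < 0 or mura < 0:
        raise ValueError(
            f"amino-sugar concentrations must be >= 0, got GluN={glun}, MurA={mura}"
        )
    fungal = (glun / c.glun_molar_mass - 2.0 * mura / c.mura_molar_mass) \
        * c.glun_molar_mass * c.fungal_factor
    clamped = fungal < 0
    fungal = max(0.0, fungal)
    bacterial = mura * c.bacterial_factor
    return MncEstimate(
        fungal_C=fungal,
        bacterial_C=bacterial,
        total_C=fungal + bacterial,
        clamped=bool(clamped),
    )


def mnc_table(
    profiles: pd.DataFrame,
    coefficients: ConversionCoefficients | None = None,
) -> pd.DataFrame:
    """Vectorized conversion of an amino-sugar profile table.

    ``profiles`` needs ``GluN`` and ``MurA`` columns (mg/g); ``GalN``/``ManN``
    are carried through I/O untouched and play no role in the conversion.
    Returns a frame indexed like ``profiles`` with columns ``fungal_C``,
    ``bacterial_C``, ``total_C`` and ``clamped``.
    """
    c = coefficients or ConversionCoefficients()
    glun = profiles["GluN"].to_numpy(dtype=float)
    mura = profiles["MurA"].to_numpy(dtype=float)
    if (glun < 0).any() or (mura < 0).any():
        raise ValueError("amino-sugar concentrations must be >= 0")
    fungal = (glun / c.glun_molar_mass - 2.0 * mura / c.mura_molar_mass) \
        * c.glun_molar_mass * c.fungal_factor
    clamped = fungal < 0
    fungal = np.maximum(fungal, 0.0)
    bacterial = mura * c.bacterial_factor
    out = pd.DataFrame(
        {
            "fungal_C": fungal,
            "bacterial_C": bacterial,
            "total_C": fungal + bacterial,
            "clamped": clamped,
        },
        index=profiles.index,
    )
    if "site_id" in profiles.columns:
        out.insert(0, "site_id", profiles["site_id"].to_numpy())
    return out


def qpcr_relative_quant(ct: float) -> float:
    """Relative quantity 10**((31 - Ct) / (10/3)) for one cycle threshold.

    Ct must lie in (0, 45]. A Ct of 31 maps to 1.0, and every 10/3-cycle
    decrease multiplies the quantity by 10.
    """
    if not (0 < ct <= 45):
        raise ValueError(f"Ct must be in (0, 45], got {ct}")
    return 10.0 ** ((31.0 - ct) / (10.0 / 3.0))


def qpcr_call(record: CtRecord) -> tuple[bool, float | None]:
    """Positivity call and mean relative quantity for a three-replicate record.

    A gene is positive only when all three technical replicates amplified
    (no missing Ct); the returned quantity is the mean of the three
    per-replicate relative quantities (not the quantity of the mean Ct).
    """
    reps = record.ct_replicates
    if len(reps) != 3:
        raise ValueError(f"expected exactly 3 replicate slots, got {len(reps)}")
    present = [r for r in reps if r is not None and not (
        isinstance(r, float) and math.isnan(r))]
    if len(present) < 3:
        return False, None
    return True, float(np.mean([qpcr_relative_quant(r) for r in present]))
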