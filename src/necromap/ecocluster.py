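"""Eco-cluster inference from phylotype relative-abundance tables.

Dominant phylotypes (top fraction by mean relative abundance AND present in
more than half of the samples) are screened for habitat preference with a
random-forest regression of abundance on all environmental variables,
keeping those whose out-of-bag variance explained reaches a threshold
(default 30%). Screened phylotypes are grouped by the similarity of their
abundance profiles — pairwise semi-partial Spearman correlation with the
spatial coordinates rank-partialled out of the second variable — via
average-linkage agglomerative clustering. Clusters are named after the
modal habitat preference of their members (e.g. ``HMAP&LMAT`` = high mean
annual precipitation, low mean annual temperature), and per-site cluster
relative abundances are the sums of member abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import silhouette_score

__all__ = [
    "EcoClusterSet",
    "select_dominant_phylotypes",
    "screen_habitat_preference",
    "semi_partial_spearman",
    "cluster_phylotypes",
    "name_cluster",
    "cluster_relative_abundance",
]

# display abbreviations used in cluster labels
_LABEL_ABBREV = {"elevation": "ele"}


@dataclass
class EcoClusterSet:
    """Phylotype -> cluster assignment with habitat-preference-derived names."""

    assignments: dict[str, str]                 # phylotype -> cluster label
    preference_table: pd.DataFrame              # per-phylotype screen results
    names: list[str] = field(default_factory=list)

    def members(self, name: str) -> list[str]:
        return [p for p, c in self.assignments.items() if c == name]

    def to_dict(self) -> dict:
        return {"assignments": self.assignments, "names": self.names}


def select_dominant_phylotypes(
    table: pd.DataFrame,
    top_frac: float = 0.10,
    occupancy_frac: float = 0.5,
) -> list[str]:
    """Phylotypes in the top ``top_frac`` by mean relative abundance AND
    present (abundance > 0) in strictly more than ``occupancy_frac`` of
    samples.

    The abundance rank uses the mean relative abundance across samples; the
    top set has ``ceil(top_frac * n_phylotypes)`` members before the
    occupancy filter is applied.
    """
    if table.shape[1] == 0 or table.shape[0] == 0:
        raise ValueError("empty phylotype table")
    n_top = max(1, math.ceil(top_frac * table.shape[1]))
    means = table.mean(axis=0)
    # stable deterministic ranking: abundance desc, then column name
    order = sorted(table.columns, key=lambda p: (-means[p], p))
    top = set(order[:n_top])
    occ = (table > 0).sum(axis=0) / table.shape[0]
    return [p for p in table.columns if p in top and occ[p] > occupancy_frac]


def screen_habitat_preference(
    table: pd.DataFrame,
    phylotypes: list[str],
    env: pd.DataFrame,
    threshold: float = 30.0,
    n_trees: int = 500,
    seed: int = 0,
    env_variables: list[str] | None = None,
) -> pd.DataFrame:
    """Random-forest habitat-preference screen for each candidate phylotype.

    Fits an RF regression of the phylotype's relative abundance on all
    environmental variables jointly and records the out-of-bag variance
    explained (OOB R-squared x 100, floored at 0), the top-importance driver
    and the sign of the driver's Spearman association with abundance.
    Phylotypes at or above ``threshold`` % variance explained are marked kept.

    Returns a frame with columns ``phylotype, variance_explained, driver,
    direction, kept``.
    """
    if len(table) != len(env):
        raise ValueError("env rows must align with phylotype-table samples")
    from .synthetic import ENV_VARIABLES

    variables = env_variables or [v for v in ENV_VARIABLES if v in env.columns]
    X = env[variables].to_numpy(dtype=float)
    rows = []
    for i, p in enumerate(phylotypes):
        y = table[p].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows.append((p, 0.0, variables[0], 0, False))
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            oob_score=True,
            random_state=seed + i,
            n_jobs=1,
            bootstrap=True,
        )
        rf.fit(X, y)
        ve = max(0.0, float(rf.oob_score_)) * 100.0
        driver = variables[int(np.argmax(rf.feature_importances_))]
        rho = spearmanr(env[driver].to_numpy(dtype=float), y).statistic
        direction = int(np.sign(rho)) if np.isfinite(rho) and rho != 0 else 0
        rows.append((p, ve, driver, direction, ve >= threshold))
    return pd.DataFrame(
        rows, columns=["phylotype", "variance_explained", "driver", "direction", "kept"]
    )


def semi_partial_spearman(
    table: pd.DataFrame,
    env: pd.DataFrame,
    conditioning: tuple[str, ...] = ("lon", "lat"),
) -> pd.DataFrame:
    """Pairwise semi-partial Spearman correlation among phylotype profiles.

    For each ordered pair (i, j) the conditioning variables are
    rank-partialled out of j only (semi-partial): rho_ij = Pearson
    correlation of rank(x_i) with the residual of rank(x_j) regressed on the
    ranks of the conditioning set. The returned matrix is symmetrized by
    averaging rho_ij and rho_ji, with unit diagonal.
    """
    n = len(table)
    R = np.apply_along_axis(rankdata, 0, table.to_numpy(dtype=float))
    C = np.column_stack(
        [np.ones(n)] + [rankdata(env[c].to_numpy(dtype=float)) for c in conditioning]
    )
    beta, *_ = np.linalg.lstsq(C, R, rcond=None)
    E = R - C @ beta  # residual ranks, conditioning removed from the second slot
    Rc = R - R.mean(axis=0)
    Ec = E - E.mean(axis=0)
    sd_r = np.sqrt((Rc**2).sum(axis=0))
    sd_e = np.sqrt((Ec**2).sum(axis=0))
    sd_r[sd_r == 0] = 1.0
    sd_e[sd_e == 0] = 1.0
    M = (Rc.T @ Ec) / np.outer(sd_r, sd_e)
    S = (M + M.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=table.columns, columns=table.columns)


def name_cluster(
    members: list[str],
    preference_table: pd.DataFrame,
    max_parts: int = 2,
    support_frac: float = 0.25,
) -> str:
    """Label a cluster from the modal habitat preferences of its members.

    Each member contributes one (driver, direction) preference; preferences
    are grouped and ranked by member count, then mean variance explained,
    then alphabetical label. Up to ``max_parts`` groups supported by at least
    ``support_frac`` of the members are concatenated as ``H<var>``/``L<var>``
    joined with ``&`` (e.g. ``HMAP&LMAT``); elevation abbreviates to ``ele``.
    """
    if not members:
        raise ValueError("empty cluster")
    pref = preference_table.set_index("phylotype").loc[
        [m for m in members if m in set(preference_table["phylotype"])]
    ]
    groups: dict[str, list[float]] = {}
    for _, row in pref.iterrows():
        if row["direction"] == 0:
            continue
        disp = _LABEL_ABBREV.get(row["driver"], row["driver"])
        label = ("H" if row["direction"] > 0 else "L") + disp
        groups.setdefault(label, []).append(float(row["variance_explained"]))
    if not groups:
        return "unresolved"
    ranked = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), -float(np.mean(kv[1])), kv[0]),
    )
    min_support = max(1, math.ceil(support_frac * len(members)))
    parts = [lab for lab, ves in ranked if len(ves) >= min_support][:max_parts]
    if not parts:
        parts = [ranked[0][0]]
    return "&".join(parts)


def cluster_phylotypes(
    preference_table: pd.DataFrame,
    table: pd.DataFrame,
    env: pd.DataFrame,
    k: int | str = "auto",
    k_max: int = 12,
    conditioning: tuple[str, ...] = ("lon", "lat"),
) -> EcoClusterSet:
    """Group screened phylotypes into named eco-clusters.

    The semi-partial Spearman correlation matrix is converted to the
    distance 1 - rho and cut by average-linkage agglomerative clustering.
    With ``k="auto"`` the cut maximizing the mean silhouette over k = 2..k_max
    is chosen (smaller k on ties); an integer pins the cluster count.
    """
    kept = preference_table.loc[preference_table["kept"], "phylotype"].tolist()
    if len(kept) < 2:
        raise ValueError("need at least 2 screened phylotypes to cluster")
    sub = table[kept]
    S = semi_partial_spearman(sub, env, conditioning=conditioning)
    D = np.clip(1.0 - S.to_numpy(), 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")

    if k == "auto":
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(k_max, len(kept) - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(D, labels, metric="precomputed")
            if score > best_score + 1e-12:
                best_k, best_score = kk, score
        k = best_k
    elif k == 1:
        labels = np.ones(len(kept), dtype=int)
    if k != 1:
        labels = fcluster(Z, t=int(k), criterion="maxclust")

    assignments: dict[str, str] = {}
    names: list[str] = []
    for cl in sorted(np.unique(labels)):
        members = [kept[i] for i in range(len(kept)) if labels[i] == cl]
        label = name_cluster(members, preference_table)
        if label in names:  # keep names unique
            label = f"{label}_{names.count(label) + sum(n.startswith(label + '_') for n in names) + 1}"
        names.append(label)
        for m in members:
            assignments[m] = label
    return EcoClusterSet(assignments=assignments, preference_table=preference_table,
                         names=names)


def cluster_relative_abundance(
    table: pd.DataFrame,
    clusters: EcoClusterSet,
) -> pd.DataFrame:
    """Per-site eco-cluster relative abundance: the sum of member phylotype
    relative abundances in each sample. Sites x clusters."""
    out = {}
    for name in clusters.names:
        members = [m for m in clusters.members(name) if m in table.columns]
        out[name] = table[members].sum(axis=1) if members else pd.Series(0.0, index=table.index)
    return pd.DataFrame(out, index=table.index)
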