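"""Warming-scenario projection of eco-cluster abundances and MNC.

Given fitted rule models (environment -> eco-cluster abundance), a trained
CE regressor and two aligned site tables (current and scenario climate,
with soil properties held at current values), the projection recomputes
cluster abundances and MNC under both climates. The per-site change is the
D-value (projected minus current). Per-cluster abundance shifts are tested
with the Mann-Whitney U test run on each eco-cluster separately, and MNC
changes are summarized per grassland class and over the whole grassland.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScenarioDelta",
    "mann_whitney_u",
    "compare_cluster_shift",
    "project_scenario",
    "summarize_by_class",
]

#: sum of sample sizes at or below which the exact (enumeration) p-value is
#: used when there are no ties
EXACT_N_LIMIT = 12


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic of ``x`` (rank-sum with midrank ties) and its
    p-value.

    The p-value is exact (full enumeration) when n1 + n2 <= 12 and the
    pooled sample has no ties; otherwise the normal approximation with tie
    correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_N_LIMIT and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_cluster_shift(
    abund_now: pd.DataFrame,
    abund_future: pd.DataFrame,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-cluster Mann-Whitney U test of current vs projected abundances.

    Returns a frame with columns ``cluster, U, p_value, significant`` (and
    ``p_adjusted`` when Benjamini-Hochberg correction is requested; it is
    off by default, matching a per-cluster testing convention).
    """
    if list(abund_now.columns) != list(abund_future.columns):
        raise ValueError("cluster sets must match between the two tables")
    rows = []
    for cl in abund_now.columns:
        u, p = mann_whitney_u(
            abund_now[cl].to_numpy(), abund_future[cl].to_numpy(),
            alternative=alternative,
        )
        rows.append({"cluster": cl, "U": u, "p_value": p})
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in enumerate(order[::-1]):
            i = m - rank
            prev = min(prev, out["p_value"].iloc[idx] * m / i)
            adj[idx] = prev
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


@dataclass
class ScenarioDelta:
    """Per-site current/projected MNC with D-values and summaries."""

    per_site: pd.DataFrame            # site_id, class, current_mnc, future_mnc, d_value
    class_summary: pd.DataFrame       # per class + grassland: mean/median stats
    shift_tests: pd.DataFrame         # per-cluster Mann-Whitney results
    abund_now: pd.DataFrame = field(default_factory=pd.DataFrame)
    abund_future: pd.DataFrame = field(default_factory=pd.DataFrame)


def _predict_mnc(ce_model, env: pd.DataFrame, cluster_abund: pd.DataFrame,
                 feature_names: list[str]) -> np.ndarray:
    joined = pd.concat(
        [env.reset_index(drop=True), cluster_abund.reset_index(drop=True)], axis=1)
    missing = [f for f in feature_names if f not in joined.columns]
    if missing:
        raise KeyError(f"CE features missing from inputs: {missing}")
    return np.asarray(ce_model.predict(joined[feature_names].to_numpy(dtype=float)))


def project_scenario(
    rule_models: dict[str, "RuleModel"],
    ce_model,
    ce_features: list[str],
    env_now: pd.DataFrame,
    env_future: pd.DataFrame,
    alpha: float = 0.05,
    freeze_climate_insensitive: bool = False,
) -> ScenarioDelta:
    """Project MNC under a perturbed climate.

    Cluster abundances are recomputed from each environment table via the
    fitted rule models and fed, together with the (selected) environmental
    variables, into the CE regressor. Soil columns must be identical between
    the two tables — only climate changes between scenarios.

    With ``freeze_climate_insensitive`` set, clusters whose rule model never
    conditions on MAT/MAP/AI keep their current abundances under the
    scenario (their warming response is negligible by construction).
    """
    if list(env_now["site_id"]) != list(env_future["site_id"]):
        raise ValueError("site sets must match between current and future tables")
    abund_now = pd.DataFrame(index=env_now.index)
    abund_future = pd.DataFrame(index=env_future.index)
    for name, rm in rule_models.items():
        abund_now[name] = rm.predict(env_now)
        if freeze_climate_insensitive and not rm.uses_variables(["MAT", "MAP", "AI"]):
            abund_future[name] = abund_now[name].to_numpy()
        else:
            abund_future[name] = rm.predict(env_future)

    current = _predict_mnc(ce_model, env_now, abund_now, ce_features)
    future = _predict_mnc(ce_model, env_future, abund_future, ce_features)
    per_site = pd.DataFrame(
        {
            "site_id": env_now["site_id"].to_numpy(),
            "grassland_class": env_now["grassland_class"].to_numpy(),
            "current_mnc": current,
            "future_mnc": future,
            "d_value": future - current,
        }
    )
    summary = summarize_by_class(per_site)
    tests = compare_cluster_shift(abund_now, abund_future, alpha=alpha)
    return ScenarioDelta(
        per_site=per_site, class_summary=summary, shift_tests=tests,
        abund_now=abund_now, abund_future=abund_future,
    )


def summarize_by_class(
    per_site: pd.DataFrame,
    classes: tuple[str, ...] = ("steppe", "meadow"),
) -> pd.DataFrame:
    """Mean/median current, projected and D-value statistics per grassland
    class plus the whole-grassland row (union of the classes, so class counts
    add up exactly)."""
    labels = per_site["grassland_class"].to_numpy()
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    rows = []
    groups = [(c, per_site[labels == c]) for c in classes]
    groups.append(("grassland", per_site))
    for name, g in groups:
        rows.append({
            "class": name,
            "n": len(g),
            "mean_current": g["current_mnc"].mean(),
            "median_current": g["current_mnc"].median(),
            "mean_future": g["future_mnc"].mean(),
            "median_future": g["future_mnc"].median(),
            "mean_d": g["d_value"].mean(),
            "median_d": g["d_value"].median(),
        })
    return pd.DataFrame(rows)
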