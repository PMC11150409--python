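"""Warming projection: Mann-Whitney tests, cluster shifts, class summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from necromap import synthetic as S
from necromap.projection import (
    compare_cluster_shift,
    mann_whitney_u,
    project_scenario,
    summarize_by_class,
)
from necromap.rules import fit_abundance_mapper


def brute_force_mw(x, y, alternative="two-sided"):
    """Enumeration oracle: distribution of U over all assignments of the
    pooled sample to group labels (valid without ties)."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in comb]
        gy = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(sum(1 for a in gx for b in gy if a > b))
    us = np.array(us, dtype=float)
    eps = 1e-9
    if alternative == "two-sided":
        p = min(1.0, 2 * min((us <= u_obs + eps).mean(), (us >= u_obs - eps).mean()))
    elif alternative == "less":
        p = (us <= u_obs + eps).mean()
    else:
        p = (us >= u_obs - eps).mean()
    return u_obs, p


class TestMannWhitney:
    def test_small_sample_one_sided_enumeration(self):
        u, p = mann_whitney_u([1, 2], [3, 4], alternative="less")
        assert u == 0
        assert p == pytest.approx(1 / 6)

    def test_identical_samples_two_sided_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0] * 4
        u, p = mann_whitney_u(x, list(x))
        assert p == pytest.approx(1.0, abs=0.05)

    def test_u_statistics_sum_to_n1_n2(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 15, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            ux, _ = mann_whitney_u(x, y)
            uy, _ = mann_whitney_u(y, x)
            assert ux + uy == pytest.approx(n1 * n2)

    def test_exact_p_equals_enumeration_small_samples(self, rng):
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                for alt in ("two-sided", "less", "greater"):
                    u, p = mann_whitney_u(x, y, alternative=alt)
                    u_ref, p_ref = brute_force_mw(x, y, alternative=alt)
                    assert u == pytest.approx(u_ref)
                    assert p == pytest.approx(p_ref, abs=1e-12), (n1, n2, alt)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestClusterShift:
    def test_unchanged_abundances_not_flagged(self, rng):
        ab = pd.DataFrame(rng.uniform(0, 1, (30, 3)), columns=list("abc"))
        out = compare_cluster_shift(ab, ab.copy(), alpha=0.05)
        assert not out["significant"].any()

    def test_alpha_zero_flags_nothing(self, rng):
        now = pd.DataFrame({"a": rng.uniform(0, 1, 30)})
        fut = pd.DataFrame({"a": now["a"] * 3.0})
        out = compare_cluster_shift(now, fut, alpha=0.0)
        assert not out["significant"].any()

    def test_planted_shift_power_and_null_size(self):
        hits, null_flags = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            base = rng.lognormal(-2.0, 0.5, size=(60, 3))
            now = pd.DataFrame(base, columns=["shifted", "null1", "null2"])
            fut = now.copy()
            fut["shifted"] = now["shifted"] * 1.5  # planted +50% shift
            out = compare_cluster_shift(now, fut, alpha=0.05).set_index("cluster")
            hits += bool(out.loc["shifted", "significant"])
            null_flags += int(out.loc[["null1", "null2"], "significant"].sum())
        assert hits >= 0.8 * n_seeds
        # two null clusters per seed: false-positive rate near alpha
        assert null_flags / (2 * n_seeds) <= 0.15

    def test_mismatched_cluster_sets_rejected(self, rng):
        a = pd.DataFrame({"x": rng.uniform(size=5)})
        b = pd.DataFrame({"y": rng.uniform(size=5)})
        with pytest.raises(ValueError):
            compare_cluster_shift(a, b)


class _LinearCE:
    """Deterministic stand-in CE model: weighted sum of its input columns."""

    def __init__(self, weights):
        self.w = np.asarray(weights, dtype=float)

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.w


@pytest.fixture(scope="module")
def fitted_world():
    env = S.generate_environment(60, seed=41)
    table, truth = S.generate_phylotypes(env, 100, seed=42)
    names = truth.cluster_names()
    abund = pd.DataFrame(
        {c: table[truth.members(c)].sum(axis=1) for c in names}).reset_index(drop=True)
    rule_models = {c: fit_abundance_mapper(env, abund, c, seed=43) for c in names}
    ce_features = [*names, "NDVI", "silt"]
    ce_model = _LinearCE([30.0, -6.0, 12.0, 0.05])
    return env, rule_models, ce_model, ce_features, truth


class TestProjectScenario:
    def test_identity_scenario_is_fixed_point(self, fitted_world):
        env, rms, ce, feats, _ = fitted_world
        delta = project_scenario(rms, ce, feats, env, env.copy())
        np.testing.assert_allclose(delta.per_site["d_value"], 0.0, atol=1e-12)
        assert not delta.shift_tests["significant"].any()

    def test_d_value_antisymmetry(self, fitted_world):
        env, rms, ce, feats, _ = fitted_world
        fut = S.scenario_perturb(env, delta_mat=2.2, delta_map_frac=0.06)
        fwd = project_scenario(rms, ce, feats, env, fut)
        # swapping the roles of the two environments negates every D-value
        rev_sites = pd.DataFrame({
            "site_id": env["site_id"],
            "grassland_class": env["grassland_class"],
        })
        rev = project_scenario(rms, ce, feats,
                               fut.assign(grassland_class=env["grassland_class"]),
                               env)
        np.testing.assert_allclose(
            fwd.per_site["d_value"], -rev.per_site["d_value"], atol=1e-9)

    def test_mean_d_sign_matches_planted_warming_effect(self, fitted_world):
        env, rms, ce, feats, truth = fitted_world
        fut = S.scenario_perturb(env, delta_mat=2.2, delta_map_frac=0.06)
        delta = project_scenario(rms, ce, feats, env, fut)
        # planted direction: warming lowers the wet-cold cluster (weight +30)
        # and leaves the elevation cluster unchanged, so MNC must decline
        zshift = {}
        for var in ("MAT", "MAP", "AI"):
            now, then = env[var].to_numpy(), fut[var].to_numpy()
            zshift[var] = (then - now).mean() / now.std()
        planted = 0.0
        coef = S.default_mnc_coefficients(truth.cluster_names())
        for cl, drivers in truth.driver_spec.items():
            resp = sum(eff * sign * zshift.get(var, 0.0) for var, sign, eff in drivers)
            planted += coef[cl] * resp
        assert planted != 0
        assert np.sign(delta.per_site["d_value"].mean()) == np.sign(planted)

    def test_mismatched_sites_rejected(self, fitted_world):
        env, rms, ce, feats, _ = fitted_world
        with pytest.raises(ValueError):
            project_scenario(rms, ce, feats, env, env.iloc[::-1].reset_index(drop=True))


class TestSummaries:
    def _sites(self, classes, d):
        n = len(classes)
        return pd.DataFrame({
            "site_id": [f"S{i}" for i in range(n)],
            "grassland_class": classes,
            "current_mnc": np.full(n, 10.0),
            "future_mnc": 10.0 + np.asarray(d, dtype=float),
            "d_value": np.asarray(d, dtype=float),
        })

    def test_single_class_mean(self):
        out = summarize_by_class(self._sites(["steppe", "steppe"], [2, 4]))
        assert out.set_index("class").loc["steppe", "mean_d"] == pytest.approx(3)

    def test_grassland_is_count_weighted_mean_of_classes(self):
        out = summarize_by_class(
            self._sites(["meadow"] * 3 + ["steppe"] * 2, [1, 2, 3, 10, 20])
        ).set_index("class")
        expect = (3 * out.loc["meadow", "mean_d"] + 2 * out.loc["steppe", "mean_d"]) / 5
        assert out.loc["grassland", "mean_d"] == pytest.approx(expect)
        assert out.loc["grassland", "n"] == out.loc["meadow", "n"] + out.loc["steppe", "n"]

    def test_meadow_specific_effect_shows_in_class_means(self):
        classes = ["meadow"] * 10 + ["steppe"] * 10
        d = [5.0] * 10 + [0.5] * 10  # warming effect planted in the meadow only
        out = summarize_by_class(self._sites(classes, d)).set_index("class")
        assert out.loc["meadow", "mean_d"] > out.loc["steppe", "mean_d"]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_class(self._sites(["desert"], [1.0]))
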