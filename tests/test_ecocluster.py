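"""Dominant-phylotype selection, habitat screening, clustering, naming."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from necromap import synthetic as S
from necromap.ecocluster import (
    cluster_phylotypes,
    cluster_relative_abundance,
    name_cluster,
    screen_habitat_preference,
    select_dominant_phylotypes,
    semi_partial_spearman,
)


def brute_force_dominant(table, top_frac=0.10, occupancy_frac=0.5):
    """Independent two-filter oracle: rank means, take ceil(frac*P), filter
    by strict presence in more than half the samples."""
    means = {p: table[p].mean() for p in table.columns}
    n_top = max(1, math.ceil(top_frac * table.shape[1]))
    ranked = sorted(table.columns, key=lambda p: (-means[p], p))[:n_top]
    out = []
    for p in table.columns:
        present = (table[p] > 0).sum()
        if p in ranked and present > occupancy_frac * len(table):
            out.append(p)
    return out


class TestDominantSelection:
    def test_forced_single_dominant(self):
        data = {"p0": [0.5] * 6}
        for i in range(1, 10):
            data[f"p{i}"] = [0.01] * 6
        table = pd.DataFrame(data)
        assert select_dominant_phylotypes(table) == ["p0"]

    def test_low_occupancy_dominant_excluded(self):
        n = 10
        table = pd.DataFrame({f"p{i}": [0.01] * n for i in range(1, 10)})
        # huge mean but present in only 40% of samples
        table.insert(0, "p0", [0.9] * 4 + [0.0] * 6)
        assert "p0" not in select_dominant_phylotypes(table)

    def test_ubiquitous_table_selects_largest_means(self, rng):
        table = pd.DataFrame(
            rng.uniform(0.001, 0.02, size=(20, 100)),
            columns=[f"p{i:03d}" for i in range(100)],
        )
        got = select_dominant_phylotypes(table)
        top10 = sorted(table.columns, key=lambda p: -table[p].mean())[:10]
        assert sorted(got) == sorted(top10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_dominant_phylotypes(pd.DataFrame())

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(5, 30), rng.integers(10, 200)
        table = pd.DataFrame(
            rng.uniform(0, 1, (n, p)) * (rng.random((n, p)) > 0.3),
            columns=[f"p{i:03d}" for i in range(p)],
        )
        assert select_dominant_phylotypes(table) == brute_force_dominant(table)


class TestHabitatScreen:
    def test_deterministic_mat_responder_is_kept(self):
        env = S.generate_environment(80, seed=31)
        abund = 0.1 + 0.05 * (env["MAT"] - env["MAT"].min()) / np.ptp(env["MAT"])
        table = pd.DataFrame({"resp": abund, "other": 0.01})
        pref = screen_habitat_preference(table, ["resp"], env, seed=31)
        row = pref.iloc[0]
        assert row["variance_explained"] > 30
        assert row["kept"]
        assert row["driver"] == "MAT"
        assert row["direction"] == 1

    def test_constant_phylotype_dropped(self, env80):
        table = pd.DataFrame({"const": [0.05] * len(env80)})
        pref = screen_habitat_preference(table, ["const"], env80, seed=1)
        assert pref.iloc[0]["variance_explained"] == 0.0
        assert not pref.iloc[0]["kept"]

    def test_misaligned_tables_rejected(self, env80):
        table = pd.DataFrame({"p": np.linspace(0, 1, 10)})
        with pytest.raises(ValueError):
            screen_habitat_preference(table, ["p"], env80)


class TestSemiPartialSpearman:
    def test_agrees_with_pingouin(self, env80, rng):
        pingouin = pytest.importorskip("pingouin")
        table = pd.DataFrame(rng.normal(size=(len(env80), 3)),
                             columns=["a", "b", "c"])
        S_mat = semi_partial_spearman(table, env80)
        df = pd.concat(
            [table, env80[["lon", "lat"]].reset_index(drop=True)], axis=1)
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            r_xy = pingouin.partial_corr(
                df, x=x, y=y, y_covar=["lon", "lat"], method="spearman")["r"].iloc[0]
            r_yx = pingouin.partial_corr(
                df, x=y, y=x, y_covar=["lon", "lat"], method="spearman")["r"].iloc[0]
            assert S_mat.loc[x, y] == pytest.approx((r_xy + r_yx) / 2, abs=1e-10)

    def test_unit_diagonal_and_symmetry(self, env80, rng):
        table = pd.DataFrame(rng.normal(size=(len(env80), 4)))
        table.columns = list("wxyz")
        M = semi_partial_spearman(table, env80)
        np.testing.assert_allclose(np.diag(M), 1.0)
        np.testing.assert_allclose(M, M.T)


def _pref(rows):
    return pd.DataFrame(
        rows, columns=["phylotype", "variance_explained", "driver", "direction", "kept"])


class TestClustering:
    def test_perfect_block_structure(self, env80, rng):
        base1 = rng.normal(size=len(env80))
        base2 = rng.normal(size=len(env80))
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = base1 + 0.01 * rng.normal(size=len(env80))
        for i in range(3):
            cols[f"b{i}"] = base2 + 0.01 * rng.normal(size=len(env80))
        table = pd.DataFrame(cols)
        pref = _pref([(c, 50.0, "MAT", 1, True) for c in table.columns])
        cs = cluster_phylotypes(pref, table, env80, k=2)
        truth = [c[0] for c in table.columns]
        inferred = [cs.assignments[c] for c in table.columns]
        assert adjusted_rand_score(truth, inferred) == 1.0

    def test_recovers_planted_clusters(self, landscape):
        env, table, truth = landscape
        dom = select_dominant_phylotypes(table)
        pref = screen_habitat_preference(table, dom, env, seed=4)
        cs = cluster_phylotypes(pref, table, env)
        kept = pref.loc[pref["kept"], "phylotype"].tolist()
        t = [truth.cluster_membership[p] for p in kept]
        i = [cs.assignments[p] for p in kept]
        assert adjusted_rand_score(t, i) >= 0.8

    def test_single_cluster_cut(self, env80, rng):
        table = pd.DataFrame(rng.normal(size=(len(env80), 4)),
                             columns=list("abcd"))
        pref = _pref([(c, 40.0, "MAP", 1, True) for c in table.columns])
        cs = cluster_phylotypes(pref, table, env80, k=1)
        assert len(cs.names) == 1
        assert set(cs.assignments) == set("abcd")

    def test_too_few_phylotypes_rejected(self, env80):
        table = pd.DataFrame({"a": np.linspace(0, 1, len(env80))})
        pref = _pref([("a", 40.0, "MAP", 1, True)])
        with pytest.raises(ValueError):
            cluster_phylotypes(pref, table, env80)


class TestNaming:
    def test_two_part_wet_cold_label(self):
        pref = _pref([
            ("p1", 50.0, "MAP", 1, True),
            ("p2", 45.0, "MAP", 1, True),
            ("p3", 48.0, "MAT", -1, True),
            ("p4", 44.0, "MAT", -1, True),
        ])
        assert name_cluster(["p1", "p2", "p3", "p4"], pref) == "HMAP&LMAT"

    def test_single_preference_elevation_label(self):
        pref = _pref([
            ("p1", 60.0, "elevation", 1, True),
            ("p2", 55.0, "elevation", 1, True),
        ])
        assert name_cluster(["p1", "p2"], pref) == "Hele"

    def test_equal_support_alphabetical_tie_break(self):
        pref = _pref([
            ("p1", 40.0, "TN", 1, True),
            ("p2", 40.0, "SOC", 1, True),
        ])
        # identical counts and variance explained: alphabetical order decides
        assert name_cluster(["p1", "p2"], pref) == "HSOC&HTN"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            name_cluster([], _pref([]))


class TestClusterAbundance:
    def test_additivity(self, env80):
        table = pd.DataFrame({"A": [0.1, 0.0], "B": [0.2, 0.0], "C": [0.3, 0.1]})
        pref = _pref([(c, 40.0, "MAP", 1, True) for c in "ABC"])
        from necromap.ecocluster import EcoClusterSet

        cs = EcoClusterSet(
            assignments={"A": "c1", "B": "c1", "C": "c2"},
            preference_table=pref, names=["c1", "c2"])
        ab = cluster_relative_abundance(table, cs)
        assert ab.loc[0, "c1"] == pytest.approx(0.3)
        # empty sample row gives zero for every cluster
        assert ab.loc[1, "c1"] == pytest.approx(0.0)

    def test_bounded_by_total_abundance(self, landscape):
        env, table, truth = landscape
        dom = select_dominant_phylotypes(table)
        pref = screen_habitat_preference(table, dom, env, seed=4)
        cs = cluster_phylotypes(pref, table, env)
        ab = cluster_relative_abundance(table, cs)
        dominant_total = table[dom].sum(axis=1)
        assert (ab.sum(axis=1) <= dominant_total.to_numpy() + 1e-9).all()
        assert (dominant_total <= 1 + 1e-9).all()
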