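"""Null models: betaMNTD oracle, betaNTI calibration, RC_bray, partition."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import patchassembly as pa
from patchassembly.assembly import (_bray_curtis, _null_assemblage,
                                    classify_pairs)
from patchassembly.simulate import PatchLayout, SimulationParams, \
    simulate_dispersal_limited_dataset, simulate_selection_dataset
from conftest import patch_labels


def bmntd_oracle(a, b, dmat, weighted=True):
    """Brute-force double loop over taxa of both communities."""
    ia = [i for i, v in enumerate(a) if v > 0]
    ib = [j for j, v in enumerate(b) if v > 0]
    ta = sum(a[i] for i in ia)
    tb = sum(b[j] for j in ib)
    acc_a = 0.0
    for i in ia:
        nearest = min(dmat[i][j] for j in ib)
        acc_a += (a[i] / ta if weighted else 1 / len(ia)) * nearest
    acc_b = 0.0
    for j in ib:
        nearest = min(dmat[i][j] for i in ia)
        acc_b += (b[j] / tb if weighted else 1 / len(ib)) * nearest
    return 0.5 * (acc_a + acc_b)


class TestBmntd:
    def test_identical_communities_zero(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        assert pa.bmntd([3, 2], [3, 2], d) == pytest.approx(0.0)

    def test_two_singletons_equal_patristic(self):
        d = np.array([[0, 0.8], [0.8, 0]])
        assert pa.bmntd([1, 0], [0, 1], d) == pytest.approx(0.8)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = 5
            # random symmetric distance matrix with zero diagonal
            m = rng.uniform(0.05, 2.0, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            a = rng.integers(0, 5, n)
            b = rng.integers(0, 5, n)
            if a.sum() == 0 or b.sum() == 0:
                continue
            got = pa.bmntd(a, b, d, abundance_weighted=weighted)
            want = bmntd_oracle(a, b, d, weighted=weighted)
            assert got == pytest.approx(want, abs=1e-12)

    def test_empty_community_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(pa.ValidationError):
            pa.bmntd([0, 0], [1, 1], d)


class TestBntiMatrix:
    def test_symmetric_star_tree_degenerates(self):
        # equal pendant branches: every taxon shuffle leaves distances
        # unchanged, so the null has zero variance and pairs are undefined
        newick = "(" + ",".join(f"T{i}:1.0" for i in range(6)) + ");"
        phylo = pa.Phylogeny.from_newick_string(newick)
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(1, 9, size=(6, 4)),
                          index=[f"T{i}" for i in range(6)],
                          columns=list("WXYZ"))
        out = pa.bnti_matrix(pa.AbundanceTable(df), phylo, n_null=19, seed=1)
        assert out["undefined"].all()
        assert out["bnti"].isna().all()

    def test_matrix_is_symmetric_information(self, neutral_small_metrics):
        # pair (a,b) recorded once; values finite where defined
        m = neutral_small_metrics
        assert m.index.is_unique
        defined = m.loc[~m["undefined"], "bnti"]
        assert np.isfinite(defined).all()

    def test_neutral_data_mostly_stochastic(self, neutral_small_metrics):
        frac = (neutral_small_metrics["bnti"].abs() < 2).mean()
        assert frac >= 0.8

    def test_selection_contrast_between_vs_within(self):
        layout = PatchLayout(areas=(4.0, 592.0), quadrats=(10, 10),
                             env=(-1.5, 1.5))
        ds = simulate_selection_dataset(
            SimulationParams(n_taxa=100, reads_per_sample=1000,
                             regime="selection", selection_sigma=0.3, m=0.3,
                             seed=5), layout)
        met = pa.bnti_matrix(ds.table, ds.phylogeny, n_null=99, seed=7)
        a, b = patch_labels(met)
        between = a != b
        assert met.loc[between, "bnti"].median() > met.loc[~between, "bnti"].median()
        assert met.loc[between, "bnti"].median() > 2
        # within-environment pairs sit below the between-environment ones and
        # below zero: the pool-relative homogeneous-selection signature
        assert met.loc[~between, "bnti"].median() < 0

    def test_reproducible_for_seed(self, neutral_small):
        m1 = pa.bnti_matrix(neutral_small.table, neutral_small.phylogeny,
                            n_null=9, seed=3)
        m2 = pa.bnti_matrix(neutral_small.table, neutral_small.phylogeny,
                            n_null=9, seed=3)
        pd.testing.assert_frame_equal(m1, m2)


class TestRcBray:
    def test_bounds_on_simulated_data(self, neutral_small_metrics):
        rc = neutral_small_metrics["rc_bray"]
        assert (rc >= -1).all() and (rc <= 1).all()

    def test_boundary_values(self):
        # hand-built nulls via the tie rule
        null = np.array([0.5, 0.6, 0.7, 0.8])
        for obs, expected in ((0.4, -1.0), (0.9, 1.0)):
            ties = np.isclose(null, obs)
            below = (null < obs) & ~ties
            rc = 2 * (below.sum() + 0.5 * ties.sum()) / len(null) - 1
            assert rc == expected

    def test_matches_enumerated_seeded_oracle(self):
        """Replay the seeded null draws and apply the tie rule by hand."""
        df = pd.DataFrame({"S1": [6, 3, 1], "S2": [2, 0, 8]},
                          index=["A", "B", "C"])
        table = pa.AbundanceTable(df)
        n_null, seed = 4, 13
        got = pa.rc_bray_matrix(table, n_null=n_null, seed=seed)

        # oracle: identical draw sequence, explicit rank computation
        X = df.to_numpy()
        occ_w = (X > 0).sum(axis=1) / (X > 0).sum()
        ab_w = X.sum(axis=1) / X.sum()
        rng = np.random.default_rng(seed)
        nulls = []
        for j in range(2):
            k = int((X[:, j] > 0).sum())
            total = int(X[:, j].sum())
            reps = [_null_assemblage(k, total, occ_w, ab_w, rng)
                    for _ in range(n_null)]
            nulls.append(reps)
        obs = _bray_curtis(X[:, 0].astype(float), X[:, 1].astype(float))
        null_bc = [_bray_curtis(nulls[0][r].astype(float),
                                nulls[1][r].astype(float))
                   for r in range(n_null)]
        below = sum(1 for v in null_bc
                    if v < obs and not np.isclose(v, obs, atol=1e-12))
        ties = sum(1 for v in null_bc if np.isclose(v, obs, atol=1e-12))
        want = 2 * (below + 0.5 * ties) / n_null - 1
        assert got.loc[("S1", "S2"), "rc_bray"] == pytest.approx(want)

    def test_null_preserves_richness_and_total(self):
        rng = np.random.default_rng(5)
        occ_w = np.full(30, 1 / 30)
        ab_w = rng.dirichlet(np.ones(30))
        out = _null_assemblage(12, 500, occ_w, ab_w, rng)
        assert (out > 0).sum() == 12
        assert out.sum() == 500


class TestPartition:
    def test_all_variable_selection(self):
        metrics = pd.DataFrame(
            {"bnti": [3.0, 4.0, 2.5], "rc_bray": [0.1, 0.99, -0.99]},
            index=pd.MultiIndex.from_tuples(
                [("a", "b"), ("a", "c"), ("b", "c")],
                names=["sample_a", "sample_b"]))
        parts = pa.partition_processes(metrics)
        frac = parts[0].fractions()
        assert frac["variable_selection"] == 1
        assert sum(frac.values()) == 1

    def test_printed_threshold_rule(self):
        """betaNTI = 1 with RC_bray = 0.96 is dispersal limitation."""
        metrics = pd.DataFrame(
            {"bnti": [1.0], "rc_bray": [0.96]},
            index=pd.MultiIndex.from_tuples([("a", "b")],
                                            names=["sample_a", "sample_b"]))
        assert classify_pairs(metrics).iloc[0] == "dispersal_limitation"

    @pytest.mark.parametrize("bnti,rc,expected", [
        (2.5, 0.0, "variable_selection"),
        (-2.5, 0.0, "homogeneous_selection"),
        (0.0, 0.96, "dispersal_limitation"),
        (0.0, -0.96, "homogenizing_dispersal"),
        (0.0, 0.0, "undominated"),
        (2.0, 0.99, "dispersal_limitation"),   # boundary falls to weaker class
        (-2.0, 0.5, "undominated"),
        (1.0, 0.95, "undominated"),            # RC boundary -> undominated
    ])
    def test_boundary_conventions(self, bnti, rc, expected):
        metrics = pd.DataFrame(
            {"bnti": [bnti], "rc_bray": [rc]},
            index=pd.MultiIndex.from_tuples([("a", "b")],
                                            names=["sample_a", "sample_b"]))
        assert classify_pairs(metrics).iloc[0] == expected

    def test_fractions_sum_to_one_exactly_on_random_inputs(self):
        rng = np.random.default_rng(17)
        pairs = list(combinations([f"s{i}" for i in range(12)], 2))
        metrics = pd.DataFrame(
            {"bnti": rng.normal(0, 3, len(pairs)),
             "rc_bray": rng.uniform(-1, 1, len(pairs))},
            index=pd.MultiIndex.from_tuples(pairs,
                                            names=["sample_a", "sample_b"]))
        for part in pa.partition_processes(metrics):
            assert sum(part.fractions().values()) == Fraction(1)
            roll = part.rollup()
            assert roll["deterministic"] + roll["stochastic"] == Fraction(1)

    def test_undefined_pairs_excluded_and_counted(self):
        metrics = pd.DataFrame(
            {"bnti": [3.0, np.nan], "rc_bray": [0.0, 0.5]},
            index=pd.MultiIndex.from_tuples([("a", "b"), ("a", "c")],
                                            names=["sample_a", "sample_b"]))
        part = pa.partition_processes(metrics)[0]
        assert part.n_pairs == 1
        assert part.n_undefined == 1
        assert part.fractions()["variable_selection"] == 1

    def test_patch_groupings(self, neutral_small_metrics, neutral_small):
        parts = pa.partition_processes(neutral_small_metrics,
                                       neutral_small.metadata)
        names = {p.group for p in parts}
        assert "all" in names and "between_patch" in names
        assert any(n.startswith("within:") for n in names)


class TestRegimeContrasts:
    def test_dispersal_limited_exceeds_neutral_dl_fraction(
            self, neutral_small_metrics):
        layout = PatchLayout(areas=(4.0, 592.0), quadrats=(10, 10))
        ds = simulate_dispersal_limited_dataset(
            SimulationParams(n_taxa=100, reads_per_sample=1000, m=0.1,
                             regime="dispersal_limited", divergence=0.6,
                             seed=5), layout)
        met = pa.assembly_metrics(ds.table, ds.phylogeny, n_null=99, seed=7)
        a, b = patch_labels(met)
        between = a != b

        def dl_fraction(metrics, mask):
            sub = metrics[mask]
            return ((sub["bnti"].abs() < 2) & (sub["rc_bray"] > 0.95)).mean()

        an, bn = patch_labels(neutral_small_metrics)
        assert dl_fraction(met, between) > dl_fraction(
            neutral_small_metrics, an != bn)
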