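"""Synthetic-community generator: layouts, trees, regimes, ground truth."""

import numpy as np
import pandas as pd
import pytest

import patchassembly as pa
from patchassembly.simulate import (DEFAULT_AREAS, DEFAULT_QUADRATS,
                                    bacteria_like_params, fungi_like_params)


class TestPatchLayout:
    def test_default_mirrors_study_scale(self):
        layout = pa.PatchLayout()
        assert layout.n_patches == 6
        assert layout.n_samples == 51
        assert min(layout.areas) == 4.0 and max(layout.areas) == 592.0
        assert min(layout.quadrats) >= 3 and max(layout.quadrats) <= 15

    def test_validation(self):
        with pytest.raises(pa.ValidationError):
            pa.PatchLayout(areas=(4.0, 4.0), quadrats=(3, 3))
        with pytest.raises(pa.ValidationError):
            pa.PatchLayout(areas=(4.0, 9.0), quadrats=(0, 3))
        with pytest.raises(pa.ValidationError):
            pa.PatchLayout(areas=(4.0, -9.0), quadrats=(3, 3))


class TestSimulateTree:
    def test_two_taxa_cherry(self):
        phylo = pa.simulate_tree(2, seed=1)
        assert phylo.n_tips == 2
        labels, d = phylo.patristic_matrix()
        tips = list(phylo.tree.tips())
        assert d[0, 1] == pytest.approx(tips[0].length + tips[1].length)

    def test_seed_reproducibility(self):
        import io
        t1, t2 = pa.simulate_tree(20, seed=9), pa.simulate_tree(20, seed=9)
        s1, s2 = io.StringIO(), io.StringIO()
        t1.tree.write(s1, format="newick")
        t2.tree.write(s2, format="newick")
        assert s1.getvalue() == s2.getvalue()

    def test_hundred_tips_nonnegative_distances(self):
        phylo = pa.simulate_tree(100, seed=2)
        assert phylo.n_tips == 100
        _, d = phylo.patristic_matrix()
        assert (d >= 0).all()
        assert np.allclose(d, d.T)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(pa.ValidationError):
            pa.simulate_tree(1, seed=0)


class TestNeutralRegime:
    def test_dataset_is_valid_and_consistent(self, neutral_small):
        table, phylo, meta = (neutral_small.table, neutral_small.phylogeny,
                              neutral_small.metadata)
        assert sorted(phylo.tip_names) == sorted(table.taxon_ids)
        assert set(table.sample_ids) <= set(meta.sample_ids)
        assert (table.sample_sums() == 1000).all()
        assert neutral_small.truth["regime"] == "neutral"
        assert neutral_small.truth["m"] == 0.1

    def test_high_migration_reduces_beta_diversity(self):
        layout = pa.PatchLayout(areas=(4.0, 592.0), quadrats=(8, 8))
        bc_means = {}
        for m in (0.01, 0.99):
            ds = pa.simulate_neutral_dataset(
                pa.SimulationParams(n_taxa=100, reads_per_sample=1000, m=m,
                                    regime="neutral", seed=21), layout)
            bc = pa.bray_curtis_matrix(ds.table).to_numpy()
            bc_means[m] = bc[np.triu_indices(16, 1)].mean()
        assert bc_means[0.99] < bc_means[0.01]

    def test_single_taxon_metacommunity_degenerate(self):
        # one dominant taxon: force via 2-taxon tree and near-degenerate SAD
        layout = pa.PatchLayout(areas=(4.0, 9.0), quadrats=(2, 2))
        ds = pa.simulate_neutral_dataset(
            pa.SimulationParams(n_taxa=2, reads_per_sample=50, m=1.0,
                                regime="neutral", seed=0), layout)
        assert ds.table.n_taxa <= 2

    def test_regime_mismatch_rejected(self):
        with pytest.raises(pa.ValidationError):
            pa.simulate_neutral_dataset(
                pa.SimulationParams(regime="selection"))


class TestSelectionRegime:
    def test_truth_records_env_and_optima(self):
        ds = pa.simulate_selection_dataset(
            pa.SimulationParams(regime="selection", n_taxa=50,
                                reads_per_sample=500, seed=3))
        assert ds.truth["regime"] == "selection"
        assert len(ds.truth["env"]) == 6
        # environment declines with patch area
        env = [ds.truth["env"][p] for p in ("P1", "P2", "P3", "P4", "P5", "P6")]
        assert all(a >= b for a, b in zip(env, env[1:]))

    def test_wide_niche_approaches_neutral(self):
        """sigma -> infinity removes the filter: per-sample expected
        composition equals the metacommunity."""
        layout = pa.PatchLayout(areas=(4.0, 592.0), quadrats=(12, 12))
        ds = pa.simulate_selection_dataset(
            pa.SimulationParams(regime="selection", n_taxa=100,
                                reads_per_sample=4000, m=0.9,
                                selection_sigma=1e6, seed=3), layout)
        patch = ds.metadata.patch_of().reindex(ds.table.sample_ids)
        rel = ds.table.relative_abundance()
        mean_small = rel.loc[:, np.asarray(patch == "P1")].mean(axis=1)
        mean_large = rel.loc[:, np.asarray(patch == "P2")].mean(axis=1)
        # no systematic compositional difference between patches
        assert np.abs(mean_small - mean_large).sum() < 0.35

    def test_alpha_diversity_declines_with_area(self):
        ds = pa.simulate_selection_dataset(bacteria_like_params(42))
        alpha = pa.alpha_diversity_table(ds.table)
        fit = pa.sar_regression(
            ds.metadata.df["area_m2"].reindex(alpha.index),
            alpha["shannon"], "shannon")
        assert fit.slope < 0
        assert fit.pvalue < 0.01

    def test_invalid_sigma_rejected(self):
        with pytest.raises(pa.ValidationError):
            pa.SimulationParams(regime="selection", selection_sigma=0.0)


class TestDispersalRegime:
    def test_zero_divergence_collapses_to_neutral(self):
        layout = pa.PatchLayout(areas=(4.0, 592.0), quadrats=(6, 6))
        kw = dict(n_taxa=80, reads_per_sample=800, m=0.2, seed=14)
        ds_d = pa.simulate_dispersal_limited_dataset(
            pa.SimulationParams(regime="dispersal_limited", divergence=0.0, **kw),
            layout)
        # patch pools equal the metacommunity when divergence is zero
        assert ds_d.truth["patch_scale"] == {"P1": 0.0, "P2": 0.0}

    def test_beta_diversity_rises_with_area(self):
        ds = pa.simulate_dispersal_limited_dataset(fungi_like_params(42))
        beta = pa.within_patch_beta(ds.table, ds.metadata)
        fit = pa.sar_regression(
            ds.metadata.area_of_patch().reindex(beta.index), beta, "beta")
        assert fit.slope > 0
        assert fit.pvalue < 0.05

    def test_divergence_raises_between_patch_distance(self):
        layout = pa.PatchLayout(areas=(4.0, 592.0), quadrats=(8, 8))
        means = {}
        for div in (0.0, 0.9):
            ds = pa.simulate_dispersal_limited_dataset(
                pa.SimulationParams(regime="dispersal_limited", n_taxa=100,
                                    reads_per_sample=1000, m=0.3,
                                    divergence=div, seed=9), layout)
            bc = pa.bray_curtis_matrix(ds.table)
            patch = ds.metadata.patch_of().reindex(ds.table.sample_ids)
            across = bc.loc[np.asarray(patch == "P1"),
                            np.asarray(patch == "P2")].to_numpy()
            means[div] = across.mean()
        assert means[0.9] > means[0.0]

    def test_fixed_seed_reproducible(self):
        kw = pa.SimulationParams(regime="dispersal_limited", n_taxa=50,
                                 reads_per_sample=400, seed=6)
        d1 = pa.simulate_dispersal_limited_dataset(kw)
        d2 = pa.simulate_dispersal_limited_dataset(kw)
        assert d1.table == d2.table


class TestWriteRoundTrip:
    def test_written_triple_reloads(self, tmp_path, neutral_small):
        paths = neutral_small.write(tmp_path / "out")
        table, phylo, meta = pa.read_dataset(
            paths["counts"], paths["tree"], paths["metadata"])
        assert table == neutral_small.table
        assert sorted(phylo.tip_names) == sorted(neutral_small.table.taxon_ids)

    def test_generated_tables_pass_validation(self, neutral_small):
        # constructing AbundanceTable re-runs all invariant checks
        pa.AbundanceTable(neutral_small.table.counts)
        pa.SampleMetadata(neutral_small.metadata.df)
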