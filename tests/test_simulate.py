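"""Tests of the ground-truth study simulator."""

import numpy as np
import pandas as pd
import pytest

from aarspatial.errors import ConfigurationError
from aarspatial.simulate import (
    SimConfig,
    make_region_layout,
    plant_effects,
    sample_counts,
    simulate_study,
)


class TestRegionLayout:
    def test_partition_and_compartments(self):
        ann = make_region_layout(20, 20)
        t = ann.table
        assert len(t) == 400
        assert not t.duplicated(["array_row", "array_col"]).any()
        somatic = t[t.region == "somatic"]
        dendritic = t[t.region == "dendritic"]
        assert len(somatic) > 0 and len(dendritic) > 0
        assert {"cortex_band_1", "cortex_band_2", "background"} <= set(t.region)

    def test_thin_arc_somatic_embedded_in_dendritic(self):
        """Every somatic spot of a 1-cell arc touches dendritic tissue."""
        ann = make_region_layout(8, 8, "thin_arc")
        lut = {
            (r, c): reg
            for r, c, reg in ann.table[["array_row", "array_col", "region"]].itertuples(
                index=False
            )
        }
        somatic = [k for k, v in lut.items() if v == "somatic"]
        assert somatic
        for r, c in somatic:
            neighbours = {
                lut.get((r + dr, c + dc))
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            }
            assert "dendritic" in neighbours

    def test_unknown_layout_errors(self):
        with pytest.raises(ConfigurationError, match="nonexistent"):
            make_region_layout(20, 20, "nonexistent")

    def test_too_small_grid_errors(self):
        with pytest.raises(ConfigurationError):
            make_region_layout(4, 4)


class TestPlantEffects:
    @pytest.fixture()
    def tiny(self):
        config = SimConfig(
            n_genes=3,
            grid_rows=8,
            grid_cols=8,
            n_aar_genes=1,
            n_marker_genes_per_region=0,
            mito_fraction=0.0,
            n_bad_spots=0,
        )
        spots = pd.DataFrame(
            {
                "array_row": [0, 0, 1],
                "array_col": [0, 1, 0],
                "region": ["dendritic", "somatic", "dendritic"],
            }
        )
        genes = pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "role": ["aar", "background", "aar"],
                "region": ["dendritic", "", "somatic"],
            }
        )
        from aarspatial.simulate import TruthTable

        return config, TruthTable(genes=genes, spots=spots)

    def test_aar_multiplier_chain(self, tiny):
        config, truth = tiny
        means = plant_effects(np.array([10.0, 10.0, 10.0]), truth, config)
        # dendritic spot, AAR gene targeted at dendritic
        got = [means[c][0, 0] for c in config.conditions]
        assert got == pytest.approx([10.0, 15.0, 7.5, 13.5])

    def test_background_gene_flat(self, tiny):
        config, truth = tiny
        means = plant_effects(np.array([10.0, 4.0, 10.0]), truth, config)
        assert [means[c][0, 1] for c in config.conditions] == pytest.approx([4.0] * 4)

    def test_aar_gene_outside_target_region_flat(self, tiny):
        config, truth = tiny
        means = plant_effects(np.array([10.0, 10.0, 6.0]), truth, config)
        # gC targets somatic; in the dendritic spot it stays flat
        assert [means[c][0, 2] for c in config.conditions] == pytest.approx([6.0] * 4)
        # and follows the chain in the somatic spot
        assert [means[c][1, 2] for c in config.conditions] == pytest.approx(
            [6.0, 9.0, 4.5, 8.1]
        )


class TestSampleCounts:
    def test_zero_mean_gives_zero_counts(self):
        counts = sample_counts(np.zeros((5, 4)), 2.0, np.ones(5), seed=1)
        assert counts.shape == (5, 4)
        assert not counts.any()

    def test_poisson_limit(self):
        """theta -> inf recovers Poisson: variance ~= mean."""
        counts = sample_counts(
            np.full((10_000, 1), 5.0), 1e9, np.ones(10_000), seed=2
        ).ravel()
        assert counts.mean() == pytest.approx(5.0, rel=0.05)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_nb_moments(self):
        """mean mu, variance mu + mu^2/theta at mu=5, theta=2."""
        counts = sample_counts(
            np.full((10_000, 1), 5.0), 2.0, np.ones(10_000), seed=3
        ).ravel()
        assert counts.mean() == pytest.approx(5.0, rel=0.1)
        assert counts.var() == pytest.approx(17.5, rel=0.1)

    def test_depth_scales_mean(self):
        counts = sample_counts(
            np.full((20_000, 1), 5.0), 2.0, np.full(20_000, 2.0), seed=4
        ).ravel()
        assert counts.mean() == pytest.approx(10.0, rel=0.05)

    def test_invalid_parameters(self):
        with pytest.raises(ConfigurationError):
            sample_counts(np.ones((2, 2)), 0.0, np.ones(2), seed=0)
        with pytest.raises(ConfigurationError):
            sample_counts(np.ones((2, 2)), 1.0, np.array([1.0, -1.0]), seed=0)


class TestSimulateStudy:
    def test_same_seed_identical(self):
        kw = dict(n_genes=120, grid_rows=10, grid_cols=10, n_aar_genes=5,
                  n_marker_genes_per_region=2, mito_fraction=0.02, n_bad_spots=4)
        a = simulate_study(seed=7, **kw)
        b = simulate_study(seed=7, **kw)
        for cond in a.samples:
            assert (a.samples[cond].counts != b.samples[cond].counts).nnz == 0
            assert a.samples[cond].barcodes == b.samples[cond].barcodes
        pd.testing.assert_frame_equal(a.truth.genes, b.truth.genes)
        pd.testing.assert_frame_equal(a.truth.spots, b.truth.spots)

    def test_truth_bookkeeping(self, small_bundle):
        cfg = small_bundle.config
        assert len(small_bundle.truth.aar_gene_ids) == cfg.n_aar_genes
        roles = small_bundle.truth.genes["role"].value_counts()
        assert roles["mito"] == cfg.n_mito_genes
        assert roles["marker"] == cfg.n_marker_genes_per_region * 5

    def test_samples_share_genes_and_spot_counts(self, small_bundle):
        genes = {tuple(s.gene_ids) for s in small_bundle}
        assert len(genes) == 1
        n_spots = {s.n_spots for s in small_bundle}
        assert len(n_spots) == 1

    def test_bad_spots_fail_qc_rules(self, small_bundle):
        """Planted bad spots violate the QC gates they were built for."""
        truth = small_bundle.truth.spots
        sample = small_bundle.samples["4WT"]
        counts = np.asarray(sample.counts.todense())
        mito = np.array([g.startswith("mt-") for g in sample.gene_ids])
        genes_per_spot = (counts > 0).sum(axis=1)
        mito_share = counts[:, mito].sum(axis=1) / counts.sum(axis=1)
        low = truth["bad"].to_numpy() == "low_genes"
        high = truth["bad"].to_numpy() == "high_mito"
        assert (genes_per_spot[low] < 200).all()
        assert (mito_share[high] > 0.30).all()

    def test_expressed_genes_exceed_qc_floor(self, default_bundle):
        truth = default_bundle.truth.spots
        good = truth["bad"].to_numpy() == ""
        for sample in default_bundle:
            counts = sample.counts
            genes_per_spot = np.asarray((counts > 0).sum(axis=1)).ravel()
            assert genes_per_spot[good].mean() > 200

    def test_planted_effect_ordering_in_target_region(self, default_bundle):
        """Group means of planted genes in the target region follow
        up (aging), down (AD), up (rescue)."""
        truth = default_bundle.truth
        region = default_bundle.config.aar_region
        in_region = (truth.spots["region"] == region).to_numpy()
        gene_idx = truth.genes.index[truth.genes["role"] == "aar"].to_numpy()
        means = {}
        for cond, sample in default_bundle.samples.items():
            sub = np.asarray(sample.counts[in_region][:, gene_idx].todense())
            means[cond] = sub.mean(axis=0)
        assert (means["24WT"] > means["4WT"]).all()
        assert (means["24AD"] < means["24WT"]).all()
        assert (means["24SL"] > means["24AD"]).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(alpha=0.9)
        with pytest.raises(ConfigurationError):
            SimConfig(delta=1.5)
        with pytest.raises(ConfigurationError):
            SimConfig(nb_dispersion=-1.0)
        with pytest.raises(ConfigurationError):
            SimConfig(conditions=("WT", "AD", "SL", "X"))
        with pytest.raises(ConfigurationError):
            SimConfig(n_genes=40, n_aar_genes=30, n_marker_genes_per_region=10)
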