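"""Tests of over-representation analysis and pathway-level AAR
classification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from aarspatial.datatypes import GeneSetCollection
from aarspatial.errors import DegenerateDataWarning, ValidationError
from aarspatial.pathways import (
    PathwayActivityModel,
    classify_aar_pathways,
    diff_pathway,
    enrich_gene_sets,
    ora_test,
    sample_scores,
    score_matrix,
)


def brute_force_hypergeom_tail(N, K, n, k):
    """P(X >= k) by enumerating all n-subsets of an N-universe."""
    universe = list(range(N))
    pathway = set(range(K))
    hits = total = 0
    for combo in itertools.combinations(universe, n):
        total += 1
        if len(pathway & set(combo)) >= k:
            hits += 1
    return hits / total


class TestORA:
    def test_perfect_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        pathway = universe[:5]
        k, p = ora_test(pathway, pathway, universe)
        assert k == 5
        assert p == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        k, p = ora_test(universe[5:7], universe[:5], universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_complement_enumeration(self):
        universe = [f"g{i}" for i in range(10)]
        k, p = ora_test([universe[0], universe[9]], universe[:5], universe)
        # overlap 1: P(X >= 1) = 1 - C(5,2)/C(10,2) = 7/9
        assert k == 1
        assert p == pytest.approx(7 / 9)

    def test_matches_enumeration_small_universes(self, rng):
        for _ in range(25):
            N = int(rng.integers(4, 15))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            selected = list(rng.choice(universe, size=n, replace=False))
            k, p = ora_test(selected, universe[:K], universe)
            assert p == pytest.approx(brute_force_hypergeom_tail(N, K, n, k))

    def test_empty_universe_errors(self):
        with pytest.raises(ValidationError):
            ora_test(["a"], ["a"], [])

    def test_enrichment_wrapper_sorted_with_q(self):
        universe = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection(
            sets={"hit": frozenset(universe[:5]), "miss": frozenset(universe[25:])}
        )
        tbl = enrich_gene_sets(universe[:5], coll, universe)
        assert tbl.iloc[0]["set"] == "hit"
        assert (tbl["q"] >= tbl["p"] - 1e-15).all()


class TestSampleScores:
    def test_all_genes_pathway_scores_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 7)), columns=list("abcdefg"))
        assert sample_scores(X, set("abcdefg")) == pytest.approx(np.zeros(4))

    def test_top_expressed_pair(self):
        X = pd.DataFrame(
            np.arange(10, dtype=float)[None, :], columns=[f"g{j}" for j in range(10)]
        )
        s = sample_scores(X, {"g8", "g9"})  # ranks 9 and 10
        assert s[0] == pytest.approx(9.5 / 11 - 0.5)

    def test_tied_spot_scores_zero(self):
        X = pd.DataFrame(np.ones((2, 6)), columns=[f"g{j}" for j in range(6)])
        assert sample_scores(X, {"g0", "g3"}) == pytest.approx(np.zeros(2))

    def test_monotone_transform_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 12)),
                         columns=[f"g{j}" for j in range(12)])
        pathway = {"g1", "g5", "g9"}
        base = sample_scores(X, pathway)
        assert sample_scores(np.exp(X) * 3 + 1, pathway) == pytest.approx(base)

    def test_bounds(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 20)),
                         columns=[f"g{j}" for j in range(20)])
        s = sample_scores(X, {"g0"})
        assert (s > -0.5).all() and (s < 0.5).all()

    def test_disjoint_pathway_skipped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        with pytest.warns(DegenerateDataWarning):
            assert sample_scores(X, {"zz"}) is None


class TestDiffPathway:
    def test_identical_scores_no_signal(self):
        t, p, _, passes = diff_pathway([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == pytest.approx(0.0) and not passes

    def test_hand_welch_example(self):
        t, p, direction, passes = diff_pathway([0.0, 0.1, 0.2], [1.0, 1.1, 1.2])
        assert abs(t) == pytest.approx(12.247, abs=1e-3)
        assert p == pytest.approx(2.6e-4, rel=0.05)
        assert direction == "up" and passes

    def test_t_gate_required_even_with_small_p(self):
        # significance alone is not enough: |t| must clear the gate too
        t, p, _, passes = diff_pathway(
            [0.0, 0.1, 0.2], [1.0, 1.1, 1.2], t_min=20.0
        )
        assert p < 0.05 and abs(t) < 20.0
        assert not passes


class TestClassifyAARPathways:
    def groups(self, n=30):
        return np.repeat(["4WT", "24WT", "24AD", "24SL"], n)

    def scores_with_pattern(self, deltas, n=30, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        return np.concatenate(
            [rng.normal(d, noise, n) for d in deltas]
        )

    def test_aar_pattern_flagged(self):
        s = self.scores_with_pattern([0.0, 0.2, -0.1, 0.15])
        scores = pd.DataFrame({"pw": s})
        res = classify_aar_pathways(scores, self.groups())
        assert res.table.loc["pw", "is_aar"]

    def test_monotone_pattern_rejected(self):
        s = self.scores_with_pattern([0.0, 0.1, 0.2, 0.3])  # up, up, up
        res = classify_aar_pathways(pd.DataFrame({"pw": s}), self.groups())
        row = res.table.loc["pw"]
        assert row[["passes_aging", "passes_AD", "passes_rescue"]].all()
        assert not row["is_aar"]

    def test_missing_group_errors(self):
        scores = pd.DataFrame({"pw": np.zeros(20)})
        groups = np.repeat(["4WT", "24WT"], 10)
        with pytest.raises(ValidationError):
            classify_aar_pathways(scores, groups)

    def test_tighter_gates_shrink_flag_set(self):
        rng = np.random.default_rng(1)
        cols = {
            f"pw{i}": self.scores_with_pattern(
                [0.0, rng.uniform(0.01, 0.2), -0.05, 0.1], seed=i
            )
            for i in range(8)
        }
        res = classify_aar_pathways(pd.DataFrame(cols), self.groups())
        tighter = res.at_gates(t_min=5.0)
        assert set(tighter.aar_pathways) <= set(res.aar_pathways)

    def test_planted_pathway_recovered_on_synthetic_study(
        self, default_bundle, default_fit
    ):
        model, _ = default_fit
        planted = default_bundle.truth.aar_gene_ids
        mask = model.regions == "dendritic"
        coll = GeneSetCollection(sets={"planted": frozenset(planted)})
        pres = PathwayActivityModel(
            model.expression.loc[mask], coll, model.groups[mask]
        ).fit()
        assert pres.table.loc["planted", "is_aar"]
        assert "planted" in pres.summary()

    def test_background_pathway_not_flagged(self, default_bundle, default_fit):
        model, _ = default_fit
        rng = np.random.default_rng(5)
        background = default_bundle.truth.genes.query("role == 'background'")[
            "gene_id"
        ].tolist()
        mask = model.regions == "dendritic"
        sets = {
            f"rand{i}": frozenset(rng.choice(background, size=50, replace=False))
            for i in range(5)
        }
        pres = PathwayActivityModel(
            model.expression.loc[mask], GeneSetCollection(sets=sets), model.groups[mask]
        ).fit()
        assert not pres.table["is_aar"].any()
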