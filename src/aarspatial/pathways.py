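"""Gene-set over-representation and pathway-level AAR classification.

Over-representation of a selected gene list in a pathway is tested with
the hypergeometric upper tail against the measured gene universe.
Pathway activity is summarized per spot by a rank-based single-sample
score: the mean rank of the pathway's genes within the spot's expression
profile, centered and scaled to (-0.5, 0.5). Group differences of the
scores are tested with Welch's t using the gates p < 0.05 and |t| > 2; a
pathway whose three ordered contrasts pass the gates with directions
(up, down, up) is an AAR pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import GeneSetCollection
from .errors import DegenerateDataWarning, ValidationError
from .stats import bh_fdr, welch_t
from .aar import Comparison, DEFAULT_COMPARISONS

__all__ = [
    "ora_test",
    "enrich_gene_sets",
    "sample_scores",
    "score_matrix",
    "diff_pathway",
    "classify_aar_pathways",
    "PathwayActivityModel",
    "PathwayAARResults",
]


def ora_test(selected, pathway, universe) -> tuple[int, float]:
    """Hypergeometric over-representation test.

    Both gene lists are intersected with ``universe`` first; returns the
    overlap size k and P(X >= k) for X ~ Hypergeom(N=|universe|,
    K=|pathway|, n=|selected|).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("ora_test requires a non-empty universe")
    pathway = set(pathway) & universe
    selected = set(selected) & universe
    k = len(selected & pathway)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(pathway), len(selected)))
    return k, min(p, 1.0)


def enrich_gene_sets(
    selected, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """ORA across a collection, BH-corrected; sorted by p ascending."""
    rows = []
    for name, members in collection.items():
        k, p = ora_test(selected, members, universe)
        rows.append((name, len(set(members) & set(universe)), k, p))
    tbl = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    tbl["q"] = bh_fdr(tbl["p"].to_numpy())
    return tbl.sort_values(["p", "set"]).reset_index(drop=True)


def sample_scores(X: pd.DataFrame, pathway) -> np.ndarray | None:
    """Per-spot rank-based activity score of one gene set.

    Genes are ranked ascending within each spot (average ranks for
    ties); the score is ``meanRank(pathway genes) / (G + 1) - 0.5``,
    bounded in (-0.5, 0.5) and 0-centered under exchangeability. Returns
    None (with a warning) when the pathway does not intersect the
    measured genes.
    """
    cols = [g for g in X.columns if g in set(pathway)]
    if not cols:
        warnings.warn(
            "pathway has no overlap with measured genes; skipped",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return None
    ranks = sps.rankdata(X.to_numpy(dtype=float), axis=1)
    idx = [X.columns.get_loc(c) for c in cols]
    g = X.shape[1]
    return ranks[:, idx].mean(axis=1) / (g + 1) - 0.5


def score_matrix(X: pd.DataFrame, collection: GeneSetCollection) -> pd.DataFrame:
    """Spots x pathways score matrix (pathways without overlap dropped)."""
    ranks = sps.rankdata(X.to_numpy(dtype=float), axis=1)
    g = X.shape[1]
    col_of = {c: i for i, c in enumerate(X.columns)}
    out = {}
    for name, members in collection.items():
        idx = [col_of[m] for m in members if m in col_of]
        if not idx:
            warnings.warn(
                f"pathway {name!r} has no overlap with measured genes; skipped",
                DegenerateDataWarning,
                stacklevel=2,
            )
            continue
        out[name] = ranks[:, idx].mean(axis=1) / (g + 1) - 0.5
    return pd.DataFrame(out, index=X.index)


def diff_pathway(
    scores_from, scores_to, p_max: float = 0.05, t_min: float = 2.0
) -> tuple[float, float, str, bool]:
    """Welch's t on activity scores for one ordered contrast.

    Returns ``(t, p, direction, passes)`` with ``t`` oriented "to minus
    from"; the contrast passes when p < p_max and |t| > t_min. The
    magnitude gate uses |t| so that downward contrasts can pass; the
    direction itself feeds the pattern check.
    """
    t, p = welch_t(scores_from, scores_to)
    direction = "up" if t > 0 else "down"
    passes = bool(p < p_max and abs(t) > t_min)
    return t, p, direction, passes


@dataclass
class PathwayAARResults:
    """Per-pathway contrast statistics and AAR flags."""

    table: pd.DataFrame  # index pathway; per-contrast t/p/direction/passes, is_aar
    scores: pd.DataFrame
    groups: np.ndarray
    comparisons: tuple[Comparison, ...]
    p_max: float
    t_min: float

    @property
    def aar_pathways(self) -> list[str]:
        return self.table.index[self.table["is_aar"]].tolist()

    def at_gates(self, p_max: float | None = None, t_min: float | None = None):
        """Re-gate the fitted statistics; tighter gates only shrink the
        AAR pathway set."""
        p_max = self.p_max if p_max is None else p_max
        t_min = self.t_min if t_min is None else t_min
        tbl = self.table.copy()
        all_pass = np.ones(len(tbl), dtype=bool)
        pattern = np.ones(len(tbl), dtype=bool)
        for cmp, want in zip(self.comparisons, ("up", "down", "up")):
            ok = (tbl[f"p_{cmp.label}"] < p_max) & (
                tbl[f"t_{cmp.label}"].abs() > t_min
            )
            tbl[f"passes_{cmp.label}"] = ok
            all_pass &= ok
            pattern &= tbl[f"dir_{cmp.label}"] == want
        tbl["is_aar"] = all_pass & pattern
        return PathwayAARResults(
            table=tbl,
            scores=self.scores,
            groups=self.groups,
            comparisons=self.comparisons,
            p_max=p_max,
            t_min=t_min,
        )

    def summary(self) -> str:
        lines = [
            "Pathway AAR analysis",
            "====================",
            f"pathways scored: {self.table.shape[0]}   "
            f"gates: p < {self.p_max:g} and |t| > {self.t_min:g}",
            f"AAR pathways: {len(self.aar_pathways)}",
        ]
        for name in self.aar_pathways:
            row = self.table.loc[name]
            trip = ", ".join(
                f"{c.label}: t={row[f't_{c.label}']:.2f}" for c in self.comparisons
            )
            lines.append(f"  {name}  ({trip})")
        return "\n".join(lines)

    def plot_scores(self, pathway: str, ax=None):
        """Condition-wise box plot of one pathway's activity scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        order = []
        for cmp in self.comparisons:
            for g in (cmp.group_from, cmp.group_to):
                if g not in order:
                    order.append(g)
        data = [self.scores.loc[self.groups == g, pathway] for g in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel("activity score")
        ax.set_title(pathway, fontsize=9)
        return ax


class PathwayActivityModel:
    """Single-sample pathway activity with AAR-pattern classification.

    ``expression`` is the normalized spots x genes matrix (optionally
    already restricted to one region); ``groups`` the per-spot condition
    labels.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        collection: GeneSetCollection,
        groups,
        comparisons: tuple[Comparison, ...] = DEFAULT_COMPARISONS,
        p_max: float = 0.05,
        t_min: float = 2.0,
    ) -> None:
        self.expression = expression
        self.collection = collection
        self.groups = np.asarray(groups)
        if len(self.groups) != expression.shape[0]:
            raise ValidationError("groups must align with expression rows")
        self.comparisons = tuple(comparisons)
        self.p_max = float(p_max)
        self.t_min = float(t_min)

    def fit(self) -> PathwayAARResults:
        scores = score_matrix(self.expression, self.collection)
        return classify_aar_pathways(
            scores, self.groups, self.comparisons, self.p_max, self.t_min
        )


def classify_aar_pathways(
    scores: pd.DataFrame,
    groups,
    comparisons: tuple[Comparison, ...] = DEFAULT_COMPARISONS,
    p_max: float = 0.05,
    t_min: float = 2.0,
) -> PathwayAARResults:
    """Classify pre-computed activity scores (spots x pathways)."""
    groups = np.asarray(groups)
    needed = {g for c in comparisons for g in (c.group_from, c.group_to)}
    missing = needed - set(np.unique(groups))
    if missing:
        raise ValidationError(f"missing condition groups: {sorted(missing)}")
    rows = {}
    for name in scores.columns:
        s = scores[name]
        rec: dict[str, object] = {}
        all_pass, pattern_ok = True, True
        for cmp, want in zip(comparisons, ("up", "down", "up")):
            t, p, direction, passes = diff_pathway(
                s[groups == cmp.group_from], s[groups == cmp.group_to], p_max, t_min
            )
            rec[f"t_{cmp.label}"] = t
            rec[f"p_{cmp.label}"] = p
            rec[f"dir_{cmp.label}"] = direction
            rec[f"passes_{cmp.label}"] = passes
            all_pass &= passes
            pattern_ok &= direction == want
        rec["is_aar"] = all_pass and pattern_ok
        rows[name] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "pathway"
    return PathwayAARResults(
        table=table,
        scores=scores,
        groups=groups,
        comparisons=comparisons,
        p_max=p_max,
        t_min=t_min,
    )
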