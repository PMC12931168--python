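"""Region-stratified three-way differential expression and the
aging-AD-rescue (AAR) sign-pattern classification.

The design is three ordered pairwise comparisons across the four
conditions — aging (4WT vs 24WT), AD (24WT vs 24AD) and rescue (24AD vs
24SL) — tested per gene with the Wilcoxon rank-sum test inside each
region, with Benjamini-Hochberg FDR control within each (region,
comparison) stratum. Genes significant in all three comparisons are
classified by their direction triple into one of 2 x 2 x 2 = 8 pattern
classes; the (up, down, up) class — up in healthy aging, down in AD,
restored under treatment — is the AAR class.

The model/results pair follows the statsmodels idiom:
``AARPatternModel(expression, groups, regions).fit()`` returns an
:class:`AARPatternResults` holding the per-comparison statistics, the
pattern table, per-region pattern counts and ANOVA-based gene ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CONDITIONS, QCParams, RegionAnnotation, SpatialSample
from .errors import DegenerateDataWarning, ValidationError
from .stats import anova_oneway, bh_fdr, log2fc, rank_sum_matrix, rank_sum_test

__all__ = [
    "Comparison",
    "DEFAULT_COMPARISONS",
    "AAR_PATTERN_CODE",
    "DEResult",
    "AARTable",
    "pairwise_de",
    "classify_pattern",
    "aar_table",
    "rank_aar_genes",
    "AARPatternModel",
    "AARPatternResults",
]


@dataclass(frozen=True)
class Comparison:
    """One ordered condition contrast; "up" means expression increases
    from ``group_from`` to ``group_to``."""

    group_from: str
    group_to: str
    label: str


DEFAULT_COMPARISONS: tuple[Comparison, ...] = (
    Comparison("4WT", "24WT", "aging"),
    Comparison("24WT", "24AD", "AD"),
    Comparison("24AD", "24SL", "rescue"),
)

#: binary encoding of (up, down, up) with up = 1, ordered aging/AD/rescue
AAR_PATTERN_CODE = 5


@dataclass
class DEResult:
    """Per-gene statistics for one (region, comparison) stratum."""

    comparison: Comparison
    region: str
    table: pd.DataFrame  # index gene; columns U, p, q, log2fc, direction, significant
    n_from: int
    n_to: int
    fdr_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def classify_pattern(d1: str, d2: str, d3: str) -> tuple[int, bool]:
    """Pattern code of a direction triple and whether it is the AAR class.

    Code = 4*[d1 up] + 2*[d2 up] + 1*[d3 up]; AAR is (up, down, up),
    code 5.
    """
    for d in (d1, d2, d3):
        if d not in ("up", "down"):
            raise ValidationError(f"direction must be 'up' or 'down', got {d!r}")
    code = 4 * (d1 == "up") + 2 * (d2 == "up") + 1 * (d3 == "up")
    return code, code == AAR_PATTERN_CODE


def pairwise_de(
    X: pd.DataFrame,
    groups: np.ndarray,
    regions: np.ndarray,
    comparison: Comparison,
    region: str,
    fdr_threshold: float = 0.001,
) -> DEResult:
    """Rank-sum differential expression for one comparison in one region.

    ``X`` is the normalized spots x genes matrix; ``groups`` and
    ``regions`` are per-spot labels aligned with its rows. BH correction
    runs across genes within this (region, comparison) stratum; the
    direction is the sign of the log2 fold change of expm1-scale group
    means.
    """
    groups = np.asarray(groups)
    regions = np.asarray(regions)
    if not (len(groups) == len(regions) == X.shape[0]):
        raise ValidationError("groups/regions must align with the matrix rows")
    in_region = regions == region
    m_from = in_region & (groups == comparison.group_from)
    m_to = in_region & (groups == comparison.group_to)
    for name, mask in ((comparison.group_from, m_from), (comparison.group_to, m_to)):
        if mask.sum() < 2:
            raise ValidationError(
                f"group {name!r} has fewer than 2 spots in region {region!r}"
            )
    A = X.to_numpy(dtype=float)[m_from]
    B = X.to_numpy(dtype=float)[m_to]
    if A.shape[0] + B.shape[0] <= 16:
        stats = [rank_sum_test(A[:, j], B[:, j]) for j in range(A.shape[1])]
        u = np.array([s[0] for s in stats])
        p = np.array([s[1] for s in stats])
        p = np.clip(p, np.nextafter(0, 1), 1.0)
    else:
        u, p = rank_sum_matrix(A, B)
    q = bh_fdr(p)
    mean_from = np.expm1(A).mean(axis=0)
    mean_to = np.expm1(B).mean(axis=0)
    lfc = np.array([log2fc(f, t) for f, t in zip(mean_from, mean_to)])
    table = pd.DataFrame(
        {
            "U": u,
            "p": p,
            "q": q,
            "log2fc": lfc,
            "direction": np.where(lfc > 0, "up", "down"),
            "significant": q < fdr_threshold,
        },
        index=pd.Index(X.columns, name="gene"),
    )
    return DEResult(
        comparison=comparison,
        region=region,
        table=table,
        n_from=int(m_from.sum()),
        n_to=int(m_to.sum()),
        fdr_threshold=fdr_threshold,
    )


@dataclass
class AARTable:
    """Triple-significant genes of one region with their pattern class."""

    region: str
    table: pd.DataFrame  # index gene; directions, qs, pattern_code, is_aar
    pattern_counts: pd.Series  # count per code 0..7
    fdr_threshold: float

    @property
    def aar_genes(self) -> list[str]:
        return self.table.index[self.table["is_aar"]].tolist()

    @property
    def n_aar(self) -> int:
        return int(self.table["is_aar"].sum())


def aar_table(
    de_aging: DEResult,
    de_ad: DEResult,
    de_rescue: DEResult,
    fdr_threshold: float | None = None,
) -> AARTable:
    """Combine the three ordered comparisons of one region.

    A gene enters the table iff its q-value is below the threshold in
    all three comparisons; its direction triple is then encoded into one
    of the 8 pattern classes, of which (up, down, up) is flagged AAR.
    """
    des = (de_aging, de_ad, de_rescue)
    if len({d.region for d in des}) != 1:
        raise ValidationError(
            f"mismatched regions: {[d.region for d in des]}"
        )
    if not (de_aging.table.index.equals(de_ad.table.index) and
            de_aging.table.index.equals(de_rescue.table.index)):
        raise ValidationError("the three results disagree on the gene universe")
    thr = fdr_threshold if fdr_threshold is not None else de_aging.fdr_threshold

    qs = np.column_stack([d.table["q"].to_numpy() for d in des])
    keep = (qs < thr).all(axis=1)
    dirs = np.column_stack([d.table["direction"].to_numpy() for d in des])[keep]
    lfcs = np.column_stack([d.table["log2fc"].to_numpy() for d in des])[keep]
    if np.any(lfcs == 0.0):
        warnings.warn(
            "triple-significant gene with exactly zero log2fc; direction "
            "recorded as 'down'",
            DegenerateDataWarning,
            stacklevel=2,
        )
    codes = (
        4 * (dirs[:, 0] == "up") + 2 * (dirs[:, 1] == "up") + 1 * (dirs[:, 2] == "up")
    ).astype(int)
    genes = de_aging.table.index[keep]
    table = pd.DataFrame(
        {
            "dir_aging": dirs[:, 0],
            "dir_AD": dirs[:, 1],
            "dir_rescue": dirs[:, 2],
            "q_aging": qs[keep, 0],
            "q_AD": qs[keep, 1],
            "q_rescue": qs[keep, 2],
            "pattern_code": codes,
            "is_aar": codes == AAR_PATTERN_CODE,
        },
        index=genes,
    )
    counts = pd.Series(0, index=pd.RangeIndex(8, name="pattern_code"), name="n_genes")
    vc = table["pattern_code"].value_counts()
    counts.loc[vc.index] = vc.to_numpy()
    return AARTable(
        region=de_aging.region, table=table, pattern_counts=counts, fdr_threshold=thr
    )


def rank_aar_genes(
    X: pd.DataFrame,
    groups: np.ndarray,
    genes: list[str],
    top_n: int = 30,
) -> pd.DataFrame:
    """Rank genes by one-way ANOVA p across the four conditions.

    Ties in p are broken by F descending, then gene id. Genes with zero
    within-group variance everywhere sort first with a p = 0 sentinel.
    """
    groups = np.asarray(groups)
    uniq = [g for g in CONDITIONS if g in groups]
    if len(uniq) < 4:
        raise ValidationError("rank_aar_genes requires all four conditions")
    masks = [groups == g for g in uniq]
    if any(m.sum() < 2 for m in masks):
        raise ValidationError("each condition needs >= 2 spots")
    rows = []
    for gene in genes:
        v = X[gene].to_numpy(dtype=float)
        f, p = anova_oneway([v[m] for m in masks])
        if np.isinf(f):
            warnings.warn(
                f"gene {gene}: zero within-group variance; p = 0 sentinel",
                DegenerateDataWarning,
                stacklevel=2,
            )
        rows.append((gene, f, p))
    tbl = pd.DataFrame(rows, columns=["gene", "F", "p"])
    tbl = tbl.sort_values(
        ["p", "F", "gene"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    tbl.insert(0, "rank", np.arange(1, len(tbl) + 1))
    return tbl.head(top_n)


class AARPatternModel:
    """Three-way directed differential-expression model over regions.

    Parameters
    ----------
    expression
        Normalized spots x genes DataFrame (all samples merged).
    groups
        Per-spot condition labels (the four study conditions).
    regions
        Per-spot region labels.
    comparisons
        Ordered contrasts; defaults to aging / AD / rescue.
    fdr_threshold
        BH q-value gate applied within each (region, comparison).
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        groups,
        regions,
        comparisons: tuple[Comparison, ...] = DEFAULT_COMPARISONS,
        fdr_threshold: float = 0.001,
    ) -> None:
        self.expression = expression
        self.groups = np.asarray(groups)
        self.regions = np.asarray(regions)
        if not (len(self.groups) == len(self.regions) == expression.shape[0]):
            raise ValidationError("groups/regions must align with expression rows")
        self.comparisons = tuple(comparisons)
        self.fdr_threshold = float(fdr_threshold)

    @classmethod
    def from_samples(
        cls,
        samples: dict[str, SpatialSample],
        annotation: RegionAnnotation,
        qc_params: QCParams | None = None,
        scale: float = 1e4,
        **kwargs,
    ) -> "AARPatternModel":
        """Build the merged model from raw samples: QC, mitochondrial
        removal, normalization, simple concatenation across samples."""
        from .preprocess import normalize_sample, qc_filter, strip_mito

        qc_params = qc_params or QCParams()
        frames, groups, regions = [], [], []
        reports = {}
        for cond, sample in samples.items():
            filtered, report = qc_filter(sample, qc_params)
            reports[cond] = report
            filtered = strip_mito(filtered, qc_params.mito_prefix)
            x = normalize_sample(filtered, scale=scale)
            x.index = [f"{cond}:{b}" for b in x.index]
            frames.append(x)
            groups.extend([sample.condition] * x.shape[0])
            regions.extend(annotation.region_of(filtered.array_coords()))
        merged = pd.concat(frames, axis=0)
        model = cls(merged, np.asarray(groups), np.asarray(regions), **kwargs)
        model.qc_reports = reports
        return model

    def fit(self, regions: list[str] | None = None) -> "AARPatternResults":
        """Run the three comparisons in each region and classify patterns.

        Regions where any contrast group has fewer than 2 spots are
        skipped with a warning.
        """
        if regions is None:
            regions = sorted(pd.unique(self.regions))
        de: dict[tuple[str, str], DEResult] = {}
        tables: dict[str, AARTable] = {}
        for region in regions:
            try:
                results = [
                    pairwise_de(
                        self.expression,
                        self.groups,
                        self.regions,
                        cmp,
                        region,
                        self.fdr_threshold,
                    )
                    for cmp in self.comparisons
                ]
            except ValidationError as exc:
                warnings.warn(
                    f"region {region!r} skipped: {exc}",
                    DegenerateDataWarning,
                    stacklevel=2,
                )
                continue
            for cmp, res in zip(self.comparisons, results):
                de[(region, cmp.label)] = res
            tables[region] = aar_table(*results)
        return AARPatternResults(model=self, de=de, tables=tables)


@dataclass
class AARPatternResults:
    """Fitted results: per-stratum statistics and the pattern tables."""

    model: AARPatternModel
    de: dict[tuple[str, str], DEResult]
    tables: dict[str, AARTable]
    _rank_cache: dict = field(default_factory=dict, repr=False)

    @property
    def regions(self) -> list[str]:
        return sorted(self.tables)

    def aar_genes(self, region: str | None = None) -> list[str]:
        """AAR-flagged genes of one region, or the union over regions."""
        if region is not None:
            return self.tables[region].aar_genes
        out: set[str] = set()
        for t in self.tables.values():
            out.update(t.aar_genes)
        return sorted(out)

    def pattern_counts(self) -> pd.DataFrame:
        """Regions x pattern-code matrix of triple-significant gene counts."""
        return pd.DataFrame(
            {r: t.pattern_counts for r, t in sorted(self.tables.items())}
        ).T.rename_axis("region")

    def aar_gene_table(self) -> pd.DataFrame:
        """Long-form (gene, region) table of all triple-significant genes."""
        frames = []
        for region, t in sorted(self.tables.items()):
            f = t.table.reset_index()
            f.insert(0, "region", region)
            frames.append(f)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    def at_threshold(self, fdr_threshold: float) -> "AARPatternResults":
        """Re-gate the fitted statistics at a different FDR threshold.

        The per-stratum q-values are unchanged; only the significance
        gate moves, so tightening the threshold can only shrink the AAR
        set.
        """
        de = {}
        for key, res in self.de.items():
            tbl = res.table.copy()
            tbl["significant"] = tbl["q"] < fdr_threshold
            de[key] = DEResult(
                comparison=res.comparison,
                region=res.region,
                table=tbl,
                n_from=res.n_from,
                n_to=res.n_to,
                fdr_threshold=fdr_threshold,
            )
        tables = {}
        for region in self.tables:
            trio = [de[(region, cmp.label)] for cmp in self.model.comparisons]
            tables[region] = aar_table(*trio, fdr_threshold=fdr_threshold)
        return AARPatternResults(model=self.model, de=de, tables=tables)

    def rank_genes(self, region: str, top_n: int = 30) -> pd.DataFrame:
        """ANOVA ranking of the region's AAR genes across the four
        conditions (spots restricted to the region)."""
        key = (region, top_n)
        if key not in self._rank_cache:
            mask = self.model.regions == region
            self._rank_cache[key] = rank_aar_genes(
                self.model.expression.loc[mask],
                self.model.groups[mask],
                self.tables[region].aar_genes,
                top_n=top_n,
            )
        return self._rank_cache[key]

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        lines = [
            "AAR pattern analysis",
            "====================",
            f"spots: {self.model.expression.shape[0]}   "
            f"genes: {self.model.expression.shape[1]}   "
            f"FDR threshold: {self.model.fdr_threshold:g}",
            "comparisons: "
            + ", ".join(
                f"{c.label} ({c.group_from} vs {c.group_to})"
                for c in self.model.comparisons
            ),
            "",
            f"{'region':<16}{'triple-signif':>14}{'AAR (code 5)':>14}",
        ]
        for region in self.regions:
            t = self.tables[region]
            lines.append(f"{region:<16}{len(t.table):>14}{t.n_aar:>14}")
        lines.append("")
        lines.append("pattern-code counts (aging/AD/rescue, up = 1):")
        lines.append(self.pattern_counts().to_string())
        return "\n".join(lines)

    def plot_pattern_counts(self, ax=None):
        """Bar plot of pattern-class counts per region."""
        import matplotlib.pyplot as plt

        counts = self.pattern_counts()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.5))
        counts.T.plot.bar(ax=ax)
        ax.set_xlabel("pattern code (4*aging_up + 2*AD_up + rescue_up)")
        ax.set_ylabel("genes")
        ax.axvline(AAR_PATTERN_CODE, color="k", ls=":", lw=1)
        ax.legend(title="region", fontsize=8)
        return ax
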