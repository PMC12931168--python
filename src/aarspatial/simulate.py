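"""Ground-truth simulator for four-condition Visium-like studies.

The generator emulates the study design the analysis is built for: four
brain sections (young wildtype 4WT, aged wildtype 24WT, aged AD-model
24AD, treated AD-model 24SL) profiled on a spot grid with a stylized
region geometry — two cortical bands, a hippocampal zone split into a
thin "somatic" cell-body arc embedded in a surrounding "dendritic"
neuropil, and background tissue.

A subset of genes is planted with the aging-AD-rescue (AAR) pattern in a
target region: relative to the young-wildtype base mean ``mu`` the four
condition means are ``(mu, alpha*mu, alpha*delta*mu, alpha*delta*rho*mu)``
with ``alpha > 1`` (up in healthy aging), ``0 < delta < 1`` (down in AD)
and ``rho > 1`` (up again under treatment). Region marker genes are
elevated by a constant fold in their region in every condition;
mitochondrial-named genes and deliberately broken spots exercise QC.
Counts are negative-binomial with gene-shared dispersion ``theta``
(variance ``mu + mu**2/theta``) and per-spot log-normal depth factors.

Every simulated study carries its own :class:`TruthTable`, so each
downstream stage (QC, spatially-variable-gene selection, clustering,
differential expression, pattern classification, pathway scoring) can be
checked against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import CONDITIONS, POSITION_COLUMNS, RegionAnnotation, SpatialSample
from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "TruthTable",
    "StudyBundle",
    "LAYOUTS",
    "make_region_layout",
    "plant_effects",
    "sample_counts",
    "simulate_study",
]

#: registered region-layout templates. Radii/fractions are relative to the
#: grid; ``ring_width_frac`` of None means a fixed 1-cell-wide somatic arc.
LAYOUTS: dict[str, dict] = {
    # cortex bands over a hippocampal disk whose somatic arc is ~2 cells
    # wide; on a 32x36 grid this yields ~225 dendritic and ~85 somatic
    # spots per sample, matching the regional group sizes the analysis is
    # designed around (roughly 210-235 dendritic spots per section).
    "default": {"ring_width_frac": 0.07},
    # 1-cell-wide somatic arc regardless of grid size
    "thin_arc": {"ring_width_frac": None},
    # single homogeneous region; used for null simulations
    "uniform": {"uniform": True},
}

_CORTEX1_FRAC = 0.15
_CORTEX2_FRAC = 0.30
_DISK_RADIUS_FRAC = 0.31
_RING_INNER_FRAC = 0.50  # of the disk radius


@dataclass
class SimConfig:
    """Parameters of one simulated four-condition study.

    Effect sizes: ``alpha`` (> 1) aging multiplier, ``delta`` (in (0, 1))
    AD multiplier, ``rho`` (> 1) rescue multiplier. ``nb_dispersion`` is
    the negative-binomial ``theta`` shared by all genes. Baseline gene
    means are log-normal; planted AAR genes draw their base means from a
    separate, well-expressed stratum (``aar_logmean_*``) because the
    pattern analysis targets robustly expressed transcripts.
    """

    n_genes: int = 2000
    grid_rows: int = 32
    grid_cols: int = 36
    region_layout: str = "default"
    conditions: tuple[str, ...] = CONDITIONS
    n_aar_genes: int = 50
    aar_region: str = "dendritic"
    alpha: float = 1.5
    delta: float = 0.5
    rho: float = 1.8
    n_marker_genes_per_region: int = 10
    marker_fold: float = 4.0
    baseline_logmean_mu: float = math.log(20.0)
    baseline_logmean_sigma: float = 1.0
    aar_logmean_mu: float = math.log(20.0)
    aar_logmean_sigma: float = 0.3
    mito_logmean_mu: float = math.log(300.0)
    mito_logmean_sigma: float = 0.5
    nb_dispersion: float = 2.0
    depth_log_sigma: float = 0.3
    mito_fraction: float = 0.01
    mito_prefix: str = "mt-"
    n_bad_spots: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.conditions) != CONDITIONS:
            raise ConfigurationError(
                f"conditions must be exactly {CONDITIONS} in that order"
            )
        if not (self.alpha > 1.0 and 0.0 < self.delta < 1.0 and self.rho > 1.0):
            raise ConfigurationError(
                "effect multipliers require alpha > 1, 0 < delta < 1, rho > 1"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.region_layout not in LAYOUTS:
            raise ConfigurationError(
                f"unknown region layout {self.region_layout!r}; "
                f"registered: {sorted(LAYOUTS)}"
            )
        n_regions = 1 if LAYOUTS[self.region_layout].get("uniform") else 5
        n_mito = self.n_mito_genes
        planted = self.n_aar_genes + self.n_marker_genes_per_region * n_regions + n_mito
        if planted > self.n_genes:
            raise ConfigurationError(
                f"{planted} planted genes exceed n_genes={self.n_genes}"
            )

    @property
    def n_mito_genes(self) -> int:
        return int(round(self.mito_fraction * self.n_genes))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth of a simulated study.

    ``genes``: per gene — role (aar/marker/mito/background), target
    region (where applicable), base mean and the effect multipliers.
    ``spots``: per grid position — true region and, for deliberately
    broken spots, which QC rule they violate.
    """

    genes: pd.DataFrame
    spots: pd.DataFrame

    @property
    def aar_gene_ids(self) -> list[str]:
        return self.genes.loc[self.genes["role"] == "aar", "gene_id"].tolist()

    @property
    def marker_gene_ids(self) -> list[str]:
        return self.genes.loc[self.genes["role"] == "marker", "gene_id"].tolist()


@dataclass
class StudyBundle:
    """Four simulated samples plus region annotation and ground truth."""

    samples: dict[str, SpatialSample]
    regions: RegionAnnotation
    truth: TruthTable
    config: SimConfig = field(repr=False)

    def __iter__(self):
        return iter(self.samples.values())


def make_region_layout(
    grid_rows: int, grid_cols: int, layout_spec: str = "default"
) -> RegionAnnotation:
    """Assign every grid position to exactly one region.

    Geometry (non-uniform templates): the top ~30% of rows form two
    cortical bands; a disk in the remaining tissue is the hippocampal
    zone, inside which a thin arc of cells at about half the disk radius
    is "somatic" and the rest "dendritic"; everything else is background.
    """
    if layout_spec not in LAYOUTS:
        raise ConfigurationError(
            f"unknown region layout {layout_spec!r}; registered: {sorted(LAYOUTS)}"
        )
    if grid_rows < 8 or grid_cols < 8:
        raise ConfigurationError("grid must be at least 8x8")
    spec = LAYOUTS[layout_spec]
    rr, cc = np.meshgrid(np.arange(grid_rows), np.arange(grid_cols), indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    region = np.full(rr.size, "background", dtype=object)

    if not spec.get("uniform"):
        c1_end = math.ceil(_CORTEX1_FRAC * grid_rows)
        c2_end = math.ceil(_CORTEX2_FRAC * grid_rows)
        region[rr < c1_end] = "cortex_band_1"
        region[(rr >= c1_end) & (rr < c2_end)] = "cortex_band_2"

        short = min(grid_rows, grid_cols)
        center_r = (c2_end + grid_rows - 1) / 2.0
        center_c = (grid_cols - 1) / 2.0
        disk_r = _DISK_RADIUS_FRAC * short
        ring_in = _RING_INNER_FRAC * disk_r
        width_frac = spec.get("ring_width_frac")
        ring_w = 1.0 if width_frac is None else max(1.0, width_frac * short)
        # the arc must stay strictly inside the disk so that every somatic
        # spot touches dendritic tissue
        ring_out = min(ring_in + ring_w, disk_r - 0.7)

        dist = np.hypot(rr - center_r, cc - center_c)
        hippo = (rr >= c2_end) & (dist < disk_r)
        region[hippo] = "dendritic"
        somatic = hippo & (dist >= ring_in) & (dist < ring_out)
        if not somatic.any():  # tiny grids: take the cells nearest the arc
            cand = np.where(hippo)[0]
            if cand.size == 0:
                raise ConfigurationError(
                    f"grid {grid_rows}x{grid_cols} too small for layout "
                    f"{layout_spec!r}"
                )
            nearest = cand[np.argsort(np.abs(dist[cand] - ring_in))[:2]]
            somatic = np.zeros_like(hippo)
            somatic[nearest] = True
        region[somatic] = "somatic"
        for needed in ("cortex_band_1", "cortex_band_2", "dendritic", "background"):
            if not (region == needed).any():
                raise ConfigurationError(
                    f"grid {grid_rows}x{grid_cols} too small to place region "
                    f"{needed!r}"
                )

    table = pd.DataFrame({"array_row": rr, "array_col": cc, "region": region})
    return RegionAnnotation(table)


def _assign_gene_roles(config: SimConfig, regions: list[str]) -> pd.DataFrame:
    """Gene ids, roles and target regions for one study."""
    n_mito = config.n_mito_genes
    width = len(str(config.n_genes))
    rows: list[tuple[str, str, str]] = []
    idx = 0
    for _ in range(n_mito):
        rows.append((f"{config.mito_prefix}gene{idx:0{width}d}", "mito", ""))
        idx += 1
    for region in regions:
        for _ in range(config.n_marker_genes_per_region):
            rows.append((f"gene{idx:0{width}d}", "marker", region))
            idx += 1
    for _ in range(config.n_aar_genes):
        rows.append((f"gene{idx:0{width}d}", "aar", config.aar_region))
        idx += 1
    while idx < config.n_genes:
        rows.append((f"gene{idx:0{width}d}", "background", ""))
        idx += 1
    return pd.DataFrame(rows, columns=["gene_id", "role", "region"])


def _draw_base_means(genes: pd.DataFrame, config: SimConfig, rng) -> np.ndarray:
    mu = rng.lognormal(
        config.baseline_logmean_mu, config.baseline_logmean_sigma, len(genes)
    )
    role = genes["role"].to_numpy()
    n_aar = int((role == "aar").sum())
    n_mito = int((role == "mito").sum())
    if n_aar:
        mu[role == "aar"] = rng.lognormal(
            config.aar_logmean_mu, config.aar_logmean_sigma, n_aar
        )
    if n_mito:
        mu[role == "mito"] = rng.lognormal(
            config.mito_logmean_mu, config.mito_logmean_sigma, n_mito
        )
    return mu


def plant_effects(
    base_means: np.ndarray, truth: TruthTable, config: SimConfig
) -> dict[str, np.ndarray]:
    """Expected-mean matrices (spots x genes) for each condition.

    Pure function of the truth table: an AAR gene with base mean ``mu``
    has condition means ``(mu, alpha*mu, alpha*delta*mu,
    alpha*delta*rho*mu)`` inside its target region and ``mu`` elsewhere;
    markers are ``marker_fold * mu`` in their region in every condition;
    background and mito genes are flat.
    """
    base_means = np.asarray(base_means, dtype=float)
    if np.any(base_means <= 0):
        raise ConfigurationError("base means must be strictly positive")
    spot_region = truth.spots["region"].to_numpy()
    n_spots = spot_region.size
    genes = truth.genes
    flat = np.tile(base_means, (n_spots, 1))

    # condition-independent marker folds
    for region, cols in genes.groupby("region").groups.items():
        sub = genes.loc[cols]
        marker_cols = sub.index[sub["role"] == "marker"].to_numpy()
        if region and marker_cols.size:
            rows = np.where(spot_region == region)[0]
            flat[np.ix_(rows, marker_cols)] *= config.marker_fold

    cum = {
        config.conditions[0]: 1.0,
        config.conditions[1]: config.alpha,
        config.conditions[2]: config.alpha * config.delta,
        config.conditions[3]: config.alpha * config.delta * config.rho,
    }
    aar = genes[genes["role"] == "aar"]
    out: dict[str, np.ndarray] = {}
    for cond, factor in cum.items():
        m = flat.copy()
        for region, sub in aar.groupby("region"):
            cols = sub.index.to_numpy()
            rows = np.where(spot_region == region)[0]
            if cols.size and rows.size:
                m[np.ix_(rows, cols)] *= factor
        out[cond] = m
    return out


def sample_counts(
    mean_matrix: np.ndarray,
    nb_dispersion: float,
    depth_factors: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Draw negative-binomial counts around ``depth * mean``.

    Entry (s, g) ~ NB with mean ``d_s * mu_sg`` and variance
    ``d_s*mu_sg + (d_s*mu_sg)**2 / theta``; identical seed, identical
    draw.
    """
    if nb_dispersion <= 0:
        raise ConfigurationError("nb_dispersion must be positive")
    depth = np.asarray(depth_factors, dtype=float).reshape(-1, 1)
    if np.any(depth <= 0):
        raise ConfigurationError("depth factors must be strictly positive")
    mean = np.asarray(mean_matrix, dtype=float) * depth
    if np.any(mean < 0):
        raise ConfigurationError("mean matrix must be non-negative")
    rng = np.random.default_rng(seed)
    p = nb_dispersion / (nb_dispersion + mean)
    return rng.negative_binomial(nb_dispersion, p).astype(np.int64)


def simulate_study(config: SimConfig | None = None, **overrides) -> StudyBundle:
    """Simulate one four-condition study with ground truth.

    Keyword overrides are applied on top of ``config`` (or defaults), so
    ``simulate_study(seed=7, n_aar_genes=0)`` is a null study.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**config.to_dict(), **overrides})

    rng = np.random.default_rng(config.seed)
    annotation = make_region_layout(
        config.grid_rows, config.grid_cols, config.region_layout
    )
    regions = annotation.regions
    genes = _assign_gene_roles(config, regions)
    base_means = _draw_base_means(genes, config, rng)

    spots = annotation.table.copy()
    spots["bad"] = ""
    n_spots = len(spots)
    if config.n_bad_spots:
        bg = np.where(spots["region"].to_numpy() == "background")[0]
        if bg.size < config.n_bad_spots:
            raise ConfigurationError(
                "not enough background spots to place n_bad_spots"
            )
        chosen = rng.choice(bg, size=config.n_bad_spots, replace=False)
        half = config.n_bad_spots // 2
        spots.iloc[chosen[:half], spots.columns.get_loc("bad")] = "low_genes"
        spots.iloc[chosen[half:], spots.columns.get_loc("bad")] = "high_mito"

    gtable = genes.copy()
    gtable["base_mean"] = base_means
    gtable["alpha"] = np.where(gtable["role"] == "aar", config.alpha, np.nan)
    gtable["delta"] = np.where(gtable["role"] == "aar", config.delta, np.nan)
    gtable["rho"] = np.where(gtable["role"] == "aar", config.rho, np.nan)
    gtable["marker_fold"] = np.where(
        gtable["role"] == "marker", config.marker_fold, np.nan
    )
    truth = TruthTable(genes=gtable, spots=spots)

    means = plant_effects(base_means, truth, config)

    mito_cols = genes.index[genes["role"] == "mito"].to_numpy()
    low_rows = np.where(spots["bad"].to_numpy() == "low_genes")[0]
    mito_rows = np.where(spots["bad"].to_numpy() == "high_mito")[0]

    barcodes = [
        f"r{r:03d}c{c:03d}"
        for r, c in spots[["array_row", "array_col"]].itertuples(index=False)
    ]
    samples: dict[str, SpatialSample] = {}
    seeds = rng.integers(0, 2**31 - 1, size=len(config.conditions))
    for cond, child_seed in zip(config.conditions, seeds):
        depth = np.exp(rng.normal(0.0, config.depth_log_sigma, n_spots))
        depth /= depth.mean()
        depth[low_rows] *= 0.002  # starved spots: fail the expressed-genes gate
        mean = means[cond]
        if mito_rows.size and mito_cols.size:
            mean = mean.copy()
            # mito-flooded spots: mitochondrial UMI share pushed past 30%
            mean[np.ix_(mito_rows, mito_cols)] *= 25.0
        counts = sample_counts(mean, config.nb_dispersion, depth, int(child_seed))
        positions = pd.DataFrame(
            {
                "barcode": barcodes,
                "in_tissue": 1,
                "array_row": spots["array_row"].to_numpy(),
                "array_col": spots["array_col"].to_numpy(),
                "pxl_row_in_fullres": spots["array_row"].to_numpy() * 118.5 + 600.0,
                "pxl_col_in_fullres": spots["array_col"].to_numpy() * 118.5 + 750.0,
            }
        )[POSITION_COLUMNS]
        samples[cond] = SpatialSample(
            sample_id=cond,
            condition=cond,
            counts=sparse.csr_matrix(counts),
            gene_ids=genes["gene_id"].tolist(),
            barcodes=barcodes,
            positions=positions,
        )
    return StudyBundle(samples=samples, regions=annotation, truth=truth, config=config)
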