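"""Spot quality control, mitochondrial-gene removal and normalization.

QC keeps spots expressing at least ``min_genes_per_spot`` genes with a
mitochondrial UMI share of at most ``max_mito_fraction`` (both computed
on the unfiltered gene set). Mitochondrial genes are then dropped from
all downstream analysis. Normalization is depth-scaling to a fixed total
followed by log1p: ``log1p(count * scale / spot_total)``. The rank-based
tests downstream are invariant to any monotone per-spot transform, so
this simple scheme preserves the structure the analysis depends on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import QCParams, QCReport, SpatialSample
from .errors import EmptyResultWarning, ValidationError

__all__ = ["qc_filter", "strip_mito", "normalize", "normalize_sample"]


def _mito_mask(gene_ids: list[str], prefix: str) -> np.ndarray:
    p = prefix.lower()
    return np.array([g.lower().startswith(p) for g in gene_ids], dtype=bool)


def qc_filter(
    sample: SpatialSample, params: QCParams | None = None
) -> tuple[SpatialSample, QCReport]:
    """Remove low-complexity and mitochondria-dominated spots.

    The mitochondrial share is computed before any gene removal. Spots
    failing both rules are attributed to the low-genes rule in the
    report. Applying the filter twice removes nothing the second time.
    """
    params = params or QCParams()
    counts = sample.counts
    genes_per_spot = np.asarray((counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    mito = _mito_mask(sample.gene_ids, params.mito_prefix)
    mito_umis = np.asarray(counts[:, mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_share = np.where(totals > 0, mito_umis / np.maximum(totals, 1.0), 0.0)

    low = genes_per_spot < params.min_genes_per_spot
    high_mito = mito_share > params.max_mito_fraction
    keep = ~(low | high_mito)
    report = QCReport(
        spots_in=sample.n_spots,
        spots_removed_low_genes=int(low.sum()),
        spots_removed_high_mito=int((high_mito & ~low).sum()),
        spots_out=int(keep.sum()),
    )
    if report.spots_out == 0:
        warnings.warn(
            f"QC removed every spot of sample {sample.sample_id}",
            EmptyResultWarning,
            stacklevel=2,
        )
    return sample.subset_spots(keep), report


def strip_mito(sample: SpatialSample, prefix: str = "mt-") -> SpatialSample:
    """Drop genes whose id starts with ``prefix`` (case-insensitive)."""
    mito = _mito_mask(sample.gene_ids, prefix)
    if mito.all():
        warnings.warn(
            f"mitochondrial prefix {prefix!r} matches every gene of sample "
            f"{sample.sample_id}",
            EmptyResultWarning,
            stacklevel=2,
        )
    if not mito.any():
        return sample
    return sample.subset_genes(~mito)


def normalize(counts, scale: float = 1e4) -> np.ndarray:
    """Depth-normalize and log-transform a spot-by-gene count matrix.

    Returns ``log1p(count * scale / spot_total)`` as a dense array; for
    each spot ``sum(expm1(out)) == scale`` up to rounding.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    if sparse.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError(
            "normalize: zero-total spot encountered; run qc_filter first"
        )
    return np.log1p(counts * (scale / totals[:, None]))


def normalize_sample(sample: SpatialSample, scale: float = 1e4) -> pd.DataFrame:
    """Normalized expression as a barcode x gene DataFrame."""
    x = normalize(sample.counts, scale=scale)
    return pd.DataFrame(x, index=sample.barcodes, columns=sample.gene_ids)
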