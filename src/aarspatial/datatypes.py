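"""Core data containers shared by the I/O, QC and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ValidationError

#: the four study conditions, in experimental order: young wildtype,
#: aged wildtype, aged AD model, aged AD model under treatment.
CONDITIONS = ("4WT", "24WT", "24AD", "24SL")

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass
class SpatialSample:
    """One sample's spot-by-gene count matrix plus spot coordinates.

    ``counts`` is spots x genes (rows follow ``barcodes``, columns follow
    ``gene_ids``), non-negative integers, stored sparse. ``positions``
    carries the 10x-style tissue-position columns, one row per barcode in
    barcode order.
    """

    sample_id: str
    condition: str
    counts: sparse.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    positions: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.barcodes = list(self.barcodes)
        self.validate()

    def validate(self) -> None:
        n_spots, n_genes = self.counts.shape
        if n_spots != len(self.barcodes):
            raise ValidationError(
                f"sample {self.sample_id}: {n_spots} matrix rows vs "
                f"{len(self.barcodes)} barcodes"
            )
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"sample {self.sample_id}: {n_genes} matrix columns vs "
                f"{len(self.gene_ids)} gene ids"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError(f"sample {self.sample_id}: duplicate barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"sample {self.sample_id}: duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError(f"sample {self.sample_id}: negative counts")
        data = self.counts.data
        if (
            data.size
            and not np.issubdtype(data.dtype, np.integer)
            and np.any(data != np.round(data))
        ):
            raise ValidationError(f"sample {self.sample_id}: non-integral counts")
        missing = set(self.barcodes) - set(self.positions["barcode"])
        if missing:
            raise ValidationError(
                f"sample {self.sample_id}: positions missing barcodes "
                f"{sorted(missing)[:3]}..."
            )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, mask: np.ndarray) -> "SpatialSample":
        mask = np.asarray(mask, dtype=bool)
        barcodes = [b for b, keep in zip(self.barcodes, mask) if keep]
        pos = self.positions.set_index("barcode").loc[barcodes].reset_index()
        return replace(
            self,
            counts=self.counts[mask],
            barcodes=barcodes,
            positions=pos[POSITION_COLUMNS],
        )

    def subset_genes(self, mask: np.ndarray) -> "SpatialSample":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            counts=sparse.csr_matrix(self.counts[:, mask]),
            gene_ids=[g for g, keep in zip(self.gene_ids, mask) if keep],
        )

    def array_coords(self) -> np.ndarray:
        """(n_spots, 2) array of (array_row, array_col) in barcode order."""
        pos = self.positions.set_index("barcode").loc[self.barcodes]
        return pos[["array_row", "array_col"]].to_numpy(dtype=int)

    def to_anndata(self):
        """Optional AnnData view (anndata is not a hard dependency)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.positions.set_index("barcode").loc[self.barcodes].copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obs["sample_id"] = self.sample_id
        adata.obs["condition"] = self.condition
        return adata


@dataclass
class RegionAnnotation:
    """Per-grid-position region labels (shared by all samples of a study).

    ``table`` has columns array_row, array_col, region.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"array_row", "array_col", "region"}
        if not need.issubset(self.table.columns):
            raise ValidationError(f"region annotation needs columns {sorted(need)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def region_of(self, coords: np.ndarray) -> np.ndarray:
        """Region label for each (array_row, array_col) pair in ``coords``."""
        lut = {
            (int(r), int(c)): reg
            for r, c, reg in self.table[["array_row", "array_col", "region"]].itertuples(
                index=False
            )
        }
        try:
            return np.array([lut[(int(r), int(c))] for r, c in coords], dtype=object)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"position {exc} has no region annotation") from exc

    def counts_by_region(self) -> pd.Series:
        return self.table["region"].value_counts().sort_index()


@dataclass
class QCParams:
    """Spot-level quality-control gates.

    A spot is kept when it expresses at least ``min_genes_per_spot`` genes
    (count > 0) and at most ``max_mito_fraction`` of its UMIs come from
    genes whose id starts with ``mito_prefix`` (case-insensitive). Both
    gates are strict in the removal direction: exactly 200 genes or
    exactly 30% mitochondrial UMIs is kept.
    """

    min_genes_per_spot: int = 200
    max_mito_fraction: float = 0.30
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_mito_fraction < 1.0):
            raise ValidationError("max_mito_fraction must be in (0, 1)")
        if self.min_genes_per_spot < 1:
            raise ValidationError("min_genes_per_spot must be >= 1")


@dataclass
class QCReport:
    spots_in: int
    spots_removed_low_genes: int
    spots_removed_high_mito: int
    spots_out: int
    mito_genes_removed: int = 0

    def __post_init__(self) -> None:
        removed = self.spots_removed_low_genes + self.spots_removed_high_mito
        if self.spots_out != self.spots_in - removed:
            raise ValidationError("QCReport counts are inconsistent")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways from a GMT file)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()
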