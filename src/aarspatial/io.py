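"""Reading and writing the on-disk study layout.

Each sample is a directory holding ``matrix.mtx`` (MatrixMarket
coordinate integers, genes x spots as in 10x output), ``features.tsv``
(one or three columns), ``barcodes.tsv`` and ``tissue_positions.csv``
(10x dialect with header). Gene sets come from GMT files. A whole
simulated study round-trips through :func:`write_bundle` /
:func:`read_bundle`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import yaml
from scipy import sparse

from .datatypes import GeneSetCollection, POSITION_COLUMNS, RegionAnnotation, SpatialSample
from .errors import FormatError
from .simulate import SimConfig, StudyBundle, TruthTable

__all__ = [
    "read_sample",
    "write_sample",
    "read_gmt",
    "write_gmt",
    "read_bundle",
    "write_bundle",
]

_MATRIX = "matrix.mtx"
_FEATURES = "features.tsv"
_BARCODES = "barcodes.tsv"
_POSITIONS = "tissue_positions.csv"


def write_sample(sample: SpatialSample, directory: str) -> dict[str, str]:
    """Write one sample to ``directory``; returns the file paths."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "matrix": os.path.join(directory, _MATRIX),
        "features": os.path.join(directory, _FEATURES),
        "barcodes": os.path.join(directory, _BARCODES),
        "positions": os.path.join(directory, _POSITIONS),
    }
    # 10x convention: features are rows
    scipy.io.mmwrite(paths["matrix"], sample.counts.T.tocoo(), field="integer")
    with open(paths["features"], "w") as fh:
        for gid in sample.gene_ids:
            fh.write(f"{gid}\t{gid}\tGene Expression\n")
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(f"{b}\n" for b in sample.barcodes)
    sample.positions[POSITION_COLUMNS].to_csv(paths["positions"], index=False)
    meta = {"sample_id": sample.sample_id, "condition": sample.condition}
    with open(os.path.join(directory, "sample.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
    return paths


def _read_single_column_or_10x(path: str) -> list[str]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    out = []
    for ln in lines:
        fields = ln.split("\t")
        out.append(fields[0])
    return out


def read_sample(
    directory: str, sample_id: str | None = None, condition: str | None = None
) -> SpatialSample:
    """Read a sample directory written by :func:`write_sample` (or any
    10x-style triplet plus positions file)."""
    mtx_path = os.path.join(directory, _MATRIX)
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:
        raise FormatError(f"{mtx_path}: {exc}") from exc
    mat = sparse.csr_matrix(mat.T)  # back to spots x genes
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative count entries")

    gene_ids = _read_single_column_or_10x(os.path.join(directory, _FEATURES))
    barcodes = _read_single_column_or_10x(os.path.join(directory, _BARCODES))
    if len(gene_ids) != mat.shape[1]:
        raise FormatError(
            f"{os.path.join(directory, _FEATURES)}: {len(gene_ids)} features vs "
            f"{mat.shape[1]} matrix rows"
        )
    if len(barcodes) != mat.shape[0]:
        raise FormatError(
            f"{os.path.join(directory, _BARCODES)}: {len(barcodes)} barcodes vs "
            f"{mat.shape[0]} matrix columns"
        )

    pos_path = os.path.join(directory, _POSITIONS)
    positions = pd.read_csv(pos_path)
    missing = [c for c in POSITION_COLUMNS if c not in positions.columns]
    if missing:
        raise FormatError(f"{pos_path}: missing columns {missing}")
    unknown = set(positions["barcode"]) - set(barcodes)
    if unknown:
        raise FormatError(
            f"{pos_path}: barcodes not present in {_BARCODES}: "
            f"{sorted(unknown)[:3]}..."
        )
    if set(barcodes) - set(positions["barcode"]):
        raise FormatError(f"{pos_path}: positions do not cover all barcodes")
    positions = (
        positions.set_index("barcode").loc[barcodes].reset_index()[POSITION_COLUMNS]
    )

    meta_path = os.path.join(directory, "sample.yaml")
    meta = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    return SpatialSample(
        sample_id=sample_id or meta.get("sample_id", os.path.basename(directory)),
        condition=condition or meta.get("condition", "unknown"),
        counts=mat,
        gene_ids=gene_ids,
        barcodes=barcodes,
        positions=positions,
    )


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str) -> str:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
    return path


def write_bundle(bundle: StudyBundle, directory: str) -> str:
    """Write a simulated study: one directory per sample plus truth,
    region annotation and the config echo."""
    os.makedirs(directory, exist_ok=True)
    for cond, sample in bundle.samples.items():
        write_sample(sample, os.path.join(directory, cond))
    bundle.regions.table.to_csv(
        os.path.join(directory, "regions.tsv"), sep="\t", index=False
    )
    bundle.truth.genes.to_csv(
        os.path.join(directory, "truth_genes.tsv"), sep="\t", index=False
    )
    bundle.truth.spots.to_csv(
        os.path.join(directory, "truth_spots.tsv"), sep="\t", index=False
    )
    with open(os.path.join(directory, "sim_config.yaml"), "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
    return directory


def read_bundle(directory: str) -> StudyBundle:
    with open(os.path.join(directory, "sim_config.yaml")) as fh:
        config = SimConfig.from_dict(yaml.safe_load(fh))
    samples = {
        cond: read_sample(os.path.join(directory, cond)) for cond in config.conditions
    }
    regions = RegionAnnotation(
        pd.read_csv(os.path.join(directory, "regions.tsv"), sep="\t")
    )
    genes = pd.read_csv(os.path.join(directory, "truth_genes.tsv"), sep="\t")
    spots = pd.read_csv(
        os.path.join(directory, "truth_spots.tsv"), sep="\t", keep_default_na=False
    )
    for col in ("region", "bad"):
        if col in spots.columns:
            spots[col] = spots[col].astype(str)
    genes["region"] = genes["region"].fillna("").astype(str)
    truth = TruthTable(genes=genes, spots=spots)
    return StudyBundle(samples=samples, regions=regions, truth=truth, config=config)
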