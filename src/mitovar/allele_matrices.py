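"""Alternative-allele count and coverage matrices, and allele frequencies.

Two sparse matrices summarise a pileup run:

* coverage — positions × cells, counted-base depth;
* alt counts — variants × cells, reads carrying each non-reference base.

Every position with a non-N reference base contributes all three
possible alt rows (materialised sparsely), so the row universe is a
function of the reference alone and matrices from different runs align.
Allele frequency is alt / coverage per cell; entries with coverage below
``min_coverage`` are missing (NaN), which downstream statistics drop —
a dropout is never treated as evidence for the reference allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from . import __version__
from .pileup_engine import BaseCountTensor, CellIndex, PileupFilters
from .reference_io import BASES, MitoReference, Variant, enumerate_variants

_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

MANIFEST_NAME = "manifest.json"
_FILES = ("alt_counts.mtx", "coverage.mtx", "variants.tsv", "cells.tsv")


@dataclass
class CoverageMatrix:
    """Counted-base depth, positions (1..L) × cells; CSR sparse."""

    X: sp.csr_matrix
    cell_ids: list[str]
    contig_name: str

    @property
    def n_positions(self) -> int:
        return self.X.shape[0]

    def depth(self, position: int, cell: str) -> int:
        return int(self.X[position - 1, self.cell_ids.index(cell)])


@dataclass
class AltCountMatrix:
    """Reads carrying the alt base, variants × cells; CSR sparse.

    Rows are ordered position ascending then alt base A<C<G<T; N-reference
    positions have no rows.
    """

    X: sp.csr_matrix
    variants: list[Variant]
    cell_ids: list[str]
    contig_name: str

    def row_of(self, variant: Variant) -> int:
        try:
            return self._row_index[variant]
        except AttributeError:
            self._row_index = {v: i for i, v in enumerate(self.variants)}
            return self._row_index[variant]


@dataclass
class AlleleFrequencyMatrix:
    """Alt-allele fractions, variants × cells, dense with NaN = missing."""

    values: np.ndarray
    variants: list[Variant]
    cell_ids: list[str]

    def row_of(self, variant: Variant) -> int:
        try:
            return self._row_index[variant]
        except AttributeError:
            self._row_index = {v: i for i, v in enumerate(self.variants)}
            return self._row_index[variant]

    def row(self, variant: Variant) -> pd.Series:
        """AF across cells for one variant (NaN = no coverage)."""
        return pd.Series(
            self.values[self.row_of(variant)], index=self.cell_ids, name=variant.label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[v.label for v in self.variants],
            columns=self.cell_ids,
        )


def build_matrices(
    tensors: Sequence[BaseCountTensor],
    reference: MitoReference,
    index: CellIndex,
) -> tuple[AltCountMatrix, CoverageMatrix]:
    """Assemble the two core matrices from per-cell base-count tensors."""
    if [t.cell_id for t in tensors] != list(index.cell_ids):
        raise ValueError("tensor cell ids do not match the cell index")
    variants = enumerate_variants(reference)
    pos_idx = np.array([v.position - 1 for v in variants], dtype=np.int64)
    base_idx = np.array([_BASE_TO_CODE[v.alt] for v in variants], dtype=np.int64)

    n_cells = len(tensors)
    L = reference.length
    cov_cols = []
    alt_rows_nz: list[np.ndarray] = []
    alt_cols_nz: list[np.ndarray] = []
    alt_data_nz: list[np.ndarray] = []
    for j, t in enumerate(tensors):
        if t.counts.shape != (4, L):
            raise ValueError(
                f"tensor {t.cell_id!r} has shape {t.counts.shape}, expected (4, {L})"
            )
        cov_cols.append(sp.csr_matrix(t.depth().reshape(-1, 1)))
        vals = t.counts[base_idx, pos_idx]
        nz = np.flatnonzero(vals)
        alt_rows_nz.append(nz)
        alt_cols_nz.append(np.full(nz.size, j, dtype=np.int64))
        alt_data_nz.append(vals[nz])
    if n_cells:
        cov_X = sp.hstack(cov_cols, format="csr")
        alt_X = sp.csr_matrix(
            (
                np.concatenate(alt_data_nz),
                (np.concatenate(alt_rows_nz), np.concatenate(alt_cols_nz)),
            ),
            shape=(len(variants), n_cells),
            dtype=np.int64,
        )
    else:
        cov_X = sp.csr_matrix((L, 0), dtype=np.int64)
        alt_X = sp.csr_matrix((len(variants), 0), dtype=np.int64)
    cov_X = cov_X.astype(np.int64)
    cell_ids = list(index.cell_ids)
    return (
        AltCountMatrix(
            X=alt_X, variants=variants, cell_ids=cell_ids,
            contig_name=reference.contig_name,
        ),
        CoverageMatrix(
            X=cov_X, cell_ids=cell_ids, contig_name=reference.contig_name
        ),
    )


def calc_allele_frequency(
    alt: AltCountMatrix,
    cov: CoverageMatrix,
    min_coverage: int = 1,
) -> AlleleFrequencyMatrix:
    """AF(v, c) = alt / coverage where coverage >= min_coverage, else NaN."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if alt.cell_ids != cov.cell_ids:
        raise ValueError("alt and coverage matrices have different cell columns")
    pos_idx = np.array([v.position - 1 for v in alt.variants], dtype=np.int64)
    if pos_idx.size and pos_idx.max() >= cov.n_positions:
        raise ValueError("variant positions exceed the coverage matrix")
    cov_dense = np.asarray(cov.X.todense(), dtype=np.float64)[pos_idx, :]
    alt_dense = np.asarray(alt.X.todense(), dtype=np.float64)
    if alt_dense.shape != cov_dense.shape:
        raise ValueError("shape mismatch between alt and coverage")
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(cov_dense >= min_coverage, alt_dense / cov_dense, np.nan)
    return AlleleFrequencyMatrix(
        values=af, variants=list(alt.variants), cell_ids=list(alt.cell_ids)
    )


def write_matrices(
    out_dir: str | Path,
    alt: AltCountMatrix,
    cov: CoverageMatrix,
    index: CellIndex,
    reference: MitoReference,
    filters: PileupFilters | None = None,
) -> Path:
    """Persist matrices as MatrixMarket plus TSV sidecars and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "alt_counts.mtx"), alt.X.tocoo())
    mmwrite(str(out / "coverage.mtx"), cov.X.tocoo())
    pd.DataFrame(
        {
            "label": [v.label for v in alt.variants],
            "position": [v.position for v in alt.variants],
            "ref": [v.ref for v in alt.variants],
            "alt": [v.alt for v in alt.variants],
        }
    ).to_csv(out / "variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cell_id": index.cell_ids,
            "total_reads": [index.total_reads.get(c, 0) for c in index.cell_ids],
        }
    ).to_csv(out / "cells.tsv", sep="\t", index=False)
    manifest = {
        "tool": "mitovar",
        "version": __version__,
        "contig_name": reference.contig_name,
        "reference_length": reference.length,
        "mode": index.mode,
        "n_cells": len(index.cell_ids),
        "n_variants": len(alt.variants),
        "filters": _filters_dict(filters),
    }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _filters_dict(filters: PileupFilters | None) -> dict | None:
    if filters is None:
        return None
    d = asdict(filters)
    d["exclude_flags"] = sorted(d["exclude_flags"])
    return d


def read_matrices(
    in_dir: str | Path,
    reference: MitoReference | None = None,
) -> tuple[AltCountMatrix, CoverageMatrix, CellIndex, dict]:
    """Load a matrices directory written by :func:`write_matrices`.

    When *reference* is given, its contig name and length are checked
    against the manifest.
    """
    src = Path(in_dir)
    missing = [f for f in (*_FILES, MANIFEST_NAME) if not (src / f).exists()]
    if missing:
        raise ValueError(f"matrices directory {src} is incomplete: missing {missing}")
    manifest = json.loads((src / MANIFEST_NAME).read_text())
    if reference is not None:
        if manifest["reference_length"] != reference.length:
            raise ValueError(
                f"manifest reference length {manifest['reference_length']} != "
                f"supplied FASTA length {reference.length}"
            )
        if manifest["contig_name"] != reference.contig_name:
            raise ValueError(
                f"manifest contig {manifest['contig_name']!r} != "
                f"supplied {reference.contig_name!r}"
            )
    var_tab = pd.read_csv(src / "variants.tsv", sep="\t")
    cell_tab = pd.read_csv(src / "cells.tsv", sep="\t", dtype={"cell_id": str})
    variants = [
        Variant(position=int(p), ref=r, alt=a)
        for p, r, a in zip(var_tab["position"], var_tab["ref"], var_tab["alt"])
    ]
    cell_ids = list(cell_tab["cell_id"])
    alt_X = sp.csr_matrix(mmread(str(src / "alt_counts.mtx"))).astype(np.int64)
    cov_X = sp.csr_matrix(mmread(str(src / "coverage.mtx"))).astype(np.int64)
    if alt_X.shape != (len(variants), len(cell_ids)):
        raise ValueError(
            f"alt matrix shape {alt_X.shape} does not match sidecars "
            f"({len(variants)} variants, {len(cell_ids)} cells)"
        )
    if cov_X.shape != (manifest["reference_length"], len(cell_ids)):
        raise ValueError(
            f"coverage matrix shape {cov_X.shape} does not match manifest"
        )
    index = CellIndex(
        mode=manifest.get("mode", "well"),
        cell_ids=cell_ids,
        total_reads=dict(zip(cell_tab["cell_id"], cell_tab["total_reads"])),
    )
    contig = manifest["contig_name"]
    return (
        AltCountMatrix(X=alt_X, variants=variants, cell_ids=cell_ids, contig_name=contig),
        CoverageMatrix(X=cov_X, cell_ids=cell_ids, contig_name=contig),
        index,
        manifest,
    )
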