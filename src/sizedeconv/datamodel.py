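"""Core containers for reference-based deconvolution.

The method estimates cell-type proportions ``P`` (K types x J samples) from a
bulk expression matrix ``Y`` (G genes x J samples) using a cell-type signature
``Z`` (G genes x K types) of mean reference expression, optionally rescaled
column-wise by per-type cell-size factors ``s``:

    Y  =  Z . diag(s) . P

Larger cells contribute more mRNA per cell, so solving against the unscaled
``Z`` yields the RNA fraction attributable to each type rather than the cell
fraction; multiplying each signature column by the type's size factor converts
the estimates back to cell fractions.

All containers are lightweight dataclasses over dense numpy arrays with
explicit identifier axes, validated at construction.  Sparse single-cell
counts are accepted and densified per marker subset only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse as sp

__all__ = [
    "SignatureMatrix",
    "CellScaleFactors",
    "ProportionMatrix",
    "BulkMatrix",
    "SingleCellDataset",
    "AlignmentReport",
    "ValidationError",
    "AlignmentError",
    "apply_scale_factors",
    "normalize_proportions",
    "align",
]

PROPORTION_TOL = 1e-8


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


class AlignmentError(ValueError):
    """Raised when matrices cannot be aligned (no shared genes/types)."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicated {what} identifiers: {dupes[:5]}")
    return ids


@dataclass(frozen=True)
class SignatureMatrix:
    """Mean reference expression, genes x cell types (the signature ``Z``)."""

    values: np.ndarray
    gene_ids: list[str]
    type_ids: list[str]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        object.__setattr__(self, "type_ids", _check_unique(self.type_ids, "cell-type"))
        if values.ndim != 2 or values.shape != (len(self.gene_ids), len(self.type_ids)):
            raise ValidationError(
                f"signature shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.type_ids)} types"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("signature contains non-finite entries")
        if np.any(values < 0):
            raise ValidationError("signature contains negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.type_ids)

    def subset_genes(self, genes: Sequence[str]) -> "SignatureMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise AlignmentError(f"genes not in signature: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return SignatureMatrix(self.values[rows], list(genes), list(self.type_ids))


@dataclass(frozen=True)
class CellScaleFactors:
    """Per-cell-type size multipliers ``s`` (strictly positive).

    Units are arbitrary but must be consistent across types; only ratios
    matter because estimated proportions are renormalized to sum to one.
    """

    sizes: Mapping[str, float]

    def __post_init__(self):
        sizes = {str(k): float(v) for k, v in dict(self.sizes).items()}
        for k, v in sizes.items():
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"scale factor for {k!r} must be positive and finite, got {v}")
        object.__setattr__(self, "sizes", sizes)

    def vector(self, type_ids: Sequence[str]) -> np.ndarray:
        missing = [t for t in type_ids if t not in self.sizes]
        if missing:
            raise AlignmentError(f"no scale factor for cell type(s): {missing}")
        return np.array([self.sizes[t] for t in type_ids], dtype=float)

    def inverse(self) -> "CellScaleFactors":
        return CellScaleFactors({k: 1.0 / v for k, v in self.sizes.items()})

    def __contains__(self, t: str) -> bool:
        return t in self.sizes


@dataclass(frozen=True)
class ProportionMatrix:
    """Cell-type proportions, K types x J samples; columns sum to one."""

    values: np.ndarray
    type_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "type_ids", _check_unique(self.type_ids, "cell-type"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        if values.shape != (len(self.type_ids), len(self.sample_ids)):
            raise ValidationError(
                f"proportion shape {values.shape} does not match "
                f"{len(self.type_ids)} types x {len(self.sample_ids)} samples"
            )
        if np.any(values < -PROPORTION_TOL):
            raise ValidationError("proportions contain negative entries")
        colsums = values.sum(axis=0)
        bad = np.where(np.abs(colsums - 1.0) > PROPORTION_TOL)[0]
        if bad.size:
            raise ValidationError(
                f"proportion columns must sum to 1 (sample {self.sample_ids[bad[0]]} "
                f"sums to {colsums[bad[0]]:.6g})"
            )

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.type_ids, columns=self.sample_ids)

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]


#: recognised expression-unit tags for bulk matrices
BULK_UNITS = ("counts", "cpm", "rpkm", "tpm", "lognorm")


@dataclass(frozen=True)
class BulkMatrix:
    """Bulk (or pseudobulk) expression, genes x samples."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    unit: str = "counts"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", _check_unique(self.gene_ids, "gene"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"bulk shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.unit not in BULK_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {BULK_UNITS}")
        if self.unit != "lognorm" and np.any(values < 0):
            raise ValidationError(f"negative entries not allowed for unit {self.unit!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str], fill_missing: bool = False) -> "BulkMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        if fill_missing:
            out = np.zeros((len(genes), self.n_samples))
            for r, g in enumerate(genes):
                if g in idx:
                    out[r] = self.values[idx[g]]
            return BulkMatrix(out, list(genes), list(self.sample_ids), self.unit)
        missing = [g for g in genes if g not in idx]
        if missing:
            raise AlignmentError(f"genes not in bulk matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return BulkMatrix(self.values[rows], list(genes), list(self.sample_ids), self.unit)


@dataclass
class SingleCellDataset:
    """Single-cell/nucleus counts with per-cell type, sample and batch labels.

    ``hierarchy`` maps fine cell-type labels to coarse ones (e.g. Excit ->
    neuron) so a signature can be built at either resolution.
    """

    counts: sp.spmatrix | np.ndarray  # genes x cells, nonnegative integers
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type: list[str]
    sample_id: list[str]
    batch_id: list[str]
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for name, labels in (
            ("cell_type", self.cell_type),
            ("sample_id", self.sample_id),
            ("batch_id", self.batch_id),
        ):
            if len(labels) != n_cells:
                raise ValidationError(f"{name} has {len(labels)} labels for {n_cells} cells")
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError("counts must be nonnegative integers")
        present = set(self.cell_type)
        if self.hierarchy:
            unmapped = present - set(self.hierarchy)
            if unmapped:
                raise ValidationError(f"hierarchy does not map cell types: {sorted(unmapped)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def mapped_types(self, level: Mapping[str, str] | None = None) -> list[str]:
        """Per-cell labels after mapping through ``level`` (or the stored hierarchy)."""
        mapping = dict(level) if level is not None else self.hierarchy
        if not mapping:
            return list(self.cell_type)
        return [mapping.get(t, t) for t in self.cell_type]

    def obs(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_type": self.cell_type, "sample_id": self.sample_id, "batch_id": self.batch_id},
            index=self.cell_ids,
        )


@dataclass(frozen=True)
class AlignmentReport:
    dropped_genes_bulk: list[str]
    dropped_genes_signature: list[str]
    dropped_types_signature: list[str]
    n_shared_genes: int
    n_shared_types: int

    @property
    def empty(self) -> bool:
        return not (
            self.dropped_genes_bulk
            or self.dropped_genes_signature
            or self.dropped_types_signature
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def apply_scale_factors(Z: SignatureMatrix, s: CellScaleFactors) -> SignatureMatrix:
    """Rescale each signature column by its cell-size factor: Z' = Z . diag(s).

    Column k of the result is column k of ``Z`` times ``s[k]``; gene and type
    ordering is preserved.  Raises :class:`AlignmentError` when a type in ``Z``
    has no factor in ``s``.
    """
    svec = s.vector(Z.type_ids)
    return SignatureMatrix(Z.values * svec[None, :], list(Z.gene_ids), list(Z.type_ids))


def normalize_proportions(q: np.ndarray) -> tuple[np.ndarray, bool]:
    """Project a nonnegative coefficient vector onto the simplex by q / sum(q).

    Returns ``(proportions, degenerate)``.  An all-zero input has no defined
    direction; it maps to the uniform vector with ``degenerate=True`` so the
    result matrix stays valid while the pathology is flagged.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValidationError("coefficient vector has negative entries")
    total = q.sum()
    if total == 0:
        return np.full(q.shape, 1.0 / q.size), True
    return q / total, False


def align(
    Y: BulkMatrix, Z: SignatureMatrix, s: CellScaleFactors | None = None
) -> tuple[BulkMatrix, SignatureMatrix, CellScaleFactors | None, AlignmentReport]:
    """Restrict Y, Z (and s) to shared genes and types, in the signature's order.

    The signature is the reference object: shared genes keep ``Z``'s gene
    order and shared types keep ``Z``'s type order, so alignment is
    deterministic and idempotent.
    """
    y_genes = set(Y.gene_ids)
    shared_genes = [g for g in Z.gene_ids if g in y_genes]
    if not shared_genes:
        raise AlignmentError("no shared genes between bulk and signature")
    dropped_genes_sig = [g for g in Z.gene_ids if g not in y_genes]
    z_genes = set(shared_genes)
    dropped_genes_bulk = [g for g in Y.gene_ids if g not in z_genes]

    if s is not None:
        shared_types = [t for t in Z.type_ids if t in s]
    else:
        shared_types = list(Z.type_ids)
    dropped_types = [t for t in Z.type_ids if t not in shared_types]
    if len(shared_types) < 2:
        raise AlignmentError(
            f"fewer than 2 shared cell types after alignment ({shared_types})"
        )

    gidx = {g: i for i, g in enumerate(Z.gene_ids)}
    tidx = {t: i for i, t in enumerate(Z.type_ids)}
    Z_out = SignatureMatrix(
        Z.values[np.ix_([gidx[g] for g in shared_genes], [tidx[t] for t in shared_types])],
        shared_genes,
        shared_types,
    )
    Y_out = Y.subset_genes(shared_genes)
    s_out = None
    if s is not None:
        s_out = CellScaleFactors({t: s.sizes[t] for t in shared_types})
    report = AlignmentReport(
        dropped_genes_bulk=dropped_genes_bulk,
        dropped_genes_signature=dropped_genes_sig,
        dropped_types_signature=dropped_types,
        n_shared_genes=len(shared_genes),
        n_shared_types=len(shared_types),
    )
    return Y_out, Z_out, s_out, report
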