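"""Reference construction: signatures, Mean Ratio markers, downsampling, QC.

The signature matrix is the per-type arithmetic mean of single-cell (or
single-nucleus) expression profiles.  Marker genes are ranked per target type
by the Mean Ratio statistic: the gene's mean expression in the target type
divided by its highest mean among the remaining types.  A ratio well above 1
marks a gene whose expression is specific to the target type.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse as sp

from .datamodel import (
    BulkMatrix,
    SignatureMatrix,
    SingleCellDataset,
    ValidationError,
)

__all__ = [
    "MarkerTable",
    "QCReport",
    "build_signature",
    "type_means",
    "mean_ratio_markers",
    "concordant_markers",
    "downsample_batches",
    "qc_filter_bulk",
    "normalize_bulk",
]

# bulk QC defaults: minimum total marker counts and maximum number of
# zero-expression markers tolerated per sample
QC_MIN_MARKER_COUNTS = 38_750
QC_MAX_ZERO_MARKERS = 30


@dataclass(frozen=True)
class MarkerTable:
    """Ranked marker genes per target cell type.

    ``table`` columns: gene_id, target_type, mean_ratio, rank.  Within each
    target type ranks run 1..n with nonincreasing mean_ratio; infinite ratios
    (no off-target expression at all) rank above every finite ratio.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "target_type", "mean_ratio", "rank"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"marker table missing columns: {sorted(missing)}")
        for t, grp in self.table.groupby("target_type"):
            if grp["gene_id"].duplicated().any():
                raise ValidationError(f"duplicate gene for target type {t!r}")
            ranks = np.sort(grp["rank"].to_numpy())
            if not np.array_equal(ranks, np.arange(1, len(grp) + 1)):
                raise ValidationError(f"ranks for {t!r} are not 1..n")
            ordered = grp.sort_values("rank")["mean_ratio"].to_numpy()
            if np.any(np.diff(ordered) > 1e-12):
                raise ValidationError(f"mean_ratio not nonincreasing for {t!r}")

    @property
    def genes(self) -> list[str]:
        """Union of marker genes across target types (first-seen order)."""
        return list(dict.fromkeys(self.table.sort_values(["target_type", "rank"])["gene_id"]))

    def for_type(self, target_type: str) -> pd.DataFrame:
        return (
            self.table[self.table["target_type"] == target_type]
            .sort_values("rank")
            .reset_index(drop=True)
        )

    def top(self, n: int) -> "MarkerTable":
        sub = self.table[self.table["rank"] <= n].reset_index(drop=True)
        return MarkerTable(sub)


@dataclass(frozen=True)
class QCReport:
    """Per-sample marker-expression QC summary."""

    table: pd.DataFrame  # sample_id, total_marker_counts, zero_markers, pass
    min_counts: float
    max_zeros: int

    @property
    def passed(self) -> list[str]:
        return list(self.table.loc[self.table["pass"], "sample_id"])

    @property
    def failed(self) -> list[str]:
        return list(self.table.loc[~self.table["pass"], "sample_id"])


def type_means(
    sc: SingleCellDataset,
    level: Mapping[str, str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-type mean expression (genes x types DataFrame), after label mapping."""
    labels = np.asarray(sc.mapped_types(level))
    types = sorted(set(labels))
    if genes is not None:
        gidx = {g: i for i, g in enumerate(sc.gene_ids)}
        missing = [g for g in genes if g not in gidx]
        if missing:
            raise ValidationError(f"genes not in dataset: {missing[:5]}")
        rows = [gidx[g] for g in genes]
        counts = sc.counts[rows] if sp.issparse(sc.counts) else np.asarray(sc.counts)[rows]
        gene_ids = list(genes)
    else:
        counts = sc.counts
        gene_ids = list(sc.gene_ids)
    out = np.empty((len(gene_ids), len(types)))
    for k, t in enumerate(types):
        mask = labels == t
        sub = counts[:, mask]
        if sp.issparse(sub):
            out[:, k] = np.asarray(sub.mean(axis=1)).ravel()
        else:
            out[:, k] = np.asarray(sub, dtype=float).mean(axis=1)
    return pd.DataFrame(out, index=gene_ids, columns=types)


def build_signature(
    sc: SingleCellDataset,
    level: Mapping[str, str] | None = None,
    genes: Sequence[str] | None = None,
) -> SignatureMatrix:
    """Build a signature matrix as the per-type mean expression profile.

    Entry (g, k) is the arithmetic mean of gene g over all cells assigned to
    type k after mapping fine labels through ``level`` (or the dataset's
    stored hierarchy).  Every requested type must have at least one cell.
    """
    labels = sc.mapped_types(level)
    counts_per_type = pd.Series(labels).value_counts()
    empty = [t for t, n in counts_per_type.items() if n == 0]
    if level is not None:
        requested = set(level.values())
        empty.extend(sorted(requested - set(labels)))
    if empty:
        raise ValidationError(f"cell type(s) with zero cells: {sorted(set(empty))}")
    means = type_means(sc, level=level, genes=genes)
    return SignatureMatrix(means.to_numpy(), list(means.index), list(means.columns))


def mean_ratio_markers(
    source: SingleCellDataset | SignatureMatrix | pd.DataFrame,
    n_per_type: int,
    level: Mapping[str, str] | None = None,
) -> MarkerTable:
    """Select the top ``n_per_type`` Mean Ratio marker genes per cell type.

    For gene g and target type k,

        mean_ratio(g, k) = mean_k(g) / max_{k' != k} mean_{k'}(g)

    Genes are ranked per target type by descending ratio.  When the off-target
    maximum is zero the ratio is infinite; infinite-ratio genes rank above all
    finite ones, ordered among themselves by descending target-type mean, then
    lexicographic gene id (the same tie-break applies to equal finite ratios).
    The statistic is computed on whatever expression representation is
    supplied — no hidden normalization.
    """
    if n_per_type < 1:
        raise ValidationError("n_per_type must be a positive integer")
    if isinstance(source, SingleCellDataset):
        means = type_means(source, level=level)
    elif isinstance(source, SignatureMatrix):
        means = source.to_frame()
    else:
        means = source
    if means.shape[1] < 2:
        raise ValidationError("mean ratio requires at least 2 cell types")
    if n_per_type > means.shape[0]:
        warnings.warn(
            f"n_per_type={n_per_type} exceeds the {means.shape[0]} available genes; "
            "returning all genes",
            stacklevel=2,
        )

    M = means.to_numpy(dtype=float)
    gene_ids = np.asarray(means.index.astype(str))
    rows = []
    for k, target in enumerate(means.columns):
        target_mean = M[:, k]
        off = np.delete(M, k, axis=1)
        off_max = off.max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(off_max > 0, target_mean / np.where(off_max > 0, off_max, 1.0), np.inf)
        # genes silent everywhere carry no information: 0/0 -> ratio 0
        silent = (target_mean == 0) & (off_max == 0)
        ratio = np.where(silent, 0.0, ratio)
        # sort: descending ratio, then descending target mean, then gene id
        order = sorted(
            range(len(gene_ids)),
            key=lambda i: (-ratio[i], -target_mean[i], gene_ids[i]),
        )
        take = order[: min(n_per_type, len(order))]
        for rank, i in enumerate(take, start=1):
            rows.append((gene_ids[i], str(target), float(ratio[i]), rank))
    table = pd.DataFrame(rows, columns=["gene_id", "target_type", "mean_ratio", "rank"])
    return MarkerTable(table)


def concordant_markers(
    tables: Sequence[MarkerTable], min_runs: int
) -> pd.DataFrame:
    """Cross-run marker filter: keep (gene, type) pairs selected in >= min_runs runs.

    Operationalizes marker concordance across per-sample selection runs (e.g.
    independent slides).  Returns gene_id, target_type, n_runs sorted by
    support.  Off by default in the pipeline; apply when multiple per-sample
    marker tables exist.
    """
    if min_runs < 1 or min_runs > len(tables):
        raise ValidationError(f"min_runs must be in 1..{len(tables)}")
    pairs = pd.concat(
        [t.table[["gene_id", "target_type"]] for t in tables], ignore_index=True
    )
    counts = (
        pairs.value_counts().rename("n_runs").reset_index()
    )
    keep = counts[counts["n_runs"] >= min_runs]
    return keep.sort_values(
        ["n_runs", "target_type", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def downsample_batches(sc: SingleCellDataset, seed: int) -> SingleCellDataset:
    """Equalize library sizes across batches within each cell type by thinning.

    Within each cell type, the batch "library size" is the median per-cell
    total count in the batch x type stratum (robust to outlier cells).  Cells
    in a batch are binomially thinned with retention probability
    ``L_min / L_batch`` (capped at 1), where ``L_min`` is the smallest batch
    library size for that type.  Seeded and fully reproducible.
    """
    rng = np.random.default_rng(seed)
    dense = sc.dense_counts()
    totals = dense.sum(axis=0)
    ctype = np.asarray(sc.cell_type)
    batch = np.asarray(sc.batch_id)
    out = dense.copy()
    for t in sorted(set(ctype)):
        tmask = ctype == t
        batches = sorted(set(batch[tmask]))
        lib = {}
        for b in batches:
            bmask = tmask & (batch == b)
            if not bmask.any():
                warnings.warn(f"empty batch {b!r} for type {t!r}; skipped", stacklevel=2)
                continue
            lib[b] = float(np.median(totals[bmask]))
        if not lib:
            continue
        L_min = min(lib.values())
        for b, L in lib.items():
            p = 1.0 if L <= 0 else min(1.0, L_min / L)
            if p >= 1.0:
                continue
            bmask = tmask & (batch == b)
            block = out[:, bmask]
            out[:, bmask] = rng.binomial(block.astype(np.int64), p)
    return SingleCellDataset(
        counts=out.astype(np.int64),
        gene_ids=list(sc.gene_ids),
        cell_ids=list(sc.cell_ids),
        cell_type=list(sc.cell_type),
        sample_id=list(sc.sample_id),
        batch_id=list(sc.batch_id),
        hierarchy=dict(sc.hierarchy),
    )


def qc_filter_bulk(
    Y: BulkMatrix,
    markers: Sequence[str],
    min_counts: float = QC_MIN_MARKER_COUNTS,
    max_zeros: int = QC_MAX_ZERO_MARKERS,
) -> tuple[BulkMatrix, QCReport]:
    """Drop bulk samples with too little marker signal.

    A sample passes when its total counts over the marker set are at least
    ``min_counts`` and at most ``max_zeros`` markers have zero expression.
    Markers absent from ``Y`` count as zero-expression markers.
    """
    markers = list(dict.fromkeys(markers))
    gidx = {g: i for i, g in enumerate(Y.gene_ids)}
    present = [g for g in markers if g in gidx]
    n_absent = len(markers) - len(present)
    sub = Y.values[[gidx[g] for g in present]] if present else np.zeros((0, Y.n_samples))
    totals = sub.sum(axis=0)
    zeros = (sub == 0).sum(axis=0) + n_absent
    passing = (totals >= min_counts) & (zeros <= max_zeros)
    report = QCReport(
        table=pd.DataFrame(
            {
                "sample_id": Y.sample_ids,
                "total_marker_counts": totals,
                "zero_markers": zeros.astype(int),
                "pass": passing,
            }
        ),
        min_counts=min_counts,
        max_zeros=max_zeros,
    )
    keep = [j for j, ok in enumerate(passing) if ok]
    if not keep:
        warnings.warn("no bulk samples pass marker QC", stacklevel=2)
    filtered = BulkMatrix(
        Y.values[:, keep],
        list(Y.gene_ids),
        [Y.sample_ids[j] for j in keep],
        Y.unit,
    )
    return filtered, report


def normalize_bulk(
    counts: BulkMatrix,
    gene_lengths: Mapping[str, float] | None = None,
    method: str = "rpkm",
    log2: bool = False,
    pseudocount: float = 1.0,
) -> BulkMatrix:
    """Library-size normalization of bulk counts (RPKM or CPM), optional log2.

    rpkm(g, j) = counts(g, j) * 1e9 / (libsize_j * length_g)
    cpm(g, j)  = counts(g, j) * 1e6 /  libsize_j

    With ``log2=True`` each value becomes log2(value + pseudocount).
    """
    if method not in ("rpkm", "cpm"):
        raise ValidationError(f"unknown normalization method {method!r}")
    libsize = counts.values.sum(axis=0)
    if np.any(libsize == 0):
        zero = [counts.sample_ids[j] for j in np.where(libsize == 0)[0]]
        raise ValidationError(f"zero library size for sample(s): {zero}")
    if method == "rpkm":
        if gene_lengths is None:
            raise ValidationError("rpkm requires gene lengths")
        missing = [g for g in counts.gene_ids if g not in gene_lengths]
        if missing:
            raise ValidationError(f"missing gene length for: {missing[:5]}")
        lengths = np.array([float(gene_lengths[g]) for g in counts.gene_ids])
        if np.any(lengths <= 0):
            raise ValidationError("gene lengths must be positive")
        vals = counts.values * 1e9 / (libsize[None, :] * lengths[:, None])
        unit = "rpkm"
    else:
        vals = counts.values * 1e6 / libsize[None, :]
        unit = "cpm"
    if log2:
        vals = np.log2(vals + pseudocount)
        unit = "lognorm"
    return BulkMatrix(vals, list(counts.gene_ids), list(counts.sample_ids), unit)
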