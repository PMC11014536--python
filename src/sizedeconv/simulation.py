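"""Pseudobulk generation, proportion grids, shuffle experiments, synthetic data.

A pseudobulk sample is the exact matrix product Y = Z . diag(s) . P: the
signature times the cell-size factors times known proportions.  Because the
generative model matches the deconvolution model, recovery with the correct
factors is exact (to solver precision), which makes pseudobulks the ground
truth for benchmarking.

Shuffle experiments deliberately mismatch the five terms of the generative
equation between the pseudobulk side and the deconvolution side —
Z_pseudobulk, S_pseudobulk, P_pseudobulk versus Z_deconvolution,
S_deconvolution — to probe how robust proportion estimates are when the
reference or the cell sizes come from a different sample than the mixture.

The synthetic single-cell generator draws negative-binomial counts with
cell-type marker structure so the whole pipeline (signature building, marker
selection, deconvolution, evaluation) is testable without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    BulkMatrix,
    CellScaleFactors,
    ProportionMatrix,
    SignatureMatrix,
    SingleCellDataset,
    ValidationError,
)
from .deconvolution import deconvolute
from .evaluation import rmse

__all__ = [
    "SHUFFLE_TERMS",
    "ShuffleDesign",
    "ShuffleSample",
    "SynthConfig",
    "pseudobulk",
    "proportion_grid",
    "run_shuffle",
    "synth_sc",
]


def pseudobulk(
    Z: SignatureMatrix,
    s: CellScaleFactors | None,
    P: ProportionMatrix,
) -> BulkMatrix:
    """Generate bulk expression as the exact product Y = Z . diag(s) . P."""
    if list(P.type_ids) != list(Z.type_ids):
        if set(P.type_ids) != set(Z.type_ids):
            raise ValidationError(
                f"cell types differ: signature {Z.type_ids} vs proportions {P.type_ids}"
            )
        order = [P.type_ids.index(t) for t in Z.type_ids]
        P = ProportionMatrix(P.values[order], list(Z.type_ids), list(P.sample_ids))
    svec = s.vector(Z.type_ids) if s is not None else np.ones(Z.n_types)
    Y = Z.values @ (svec[:, None] * P.values)
    return BulkMatrix(Y, list(Z.gene_ids), list(P.sample_ids), unit="counts")


def proportion_grid(
    n_samples: int,
    p_min: float,
    p_max: float,
    type_ids: Sequence[str] = ("neuron", "glial"),
    allocation: Sequence[float] | None = None,
) -> ProportionMatrix:
    """Evenly spaced mixture grid for the first cell type.

    The first type's proportion runs from ``p_min`` to ``p_max`` inclusive
    over ``n_samples`` columns; the complement is split among the remaining
    types, uniformly or per ``allocation`` (a nonnegative weight vector over
    the remaining K-1 types).
    """
    if n_samples < 2:
        raise ValidationError("need at least 2 grid samples")
    if not (0 <= p_min < p_max <= 1):
        raise ValidationError(f"invalid proportion range [{p_min}, {p_max}]")
    K = len(type_ids)
    if K < 2:
        raise ValidationError("need at least 2 cell types")
    first = np.linspace(p_min, p_max, n_samples)
    if allocation is None:
        alloc = np.full(K - 1, 1.0 / (K - 1))
    else:
        alloc = np.asarray(allocation, dtype=float)
        if alloc.size != K - 1 or np.any(alloc < 0) or alloc.sum() == 0:
            raise ValidationError("allocation must be a nonnegative weight vector of length K-1")
        alloc = alloc / alloc.sum()
    values = np.vstack([first, np.outer(alloc, 1.0 - first)])
    sample_ids = [f"mix{j + 1:02d}" for j in range(n_samples)]
    return ProportionMatrix(values, list(type_ids), sample_ids)


# ---------------------------------------------------------------------------
# shuffle experiments
# ---------------------------------------------------------------------------

SHUFFLE_TERMS = (
    "Z_pseudobulk",
    "S_pseudobulk",
    "P_pseudobulk",
    "Z_deconvolution",
    "S_deconvolution",
)


@dataclass(frozen=True)
class ShuffleSample:
    """One library entry: a sample's reference, cell sizes and true proportions."""

    Z: SignatureMatrix
    s: CellScaleFactors
    P: ProportionMatrix  # single column: this sample's composition


@dataclass(frozen=True)
class ShuffleDesign:
    """Binding of the five generative/deconvolution terms for a shuffle run.

    Each term is bound to ``"matched"`` (the base sample's own object),
    ``"shuffle"`` (a seeded draw, without replacement, from the other library
    samples), or an explicit sample id (fixed across runs).  ``held_constant``
    names the term that is fixed; it must be bound to an explicit sample id.
    """

    bindings: dict[str, str]
    held_constant: str | None = None
    seed: int = 0

    def __post_init__(self):
        missing = set(SHUFFLE_TERMS) - set(self.bindings)
        if missing:
            raise ValidationError(f"unbound shuffle terms: {sorted(missing)}")
        extra = set(self.bindings) - set(SHUFFLE_TERMS)
        if extra:
            raise ValidationError(f"unknown shuffle terms: {sorted(extra)}")
        if self.held_constant is not None:
            if self.held_constant not in SHUFFLE_TERMS:
                raise ValidationError(f"unknown held_constant term {self.held_constant!r}")
            if self.bindings[self.held_constant] in ("matched", "shuffle"):
                raise ValidationError(
                    "held_constant term must be bound to an explicit sample id"
                )

    @classmethod
    def matched(cls, seed: int = 0) -> "ShuffleDesign":
        return cls(bindings={t: "matched" for t in SHUFFLE_TERMS}, seed=seed)


def _shuffle_assignment(sample_ids: list[str], rng: np.random.Generator) -> dict[str, str]:
    """Seeded derangement-style permutation: each sample draws another sample."""
    n = len(sample_ids)
    if n < 2:
        raise ValidationError("need at least 2 library samples for a shuffle")
    perm = rng.permutation(n)
    # repair fixed points so no sample draws itself
    for i in np.where(perm == np.arange(n))[0]:
        j = (i + 1) % n
        perm[i], perm[j] = perm[j], perm[i]
    return {sample_ids[i]: sample_ids[perm[i]] for i in range(n)}


def run_shuffle(
    design: ShuffleDesign,
    library: Mapping[str, ShuffleSample],
) -> pd.DataFrame:
    """Run one shuffle experiment over every sample in the library.

    For each base sample, the pseudobulk-side terms generate
    Y = Z_pb . diag(S_pb) . P_pb and the deconvolution-side terms estimate
    proportions from Y.  The known truth is always P_pseudobulk.  Runs whose
    shuffled terms have inconsistent cell-type sets are skipped with a
    warning.  Returns one row per run with term sources, RMSE and per-type
    signed errors (predicted minus known).
    """
    sample_ids = list(library)
    rng = np.random.default_rng(design.seed)
    assignments: dict[str, dict[str, str]] = {}
    for term in SHUFFLE_TERMS:
        if design.bindings[term] == "shuffle":
            assignments[term] = _shuffle_assignment(sample_ids, rng)

    def resolve(term: str, base: str) -> str:
        binding = design.bindings[term]
        if binding == "matched":
            return base
        if binding == "shuffle":
            return assignments[term][base]
        if binding not in library:
            raise ValidationError(f"sample {binding!r} bound to {term} not in library")
        return binding

    rows = []
    for base in sample_ids:
        src = {term: resolve(term, base) for term in SHUFFLE_TERMS}
        Z_pb = library[src["Z_pseudobulk"]].Z
        s_pb = library[src["S_pseudobulk"]].s
        P_pb = library[src["P_pseudobulk"]].P
        Z_dc = library[src["Z_deconvolution"]].Z
        s_dc = library[src["S_deconvolution"]].s
        type_sets = [set(Z_pb.type_ids), set(P_pb.type_ids), set(Z_dc.type_ids),
                     set(s_pb.sizes), set(s_dc.sizes)]
        if any(ts != type_sets[0] for ts in type_sets[1:]):
            warnings.warn(
                f"run {base!r} skipped: inconsistent cell-type sets across shuffled terms",
                stacklevel=2,
            )
            continue
        Y = pseudobulk(Z_pb, s_pb, P_pb)
        result = deconvolute(Y, Z_dc, s_dc)
        pred = result.proportions
        known_vec = P_pb.to_frame().iloc[:, 0].reindex(pred.type_ids).to_numpy()
        pred_vec = pred.values[:, 0]
        row = {"run": base, **{f"src_{t}": src[t] for t in SHUFFLE_TERMS}}
        row["rmse"] = rmse(known_vec, pred_vec, pooling="pooled")
        for k, t in enumerate(pred.type_ids):
            row[f"err_{t}"] = float(pred_vec[k] - known_vec[k])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic single-cell fixture generator
# ---------------------------------------------------------------------------

def _default_type_ids(n_types: int) -> tuple[str, ...]:
    if n_types == 2:
        return ("neuron", "glial")
    if n_types == 3:
        return ("Excit", "Inhib", "glial")
    return tuple(f"type{k + 1}" for k in range(n_types))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the negative-binomial single-cell generator.

    Marker genes of type k have NB mean ``nb_mean * marker_fold_change *
    size_factor_k`` in type-k cells and ``nb_mean`` elsewhere; non-marker
    genes have mean ``nb_mean`` in every type.  The size factor enters the
    marker means because larger cells carry proportionally more transcripts
    of their own marker genes.  ``nb_dispersion`` is the NB size parameter
    (variance = mu + mu^2 / dispersion), shared across genes.  Per-batch
    multipliers (mean 1 across batches) emulate library-size differences
    between sequencing batches.
    """

    n_genes: int = 200
    n_types: int = 2
    markers_per_type: int = 40
    cells_per_type: int = 500
    nb_mean: float = 5.0
    nb_dispersion: float = 2.0
    marker_fold_change: float = 8.0
    size_factors: Mapping[str, float] | None = None
    type_ids: tuple[str, ...] | None = None
    n_donors: int = 3
    batch_libsize_factors: tuple[float, ...] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_types, self.markers_per_type, self.cells_per_type) < 1:
            raise ValidationError("all synthetic counts must be positive")
        if self.n_types < 2:
            raise ValidationError("need at least 2 cell types")
        if self.marker_fold_change <= 1:
            raise ValidationError("marker fold change must exceed 1")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("nb_mean and nb_dispersion must be positive")
        if self.n_genes < self.n_types * self.markers_per_type:
            raise ValidationError(
                f"n_genes={self.n_genes} cannot hold "
                f"{self.n_types} x {self.markers_per_type} markers"
            )
        if abs(float(np.mean(self.batch_libsize_factors)) - 1.0) > 1e-9:
            raise ValidationError("batch library-size factors must average to 1")
        types = self.type_ids or _default_type_ids(self.n_types)
        if len(types) != self.n_types:
            raise ValidationError("type_ids length must equal n_types")
        object.__setattr__(self, "type_ids", tuple(types))
        if self.size_factors is None:
            if self.n_types == 2:
                sf = {"neuron": 10.0, "glial": 3.0}
            else:
                sf = {t: 1.0 for t in types}
            object.__setattr__(self, "size_factors", sf)

    def scale_factors(self) -> CellScaleFactors:
        return CellScaleFactors(self.size_factors)


def synth_sc(
    config: SynthConfig,
) -> tuple[SingleCellDataset, SignatureMatrix, CellScaleFactors]:
    """Draw a synthetic single-cell dataset with known generating parameters.

    Returns the dataset, the true signature matrix (the NB mean of every gene
    in every type) and the true cell-size factors.  Bit-reproducible from
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.type_ids)
    s = cfg.scale_factors()
    svec = s.vector(types)

    marker_ids = [
        f"mk_{t}_{i + 1:03d}" for t in types for i in range(cfg.markers_per_type)
    ]
    n_bg = cfg.n_genes - len(marker_ids)
    gene_ids = marker_ids + [f"bg_{i + 1:04d}" for i in range(n_bg)]

    # genes x types matrix of generating NB means
    mu = np.full((cfg.n_genes, len(types)), cfg.nb_mean, dtype=float)
    for k in range(len(types)):
        rows = slice(k * cfg.markers_per_type, (k + 1) * cfg.markers_per_type)
        mu[rows, k] = cfg.nb_mean * cfg.marker_fold_change * svec[k]
    Z_true = SignatureMatrix(mu, gene_ids, types)

    n_cells = cfg.cells_per_type * len(types)
    cell_type = [t for t in types for _ in range(cfg.cells_per_type)]
    cell_ids = [f"cell{c + 1:05d}" for c in range(n_cells)]
    batches = [f"batch{(c % len(cfg.batch_libsize_factors)) + 1}" for c in range(n_cells)]
    donors = [f"donor{(c % cfg.n_donors) + 1}" for c in range(n_cells)]
    batch_mult = np.array(
        [cfg.batch_libsize_factors[c % len(cfg.batch_libsize_factors)] for c in range(n_cells)]
    )

    counts = np.empty((cfg.n_genes, n_cells), dtype=np.int64)
    size = cfg.nb_dispersion
    for k, t in enumerate(types):
        cols = np.array([c for c in range(n_cells) if cell_type[c] == t])
        cell_mu = mu[:, [k]] * batch_mult[cols][None, :]
        p = size / (size + cell_mu)
        counts[:, cols] = rng.negative_binomial(size, p)

    sc = SingleCellDataset(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_type=cell_type,
        sample_id=donors,
        batch_id=batches,
        hierarchy={t: t for t in types},
    )
    return sc, Z_true, s
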