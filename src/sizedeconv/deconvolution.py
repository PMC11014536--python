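"""Proportion estimation by NNLS on the (optionally size-rescaled) signature.

For each bulk sample y_j the built-in algorithm solves

    q_j = argmin_{q >= 0} || y_j - Z' q ||_2,    Z' = Z . diag(s)

with the Lawson-Hanson active-set solver, then renormalizes q_j to the
simplex so proportions sum to one.  Without ``s`` the signature is used as
supplied, i.e. cell sizes are assumed equal — on data generated with unequal
sizes this recovers the RNA fraction per type, over-predicting large cell
types and under-predicting small ones.

Alternative algorithms (MuSiC, Bisque, EPIC, DeconRNASeq, ...) plug in
through :class:`AlgorithmAdapter`; the size-rescaled signature is handed to
the adapter transparently, so any reference-based method gains the cell-size
adjustment without modification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.optimize

from .datamodel import (
    AlignmentReport,
    BulkMatrix,
    CellScaleFactors,
    ProportionMatrix,
    SignatureMatrix,
    ValidationError,
    align,
    apply_scale_factors,
    normalize_proportions,
)

__all__ = [
    "DeconvolutionResult",
    "AlgorithmAdapter",
    "nnls_solve",
    "deconvolute",
    "register_algorithm",
    "unregister_algorithm",
    "list_algorithms",
    "independent_bulk_filter",
]


@dataclass(frozen=True)
class DeconvolutionResult:
    """Estimated proportions plus the raw (pre-normalization) coefficients."""

    proportions: ProportionMatrix
    raw_coefficients: np.ndarray  # K x J, nonnegative
    algorithm: str
    scaled: bool
    degenerate_samples: list[str] = field(default_factory=list)
    alignment: AlignmentReport | None = None

    def __post_init__(self):
        if np.any(self.raw_coefficients < 0):
            raise ValidationError("raw coefficients must be nonnegative")


# an adapter maps (Y values, signature values already size-rescaled) to a
# K x J nonnegative coefficient matrix; column j is the raw solution for
# sample j before simplex normalization
AdapterFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class AlgorithmAdapter:
    """Uniform wrapper contract for deconvolution algorithms.

    ``required_inputs`` documents what the wrapped method consumes:
    "signature-based" (a G x K reference, like NNLS/DeconRNASeq),
    "single-cell-based" (cell-level counts, like MuSiC/Bisque), or
    "independent-bulk" (bulk samples disjoint from the reference source).
    The callable always receives the signature with cell-size factors already
    applied, so every registered method is size-aware for free.
    """

    name: str
    fn: AdapterFn
    required_inputs: str = "signature-based"

    def __post_init__(self):
        if not self.name:
            raise ValidationError("adapter name must be non-empty")
        if self.required_inputs not in (
            "signature-based",
            "single-cell-based",
            "independent-bulk",
        ):
            raise ValidationError(f"unknown required_inputs {self.required_inputs!r}")


def nnls_solve(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Nonnegative least squares: argmin_{q>=0} ||y - A q||_2 (Lawson-Hanson)."""
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y))):
        raise ValidationError("nnls inputs must be finite")
    if A.ndim != 2 or y.ndim != 1 or A.shape[0] != y.size:
        raise ValidationError(f"incompatible shapes A {A.shape}, y {y.shape}")
    if A.shape[0] < A.shape[1]:
        raise ValidationError("underdetermined system: need G >= K")
    q, _ = scipy.optimize.nnls(A, y)
    return q


def _nnls_adapter(Y: np.ndarray, Zp: np.ndarray) -> np.ndarray:
    out = np.empty((Zp.shape[1], Y.shape[1]))
    for j in range(Y.shape[1]):
        out[:, j] = nnls_solve(Zp, Y[:, j])
    return out


_REGISTRY: dict[str, AlgorithmAdapter] = {}


def register_algorithm(adapter: AlgorithmAdapter) -> None:
    """Register an adapter under its unique name."""
    if adapter.name in _REGISTRY:
        raise ValidationError(f"algorithm {adapter.name!r} is already registered")
    _REGISTRY[adapter.name] = adapter


def unregister_algorithm(name: str) -> None:
    if name == "nnls":
        raise ValidationError("the built-in 'nnls' algorithm cannot be removed")
    _REGISTRY.pop(name, None)


def list_algorithms() -> list[str]:
    return sorted(_REGISTRY)


register_algorithm(AlgorithmAdapter(name="nnls", fn=_nnls_adapter))


def independent_bulk_filter(
    Y: BulkMatrix, Z: SignatureMatrix
) -> tuple[BulkMatrix, list[str]]:
    """Restrict bulk samples to the signature's marker genes, in its order.

    For bulk cohorts collected independently of the reference, markers absent
    from ``Y`` are imputed as zero rows (and reported) rather than dropped, so
    the design matrix keeps the full marker panel.
    """
    missing = [g for g in Z.gene_ids if g not in set(Y.gene_ids)]
    out = Y.subset_genes(Z.gene_ids, fill_missing=True)
    return out, missing


def deconvolute(
    Y: BulkMatrix,
    Z: SignatureMatrix,
    s: CellScaleFactors | None = None,
    algorithm: str = "nnls",
) -> DeconvolutionResult:
    """Estimate cell-type proportions for every bulk sample.

    Aligns ``Y`` and ``Z`` (and ``s``) on shared genes/types, rescales the
    signature by the cell-size factors when given, runs the named algorithm,
    and renormalizes each sample's coefficient vector to the simplex.
    Samples whose raw solution is identically zero are mapped to uniform
    proportions and listed in ``degenerate_samples``.
    """
    if algorithm not in _REGISTRY:
        raise ValidationError(
            f"unregistered algorithm {algorithm!r}; registered: {list_algorithms()}"
        )
    Y_al, Z_al, s_al, report = align(Y, Z, s)
    if s_al is not None:
        Z_run = apply_scale_factors(Z_al, s_al)
    else:
        Z_run = Z_al
    adapter = _REGISTRY[algorithm]
    raw = np.asarray(adapter.fn(Y_al.values, Z_run.values), dtype=float)
    if raw.shape != (Z_run.n_types, Y_al.n_samples):
        raise ValidationError(
            f"adapter {algorithm!r} returned shape {raw.shape}, "
            f"expected {(Z_run.n_types, Y_al.n_samples)}"
        )
    if np.any(raw < 0):
        raise ValidationError(f"adapter {algorithm!r} returned negative coefficients")

    props = np.empty_like(raw)
    degenerate = []
    for j in range(raw.shape[1]):
        props[:, j], bad = normalize_proportions(raw[:, j])
        if bad:
            degenerate.append(Y_al.sample_ids[j])
    if degenerate:
        warnings.warn(
            f"all-zero coefficient vector(s) mapped to uniform proportions for "
            f"sample(s): {degenerate}",
            stacklevel=2,
        )
    return DeconvolutionResult(
        proportions=ProportionMatrix(props, list(Z_run.type_ids), list(Y_al.sample_ids)),
        raw_coefficients=raw,
        algorithm=algorithm,
        scaled=s is not None,
        degenerate_samples=degenerate,
        alignment=report,
    )
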