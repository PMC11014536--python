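"""Readers and writers for the toolkit's on-disk formats.

TSV is the canonical delimited dialect (tab, UTF-8, header row, "." decimal);
CSV is accepted on read by delimiter sniffing.  Matrix Market files follow
the 1-based index convention on disk; all in-memory coordinates are 0-based.
Writer/reader pairs round-trip bit-exactly for integer counts and to 1e-12
for reals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import (
    BulkMatrix,
    CellScaleFactors,
    ProportionMatrix,
    SignatureMatrix,
    SingleCellDataset,
    ValidationError,
)
from .reference import MarkerTable

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_bulk",
    "write_bulk",
    "read_signature",
    "write_signature",
    "read_proportions",
    "write_proportions",
    "read_scale_factors",
    "write_scale_factors",
    "read_marker_table",
    "write_marker_table",
    "read_gene_lengths",
    "read_single_cell",
    "write_single_cell",
    "load_synth_config",
    "load_shuffle_design",
    "write_run_manifest",
]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Headered matrix with ids in the first column; sniffs tab vs comma."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return _read_delimited(path)


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_bulk(path: str | Path, unit: str = "counts") -> BulkMatrix:
    frame = _read_delimited(path)
    return BulkMatrix(
        frame.to_numpy(dtype=float),
        [str(g) for g in frame.index],
        [str(s) for s in frame.columns],
        unit,
    )


def write_bulk(Y: BulkMatrix, path: str | Path) -> None:
    write_matrix(Y.to_frame(), path)


def read_signature(path: str | Path) -> SignatureMatrix:
    frame = _read_delimited(path)
    return SignatureMatrix(
        frame.to_numpy(dtype=float),
        [str(g) for g in frame.index],
        [str(t) for t in frame.columns],
    )


def write_signature(Z: SignatureMatrix, path: str | Path) -> None:
    write_matrix(Z.to_frame(), path)


def read_proportions(path: str | Path) -> ProportionMatrix:
    frame = _read_delimited(path)
    return ProportionMatrix(
        frame.to_numpy(dtype=float),
        [str(t) for t in frame.index],
        [str(s) for s in frame.columns],
    )


def write_proportions(P: ProportionMatrix, path: str | Path) -> None:
    write_matrix(P.to_frame(), path)


def read_scale_factors(path: str | Path) -> CellScaleFactors:
    """Two-column headered TSV: cell_type <TAB> size; sizes must be positive."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
        sizes: dict[str, float] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValidationError(f"{path.name}:{lineno}: expected 2 columns")
            t = parts[0].strip()
            try:
                v = float(parts[1])
            except ValueError:
                raise ValidationError(
                    f"{path.name}:{lineno}: non-numeric size {parts[1]!r}"
                ) from None
            if t in sizes:
                raise ValidationError(f"{path.name}:{lineno}: duplicate cell type {t!r}")
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{path.name}:{lineno}: size must be positive, got {v}")
            sizes[t] = v
    if not sizes:
        raise ValidationError(f"{path.name}: no scale factors found")
    return CellScaleFactors(sizes)


def write_scale_factors(s: CellScaleFactors, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cell_type\tsize\n")
        for t, v in s.sizes.items():
            fh.write(f"{t}\t{v:.17g}\n")


def read_marker_table(path: str | Path) -> MarkerTable:
    frame = pd.read_csv(path, sep="\t")
    frame["mean_ratio"] = frame["mean_ratio"].replace("inf", np.inf).astype(float)
    return MarkerTable(frame)


def write_marker_table(markers: MarkerTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = markers.table.copy()
    out["mean_ratio"] = out["mean_ratio"].map(
        lambda v: "inf" if np.isinf(v) else f"{v:.17g}"
    )
    out.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> dict[str, float]:
    """Two-column TSV gene_id, length_bp."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValidationError("gene-length table needs two columns")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(float)))


# ---------------------------------------------------------------------------
# single-cell MTX triplet
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ("cell_id", "cell_type", "sample_id", "batch_id")


def read_single_cell(directory: str | Path) -> SingleCellDataset:
    """Read an MTX triplet: matrix.mtx (genes x cells), genes.tsv, cells.tsv.

    cells.tsv must carry cell_id, cell_type, sample_id and batch_id columns;
    an optional hierarchy.json maps fine to coarse type labels.
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    if not mtx.exists():
        raise ValidationError(f"missing {mtx}")
    counts = scipy.io.mmread(mtx)  # mmread handles the 1-based MTX convention
    counts = sp.csc_matrix(counts)
    if counts.nnz == 0 and counts.shape[0] * counts.shape[1] == 0:
        raise ValidationError("empty single-cell matrix")
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")
    gene_col = "gene_id" if "gene_id" in genes.columns else genes.columns[0]
    gene_ids = [str(g) for g in genes[gene_col]]
    cells = pd.read_csv(directory / "cells.tsv", sep="\t")
    missing = [c for c in _CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cells.tsv missing column(s): {missing}")
    if counts.shape != (len(gene_ids), len(cells)):
        raise ValidationError(
            f"matrix is {counts.shape[0]} genes x {counts.shape[1]} cells but "
            f"sidecars list {len(gene_ids)} genes and {len(cells)} cells"
        )
    hierarchy = {}
    hpath = directory / "hierarchy.json"
    if hpath.exists():
        hierarchy = {str(k): str(v) for k, v in json.loads(hpath.read_text()).items()}
    return SingleCellDataset(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=[str(c) for c in cells["cell_id"]],
        cell_type=[str(c) for c in cells["cell_type"]],
        sample_id=[str(c) for c in cells["sample_id"]],
        batch_id=[str(c) for c in cells["batch_id"]],
        hierarchy=hierarchy,
    )


def write_single_cell(sc_data: SingleCellDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sc_data.counts if sp.issparse(sc_data.counts) else sp.coo_matrix(sc_data.counts)
    scipy.io.mmwrite(directory / "matrix.mtx", mat, field="integer")
    pd.DataFrame({"gene_id": sc_data.gene_ids}).to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "cell_id": sc_data.cell_ids,
            "cell_type": sc_data.cell_type,
            "sample_id": sc_data.sample_id,
            "batch_id": sc_data.batch_id,
        }
    ).to_csv(directory / "cells.tsv", sep="\t", index=False)
    if sc_data.hierarchy:
        (directory / "hierarchy.json").write_text(json.dumps(sc_data.hierarchy, indent=1))


def _load_mapping(path: Path) -> dict:
    import yaml

    payload = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    if not isinstance(payload, dict):
        raise ValidationError(f"{path.name}: expected a mapping at top level")
    return payload


def load_synth_config(path: str | Path):
    """Read a SynthConfig from a YAML or JSON mapping of field names."""
    from .simulation import SynthConfig

    payload = _load_mapping(Path(path))
    for key in ("batch_libsize_factors", "type_ids"):
        if key in payload and payload[key] is not None:
            payload[key] = tuple(payload[key])
    try:
        return SynthConfig(**payload)
    except TypeError as exc:
        raise ValidationError(f"bad synthetic-config field: {exc}") from None


def load_shuffle_design(path: str | Path):
    """Read a ShuffleDesign from a YAML or JSON mapping.

    Expected keys: ``bindings`` (term -> matched | shuffle | sample id),
    optional ``held_constant`` and ``seed``.
    """
    from .simulation import ShuffleDesign

    payload = _load_mapping(Path(path))
    unknown = set(payload) - {"bindings", "held_constant", "seed"}
    if unknown:
        raise ValidationError(f"unknown shuffle-design key(s): {sorted(unknown)}")
    return ShuffleDesign(
        bindings=dict(payload.get("bindings", {})),
        held_constant=payload.get("held_constant"),
        seed=int(payload.get("seed", 0)),
    )


def write_run_manifest(path: str | Path, **fields) -> None:
    """JSON manifest of a run's inputs, parameters and seed."""
    import sizedeconv

    payload = {"package_version": sizedeconv.__version__, **fields}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
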