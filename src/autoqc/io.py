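"""Readers and writers for the formats the pipeline touches.

Count matrices arrive either as a 10x-style Matrix Market triplet directory
(``matrix.mtx[.gz]`` with features as rows and barcodes as columns, plus
``barcodes.tsv[.gz]`` and ``features.tsv[.gz]``) or as a dense CSV with one
row per barcode and a header of gene identifiers.  Internally cells are
always rows.  All outputs are plain text with deterministic field order and
fixed float precision, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import gzip
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .errors import IOFormatError
from .gmm import PassInterval
from .pipeline import QCResult, apply_doublet_gate, classify_cells, vote_clusters
from .qc_metrics import AuxiliaryCellData, CountsMatrix, METRIC_COLUMNS

SCHEMA_VERSION = 1

CELL_CSV_COLUMNS = METRIC_COLUMNS + [
    "cluster_id",
    "cell_pass",
    "final_pass",
    "doublet_flag",
    "valid",
]


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _find(outdir: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = outdir / name
        if p.exists():
            return p
    raise IOFormatError(f"{stem}[.gz] not found in {outdir}")


def read_mtx_triplet(directory: str | Path) -> CountsMatrix:
    """Read a matrix.mtx + barcodes.tsv + features.tsv triplet directory.

    The matrix is features x barcodes on disk (the 10x convention) and is
    transposed to cells x genes; a matrix already stored cells x genes is
    accepted when the dimensions disambiguate it.
    """
    directory = Path(directory)
    mat = scipy.io.mmread(str(_find(directory, "matrix.mtx")))
    barcodes = _read_lines(_find(directory, "barcodes.tsv"))
    features = _read_lines(_find(directory, "features.tsv"))

    shape = mat.shape
    if shape == (len(features), len(barcodes)):
        mat = mat.T
    elif shape != (len(barcodes), len(features)):
        raise IOFormatError(
            f"matrix shape {shape} matches neither {len(features)} features x "
            f"{len(barcodes)} barcodes nor its transpose"
        )
    return CountsMatrix(barcodes, features, sp.csr_matrix(mat))


def write_mtx_triplet(counts: CountsMatrix, outdir: str | Path) -> None:
    """Write counts as matrix.mtx (features x barcodes) + barcodes/features TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), sp.coo_matrix(counts.counts.T), field="integer"
    )
    (outdir / "barcodes.tsv").write_text("".join(b + "\n" for b in counts.cell_ids))
    (outdir / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in counts.gene_ids)
    )


def read_dense_csv(path: str | Path) -> CountsMatrix:
    """Dense cells x genes CSV: header row of gene IDs, first column barcodes."""
    df = pd.read_csv(path, index_col=0)
    mat = df.to_numpy()
    if (mat < 0).any():
        raise IOFormatError("negative entries in count matrix")
    return CountsMatrix(
        [str(b) for b in df.index], [str(g) for g in df.columns], sp.csr_matrix(mat)
    )


def read_counts(path: str | Path, format: str = "auto") -> CountsMatrix:
    """Read a count matrix from a triplet directory, .mtx file or dense CSV."""
    path = Path(path)
    if format == "auto":
        if path.is_dir():
            format = "mtx"
        elif path.suffix in (".csv",) or str(path).endswith(".csv.gz"):
            format = "csv"
        elif ".mtx" in path.suffixes or path.suffix == ".mtx":
            format = "mtx"
        else:
            raise IOFormatError(f"cannot infer format of {path}")
    if format == "mtx":
        return read_mtx_triplet(path if path.is_dir() else path.parent)
    if format == "csv":
        return read_dense_csv(path)
    raise IOFormatError(f"unknown format {format!r}")


def read_cell_csv(path: str | Path, value_column: str | int = 1) -> pd.Series:
    """Two-or-more-column CSV keyed by barcode; returns a barcode-indexed Series."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise IOFormatError(f"{path}: expected barcode,value columns")
    if df.iloc[:, 0].duplicated().any():
        raise IOFormatError(f"{path}: duplicate barcodes")
    col = df.columns[value_column] if isinstance(value_column, int) else value_column
    return pd.Series(df[col].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))


def _aligned(series: pd.Series | None, cell_ids: list[str], what: str) -> np.ndarray | None:
    if series is None:
        return None
    missing = [b for b in cell_ids if b not in series.index]
    if missing:
        raise IOFormatError(
            f"{what}: {len(missing)} barcodes absent (first: {missing[0]})"
        )
    return series.reindex(cell_ids).to_numpy(dtype=float)


def read_aux(
    cell_ids: list[str],
    soup_csv: str | Path | None = None,
    doublet_csv: str | Path | None = None,
    spliced_csv: str | Path | None = None,
) -> AuxiliaryCellData:
    """Assemble AuxiliaryCellData from optional per-cell CSVs, barcode-aligned."""
    spliced = unspliced = None
    if spliced_csv is not None:
        spliced = _aligned(read_cell_csv(spliced_csv, 1), cell_ids, "spliced totals")
        unspliced = _aligned(read_cell_csv(spliced_csv, 2), cell_ids, "unspliced totals")
    return AuxiliaryCellData(
        spliced_total=spliced,
        unspliced_total=unspliced,
        soup_fraction=_aligned(
            read_cell_csv(soup_csv) if soup_csv else None, cell_ids, "soup fractions"
        ),
        doublet_score=_aligned(
            read_cell_csv(doublet_csv) if doublet_csv else None, cell_ids, "doublet scores"
        ),
    )


def _num(x):
    """Fixed-precision, JSON-safe number (inf -> None)."""
    x = float(x)
    if math.isinf(x):
        return None
    return round(x, 8)


def report_dict(result: QCResult) -> dict:
    """The run report: everything needed to re-derive the verdicts."""
    return {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": result.seed,
        "config": result.config,
        "sample": {
            "n_cells": result.n_cells,
            "n_pass": result.n_pass,
            "frac_pass": _num(result.frac_pass),
            "sample_kept": result.sample_kept,
            "reason": result.reason,
        },
        "gmm": {
            m: {
                "n_components": f.n_components,
                "weights": [_num(w) for w in f.weights],
                "means": [_num(v) for v in f.means],
                "variances": [_num(v) for v in f.variances],
                "bic_by_k": {str(k): _num(b) for k, b in sorted(f.bic_by_k.items())},
                "fixed_k": f.fixed_k,
                "data_range": [_num(f.data_min), _num(f.data_max)],
            }
            for m, f in result.gmm_fits.items()
        },
        "intervals": {
            m: {
                "low": _num(iv.low),
                "high": _num(iv.high),
                "pass_components": list(iv.pass_components),
            }
            for m, iv in result.intervals.items()
        },
        "warnings": result.warnings,
    }


def emit_report(result: QCResult, outdir: str | Path) -> dict[str, Path]:
    """Write cells.csv, clusters.csv, report.json (and layout.csv if present)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / "cells.csv",
        "clusters": outdir / "clusters.csv",
        "report": outdir / "report.json",
    }
    cells = result.cells[CELL_CSV_COLUMNS]
    cells.to_csv(paths["cells"], float_format="%.6f")
    result.clusters.to_csv(paths["clusters"], index=False, float_format="%.6f")
    paths["report"].write_text(json.dumps(report_dict(result), indent=2) + "\n")
    if result.layout is not None:
        paths["layout"] = outdir / "layout.csv"
        pd.DataFrame(
            result.layout, index=result.cells.index, columns=["dim1", "dim2"]
        ).to_csv(paths["layout"], float_format="%.6f")
    return paths


def replay_verdicts(report: dict, cells: pd.DataFrame) -> np.ndarray:
    """Recompute final_pass from a report and the per-cell CSV (self-check).

    Applies the reported pass intervals, the cluster vote at the reported
    threshold, and the recorded doublet flags.  Must reproduce the
    ``final_pass`` column exactly.
    """
    intervals = {
        m: PassInterval(
            m,
            -math.inf if d["low"] is None else d["low"],
            math.inf if d["high"] is None else d["high"],
            tuple(d["pass_components"]),
        )
        for m, d in report["intervals"].items()
    }
    cell_pass = classify_cells(cells, intervals)
    _, final = vote_clusters(
        cell_pass,
        cells["cluster_id"].to_numpy(),
        report["config"]["pass_fraction_threshold"],
    )
    return final & ~cells["doublet_flag"].to_numpy(dtype=bool)
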