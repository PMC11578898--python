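"""The two-step QC decision engine and full per-sample pipeline.

Classification of cells as passing or failing QC is a two-step process:
first each cell is scored against per-metric pass intervals derived from
Gaussian-mixture fits (a conjunction over the selected metrics); then whole
QC clusters vote — a cluster passes if at least half of its cells passed
individually, and every cell inherits its cluster's verdict.  Cells in
passing clusters that individually failed are thereby rescued, and vice
versa.  A doublet-score gate and a sample-level filter (reject the sample
when fewer than 10% of cells or fewer than 100 cells pass) complete the
pipeline.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterResult, embed_and_cluster
from .config import QCConfig
from .errors import ConfigError, DegenerateSampleError, FitError
from .gmm import GMMFit, PassInterval, derive_pass_interval, fit_metric_gmm
from .qc_metrics import (
    AuxiliaryCellData,
    CountsMatrix,
    METRIC_COLUMNS,
    compute_qc_metrics,
)


@dataclass
class QCResult:
    """Complete per-cell, per-cluster and per-sample QC verdicts.

    ``cells`` is indexed by barcode and holds the eight metrics plus
    ``valid``, ``cluster_id``, ``cell_pass`` (pre-vote), ``final_pass``
    (post-vote, post-doublet-gate) and ``doublet_flag``.
    """

    cells: pd.DataFrame
    clusters: pd.DataFrame
    n_cells: int
    n_pass: int
    frac_pass: float
    sample_kept: bool
    reason: str
    gmm_fits: dict[str, GMMFit] = field(default_factory=dict)
    intervals: dict[str, PassInterval] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0
    warnings: list[str] = field(default_factory=list)
    layout: np.ndarray | None = None


def classify_cells(
    metrics: pd.DataFrame, intervals: dict[str, PassInterval]
) -> np.ndarray:
    """Per-cell pre-vote verdict: pass iff inside every metric's interval.

    A value missing for an individual cell counts as a pass for that metric;
    cells flagged invalid (zero total counts) fail outright.
    """
    if not intervals:
        raise ConfigError("no pass intervals: empty decision-metric subset")
    ok = np.ones(len(metrics), dtype=bool)
    for name, interval in intervals.items():
        vals = metrics[name].to_numpy(dtype=float)
        missing = ~np.isfinite(vals)
        ok &= interval.contains(vals) | missing
    if "valid" in metrics:
        ok &= metrics["valid"].to_numpy(dtype=bool)
    return ok


def vote_clusters(
    cell_pass: np.ndarray,
    cluster_id: np.ndarray,
    pass_fraction_threshold: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster vote: a cluster passes when >= threshold of its cells passed.

    Returns the per-cluster summary table and the per-cell ``final_pass``
    vector (every cell takes its cluster's verdict).
    """
    df = pd.DataFrame({"cluster_id": cluster_id, "cell_pass": cell_pass})
    grp = df.groupby("cluster_id", sort=True)["cell_pass"]
    summary = pd.DataFrame(
        {
            "n_cells": grp.size(),
            "n_pass": grp.sum().astype(int),
        }
    )
    summary["pass_fraction"] = summary["n_pass"] / summary["n_cells"]
    summary["cluster_verdict"] = summary["pass_fraction"] >= pass_fraction_threshold
    final = summary["cluster_verdict"].reindex(cluster_id).to_numpy(dtype=bool)
    return summary.reset_index(), final


def apply_doublet_gate(
    final_pass: np.ndarray,
    doublet_score: np.ndarray | None,
    threshold: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove presumed doublets: score > threshold fails the cell.

    Missing scores (or an absent vector) leave cells untouched and unflagged.
    Returns ``(final_pass, doublet_flag)``.
    """
    n = len(final_pass)
    if doublet_score is None:
        return final_pass.copy(), np.zeros(n, dtype=bool)
    score = np.asarray(doublet_score, dtype=float)
    flag = np.isfinite(score) & (score > threshold)
    return final_pass & ~flag, flag


def filter_sample(
    n_cells: int, n_pass: int, min_frac: float = 0.10, min_cells: int = 100
) -> tuple[bool, float, str]:
    """Sample-level filter: reject when frac_pass < min_frac OR n_pass < min_cells.

    Both comparisons are strict, so a sample with exactly ``min_cells``
    passing at exactly ``min_frac`` is kept.
    """
    frac = n_pass / n_cells if n_cells else 0.0
    reasons = []
    if frac < min_frac:
        reasons.append(f"frac_pass {frac:.4f} < {min_frac}")
    if n_pass < min_cells:
        reasons.append(f"n_pass {n_pass} < {min_cells}")
    if reasons:
        return False, frac, "rejected: " + " and ".join(reasons)
    return True, frac, "kept"


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {
        stage: int(rng.integers(2**31))
        for stage in ("cluster", "gmm", "layout")
    }


def run_scautoqc(
    counts: CountsMatrix,
    aux: AuxiliaryCellData | None = None,
    config: QCConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> QCResult:
    """Run the full automated QC pipeline on one sample.

    Orchestrates metric computation, QC clustering, per-metric mixture fits
    and threshold derivation, the two-step cell/cluster classification, the
    doublet gate and the sample-level filter.  Deterministic for a fixed
    seed and config.  A degenerate sample (too few cells, or no informative
    metric) yields ``sample_kept=False`` with all cells failing, rather than
    an exception.
    """
    config = config or QCConfig()
    aux = aux or AuxiliaryCellData()
    seeds = _stage_seeds(seed)
    warnings_log: list[str] = []
    t0 = time.perf_counter()

    cells = compute_qc_metrics(counts, aux, config.genesets)

    def _degenerate(reason: str) -> QCResult:
        out = cells.copy()
        out["cluster_id"] = -1
        out["cell_pass"] = False
        out["final_pass"] = False
        out["doublet_flag"] = False
        return QCResult(
            cells=out,
            clusters=pd.DataFrame(
                columns=["cluster_id", "n_cells", "n_pass", "pass_fraction", "cluster_verdict"]
            ),
            n_cells=len(out),
            n_pass=0,
            frac_pass=0.0,
            sample_kept=False,
            reason=f"rejected: degenerate sample ({reason})",
            config=config.snapshot(),
            seed=seed,
            warnings=warnings_log + [reason],
        )

    try:
        clustering: ClusterResult = embed_and_cluster(
            cells,
            k_neighbors=config.k_neighbors,
            resolution=config.resolution,
            seed=seeds["cluster"],
            layout=config.layout,
        )
    except DegenerateSampleError as exc:
        return _degenerate(str(exc))

    fits: dict[str, GMMFit] = {}
    intervals: dict[str, PassInterval] = {}
    valid = cells["valid"].to_numpy(dtype=bool)
    for metric in config.metrics:
        vals = cells[metric].to_numpy(dtype=float)[valid]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings_log.append(f"{metric}: missing for the whole sample, dropped")
            continue
        try:
            fit = fit_metric_gmm(
                vals,
                metric=metric,
                k_max=config.k_max,
                fixed_k=config.fixed_k,
                seed=seeds["gmm"],
            )
        except FitError as exc:
            warnings_log.append(f"{metric}: {exc}; metric dropped")
            continue
        warnings_log.extend(f"{metric}: {w}" for w in fit.warnings)
        fits[metric] = fit
        intervals[metric] = derive_pass_interval(fit, config.guidance_for(metric))
    if not intervals:
        return _degenerate("no decision metric could be fitted")

    cell_pass = classify_cells(cells, intervals)
    cluster_table, final_pass = vote_clusters(
        cell_pass, clustering.cluster_id, config.pass_fraction_threshold
    )
    final_pass, doublet_flag = apply_doublet_gate(
        final_pass, aux.doublet_score, config.doublet_threshold
    )

    n_pass = int(final_pass.sum())
    kept, frac, reason = filter_sample(
        len(cells), n_pass, config.min_frac, config.min_cells
    )

    out = cells.copy()
    out["cluster_id"] = clustering.cluster_id
    out["cell_pass"] = cell_pass
    out["final_pass"] = final_pass
    out["doublet_flag"] = doublet_flag

    if verbose:  # timings stay out of the report so reruns are byte-identical
        print(
            f"[autoqc] {len(cells)} cells, {clustering.n_clusters} QC clusters, "
            f"{n_pass} passing ({100 * frac:.1f}%), {reason} "
            f"[{time.perf_counter() - t0:.2f}s]",
            file=sys.stderr,
        )

    return QCResult(
        cells=out,
        clusters=cluster_table,
        n_cells=len(cells),
        n_pass=n_pass,
        frac_pass=frac,
        sample_kept=kept,
        reason=reason,
        gmm_fits=fits,
        intervals=intervals,
        config=config.snapshot(),
        seed=seed,
        warnings=warnings_log,
        layout=clustering.layout,
    )
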