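"""Per-metric Gaussian-mixture thresholding.

For each selected QC metric a one-dimensional Gaussian mixture is fitted to
the per-cell values.  The number of components is either fixed (the
historical overfit mode, k = 10) or chosen automatically among 1..k_max by
minimum BIC.  A guidance anchor interval — e.g. percent_mito in [0, 20] —
then selects which mixture components represent "good" cells, and the pass
interval is read off the component-responsibility structure on a grid: the
maximal contiguous region where a pass component has the highest weighted
density.  Anchors only steer component selection; the actual cut-offs come
from the fitted mixture, which is what makes small anchor changes (15% vs
20% mitochondrial) land on the same thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .errors import ConfigError, FitError

#: Default guidance anchors for the four decision metrics: minimum ~250
#: counts, ~100 genes, at most 20% mitochondrial, 50–97.5% spliced.
DEFAULT_GUIDANCE: dict[str, tuple[float, float]] = {
    "log1p_n_counts": (math.log(251.0), math.inf),
    "log1p_n_genes": (math.log(101.0), math.inf),
    "percent_mito": (0.0, 20.0),
    "percent_spliced": (50.0, 97.5),
}


@dataclass
class MetricGuidance:
    """Anchor interval for one metric; steers pass-component selection only."""

    metric: str
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigError(f"degenerate guidance interval for {self.metric}")

    @classmethod
    def default(cls, metric: str) -> "MetricGuidance":
        if metric not in DEFAULT_GUIDANCE:
            return cls(metric)
        low, high = DEFAULT_GUIDANCE[metric]
        return cls(metric, low, high)


@dataclass
class GMMFit:
    """A 1-D Gaussian mixture fitted to one metric (components sorted by mean)."""

    metric: str
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic_by_k: dict[int, float]
    seed: int
    data_min: float
    data_max: float
    fixed_k: bool = False
    warnings: list[str] = field(default_factory=list)

    def component_logpdf(self, x: np.ndarray) -> np.ndarray:
        """(n_components, len(x)) weighted log-density of each component."""
        x = np.asarray(x, dtype=float)
        out = np.empty((self.n_components, x.size))
        for j in range(self.n_components):
            out[j] = np.log(self.weights[j]) + norm.logpdf(
                x, loc=self.means[j], scale=math.sqrt(self.variances[j])
            )
        return out


@dataclass
class PassInterval:
    """Closed pass range for one metric; ±inf means unbounded on that side."""

    metric: str
    low: float
    high: float
    pass_components: tuple[int, ...]

    def contains(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return (values >= self.low) & (values <= self.high)


def fit_metric_gmm(
    values: np.ndarray,
    metric: str = "",
    k_max: int = 10,
    fixed_k: int | None = None,
    seed: int = 0,
    n_init: int = 3,
    tol: float = 1e-4,
    max_iter: int = 200,
    min_values: int = 50,
) -> GMMFit:
    """Fit 1-D Gaussian mixtures by EM and select the component count by BIC.

    With ``fixed_k`` the mixture has exactly that many components (the
    historical overfit mode); otherwise every k in 1..k_max is fitted and the
    minimum-BIC model wins (ties toward smaller k).  BIC here is
    ``(3k - 1)·ln(n) − 2·logLik``.  Missing values must already be removed.
    Candidate k values whose EM run fails are dropped with a recorded
    warning; if all fail a :class:`FitError` is raised.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_values:
        raise FitError(
            f"{metric or 'metric'}: {x.size} values < {min_values} required for a GMM fit"
        )
    n_distinct = np.unique(x).size
    X = x.reshape(-1, 1)

    candidates = [fixed_k] if fixed_k is not None else list(range(1, k_max + 1))
    fits: dict[int, GaussianMixture] = {}
    bic_by_k: dict[int, float] = {}
    warns: list[str] = []
    for k in candidates:
        if k > n_distinct:
            warns.append(f"k={k} skipped: only {n_distinct} distinct values")
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type="full",
                    n_init=n_init,
                    tol=tol,
                    max_iter=max_iter,
                    random_state=int(seed) % (2**31),
                ).fit(X)
            fits[k] = gm
            bic_by_k[k] = float(gm.bic(X))
        except Exception as exc:  # pragma: no cover - rare numerical failure
            warns.append(f"k={k} failed: {exc}")
    if not fits:
        raise FitError(f"{metric or 'metric'}: every mixture fit failed")

    best_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    gm = fits[best_k]
    means = gm.means_.ravel()
    order = np.argsort(means)
    return GMMFit(
        metric=metric,
        n_components=best_k,
        weights=gm.weights_[order],
        means=means[order],
        variances=gm.covariances_.ravel()[order],
        bic_by_k=bic_by_k,
        seed=int(seed),
        data_min=float(x.min()),
        data_max=float(x.max()),
        fixed_k=fixed_k is not None,
        warnings=warns,
    )


def _select_pass_components(fit: GMMFit, guidance: MetricGuidance) -> tuple[int, ...]:
    inside = [
        j
        for j in range(fit.n_components)
        if guidance.low <= fit.means[j] <= guidance.high
    ]
    if inside:
        return tuple(inside)
    # No component mean falls inside the anchor: take the single nearest one.
    dist = [
        max(guidance.low - m, m - guidance.high, 0.0) for m in fit.means
    ]
    return (int(np.argmin(dist)),)


def derive_pass_interval(
    fit: GMMFit,
    guidance: MetricGuidance | None = None,
    grid_points: int = 1000,
) -> PassInterval:
    """Turn a fitted mixture plus a guidance anchor into a pass interval.

    The weighted density of each component is evaluated on a uniform grid
    over the observed data range; each grid point is labelled with its argmax
    component (ties toward the lower-mean component).  The pass interval is
    the maximal contiguous run of pass-component points containing the mean
    of the highest-weight pass component; a run touching a grid edge is
    unbounded on that side.
    """
    guidance = guidance or MetricGuidance.default(fit.metric)
    if guidance.metric and fit.metric and guidance.metric != fit.metric:
        raise ConfigError(
            f"guidance for {guidance.metric!r} applied to fit of {fit.metric!r}"
        )
    pass_components = _select_pass_components(fit, guidance)

    grid = np.linspace(fit.data_min, fit.data_max, grid_points)
    logdens = fit.component_logpdf(grid)
    winner = np.argmax(logdens, axis=0)  # first max -> lower-mean component
    is_pass = np.isin(winner, pass_components)

    # Anchor the run at the highest-weight pass component's mean.
    anchor_comp = max(pass_components, key=lambda j: (fit.weights[j], -j))
    anchor_idx = int(np.argmin(np.abs(grid - fit.means[anchor_comp])))
    if not is_pass[anchor_idx]:
        # The mean's grid point can be claimed by a denser neighbour; fall
        # back to the pass point closest to the anchor mean.
        pass_idx = np.flatnonzero(is_pass)
        if pass_idx.size == 0:
            # Degenerate: pass components nowhere dominant; pass everything
            # rather than silently failing all cells on this metric.
            return PassInterval(fit.metric, -math.inf, math.inf, pass_components)
        anchor_idx = int(pass_idx[np.argmin(np.abs(pass_idx - anchor_idx))])

    lo = anchor_idx
    while lo > 0 and is_pass[lo - 1]:
        lo -= 1
    hi = anchor_idx
    while hi < grid_points - 1 and is_pass[hi + 1]:
        hi += 1

    low = -math.inf if lo == 0 else float(grid[lo])
    high = math.inf if hi == grid_points - 1 else float(grid[hi])
    return PassInterval(fit.metric, low, high, pass_components)
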