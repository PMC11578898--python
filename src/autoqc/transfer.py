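"""Weighted-kNN label transfer with uncertainty, unknown flagging and repair.

Query cells embedded in the same latent space as an annotated reference
receive the label of their k nearest reference cells by weighted majority
vote.  Neighbour i at distance d_i contributes weight exp(-d_i^2 / sigma^2)
with the adaptive bandwidth sigma equal to the distance of the k-th
neighbour; the uncertainty score is 1 minus the winning label's share of the
total weight.  Cells whose uncertainty exceeds the 90th percentile of their
group (e.g. lineage, or cancer vs non-cancer) are flagged "unknown" and then
repaired, where possible, by Leiden clustering of the query embedding and
majority vote of the confidently labelled cells in each cluster; clusters
with no confident member stay unknown and are surfaced for manual review.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .clustering import leiden_cluster
from .errors import ConfigError

UNKNOWN = "unknown"


def knn_transfer(
    ref_latent: np.ndarray,
    ref_labels: np.ndarray,
    query_latent: np.ndarray,
    k: int = 30,
) -> pd.DataFrame:
    """Transfer reference labels to query cells by weighted kNN vote.

    Returns a DataFrame with ``predicted_label`` and ``uncertainty`` per
    query cell.  Vote ties break toward the lexicographically smallest
    label.  Uncertainty 0 means a unanimous weighted vote.
    """
    ref_latent = np.asarray(ref_latent, dtype=float)
    query_latent = np.asarray(query_latent, dtype=float)
    if ref_latent.shape[1] != query_latent.shape[1]:
        raise ConfigError(
            f"latent dimensionality mismatch: reference D={ref_latent.shape[1]}, "
            f"query D={query_latent.shape[1]}"
        )
    if k > ref_latent.shape[0]:
        raise ConfigError(f"k={k} exceeds reference size {ref_latent.shape[0]}")

    labels = pd.Categorical(np.asarray(ref_labels))
    categories = np.asarray(labels.categories)  # sorted -> lexicographic ties
    codes = np.asarray(labels.codes)

    nn = NearestNeighbors(n_neighbors=k).fit(ref_latent)
    dist, idx = nn.kneighbors(query_latent)

    sigma = dist[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-(dist**2) / sigma[:, None] ** 2)
    w[sigma == 0] = 1.0  # all k neighbours coincide with the query point

    n_query = query_latent.shape[0]
    votes = np.zeros((n_query, len(categories)))
    rows = np.repeat(np.arange(n_query), k)
    np.add.at(votes, (rows, codes[idx].ravel()), w.ravel())

    winner = np.argmax(votes, axis=1)  # first max -> lexicographically smallest
    total = votes.sum(axis=1)
    uncertainty = 1.0 - votes[np.arange(n_query), winner] / total
    return pd.DataFrame(
        {
            "predicted_label": categories[winner],
            "uncertainty": np.clip(uncertainty, 0.0, 1.0),
        }
    )


def flag_unknown(
    results: pd.DataFrame,
    groups: np.ndarray | None = None,
    quantile: float = 0.90,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag cells whose uncertainty is strictly above their group's quantile.

    The threshold is the empirical quantile (linear interpolation) of the
    uncertainty scores computed separately within each group, so each group
    contributes its own ~10% (at the default 0.90) rather than a pooled top
    decile.  Returns the augmented results (``unknown``, ``final_label``) and
    the per-group thresholds.
    """
    out = results.copy()
    n = len(out)
    grp = np.asarray(groups) if groups is not None else np.full(n, "all")
    if grp.shape != (n,):
        raise ConfigError("groups do not align with transfer results")

    unknown = np.zeros(n, dtype=bool)
    thresholds: dict[str, float] = {}
    for g in pd.unique(grp):
        mask = grp == g
        if mask.sum() < 10:
            _warnings.warn(f"group {g!r} has only {int(mask.sum())} cells")
        thr = float(np.quantile(out.loc[mask, "uncertainty"], quantile))
        thresholds[str(g)] = thr
        unknown[mask] = out.loc[mask, "uncertainty"].to_numpy() > thr

    out["group"] = grp
    out["unknown"] = unknown
    out["final_label"] = np.where(unknown, UNKNOWN, out["predicted_label"])
    return out, thresholds


def reassign_unknown(
    query_latent: np.ndarray,
    results: pd.DataFrame,
    resolution: float = 1.0,
    seed: int = 0,
    k_neighbors: int = 15,
) -> tuple[pd.DataFrame, list[int]]:
    """Repair unknown labels by cluster-majority vote of confident cells.

    Query cells are Leiden-clustered on a kNN graph of their latent
    coordinates; each unknown cell adopts the majority ``predicted_label``
    among the non-unknown cells of its cluster.  Returns the updated results
    (with ``query_cluster``) and the ids of clusters that had no confident
    member and therefore remain unknown.
    """
    out = results.copy()
    X = np.asarray(query_latent, dtype=float)
    if X.shape[0] != len(out):
        raise ConfigError("query latent does not align with transfer results")
    clusters = leiden_cluster(X, min(k_neighbors, X.shape[0] - 1), resolution, seed)
    out["query_cluster"] = clusters

    unresolved: list[int] = []
    for c in np.unique(clusters):
        mask = clusters == c
        known = mask & ~out["unknown"].to_numpy()
        if not known.any():
            unresolved.append(int(c))
            continue
        majority = (
            out.loc[known, "predicted_label"].value_counts().sort_index().idxmax()
        )
        sel = mask & out["unknown"].to_numpy()
        out.loc[sel, "final_label"] = majority
    return out, unresolved


@dataclass
class CovariateReport:
    """Variance in each latent dimension explained by one covariate.

    Caveat: correlated covariates (study vs protocol vs age...) can explain
    the same variance, so per-covariate R^2 values are not additive.
    """

    covariate: str
    r2_per_dim: np.ndarray

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_per_dim))


def covariate_variance(
    latent: np.ndarray, covariate: np.ndarray, name: str = "covariate"
) -> CovariateReport:
    """OLS of each latent dimension on one covariate; returns per-dim R^2.

    Numeric covariates enter as a single regressor; categoricals are one-hot
    encoded with the first level dropped.  A constant covariate yields R^2 = 0
    for every dimension (with a warning).
    """
    Y = np.asarray(latent, dtype=float)
    cov = pd.Series(np.asarray(covariate))
    if len(cov) != Y.shape[0]:
        raise ConfigError("covariate does not align with latent rows")

    if pd.api.types.is_numeric_dtype(cov):
        design = cov.to_numpy(dtype=float).reshape(-1, 1)
    else:
        design = pd.get_dummies(cov, drop_first=True).to_numpy(dtype=float)

    if design.size == 0 or np.all(design.std(axis=0) == 0):
        _warnings.warn(f"covariate {name!r} is constant; R^2 = 0")
        return CovariateReport(name, np.zeros(Y.shape[1]))

    X = np.column_stack([np.ones(Y.shape[0]), design])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return CovariateReport(name, np.clip(r2, 0.0, 1.0))
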