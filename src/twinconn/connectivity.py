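"""Whole-brain directed (Granger) and undirected (Pearson) networks.

Effective connectivity (EC) here is the bivariate coefficient-based
Granger measure at lag 1: for an ordered region pair (x -> y) it is the
signed coefficient b in the least-squares fit

    y_t = c + a * y_{t-1} + b * x_{t-1} + e_t,   t = 2..T,

computed after z-scoring both series (so coefficients are comparable
across subjects; the sign is unaffected by rescaling either way).  The
signed coefficient — rather than an F statistic or log-variance ratio —
is used because group-level analyses rely on the direction of the
influence (positive vs negative couplings).

Functional connectivity (FC) is the zero-lag Pearson correlation of the
two regional series; group statistics on FC operate on Fisher-z values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ConnectivityMatrices, RegionTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "GCConfig",
    "ZeroVarianceError",
    "DegeneratePairError",
    "fit_bivariate_gc",
    "build_ec_matrix",
    "build_fc_matrix",
    "build_connectivity",
    "fisher_z",
    "count_directed_pairs",
    "vectorize_edges",
    "devectorize_edges",
]


class ZeroVarianceError(ValueError):
    """A series with zero variance cannot enter a correlation/GC fit."""


class DegeneratePairError(ValueError):
    """Lagged regressors are exactly collinear (e.g. y is identical to x)."""


@dataclass(frozen=True)
class GCConfig:
    """Bivariate Granger fit options; lag order is fixed at 1."""

    lag_order: int = 1
    standardize: bool = True
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if self.lag_order != 1:
            raise ValueError("only lag order 1 is supported")


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def fit_bivariate_gc(x: np.ndarray, y: np.ndarray, config: GCConfig = GCConfig()) -> float:
    """Signed lag-1 influence of ``x`` on ``y`` (EC for the edge x -> y).

    Returns the coefficient of ``x_{t-1}`` in the OLS fit of ``y_t`` on
    an intercept, ``y_{t-1}`` and ``x_{t-1}``.

    Raises
    ------
    ZeroVarianceError
        if either input is constant.
    DegeneratePairError
        if the lagged regressors are exactly collinear.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    t = x.size
    if t < 10:
        raise ValueError(f"need at least 10 time points, got {t}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input series")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ZeroVarianceError("zero-variance series in Granger fit")
    if config.standardize:
        x = _zscore(x)
        y = _zscore(y)
    cols = [y[:-1], x[:-1]]
    if config.include_intercept:
        cols.insert(0, np.ones(t - 1))
    design = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(design, y[1:], rcond=None)
    if rank < design.shape[1]:
        raise DegeneratePairError(
            "lagged regressors are collinear; the pair is degenerate"
        )
    return float(beta[-1])


def build_ec_matrix(series: RegionTimeSeries, config: GCConfig = GCConfig()) -> np.ndarray:
    """R x R directed EC matrix; entry (i, j) is the fit for edge i -> j.

    Performs exactly R*(R-1) bivariate fits — the (i, j) entry depends
    only on the data of regions i and j.  The diagonal is NaN.  A
    degenerate pair yields a NaN entry and a logged warning rather than
    aborting the whole matrix.
    """
    data = series.data
    r = series.n_regions
    ec = np.full((r, r), np.nan)
    for i in range(r):
        for j in range(r):
            if i == j:
                continue
            try:
                ec[i, j] = fit_bivariate_gc(data[i], data[j], config)
            except DegeneratePairError:
                logger.warning(
                    "degenerate pair %s -> %s in subject %s; edge masked",
                    series.region_ids[i],
                    series.region_ids[j],
                    series.subject_id,
                )
    return ec


def build_fc_matrix(series: RegionTimeSeries) -> np.ndarray:
    """Pearson correlation matrix (symmetric, unit diagonal)."""
    sds = series.data.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = [series.region_ids[k] for k in np.flatnonzero(sds == 0)]
        raise ZeroVarianceError(f"zero-variance region(s): {bad}")
    fc = np.corrcoef(series.data)
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def build_connectivity(
    series: RegionTimeSeries, config: GCConfig = GCConfig()
) -> ConnectivityMatrices:
    """Convenience: both networks for one subject."""
    return ConnectivityMatrices(
        subject_id=series.subject_id,
        group=series.group,
        ec=build_ec_matrix(series, config),
        fc=build_fc_matrix(series),
        region_ids=series.region_ids,
    )


def fisher_z(r) -> float | np.ndarray:
    """Variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def count_directed_pairs(n_regions: int) -> int:
    """Number of ordered region pairs, R*(R-1); 272 regions -> 73,712."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    return n_regions * (n_regions - 1)


def _directed_index(region_ids) -> list[tuple[int, int]]:
    return [(a, b) for a in region_ids for b in region_ids if a != b]


def _undirected_index(region_ids) -> list[tuple[int, int]]:
    r = len(region_ids)
    return [(region_ids[i], region_ids[j]) for i in range(r) for j in range(i + 1, r)]


def vectorize_edges(matrix: np.ndarray, kind: str, region_ids=None):
    """Flatten a connectivity matrix into a feature vector plus edge index.

    directed: length R(R-1), row-major over (source, target), diagonal
    skipped.  undirected: length R(R-1)/2, upper triangle row-major; the
    matrix must be symmetric to 1e-10.  The index maps each position to a
    (region_i, region_j) label pair and round-trips with
    :func:`devectorize_edges`.
    """
    matrix = np.asarray(matrix, dtype=float)
    r = matrix.shape[0]
    if matrix.shape != (r, r):
        raise ValueError("matrix must be square")
    region_ids = tuple(region_ids) if region_ids is not None else tuple(range(1, r + 1))
    if len(region_ids) != r:
        raise ValueError("region_ids length mismatch")
    if kind == "directed":
        mask = ~np.eye(r, dtype=bool)
        return matrix[mask], _directed_index(region_ids)
    if kind == "undirected":
        off = ~np.eye(r, dtype=bool)
        asym = np.nanmax(np.abs((matrix - matrix.T)[off])) if r > 1 else 0.0
        if asym > 1e-10:
            raise ValueError(
                f"matrix is asymmetric (max |M - M.T| = {asym:.3g}) — "
                "not an undirected network"
            )
        iu = np.triu_indices(r, k=1)
        return matrix[iu], _undirected_index(region_ids)
    raise ValueError(f"unknown kind {kind!r}")


def devectorize_edges(vector: np.ndarray, kind: str, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`.

    directed: diagonal NaN.  undirected: symmetric with unit diagonal
    (the FC convention).
    """
    vector = np.asarray(vector, dtype=float)
    if kind == "directed":
        if vector.size != n_regions * (n_regions - 1):
            raise ValueError("vector length does not match R(R-1)")
        mat = np.full((n_regions, n_regions), np.nan)
        mat[~np.eye(n_regions, dtype=bool)] = vector
        return mat
    if kind == "undirected":
        if vector.size != n_regions * (n_regions - 1) // 2:
            raise ValueError("vector length does not match R(R-1)/2")
        mat = np.eye(n_regions)
        iu = np.triu_indices(n_regions, k=1)
        mat[iu] = vector
        mat[(iu[1], iu[0])] = vector
        return mat
    raise ValueError(f"unknown kind {kind!r}")
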