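"""Core in-memory containers shared across the pipeline stages.

Conventions used throughout the package:

* a regional time-series matrix is regions x time (R x T), time on the
  last axis;
* a directed connectivity matrix is oriented rows = source region,
  columns = target region;
* edge vectors are laid out row-major over the matrix with the diagonal
  skipped (directed) or over the upper triangle (undirected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RegionTimeSeries",
    "ConnectivityMatrices",
    "EdgeStatResult",
    "ClassificationResult",
]


@dataclass
class RegionTimeSeries:
    """One subject's cleaned regional BOLD time series.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        Cohort label (e.g. ``"HC"``, ``"COTWIN"``, ``"SZ"``).
    data : ndarray of shape (R, T)
        Regions x time points; must be finite.
    tr_seconds : float
        Repetition time of the acquisition, in seconds.
    region_ids : sequence of int
        Ordered region labels of length R; the order is fixed and must be
        identical across subjects of a cohort.
    """

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float = 2.0
    region_ids: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D regions x time matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in series of {self.subject_id!r}")
        if len(self.region_ids) == 0:
            self.region_ids = tuple(range(1, self.data.shape[0] + 1))
        else:
            self.region_ids = tuple(int(r) for r in self.region_ids)
        if len(self.region_ids) != self.data.shape[0]:
            raise ValueError("region_ids length does not match number of rows")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RegionTimeSeries":
        """Return a copy carrying ``data`` but the same metadata."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ConnectivityMatrices:
    """Per-subject directed (EC) and undirected (FC) connectivity.

    ``ec[i, j]`` is the signed lag-1 influence of region ``i``'s past on
    region ``j``'s present (diagonal is NaN-masked).  ``fc`` is the Pearson
    correlation matrix (symmetric, unit diagonal) and ``fc_z`` its Fisher-z
    transform (diagonal NaN: atanh(1) is undefined).
    """

    subject_id: str
    group: str
    ec: np.ndarray
    fc: np.ndarray
    region_ids: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.ec = np.asarray(self.ec, dtype=float)
        self.fc = np.asarray(self.fc, dtype=float)
        if self.ec.shape != self.fc.shape or self.ec.shape[0] != self.ec.shape[1]:
            raise ValueError("ec and fc must be square matrices of equal shape")
        if len(self.region_ids) == 0:
            self.region_ids = tuple(range(1, self.ec.shape[0] + 1))

    @property
    def n_regions(self) -> int:
        return self.ec.shape[0]

    @property
    def fc_z(self) -> np.ndarray:
        z = np.full_like(self.fc, np.nan)
        off = ~np.eye(self.n_regions, dtype=bool)
        z[off] = np.arctanh(np.clip(self.fc[off], -1.0, 1.0))
        return z


@dataclass
class EdgeStatResult:
    """Outcome of a max-|t| permutation test over a family of edges.

    ``p_corrected[e]`` is the fraction of the ``n_perm`` null maxima of
    |t| that are >= |true_t[e]| — a family-wise-error-corrected p value.
    ``sign[e]`` is the sign of the true t.  p values of exactly 0 mean
    "below 1/n_perm resolution" and should be reported as p < 1/n_perm.
    """

    true_t: np.ndarray
    p_corrected: np.ndarray
    null_max_abs_t: np.ndarray
    n_perm: int
    alpha: float = 0.05
    edge_index: Sequence[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.true_t = np.asarray(self.true_t, dtype=float)
        self.p_corrected = np.asarray(self.p_corrected, dtype=float)
        self.null_max_abs_t = np.asarray(self.null_max_abs_t, dtype=float)

    @property
    def sign(self) -> np.ndarray:
        return np.sign(self.true_t).astype(int)

    @property
    def significant(self) -> np.ndarray:
        return self.p_corrected < self.alpha

    @property
    def n_edges(self) -> int:
        return self.true_t.shape[0]


@dataclass
class ClassificationResult:
    """LOOCV classification outcome, optionally with a permutation null.

    ``accuracy`` is the fraction of subjects correctly predicted across
    leave-one-out folds; ``mean_weights`` is the mean (over folds) linear
    SVM weight vector in standardized-feature space; ``p_value`` is the
    fraction of ``null_accuracies`` >= ``accuracy`` (None when no
    permutation test was run).
    """

    accuracy: float
    per_fold_predictions: np.ndarray
    mean_weights: np.ndarray
    classes: tuple[str, str]
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None
    n_perm: int = 0

    def formatted_p(self) -> str:
        """Human-readable p with the `p < 1/n_perm` convention for 0."""
        if self.p_value is None:
            return "n/a"
        if self.p_value == 0.0 and self.n_perm > 0:
            return f"p < {1.0 / self.n_perm:g}"
        return f"p = {self.p_value:g}"
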