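"""BOLD signal cleaning and atlas-based regional extraction.

Implements the in-scope preprocessing: discarding of initial volumes,
motion-based subject exclusion, averaging of voxel series over an
integer-labelled parcellation, nuisance regression (24-parameter motion
expansion, tissue and global signals), zero-phase band-pass filtering and
linear detrending.  Slice timing, realignment, spatial normalization and
smoothing are assumed to have been done upstream by standard tools and
are out of scope here.

Cleaning order is regression -> band-pass -> detrend.  The band-pass is
forward-backward (zero phase) so no temporal shift leaks into the lagged
Granger regressions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .containers import RegionTimeSeries

__all__ = [
    "PrepConfig",
    "MotionDecision",
    "discard_initial_volumes",
    "exclude_by_motion",
    "expand_motion_24",
    "extract_regional_series",
    "regress_nuisance",
    "bandpass",
    "detrend_linear",
    "clean_series",
]


@dataclass
class PrepConfig:
    """Cleaning parameters.

    ``n_discard`` initial volumes are dropped (equilibration); the motion
    exclusion rule discards a subject whose trace exceeds
    ``max_translation_mm`` in any axis or ``max_rotation_deg`` around any
    axis at any volume (strict inequalities); ``band`` is the retained
    frequency interval in Hz.
    """

    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.1)
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    detrend: bool = True


@dataclass(frozen=True)
class MotionDecision:
    keep: bool
    reason: str


def discard_initial_volumes(data, n_discard: int):
    """Drop the first ``n_discard`` time points (last axis).

    Accepts a :class:`RegionTimeSeries` or any array whose last axis is
    time (e.g. a 4-D voxel volume).
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if isinstance(data, RegionTimeSeries):
        if data.n_timepoints <= n_discard:
            raise ValueError(
                f"cannot discard {n_discard} of {data.n_timepoints} volumes"
            )
        return data.with_data(data.data[:, n_discard:])
    arr = np.asarray(data)
    if arr.shape[-1] <= n_discard:
        raise ValueError(f"cannot discard {n_discard} of {arr.shape[-1]} volumes")
    return arr[..., n_discard:]


def exclude_by_motion(
    trace: np.ndarray,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> MotionDecision:
    """Keep/exclude decision from a T x 6 rigid-body motion trace.

    Columns 0-2 are translations (mm), columns 3-5 rotations (degrees).
    Exclusion is triggered by strict exceedance only: a trace that touches
    exactly 2.0 mm / 2.0 deg is kept.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty motion trace")
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be T x 6 (3 translations, 3 rotations)")
    if not np.all(np.isfinite(trace)):
        raise ValueError("non-finite values in motion trace")
    max_trans = float(np.max(np.abs(trace[:, :3])))
    max_rot = float(np.max(np.abs(trace[:, 3:])))
    if max_trans > max_translation_mm:
        return MotionDecision(
            False, f"max displacement {max_trans:.3g} mm > {max_translation_mm:g} mm"
        )
    if max_rot > max_rotation_deg:
        return MotionDecision(
            False, f"max rotation {max_rot:.3g} deg > {max_rotation_deg:g} deg"
        )
    return MotionDecision(True, "within motion limits")


def expand_motion_24(trace: np.ndarray) -> np.ndarray:
    """Friston-style 24-parameter expansion of a T x 6 motion trace.

    Returns T x 24: the 6 parameters, their one-volume-back copies (first
    row zero-padded), and the squares of those 12.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be T x 6")
    lagged = np.vstack([np.zeros((1, 6)), trace[:-1]])
    base = np.hstack([trace, lagged])
    return np.hstack([base, base**2])


def _image_data(img) -> np.ndarray:
    """Accept a nibabel spatial image or a plain ndarray."""
    if hasattr(img, "get_fdata"):
        return np.asarray(img.get_fdata())
    return np.asarray(img)


def extract_regional_series(
    volume,
    atlas,
    *,
    tr_seconds: float = 2.0,
    subject_id: str = "unknown",
    group: str = "",
    expected_labels: Sequence[int] | None = None,
) -> RegionTimeSeries:
    """Average voxel time series over atlas regions.

    ``volume`` is a 4-D image (x, y, z, t) and ``atlas`` a 3-D integer
    label image on the same grid; both may be nibabel images or arrays.
    Row r of the output is the mean over voxels labelled with the r-th
    label, labels taken in ascending order.  If ``expected_labels`` is
    given, a label with no voxels raises an error naming it.
    """
    vol = _image_data(volume)
    lab = np.rint(_image_data(atlas)).astype(int)
    if vol.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    if lab.shape != vol.shape[:3]:
        raise ValueError("atlas grid does not match volume grid")
    present = np.unique(lab)
    present = present[present > 0]
    labels = np.asarray(sorted(expected_labels), dtype=int) if expected_labels else present
    rows = []
    for r in labels:
        mask = lab == r
        if not mask.any():
            raise ValueError(f"atlas region {int(r)} has no voxels in this grid")
        rows.append(vol[mask].mean(axis=0))
    return RegionTimeSeries(
        subject_id=subject_id,
        group=group,
        data=np.vstack(rows),
        tr_seconds=tr_seconds,
        region_ids=labels,
    )


def _find_collinear_columns(x: np.ndarray) -> list[int]:
    """Greedy scan for columns that add no rank (for error messages)."""
    bad, rank = [], 0
    for k in range(x.shape[1]):
        new_rank = np.linalg.matrix_rank(x[:, : k + 1])
        if new_rank == rank:
            bad.append(k)
        rank = new_rank
    return bad


def regress_nuisance(series: RegionTimeSeries, nuisance: np.ndarray) -> RegionTimeSeries:
    """Replace each region's series by residuals of OLS on [1 | nuisance].

    The intercept is always included, so the output is mean-centred.
    Residuals are orthogonal to every covariate; regressing twice with the
    same covariates is a no-op.

    Raises
    ------
    ValueError
        if the design (with intercept) is rank deficient; the message
        names the offending nuisance columns.
    """
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[0] != series.n_timepoints:
        raise ValueError(
            f"nuisance has {nuisance.shape[0]} rows, series has "
            f"{series.n_timepoints} time points"
        )
    design = np.column_stack([np.ones(series.n_timepoints), nuisance])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _find_collinear_columns(design)
        # column 0 is the intercept; report 0-based nuisance indices
        bad = [b - 1 for b in bad if b > 0]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, series.data.T, rcond=None)
    resid = series.data.T - design @ beta
    return series.with_data(resid.T)


def bandpass(
    series: RegionTimeSeries,
    band: tuple[float, float] = (0.01, 0.1),
    order: int = 4,
) -> RegionTimeSeries:
    """Zero-phase Butterworth band-pass along time.

    A forward-backward (``sosfiltfilt``) 4th-order Butterworth keeps
    in-band amplitudes essentially untouched (maximally flat passband,
    squared by the two passes) while attenuating by well over 20 dB one
    octave beyond either edge, and introduces no phase shift — important
    because a lagged regression follows.
    """
    low, high = band
    fs = 1.0 / series.tr_seconds
    nyq = fs / 2.0
    if not (0 <= low < high):
        raise ValueError("band must satisfy 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz is at or above Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, series.data, axis=1)
    return series.with_data(filtered)


def detrend_linear(series: RegionTimeSeries) -> RegionTimeSeries:
    """Remove the per-region best-fit line over time."""
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 time points to detrend")
    return series.with_data(sps.detrend(series.data, axis=1, type="linear"))


def clean_series(
    series: RegionTimeSeries,
    nuisance: np.ndarray | None = None,
    config: PrepConfig | None = None,
) -> RegionTimeSeries:
    """Nuisance regression (if covariates given), band-pass, detrend."""
    config = config or PrepConfig()
    out = series
    if nuisance is not None:
        out = regress_nuisance(out, nuisance)
    out = bandpass(out, config.band)
    if config.detrend:
        out = detrend_linear(out)
    return out
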