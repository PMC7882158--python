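"""Synthetic discordant-twin cohort generator.

Regional BOLD series are simulated from a stationary first-order vector
autoregression, x_t = A x_{t-1} + eps_t with eps_t ~ N(0, Sigma).  Group
differences are planted as sparse overrides of the coupling matrix A
(directed effects, picked up by the Granger stage) and of the innovation
covariance Sigma (zero-lag effects, picked up by the Pearson stage).
Between-subject heterogeneity is modelled as Gaussian jitter on the
planted couplings only, keeping per-subject stationarity checks cheap and
the planted effects interpretable.

The generator makes no attempt to emulate hemodynamic convolution,
physiological noise or scanner drift; a VAR(1) with white innovations is
sufficient to exercise every downstream contract (lagged directed
structure, zero-lag correlation structure, group differences and nulls).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import RegionTimeSeries

__all__ = [
    "CohortSpec",
    "ClinicalScoreSpec",
    "NonStationaryError",
    "simulate_subject",
    "simulate_cohort",
    "render_voxel_volumes",
    "simulate_clinical_table",
    "DEFAULT_GROUPS",
]

#: cohort layout emulated by default: healthy control twins, unaffected
#: co-twins, and twins with schizophrenia, 20 subjects each.
DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (("HC", 20), ("COTWIN", 20), ("SZ", 20))

#: burn-in discarded before recording; at spectral radius <= 0.9 the
#: influence of the start state after 200 steps is < 0.9**200 ~ 7e-10.
BURN_IN = 200


class NonStationaryError(ValueError):
    """Raised when a coupling matrix has spectral radius >= 1."""


def _spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def _cholesky_or_raise(cov: np.ndarray, what: str) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{what} must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"{what} is not positive definite") from err


@dataclass
class CohortSpec:
    """Generative description of a synthetic multi-group cohort.

    ``base_coupling`` (A0) and ``base_noise_cov`` (Sigma0) are shared by all
    groups; per-group deviations are sparse dictionaries mapping a directed
    (source, target) index pair to an additive coupling weight, or an
    unordered {i, j} pair to an additive innovation covariance.  Indices are
    0-based row/column positions.

    Defaults mirror the emulated acquisition: 272 regions, 180 volumes at
    TR = 2 s, three groups of 20 subjects.  The default base dynamics are a
    mild uniform self-coupling (0.25 on the diagonal) with unit innovation
    covariance, i.e. weakly autocorrelated, mutually independent regions.
    """

    n_regions: int = 272
    n_volumes: int = 180
    tr_seconds: float = 2.0
    groups: Sequence[tuple[str, int]] = DEFAULT_GROUPS
    base_coupling: np.ndarray | None = None
    group_coupling_deltas: Mapping[str, Mapping[tuple[int, int], float]] = field(
        default_factory=dict
    )
    base_noise_cov: np.ndarray | None = None
    group_noise_deltas: Mapping[str, Mapping[tuple[int, int], float]] = field(
        default_factory=dict
    )
    subject_sd: float = 0.05
    self_coupling: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_coupling is None:
            self.base_coupling = self.self_coupling * np.eye(self.n_regions)
        else:
            self.base_coupling = np.asarray(self.base_coupling, dtype=float)
            if self.base_coupling.shape != (self.n_regions, self.n_regions):
                raise ValueError("base_coupling shape does not match n_regions")
        if self.base_noise_cov is None:
            self.base_noise_cov = np.eye(self.n_regions)
        else:
            self.base_noise_cov = np.asarray(self.base_noise_cov, dtype=float)
        self.validate()

    def validate(self) -> None:
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for label, n in self.groups:
            if n < 2:
                raise ValueError(f"group {label!r} must have >= 2 subjects")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        for label in itertools.chain(self.group_coupling_deltas, self.group_noise_deltas):
            if label not in labels:
                raise ValueError(f"delta refers to unknown group {label!r}")
        for deltas in (self.group_coupling_deltas, self.group_noise_deltas):
            for per_group in deltas.values():
                for i, j in per_group:
                    if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                        raise ValueError(
                            f"delta edge ({i}, {j}) outside 0..{self.n_regions - 1}"
                        )
        for label, _ in self.groups:
            a = self.group_coupling(label)
            rho = _spectral_radius(a)
            if rho >= 1.0:
                raise NonStationaryError(
                    f"group {label!r} coupling has spectral radius {rho:.3f} >= 1"
                )
            _cholesky_or_raise(self.group_noise_cov(label), f"group {label!r} noise covariance")

    def group_coupling(self, label: str) -> np.ndarray:
        a = self.base_coupling.copy()
        for (i, j), w in self.group_coupling_deltas.get(label, {}).items():
            a[i, j] += w
        return a

    def group_noise_cov(self, label: str) -> np.ndarray:
        s = self.base_noise_cov.copy()
        for (i, j), w in self.group_noise_deltas.get(label, {}).items():
            s[i, j] += w
            if i != j:
                s[j, i] += w
        return s

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.groups)


def simulate_subject(
    coupling: np.ndarray,
    noise_cov: np.ndarray,
    n_volumes: int,
    seed,
    *,
    tr_seconds: float = 2.0,
    subject_id: str = "sim",
    group: str = "",
    burn_in: int = BURN_IN,
) -> RegionTimeSeries:
    """Simulate one subject's R x T series from a stationary VAR(1).

    ``seed`` may be anything :func:`numpy.random.default_rng` accepts.  The
    first ``burn_in`` steps are discarded so the recorded series is
    effectively a draw from the stationary distribution.  Output is
    bit-reproducible for a given seed.

    Raises
    ------
    NonStationaryError
        if the coupling's spectral radius is >= 1.
    ValueError
        if ``noise_cov`` is not symmetric positive definite.
    """
    coupling = np.asarray(coupling, dtype=float)
    r = coupling.shape[0]
    if coupling.shape != (r, r):
        raise ValueError("coupling must be square")
    rho = _spectral_radius(coupling)
    if rho >= 1.0:
        raise NonStationaryError(
            f"coupling has spectral radius {rho:.3f} >= 1; VAR(1) would diverge"
        )
    chol = _cholesky_or_raise(noise_cov, "noise_cov")
    rng = np.random.default_rng(seed)
    total = burn_in + int(n_volumes)
    innov = rng.standard_normal((total, r)) @ chol.T
    out = np.empty((total, r))
    x = np.zeros(r)
    # coupling is oriented row = source, column = target, so the state
    # update contracts over sources: x_t = A^T x_{t-1} + eps_t
    a_t = coupling.T
    for t in range(total):
        x = a_t @ x + innov[t]
        out[t] = x
    return RegionTimeSeries(
        subject_id=subject_id,
        group=group,
        data=out[burn_in:].T,
        tr_seconds=tr_seconds,
        region_ids=range(1, r + 1),
    )


def _subject_entropy(master_seed: int, index: int) -> np.random.SeedSequence:
    """Stated counter scheme: subject ``index`` draws from SeedSequence
    spawned from ``(master_seed, index)`` so subjects are mutually
    independent and individually reproducible."""
    return np.random.SeedSequence([int(master_seed), int(index)])


def simulate_cohort(spec: CohortSpec) -> list[RegionTimeSeries]:
    """Simulate every subject of ``spec``; returns them in manifest order.

    Per-subject couplings equal the group coupling plus N(0, subject_sd^2)
    jitter applied to the planted edges only (edges named in the group's
    coupling deltas).  Jittered couplings are re-checked for stationarity.
    """
    spec.validate()
    subjects: list[RegionTimeSeries] = []
    index = 0
    for label, n in spec.groups:
        group_a = spec.group_coupling(label)
        cov = spec.group_noise_cov(label)
        planted = list(spec.group_coupling_deltas.get(label, {}))
        for k in range(n):
            ss = _subject_entropy(spec.seed, index)
            jitter_ss, noise_ss = ss.spawn(2)
            a = group_a.copy()
            if planted and spec.subject_sd > 0:
                jit = np.random.default_rng(jitter_ss).normal(
                    0.0, spec.subject_sd, size=len(planted)
                )
                for (i, j), dw in zip(planted, jit):
                    a[i, j] += dw
            rts = simulate_subject(
                a,
                cov,
                spec.n_volumes,
                noise_ss,
                tr_seconds=spec.tr_seconds,
                subject_id=f"{label}{k + 1:02d}",
                group=label,
            )
            subjects.append(rts)
            index += 1
    return subjects


def render_voxel_volumes(
    series: RegionTimeSeries,
    atlas: np.ndarray,
    noise_sd: float = 0.0,
    seed=0,
) -> np.ndarray:
    """Paint a regional series into a 4-D voxel volume following an atlas.

    Every voxel carrying atlas label ``r`` (1-based) receives region r's
    series plus independent N(0, noise_sd^2) noise; label-0 voxels stay
    zero.  Used to exercise the atlas-averaging extraction end to end.
    """
    atlas = np.asarray(atlas)
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    if labels.size and labels.max() > series.n_regions:
        raise ValueError(
            f"atlas label {int(labels.max())} exceeds number of regions "
            f"({series.n_regions})"
        )
    rng = np.random.default_rng(seed)
    vol = np.zeros(atlas.shape + (series.n_timepoints,))
    for r in labels:
        mask = atlas == r
        row = series.data[int(r) - 1]
        block = np.broadcast_to(row, (int(mask.sum()), row.size))
        if noise_sd > 0:
            block = block + rng.normal(0.0, noise_sd, size=block.shape)
        vol[mask] = block
    return vol


@dataclass
class ClinicalScoreSpec:
    """Per-group normal models for clinical/demographic scores.

    ``scores`` maps a score name to ``{group_label: (mean, sd)}``.  Scores
    absent for a group (e.g. symptom scales undefined for controls) are
    simply omitted from that group's mapping and emitted as NaN.
    """

    scores: Mapping[str, Mapping[str, tuple[float, float]]]
    seed: int = 0

    def __post_init__(self) -> None:
        for name, per_group in self.scores.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise ValueError(f"score {name!r}, group {g!r}: sd must be >= 0")


def simulate_clinical_table(
    spec: ClinicalScoreSpec, group_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Draw a subject x score table of independent normal scores.

    Returns a DataFrame with ``subject_id`` and ``group`` columns followed
    by one column per score; reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for group, n in group_sizes.items():
        for k in range(n):
            rows.append({"subject_id": f"{group}{k + 1:02d}", "group": group})
    df = pd.DataFrame(rows)
    for name, per_group in spec.scores.items():
        col = np.full(len(df), np.nan)
        for group, (mean, sd) in per_group.items():
            mask = (df["group"] == group).to_numpy()
            col[mask] = rng.normal(mean, sd, size=int(mask.sum())) if sd > 0 else mean
        df[name] = col
    return df
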