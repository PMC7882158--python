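"""Group-comparison statistics for demographic and clinical scores.

One-way ANOVA F across the three cohorts and pooled-variance Student t
between the two twin groups, computable either from raw per-subject
scores or from printed summary statistics (mean, sample SD, n) — the two
paths agree to numerical precision when the summaries are computed from
the same data, and F = t^2 for two groups.

``TWIN_COHORT_SUMMARIES`` carries the published demographic/clinical
summaries (mean, SD, n = 20 per group) of the discordant-twin cohort the
synthetic generator emulates: age and education, PANSS symptom severity
(twin groups only), the seven MCCB cognitive domains, and GAF global
functioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ClinicalScoreSpec

__all__ = [
    "GroupSummary",
    "anova_from_summary",
    "ttest_from_summary",
    "anova_from_raw",
    "ttest_from_raw",
    "TWIN_COHORT_SUMMARIES",
    "clinical_score_spec",
    "summary_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample (n-1) standard deviation, and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def anova_from_summary(summaries: Sequence[GroupSummary]) -> float:
    """One-way ANOVA F from group summaries.

    F = MSB / MSW with MSB = sum n_i (m_i - grand)^2 / (k-1) and
    MSW = sum (n_i - 1) sd_i^2 / sum (n_i - 1); the grand mean is
    weighted by group size.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    grand = (ns * means).sum() / ns.sum()
    msb = (ns * (means - grand) ** 2).sum() / (len(summaries) - 1)
    msw = ((ns - 1) * sds**2).sum() / (ns - 1).sum()
    if msw == 0:
        if msb == 0:
            raise ValueError("all SDs zero with equal means: F is 0/0, undefined")
        return float("inf")
    return float(msb / msw)


def ttest_from_summary(a: GroupSummary, b: GroupSummary) -> float:
    """Pooled-variance (Student) two-sample t from summaries, a vs b."""
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise ValueError("both SDs zero with equal means: t is 0/0, undefined")
        return float("inf") if a.mean > b.mean else float("-inf")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(res.statistic)


def _split(scores, groups) -> list[np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    out = []
    for g in pd.unique(groups):
        vals = scores[groups == g]
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        out.append(vals)
    return out


def anova_from_raw(scores, groups) -> float:
    """One-way ANOVA F from raw scores (delegates to scipy.f_oneway)."""
    parts = _split(scores, groups)
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    return float(stats.f_oneway(*parts).statistic)


def ttest_from_raw(scores, groups) -> float:
    """Pooled-variance two-sample t from raw scores, first group vs second."""
    parts = _split(scores, groups)
    if len(parts) != 2:
        raise ValueError("t test requires exactly 2 groups")
    return float(stats.ttest_ind(parts[0], parts[1], equal_var=True).statistic)


_HC, _COTWIN, _SZ = "HC", "COTWIN", "SZ"

#: published cohort summaries (mean, sample SD, n=20/group): healthy
#: control twins (HC), unaffected co-twins (COTWIN), twins with
#: first-episode schizophrenia (SZ).  PANSS is defined for the two twin
#: groups only.
TWIN_COHORT_SUMMARIES: Mapping[str, Mapping[str, GroupSummary]] = {
    "age": {
        _HC: GroupSummary(23.0, 2.4, 20),
        _COTWIN: GroupSummary(24.2, 3.0, 20),
        _SZ: GroupSummary(23.9, 3.5, 20),
    },
    "education_years": {
        _HC: GroupSummary(16.1, 2.5, 20),
        _COTWIN: GroupSummary(15.0, 3.0, 20),
        _SZ: GroupSummary(10.0, 3.0, 20),
    },
    "panss": {
        _COTWIN: GroupSummary(34.2, 1.5, 20),
        _SZ: GroupSummary(67.1, 6.8, 20),
    },
    "mccb_speed_processing": {
        _HC: GroupSummary(46.9, 8.4, 20),
        _COTWIN: GroupSummary(40.4, 11.2, 20),
        _SZ: GroupSummary(34.5, 7.5, 20),
    },
    "mccb_attention": {
        _HC: GroupSummary(46.3, 10.2, 20),
        _COTWIN: GroupSummary(44.7, 7.3, 20),
        _SZ: GroupSummary(30.3, 10.9, 20),
    },
    "mccb_working_memory": {
        _HC: GroupSummary(48.8, 8.2, 20),
        _COTWIN: GroupSummary(42.5, 9.6, 20),
        _SZ: GroupSummary(34.1, 12.4, 20),
    },
    "mccb_verbal_learning": {
        _HC: GroupSummary(48.1, 10.1, 20),
        _COTWIN: GroupSummary(36.4, 11.6, 20),
        _SZ: GroupSummary(34.4, 10.4, 20),
    },
    "mccb_visual_learning": {
        _HC: GroupSummary(45.0, 10.1, 20),
        _COTWIN: GroupSummary(51.2, 8.7, 20),
        _SZ: GroupSummary(42.1, 8.8, 20),
    },
    "mccb_problem_reasoning": {
        _HC: GroupSummary(44.4, 7.6, 20),
        _COTWIN: GroupSummary(46.5, 10.5, 20),
        _SZ: GroupSummary(37.0, 10.4, 20),
    },
    "mccb_social_cognition": {
        _HC: GroupSummary(44.5, 9.6, 20),
        _COTWIN: GroupSummary(40.8, 14.0, 20),
        _SZ: GroupSummary(35.7, 12.4, 20),
    },
    "gaf": {
        _HC: GroupSummary(98.5, 8.6, 20),
        _COTWIN: GroupSummary(86.0, 7.5, 20),
        _SZ: GroupSummary(78.0, 7.6, 20),
    },
}


def clinical_score_spec(seed: int = 0) -> ClinicalScoreSpec:
    """Generative clinical-score spec matching the published cohort summaries."""
    scores = {
        name: {g: (s.mean, s.sd) for g, s in per_group.items()}
        for name, per_group in TWIN_COHORT_SUMMARIES.items()
    }
    return ClinicalScoreSpec(scores=scores, seed=seed)


def summary_table(
    summaries: Mapping[str, Mapping[str, GroupSummary]] = TWIN_COHORT_SUMMARIES,
) -> pd.DataFrame:
    """Cohort-description table: per-group mean (SD) plus F or t and p.

    Scores present in all three groups get a one-way ANOVA F (p from the
    F distribution); scores present in exactly two groups get a pooled t
    (p two-sided from the t distribution).
    """
    rows = []
    for name, per_group in summaries.items():
        row: dict = {"score": name}
        for g, s in per_group.items():
            row[g] = f"{s.mean:g} ({s.sd:g})"
        groups = list(per_group.values())
        if len(groups) >= 3:
            f = anova_from_summary(groups)
            df1 = len(groups) - 1
            df2 = sum(s.n for s in groups) - len(groups)
            row["statistic"] = f
            row["stat_kind"] = "F"
            row["p"] = float(stats.f.sf(f, df1, df2))
        elif len(groups) == 2:
            t = ttest_from_summary(groups[0], groups[1])
            df = groups[0].n + groups[1].n - 2
            row["statistic"] = t
            row["stat_kind"] = "t"
            row["p"] = float(2 * stats.t.sf(abs(t), df))
        rows.append(row)
    return pd.DataFrame(rows)
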