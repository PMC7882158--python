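"""Max-statistic permutation inference on edge families.

Two procedures, both controlling the family-wise error rate by comparing
each edge's t statistic against the permutation null distribution of the
maximum |t| over all edges:

* one-sample sign-flip test for the presence of an edge within a group:
  each permutation draws one random +/-1 sign per subject and applies it
  to that subject's whole edge vector (a single sign vector shared across
  edges — sharing is what makes the max statistic a valid FWE null),
  recomputes a one-sample t per edge, and records the maximum |t|;

* two-sample label-permutation test for group differences: each
  permutation reassigns subjects to the two groups with group sizes
  preserved, recomputes a pooled-variance two-sample t per edge, and
  records the maximum |t|.

The corrected p of an edge is the fraction of null maxima >= its true
|t| (which can be exactly 0, reported as p < 1/n_perm).  Random
permutations are simple Monte-Carlo draws (repeats allowed); both tests
offer an exhaustive mode that enumerates every sign assignment /
relabelling, used for small-sample validation.

Subjects are treated as exchangeable; twin-pair dependence is ignored —
a known statistical caveat of the emulated design.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import EdgeStatResult

logger = logging.getLogger(__name__)

#: relative tolerance when counting null |t| >= true |t|: permutations
#: that tie the observed statistic in exact arithmetic (e.g. the
#: complement relabelling) must count despite floating-point jitter
_TIE_RTOL = 1e-10


def _p_from_null(null_max: np.ndarray, true_t: np.ndarray) -> np.ndarray:
    thresh = np.abs(true_t) * (1 - _TIE_RTOL) - _TIE_RTOL
    return (null_max[:, None] >= thresh[None, :]).mean(axis=0)

__all__ = [
    "EdgeFeatureTable",
    "one_sample_maxt_perm",
    "two_sample_maxt_perm",
    "EdgeReport",
    "summarize_significant_edges",
]


@dataclass
class EdgeFeatureTable:
    """Subjects x edges feature matrix with group labels and edge names."""

    values: np.ndarray
    groups: Sequence[str]
    edge_index: Sequence[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x edges")
        self.groups = tuple(self.groups)
        if len(self.groups) != self.values.shape[0]:
            raise ValueError("one group label per subject required")
        if self.edge_index and len(self.edge_index) != self.values.shape[1]:
            raise ValueError("edge_index length must match number of edges")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    def subset(self, labels: Sequence[str]) -> "EdgeFeatureTable":
        keep = [i for i, g in enumerate(self.groups) if g in labels]
        return EdgeFeatureTable(
            self.values[keep], [self.groups[i] for i in keep], self.edge_index
        )


def _t_from_signs(signs: np.ndarray, x: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
    """One-sample t per edge for each sign assignment (vectorized).

    Sign flips leave per-subject squares unchanged, so only the mean
    varies across permutations: var = (sum x^2 - n*mean^2) / (n-1).
    """
    n = x.shape[0]
    means = signs @ x / n
    var = (sumsq - n * means**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    bad = ~np.isfinite(t)
    if bad.any():
        # zero variance under this flip: treat t as 0 for that edge
        logger.debug("zero-variance edges in %d permutation cells", int(bad.sum()))
        t = np.where(bad, 0.0, t)
    return t


def one_sample_maxt_perm(
    table: EdgeFeatureTable,
    n_perm: int = 1000,
    seed=0,
    alpha: float = 0.05,
    exhaustive: bool = False,
) -> EdgeStatResult:
    """Sign-flip max-|t| permutation test for edge presence.

    With ``exhaustive=True`` all 2^n sign vectors are enumerated (n is
    the subject count) and ``n_perm`` is ignored; the resulting p values
    are exact.
    """
    x = table.values
    n, n_edges = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sumsq = (x**2).sum(axis=0)
    true_t = _t_from_signs(np.ones((1, n)), x, sumsq)[0]
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    null_t = _t_from_signs(signs, x, sumsq)
    null_max = np.abs(null_t).max(axis=1)
    p = _p_from_null(null_max, true_t)
    return EdgeStatResult(
        true_t=true_t,
        p_corrected=p,
        null_max_abs_t=null_max,
        n_perm=signs.shape[0],
        alpha=alpha,
        edge_index=table.edge_index or None,
    )


def _two_sample_t(
    in_a: np.ndarray, x: np.ndarray, sums: np.ndarray, sumsq: np.ndarray, na: int, nb: int
) -> np.ndarray:
    """Pooled-variance two-sample t per edge for each 0/1 assignment row."""
    sa = in_a @ x
    qa = in_a @ (x**2)
    sb = sums - sa
    qb = sumsq - qa
    ma, mb = sa / na, sb / nb
    ssw = (qa - na * ma**2) + (qb - nb * mb**2)
    sp2 = np.clip(ssw, 0.0, None) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    bad = ~np.isfinite(t)
    if bad.any():
        t = np.where(bad, 0.0, t)
    return t


def two_sample_maxt_perm(
    table: EdgeFeatureTable,
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed=0,
    alpha: float = 0.05,
    exhaustive: bool = False,
) -> EdgeStatResult:
    """Label-permutation max-|t| test for group differences on every edge.

    The sign of the reported t is mean(group_a) - mean(group_b).  The
    permutation scheme is canonicalized over the sorted label pair, so
    swapping ``group_a`` and ``group_b`` flips every sign and leaves
    every p value identical.  ``exhaustive=True`` enumerates all
    C(na+nb, na) relabellings.
    """
    labels = {group_a, group_b}
    if group_a == group_b:
        raise ValueError("group_a and group_b must differ")
    sub = table.subset(labels)
    g1, g2 = sorted(labels)
    flip = 1.0 if (group_a, group_b) == (g1, g2) else -1.0
    member1 = np.array([g == g1 for g in sub.groups], dtype=float)
    n1 = int(member1.sum())
    n2 = sub.n_subjects - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 subjects")
    x = sub.values
    sums = x.sum(axis=0)
    sumsq = (x**2).sum(axis=0)
    true_t = flip * _two_sample_t(member1[None, :], x, sums, sumsq, n1, n2)[0]
    n = sub.n_subjects
    if exhaustive:
        assign = np.zeros((comb(n, n1), n))
        for row, idx in enumerate(itertools.combinations(range(n), n1)):
            assign[row, list(idx)] = 1.0
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        base = np.zeros(n)
        base[:n1] = 1.0
        assign = rng.permuted(np.tile(base, (n_perm, 1)), axis=1)
    null_t = _two_sample_t(assign, x, sums, sumsq, n1, n2)
    null_max = np.abs(null_t).max(axis=1)
    p = _p_from_null(null_max, true_t)
    return EdgeStatResult(
        true_t=true_t,
        p_corrected=p,
        null_max_abs_t=null_max,
        n_perm=assign.shape[0],
        alpha=alpha,
        edge_index=sub.edge_index or None,
    )


@dataclass
class EdgeReport:
    """Significant-edge table plus sign-pattern tallies."""

    table: pd.DataFrame
    sign_pattern_counts: dict[str, int]


def summarize_significant_edges(
    result: EdgeStatResult,
    index: Sequence[tuple[int, int]] | None = None,
    table: EdgeFeatureTable | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
) -> EdgeReport:
    """Tabulate significant edges sorted by p then descending |t|.

    When the feature table and the two group labels are supplied, the
    report includes per-group mean edge values and classifies each edge's
    sign pattern (``both_positive``, ``both_negative``,
    ``positive_in_{a}_negative_in_{b}`` or the converse).
    """
    index = index or result.edge_index
    sig = np.flatnonzero(result.significant)
    rows = []
    counts: dict[str, int] = {}
    for e in sig:
        src, tgt = index[e] if index is not None else (e, e)
        row = {
            "source": src,
            "target": tgt,
            "true_t": result.true_t[e],
            "p_corrected": result.p_corrected[e],
            "sign": "+" if result.true_t[e] >= 0 else "-",
        }
        if table is not None and group_a and group_b:
            ga = np.array([g == group_a for g in table.groups])
            gb = np.array([g == group_b for g in table.groups])
            mean_a = float(table.values[ga, e].mean())
            mean_b = float(table.values[gb, e].mean())
            row[f"mean_{group_a}"] = mean_a
            row[f"mean_{group_b}"] = mean_b
            if mean_a > 0 and mean_b > 0:
                pattern = "both_positive"
            elif mean_a < 0 and mean_b < 0:
                pattern = "both_negative"
            elif mean_a >= 0 > mean_b:
                pattern = f"positive_in_{group_a}_negative_in_{group_b}"
            else:
                pattern = f"negative_in_{group_a}_positive_in_{group_b}"
            row["pattern"] = pattern
            counts[pattern] = counts.get(pattern, 0) + 1
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["p_corrected", "true_t"],
            key=lambda c: c if c.name == "p_corrected" else -c.abs(),
        ).reset_index(drop=True)
    return EdgeReport(table=df, sign_pattern_counts=counts)
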