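"""Rater and scale analytics.

Associations between regional WMH loads and ordinal visual scores are
measured with Kendall's tau-b (tie-corrected; visual scores are heavily
tied). Confidence intervals are subject-level nonparametric percentile
bootstraps (default B = 1000). Agreement between raters is the two-way
random-effects, absolute-agreement, single-measures intraclass
correlation ICC(2,1), averaged over rater pairs; intra-rater agreement
applies the same form to repeat measurements.

Regional analytics return 36-cell bullseye matrices: tau of every
region's load against a score vector (correlation map), and per-region
tau differences between one rater and the mean of the remaining raters
(discrepancy map, the pink/blue plots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .loads import RegionalLoadTable
from .scales import ScoreTable, mean_scores
from .viz import BullseyeValues
from .zones import region_zone_layer

__all__ = [
    "TauResult",
    "IccResult",
    "kendall_tau",
    "bootstrap_ci",
    "tau_with_ci",
    "tau_difference",
    "correlation_map",
    "rater_discrepancy",
    "icc_2_1",
    "icc_pairwise",
    "icc_intra",
]

log = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Statistic undefined on the given data (e.g. constant vector)."""


@dataclass
class TauResult:
    tau: float
    ci_low: float | None = None
    ci_high: float | None = None
    n: int = 0
    B: int = 0
    seed: int | None = None


@dataclass
class IccResult:
    icc: float
    ci_low: float | None = None
    ci_high: float | None = None
    design: str = "pairwise inter-rater"
    n: int = 0


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected) between two vectors.

    Raises :class:`DegenerateDataError` if either vector is constant
    (tau undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("tau undefined for a constant vector")
    return float(sps.kendalltau(x, y, variant="b").statistic)


def bootstrap_ci(statistic, data: tuple[np.ndarray, ...], B: int = 1000,
                 seed: int | None = None, alpha: float = 0.05,
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI over subject-level resamples.

    ``data`` is a tuple of equal-length arrays resampled jointly (rows =
    subjects). Degenerate resamples on which the statistic raises are
    skipped and counted. Deterministic for a fixed seed.
    """
    arrays = [np.asarray(a) for a in data]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all data arrays must share the subject axis")
    if n < 10:
        raise ValueError(f"bootstrap needs >= 10 subjects, got {n}")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    skipped = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            vals[b] = statistic(*(a[idx] for a in arrays))
        except DegenerateDataError:
            vals[b] = np.nan
            skipped += 1
    if skipped:
        log.info("bootstrap_ci: skipped %d/%d degenerate resample(s)", skipped, B)
    ok = vals[np.isfinite(vals)]
    if ok.size == 0:
        raise DegenerateDataError("all bootstrap resamples degenerate")
    low, high = np.percentile(ok, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(low), float(high)


def tau_with_ci(x, y, B: int = 1000, seed: int | None = None) -> TauResult:
    """Kendall tau-b with a subject-level bootstrap percentile CI."""
    t = kendall_tau(x, y)
    lo, hi = bootstrap_ci(kendall_tau, (np.asarray(x), np.asarray(y)),
                          B=B, seed=seed)
    return TauResult(tau=t, ci_low=lo, ci_high=hi, n=len(x), B=B, seed=seed)


def tau_difference(loads_a, loads_b, score, B: int = 1000,
                   seed: int | None = None) -> tuple[float, tuple[float, float]]:
    """Difference of two tau-b statistics against the same score vector.

    Returns (tau(a, score) - tau(b, score)) with a paired bootstrap CI:
    the same subject resample is used for both statistics, so the
    difference is estimated on matched samples.
    """
    a = np.asarray(loads_a, dtype=float)
    b = np.asarray(loads_b, dtype=float)
    s = np.asarray(score, dtype=float)
    if not (a.shape == b.shape == s.shape):
        raise ValueError("loads_a, loads_b and score must share subjects")

    def delta(aa, bb, ss):
        return kendall_tau(aa, ss) - kendall_tau(bb, ss)

    d = delta(a, b, s)
    ci = bootstrap_ci(delta, (a, b, s), B=B, seed=seed)
    return float(d), ci


def _cohort_load_matrix(cohort: list[RegionalLoadTable]) -> np.ndarray:
    return np.stack([t.load for t in cohort], axis=0)  # subjects x 36


def correlation_map(cohort: list[RegionalLoadTable], scores,
                    min_subjects: int = 10) -> BullseyeValues:
    """Per-region tau-b between regional loads and a consensus score.

    Regions with constant loads across the cohort are masked.
    """
    loads = _cohort_load_matrix(cohort)
    scores = np.asarray(scores, dtype=float)
    if loads.shape[0] != scores.shape[0]:
        raise ValueError("cohort and scores must share subjects")
    if loads.shape[0] < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects")
    n_layers = cohort[0].n_layers
    taus = np.full(loads.shape[1], np.nan)
    for r in range(loads.shape[1]):
        try:
            taus[r] = kendall_tau(loads[:, r], scores)
        except DegenerateDataError:
            pass  # masked cell
    return BullseyeValues.from_vector(taus, "correlation", n_layers)


def rater_discrepancy(cohort: list[RegionalLoadTable], scores: ScoreTable,
                      rater, subscale: str) -> BullseyeValues:
    """Per-region tau difference: one rater vs the mean of the others.

    For each region r: tau(load_r, rater's score) - tau(load_r, average
    score of the remaining raters). Positive (pink) cells mark regions
    with comparatively stronger influence on that rater's scores.
    Requires >= 3 raters.
    """
    raters = scores.raters
    if len(raters) < 3:
        raise ValueError("rater discrepancy needs >= 3 raters")
    if rater not in raters:
        raise KeyError(f"unknown rater {rater!r}")
    others = [r for r in raters if r != rater]
    own = mean_scores(scores, raters=[rater])[subscale]
    rest = mean_scores(scores, raters=others)[subscale]
    common = own.index.intersection(rest.index)
    own, rest = own.loc[common], rest.loc[common]

    loads = _cohort_load_matrix(cohort)
    if loads.shape[0] != len(common):
        raise ValueError("cohort subjects do not match score subjects")
    n_layers = cohort[0].n_layers
    diffs = np.full(loads.shape[1], np.nan)
    for r in range(loads.shape[1]):
        try:
            diffs[r] = (kendall_tau(loads[:, r], own.to_numpy())
                        - kendall_tau(loads[:, r], rest.to_numpy()))
        except DegenerateDataError:
            pass
    return BullseyeValues.from_vector(diffs, "difference", n_layers)


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is a subjects x raters matrix with no missing entries.
    Computed from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings must be subjects x raters with n,k >= 2")
    if np.isnan(m).any():
        raise ValueError("missing ratings; drop incomplete subjects first")
    n, k = m.shape
    grand = m.mean()
    row_mean = m.mean(axis=1)
    col_mean = m.mean(axis=0)
    ss_rows = k * ((row_mean - grand) ** 2).sum()
    ss_cols = n * ((col_mean - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise DegenerateDataError("ICC undefined: zero variance")
    return float((msr - mse) / denom)


def icc_pairwise(scores: ScoreTable, subscale: str, B: int = 1000,
                 seed: int | None = None) -> IccResult:
    """Average pairwise ICC(2,1) between raters, bootstrap CI over subjects."""
    wide = scores.wide(subscale).dropna()
    raters = list(wide.columns)
    if len(raters) < 2:
        raise ValueError("need >= 2 raters")
    if wide.shape[0] < 5:
        raise ValueError("need >= 5 complete subjects")
    m = wide.to_numpy(dtype=float)
    if np.all(m == m.flat[0]):
        raise DegenerateDataError("constant scores; ICC undefined")
    pairs = [(i, j) for i in range(len(raters)) for j in range(i + 1, len(raters))]

    def mean_pair_icc(mm):
        vals = []
        for i, j in pairs:
            try:
                vals.append(icc_2_1(mm[:, [i, j]]))
            except DegenerateDataError:
                continue
        if not vals:
            raise DegenerateDataError("all rater pairs degenerate")
        return float(np.mean(vals))

    icc = mean_pair_icc(m)
    lo, hi = bootstrap_ci(mean_pair_icc, (m,), B=B, seed=seed)
    return IccResult(icc=icc, ci_low=lo, ci_high=hi,
                     design="pairwise inter-rater", n=m.shape[0])


def icc_intra(scores_t1, scores_t2, B: int = 1000,
              seed: int | None = None) -> IccResult:
    """Intra-rater ICC(2,1) between two repeat measurements."""
    a = np.asarray(scores_t1, dtype=float)
    b = np.asarray(scores_t2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("repeat measurements must be paired 1D vectors")
    if a.size < 5:
        raise ValueError("need >= 5 paired measurements")
    m = np.column_stack([a, b])
    icc = icc_2_1(m)
    lo, hi = bootstrap_ci(lambda mm: icc_2_1(mm), (m,), B=B, seed=seed)
    return IccResult(icc=icc, ci_low=lo, ci_high=hi,
                     design="intra-rater repeat", n=a.size)


def correlation_map_frame(bv: BullseyeValues) -> pd.DataFrame:
    """Tabular view of a 36-cell bullseye matrix (for CSV export)."""
    rows = []
    for z in range(1, 10):
        for l in range(1, bv.n_layers + 1):
            rows.append({"zone": z, "layer": l,
                         "value": bv.values[z - 1, l - 1],
                         "masked": bool(bv.mask[z - 1, l - 1])})
    return pd.DataFrame(rows)
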