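"""Open-probability (NPo), dwell-time and group-comparison statistics.

NPo is the total time the patch spends at any open level divided by the
total recording time, NPo = t_o / T -- unweighted by how many pores are
open, which matches the convention of single-channel patch reports.  A
conductance-weighted variant is provided separately under its own name so
the two can never be confused.

The binomial occupancy check is a diagnostic for the independent-monomer
interpretation of the multi-level openings: if N identical pores gate
independently, the time fractions of levels 0..N follow Binomial(N, p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .idealization import IdealizedRecord, extract_dwells

__all__ = [
    "GatingStats",
    "npo",
    "weighted_npo",
    "dwell_summary",
    "compare_groups",
    "binomial_occupancy_check",
    "gating_report",
]


@dataclass
class GatingStats:
    """Summary of one idealized record."""

    npo: float
    level_time_fractions: np.ndarray
    mean_open_dwell: float
    mean_closed_dwell: float
    n_open_events: int
    n_closed_events: int


def npo(record: IdealizedRecord) -> float:
    """NPo = t_o / T: fraction of total time at any level above closed."""
    if record.total_time <= 0:
        raise ValueError("record has no recorded time")
    open_time = record.durations[record.levels > 0].sum()
    return float(open_time / record.total_time)


def weighted_npo(record: IdealizedRecord) -> float:
    """Level-weighted open probability: sum_m m * f_m / N.

    Equals the mean fraction of open pores per monomer; distinct from
    :func:`npo`, which counts time at any open level equally.
    """
    fractions = record.level_time_fractions()
    n = record.n_levels - 1
    return float(np.dot(np.arange(record.n_levels), fractions) / n)


def dwell_summary(dwells) -> tuple[float, float, float]:
    """(mean s, sd s, ML exponential rate 1/s) of a dwell-duration sample.

    The maximum-likelihood exponential rate is 1/mean.  The sd uses the
    n-1 denominator (0 for a single dwell).
    """
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("empty dwell list")
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return mean, sd, 1.0 / mean


def compare_groups(values_a, values_b, equal_var: bool = False):
    """Two-sided two-sample t test between groups.

    Welch's test (unequal variances) by default; ``equal_var=True`` for the
    pooled-variance textbook variant.  Two identical zero-variance groups
    return (t=0, df, p=1) rather than the indeterminate 0/0.
    Returns (t, degrees of freedom, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, float(a.size + b.size - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else float(a.size + b.size - 2)
    return float(res.statistic), df, float(res.pvalue)


def binomial_occupancy_check(
    record: IdealizedRecord,
    n_monomers: int,
    subsample_factor: float = 10.0,
):
    """Chi-square test of level occupancy against Binomial(N, p_hat).

    p_hat is the per-monomer open fraction implied by the time fractions,
    p_hat = (sum_m m f_m) / N.  The chi-square compares the observed time
    fractions with the binomial expectation.  Because consecutive stretches
    of a gating record are autocorrelated, the fractions carry fewer
    independent observations than there are events; the statistic is scaled
    by a conservative effective sample size of one independent observation
    per ``subsample_factor`` events, so the returned p-value errs toward
    non-rejection (df = levels kept - 2, one lost to the fitted p_hat).

    Returns (p_hat, chi_square, p_value).
    """
    if record.n_levels != n_monomers + 1:
        raise ValueError("record n_levels must equal n_monomers + 1")
    fractions = record.level_time_fractions()
    p_hat = float(np.dot(np.arange(record.n_levels), fractions) / n_monomers)

    n_eff = max(record.n_events / subsample_factor, 1.0)
    expected = stats.binom.pmf(np.arange(record.n_levels), n_monomers, p_hat)
    keep = expected > 1e-12
    chi2 = float(n_eff * np.sum((fractions[keep] - expected[keep]) ** 2 / expected[keep]))
    df = max(int(keep.sum()) - 2, 1)
    p_value = float(stats.chi2.sf(chi2, df))
    return p_hat, chi2, p_value


def gating_report(record: IdealizedRecord) -> GatingStats:
    """NPo, occupancy fractions and censoring-aware dwell summaries.

    Boundary-truncated first/last events are excluded from the dwell means
    (they are censored observations) but still count toward time fractions.
    """
    fractions = record.level_time_fractions()
    closed = extract_dwells(record, 0, drop_censored=True)
    open_dwells = np.concatenate(
        [extract_dwells(record, lv, drop_censored=True) for lv in range(1, record.n_levels)]
    )
    return GatingStats(
        npo=npo(record),
        level_time_fractions=fractions,
        mean_open_dwell=float(open_dwells.mean()) if open_dwells.size else float("nan"),
        mean_closed_dwell=float(closed.mean()) if closed.size else float("nan"),
        n_open_events=int(open_dwells.size),
        n_closed_events=int(closed.size),
    )
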