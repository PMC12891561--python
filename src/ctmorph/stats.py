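"""Nonparametric group comparisons and bimodality detection.

The comparisons mirror standard figure-caption statistics for this kind of
imaging data: a two-sided Mann-Whitney U test for per-nucleus measurements,
Fisher's two-tailed exact test for paired/unpaired count tables, and Levene's
test for spread differences.  ``detect_bimodality`` operationalizes the
visual "two modes with a local minimum between them" read-out of paired-arm
volume distributions with a Gaussian KDE (Silverman bandwidth) and a
prominence floor on candidate modes.

No multiple-testing correction is applied; p-values are per comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    sidedness: str = "two-sided"
    note: str = ""


@dataclass
class BimodalityResult:
    is_bimodal: bool
    antimode: float | None
    mode_locations: tuple[float, ...]
    bandwidth: float | None
    note: str = ""


def _as_sample(x, name, min_n=1):
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"sample {name} needs >= {min_n} observations")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def mann_whitney_u(a, b, *, exact_max_n=12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Small samples (n_a + n_b <= ``exact_max_n``) are evaluated exactly: by
    enumeration of the U null distribution when there are no ties, and by full
    permutation enumeration otherwise (so identical samples give p = 1
    exactly).  Larger samples use the normal approximation with midrank tie
    correction and continuity correction.  The reported statistic is U for
    the first sample.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size + b.size <= exact_max_n
    if small and not has_ties:
        method = "exact"
    elif small:
        # full enumeration (C(n_a+n_b, n_a) <= 924 below the resample cap)
        method = sp_stats.PermutationMethod(n_resamples=100000,
                                            rng=np.random.default_rng(0))
    else:
        method = "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann_whitney_u", float(res.statistic),
                      float(min(res.pvalue, 1.0)), a.size, b.size)


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's two-tailed exact test on a 2×2 count table.

    The two-tailed p sums hypergeometric probabilities (margins fixed) of all
    tables at most as probable as the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(np.int64)
        if np.any(t < 0) or not np.allclose(t, t_int):
            raise ValueError("table must hold nonnegative integers")
        t = t_int
    if t.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    odds, p = sp_stats.fisher_exact(t, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(min(p, 1.0)),
                      int(t[0].sum()), int(t[1].sum()))


def levene(a, b, *, center="median") -> TestResult:
    """Levene's test for equality of spread between two samples.

    ``center='median'`` (default) is the robust Brown-Forsythe variant;
    ``center='mean'`` gives the classical test.  Two samples whose absolute
    deviations are all zero (e.g. identical constants) return statistic 0 and
    p = 1 by convention, flagged in ``note``.
    """
    a = _as_sample(a, "a", min_n=2)
    b = _as_sample(b, "b", min_n=2)
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    cfun = np.median if center == "median" else np.mean
    dev_a = np.abs(a - cfun(a))
    dev_b = np.abs(b - cfun(b))
    pooled_dev = np.concatenate([dev_a, dev_b])
    if np.allclose(pooled_dev, pooled_dev[0]):
        return TestResult("levene", 0.0, 1.0, a.size, b.size,
                          note="degenerate: constant absolute deviations")
    stat, p = sp_stats.levene(a, b, center=center)
    return TestResult("levene", float(stat), float(min(p, 1.0)),
                      a.size, b.size, note=f"center={center}")


def detect_bimodality(values, *, bandwidth=None, prominence_floor=0.05,
                      grid_size=512, min_n=20) -> BimodalityResult:
    """Detect a bimodal distribution and locate its antimode.

    A Gaussian KDE (Silverman's rule unless ``bandwidth`` — a bw_method
    factor — is given) is evaluated on a regular grid spanning the data range
    padded by three bandwidths.  Interior local maxima whose density reaches
    at least ``prominence_floor`` × the global maximum count as modes; with
    two or more modes the distribution is bimodal and the antimode is the
    density minimum between the two highest modes.

    Samples below ``min_n`` observations or with zero variance return
    unimodal with an explanatory note.
    """
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        return BimodalityResult(False, None, (), None,
                                note=f"n={arr.size} < {min_n}")
    if np.ptp(arr) == 0:
        return BimodalityResult(False, None, (float(arr[0]),), None,
                                note="constant sample")
    kde = sp_stats.gaussian_kde(arr,
                                bw_method=bandwidth or "silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    lo, hi = arr.min() - 3 * h, arr.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    floor = prominence_floor * dens.max()
    peaks, _ = sp_signal.find_peaks(dens, height=floor)
    modes = tuple(float(grid[p]) for p in peaks)
    if len(peaks) < 2:
        return BimodalityResult(False, None, modes, h)
    # antimode between the two highest modes
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    antimode_idx = left + int(np.argmin(dens[left:right + 1]))
    return BimodalityResult(True, float(grid[antimode_idx]), modes, h)


def compare_groups(frame, value_col, group_col, group_a, group_b,
                   test="mannwhitney", **kwargs) -> TestResult:
    """Run a named two-group comparison on a tidy DataFrame."""
    a = frame.loc[frame[group_col] == group_a, value_col].to_numpy()
    b = frame.loc[frame[group_col] == group_b, value_col].to_numpy()
    if test in ("mannwhitney", "mann_whitney_u"):
        return mann_whitney_u(a, b, **kwargs)
    if test == "levene":
        return levene(a, b, **kwargs)
    raise ValueError(f"unknown test {test!r}")
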