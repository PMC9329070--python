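"""Statistical tests used throughout the pipeline.

Group sizes in two-layer bottle incubations are tiny (two replicate
bottles per condition; at most a handful of compounds pooled per class),
which is exactly the regime where the normal approximation to the
Mann-Whitney U null distribution is poor.  ``mann_whitney`` therefore
computes the exact two-sided permutation p-value by complete enumeration
of all ``C(n1+n2, n1)`` group assignments whenever the pooled sample is
small, using mid-ranks for ties and enumerating over the tied data as
observed (the conservative convention).  Larger samples fall back to the
tie-corrected normal approximation with continuity correction.

Also provided: paired and Welch two-sample t-tests, the signed
fold-change convention of R's ``gtools::foldchange`` (magnitude always
>= 1, negative when the denominator group is larger), and an optional
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InputError

__all__ = [
    "Method",
    "TestResult",
    "mann_whitney",
    "t_test",
    "fold_change",
    "benjamini_hochberg",
    "DEFAULT_EXACT_THRESHOLD",
]

#: Largest pooled sample size for which the exact permutation null is
#: enumerated by default (C(12, 6) = 924 assignments).
DEFAULT_EXACT_THRESHOLD = 12


class Method(str, enum.Enum):
    MANN_WHITNEY_EXACT = "MANN_WHITNEY_EXACT"
    MANN_WHITNEY_NORMAL = "MANN_WHITNEY_NORMAL"
    T_PAIRED = "T_PAIRED"
    T_WELCH = "T_WELCH"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: Method
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InputError(f"p-value outside [0, 1]: {self.p_value}")


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise InputError(f"sample {name!r} is empty")
    if not np.isfinite(arr).all():
        raise InputError(f"sample {name!r} contains non-finite values")
    return arr


def _exact_mann_whitney_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumeration of group assignments.

    Counts assignments whose U statistic is at least as far from the null
    mean ``n1*n2/2`` as the observed one.  Ranks are mid-ranks of the
    pooled data, so U values are exact multiples of 0.5 and the
    comparison is free of rounding concerns.
    """
    n = ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    d_obs = abs(u_obs - mu)
    offset = n1 * (n1 + 1) / 2.0
    count = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= d_obs:
            count += 1
    return count / math.comb(n, n1)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> TestResult:
    """Two-sided Mann-Whitney U test (unpaired Wilcoxon rank-sum).

    Parameters
    ----------
    x, y
        Numeric samples, each non-empty.
    mode
        ``"auto"`` (exact when ``n1+n2 <= exact_threshold``), ``"exact"``
        (force enumeration) or ``"normal"`` (force the tie-corrected
        normal approximation with continuity correction).

    Returns
    -------
    TestResult
        U statistic of the first sample and the two-sided p-value.
    """
    if mode not in {"auto", "exact", "normal"}:
        raise InputError(f"unknown mode {mode!r}")
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    n1, n2 = xa.size, ya.size
    ranks = stats.rankdata(np.concatenate([xa, ya]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    exact = mode == "exact" or (mode == "auto" and n1 + n2 <= exact_threshold)
    if exact:
        p = _exact_mann_whitney_p(ranks, n1, u1)
        return TestResult(statistic=u1, p_value=p, n1=n1, n2=n2,
                          method=Method.MANN_WHITNEY_EXACT)

    res = stats.mannwhitneyu(xa, ya, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    # All-tied data yield zero rank variance and an undefined z score.
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return TestResult(statistic=float(res.statistic), p_value=min(p, 1.0),
                      n1=n1, n2=n2, method=Method.MANN_WHITNEY_NORMAL)


def t_test(x: Sequence[float], y: Sequence[float], paired: bool = False) -> TestResult:
    """Two-sided t-test: paired, or Welch's unequal-variance when unpaired.

    Raises
    ------
    DegenerateDataError
        For zero variance of the paired differences (or of both unpaired
        samples), where the t statistic is undefined.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    if paired:
        if xa.size != ya.size:
            raise InputError("paired test requires equal sample lengths")
        if xa.size < 2:
            raise InputError("paired test requires n >= 2")
        diffs = xa - ya
        if np.std(diffs, ddof=1) == 0.0:
            raise DegenerateDataError(
                "paired differences have zero standard deviation; t undefined"
            )
        res = stats.ttest_rel(xa, ya)
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n1=xa.size, n2=ya.size, method=Method.T_PAIRED,
                          df=float(xa.size - 1))
    if xa.size < 2 or ya.size < 2:
        raise InputError("Welch test requires n >= 2 in each group")
    if np.std(xa, ddof=1) == 0.0 and np.std(ya, ddof=1) == 0.0:
        raise DegenerateDataError("both samples have zero variance; t undefined")
    with warnings.catch_warnings():
        # near-identical samples trigger a precision-loss RuntimeWarning;
        # the statistic is still well defined here
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xa, ya, equal_var=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n1=xa.size, n2=ya.size, method=Method.T_WELCH,
                      df=float(res.df))


def fold_change(num: float, denom: float) -> float:
    """Signed fold change (gtools convention).

    ``num/denom`` when ``num >= denom``, else ``-denom/num``; the
    magnitude is always >= 1 and ``fold_change(a, b) == -fold_change(b, a)``
    whenever ``a != b``.  Both inputs must be strictly positive.
    """
    if not (num > 0 and denom > 0):
        raise InputError(
            f"fold change requires strictly positive inputs, got ({num}, {denom})"
        )
    return num / denom if num >= denom else -denom / num


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default downstream)."""
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]
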