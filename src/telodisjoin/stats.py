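"""Rank-based statistical primitives shared by the pipeline.

The central tool is a self-contained Mann-Whitney-Wilcoxon test with an
exact permutation null (enumerated over the observed pooled multiset, so
ties are handled exactly) and a tie-corrected normal approximation with
continuity correction for larger samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "ReplicateSummary",
    "mann_whitney",
    "replicate_summary",
    "holm_adjust",
]

#: largest number of label assignments the exact path will enumerate.
_MAX_EXACT_ASSIGNMENTS = 2_000_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample rank test.

    ``statistic`` is the U statistic of the first sample (x), in
    ``[0, n1*n2]``. ``method`` is ``"exact"`` or ``"normal_approximation"``.
    """

    statistic: float
    n1: int
    n2: int
    p_value: float
    method: str
    alternative: str
    tie_correction: bool
    all_ties: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.statistic <= self.n1 * self.n2 + 1e-9):
            raise ValueError("U statistic outside [0, n1*n2]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value outside (0, 1]")


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float
    n: int
    single_replicate: bool = False


@lru_cache(maxsize=128)
def _combination_indices(n: int, k: int) -> np.ndarray:
    """All k-subsets of range(n), as an (C(n,k), k) integer array."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """U of x (rank-sum form, average ties), pooled ranks, tie flag."""
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    return u1, ranks, has_ties


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float, alternative: str) -> float:
    """Permutation p-value by enumerating which pooled values are labelled x."""
    n = ranks.size
    combos = _combination_indices(n, n1)
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * (n - n1) / 2.0
    eps = 1e-9
    if alternative == "two-sided":
        count = np.count_nonzero(np.abs(u_all - mu) >= abs(u_obs - mu) - eps)
    elif alternative == "greater":
        count = np.count_nonzero(u_all >= u_obs - eps)
    elif alternative == "less":
        count = np.count_nonzero(u_all <= u_obs + eps)
    else:  # pragma: no cover - validated upstream
        raise ValueError(alternative)
    return count / u_all.size


def _normal_p(
    u_obs: float, n1: int, n2: int, pooled: np.ndarray, alternative: str
) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction.

    Returns (p, sigma); sigma == 0 signals a fully tied pooled sample.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0, 0.0
    sigma = math.sqrt(var)
    if alternative == "two-sided":
        z = max(abs(u_obs - mu) - 0.5, 0.0) / sigma
        p = 2.0 * norm.sf(z)
    elif alternative == "greater":
        z = (u_obs - mu - 0.5) / sigma
        p = norm.sf(z)
    else:
        z = (u_obs - mu + 0.5) / sigma
        p = norm.cdf(z)
    return float(min(max(p, np.nextafter(0, 1)), 1.0)), sigma


def mann_whitney(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    alternative: str = "two-sided",
    method: str = "auto",
    exact_limit: int = 20,
) -> TestResult:
    """Mann-Whitney-Wilcoxon test of two independent samples.

    Parameters
    ----------
    x, y
        Non-empty samples.
    alternative
        ``"two-sided"`` (default), ``"greater"`` (x tends larger) or
        ``"less"``.
    method
        ``"exact"`` enumerates the permutation null over the observed pooled
        multiset; ``"normal_approximation"`` uses the tie-corrected normal
        approximation with continuity correction; ``"auto"`` picks exact when
        ``len(x) + len(y) <= exact_limit``.

    Notes
    -----
    The two-sided exact p-value is the null probability of
    ``|U - n1*n2/2| >= |u_obs - n1*n2/2|`` (counting convention, no
    doubling). A fully tied pooled sample yields ``p = 1`` with the
    ``all_ties`` flag set.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("auto", "exact", "normal_approximation"):
        raise ValueError(f"unknown method {method!r}")

    n1, n2 = x.size, y.size
    u_obs, ranks, has_ties = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    all_ties = bool(np.ptp(pooled) == 0)

    if method == "auto":
        method = "exact" if n1 + n2 <= exact_limit else "normal_approximation"
    if method == "exact" and math.comb(n1 + n2, n1) > _MAX_EXACT_ASSIGNMENTS:
        raise ValueError(
            f"exact enumeration infeasible for n1={n1}, n2={n2}; "
            "use the normal approximation"
        )

    if all_ties:
        return TestResult(u_obs, n1, n2, 1.0, method, alternative, has_ties, True)

    if method == "exact":
        p = _exact_p(ranks, n1, u_obs, alternative)
        return TestResult(u_obs, n1, n2, p, "exact", alternative, has_ties)

    p, sigma = _normal_p(u_obs, n1, n2, pooled, alternative)
    if sigma == 0.0:
        return TestResult(
            u_obs, n1, n2, 1.0, "normal_approximation", alternative, has_ties, True
        )
    return TestResult(u_obs, n1, n2, p, "normal_approximation", alternative, has_ties)


def replicate_summary(values: Iterable[float]) -> ReplicateSummary:
    """Mean and n-1 sample SD of replicate measurements.

    With a single replicate the SD is reported as 0 and flagged.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one replicate")
    if arr.size == 1:
        return ReplicateSummary(float(arr[0]), 0.0, 1, single_replicate=True)
    return ReplicateSummary(
        float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted
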