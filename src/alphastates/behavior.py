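"""Cohort-level statistics: mean-alpha summaries, pain change, Friedman, Pearson.

The behavioral outcome is the mean of six 0-10 VAS ratings collected every
30 s during a 3-min cold-pressor block; the change score for session s is
that session's block mean minus the pre-neurofeedback block mean of session
1 (negative = pain reduction).  Repeated-measures change across the five
sessions is tested with the Friedman rank statistic; associations between
alpha-state parameters and pain change use Pearson correlation over pooled
(participant, session) pairs within each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "FriedmanResult",
    "CorrelationResult",
    "normalized_mean_alpha",
    "pain_change",
    "vas_block_mean",
    "friedman_across_sessions",
    "correlate_with_pain",
]

VAS_RATINGS_PER_BLOCK = 6


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float
    method: str = "chi-square"

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1) and not np.isnan(self.p):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        """Two-sided significance at the conventional 0.05 level."""
        return bool(self.p < 0.05)


def normalized_mean_alpha(session_powers: list[np.ndarray]) -> np.ndarray:
    """Normalized log mean alpha power, one dimensionless score per session.

    Per-epoch powers are log-transformed, averaged within each session, then
    z-scored across the participant's sessions (sample SD).  A participant
    whose session means do not vary gets all-zero scores with a warning.
    """
    if len(session_powers) < 2:
        raise ValueError("need at least 2 sessions to normalize across sessions")
    means = []
    for p in session_powers:
        p = np.asarray(p, float)
        if (p <= 0).any():
            raise ValueError("alpha power must be positive for the log transform")
        means.append(np.log(p).mean())
    means = np.asarray(means)
    sd = means.std(ddof=1)
    if sd == 0:
        warnings.warn("session means are constant; normalized scores set to 0", UserWarning,
                      stacklevel=2)
        return np.zeros_like(means)
    return (means - means.mean()) / sd


def vas_block_mean(ratings: np.ndarray) -> float:
    """Mean of the six VAS ratings of one cold-pressor block."""
    ratings = np.asarray(ratings, float)
    if ratings.size != VAS_RATINGS_PER_BLOCK:
        raise ValueError(f"a cold-pressor block has exactly {VAS_RATINGS_PER_BLOCK} ratings, "
                         f"got {ratings.size}")
    if (ratings < 0).any() or (ratings > 10).any():
        raise ValueError("VAS ratings must lie in [0, 10]")
    return float(ratings.mean())


def pain_change(session_blocks: list[np.ndarray], baseline_block: np.ndarray) -> np.ndarray:
    """Per-session pain change: block mean minus the pre-any-NFB baseline mean.

    ``baseline_block`` is the session-1 pre-neurofeedback block.  Negative
    values mean pain reduction.
    """
    base = vas_block_mean(baseline_block)
    return np.asarray([vas_block_mean(b) - base for b in session_blocks])


def _friedman_chi2(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square; 0 when every row is fully tied."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(sstats.rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    den = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if den == 0:
        return 0.0  # all ranks tied: no evidence of any session effect
    return float(num / den)


def friedman_across_sessions(
    matrix: np.ndarray,
    *,
    method: str = "chi-square",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> FriedmanResult:
    """Friedman test of a (participants x sessions) parameter matrix.

    Ranks within each participant with average-rank tie handling; the
    statistic is referred to chi-square with df = sessions - 1 (default), or
    to a within-row permutation null (``method="permutation"``), which is
    preferable at the very small n typical of these cohorts.
    Missing cells are not supported.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2:
        raise ValueError("matrix must be participants x sessions")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 participants and >= 2 sessions")
    if np.isnan(X).any():
        raise ValueError("missing cells are not supported")
    chi2 = _friedman_chi2(X)
    df = k - 1
    if method == "chi-square":
        p = float(sstats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
        return FriedmanResult(chi2=chi2, df=df, p=p, method=method)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = np.array([rng.permutation(row) for row in X])
            if _friedman_chi2(perm) >= chi2 - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        return FriedmanResult(chi2=chi2, df=df, p=float(p), method=method)
    raise ValueError(f"unknown method {method!r}")


def correlate_with_pain(parameter: np.ndarray, pain_changes: np.ndarray) -> CorrelationResult:
    """Pearson r (two-sided p) between an alpha-state parameter and pain change.

    Pairs are pooled (participant, session) observations within one group.
    Degenerate inputs (zero variance in either variable) yield NaN r with a
    warning rather than an error.
    """
    x = np.asarray(parameter, float)
    y = np.asarray(pain_changes, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("parameter and pain_changes must be 1-d and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", UserWarning, stacklevel=2)
        return CorrelationResult(r=float("nan"), p=float("nan"), n=int(x.size))
    r, p = sstats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))
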