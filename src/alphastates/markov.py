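"""Two-state Markov chain estimation from symbolized alpha sequences.

With the emission matrix forced to the identity, the hidden state sequence
is fully observed and the maximum-likelihood transition estimate reduces to
row-normalized pair counts; the test suite asserts the equivalence to an
identity-emission hidden-Markov estimator explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["TransitionMatrix", "estimate_transitions", "stationary_distribution",
           "stationary_high"]

STATE_NAMES = ("low", "high")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 2x2 transition probabilities with underlying counts.

    Row/column order is (low, high).  A row for a never-visited state is NaN
    (its conditional distribution is undefined).
    """

    probabilities: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, float)
        c = np.asarray(self.counts)
        if p.shape != (2, 2) or c.shape != (2, 2):
            raise ValueError("probabilities and counts must be 2x2")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        for i in range(2):
            if c[i].sum() > 0:
                if np.isnan(p[i]).any() or abs(p[i].sum() - 1.0) > 1e-12:
                    raise ValueError(f"row {i} must sum to 1")
                if (p[i] < 0).any() or (p[i] > 1).any():
                    raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "counts", np.asarray(c, dtype=int))

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    @property
    def p_low_to_high(self) -> float:
        return float(self.probabilities[0, 1])

    @property
    def p_high_to_low(self) -> float:
        return float(self.probabilities[1, 0])

    def as_labeled_rows(self) -> dict[str, float]:
        """The four transition entries under their conventional labels."""
        p = self.probabilities
        return {
            "low_to_low": float(p[0, 0]),
            "low_to_high": float(p[0, 1]),
            "high_to_high": float(p[1, 1]),
            "high_to_low": float(p[1, 0]),
        }


def estimate_transitions(
    seq: np.ndarray, *, smoothing: float = 0.0, strict: bool = False
) -> TransitionMatrix:
    """Count-based MLE of the transition matrix from a 0/1 state sequence.

    ``smoothing`` adds +alpha pseudocounts to every cell before normalizing
    (off by default: extreme rows such as absorbing behavior are reported
    unsmoothed).  A never-visited from-state yields a NaN row with a warning,
    or an error when ``strict``.
    """
    seq = np.asarray(seq).astype(int)
    if seq.size < 2:
        raise ValueError("need at least 2 epochs to count transitions")
    if not np.isin(seq, (0, 1)).all():
        raise ValueError("sequence must contain only 0/1 symbols")
    counts = np.zeros((2, 2))
    np.add.at(counts, (seq[:-1], seq[1:]), 1)
    smoothed = counts + smoothing
    row_tot = smoothed.sum(axis=1)
    probs = np.full((2, 2), np.nan)
    for i in range(2):
        if row_tot[i] > 0:
            probs[i] = smoothed[i] / row_tot[i]
        else:
            msg = f"state {STATE_NAMES[i]!r} never occupied before a transition; its row is undefined"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
    return TransitionMatrix(probabilities=probs, counts=counts)


def stationary_high(p_low_to_high: float, p_high_to_low: float) -> float:
    """Closed-form stationary probability of the high state, p_LH / (p_LH + p_HL)."""
    for name, p in (("p_low_to_high", p_low_to_high), ("p_high_to_low", p_high_to_low)):
        if not (0 <= p <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    s = p_low_to_high + p_high_to_low
    if s == 0:
        raise ValueError("both off-diagonal probabilities are 0: no unique stationary distribution")
    return p_low_to_high / s


def stationary_distribution(T: TransitionMatrix | np.ndarray) -> tuple[float, float]:
    """Stationary (pi_low, pi_high) of a two-state chain; satisfies pi @ T = pi.

    Requires both rows defined.  Degenerate chains with both off-diagonal
    entries zero have no unique stationary distribution and raise.
    """
    p = T.probabilities if isinstance(T, TransitionMatrix) else np.asarray(T, float)
    if np.isnan(p).any():
        raise ValueError("transition matrix has undefined rows")
    pi_high = stationary_high(float(p[0, 1]), float(p[1, 0]))
    return (1.0 - pi_high, pi_high)
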