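"""Synthetic bistable-alpha EEG cohorts with known ground truth.

The alpha rhythm of resting EEG alternates erratically between a high- and a
low-amplitude mode.  This module realizes that picture generatively: a
two-state Markov chain at 1-s epoch resolution drives the amplitude of an
8-13 Hz oscillator riding on pink + white background noise, and a simple
pain model plants a negative dependence of cold-pressor VAS ratings on
high-state occupancy.  Everything is seeded and reproducible, so every
downstream analysis stage can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .preprocess import RawEEG

LOW, HIGH = 0, 1

__all__ = [
    "MarkovParams",
    "EmissionParams",
    "CohortSpec",
    "CohortRecord",
    "SyntheticCohort",
    "simulate_state_sequence",
    "synthesize_eeg",
    "simulate_cohort",
    "pink_noise",
]


@dataclass(frozen=True)
class MarkovParams:
    """Per-epoch transition probabilities of the two-state alpha chain.

    ``p_low_to_high`` / ``p_high_to_low`` are the probabilities of switching
    state from one 1-s epoch to the next.  ``initial_state`` may be ``"low"``,
    ``"high"`` or ``"stationary"`` (draw the first state from the stationary
    distribution, which requires a non-degenerate chain).
    """

    p_low_to_high: float
    p_high_to_low: float
    initial_state: Literal["low", "high", "stationary"] = "stationary"

    def __post_init__(self) -> None:
        for name in ("p_low_to_high", "p_high_to_low"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p!r}")
        if self.initial_state not in ("low", "high", "stationary"):
            raise ValueError(f"unknown initial_state {self.initial_state!r}")
        if self.initial_state == "stationary" and self.p_low_to_high + self.p_high_to_low == 0:
            raise ValueError("stationary initial state requires p_low_to_high + p_high_to_low > 0")

    @property
    def stationary_high(self) -> float:
        """Long-run probability of the high state, p_LH / (p_LH + p_HL)."""
        s = self.p_low_to_high + self.p_high_to_low
        if s == 0:
            raise ValueError("degenerate chain has no unique stationary distribution")
        return self.p_low_to_high / s


@dataclass(frozen=True)
class EmissionParams:
    """How a state sequence is rendered as a two-channel EEG signal.

    The alpha oscillator is phase-continuous across epoch boundaries (so
    epoch edges do not leak spectral power) with amplitude ``amp_high`` or
    ``amp_low`` (uV) according to the state of each 1-s epoch.  Background
    activity is 1/f (pink) noise of standard deviation ``pink_noise_sd`` plus
    white noise of ``white_noise_sd``, drawn independently per channel.
    """

    alpha_freq: float = 10.0
    amp_high: float = 20.0
    amp_low: float = 5.0
    pink_noise_sd: float = 2.0
    white_noise_sd: float = 1.0
    amp_jitter_sd: float = 0.0
    sampling_rate: int = 1000
    channel_labels: tuple[str, ...] = ("AF3", "AF4")

    def __post_init__(self) -> None:
        if not (self.amp_high >= self.amp_low >= 0):
            raise ValueError("require amp_high >= amp_low >= 0")
        if self.sampling_rate <= 2 * self.alpha_freq:
            raise ValueError("sampling_rate must exceed twice the alpha frequency")
        if self.pink_noise_sd < 0 or self.white_noise_sd < 0 or self.amp_jitter_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if int(self.sampling_rate) != self.sampling_rate:
            raise ValueError("sampling_rate must be an integer (samples per 1-s epoch)")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic two-group, five-session neurofeedback cohort.

    Defaults mirror the study conditions being emulated: 4 participants per
    group, 5 sessions, 2 min of eyes-open rest (120 epochs) and 2 x 5 min of
    neurofeedback (600 epochs) per session, and six 0-10 VAS pain ratings per
    3-min cold-pressor block (one rating every 30 s).

    Group baselines are the session-1 transition probabilities; ``drift_*``
    are additive per-session increments (p_low_to_high, p_high_to_low),
    clipped to [0, 1], modelling learning as a linear drift.  The pain model
    draws each rating from N(mu, vas_noise_sd) clipped to [0, 10] where the
    post-block mean decreases by ``effect_slope`` VAS units per unit gain in
    realized high-state occupancy relative to session 1.
    """

    n_per_group: int = 4
    n_sessions: int = 5
    patient_start: MarkovParams = MarkovParams(0.37, 0.22)
    healthy_start: MarkovParams = MarkovParams(0.53, 0.25)
    drift_patient: tuple[float, float] = (0.0, -0.04)
    drift_healthy: tuple[float, float] = (0.0, 0.0)
    resting_epochs: int = 120
    nfb_epochs: int = 600
    vas_per_block: int = 6
    baseline_vas: float = 6.0
    effect_slope: float = 5.0
    vas_noise_sd: float = 1.0
    emission: EmissionParams = EmissionParams()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_sessions < 1:
            raise ValueError("n_per_group and n_sessions must be >= 1")
        if not (0.0 <= self.baseline_vas <= 10.0):
            raise ValueError("baseline_vas must lie in [0, 10]")
        if self.vas_noise_sd < 0:
            raise ValueError("vas_noise_sd must be non-negative")

    def session_params(self, group: str, session: int) -> MarkovParams:
        """Transition probabilities of `group` in 1-based `session`, drift applied and clipped."""
        start = self.patient_start if group == "patient" else self.healthy_start
        d_lh, d_hl = self.drift_patient if group == "patient" else self.drift_healthy
        k = session - 1
        return MarkovParams(
            float(np.clip(start.p_low_to_high + k * d_lh, 0.0, 1.0)),
            float(np.clip(start.p_high_to_low + k * d_hl, 0.0, 1.0)),
            start.initial_state,
        )


def simulate_state_sequence(params: MarkovParams, n_epochs: int, seed: int) -> np.ndarray:
    """Simulate `n_epochs` symbols (0 = low alpha, 1 = high alpha) of the chain.

    Reproducible for a given seed.  The first symbol is the initial state
    (or a stationary draw); the remaining n-1 symbols follow the chain, so a
    length-n sequence carries exactly n-1 transitions.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    if params.initial_state == "stationary":
        state = HIGH if rng.random() < params.stationary_high else LOW
    else:
        state = HIGH if params.initial_state == "high" else LOW
    u = rng.random(n_epochs - 1)
    out = np.empty(n_epochs, dtype=np.int8)
    out[0] = state
    p_lh, p_hl = params.p_low_to_high, params.p_high_to_low
    for i in range(1, n_epochs):
        if state == LOW:
            state = HIGH if u[i - 1] < p_lh else LOW
        else:
            state = LOW if u[i - 1] < p_hl else HIGH
        out[i] = state
    return out


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise of length `n` (spectral shaping by FFT)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_eeg(states: np.ndarray, emission: EmissionParams = EmissionParams(), *, seed: int = 0) -> RawEEG:
    """Render a state sequence as raw two-channel EEG.

    Each symbol yields exactly ``sampling_rate`` samples.  The alpha
    oscillator is shared across channels and phase-continuous; pink and white
    noise are independent per channel.  When ``amp_high > amp_low`` the
    expected alpha-band power of high-state epochs exceeds that of low-state
    epochs, which is what the downstream symbolization recovers.
    """
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("state sequence must be non-empty")
    if not np.isin(states, (0, 1)).all():
        raise ValueError("state sequence must contain only 0/1 symbols")
    fs = int(emission.sampling_rate)
    n = states.size * fs
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    carrier = np.sin(2 * np.pi * emission.alpha_freq * t)  # phase-continuous
    amp = np.where(states == HIGH, emission.amp_high, emission.amp_low).astype(float)
    if emission.amp_jitter_sd > 0:
        # per-epoch lognormal amplitude jitter: broadens the within-state
        # power distribution toward what real alpha looks like
        amp = amp * np.exp(emission.amp_jitter_sd * rng.standard_normal(states.size))
    alpha = np.repeat(amp, fs) * carrier
    data = np.empty((len(emission.channel_labels), n))
    for ch in range(len(emission.channel_labels)):
        noise = emission.pink_noise_sd * pink_noise(n, rng)
        noise += emission.white_noise_sd * rng.standard_normal(n)
        data[ch] = alpha + noise
    return RawEEG(samples=data, sampling_rate=fs, channel_labels=list(emission.channel_labels))


@dataclass
class CohortRecord:
    """One participant x session of the synthetic cohort.

    EEG is synthesized lazily (``resting_eeg()`` / ``nfb_eeg()``) from the
    stored ground-truth state sequences and per-record seeds, so a cohort at
    full study scale stays cheap to hold in memory.
    """

    participant: str
    group: Literal["patient", "healthy"]
    session: int
    params: MarkovParams
    resting_states: np.ndarray
    nfb_states: np.ndarray
    vas_pre: np.ndarray
    vas_post: np.ndarray
    emission: EmissionParams
    resting_seed: int
    nfb_seed: int

    def resting_eeg(self) -> RawEEG:
        return synthesize_eeg(self.resting_states, self.emission, seed=self.resting_seed)

    def nfb_eeg(self) -> RawEEG:
        return synthesize_eeg(self.nfb_states, self.emission, seed=self.nfb_seed)

    @property
    def nfb_occupancy(self) -> float:
        """Ground-truth fraction of high-state epochs in the neurofeedback blocks."""
        return float(np.mean(self.nfb_states == HIGH))


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    records: list[CohortRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def ground_truth_frame(self):
        """Tidy per-record ground truth (generator parameters, occupancy, VAS means)."""
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append(
                {
                    "participant": r.participant,
                    "group": r.group,
                    "session": r.session,
                    "true_p_low_to_high": r.params.p_low_to_high,
                    "true_p_high_to_low": r.params.p_high_to_low,
                    "true_stationary_high": r.params.stationary_high,
                    "true_nfb_occupancy": r.nfb_occupancy,
                    "vas_pre_mean": float(r.vas_pre.mean()),
                    "vas_post_mean": float(r.vas_post.mean()),
                }
            )
        return pd.DataFrame(rows)


def _vas_block(rng: np.random.Generator, mu: float, sd: float, k: int) -> np.ndarray:
    return np.clip(rng.normal(mu, sd, size=k), 0.0, 10.0)


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate the full cohort: state sequences, VAS records, lazy EEG.

    For every participant x session the record carries a resting eyes-open
    sequence, a neurofeedback sequence, pre/post VAS blocks and the drifted
    ground-truth transition probabilities.  The session's VAS mean drops by
    ``effect_slope`` x (realized occupancy gain over session 1), which plants
    the negative occupancy/pain-change correlation the analysis should find.
    """
    root = np.random.SeedSequence(spec.seed)
    cohort = SyntheticCohort(spec=spec)
    groups = ("patient", "healthy")
    pid = 0
    for g_idx, group in enumerate(groups):
        for i in range(spec.n_per_group):
            pid += 1
            name = f"{'P' if group == 'patient' else 'H'}{i + 1:02d}"
            pseq = np.random.SeedSequence([spec.seed, g_idx, i])
            child_seeds = pseq.generate_state(4 * spec.n_sessions) % (2**31)
            occ1: float | None = None
            for s in range(1, spec.n_sessions + 1):
                k = 4 * (s - 1)
                params = spec.session_params(group, s)
                resting = simulate_state_sequence(params, spec.resting_epochs, int(child_seeds[k]))
                nfb = simulate_state_sequence(params, spec.nfb_epochs, int(child_seeds[k + 1]))
                occ = float(np.mean(nfb == HIGH))
                if occ1 is None:
                    occ1 = occ
                vas_rng = np.random.default_rng(int(child_seeds[k + 2]))
                # resilience in session s tracks that session's occupancy gain,
                # so the planted effect is visible in either CPT block
                mu_s = spec.baseline_vas - spec.effect_slope * (occ - occ1)
                vas_pre = _vas_block(vas_rng, mu_s, spec.vas_noise_sd, spec.vas_per_block)
                vas_post = _vas_block(vas_rng, mu_s, spec.vas_noise_sd, spec.vas_per_block)
                cohort.records.append(
                    CohortRecord(
                        participant=name,
                        group=group,
                        session=s,
                        params=params,
                        resting_states=resting,
                        nfb_states=nfb,
                        vas_pre=vas_pre,
                        vas_post=vas_post,
                        emission=spec.emission,
                        resting_seed=int(child_seeds[k + 3]) // 2,
                        nfb_seed=int(child_seeds[k + 3]) // 2 + 1,
                    )
                )
    return cohort
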