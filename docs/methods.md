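# Methods note

## Model

Alpha-band activity is modeled as a first-order, two-state Markov chain
observed at 1-s resolution. Each epoch `t` carries a binary symbol
`s_t ∈ {0 (low), 1 (high)}`; the chain is parameterized by the switch
probabilities `p_LH = P(s_{t+1}=1 | s_t=0)` and
`p_HL = P(s_{t+1}=0 | s_t=1)`. A length-`n` sequence carries exactly
`n − 1` transitions; the first symbol is the initial state. The stationary
high-state probability is `π_H = p_LH / (p_LH + p_HL)`, and for a chain in
its stationary regime the fractional occupancy converges to `π_H` — an
identity the test suite exercises directly.

Transition estimation is the closed-form maximum-likelihood estimator:
count consecutive pairs, normalize rows. A row with zero visits yields NaN
probabilities and a warning (optionally an error, or additive smoothing).
The estimator is cross-checked in the test suite against an independent
hidden-Markov implementation constrained to identity emissions; the two
agree to ~1e-13. The HMM library is a test oracle only, never the
implementation.

### Assumptions

- First-order Markov dynamics at the epoch timescale (no duration
  dependence beyond geometric dwell times within a state).
- Stationarity within a session; drift is modeled *across* sessions.
- The binary symbolization is meaningful, i.e. the epoch power
  distribution is bimodal enough that a single threshold separates modes.

## Signal chain and parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| Alpha band | 8–13 | Hz | conventional adult alpha range |
| Channels | AF3, AF4 | — | frontal montage of consumer headsets used in NFB |
| Epoch duration | 1.0 | s | resolution of the state sequence; 1 Hz bin spacing gives 6 band bins |
| Target rate | 250 | Hz | integer decimation factor from common 500/1000 Hz acquisition rates |
| Artifact criterion | ±100 | µV | peak-amplitude screen for blinks/motion; epochs exceeding it are dropped; a warning is raised if > 10% of epochs are rejected |
| Threshold percentages | 30, 50, 70 | % of `P_max` | the three operating points analyzed throughout |
| `P_max` convention | Tukey upper fence Q3 + 1.5·IQR | µV² | robust "maximum" of session-1 resting eyes-open power, insensitive to a single outlier epoch; a literal 1.5·IQR variant is available behind `max_power_convention` |

Offline band power is the **mean** over the 8–13 Hz bins of a
rectangular-window periodogram (`scaling='spectrum'`), averaged over
channels; `agg="sum"` totals the bins instead. Symbolization uses a strict
inequality: an epoch exactly at threshold is low.

The online feedback path intentionally differs from the offline path the
way a real-time implementation would: a 10-s sliding window, an order-4
zero-phase Butterworth band-pass, and band power of the last 2 s of the
window, **summed** over bins so that an in-band sinusoid of amplitude `a`
reads `a²/2` regardless of window length. The dial maps power linearly to
0–10 between the 2nd and 98th percentiles of the resting power
distribution, clipped at the ends. Dial updates default to 1 Hz; the first
value appears once the window is full (t = 10 s).

## Dwell-time statistics

Run lengths of the high state are summarized by mean, median, mode
(smallest value among the most frequent, so ties resolve deterministically),
coefficient of variation in percent (sample SD / mean × 100, ddof = 1), and
a tail-weight statistic. The default tail statistic is the discrete
maximum-likelihood power-law exponent `α = 1 + n / Σ ln(x_i/(x_min − ½))`
fit to dwells strictly above the median; `mean_median_ratio` and
`excess_kurtosis` are selectable alternatives. Runs touching the recording
boundary are included by default (`include_boundary_dwells`); their
truncation flags are preserved in `DwellSet` for sensitivity analyses.

## Behavioral statistics

Session effects on each state parameter are tested with a tie-corrected
Friedman statistic implemented in the package (the SciPy implementation
returns NaN on fully tied rows, where the correct degenerate value is
χ² = 0); on untied data the two agree exactly, and a Monte-Carlo
permutation mode is available for small samples. Pearson correlations with
pain change pool (session, participant) pairs within a group × threshold
cell. Pain change is the VAS block mean (exactly 6 ratings, 0–10) relative
to the participant's session-1 pre-block baseline; the `pain_block` switch
selects pre, post, or their mean (default: pre). Normalized mean alpha is
log power → session mean → z-score across the participant's own sessions
(ddof = 1), so it is a within-participant quantity by construction.

## What the generator emulates — and what it does not

The synthetic cohort generator emits ground-truth Markov state sequences
and renders them as two-channel EEG: a phase-continuous 10 Hz carrier whose
amplitude is 20 µV in the high state and 5 µV in the low state, over
independent per-channel 1/f (pink) noise plus white noise. Per-session
linear drift is applied to the transition parameters (patients: `p_HL`
−0.04/session, emulating learning; healthy: flat), and VAS ratings are
drawn from N(6.0 − 5.0·(FO_s − FO_1), 1.0²) clipped to [0, 10], planting a
negative occupancy→pain dependence in both pre and post blocks.

It does **not** emulate: eye-blink or EMG artifacts (the artifact screen is
exercised by injected spikes in tests instead), volume conduction or
channel correlation, alpha frequency variability, amplitude drift within a
state, or heavy-tailed (non-geometric) dwell distributions. With the
default noiseless amplitudes the per-epoch power distribution is nearly
two-point; a consequence is that the Tukey fence of resting power sits well
above the high-state power level, so the 50% and 70% thresholds can exceed
the high state's power entirely and classify all epochs low — real EEG,
with its broad power distributions, does not behave this way. An optional
lognormal `amp_jitter_sd` (default 0) blurs the amplitudes for more
realistic experiments. Generator defaults are the study conditions and are
not tuned per analysis.

## Numerical choices

- FIR zero-phase decimation (`scipy.signal.decimate`, `ftype='fir'`,
  `zero_phase=True`); non-integer factors are rejected.
- Epoching floors to whole epochs; trailing samples are discarded.
- Rectangular-window periodogram; note that with default constant
  detrending the DC bin is removed — the 8–13 Hz band bins are unaffected.
- Band-bin selection is inclusive at both edges with a 1e-9 Hz tolerance
  against floating-point bin frequencies.
- Quantiles (Tukey fence, dial calibration) use NumPy's default linear
  interpolation.
- Seeds are derived from a single user seed via `SeedSequence` spawning and
  reduced mod 2³¹ so they remain valid for any 32-bit consumer.
- Configuration is a frozen, validated object; a 12-hex-digit SHA-256 hash
  of its canonical JSON is stamped into every output table and run log.

## Problem sizes

Sizes used by the test suite and the reproduction script are the package's
own choices, picked so statistical tolerances are comfortable at
single-CPU runtimes: 100,000-epoch sequences for transition-recovery checks
(standard errors ~1.5×10⁻³) and a 10,000-epoch, 1 kHz, two-channel
recording (~2.8 h of signal, ~20 s to synthesize and analyze) for the
end-to-end pipeline check.

## Limitations and open decisions

- Two states only; multi-state or duration-explicit (semi-Markov) models
  are out of scope.
- The pooled Pearson correlation treats (session, participant) pairs as
  exchangeable; repeated measures within participant are not modeled.
- The Friedman test requires complete blocks; participants with a missing
  session cell yield a NaN result for that cell rather than imputation.
- No plotting: the CSV exports (`cohort_table.csv`, `stats.csv`, long-form
  dwell frames) are the interface to downstream visualization.
- EDF files can be read (via `mne`) but not written; the package's own
  on-disk format is a delimited text dialect with a two-line header
  (`# sampling_rate_hz:`, `# channels:`).
- Where two defensible conventions existed, the choice is a config switch
  with the default stated above: `max_power_convention` (Tukey fence vs
  literal 1.5·IQR), `pain_block` (pre vs post vs mean), `tail_statistic`,
  `include_boundary_dwells`, `bin_agg`, and `friedman_method`.
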