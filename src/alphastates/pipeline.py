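"""End-to-end orchestration: EEG (real or synthetic) to the cohort table and stats.

The cohort table has one row per participant x session x threshold carrying
the normalized mean-alpha score, fractional occupancy, dwell statistics, the
four transition probabilities and the session's pain change — the tabular
shape in which alpha-state neurofeedback results are reported.  A second,
tidy statistics table holds the Friedman tests across sessions and the
Pearson correlations with pain change per group, parameter and threshold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, state_metrics
from .config import AnalysisConfig
from .io import read_eeg, write_eeg_text
from .markov import estimate_transitions
from .preprocess import PowerSeries, power_pipeline
from .symbolize import compute_max_power, compute_threshold, symbolize
from .synthetic import CohortSpec, SyntheticCohort, simulate_cohort

logger = logging.getLogger("alphastates")

__all__ = [
    "COHORT_TABLE_COLUMNS",
    "ParticipantData",
    "PipelineResult",
    "analyze_cohort",
    "compute_statistics",
    "participants_from_synthetic",
    "load_participants",
    "export_synthetic_cohort",
    "run_pipeline",
]

# versioned output schema; tests assert this exact column set
COHORT_TABLE_SCHEMA_VERSION = 1
COHORT_TABLE_COLUMNS = [
    "participant", "group", "session", "threshold_percent", "max_power", "threshold",
    "mean_alpha_score", "fractional_occupancy",
    "dwell_mean", "dwell_median", "dwell_mode", "dwell_variance_pct", "dwell_tail_weight",
    "p_low_to_low", "p_low_to_high", "p_high_to_high", "p_high_to_low",
    "pain_change", "n_epochs", "n_rejected", "config_hash",
]

STATS_PARAMETERS = [
    "mean_alpha_score", "fractional_occupancy", "dwell_mean",
    "p_low_to_high", "p_high_to_low",
]


@dataclass
class ParticipantData:
    """Preprocessed per-session inputs for one participant."""

    participant: str
    group: str
    resting_powers: dict[int, PowerSeries]
    nfb_powers: dict[int, PowerSeries]
    vas_pre: dict[int, np.ndarray]
    vas_post: dict[int, np.ndarray]

    @property
    def sessions(self) -> list[int]:
        return sorted(self.nfb_powers)


@dataclass
class PipelineResult:
    cohort_table: pd.DataFrame
    stats: pd.DataFrame
    log: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort_table.to_csv(out / "cohort_table.csv", index=False)
        self.stats.to_csv(out / "stats.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, default=str)
        return out


def _session_vas(data: ParticipantData, session: int, which: str) -> np.ndarray:
    if which == "pre":
        return data.vas_pre[session]
    if which == "post":
        return data.vas_post[session]
    return np.concatenate([data.vas_pre[session], data.vas_post[session]])


def _pain_changes(data: ParticipantData, which: str) -> dict[int, float]:
    """Per-session pain change vs the session-1 pre-neurofeedback block."""
    if 1 not in data.vas_pre:
        raise ValueError(f"{data.participant}: session-1 pre-NFB VAS baseline missing")
    base = behavior.vas_block_mean(data.vas_pre[1])
    out = {}
    for s in data.sessions:
        block = _session_vas(data, s, which)
        # a "mean" block concatenates pre+post: average of block means
        if which == "mean":
            m = (behavior.vas_block_mean(block[:6]) + behavior.vas_block_mean(block[6:])) / 2
        else:
            m = behavior.vas_block_mean(block)
        out[s] = m - base
    return out


def analyze_participant(data: ParticipantData, config: AnalysisConfig) -> list[dict]:
    """All cohort-table rows of one participant (sessions x thresholds)."""
    if 1 not in data.resting_powers:
        raise ValueError(f"{data.participant}: session-1 resting recording required for thresholding")
    max_power = compute_max_power(data.resting_powers[1], config.max_power_convention)
    specs = [
        compute_threshold(max_power, pct, source=f"{data.participant}/s1-resting")
        for pct in config.thresholds
    ]
    sessions = data.sessions
    scores = behavior.normalized_mean_alpha([data.nfb_powers[s].values for s in sessions])
    score_by_session = dict(zip(sessions, scores))
    pain = _pain_changes(data, config.pain_block)
    chash = config.config_hash()
    rows = []
    for s in sessions:
        power = data.nfb_powers[s]
        for spec in specs:
            seq = symbolize(power, spec)
            occ = state_metrics.fractional_occupancy(seq)
            dwells = state_metrics.extract_dwells(seq, include_boundary=config.include_boundary_dwells)
            if dwells.high_dwells.size:
                ds = state_metrics.dwell_stats(dwells.high_dwells, tail_statistic=config.tail_statistic)
                dvals = (ds.mean, ds.median, ds.mode, ds.variance_pct, ds.tail_weight)
            else:
                dvals = (np.nan,) * 5
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # unvisited-state rows stay NaN
                tm = estimate_transitions(seq, smoothing=config.transition_smoothing)
            tp = tm.as_labeled_rows()
            rows.append({
                "participant": data.participant, "group": data.group, "session": s,
                "threshold_percent": spec.percent, "max_power": spec.max_power,
                "threshold": spec.threshold,
                "mean_alpha_score": float(score_by_session[s]),
                "fractional_occupancy": occ,
                "dwell_mean": dvals[0], "dwell_median": dvals[1], "dwell_mode": dvals[2],
                "dwell_variance_pct": dvals[3], "dwell_tail_weight": dvals[4],
                "p_low_to_low": tp["low_to_low"], "p_low_to_high": tp["low_to_high"],
                "p_high_to_high": tp["high_to_high"], "p_high_to_low": tp["high_to_low"],
                "pain_change": pain[s],
                "n_epochs": power.n_epochs, "n_rejected": int(power.rejected_mask.sum()),
                "config_hash": chash,
            })
    logger.info("%s: %d sessions x %d thresholds analyzed (max_power=%.3f)",
                data.participant, len(sessions), len(specs), max_power)
    return rows


def analyze_cohort(participants: list[ParticipantData], config: AnalysisConfig) -> pd.DataFrame:
    rows: list[dict] = []
    for p in participants:
        rows.extend(analyze_participant(p, config))
    table = pd.DataFrame(rows, columns=COHORT_TABLE_COLUMNS)
    return table.sort_values(["group", "participant", "session", "threshold_percent"],
                             ignore_index=True)


def compute_statistics(table: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Friedman across sessions and Pearson vs pain change, per group/parameter/threshold.

    Correlations pool all (participant, session) pairs within a group, one
    value per pair at the given threshold.
    """
    out = []
    for (group, pct), sub in table.groupby(["group", "threshold_percent"], sort=True):
        for param in STATS_PARAMETERS:
            wide = sub.pivot(index="participant", columns="session", values=param)
            if wide.shape[0] < 2 or wide.isna().any().any():
                fr = behavior.FriedmanResult(chi2=float("nan"), df=wide.shape[1] - 1,
                                             p=float("nan"))
            else:
                fr = behavior.friedman_across_sessions(
                    wide.to_numpy(), method=config.friedman_method, seed=config.seed)
            pairs = sub[[param, "pain_change"]].dropna()
            if len(pairs) >= 3 and pairs[param].std() > 0 and pairs["pain_change"].std() > 0:
                corr = behavior.correlate_with_pain(pairs[param].to_numpy(),
                                                    pairs["pain_change"].to_numpy())
            else:
                corr = behavior.CorrelationResult(r=float("nan"), p=float("nan"), n=len(pairs))
            out.append({
                "group": group, "parameter": param, "threshold_percent": pct,
                "friedman_chi2": fr.chi2, "friedman_df": fr.df, "friedman_p": fr.p,
                "pearson_r": corr.r, "pearson_p": corr.p, "n_pairs": corr.n,
                "n_participants": wide.shape[0],
            })
    return pd.DataFrame(out)


def participants_from_synthetic(cohort: SyntheticCohort, config: AnalysisConfig) -> list[ParticipantData]:
    """Synthesize each record's EEG and push it through the offline power chain."""
    by_participant: dict[str, ParticipantData] = {}
    for rec in cohort.records:
        pdta = by_participant.setdefault(
            rec.participant,
            ParticipantData(rec.participant, rec.group, {}, {}, {}, {}),
        )
        for kind, raw in (("resting", rec.resting_eeg()), ("nfb", rec.nfb_eeg())):
            ps = power_pipeline(
                raw, channels=config.channels, target_rate=config.target_rate,
                epoch_duration=config.epoch_duration, band=config.band,
                artifact_criterion=config.artifact_criterion,
                window=config.spectral_window, agg=config.bin_agg,
            )
            (pdta.resting_powers if kind == "resting" else pdta.nfb_powers)[rec.session] = ps
        pdta.vas_pre[rec.session] = rec.vas_pre
        pdta.vas_post[rec.session] = rec.vas_post
    return list(by_participant.values())


def export_synthetic_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a simulated cohort to disk: EEG text files, manifest, VAS and ground truth CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, vas_rows = [], []
    for rec in cohort.records:
        stem = f"{rec.participant}_s{rec.session}"
        rest_path = out / f"{stem}_resting.tsv"
        nfb_path = out / f"{stem}_nfb.tsv"
        write_eeg_text(rec.resting_eeg(), rest_path)
        write_eeg_text(rec.nfb_eeg(), nfb_path)
        manifest.append({"participant": rec.participant, "group": rec.group,
                         "session": rec.session, "resting_path": rest_path.name,
                         "nfb_path": nfb_path.name})
        for block, ratings in (("pre", rec.vas_pre), ("post", rec.vas_post)):
            for i, r in enumerate(ratings, 1):
                vas_rows.append({"participant": rec.participant, "session": rec.session,
                                 "block": block, "rating_index": i, "rating": float(r)})
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(vas_rows).to_csv(out / "vas.csv", index=False)
    cohort.ground_truth_frame().to_csv(out / "ground_truth.csv", index=False)
    return out


def load_participants(input_dir: str | Path, config: AnalysisConfig) -> list[ParticipantData]:
    """Load a cohort from a manifest directory (as written by ``export_synthetic_cohort``)."""
    input_dir = Path(input_dir)
    manifest = pd.read_csv(input_dir / "manifest.csv")
    vas = pd.read_csv(input_dir / "vas.csv")
    by_participant: dict[str, ParticipantData] = {}
    for _, row in manifest.iterrows():
        pdta = by_participant.setdefault(
            str(row["participant"]),
            ParticipantData(str(row["participant"]), str(row["group"]), {}, {}, {}, {}),
        )
        session = int(row["session"])
        for kind, col in (("resting", "resting_path"), ("nfb", "nfb_path")):
            raw = read_eeg(input_dir / str(row[col]), channels=list(config.channels))
            ps = power_pipeline(
                raw, channels=config.channels, target_rate=config.target_rate,
                epoch_duration=config.epoch_duration, band=config.band,
                artifact_criterion=config.artifact_criterion,
                window=config.spectral_window, agg=config.bin_agg,
            )
            (pdta.resting_powers if kind == "resting" else pdta.nfb_powers)[session] = ps
        sel = vas[(vas["participant"] == row["participant"]) & (vas["session"] == session)]
        for block, target in (("pre", pdta.vas_pre), ("post", pdta.vas_post)):
            b = sel[sel["block"] == block].sort_values("rating_index")["rating"].to_numpy()
            target[session] = b
    return list(by_participant.values())


def run_pipeline(
    config: AnalysisConfig,
    cohort_spec: CohortSpec | None = None,
    input_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis either on a synthetic cohort or on a manifest directory.

    Deterministic given the config seed and cohort spec; the run log records
    the config hash, per-stage counts and the threshold provenance.
    """
    if (cohort_spec is None) == (input_dir is None):
        raise ValueError("provide exactly one of cohort_spec (synthetic mode) or input_dir")
    if cohort_spec is not None:
        cohort = simulate_cohort(cohort_spec)
        participants = participants_from_synthetic(cohort, config)
        source = f"synthetic(seed={cohort_spec.seed})"
    else:
        participants = load_participants(input_dir, config)
        source = str(input_dir)
    table = analyze_cohort(participants, config)
    stats = compute_statistics(table, config)
    log = {
        "config_hash": config.config_hash(),
        "schema_version": COHORT_TABLE_SCHEMA_VERSION,
        "source": source,
        "n_participants": len(participants),
        "n_rows": int(len(table)),
        "total_epochs": int(table["n_epochs"].sum()),
        "total_rejected": int(table["n_rejected"].sum()),
        "config": json.loads(config.model_dump_json()),
    }
    return PipelineResult(cohort_table=table, stats=stats, log=log)
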