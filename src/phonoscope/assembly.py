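"""Assemble the 38-feature vector per sample and the cohort feature table.

The registry below is the single source of truth for feature naming and
ordering: 7 tempo/pause, 7 prosodic, 13 MFCC means, 8 voice-quality
(LHR/CPPs), and 3 articulation-coordination features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_io import AudioSample, frame_signal
from .coordination import acf_features, channel_delay_correlation, extract_channel_tracks
from .prosody import (
    energy_velocity,
    estimate_f0_contour,
    intensity_contour,
    moment_stats,
)
from .spectral import cpps_contour, lhr_contour, mfcc_means
from .temporal import (
    compute_tempo_features,
    count_syllable_nuclei,
    detect_speech_activity,
)

TEMPO_FEATURES = [
    "speech_rate", "articulation_rate", "talking_rate",
    "pause_dur_mean", "pause_dur_sd", "pause_rate", "ppm",
]
PROSODY_FEATURES = [
    "f0_sd", "f0_kurtosis", "f0_skewness",
    "intensity_sd", "intensity_kurtosis", "intensity_skewness", "energy_velocity",
]
MFCC_FEATURES = [f"mfcc{i}_mean" for i in range(1, 14)]
QUALITY_FEATURES = [
    "lhr_mean", "lhr_sd", "lhr_kurtosis", "lhr_skewness",
    "cpps_mean", "cpps_sd", "cpps_kurtosis", "cpps_skewness",
]
ACF_FEATURES = ["acf1", "acf2", "acf3"]

#: the frozen 38-feature registry, in canonical column order
FEATURE_NAMES: list[str] = (
    TEMPO_FEATURES + PROSODY_FEATURES + MFCC_FEATURES + QUALITY_FEATURES + ACF_FEATURES
)
assert len(FEATURE_NAMES) == 38

METADATA_COLUMNS = ["participant_id", "group", "picture_id"]
SYMPTOM_SCALES = ["HAMD", "SANS", "SAPS", "SANS_alogia", "SANS_flat_affect", "SAPS_FTD"]


@dataclass
class ExtractionConfig:
    """Tunable DSP parameters shared by all feature families."""

    frame_length_s: float = 0.025
    hop_s: float = 0.010
    f0_frame_length_s: float = 0.040
    f0_min_hz: float = 60.0
    f0_max_hz: float = 400.0
    voicing_threshold: float = 0.45
    energy_percentile: float = 35.0
    min_speech_s: float = 0.06
    min_pause_s: float = 0.25
    lhr_cutoff_hz: float = 4000.0
    n_mels: int = 26
    acf_n_delays: int = 15
    acf_min_speech_s: float = 5.0


@dataclass
class FeatureVector:
    """The 38 named features for one sample, with missing-value reasons."""

    values: dict[str, float]
    missing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.values) != set(FEATURE_NAMES):
            raise ValueError("feature vector must carry exactly the 38 registry names")

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES})


def _nearest_index_map(from_times: np.ndarray, to_times: np.ndarray) -> np.ndarray:
    """For each time in from_times, the index of the nearest time in to_times."""
    idx = np.searchsorted(to_times, from_times)
    idx = np.clip(idx, 1, len(to_times) - 1)
    left = to_times[idx - 1]
    right = to_times[idx]
    idx -= (from_times - left) < (right - from_times)
    return np.clip(idx, 0, len(to_times) - 1)


def extract_all(sample: AudioSample, config: ExtractionConfig | None = None) -> FeatureVector:
    """Run every feature family on one cleaned sample.

    Extraction is deterministic for a fixed config.  Features undefined for
    a degenerate sample (no speech, no voicing, too little speech for the
    coordination matrix) come back as NaN with machine-readable reasons.
    """
    cfg = config or ExtractionConfig()
    values: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}
    missing: dict[str, str] = {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = frame_signal(sample, cfg.frame_length_s, cfg.hop_s)
        pause_set = detect_speech_activity(
            sample, fs, cfg.energy_percentile, cfg.min_speech_s, cfg.min_pause_s
        )
        speech = pause_set.speech_mask

        # --- f0 (longer window so the lowest pitch fits twice) ---
        f0c = None
        if len(sample.samples) >= int(cfg.f0_frame_length_s * sample.rate) and speech.any():
            fs_f0 = frame_signal(sample, cfg.f0_frame_length_s, cfg.hop_s)
            emap = _nearest_index_map(fs_f0.times, fs.times)
            f0c = estimate_f0_contour(
                fs_f0, cfg.f0_min_hz, cfg.f0_max_hz, cfg.voicing_threshold,
                energy_mask=speech[emap],
            )

        # --- tempo / pause ---
        voiced_on_fs = None
        if f0c is not None and f0c.voiced_mask is not None:
            back = _nearest_index_map(fs.times, f0c.times)
            voiced_on_fs = f0c.voiced_mask[back]
        syllables = count_syllable_nuclei(fs, pause_set, voiced_mask=voiced_on_fs)
        tempo = compute_tempo_features(pause_set, syllables)
        values.update(tempo.as_dict())
        missing.update(tempo.missing)

        # --- prosody ---
        if f0c is not None and f0c.voiced_mask.any():
            stats = moment_stats(f0c.values[f0c.voiced_mask])
            values["f0_sd"] = stats.sd
            values["f0_kurtosis"] = stats.kurtosis
            values["f0_skewness"] = stats.skewness
            for k, why in stats.missing.items():
                missing[f"f0_{k}"] = why
        else:
            for name in ("f0_sd", "f0_kurtosis", "f0_skewness"):
                missing[name] = "no voiced frames"

        if speech.any():
            ic = intensity_contour(fs, speech)
            istats = moment_stats(ic.retained())
            values["intensity_sd"] = istats.sd
            values["intensity_kurtosis"] = istats.kurtosis
            values["intensity_skewness"] = istats.skewness
            values["energy_velocity"] = energy_velocity(ic, cfg.hop_s)
            if np.isnan(values["energy_velocity"]):
                missing["energy_velocity"] = "fewer than 2 adjacent speech frames"

            # --- spectrum / voice quality ---
            mf = mfcc_means(fs, speech, n_mels=cfg.n_mels)
            for i, name in enumerate(MFCC_FEATURES):
                values[name] = float(mf[i])
            lhr = lhr_contour(fs, speech, cfg.lhr_cutoff_hz)
            lvals = lhr.retained()
            values["lhr_mean"] = float(np.mean(lvals))
            lstats = moment_stats(lvals)
            values["lhr_sd"] = lstats.sd
            values["lhr_kurtosis"] = lstats.kurtosis
            values["lhr_skewness"] = lstats.skewness
        else:
            for name in PROSODY_FEATURES[3:] + MFCC_FEATURES + QUALITY_FEATURES[:4]:
                missing[name] = "no speech frames"

        if f0c is not None and f0c.voiced_mask.any():
            cc = cpps_contour(
                sample, f0c.times[f0c.voiced_mask],
                window_s=cfg.f0_frame_length_s, hop_s=cfg.hop_s,
                f0_band=(cfg.f0_min_hz, cfg.f0_max_hz),
            )
            cvals = cc.retained()
            if cvals.size:
                values["cpps_mean"] = float(np.nanmean(cvals))
                cstats = moment_stats(cvals)
                values["cpps_sd"] = cstats.sd
                values["cpps_kurtosis"] = cstats.kurtosis
                values["cpps_skewness"] = cstats.skewness
        if np.isnan(values["cpps_mean"]):
            missing.setdefault("cpps_mean", "no voiced frames")

        # --- articulation coordination ---
        try:
            tracks = extract_channel_tracks(
                fs, speech, min_speech_s=cfg.acf_min_speech_s
            )
            corr = channel_delay_correlation(tracks, n_delays=cfg.acf_n_delays)
            acf = acf_features(corr)
            values.update(acf.as_dict())
        except ValueError as exc:
            for name in ACF_FEATURES:
                missing[name] = str(exc)

    for name in FEATURE_NAMES:
        if np.isnan(values[name]):
            missing.setdefault(name, "not computed")
    return FeatureVector(values, missing)


def build_feature_table(
    rows: list[tuple[AudioSample, FeatureVector]],
    symptom_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cohort feature table: metadata columns, then the 38 features.

    ``symptom_scores`` (indexed by participant_id, columns from
    SYMPTOM_SCALES) is joined per participant when provided.
    """
    records = []
    for sample, vec in rows:
        rec = {
            "participant_id": sample.participant_id,
            "group": sample.group.value,
            "picture_id": sample.picture_id,
        }
        rec.update({k: vec.values[k] for k in FEATURE_NAMES})
        records.append(rec)
    table = pd.DataFrame.from_records(records, columns=METADATA_COLUMNS + FEATURE_NAMES)
    if symptom_scores is not None:
        table = table.join(symptom_scores, on="participant_id")
    return table


def standardize(
    table: pd.DataFrame,
    mode: str = "leakage_safe",
    train_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Z-score the feature columns of a cohort table.

    ``paper_faithful`` fits the scaling on all rows before any fold split
    (replicating a pre-split standardization, which leaks fold information);
    ``leakage_safe`` fits on ``train_index`` rows only and applies the same
    transform everywhere.  Zero-variance features are dropped with a warning.
    """
    if mode not in ("paper_faithful", "leakage_safe"):
        raise ValueError(f"unknown standardization mode: {mode!r}")
    out = table.copy()
    feats = [c for c in FEATURE_NAMES if c in out.columns]
    if mode == "leakage_safe":
        if train_index is None:
            raise ValueError("leakage_safe standardization requires train_index")
        ref = out.loc[train_index, feats]
    else:
        ref = out[feats]
    mu = ref.mean()
    sd = ref.std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance features: {dead}", stacklevel=2)
        out = out.drop(columns=dead)
        feats = [c for c in feats if c not in dead]
    out[feats] = (out[feats] - mu[feats]) / sd[feats]
    return out
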