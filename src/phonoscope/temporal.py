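"""Voice-activity detection, pause statistics, and speech-tempo features.

Pauses are silent stretches of at least ``min_pause_s`` bounded by detected
speech on both sides; leading and trailing silence never counts as a pause.
Tempo features normalize a syllable-nucleus count by either total duration
(speech rate) or phonation time (articulation rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .audio_io import SPLICE_GUARD_S, AudioSample, FrameSeries

#: absolute silence floor in dBFS; frames below are never speech
ABS_FLOOR_DB = -70.0
_DB_EPS = 1e-12


def frame_energy_db(frame_series: FrameSeries) -> np.ndarray:
    """Per-frame RMS energy in dBFS (floored at -120 dB)."""
    rms = np.sqrt(np.mean(frame_series.frames**2, axis=1))
    return np.maximum(20.0 * np.log10(rms + _DB_EPS), -120.0)


@dataclass
class PauseSet:
    """Detected pauses plus the bookkeeping needed by tempo features."""

    pauses: list[tuple[float, float]]
    total_duration_s: float
    phonation_time_s: float
    speech_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    frame_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_pauses(self) -> int:
        return len(self.pauses)

    @property
    def pause_durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.pauses])


@dataclass
class TempoFeatures:
    speech_rate: float  # syllables / s of total duration
    articulation_rate: float  # syllables / s of phonation time
    talking_rate: float  # fraction of total duration that is speech
    pause_dur_mean: float
    pause_dur_sd: float
    pause_rate: float  # pauses / s of phonation time
    ppm: float  # pauses / min of total duration
    missing: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "speech_rate": self.speech_rate,
            "articulation_rate": self.articulation_rate,
            "talking_rate": self.talking_rate,
            "pause_dur_mean": self.pause_dur_mean,
            "pause_dur_sd": self.pause_dur_sd,
            "pause_rate": self.pause_rate,
            "ppm": self.ppm,
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_speech_activity(
    sample: AudioSample,
    frame_series: FrameSeries,
    energy_percentile: float = 35.0,
    min_speech_s: float = 0.06,
    min_pause_s: float = 0.25,
) -> PauseSet:
    """Classify frames speech/silence adaptively and emit interior pauses.

    The threshold is the ``energy_percentile``-th percentile of frame
    energies minus a 10 dB floor, so the decision is invariant to global
    gain; an absolute -70 dBFS floor rejects digital silence.  Speech runs
    shorter than ``min_speech_s`` are merged into silence.  Pauses that
    overlap a splice guard band are discarded (they may be artifacts of
    excision, not of the talker).
    """
    db = frame_energy_db(frame_series)
    thr = np.percentile(db, energy_percentile) - 10.0
    speech = (db > thr) & (db > ABS_FLOOR_DB)
    hop = frame_series.hop_s
    min_speech_frames = max(1, int(round(min_speech_s / hop)))
    for a, b in _runs(speech):
        if b - a < min_speech_frames:
            speech[a:b] = False
    total = sample.duration
    if not speech.any():
        warnings.warn("no speech detected; phonation time is zero", stacklevel=2)
        return PauseSet([], total, 0.0, speech, frame_series.times)

    speech_runs = _runs(speech)
    first, last = speech_runs[0][0], speech_runs[-1][1]
    min_pause_frames = int(round(min_pause_s / hop))
    guards = [
        (t - SPLICE_GUARD_S, t + SPLICE_GUARD_S) for t in sample.splice_points
    ]
    pauses: list[tuple[float, float]] = []
    for (_, a_stop), (b_start, _) in zip(speech_runs[:-1], speech_runs[1:]):
        gap = b_start - a_stop
        if gap < min_pause_frames:
            continue
        start = frame_series.times[a_stop - 1] + hop / 2
        end = frame_series.times[b_start] - hop / 2
        if any(start < g1 and end > g0 for g0, g1 in guards):
            continue
        pauses.append((start, end))
    pause_time = sum(e - s for s, e in pauses)
    edge_silence = (first + (frame_series.n_frames - last)) * hop
    phonation = max(total - pause_time - edge_silence, 0.0)
    return PauseSet(pauses, total, phonation, speech, frame_series.times)


def count_syllable_nuclei(
    frame_series: FrameSeries,
    pause_set: PauseSet,
    voiced_mask: np.ndarray | None = None,
    min_dip_db: float = 2.0,
    min_distance_s: float = 0.10,
) -> int:
    """Count syllable nuclei as voiced intensity peaks within speech.

    A nucleus is an intensity peak that (a) exceeds the median speech
    intensity minus 2 dB, (b) rises at least ``min_dip_db`` above the
    surrounding local minima, and (c) falls on a voiced frame; peaks closer
    than ``min_distance_s`` merge into one.
    """
    if pause_set.phonation_time_s <= 0 or not pause_set.speech_mask.any():
        return 0
    db = frame_energy_db(frame_series)
    speech = pause_set.speech_mask
    contour = np.where(speech, db, -120.0)
    height = np.median(db[speech]) - 2.0
    distance = max(1, int(round(min_distance_s / frame_series.hop_s)))
    peaks, _ = find_peaks(
        contour, height=height, prominence=min_dip_db, distance=distance
    )
    if voiced_mask is not None:
        # tolerate one-frame misalignment between the voicing and energy grids
        voiced = voiced_mask.astype(bool)
        ok = []
        for p in peaks:
            lo, hi = max(0, p - 1), min(len(voiced), p + 2)
            if voiced[lo:hi].any():
                ok.append(p)
        peaks = np.array(ok, dtype=int)
    return int(len(peaks))


def compute_tempo_features(pause_set: PauseSet, syllable_count: int) -> TempoFeatures:
    """Tempo and pause features from a pause analysis and a nucleus count.

    Features undefined for a degenerate sample (zero phonation time) are
    returned as NaN with a machine-readable reason, never silently as 0.
    """
    total = pause_set.total_duration_s
    if total <= 0:
        raise ValueError("total duration must be positive")
    phonation = pause_set.phonation_time_s
    n_pauses = pause_set.n_pauses
    durs = pause_set.pause_durations
    missing: dict[str, str] = {}
    speech_rate = syllable_count / total
    if phonation > 0:
        articulation_rate = syllable_count / phonation
        pause_rate = n_pauses / phonation
    else:
        articulation_rate = pause_rate = float("nan")
        missing["articulation_rate"] = "zero phonation time"
        missing["pause_rate"] = "zero phonation time"
    return TempoFeatures(
        speech_rate=speech_rate,
        articulation_rate=articulation_rate,
        talking_rate=phonation / total,
        pause_dur_mean=float(durs.mean()) if n_pauses else 0.0,
        pause_dur_sd=float(durs.std()) if n_pauses else 0.0,
        pause_rate=pause_rate,
        ppm=60.0 * n_pauses / total,
        missing=missing,
    )
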