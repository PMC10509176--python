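"""Reading, cleaning, and framing of speech recordings.

A recording enters the pipeline as a mono waveform at a common analysis
rate (default 16 kHz).  Examiner speech and noisy stretches are excised by
concatenating the kept regions of an annotation track; splice points are
logged so that pause statistics can ignore the artificial discontinuities
this creates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

DEFAULT_RATE = 16_000
#: seconds around a splice point excluded from pause statistics
SPLICE_GUARD_S = 0.05


class Group(str, Enum):
    HC = "HC"
    MDD = "MDD"
    SSD = "SSD"
    UNKNOWN = "UNKNOWN"


@dataclass
class AudioSample:
    """One cleaned mono recording tied to participant metadata.

    ``samples`` are dimensionless amplitudes in [-1, 1]; ``rate`` is in Hz.
    ``splice_points`` holds the post-excision times (s) where non-adjacent
    audio was concatenated.
    """

    samples: np.ndarray
    rate: int
    participant_id: str = ""
    group: Group = Group.UNKNOWN
    picture_id: int = 1
    splice_points: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSample requires a mono (1-D) signal")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class RemovalTrack:
    """Intervals (start_s, end_s, label) to excise from a recording."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def normalized(self) -> "RemovalTrack":
        """Sort intervals and merge overlaps/adjacencies."""
        ivs = sorted((float(a), float(b), str(lab)) for a, b, lab in self.intervals)
        merged: list[tuple[float, float, str]] = []
        for a, b, lab in ivs:
            if a >= b:
                raise ValueError(f"empty or inverted interval ({a}, {b})")
            if merged and a <= merged[-1][1]:
                pa, pb, plab = merged[-1]
                merged[-1] = (pa, max(pb, b), plab if plab == lab else f"{plab}+{lab}")
            else:
                merged.append((a, b, lab))
        return RemovalTrack(merged)

    @classmethod
    def read(cls, path: str | Path) -> "RemovalTrack":
        """Read an Audacity-style label track: ``start<TAB>end<TAB>label``."""
        ivs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed label line: {line!r}")
            label = parts[2] if len(parts) > 2 else ""
            ivs.append((float(parts[0]), float(parts[1]), label))
        return cls(ivs)

    def write(self, path: str | Path) -> None:
        lines = [f"{a:.3f}\t{b:.3f}\t{lab}" for a, b, lab in self.intervals]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class FrameSeries:
    """Windowed frames of a signal with their center times."""

    frames: np.ndarray  # (n_frames, frame_length) windowed blocks
    times: np.ndarray  # (n_frames,) frame-center seconds
    frame_length_s: float
    hop_s: float
    rate: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def read_audio(path: str | Path, rate: int = DEFAULT_RATE) -> AudioSample:
    """Read a PCM WAV file as a mono AudioSample at the analysis rate.

    Stereo input is channel-averaged.  Integer PCM is scaled to [-1, 1];
    anything still exceeding unit amplitude after decode is peak-normalized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        sr, data = wavfile.read(str(path))
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"unreadable WAV file: {path}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    dtype = data.dtype
    if data.ndim == 2:
        data = data.mean(axis=1)
    x = np.asarray(data, dtype=np.float64)
    if np.issubdtype(dtype, np.integer):
        x = x / float(max(abs(np.iinfo(dtype).min), np.iinfo(dtype).max))
    if sr != rate:
        frac = Fraction(rate, int(sr)).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return AudioSample(x, rate)


def write_audio(path: str | Path, sample: AudioSample) -> None:
    """Write an AudioSample as 16-bit PCM WAV."""
    x = np.clip(sample.samples, -1.0, 1.0)
    wavfile.write(str(path), sample.rate, (x * 32767.0).astype(np.int16))


def apply_removals(sample: AudioSample, track: RemovalTrack) -> AudioSample:
    """Excise the annotated intervals, concatenating the kept regions.

    Splice times (in the output timeline) are recorded on the returned
    sample.  A warning is issued when removals cover more than 75% of the
    recording, the threshold at which a sample is considered unusable.
    """
    norm = track.normalized()
    if not norm.intervals:
        return replace(sample)
    dur = sample.duration
    removed = 0.0
    for a, b, _ in norm.intervals:
        if a < 0 or b > dur + 1.0 / sample.rate:
            raise ValueError(f"removal interval ({a}, {b}) outside audio of {dur:.3f}s")
        removed += b - a
    if removed > 0.75 * dur:
        warnings.warn(
            f"removals cover {100 * removed / dur:.1f}% of the recording; "
            "sample likely contains more noise than speech",
            stacklevel=2,
        )
    keep: list[np.ndarray] = []
    splices: list[float] = []
    cursor = 0
    kept_len = 0
    for a, b, _ in norm.intervals:
        ia, ib = int(round(a * sample.rate)), int(round(b * sample.rate))
        if ia > cursor:
            keep.append(sample.samples[cursor:ia])
            kept_len += ia - cursor
        # interior excisions create a splice in the output timeline
        if ib < len(sample.samples) and kept_len > 0:
            splices.append(kept_len / sample.rate)
        cursor = max(cursor, ib)
    if cursor < len(sample.samples):
        keep.append(sample.samples[cursor:])
    out = np.concatenate(keep) if keep else np.empty(0)
    return replace(
        sample,
        samples=out,
        splice_points=tuple(sample.splice_points) + tuple(splices),
    )


def frame_signal(
    sample: AudioSample,
    frame_length_s: float = 0.025,
    hop_s: float = 0.010,
    window: str = "hann",
) -> FrameSeries:
    """Slice the signal into windowed frames; the last partial frame is dropped."""
    n = int(round(frame_length_s * sample.rate))
    hop = int(round(hop_s * sample.rate))
    if n <= 0 or hop <= 0:
        raise ValueError("frame length and hop must be positive")
    if n > len(sample.samples):
        raise ValueError("frame longer than signal")
    n_frames = (len(sample.samples) - n) // hop + 1
    idx = np.arange(n)[None, :] + hop * np.arange(n_frames)[:, None]
    win = get_window(window, n, fftbins=True) if window else np.ones(n)
    frames = sample.samples[idx] * win
    times = (np.arange(n_frames) * hop + n / 2) / sample.rate
    return FrameSeries(frames, times, n / sample.rate, hop / sample.rate, sample.rate)
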