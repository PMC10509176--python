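"""Fundamental-frequency and intensity contours and their shape statistics.

f0 is estimated per frame from the window-corrected normalized
autocorrelation (the taper's own autocorrelation is divided out so the
voicing peak is unbiased), with a three-frame median filter to suppress
octave jumps.  Intensity is frame RMS referenced to the loudest frame, so
every statistic derived from it is invariant to global gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft
from scipy.stats import kurtosis as _scipy_kurtosis
from scipy.stats import skew as _scipy_skew

from .audio_io import FrameSeries
from .temporal import frame_energy_db

#: minimum number of retained values for distribution-shape statistics
MIN_STAT_N = 8


@dataclass
class Contour:
    """A per-frame track of one acoustic quantity (Hz or dB)."""

    values: np.ndarray
    times: np.ndarray
    voiced_mask: np.ndarray | None = None

    def retained(self) -> np.ndarray:
        """Values on frames kept for statistics (voiced/speech frames)."""
        if self.voiced_mask is None:
            return self.values
        return self.values[self.voiced_mask]


@dataclass
class MomentStats:
    """Population SD, skewness g1, and non-excess kurtosis (normal -> 3)."""

    sd: float
    kurtosis: float
    skewness: float
    missing: dict[str, str] = field(default_factory=dict)


def moment_stats(values: np.ndarray) -> MomentStats:
    """Distribution-shape statistics with biased (n-denominator) estimators.

    Fewer than ``MIN_STAT_N`` values, or a constant input, yields missing
    statistics rather than a numerically meaningless answer.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_STAT_N:
        return MomentStats(
            float("nan"), float("nan"), float("nan"),
            {"all": f"fewer than {MIN_STAT_N} values"},
        )
    if np.ptp(x) == 0:
        warnings.warn("constant input: shape statistics undefined", stacklevel=2)
        return MomentStats(0.0, float("nan"), float("nan"), {"all": "constant input"})
    sd = float(x.std())  # population (ddof=0)
    skew = float(_scipy_skew(x, bias=True))
    kurt = float(_scipy_kurtosis(x, fisher=False, bias=True))
    return MomentStats(sd, kurt, skew)


def estimate_f0_contour(
    frame_series: FrameSeries,
    fmin: float = 60.0,
    fmax: float = 400.0,
    voicing_threshold: float = 0.45,
    energy_mask: np.ndarray | None = None,
) -> Contour:
    """Autocorrelation pitch track with voicing decisions.

    A frame is voiced when its normalized, window-corrected autocorrelation
    peak within the [1/fmax, 1/fmin] lag band reaches ``voicing_threshold``
    and the frame is energetic (``energy_mask``, or an adaptive -40 dB
    criterion relative to the loudest frame).  Unvoiced frames are masked;
    voiced values pass a 3-frame median filter.
    """
    rate = frame_series.rate
    if not 0 < fmin < fmax < rate / 2:
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    frames = frame_series.frames
    n = frames.shape[1]
    lag_min = int(np.floor(rate / fmax))
    lag_max = int(np.ceil(rate / fmin))
    if lag_max >= n:
        raise ValueError(
            f"frame too short for fmin={fmin} Hz: need > {lag_max + 1} samples"
        )
    if energy_mask is None:
        db = frame_energy_db(frame_series)
        energy_mask = db > db.max() - 40.0

    centered = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = rfft(centered, nfft, axis=1)
    ac = irfft(spec * np.conj(spec), nfft, axis=1)[:, : lag_max + 2]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = np.inf
    # divide out the Hann window's own autocorrelation (taper bias)
    wspec = rfft(np.hanning(n), nfft)
    wac = irfft(wspec * np.conj(wspec), nfft)[: lag_max + 2]
    wac = wac / wac[0]
    norm = ac / r0[:, None] / np.maximum(wac[None, :], 1e-6)

    f0 = np.full(frame_series.n_frames, np.nan)
    voiced = np.zeros(frame_series.n_frames, dtype=bool)
    band = norm[:, lag_min : lag_max + 1]
    best = np.argmax(band, axis=1) + lag_min
    for i in np.flatnonzero(energy_mask):
        lag = best[i]
        peak = norm[i, lag]
        if peak < voicing_threshold:
            continue
        # subharmonic correction: the window correction amplifies long lags,
        # so a comparable peak at half the lag marks an octave-down error
        while lag // 2 >= lag_min:
            half = lag // 2
            lo, hi = max(lag_min, half - 2), min(half + 3, lag_max + 1)
            cand = lo + int(np.argmax(norm[i, lo:hi]))
            if norm[i, cand] >= 0.85 * peak:
                lag, peak = cand, norm[i, cand]
            else:
                break
        # parabolic interpolation around the autocorrelation peak
        flag = float(lag)
        if 0 < lag < norm.shape[1] - 1:
            ym, y0, yp = norm[i, lag - 1 : lag + 2]
            denom = ym - 2 * y0 + yp
            if denom < 0:
                flag = lag + 0.5 * (ym - yp) / denom
        voiced[i] = True
        f0[i] = rate / flag

    # 3-frame median filter over voiced frames to remove octave jumps
    vi = np.flatnonzero(voiced)
    if vi.size >= 3:
        vals = f0[vi]
        sm = vals.copy()
        sm[1:-1] = np.median(np.column_stack([vals[:-2], vals[1:-1], vals[2:]]), axis=1)
        f0[vi] = sm
    # residual octave errors: estimates more than a factor 1.5 from the
    # global voiced median are folded back by octaves or dropped
    vi = np.flatnonzero(voiced)
    if vi.size >= 8:
        med = np.median(f0[vi])
        for i in vi:
            v = f0[i]
            while v < med / 1.5 and 2 * v <= fmax:
                v *= 2.0
            while v > med * 1.5 and v / 2 >= fmin:
                v /= 2.0
            if med / 1.5 <= v <= med * 1.5:
                f0[i] = v
            else:
                voiced[i] = False
                f0[i] = np.nan
    return Contour(f0, frame_series.times, voiced)


def intensity_contour(
    frame_series: FrameSeries, speech_mask: np.ndarray | None = None
) -> Contour:
    """Frame RMS in dB re the maximum frame RMS (scale-invariant).

    Frames outside ``speech_mask`` are excluded from downstream statistics
    via the contour's mask; silence would otherwise dominate the kurtosis.
    """
    db = frame_energy_db(frame_series)
    values = db - db.max()
    mask = speech_mask.astype(bool) if speech_mask is not None else np.ones_like(values, bool)
    return Contour(values, frame_series.times, mask)


def energy_velocity(contour: Contour, hop_s: float) -> float:
    """Mean absolute intensity slope (dB/s) within contiguous speech runs.

    Differences are never taken across a pause: only frame pairs adjacent
    in time (one hop apart) contribute.
    """
    mask = (
        contour.voiced_mask
        if contour.voiced_mask is not None
        else np.ones(len(contour.values), bool)
    )
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        return float("nan")
    adjacent = np.diff(idx) == 1
    if not adjacent.any():
        return float("nan")
    dv = np.abs(np.diff(contour.values[idx]))[adjacent]
    return float(dv.mean() / hop_s)
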