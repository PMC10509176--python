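"""Spectral-envelope and voice-quality features: MFCCs, LHR, and CPPs.

MFCCs use a 26-band triangular mel filterbank to 8 kHz and an orthonormal
DCT-II; coefficient 0 (log energy) is excluded so the retained coefficients
are invariant to global gain.  The low-to-high ratio (LHR) is the band-energy
ratio below vs above 4 kHz, a spectral-balance measure used in clinical voice
assessment.  Smoothed cepstral peak prominence (CPPs) measures how far the
dominant rahmonic of the time- and quefrency-smoothed cepstrum rises above a
linear regression baseline — a harmonicity measure that is lower in dysphonic
(noisier) voices.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct, rfft

from .audio_io import AudioSample, FrameSeries, frame_signal

_EPS = 1e-30


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, rate: int, fmax: float | None = None
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft // 2 + 1)."""
    fmax = fmax if fmax is not None else rate / 2
    mel_pts = np.linspace(0.0, hz_to_mel(fmax), n_mels + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    bins = np.floor((n_fft + 1) * hz_pts / rate).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for m in range(1, n_mels + 1):
        left, center, right = bins[m - 1], bins[m], bins[m + 1]
        if center == left:
            center += 1
        if right == center:
            right += 1
        fb[m - 1, left:center] = (np.arange(left, center) - left) / (center - left)
        fb[m - 1, center:right] = (right - np.arange(center, right)) / (right - center)
    return fb


def _power_spectra(frame_series: FrameSeries, n_fft: int | None = None):
    n = frame_series.frames.shape[1]
    if n_fft is None:
        n_fft = int(2 ** np.ceil(np.log2(n)))
    spec = rfft(frame_series.frames, n_fft, axis=1)
    return np.abs(spec) ** 2, n_fft


def mfcc_frames(
    frame_series: FrameSeries,
    n_mels: int = 26,
    n_coeffs: int = 13,
    fmax: float = 8000.0,
) -> np.ndarray:
    """Per-frame MFCCs 1..n_coeffs (c0 excluded), shape (n_frames, n_coeffs)."""
    power, n_fft = _power_spectra(frame_series)
    fb = mel_filterbank(n_mels, n_fft, frame_series.rate, fmax=min(fmax, frame_series.rate / 2))
    mel_energy = power @ fb.T
    log_mel = np.log(mel_energy + _EPS)
    coeffs = dct(log_mel, type=2, norm="ortho", axis=1)
    return coeffs[:, 1 : n_coeffs + 1]


def mfcc_means(
    frame_series: FrameSeries,
    speech_mask: np.ndarray | None = None,
    n_mels: int = 26,
    n_coeffs: int = 13,
) -> np.ndarray:
    """MFCC coefficient means over speech frames; NaN vector if none."""
    coeffs = mfcc_frames(frame_series, n_mels=n_mels, n_coeffs=n_coeffs)
    if speech_mask is not None:
        coeffs = coeffs[speech_mask.astype(bool)]
    if coeffs.shape[0] == 0:
        return np.full(n_coeffs, np.nan)
    return coeffs.mean(axis=0)


def lhr_contour(
    frame_series: FrameSeries,
    speech_mask: np.ndarray | None = None,
    cutoff_hz: float = 4000.0,
    clip_db: float = 60.0,
):
    """Low-to-high spectral ratio per speech frame, in dB.

    10*log10(energy below cutoff / energy above).  A frame with no
    high-band energy is clipped at +``clip_db`` and kept (it is real
    information about spectral balance, not a missing value).
    """
    from .prosody import Contour

    if cutoff_hz >= frame_series.rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    power, n_fft = _power_spectra(frame_series)
    freqs = np.arange(power.shape[1]) * frame_series.rate / n_fft
    low = power[:, freqs < cutoff_hz].sum(axis=1)
    high = power[:, freqs >= cutoff_hz].sum(axis=1)
    ratio = 10.0 * np.log10((low + _EPS) / (high + _EPS))
    ratio = np.clip(ratio, -clip_db, clip_db)
    mask = speech_mask.astype(bool) if speech_mask is not None else np.ones(len(ratio), bool)
    return Contour(ratio, frame_series.times, mask)


def cpps_contour(
    sample: AudioSample,
    voiced_times: np.ndarray,
    window_s: float = 0.04,
    hop_s: float = 0.01,
    time_smooth_frames: int = 10,
    quefrency_smooth_bins: int = 10,
    f0_band: tuple[float, float] = (60.0, 400.0),
):
    """Smoothed cepstral peak prominence per voiced frame, in dB.

    Per frame the real cepstrum of the dB power spectrum is computed;
    cepstra are then moving-averaged over ``time_smooth_frames`` frames and
    ``quefrency_smooth_bins`` quefrency bins.  A least-squares line fitted
    to the smoothed cepstrum over quefrencies [1 ms, 1/fmin] provides the
    baseline; CPPs is the height of the cepstral peak within the pitch
    band [1/fmax, 1/fmin] above that line at the peak quefrency.
    """
    from .prosody import Contour

    from scipy.ndimage import uniform_filter1d

    fmin, fmax = f0_band
    if len(sample.samples) < int(window_s * sample.rate):
        return Contour(np.empty(0), np.empty(0), np.empty(0, bool))
    fs = frame_signal(sample, window_s, hop_s, window="hann")
    n = fs.frames.shape[1]
    n_fft = int(2 ** np.ceil(np.log2(n)))
    spec = rfft(fs.frames, n_fft, axis=1)
    log_power_db = 10.0 * np.log10(np.abs(spec) ** 2 + _EPS)
    # cepstrum of the symmetric log spectrum, expressed as dB cepstral power
    full = np.concatenate([log_power_db, log_power_db[:, -2:0:-1]], axis=1)
    ceps = 10.0 * np.log10(np.abs(rfft(full, axis=1)) ** 2 + _EPS)

    if time_smooth_frames > 1:
        ceps = uniform_filter1d(ceps, time_smooth_frames, axis=0, mode="nearest")
    if quefrency_smooth_bins > 1:
        ceps = uniform_filter1d(ceps, quefrency_smooth_bins, axis=1, mode="nearest")

    quef = np.arange(ceps.shape[1]) / sample.rate  # seconds
    peak_lo = int(np.ceil(sample.rate / fmax))
    peak_hi = min(int(np.floor(sample.rate / fmin)), ceps.shape[1] - 1)
    reg_lo = int(np.ceil(0.001 * sample.rate))
    reg_hi = peak_hi

    # least-squares baseline over [1 ms, 1/fmin], fitted to all frames at once
    q_reg = quef[reg_lo:reg_hi]
    design = np.column_stack([q_reg, np.ones_like(q_reg)])
    coeffs = ceps[:, reg_lo:reg_hi] @ np.linalg.pinv(design).T  # (n_frames, 2)

    # keep frames whose center aligns with a voiced analysis frame
    if voiced_times.size:
        vt = np.sort(voiced_times)
        pos = np.searchsorted(vt, fs.times)
        left = vt[np.clip(pos - 1, 0, len(vt) - 1)]
        right = vt[np.clip(pos, 0, len(vt) - 1)]
        nearest = np.minimum(np.abs(fs.times - left), np.abs(right - fs.times))
        keep = nearest <= hop_s / 2 + 1e-9
    else:
        keep = np.zeros(fs.n_frames, bool)

    seg = ceps[:, peak_lo : peak_hi + 1]
    peak_idx = np.argmax(seg, axis=1) + peak_lo
    peak_val = np.take_along_axis(ceps, peak_idx[:, None], axis=1)[:, 0]
    baseline = coeffs[:, 0] * quef[peak_idx] + coeffs[:, 1]
    values = np.where(keep, peak_val - baseline, np.nan)
    return Contour(values, fs.times, keep)
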