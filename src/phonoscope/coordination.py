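"""Articulation-coordination features from a channel-delay correlation matrix.

The construction correlates several parallel articulatory-proxy time series
with time-delayed copies of themselves and each other, then summarizes the
eigenvalue spectrum of the resulting correlation matrix.  Tightly coupled,
slowly varying articulation concentrates variance in few eigenvalues (high
top-quartile mass, low entropy); complex, independent movement spreads it.

The canonical inputs are vocal-tract variables from a speech-inversion
model; this implementation uses MFCC 1-6 trajectories over speech frames as
pluggable proxy channels preserving the same eigenspectrum construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import FrameSeries
from .spectral import mfcc_frames

#: minimum seconds of speech for a stable correlation matrix
MIN_SPEECH_S = 5.0


@dataclass
class ChannelTracks:
    """C parallel z-normalized proxy time series at the frame hop."""

    channels: np.ndarray  # (C, T)
    channel_names: list[str]
    hop_s: float


@dataclass
class ACFFeatures:
    acf1: float  # top-quartile eigenvalue mass, (0, 1]
    acf2: float  # normalized eigenvalue entropy, [0, 1]
    acf3: float  # bottom-quartile eigenvalue mass, [0, 1)

    def as_dict(self) -> dict[str, float]:
        return {"acf1": self.acf1, "acf2": self.acf2, "acf3": self.acf3}


def extract_channel_tracks(
    frame_series: FrameSeries,
    speech_mask: np.ndarray | None = None,
    source: str = "mfcc6",
    min_speech_s: float = MIN_SPEECH_S,
) -> ChannelTracks:
    """Build articulatory-proxy channels over speech frames.

    ``mfcc6`` uses MFCC coefficients 1-6; each channel is z-normalized over
    the retained frames.  Raises when less than ``min_speech_s`` of speech
    is available (the correlation matrix would be unstable) or when a
    channel is degenerate (zero variance).
    """
    if source != "mfcc6":
        raise ValueError(f"unknown channel source: {source!r}")
    coeffs = mfcc_frames(frame_series, n_coeffs=6)
    if speech_mask is not None:
        coeffs = coeffs[speech_mask.astype(bool)]
    if coeffs.shape[0] * frame_series.hop_s < min_speech_s:
        raise ValueError(
            f"insufficient speech ({coeffs.shape[0] * frame_series.hop_s:.1f}s "
            f"< {min_speech_s}s) for coordination analysis"
        )
    tracks = coeffs.T.astype(float)
    names = [f"mfcc{i}" for i in range(1, 7)]
    sd = tracks.std(axis=1)
    for name, s in zip(names, sd):
        if s == 0:
            raise ValueError(f"degenerate (zero-variance) channel: {name}")
    tracks = (tracks - tracks.mean(axis=1, keepdims=True)) / sd[:, None]
    return ChannelTracks(tracks, names, frame_series.hop_s)


def delay_embed(
    tracks: ChannelTracks, n_delays: int = 15, delay_step_frames: int = 1
) -> np.ndarray:
    """Materialize the delayed copies: shape (C * n_delays, T')."""
    x = tracks.channels
    c, t = x.shape
    span = (n_delays - 1) * delay_step_frames
    if t <= span + 10:
        raise ValueError("track too short for the requested delay embedding")
    rows = []
    for ci in range(c):
        for d in range(n_delays):
            off = d * delay_step_frames
            rows.append(x[ci, off : t - span + off])
    return np.asarray(rows)


def channel_delay_correlation(
    tracks: ChannelTracks, n_delays: int = 15, delay_step_frames: int = 1
) -> np.ndarray:
    """Correlation matrix of the delay-embedded channel stack (CD x CD)."""
    stack = delay_embed(tracks, n_delays, delay_step_frames)
    sd = stack.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance delayed channel at stack row {bad[0]}")
    return np.corrcoef(stack)


def acf_features(corr_matrix: np.ndarray, psd_tol: float = 1e-8) -> ACFFeatures:
    """Eigenspectrum summaries of a channel-delay correlation matrix.

    Eigenvalues are normalized to sum 1; ACF1/ACF3 are the mass of the top
    and bottom ceil(CD/4) eigenvalues, ACF2 the spectral entropy normalized
    by ln(CD).
    """
    m = np.asarray(corr_matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh(m)[::-1]
    if lam[-1] < -psd_tol:
        raise ValueError(f"matrix is not positive semi-definite (min eig {lam[-1]:.3g})")
    lam = np.clip(lam, 0.0, None)
    lam = lam / lam.sum()
    cd = len(lam)
    k = int(np.ceil(cd / 4))
    nz = lam[lam > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(cd))
    return ACFFeatures(
        acf1=float(lam[:k].sum()),
        acf2=entropy,
        acf3=float(lam[-k:].sum()),
    )
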