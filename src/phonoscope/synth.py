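"""Source-filter synthesis of speech-like utterances and whole cohorts.

Every acoustic property of a synthetic utterance is analytically known:
a glottal pulse train follows a commanded f0 contour, aspiration noise is
mixed in at a commanded level (the harmonicity/CPPs driver), the spectrum
is shaped to a commanded tilt (the LHR driver), a syllable-rate amplitude
modulation creates countable nuclei, and silences are inserted at an exact
pause schedule.  Cohort generation layers group effect multipliers and
within-participant parameter correlation on top, and symptom scores can be
generated with target correlations to chosen features.

The defaults emulate the study conditions this package is designed around:
three groups (HC, MDD, SSD) of 20 participants, four picture-description
samples each, with patient groups producing fewer but longer pauses, a
flatter pitch contour, less variable harmonicity, and simpler, more tightly
coupled articulatory movement than controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import DEFAULT_RATE, AudioSample, Group, write_audio

_TWO_PI = 2.0 * np.pi


@dataclass
class UtteranceSpec:
    """Commanded acoustic structure of one synthetic utterance."""

    duration_s: float = 60.0
    f0_mean_hz: float = 140.0
    f0_sd_hz: float = 20.0  # SD of the sinusoidal f0 contour
    f0_mod_hz: float = 0.4  # intonation modulation rate
    pause_schedule: list[tuple[float, float]] = field(default_factory=list)
    syllable_rate_hz: float = 4.0  # amplitude-modulation rate
    tilt_db_per_oct: float = -6.0  # spectral slope re 500 Hz
    artic_depth_db: float = 6.0  # depth of spectral-shape modulation
    artic_bw_hz: float = 3.0  # bandwidth of the articulation carriers
    articulation_complexity: float = 0.75  # 1 = rich independent movement,
    # 0 = a single shared slow pattern (the ACF coupling driver)
    noise_mix: float = 0.25  # aspiration level in [0, 1]
    noise_mix_depth: float = 0.0  # slow within-utterance noise_mix swing
    intensity_dynamics_db: float = 6.0  # slow loudness swing (peak-to-peak)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_mix <= 1.0:
            raise ValueError("noise_mix must be in [0, 1]")
        if not 0.0 <= self.articulation_complexity <= 1.0:
            raise ValueError("articulation_complexity must be in [0, 1]")
        last = 0.0
        for s, e in sorted(self.pause_schedule):
            if s < last or e <= s or e > self.duration_s:
                raise ValueError("pause schedule must be non-overlapping and interior")
            last = e


@dataclass
class GroundTruth:
    """Exact construction parameters recorded alongside the waveform."""

    pause_count: int
    pause_schedule: list[tuple[float, float]]
    f0_mean_hz: float
    f0_sd_hz: float
    tilt_db_per_oct: float
    noise_mix: float
    syllable_rate_hz: float
    articulation_complexity: float
    speech_time_s: float
    expected_syllables: float


def random_pause_schedule(
    duration_s: float,
    n_pauses: int,
    pause_dur_mean_s: float,
    pause_dur_sd_s: float,
    rng: np.random.Generator,
    edge_margin_s: float = 2.0,
    min_gap_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Place ``n_pauses`` non-overlapping interior silences at random onsets."""
    for _ in range(200):
        durs = np.clip(
            rng.normal(pause_dur_mean_s, pause_dur_sd_s, n_pauses), 0.3, None
        )
        usable = duration_s - 2 * edge_margin_s - durs.sum() - (n_pauses - 1) * min_gap_s
        if usable <= 0:
            continue
        gaps = rng.dirichlet(np.ones(n_pauses + 1)) * usable
        schedule = []
        cursor = edge_margin_s
        for i in range(n_pauses):
            cursor += gaps[i]
            schedule.append((cursor, cursor + durs[i]))
            cursor += durs[i] + min_gap_s
        return schedule
    raise ValueError(
        f"cannot fit {n_pauses} pauses of ~{pause_dur_mean_s}s into {duration_s}s"
    )


#: band edges (Hz) of the articulation modulation and the fixed spectral
#: shape of the shared "simple" pattern across them
_ARTIC_BANDS = [(0.0, 800.0), (800.0, 2500.0), (2500.0, 8000.0)]
_ARTIC_SHAPE = [1.0, -1.0, 1.0]


def _articulation_modulation(
    x: np.ndarray,
    rate: int,
    t: np.ndarray,
    complexity: float,
    bw_hz: float,
    depth_db: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Time-varying band-gain modulation with controllable coupling.

    At ``complexity`` 1 each band follows its own band-limited noise
    carrier (rich, independent spectral movement); at 0 every band follows
    a single shared slow sinusoid with a fixed spectral shape (stereotyped,
    tightly coupled movement).  Carriers are synthesized spectrally so they
    are stationary (no filter edge transients), and the modulation weight is
    bounded at 2.5 standard deviations.
    """
    n = len(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    carrier_mask = (freqs > 0.05) & (freqs <= bw_hz)
    shared = np.sqrt(2.0) * np.sin(_TWO_PI * 1.0 * t + rng.uniform(0, _TWO_PI))
    norm = np.sqrt(complexity**2 + (1.0 - complexity) ** 2)
    out = np.zeros(n)
    for (lo, hi), sk in zip(_ARTIC_BANDS, _ARTIC_SHAPE):
        gk = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * carrier_mask, n)
        gk /= gk.std() + 1e-12
        w = (complexity * gk + (1.0 - complexity) * sk * shared) / norm
        w = np.clip(w, -2.5, 2.5)
        band = np.fft.irfft(spec * ((freqs >= lo) & (freqs < hi)), n)
        out += band * 10.0 ** (depth_db * w / 40.0)
    return out


def _tilt_filter(x: np.ndarray, rate: int, tilt_db_per_oct: float) -> np.ndarray:
    """Shape a signal to the commanded spectral slope (dB/octave re 500 Hz)."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
    f = np.maximum(freqs, 100.0)
    gain_db = tilt_db_per_oct * np.log2(f / 500.0)
    spec *= 10.0 ** (gain_db / 20.0)
    return np.fft.irfft(spec, len(x))


def synth_utterance(
    spec: UtteranceSpec, rate: int = DEFAULT_RATE
) -> tuple[AudioSample, GroundTruth]:
    """Render one utterance and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * rate))
    t = np.arange(n) / rate

    # f0 contour: sinusoidal intonation plus a touch of jitter
    phase0 = rng.uniform(0, _TWO_PI)
    f0 = spec.f0_mean_hz + np.sqrt(2.0) * spec.f0_sd_hz * np.sin(
        _TWO_PI * spec.f0_mod_hz * t + phase0
    )
    f0 = np.clip(f0, 40.0, rate / 4)

    # glottal pulse train via phase accumulation
    phase = np.cumsum(f0) / rate
    pulses = np.zeros(n)
    pulses[np.flatnonzero(np.diff(np.floor(phase)) > 0) + 1] = 1.0
    harmonic = _tilt_filter(pulses, rate, spec.tilt_db_per_oct)

    noise = _tilt_filter(rng.standard_normal(n), rate, spec.tilt_db_per_oct)
    h_rms = harmonic.std() + 1e-12
    n_rms = noise.std() + 1e-12
    noise *= h_rms / n_rms
    mix = spec.noise_mix + spec.noise_mix_depth * np.sin(_TWO_PI * 0.15 * t)
    mix = np.clip(mix, 0.0, 1.0)
    x = (1.0 - mix) * harmonic + mix * noise

    # articulatory spectral-shape modulation: three frequency bands are
    # gain-modulated by a blend of independent band-limited carriers
    # (complex, uncoupled movement) and a single shared slow pattern
    # (simple, coupled movement); the blend drives the coordination features
    if spec.artic_depth_db > 0:
        x = _articulation_modulation(
            x, rate, t, spec.articulation_complexity, spec.artic_bw_hz,
            spec.artic_depth_db, rng,
        )

    # syllable-rate amplitude modulation (deep dips -> countable nuclei)
    env = 0.08 + 0.92 * 0.5 * (1.0 - np.cos(_TWO_PI * spec.syllable_rate_hz * t))
    x *= env
    # slow intensity dynamics
    if spec.intensity_dynamics_db > 0:
        g_db = 0.5 * spec.intensity_dynamics_db * np.sin(
            _TWO_PI * 0.3 * t + rng.uniform(0, _TWO_PI)
        )
        x *= 10.0 ** (g_db / 20.0)

    # excise pauses with short cosine ramps
    ramp = int(0.005 * rate)
    win = 0.5 * (1 + np.cos(np.linspace(0, np.pi, ramp)))
    for s, e in spec.pause_schedule:
        i0, i1 = int(round(s * rate)), int(round(e * rate))
        if i0 - ramp >= 0:
            x[i0 - ramp : i0] *= win
        x[i0:i1] = 0.0
        if i1 + ramp <= n:
            x[i1 : i1 + ramp] *= win[::-1]

    peak = np.max(np.abs(x)) + 1e-12
    x = 0.7 * x / peak

    pause_time = sum(e - s for s, e in spec.pause_schedule)
    speech_time = spec.duration_s - pause_time
    gt = GroundTruth(
        pause_count=len(spec.pause_schedule),
        pause_schedule=list(spec.pause_schedule),
        f0_mean_hz=spec.f0_mean_hz,
        f0_sd_hz=spec.f0_sd_hz,
        tilt_db_per_oct=spec.tilt_db_per_oct,
        noise_mix=spec.noise_mix,
        syllable_rate_hz=spec.syllable_rate_hz,
        articulation_complexity=spec.articulation_complexity,
        speech_time_s=speech_time,
        expected_syllables=spec.syllable_rate_hz * speech_time,
    )
    return AudioSample(x, rate), gt


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroupEffects:
    """Multiplicative effects on the base utterance parameters vs HC."""

    ppm: float = 1.0  # pause-count multiplier
    pause_dur: float = 1.0  # pause-duration multiplier
    f0_sd: float = 1.0
    noise_mix_depth: float = 1.0  # harmonicity-variability (CPPs SD) driver
    syllable_rate: float = 1.0
    complexity: float = 1.0  # articulation-complexity multiplier (ACF driver)


#: default per-group effects encoding the qualitative clinical directions:
#: patients pause less often but longer, speak with a flatter pitch contour,
#: vary their voice quality less, and move their articulators in simpler,
#: more tightly coupled patterns.
DEFAULT_GROUP_EFFECTS: dict[str, GroupEffects] = {
    "HC": GroupEffects(),
    "MDD": GroupEffects(
        ppm=0.80, pause_dur=1.7, f0_sd=0.95, noise_mix_depth=0.55,
        syllable_rate=0.85, complexity=0.62,
    ),
    "SSD": GroupEffects(
        ppm=0.78, pause_dur=1.8, f0_sd=0.82, noise_mix_depth=0.60,
        syllable_rate=0.82, complexity=0.57,
    ),
}

#: per-group symptom-score mean/SD used to rescale generated scores
DEFAULT_SCORE_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "HAMD": {"HC": (0.82, 1.78), "MDD": (6.15, 7.26), "SSD": (8.35, 8.42)},
    "SANS": {"HC": (0.12, 0.49), "MDD": (6.2, 8.5), "SSD": (17.3, 11.39)},
    "SAPS": {"HC": (0.0, 0.1), "MDD": (1.47, 2.15), "SSD": (19.32, 15.43)},
    "SANS_alogia": {"HC": (0.0, 0.1), "MDD": (1.06, 2.26), "SSD": (2.35, 2.50)},
    "SANS_flat_affect": {"HC": (0.0, 0.1), "MDD": (2.1, 2.4), "SSD": (4.0, 3.1)},
    "SAPS_FTD": {"HC": (0.0, 0.1), "MDD": (1.67, 2.50), "SSD": (9.35, 9.20)},
}


@dataclass
class CohortSpec:
    """Design of a synthetic cohort: 3 groups x 20 participants x 4 samples."""

    n_participants: int = 20
    samples_per_participant: int = 4
    duration_s: float = 180.0
    base_ppm: float = 10.0  # HC pauses per minute of recording
    base_pause_dur_s: float = 0.8
    base_pause_dur_sd_s: float = 0.25
    group_effects: dict[str, GroupEffects] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    within_participant_jitter: float = 0.06  # per-sample parameter CV
    master_seed: int = 0


def _participant_params(
    group: str, eff: GroupEffects, spec: CohortSpec, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one participant's base parameters (then perturbed per sample)."""
    return {
        "f0_mean_hz": float(np.clip(rng.normal(140.0, 25.0), 85.0, 260.0)),
        "f0_sd_hz": float(np.clip(rng.normal(20.0, 4.0) * eff.f0_sd, 3.0, 60.0)),
        "n_pauses_per_min": float(
            np.clip(rng.normal(spec.base_ppm, 1.5) * eff.ppm, 1.0, 30.0)
        ),
        "pause_dur_s": float(
            np.clip(rng.normal(spec.base_pause_dur_s, 0.1) * eff.pause_dur, 0.35, 4.0)
        ),
        "syllable_rate_hz": float(
            np.clip(rng.normal(4.2, 0.3) * eff.syllable_rate, 2.0, 7.0)
        ),
        "tilt_db_per_oct": float(rng.normal(-6.0, 1.0)),
        "articulation_complexity": float(
            np.clip(rng.normal(0.75, 0.05) * eff.complexity, 0.05, 1.0)
        ),
        "noise_mix": float(np.clip(rng.normal(0.25, 0.05), 0.02, 0.6)),
        "noise_mix_depth": float(
            np.clip(rng.normal(0.16, 0.03) * eff.noise_mix_depth, 0.0, 0.35)
        ),
        "intensity_dynamics_db": float(np.clip(rng.normal(6.0, 1.5), 1.0, 12.0)),
    }


def synth_cohort(
    spec: CohortSpec | None = None,
    out_dir: str | Path | None = None,
    rate: int = DEFAULT_RATE,
) -> tuple[list[tuple[AudioSample, GroundTruth]], pd.DataFrame]:
    """Generate the full cohort (audio + ground truth + metadata).

    Deterministic under ``spec.master_seed``.  When ``out_dir`` is given,
    WAV files and ``metadata.csv`` are written there.
    """
    spec = spec or CohortSpec()
    root = np.random.SeedSequence(spec.master_seed)
    corpus: list[tuple[AudioSample, GroundTruth]] = []
    meta_rows = []
    for gi, (group, eff) in enumerate(sorted(spec.group_effects.items())):
        gseq = root.spawn(1)[0]
        grng = np.random.default_rng(gseq)
        for p in range(spec.n_participants):
            pid = f"{group}{p + 1:02d}"
            base = _participant_params(group, eff, spec, grng)
            for s in range(spec.samples_per_participant):
                srng = np.random.default_rng(
                    np.random.SeedSequence([spec.master_seed, gi, p, s])
                )
                params = {
                    k: v
                    * float(
                        np.clip(
                            srng.normal(1.0, spec.within_participant_jitter), 0.7, 1.3
                        )
                    )
                    for k, v in base.items()
                }
                n_pauses = max(
                    1,
                    int(round(params["n_pauses_per_min"] * spec.duration_s / 60.0)),
                )
                schedule = random_pause_schedule(
                    spec.duration_s, n_pauses, params["pause_dur_s"],
                    spec.base_pause_dur_sd_s, srng,
                )
                useq = int(srng.integers(0, 2**31 - 1))
                u = UtteranceSpec(
                    duration_s=spec.duration_s,
                    f0_mean_hz=params["f0_mean_hz"],
                    f0_sd_hz=params["f0_sd_hz"],
                    pause_schedule=schedule,
                    syllable_rate_hz=params["syllable_rate_hz"],
                    tilt_db_per_oct=params["tilt_db_per_oct"],
                    articulation_complexity=params["articulation_complexity"],
                    noise_mix=params["noise_mix"],
                    noise_mix_depth=params["noise_mix_depth"],
                    intensity_dynamics_db=params["intensity_dynamics_db"],
                    seed=useq,
                )
                audio, gt = synth_utterance(u, rate=rate)
                audio = replace(
                    audio, participant_id=pid, group=Group(group), picture_id=s + 1
                )
                corpus.append((audio, gt))
                meta_rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "picture_id": s + 1,
                        "duration_s": spec.duration_s,
                        "true_pause_count": gt.pause_count,
                        "true_ppm": 60.0 * gt.pause_count / spec.duration_s,
                        "true_f0_sd_hz": gt.f0_sd_hz,
                        "true_talking_rate": gt.speech_time_s / spec.duration_s,
                    }
                )
    meta = pd.DataFrame(meta_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for audio, _ in corpus:
            write_audio(
                out / f"{audio.participant_id}_p{audio.picture_id}.wav", audio
            )
        meta.to_csv(out / "metadata.csv", index=False)
    return corpus, meta


# ---------------------------------------------------------------------------
# direct feature-table and symptom-score fixtures
# ---------------------------------------------------------------------------

def synth_feature_table(
    n_per_group: int,
    effect_vectors: dict[str, np.ndarray],
    within_participant_rho: float = 0.3,
    seed: int = 0,
    samples_per_participant: int = 4,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Multivariate-normal feature table with known group separation.

    Each group's mean is shifted by its effect vector (in SD units); rows
    within a participant share a random effect so that the exchangeable
    within-participant correlation equals ``within_participant_rho``.
    """
    from .assembly import FEATURE_NAMES

    names = feature_names or FEATURE_NAMES
    p = len(names)
    if not 0.0 <= within_participant_rho < 1.0:
        raise ValueError("within_participant_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for group, effect in effect_vectors.items():
        effect = np.asarray(effect, float)
        if effect.shape != (p,):
            raise ValueError(f"effect vector for {group} must have length {p}")
        for i in range(n_per_group):
            pid = f"{group}{i + 1:02d}"
            b = rng.standard_normal(p)
            for s in range(samples_per_participant):
                e = rng.standard_normal(p)
                x = effect + np.sqrt(within_participant_rho) * b + np.sqrt(
                    1.0 - within_participant_rho
                ) * e
                rows.append(
                    {"participant_id": pid, "group": group, "picture_id": s + 1}
                    | dict(zip(names, x))
                )
    return pd.DataFrame(rows)


def synth_symptom_scores(
    table: pd.DataFrame,
    target_correlations: dict[tuple[str, str], tuple[str, float]] | None = None,
    seed: int = 0,
    score_distributions: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Per-participant symptom scores, optionally correlated with features.

    ``target_correlations`` maps (scale, group) to (feature_name, r): the
    score is built as r*z(feature) + sqrt(1-r^2)*noise at the participant
    level, then rescaled to the group's score mean/SD and floored at 0.
    """
    dists = score_distributions or DEFAULT_SCORE_DISTRIBUTIONS
    targets = target_correlations or {}
    rng = np.random.default_rng(seed)
    part = (
        table.groupby(["participant_id", "group"], sort=True)
        .mean(numeric_only=True)
        .reset_index()
    )
    out = pd.DataFrame({"participant_id": part["participant_id"]})
    for scale, groups in dists.items():
        vals = np.zeros(len(part))
        for group, (mu, sd) in groups.items():
            mask = (part["group"] == group).to_numpy()
            if not mask.any():
                continue
            n = int(mask.sum())
            z = rng.standard_normal(n)
            key = (scale, group)
            if key in targets:
                feat, r = targets[key]
                if not abs(r) < 1.0:
                    raise ValueError("target correlation must satisfy |r| < 1")
                f = part.loc[mask, feat].to_numpy()
                fz = (f - f.mean()) / (f.std() + 1e-12)
                z = r * fz + np.sqrt(1.0 - r * r) * z
            vals[mask] = np.maximum(mu + sd * z, 0.0)
        out[scale] = vals
    return out.set_index("participant_id")
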