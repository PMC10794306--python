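"""Synthetic oddball-EEG studies with a controllable group effect.

Emulates the statistical structure the downstream analysis assumes: a
cohort of older adults (healthy cognitive aging vs. mild cognitive
impairment), 8-channel scalp EEG at 250 Hz, an oddball design of 8
sessions x 9 stimulus displays = 72 epochs per participant with
cue/target/ignored roles and reminiscent-vs-contemporary image
categories, eye-blink-like transients, and integer MoCA scores (0-30)
tied to cohort severity.

Signal model (invented, with no claim of physiological realism): pink
(1/f) background noise plus stimulus-locked damped alpha-band bursts
whose amplitude and cross-channel phase coherence scale with
``1 - severity * effect_size``. A coherent burst with a phase gradient
across channels traces a large clean loop in 8-dimensional channel
space, so healthy subjects' epochs are cycle-rich while impaired
subjects' epochs degrade toward an isotropic noise cloud — the
"fewer cycles under impairment" structure the topological features
are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StudyConfig",
    "SubjectProfile",
    "Recording",
    "DEFAULT_CHANNELS",
    "generate_study",
    "generate_recording",
    "sample_moca",
    "inject_artifacts",
]

DEFAULT_CHANNELS = ("Fz", "C3", "Cz", "C4", "Pz", "PO7", "Oz", "PO8")

# frontal-to-posterior weighting of ocular artifacts
_BLINK_TOPOGRAPHY = {
    "Fz": 1.0, "C3": 0.55, "Cz": 0.55, "C4": 0.55,
    "Pz": 0.3, "PO7": 0.15, "Oz": 0.15, "PO8": 0.15,
}

# stimulus-onset asynchrony: 2-s epoch + inter-stimulus gap, in seconds
_SOA_S = 2.6
_SESSION_GAP_S = 3.0
_ALPHA_HZ = 10.0        # burst carrier frequency
_BURST_AMP_UV = 25.0    # healthy-limit burst amplitude per channel
_BURST_TAU_S = 1.0      # burst amplitude decay constant
_NOISE_STD_UV = 5.0     # pink background noise std per channel
_PHASE_JITTER_MAX = np.pi  # coherence loss at severity * effect_size = 1


class ConfigurationError(ValueError):
    """Invalid study configuration."""


@dataclass(frozen=True)
class StudyConfig:
    """Design and effect parameters of one synthetic study.

    ``effect_size`` in [0, 1] dials the cohort separation: 0 makes the
    two groups' EEG exchangeable (a null study), 1 gives the full
    severity-scaled degradation of burst amplitude and coherence.
    """

    n_subjects: int = 23
    n_mci: int = 16
    n_channels: int = 8
    sampling_rate_hz: float = 250.0
    n_sessions: int = 8
    n_images_per_session: int = 8
    age_mean_years: float = 70.70
    age_sd_years: float = 5.32
    effect_size: float = 1.0
    artifact_rate_per_min: float = 0.0
    artifact_peak_uv: float = 200.0
    cue_counts_as_target: bool = True
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0 or self.n_mci < 0 or self.n_mci > self.n_subjects:
            raise ConfigurationError(
                f"need 0 <= n_mci <= n_subjects, got {self.n_mci}/{self.n_subjects}")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be positive")
        if self.n_sessions < 0 or self.n_images_per_session < 0:
            raise ConfigurationError("design counts must be nonnegative")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ConfigurationError("effect_size must be in [0, 1]")
        if self.artifact_rate_per_min < 0:
            raise ConfigurationError("artifact_rate_per_min must be >= 0")

    @property
    def displays_per_session(self) -> int:
        """One cue display plus the stimulus stream."""
        return self.n_images_per_session + 1

    @property
    def events_per_subject(self) -> int:
        return self.n_sessions * self.displays_per_session


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str           # "healthy" | "mci"
    severity: float      # 0 = fully healthy .. 1 = most impaired
    moca: int            # 0..30; >= 26 healthy, < 26 mci by convention
    age_years: float

    def __post_init__(self):
        if self.group not in ("healthy", "mci"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= self.moca <= 30:
            raise ValueError("moca must be in [0, 30]")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")


@dataclass
class Recording:
    """One subject's continuous multichannel EEG plus its event table.

    ``data`` is (n_channels, n_samples) in microvolts. ``events`` is a
    DataFrame with columns onset_sample, session, role, category,
    image_id, ordered by onset.
    """

    subject_id: str
    channel_names: tuple
    sampling_rate_hz: float
    data: np.ndarray
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("data rows must match channel names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _severity(group: str, rng: np.random.Generator) -> float:
    # healthy subjects occupy the low end of the severity axis, impaired
    # subjects a disjoint upper range; within-group spread drives the
    # MoCA regression target
    if group == "healthy":
        return float(rng.uniform(0.0, 0.25))
    return float(rng.uniform(0.35, 1.0))


def sample_moca(group: str, severity: float, rng: np.random.Generator) -> int:
    """Integer MoCA score linked monotonically (in expectation) to severity.

    Healthy scores land in 26..30, impaired below 26 (the standard MoCA
    screening cutoff); expectation decreases linearly with severity.
    """
    raw = 30.0 - 12.0 * severity + rng.normal(0.0, 1.0)
    score = int(np.rint(raw))
    if group == "healthy":
        return int(np.clip(score, 26, 30))
    return int(np.clip(score, 0, 25))


def _sample_events(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    fs = config.sampling_rate_hz
    rows = []
    t = 1.0  # lead-in seconds
    n_img = config.n_images_per_session
    n_rem = n_img // 2
    for sess in range(config.n_sessions):
        target_image = int(rng.integers(n_img)) if n_img else 0
        stream = rng.permutation(n_img)
        displays = [("cue", target_image)] + [
            ("target" if img == target_image else "ignored", int(img))
            for img in stream
        ]
        for role, img in displays:
            onset = int(round(t * fs))
            rows.append({
                "onset_sample": onset,
                "session": sess,
                "role": role,
                "category": "reminiscent" if img < n_rem else "contemporary",
                "image_id": img,
            })
            t += _SOA_S + float(rng.uniform(-0.1, 0.1))
        t += _SESSION_GAP_S
    return pd.DataFrame(
        rows, columns=["onset_sample", "session", "role", "category", "image_id"])


def _pink_noise(n_channels: int, n_samples: int,
                rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude background noise, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    return pink


def generate_recording(profile: SubjectProfile, config: StudyConfig,
                       rng: np.random.Generator | None = None) -> Recording:
    """One subject's continuous EEG: pink noise + stimulus-locked bursts.

    Burst amplitude and cross-channel phase coherence both scale with
    ``1 - severity * effect_size``; at full effect and severity the
    post-stimulus signal is indistinguishable from background.
    """
    if rng is None:
        rng = np.random.default_rng(config.master_seed)
    fs = config.sampling_rate_hz
    events = _sample_events(config, rng)
    epoch_len = int(round(2.0 * fs))
    if len(events):
        n_samples = int(events["onset_sample"].iloc[-1]) + epoch_len + int(fs)
    else:
        n_samples = int(10 * fs)
    data = _pink_noise(config.n_channels, n_samples, rng) * _NOISE_STD_UV

    degradation = profile.severity * config.effect_size
    amp = _BURST_AMP_UV * (1.0 - degradation)
    phase_jitter = _PHASE_JITTER_MAX * degradation
    ch_phase = 2.0 * np.pi * np.arange(config.n_channels) / config.n_channels
    t = np.arange(epoch_len) / fs
    envelope = np.exp(-t / _BURST_TAU_S)
    for onset in events["onset_sample"]:
        base = float(rng.uniform(0.0, 2.0 * np.pi))
        jitter = rng.normal(0.0, 1.0, config.n_channels) * phase_jitter
        phases = base + ch_phase + jitter
        burst = amp * envelope * np.sin(
            2.0 * np.pi * _ALPHA_HZ * t[None, :] + phases[:, None])
        data[:, onset:onset + epoch_len] += burst
    channels = tuple(DEFAULT_CHANNELS[: config.n_channels]) if (
        config.n_channels <= len(DEFAULT_CHANNELS)
    ) else tuple(f"CH{i}" for i in range(config.n_channels))
    rec = Recording(
        subject_id=profile.subject_id,
        channel_names=channels,
        sampling_rate_hz=fs,
        data=data,
        events=events,
        meta={"group": profile.group, "moca": profile.moca,
              "severity": profile.severity},
    )
    if config.artifact_rate_per_min > 0:
        rec = inject_artifacts(
            rec, config.artifact_rate_per_min, config.artifact_peak_uv,
            seed=int(rng.integers(2**31)))
    return rec


def generate_study(config: StudyConfig):
    """Full synthetic cohort: list of (SubjectProfile, Recording).

    A pure function of the configuration (including ``master_seed``):
    the same config yields bitwise-identical output.
    """
    root = np.random.SeedSequence(config.master_seed)
    study = []
    groups = ["mci"] * config.n_mci + \
             ["healthy"] * (config.n_subjects - config.n_mci)
    for idx, (group, ss) in enumerate(zip(groups, root.spawn(config.n_subjects))):
        rng = np.random.default_rng(ss)
        severity = _severity(group, rng)
        profile = SubjectProfile(
            subject_id=f"sub-{idx:02d}",
            group=group,
            severity=severity,
            moca=sample_moca(group, severity, rng),
            age_years=float(np.clip(
                rng.normal(config.age_mean_years, config.age_sd_years), 60, 90)),
        )
        study.append((profile, generate_recording(profile, config, rng)))
    return study


def inject_artifacts(recording: Recording, rate_per_min: float,
                     peak_amplitude_uv: float, seed: int) -> Recording:
    """Superpose eye-blink-like transients; returns a new Recording.

    Blinks are smooth monophasic waves (~0.4 s Hann-squared bumps, spectral
    content below 5 Hz), strongest frontally, at Poisson-like random onsets.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    if peak_amplitude_uv < 0:
        raise ValueError("peak_amplitude_uv must be >= 0")
    if rate_per_min == 0:
        return replace(recording, data=recording.data.copy(),
                       events=recording.events.copy())
    rng = np.random.default_rng(seed)
    fs = recording.sampling_rate_hz
    n = recording.n_samples
    width = int(round(0.4 * fs))
    bump = np.hanning(width) ** 2  # unit peak, smooth, < 5 Hz content
    n_blinks = rng.poisson(rate_per_min * n / fs / 60.0)
    data = recording.data.copy()
    weights = np.array([
        _BLINK_TOPOGRAPHY.get(ch, 0.4) for ch in recording.channel_names])
    for onset in np.sort(rng.integers(0, max(n - width, 1), size=n_blinks)):
        amp = peak_amplitude_uv * float(rng.uniform(0.8, 1.0))
        data[:, onset:onset + width] += amp * np.outer(
            weights, bump[: n - onset])
    return replace(recording, data=data, events=recording.events.copy())
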