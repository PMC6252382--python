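"""Synthetic motor-imagery HD-EEG studies.

Generates complete multi-subject recordings with the statistical structure the
downstream analysis assumes: seven task conditions (move / imagine / observe
foot and hand, plus rest), 25 trials of 6 s per condition in randomized order,
1/f background activity, and condition-dependent sensorimotor rhythm
modulation (event-related desynchronization of the mu and beta bands, strongest
for overt movement, weaker for imagery, absent for observation and rest).

Signal model, per channel of a synthetic sensor net:

* a 1/f-shaped Gaussian background source,
* narrow-band oscillators (mu ~10 Hz, beta ~22 Hz) over the hand area
  (around C3/C4) and the foot area (vertex), whose amplitude within each trial
  epoch is scaled by the condition's configured power-modulation factor,
* instantaneous mixing across channels with distance-decaying weights to
  emulate volume conduction,
* optional 50 Hz line noise and optional latent sources with ground-truth
  directed MVAR coupling.

Patient-profile recordings shift the reactive mu rhythm down in frequency
(10 -> 8 Hz by default), emulating the cortical slowing reported after spinal
cord injury.  Generated data is declared Cz-referenced; Cz itself carries no
channel.  All randomness flows from explicit integer seeds, so identical
configurations reproduce bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .montage import ScalpLayout, make_layout

__all__ = [
    "CONDITIONS",
    "BAND_CENTERS",
    "StudyConfig",
    "Recording",
    "CouplingSpec",
    "default_effect_map",
    "null_effect_map",
    "generate_recording",
    "generate_study",
    "simulate_mvar",
]

#: Task conditions: move foot/hand, imagine foot/hand, observe foot/hand, rest.
CONDITIONS = ("MF", "MH", "IF", "IH", "OF", "OH", "RS")

#: Center frequency (Hz) of each modelled sensorimotor rhythm.
BAND_CENTERS = {"mu": 10.0, "beta": 22.0}

#: Per-trial uniform frequency jitter half-width (Hz) around the band center.
_FREQ_JITTER = {"mu": 1.0, "beta": 3.0}

#: Oscillator amplitudes relative to unit-variance background, chosen so the
#: rhythm dominates its band at the generating channels and planted power
#: ratios are recoverable from 25 trials.
_BAND_AMPLITUDE = {"mu": 2.0, "beta": 1.2}

_HAND_CENTERS = np.array([[-0.5, 0.0], [0.5, 0.0]])  # C3, C4
_FOOT_CENTER = np.array([0.0, 0.0])  # vertex (around the Cz reference)
_GROUP_RADIUS = 0.27

EffectMap = Mapping[str, Mapping[tuple[str, str], float]]


def default_effect_map() -> dict[str, dict[tuple[str, str], float]]:
    """Condition -> (group, band) -> multiplicative power factor vs. rest.

    Movement desynchronizes most strongly over the contralateral/effector
    area, imagery more weakly and symmetrically (so the two imagery conditions
    are mutually indistinguishable), and observation and rest carry the
    unmodulated baseline rhythm.
    """
    return {
        "MF": {("foot", "mu"): 0.35, ("foot", "beta"): 0.5,
               ("hand", "mu"): 0.6, ("hand", "beta"): 0.7},
        "MH": {("hand", "mu"): 0.35, ("hand", "beta"): 0.5,
               ("foot", "mu"): 0.6, ("foot", "beta"): 0.7},
        "IF": {("foot", "mu"): 0.7, ("hand", "mu"): 0.7},
        "IH": {("foot", "mu"): 0.7, ("hand", "mu"): 0.7},
        "OF": {},
        "OH": {},
        "RS": {},
    }


def null_effect_map() -> dict[str, dict[tuple[str, str], float]]:
    """All-ones effect map: no condition modulates any band anywhere."""
    return {c: {} for c in CONDITIONS}


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth directed coupling injected through latent MVAR sources."""

    coefficients: tuple[np.ndarray, ...]
    innovation_cov: np.ndarray
    amplitude: float = 1.0

    @property
    def n_sources(self) -> int:
        return self.coefficients[0].shape[0]


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a synthetic study; defaults mirror the emulated protocol
    (25 trials x 7 conditions x 6 s at 250 Hz, Cz-referenced net)."""

    n_control_recordings: int = 22
    n_patient_recordings: int = 14
    n_channels: int = 64
    sampling_rate: float = 250.0
    n_trials_per_condition: int = 25
    epoch_duration: float = 6.0
    inter_trial_gap: float = 1.0
    conditions: tuple[str, ...] = CONDITIONS
    effect_map: EffectMap | None = None
    patient_peak_shift: float = 2.0
    noise_exponent: float = 1.0
    line_noise_amplitude: float = 0.0
    coupling_spec: CouplingSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) != 7 or len(set(self.conditions)) != 7:
            raise ValueError("exactly 7 distinct conditions are required")
        n_epoch = self.sampling_rate * self.epoch_duration
        if abs(n_epoch - round(n_epoch)) > 1e-9:
            raise ValueError("sampling_rate * epoch_duration must be an integer")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.effect_map is not None:
            for cond, entries in self.effect_map.items():
                for key, factor in entries.items():
                    if factor <= 0:
                        raise ValueError(
                            f"modulation factor must be > 0: {cond}/{key} = {factor}"
                        )

    @property
    def epoch_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_duration))

    def resolved_effect_map(self) -> EffectMap:
        return self.effect_map if self.effect_map is not None else default_effect_map()


@dataclass(frozen=True)
class Recording:
    """One continuous Cz-referenced multichannel recording with its events."""

    data: np.ndarray  # [n_channels, n_samples]
    channel_labels: tuple[str, ...]
    sampling_rate: float
    events: tuple[tuple[int, str, int], ...]  # (onset sample, condition, trial id)
    subject_profile: str  # "control" | "patient"
    subject_id: str = ""
    session: int = 1
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel labels")
        onsets = [ev[0] for ev in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return shaped


def _mixing_matrix(layout: ScalpLayout, decay: float = 0.18) -> np.ndarray:
    """Row-normalized distance-decaying mixing (volume-conduction stand-in)."""
    d = np.linalg.norm(layout.positions[:, None, :] - layout.positions[None, :, :], axis=2)
    w = np.exp(-d / decay)
    return w / w.sum(axis=1, keepdims=True)


def _channel_groups(layout: ScalpLayout) -> dict[str, np.ndarray]:
    pos = layout.positions
    hand = np.flatnonzero(
        np.minimum(
            np.linalg.norm(pos - _HAND_CENTERS[0], axis=1),
            np.linalg.norm(pos - _HAND_CENTERS[1], axis=1),
        )
        <= _GROUP_RADIUS
    )
    foot = np.flatnonzero(np.linalg.norm(pos - _FOOT_CENTER, axis=1) <= _GROUP_RADIUS)
    return {"hand": hand, "foot": foot}


def generate_recording(
    config: StudyConfig, profile: str, session: int = 1, seed: int = 0
) -> Recording:
    """Generate one continuous recording for a control- or patient-profile subject.

    All 7 conditions are presented ``n_trials_per_condition`` times in a
    seeded random intermixed order, separated by the configured inter-trial
    gap; each trial epoch carries its condition's band-power modulation over
    the configured channel groups.
    """
    if profile not in ("control", "patient"):
        raise ValueError(f"profile must be 'control' or 'patient', got {profile!r}")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    layout = make_layout(config.n_channels)
    groups = _channel_groups(layout)
    effect_map = config.resolved_effect_map()

    n_epoch = config.epoch_samples
    n_gap = int(round(config.inter_trial_gap * fs))
    lead = 2 * int(fs)
    n_trials = config.n_trials_per_condition
    sequence = np.repeat(np.arange(7), n_trials)
    rng.shuffle(sequence)
    onsets = lead + np.arange(sequence.size) * (n_epoch + n_gap)
    n_samples = int(onsets[-1] + n_epoch + lead)
    events = tuple(
        (int(onset), config.conditions[cond_idx], int(trial))
        for trial, (onset, cond_idx) in enumerate(zip(onsets, sequence))
    )

    sources = _pink_noise(rng, config.n_channels, n_samples, config.noise_exponent)

    centers = dict(BAND_CENTERS)
    if profile == "patient":
        centers["mu"] = centers["mu"] - config.patient_peak_shift

    t_epoch = np.arange(n_epoch) / fs
    for onset, cond_idx in zip(onsets, sequence):
        cond = config.conditions[cond_idx]
        entries = effect_map.get(cond, {})
        for group_name, chan_idx in groups.items():
            if chan_idx.size == 0:
                continue
            for band, base_amp in _BAND_AMPLITUDE.items():
                factor = entries.get((group_name, band), 1.0)
                freq = centers[band] + rng.uniform(-1, 1, chan_idx.size) * _FREQ_JITTER[band]
                phase = rng.uniform(0, 2 * np.pi, chan_idx.size)
                jitter = np.exp(0.1 * rng.standard_normal(chan_idx.size))
                amp = base_amp * np.sqrt(factor) * jitter
                wave = amp[:, None] * np.sin(
                    2 * np.pi * freq[:, None] * t_epoch[None, :] + phase[:, None]
                )
                sources[chan_idx, onset : onset + n_epoch] += wave

    gt_coupling = None
    if config.coupling_spec is not None:
        spec = config.coupling_spec
        latent = simulate_mvar(
            spec.coefficients,
            spec.innovation_cov,
            n_samples,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        k = spec.n_sources
        sources[:k] += spec.amplitude * latent
        gt_coupling = {
            "coefficients": [a.tolist() for a in spec.coefficients],
            "amplitude": spec.amplitude,
            "source_channels": list(layout.labels[:k]),
        }

    data = _mixing_matrix(layout) @ sources

    if config.line_noise_amplitude > 0:
        t = np.arange(n_samples) / fs
        data += config.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t)

    ground_truth = {
        "effect_map": {c: {f"{g}/{b}": v for (g, b), v in e.items()}
                       for c, e in effect_map.items()},
        "band_centers": centers,
        "groups": {name: [layout.labels[i] for i in idx] for name, idx in groups.items()},
        "profile": profile,
        "coupling": gt_coupling,
    }
    return Recording(
        data=data,
        channel_labels=layout.labels,
        sampling_rate=fs,
        events=events,
        subject_profile=profile,
        session=session,
        ground_truth=ground_truth,
    )


# Recordings per patient, mirroring a cohort where some patients return for
# repeat sessions (default pattern sums to 14 recordings over 7 patients).
_PATIENT_SESSION_PATTERN = (2, 4, 2, 3, 1, 1, 1)


def _patient_session_counts(n_recordings: int) -> list[int]:
    if n_recordings == sum(_PATIENT_SESSION_PATTERN):
        return list(_PATIENT_SESSION_PATTERN)
    n_subjects = min(7, n_recordings) or 0
    counts = [0] * n_subjects
    for i in range(n_recordings):
        counts[i % n_subjects] += 1
    return counts


def generate_study(config: StudyConfig) -> list[Recording]:
    """Generate the full study: control recordings (one session each) followed
    by patient recordings, with repeat sessions for designated patients and a
    distinct derived seed per recording."""
    root = np.random.default_rng(config.seed)
    n_total = config.n_control_recordings + config.n_patient_recordings
    seeds = root.integers(0, 2**31 - 1, size=n_total)
    recordings: list[Recording] = []
    i = 0
    for c in range(config.n_control_recordings):
        rec = generate_recording(config, "control", session=1, seed=int(seeds[i]))
        recordings.append(replace(rec, subject_id=f"C{c + 1:02d}"))
        i += 1
    for p, n_sessions in enumerate(_patient_session_counts(config.n_patient_recordings)):
        for s in range(1, n_sessions + 1):
            rec = generate_recording(config, "patient", session=s, seed=int(seeds[i]))
            recordings.append(replace(rec, subject_id=f"P{p + 1:02d}"))
            i += 1
    return recordings


def _companion(coefficients: Sequence[np.ndarray]) -> np.ndarray:
    p = len(coefficients)
    m = coefficients[0].shape[0]
    comp = np.zeros((m * p, m * p))
    comp[:m] = np.hstack([np.asarray(a, float) for a in coefficients])
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return comp


def simulate_mvar(
    coefficients: Sequence[np.ndarray],
    innovation_cov: np.ndarray,
    n_samples: int,
    seed: int = 0,
    burn_in: int = 1000,
) -> np.ndarray:
    """Stationary realization of x(t) = sum_k A_k x(t-k) + e(t).

    Returns a [channels x n_samples] array after discarding ``burn_in``
    samples.  The model must be stable (companion spectral radius < 1) and the
    innovation covariance positive definite.
    """
    coeffs = [np.asarray(a, float) for a in coefficients]
    m = coeffs[0].shape[0]
    if any(a.shape != (m, m) for a in coeffs):
        raise ValueError("all coefficient matrices must be square and same size")
    radius = np.abs(np.linalg.eigvals(_companion(coeffs))).max()
    if radius >= 1.0:
        raise ValueError(f"unstable MVAR model (companion spectral radius {radius:.3f})")
    cov = np.asarray(innovation_cov, float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("innovation covariance must be positive definite") from exc

    rng = np.random.default_rng(seed)
    p = len(coeffs)
    total = n_samples + burn_in
    innovations = rng.standard_normal((total, m)) @ chol.T
    x = np.zeros((total, m))
    for t in range(total):
        acc = innovations[t].copy()
        for k, a in enumerate(coeffs, start=1):
            if t - k >= 0:
                acc += a @ x[t - k]
        x[t] = acc
    return x[burn_in:].T
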