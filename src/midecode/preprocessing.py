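"""Filtering, epoching and montage reduction of continuous recordings.

The preparation chain is deliberately minimal, matching a protocol in which
every trial is retained: a 1 Hz high-pass IIR filter and a 50 Hz notch on the
continuous record, segmentation into 6 s condition epochs from the pacing-tone
onset, sub-segmentation of each epoch into six non-overlapping 1 s units (a
data-augmentation step that multiplies the sample count by six), and reduction
to one of the four montage configurations.  No artifact rejection,
re-referencing or baseline correction is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .montage import MontageConfig
from .synthetic import Recording

__all__ = [
    "SegmentSet",
    "highpass_filter",
    "notch_filter",
    "preprocess",
    "segment_trials",
    "subsegment",
    "apply_montage",
    "segments_from_recording",
]

#: samples per 1 s classification segment at the 250 Hz sampling rate
SEGMENT_SAMPLES = 250
N_SUBSEGMENTS = 6


@dataclass(frozen=True)
class SegmentSet:
    """1 s classification units cut from condition epochs.

    ``segments`` is [n_segments, n_channels, n_samples]; every trial
    contributes exactly six consecutive sub-segments which inherit its
    condition label and trial id.
    """

    segments: np.ndarray
    condition: np.ndarray  # str per segment
    trial_id: np.ndarray  # int per segment
    subsegment_index: np.ndarray  # 1..6 per segment
    channel_labels: tuple[str, ...]
    sampling_rate: float

    def __post_init__(self) -> None:
        n = self.segments.shape[0]
        for name in ("condition", "trial_id", "subsegment_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per segment")
        if self.segments.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis must match channel_labels")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]

    def select_conditions(self, conditions) -> "SegmentSet":
        mask = np.isin(self.condition, list(conditions))
        return replace(
            self,
            segments=self.segments[mask],
            condition=self.condition[mask],
            trial_id=self.trial_id[mask],
            subsegment_index=self.subsegment_index[mask],
        )


def _check_cutoff(freq: float, sampling_rate: float) -> None:
    if freq >= sampling_rate / 2:
        raise ValueError(
            f"frequency {freq} Hz is at or above Nyquist ({sampling_rate / 2} Hz)"
        )


def highpass_filter(
    data: np.ndarray, sampling_rate: float, cutoff: float = 1.0, order: int = 4
) -> np.ndarray:
    """Causal Butterworth high-pass applied per channel (removes DC and drift)."""
    _check_cutoff(cutoff, sampling_rate)
    sos = signal.butter(order, cutoff, btype="highpass", fs=sampling_rate, output="sos")
    return signal.sosfilt(sos, np.asarray(data, float), axis=-1)


def notch_filter(
    data: np.ndarray, sampling_rate: float, freq: float = 50.0, quality: float = 30.0
) -> np.ndarray:
    """Narrow IIR notch (line-noise rejection) applied per channel."""
    _check_cutoff(freq, sampling_rate)
    b, a = signal.iirnotch(freq, quality, fs=sampling_rate)
    return signal.lfilter(b, a, np.asarray(data, float), axis=-1)


def preprocess(
    recording: Recording,
    highpass_cutoff: float = 1.0,
    notch_freq: float | None = 50.0,
) -> Recording:
    """Apply the standard filter chain to a continuous recording."""
    data = highpass_filter(recording.data, recording.sampling_rate, highpass_cutoff)
    if notch_freq is not None:
        data = notch_filter(data, recording.sampling_rate, notch_freq)
    return replace(recording, data=data)


def segment_trials(recording: Recording) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut one 6 s epoch per trial event, starting at the pacing-tone onset.

    Returns ``(epochs [n_events, n_channels, epoch_samples], condition, trial_id)``.
    """
    fs = recording.sampling_rate
    n_epoch = int(round(6.0 * fs))
    epochs, conds, trials = [], [], []
    for onset, cond, trial in recording.events:
        if onset + n_epoch > recording.n_samples:
            raise ValueError(
                f"trial {trial} epoch [{onset}, {onset + n_epoch}) exceeds "
                f"recording length {recording.n_samples}"
            )
        epochs.append(recording.data[:, onset : onset + n_epoch])
        conds.append(cond)
        trials.append(trial)
    return (
        np.stack(epochs),
        np.array(conds, dtype=object),
        np.array(trials, dtype=int),
    )


def subsegment(
    epochs: np.ndarray,
    condition: np.ndarray,
    trial_id: np.ndarray,
    channel_labels,
    sampling_rate: float = 250.0,
) -> SegmentSet:
    """Split each epoch into 6 consecutive non-overlapping 1 s segments."""
    n_events, n_channels, n_epoch = epochs.shape
    if n_epoch % SEGMENT_SAMPLES != 0:
        raise ValueError(
            f"epoch length {n_epoch} is not divisible by {SEGMENT_SAMPLES}"
        )
    n_sub = n_epoch // SEGMENT_SAMPLES
    if n_sub != N_SUBSEGMENTS:
        raise ValueError(
            f"expected {N_SUBSEGMENTS} sub-segments per epoch, got {n_sub}"
        )
    segs = epochs.reshape(n_events, n_channels, n_sub, SEGMENT_SAMPLES)
    segs = segs.transpose(0, 2, 1, 3).reshape(n_events * n_sub, n_channels, SEGMENT_SAMPLES)
    return SegmentSet(
        segments=segs,
        condition=np.repeat(condition, n_sub),
        trial_id=np.repeat(trial_id, n_sub),
        subsegment_index=np.tile(np.arange(1, n_sub + 1), n_events),
        channel_labels=tuple(channel_labels),
        sampling_rate=sampling_rate,
    )


def apply_montage(segments: SegmentSet, montage: MontageConfig) -> SegmentSet:
    """Reduce the channel axis to the montage's channels, in montage order."""
    lut = {lab: i for i, lab in enumerate(segments.channel_labels)}
    missing = [lab for lab in montage.channel_labels if lab not in lut]
    if missing:
        raise KeyError(
            f"montage {montage.name!r} references absent channel(s): {', '.join(missing)}"
        )
    idx = [lut[lab] for lab in montage.channel_labels]
    return replace(
        segments,
        segments=segments.segments[:, idx, :],
        channel_labels=tuple(montage.channel_labels),
    )


def segments_from_recording(
    recording: Recording,
    montage: MontageConfig | None = None,
    highpass_cutoff: float = 1.0,
    notch_freq: float | None = 50.0,
) -> SegmentSet:
    """Full preparation chain: filter, epoch, sub-segment, optional montage."""
    filtered = preprocess(recording, highpass_cutoff, notch_freq)
    epochs, cond, trial = segment_trials(filtered)
    segs = subsegment(epochs, cond, trial, recording.channel_labels, recording.sampling_rate)
    if montage is not None:
        segs = apply_montage(segs, montage)
    return segs
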