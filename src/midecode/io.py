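"""Reading and writing the internal array container and optional EDF input.

A recording is stored as a binary array file (``<name>.npy``, channels x
samples) plus a JSON sidecar (``<name>.json``) holding channel labels,
sampling rate, trial-onset events, subject profile/session and — for
synthetic data — the generating ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import Recording

__all__ = ["save_recording", "load_recording", "read_edf"]


def save_recording(recording: Recording, basename: str | Path) -> None:
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.save(base.with_suffix(".npy"), recording.data)
    sidecar = {
        "channel_labels": list(recording.channel_labels),
        "sampling_rate": recording.sampling_rate,
        "events": [[int(o), c, int(t)] for o, c, t in recording.events],
        "subject_profile": recording.subject_profile,
        "subject_id": recording.subject_id,
        "session": recording.session,
        "ground_truth": recording.ground_truth,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(basename: str | Path) -> Recording:
    base = Path(basename)
    data = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return Recording(
        data=data,
        channel_labels=tuple(meta["channel_labels"]),
        sampling_rate=meta["sampling_rate"],
        events=tuple((int(o), c, int(t)) for o, c, t in meta["events"]),
        subject_profile=meta["subject_profile"],
        subject_id=meta.get("subject_id", ""),
        session=meta.get("session", 1),
        ground_truth=meta.get("ground_truth"),
    )


def read_edf(path: str | Path, events: list[tuple[int, str, int]],
             subject_profile: str = "control", session: int = 1) -> Recording:
    """Load a real EEG recording from a European Data Format file.

    ``events`` supplies the trial onsets as (onset sample, condition label,
    trial id) since EDF annotation conventions vary between systems.
    Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data(),
        channel_labels=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        events=tuple(events),
        subject_profile=subject_profile,
        session=session,
    )
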