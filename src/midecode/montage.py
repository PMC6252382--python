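"""Scalp layouts and the four spatial channel configurations.

The analysis compares four montage densities:

``LD-SM``
    low-density sensorimotor — the two 10-10 central electrodes C3 and C4.
``LD-whole``
    low-density whole brain — 19 standard 10-20 positions.
``HD-SM``
    high-density sensorimotor — 27 channels along the central strip of a
    high-density net.
``HD-whole``
    high-density whole brain — every channel of the net except a declared
    face/neck exclusion ring (197 channels on the 256-channel net).

Because the recording reference is Cz, Cz itself never appears as a data
channel; the 19-channel low-density set therefore substitutes Oz for Cz.

Each montage carries the autoregressive model order used for connectivity
estimation on its channel count.  Default orders follow the rule that
``n_samples / (n_channels * order) > 1`` for 250-sample segments, except the
two-channel sensorimotor montage where a deliberately high order (50) is used
for spectral resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources as _resources
from pathlib import Path

import numpy as np

__all__ = [
    "MONTAGE_NAMES",
    "DEFAULT_MODEL_ORDERS",
    "ScalpLayout",
    "MontageConfig",
    "make_layout",
    "build_montage",
    "load_montage",
    "save_montage",
]

MONTAGE_NAMES = ("LD-SM", "LD-whole", "HD-SM", "HD-whole")

DEFAULT_MODEL_ORDERS = {"LD-SM": 50, "LD-whole": 12, "HD-SM": 9, "HD-whole": 1}

# Approximate 2-D positions on a unit-radius head (x: left->right, y: back->front).
# Cz sits at the origin and is the reference, so it is not a data channel.
_TEN_TWENTY = {
    "Fp1": (-0.31, 0.95),
    "Fp2": (0.31, 0.95),
    "F7": (-0.80, 0.58),
    "F3": (-0.40, 0.52),
    "Fz": (0.00, 0.50),
    "F4": (0.40, 0.52),
    "F8": (0.80, 0.58),
    "T7": (-1.00, 0.00),
    "C3": (-0.50, 0.00),
    "C4": (0.50, 0.00),
    "T8": (1.00, 0.00),
    "P7": (-0.80, -0.58),
    "P3": (-0.40, -0.52),
    "Pz": (0.00, -0.50),
    "P4": (0.40, -0.52),
    "P8": (0.80, -0.58),
    "O1": (-0.31, -0.95),
    "O2": (0.31, -0.95),
    "Oz": (0.00, -1.00),
}

TEN_TWENTY_LABELS = tuple(_TEN_TWENTY)

# Channels on the full net beyond this many scalp positions form the
# face/neck ring that the high-density whole-brain montage excludes
# (256 - 197 = 59 ring channels).
_N_SCALP = 197
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class ScalpLayout:
    """Channel labels with 2-D scalp positions."""

    labels: tuple[str, ...]
    positions: np.ndarray  # [n_channels, 2]

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (len(self.labels), 2):
            raise ValueError("positions must be [n_channels, 2]")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index_of(self, labels) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in lut]
        if missing:
            raise KeyError(f"channel label(s) not in layout: {', '.join(missing)}")
        return np.array([lut[lab] for lab in labels], dtype=int)

    def radius(self) -> np.ndarray:
        return np.hypot(self.positions[:, 0], self.positions[:, 1])


def make_layout(n_channels: int = 64) -> ScalpLayout:
    """Deterministic synthetic net layout with ``n_channels`` positions.

    The first 19 channels are the standard 10-20 positions (Oz in place of the
    Cz reference); further channels fill the scalp on a golden-angle spiral.
    When more than 197 channels are requested the excess is placed on an outer
    face/neck ring (radius > 1), which the HD-whole montage excludes.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if n_channels < len(_TEN_TWENTY):
        labels = TEN_TWENTY_LABELS[:n_channels]
        pos = np.array([_TEN_TWENTY[lab] for lab in labels], float)
        return ScalpLayout(labels, pos)

    labels = list(TEN_TWENTY_LABELS)
    pos = [list(_TEN_TWENTY[lab]) for lab in labels]
    n_extra = n_channels - len(labels)
    n_scalp_extra = max(0, min(n_channels, _N_SCALP) - len(labels))
    for i in range(n_extra):
        theta = (i + 1) * _GOLDEN_ANGLE
        if i < n_scalp_extra:
            r = 0.98 * math.sqrt((i + 0.5) / max(n_scalp_extra, 1))
        else:  # face/neck ring, excluded by HD-whole
            j = i - n_scalp_extra
            n_ring = n_extra - n_scalp_extra
            r = 1.02 + 0.13 * (j + 0.5) / max(n_ring, 1)
        labels.append(f"E{len(labels) + 1}")
        pos.append([r * math.cos(theta), r * math.sin(theta)])
    return ScalpLayout(tuple(labels), np.asarray(pos, float))


@dataclass(frozen=True)
class MontageConfig:
    """A named channel subset plus the MVAR model order used on it."""

    name: str
    channel_labels: tuple[str, ...]
    model_order: int

    def __post_init__(self) -> None:
        if not self.channel_labels:
            raise ValueError("montage channel list is empty")
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("montage channel labels must be unique")
        if self.model_order < 1:
            raise ValueError("model_order must be >= 1")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


def _central_strip_order(layout: ScalpLayout) -> np.ndarray:
    """Scalp channel indices sorted by distance from the central (C3-Cz-C4) strip."""
    x, y = layout.positions[:, 0], layout.positions[:, 1]
    score = np.abs(y) + 0.5 * np.maximum(0.0, np.abs(x) - 0.85)
    score = np.where(layout.radius() <= 1.0, score, np.inf)
    return np.argsort(score, kind="stable")


def build_montage(name: str, layout: ScalpLayout, model_order: int | None = None) -> MontageConfig:
    """Derive a montage of the given name from a layout.

    For nets smaller than the full 256-channel layout the high-density
    montages adapt: HD-SM takes the 27 channels nearest the central strip and
    HD-whole takes every channel inside the scalp margin (radius <= 1).
    """
    if name not in MONTAGE_NAMES:
        raise ValueError(f"unknown montage {name!r}; expected one of {MONTAGE_NAMES}")
    if name == "LD-SM":
        labels = ("C3", "C4")
        layout.index_of(labels)
    elif name == "LD-whole":
        labels = TEN_TWENTY_LABELS
        layout.index_of(labels)
    elif name == "HD-SM":
        order_idx = _central_strip_order(layout)
        if layout.n_channels < 27:
            raise ValueError("HD-SM needs a layout with at least 27 scalp channels")
        idx = np.sort(order_idx[:27])
        labels = tuple(layout.labels[i] for i in idx)
    else:  # HD-whole
        keep = np.flatnonzero(layout.radius() <= 1.0)
        labels = tuple(layout.labels[i] for i in keep)
    if model_order is None:
        model_order = DEFAULT_MODEL_ORDERS[name]
    return MontageConfig(name=name, channel_labels=labels, model_order=model_order)


def save_montage(montage: MontageConfig, path: str | Path) -> None:
    """Write a montage as an editable tab-separated text resource."""
    lines = [f"name\t{montage.name}", f"model_order\t{montage.model_order}"]
    lines += [f"channel\t{lab}" for lab in montage.channel_labels]
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_montage(text: str) -> MontageConfig:
    name = None
    order = None
    labels: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        if key == "name":
            name = value
        elif key == "model_order":
            order = int(value)
        elif key == "channel":
            labels.append(value)
        else:
            raise ValueError(f"unrecognized montage line: {line!r}")
    if name is None or order is None:
        raise ValueError("montage file must declare name and model_order")
    return MontageConfig(name=name, channel_labels=tuple(labels), model_order=order)


def load_montage(source: str | Path) -> MontageConfig:
    """Load a montage from a file path or, for a bare montage name, from the
    packaged defaults (which describe the 256-channel net)."""
    if str(source) in MONTAGE_NAMES:
        fname = str(source).lower().replace("-", "_") + ".tsv"
        text = _resources.files("midecode.resources").joinpath(fname).read_text()
        return _parse_montage(text)
    return _parse_montage(Path(source).read_text())
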