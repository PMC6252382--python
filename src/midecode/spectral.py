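"""FFT power-spectrum features averaged into 13 frequency bands.

Each 1 s segment (250 samples at 250 Hz) yields a one-sided power spectrum at
integer frequencies; the 1-48 Hz range is averaged into 13 bands — 2 Hz bands
up to 20 Hz, then 21-30, 31-40 and 41-48 Hz — and flattened channel-major into
one feature vector per segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import SegmentSet

__all__ = [
    "BandScheme",
    "FeatureTable",
    "default_band_scheme",
    "power_spectrum",
    "band_average",
    "build_fft_features",
]

N_FREQ_BINS = 48  # 1..48 Hz at 1 Hz resolution


@dataclass(frozen=True)
class BandScheme:
    """Ordered partition of the 1-48 Hz bins into labelled bands."""

    bands: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        if len(self.bands) != 13:
            raise ValueError(f"expected 13 bands, got {len(self.bands)}")
        all_bins = [b for _, bins in self.bands for b in bins]
        if sorted(all_bins) != list(range(1, N_FREQ_BINS + 1)):
            raise ValueError("bands must partition the integer bins 1..48 Hz")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def default_band_scheme() -> BandScheme:
    """2 Hz bands 1-2 .. 19-20, then 21-30, 31-40 and 41-48 Hz (13 bands).

    Boundary bins are assigned exclusively to the lower band so the scheme is
    a true partition of 1-48 Hz.
    """
    bands: list[tuple[str, tuple[int, ...]]] = []
    for lo in range(1, 20, 2):
        bands.append((f"{lo}-{lo + 1}", (lo, lo + 1)))
    bands.append(("21-30", tuple(range(21, 31))))
    bands.append(("31-40", tuple(range(31, 41))))
    bands.append(("41-48", tuple(range(41, 49))))
    return BandScheme(tuple(bands))


def power_spectrum(
    segment: np.ndarray, sampling_rate: float = 250.0, bins: str = "band"
) -> np.ndarray:
    """One-sided FFT power spectrum of a 1 s segment at 1 Hz resolution.

    With ``bins="band"`` (default) returns the [.., 48] powers at 1..48 Hz;
    ``bins="full"`` returns every one-sided bin including DC and Nyquist, whose
    sum equals the time-domain mean-square power (Parseval).  No taper and no
    detrending are applied: the segment length already gives integer-Hz bins.
    """
    segment = np.asarray(segment, float)
    if not np.all(np.isfinite(segment)):
        raise ValueError("segment contains non-finite values")
    n = segment.shape[-1]
    if abs(n / sampling_rate - 1.0) > 1e-9:
        raise ValueError(
            f"expected a 1 s segment ({int(sampling_rate)} samples), got {n}"
        )
    spec = np.fft.rfft(segment, axis=-1)
    power = np.abs(spec) ** 2 / n**2
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0  # Nyquist bin is not duplicated
    if bins == "full":
        return power
    if bins != "band":
        raise ValueError("bins must be 'band' or 'full'")
    return power[..., 1 : N_FREQ_BINS + 1]


def band_average(spectrum: np.ndarray, scheme: BandScheme | None = None) -> np.ndarray:
    """Average per-frequency values (last axis = bins 1..48 Hz) into bands."""
    if scheme is None:
        scheme = default_band_scheme()
    spectrum = np.asarray(spectrum, float)
    if spectrum.shape[-1] != N_FREQ_BINS:
        raise ValueError(
            f"expected {N_FREQ_BINS} frequency bins on the last axis, "
            f"got {spectrum.shape[-1]}"
        )
    out = np.empty(spectrum.shape[:-1] + (scheme.n_bands,))
    for i, (_, bins) in enumerate(scheme.bands):
        idx = np.array(bins) - 1
        out[..., i] = spectrum[..., idx].mean(axis=-1)
    return out


@dataclass(frozen=True)
class FeatureTable:
    """Segments x features matrix plus a map from feature column to meaning.

    ``index_map`` has one row per feature with columns ``channel`` (FFT) or
    ``source``/``sink`` (ffDTF) and ``band``.
    """

    values: np.ndarray
    index_map: pd.DataFrame
    feature_kind: str  # "FFT" | "ffDTF"

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D [n_segments, n_features]")
        if len(self.index_map) != self.values.shape[1]:
            raise ValueError("index_map must have one row per feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_names(self) -> list[str]:
        cols = [c for c in ("channel", "source", "sink", "band") if c in self.index_map]
        return [
            "|".join(str(row[c]) for c in cols) for _, row in self.index_map.iterrows()
        ]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names())
        df.to_csv(path, index=False)


def build_fft_features(
    segments: SegmentSet, scheme: BandScheme | None = None, log_power: bool = False
) -> FeatureTable:
    """Band-averaged FFT power features: one row per segment, channel-major
    then band order, M x 13 features for M channels."""
    if scheme is None:
        scheme = default_band_scheme()
    spectra = power_spectrum(segments.segments, segments.sampling_rate)
    banded = band_average(spectra, scheme)  # [n_segments, n_channels, 13]
    if log_power:
        banded = np.log(banded + np.finfo(float).tiny)
    n_seg, n_chan, n_band = banded.shape
    values = banded.reshape(n_seg, n_chan * n_band)
    index_map = pd.DataFrame(
        {
            "channel": np.repeat(segments.channel_labels, n_band),
            "band": np.tile(scheme.labels, n_chan),
        }
    )
    return FeatureTable(values=values, index_map=index_map, feature_kind="FFT")
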