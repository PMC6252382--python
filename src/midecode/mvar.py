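"""Multivariate autoregressive (MVAR) models and ffDTF connectivity features.

Each 1 s segment is modelled as x(t) = sum_k A_k x(t-k) + e(t).  Coefficients
are estimated with the Vieira-Morf lattice (forward/backward prediction-error
partial-correlation recursion) using unbiased covariance normalization; an
ordinary-least-squares fit is provided as an independent cross-check for
small channel counts.

From the fitted model the spectral transfer matrix H(f) = (I - sum_k A_k
e^{-i 2 pi f k / fs})^{-1} is evaluated on the 1..48 Hz grid, and the
full-frequency Directed Transfer Function

    eta2_ij(f) = |H_ij(f)|^2 / sum_{f'} sum_m |H_im(f')|^2

normalizes each inflow |H_ij|^2 by the total inflow to sink channel i over
the *whole* frequency interval, so that per sink the values over all sources
and frequencies sum to one.  Band-averaged ffDTF values for every ordered
channel pair (self-flows included) form the connectivity feature vector of
length M * M * 13.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import MontageConfig
from .preprocessing import SegmentSet
from .spectral import BandScheme, FeatureTable, band_average, default_band_scheme

__all__ = [
    "MVARModel",
    "SpectralConnectivity",
    "max_model_order",
    "fit_mvar",
    "fit_mvar_ols",
    "transfer_function",
    "ffdtf",
    "spectral_connectivity",
    "build_ffdtf_features",
]

FULL_GRID = np.arange(1.0, 49.0)  # 1..48 Hz at 1 Hz steps


@dataclass(frozen=True)
class MVARModel:
    """Fitted MVAR coefficients A_1..A_p plus innovation covariance."""

    order: int
    coefficients: tuple[np.ndarray, ...]
    innovation_cov: np.ndarray
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.order < 1 or len(self.coefficients) != self.order:
            raise ValueError("need one coefficient matrix per lag, order >= 1")
        m = self.coefficients[0].shape[0]
        if any(a.shape != (m, m) for a in self.coefficients):
            raise ValueError("coefficient matrices must all be M x M")
        if not all(np.all(np.isfinite(a)) for a in self.coefficients):
            raise ValueError("coefficients must be finite")

    @property
    def n_channels(self) -> int:
        return self.coefficients[0].shape[0]

    def companion_spectral_radius(self) -> float:
        m, p = self.n_channels, self.order
        comp = np.zeros((m * p, m * p))
        comp[:m] = np.hstack(self.coefficients)
        if p > 1:
            comp[m:, :-m] = np.eye(m * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    def is_stable(self) -> bool:
        return self.companion_spectral_radius() < 1.0


@dataclass(frozen=True)
class SpectralConnectivity:
    """Transfer matrix and ffDTF on a frequency grid ([freq, sink, source])."""

    frequencies: np.ndarray
    transfer: np.ndarray
    ffdtf: np.ndarray


def max_model_order(n_samples: int, n_channels: int) -> int:
    """Largest order p satisfying n_samples / (n_channels * p) > 1.

    This balances the number of estimated coefficients (M^2 p) against the
    available samples; e.g. 250 samples admit p=9 at 27 channels but only
    p=1 at 197 channels.
    """
    p = (n_samples - 1) // n_channels
    if p < 1:
        raise ValueError(
            f"no valid model order: {n_samples} samples <= {n_channels} channels"
        )
    return int(p)


def fit_mvar(segment: np.ndarray, order: int, sampling_rate: float = 250.0) -> MVARModel:
    """Vieira-Morf lattice estimate of an order-p MVAR model on [M, N] data.

    Forward/backward prediction-error covariances are normalized by the
    number of contributing samples at each stage (unbiased estimates); the
    normalized partial-correlation (reflection) matrix at each stage updates
    the coefficient set via the multichannel Levinson recursion.  The
    innovation covariance comes from the final forward residuals.
    """
    x = np.asarray(segment, float)
    if x.ndim != 2:
        raise ValueError("segment must be a [channels, samples] matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")
    m, n = x.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= order + m:
        raise ValueError(f"too few samples ({n}) for {m} channels at order {order}")

    ef = x.copy()
    eb = x.copy()
    a: list[np.ndarray] = []  # forward coefficients A_1..A_k
    b: list[np.ndarray] = []  # backward coefficients

    for k in range(1, order + 1):
        f = ef[:, k:]
        g = eb[:, k - 1 : -1]
        nk = n - k
        rf = f @ f.T / nk
        rb = g @ g.T / nk
        rfb = f @ g.T / nk
        try:
            sf = np.linalg.cholesky(rf)
            sb = np.linalg.cholesky(rb)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"rank-deficient residual covariance at lattice stage {k}"
            ) from exc
        # normalized partial correlation: sf^-1 rfb sb^-T
        gmat = np.linalg.solve(sf, rfb) @ np.linalg.inv(sb).T
        kf = sf @ gmat @ np.linalg.inv(sb)
        kb = sb @ gmat.T @ np.linalg.inv(sf)

        a_new = [a[j] - kf @ b[k - 2 - j] for j in range(k - 1)] + [kf]
        b_new = [b[j] - kb @ a[k - 2 - j] for j in range(k - 1)] + [kb]
        a, b = a_new, b_new

        ef_next = ef.copy()
        eb_next = eb.copy()
        ef_next[:, k:] = ef[:, k:] - kf @ eb[:, k - 1 : -1]
        eb_next[:, k:] = eb[:, k - 1 : -1] - kb @ ef[:, k:]
        ef, eb = ef_next, eb_next

    resid = ef[:, order:]
    cov = resid @ resid.T / (n - order)
    return MVARModel(
        order=order,
        coefficients=tuple(a),
        innovation_cov=cov,
        sampling_rate=sampling_rate,
    )


def fit_mvar_ols(segment: np.ndarray, order: int, sampling_rate: float = 250.0) -> MVARModel:
    """Ordinary least-squares MVAR fit (regression on stacked lags).

    Independent of the lattice recursion; intended as a cross-check for small
    channel counts.
    """
    x = np.asarray(segment, float)
    m, n = x.shape
    if n - order <= m * order:
        raise ValueError("too few samples for an OLS fit at this order")
    y = x[:, order:].T  # [n - p, m]
    design = np.hstack([x[:, order - k : n - k].T for k in range(1, order + 1)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a = tuple(coef[(k - 1) * m : k * m, :].T for k in range(1, order + 1))
    resid = y - design @ coef
    cov = resid.T @ resid / (n - order - m * order)
    return MVARModel(order=order, coefficients=a, innovation_cov=cov,
                     sampling_rate=sampling_rate)


def transfer_function(model: MVARModel, frequencies: np.ndarray | None = None) -> np.ndarray:
    """H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1} on the given grid."""
    if frequencies is None:
        frequencies = FULL_GRID
    freqs = np.asarray(frequencies, float)
    m = model.n_channels
    eye = np.eye(m)
    coeffs = np.stack(model.coefficients)  # [p, m, m]
    k = np.arange(1, model.order + 1)
    # phase[f, k] = exp(-i 2 pi f k / fs)
    phase = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / model.sampling_rate)
    abar = eye[None] - np.einsum("fk,kij->fij", phase, coeffs)
    out = np.empty_like(abar)
    for i, f in enumerate(freqs):
        try:
            out[i] = np.linalg.inv(abar[i])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular spectral matrix A(f) at f = {f:g} Hz"
            ) from exc
    return out


def ffdtf(transfer: np.ndarray, squared: bool = True) -> np.ndarray:
    """Full-frequency DTF from a [freq, M, M] transfer array.

    Each |H_ij(f)|^2 (inflow from source j to sink i) is divided by the total
    inflow to sink i summed over *all* grid frequencies and sources, so
    sum_f sum_j eta2_ij(f) = 1 for every sink i.  ``squared=False`` gives the
    magnitude (non-squared) variant of the same normalization.
    """
    h2 = np.abs(transfer) ** 2 if squared else np.abs(transfer)
    denom = h2.sum(axis=(0, 2))  # per sink row i
    if np.any(denom == 0):
        raise ValueError("zero total inflow for at least one sink channel")
    return h2 / denom[None, :, None]


def spectral_connectivity(
    model: MVARModel, frequencies: np.ndarray | None = None, squared: bool = True
) -> SpectralConnectivity:
    if frequencies is None:
        frequencies = FULL_GRID
    h = transfer_function(model, frequencies)
    return SpectralConnectivity(
        frequencies=np.asarray(frequencies, float), transfer=h,
        ffdtf=ffdtf(h, squared=squared),
    )


def build_ffdtf_features(
    segments: SegmentSet,
    montage: MontageConfig,
    scheme: BandScheme | None = None,
    squared: bool = True,
) -> FeatureTable:
    """Band-averaged ffDTF features, M * M * 13 per segment.

    Per segment: fit the montage-order MVAR model, evaluate H(f) on 1..48 Hz,
    form the ffDTF and average it within each band for every ordered (source,
    sink) pair including self-flows.  A segment whose model cannot be fitted
    aborts with its segment index in the error message.
    """
    if scheme is None:
        scheme = default_band_scheme()
    if tuple(segments.channel_labels) != tuple(montage.channel_labels):
        raise ValueError("apply the montage to the segments before ffDTF features")
    n_seg = segments.n_segments
    m = segments.n_channels
    n_band = scheme.n_bands
    values = np.empty((n_seg, m * m * n_band))
    for s in range(n_seg):
        try:
            model = fit_mvar(segments.segments[s], montage.model_order,
                             segments.sampling_rate)
            eta = ffdtf(transfer_function(model), squared=squared)  # [48, m, m]
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"segment {s}: {exc}") from exc
        banded = band_average(np.moveaxis(eta, 0, -1), scheme)  # [m(sink), m(src), 13]
        values[s] = banded.reshape(-1)
    labels = segments.channel_labels
    index_map = pd.DataFrame(
        {
            "sink": np.repeat(labels, m * n_band),
            "source": np.tile(np.repeat(labels, n_band), m),
            "band": np.tile(scheme.labels, m * m),
        }
    )
    return FeatureTable(values=values, index_map=index_map, feature_kind="ffDTF")
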