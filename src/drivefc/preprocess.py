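"""fNIRS preprocessing: optical density, modified Beer-Lambert law,
band-pass filtering, and short-separation regression.

The chain for raw dual-wavelength intensities is fixed:

    intensity -> optical density -> (HbO, HbR) -> 0.01-0.1 Hz band-pass
              -> short-separation regression (SSR)

Optical density is defined base-10 against the channel's geometric-mean
intensity, so OD changes are zero-mean in log space.  Sessions that already
carry hemoglobin concentration changes skip the first two steps; for those
the band-pass is optional (see :class:`PreprocessConfig`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class OpticalConstants:
    """Constants of the modified Beer-Lambert law.

    Extinction coefficients are in 1/(mM*mm), base-10 convention, at the
    instrument wavelengths (760, 850) nm; rows are wavelengths, columns
    (HbO, HbR).  Differential pathlength factors are typical adult-head
    values; source-detector separations are 30 mm (long) and 8 mm (short).
    All values are overridable — they are instrument conventions, not
    fitted quantities.
    """

    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    extinction: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0586, 0.1548),
        (0.1058, 0.0691),
    )
    dpf: tuple[float, float] = (6.2, 5.6)
    distance_long_mm: float = 30.0
    distance_short_mm: float = 8.0

    def forward_matrix(self, distance_mm: float | None = None) -> np.ndarray:
        """2x2 matrix mapping (dHbO, dHbR) in mM to dOD per wavelength."""
        d = self.distance_long_mm if distance_mm is None else distance_mm
        e = np.asarray(self.extinction, dtype=float)
        m = d * np.diag(self.dpf) @ e
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("singular extinction matrix")
        return m


@dataclass
class PreprocessConfig:
    """Switches and constants for the denoising chain.

    ``apply_bandpass`` defaults to True for raw-intensity input.  Sessions
    in the hemoglobin dialect are treated as already band-limited (the
    synthetic generator emits them on an effective-sample scale), so
    pipeline code passes ``apply_bandpass=False`` for those.
    """

    constants: OpticalConstants = field(default_factory=OpticalConstants)
    band_hz: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 4
    apply_bandpass: bool = True
    apply_ssr: bool = True


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Convert raw intensity to optical-density change.

    OD(t) = -log10(I(t) / I_ref) with I_ref the channel's geometric-mean
    intensity, so each channel's OD series has zero mean by construction.

    Raises
    ------
    ValueError
        On non-positive intensities, naming the first offending channel
        and sample.
    """
    I = np.asarray(intensity, dtype=float)
    bad = ~(I > 0)
    if bad.any():
        s, c = np.argwhere(bad)[0] if I.ndim == 2 else (int(np.flatnonzero(bad)[0]), 0)
        raise ValueError(
            f"non-positive intensity at sample {int(s)}, channel {int(c)}"
        )
    log_i = np.log10(I)
    return -(log_i - log_i.mean(axis=0, keepdims=True))


def od_to_hb(
    od_wl1: np.ndarray,
    od_wl2: np.ndarray,
    constants: OpticalConstants | None = None,
    distance_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law per sample and channel.

    Solves the 2x2 system dOD_lambda = d * DPF_lambda * (e_HbO dHbO +
    e_HbR dHbR) and returns (dHbO, dHbR) in mM.
    """
    constants = constants or OpticalConstants()
    m = constants.forward_matrix(distance_mm)
    inv = np.linalg.inv(m)
    od = np.stack([np.asarray(od_wl1, float), np.asarray(od_wl2, float)])
    hb = np.einsum("ij,j...->i...", inv, od)
    return hb[0], hb[1]


def hb_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    constants: OpticalConstants | None = None,
    distance_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward modified Beer-Lambert law: (dHbO, dHbR) in mM to dOD."""
    constants = constants or OpticalConstants()
    m = constants.forward_matrix(distance_mm)
    hb = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)])
    od = np.einsum("ij,j...->i...", m, hb)
    return od[0], od[1]


def bandpass(
    x: np.ndarray,
    fs: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time (first) axis.

    Forward-backward filtering avoids group delay, which would otherwise
    shift signal relative to the event-locked windows.
    """
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(f"passband edge {high_hz} Hz at/above Nyquist {fs / 2} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def short_separation_regression(
    long_series: np.ndarray,
    short_series: np.ndarray,
    pairing: np.ndarray,
) -> np.ndarray:
    """Remove scalp/systemic physiology by per-channel OLS on a short channel.

    Each long channel is regressed on [intercept, its paired short channel];
    the residual is returned, so it is exactly uncorrelated with the
    regressor.  A constant short channel degrades to mean removal with a
    warning.

    Parameters
    ----------
    long_series : (n, n_long) array
    short_series : (n, n_short) array
    pairing : (n_long,) int array, long channel -> short channel column
    """
    L = np.asarray(long_series, dtype=float)
    S = np.asarray(short_series, dtype=float)
    pairing = np.asarray(pairing, dtype=int)
    if L.shape[0] != S.shape[0]:
        raise ValueError("long and short series have mismatched lengths")
    if pairing.shape[0] != L.shape[1]:
        raise ValueError("need one short-channel assignment per long channel")
    out = np.empty_like(L)
    n = L.shape[0]
    for c in range(L.shape[1]):
        s = S[:, pairing[c]]
        if s.std() < 1e-12:
            warnings.warn(
                f"constant short channel for long channel {c}; "
                "SSR reduces to mean removal",
                stacklevel=2,
            )
            out[:, c] = L[:, c] - L[:, c].mean()
            continue
        A = np.column_stack([np.ones(n), s])
        beta, *_ = np.linalg.lstsq(A, L[:, c], rcond=None)
        out[:, c] = L[:, c] - A @ beta
    return out


def preprocess_intensity(
    intensity_wl1: np.ndarray,
    intensity_wl2: np.ndarray,
    short_wl1: np.ndarray,
    short_wl2: np.ndarray,
    fs: float,
    pairing: np.ndarray,
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full chain on raw intensities: OD -> MBLL -> band-pass -> SSR.

    Returns (oxy, deoxy) for the long channels; the short channels are run
    through the same OD/MBLL/band-pass steps before serving as SSR
    regressors.  Pipeline order is fixed.
    """
    cfg = config or PreprocessConfig()
    c = cfg.constants
    od1, od2 = intensity_to_od(intensity_wl1), intensity_to_od(intensity_wl2)
    hbo, hbr = od_to_hb(od1, od2, c)
    sod1, sod2 = intensity_to_od(short_wl1), intensity_to_od(short_wl2)
    s_hbo, _s_hbr = od_to_hb(sod1, sod2, c, distance_mm=c.distance_short_mm)
    if cfg.apply_bandpass:
        lo, hi = cfg.band_hz
        hbo = bandpass(hbo, fs, lo, hi, cfg.filter_order)
        hbr = bandpass(hbr, fs, lo, hi, cfg.filter_order)
        s_hbo = bandpass(s_hbo, fs, lo, hi, cfg.filter_order)
    if cfg.apply_ssr:
        hbo = short_separation_regression(hbo, s_hbo, pairing)
    return hbo, hbr


def preprocess_hb(
    oxy: np.ndarray,
    short_oxy: np.ndarray,
    fs: float,
    pairing: np.ndarray,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Denoise an oxy-Hb session (band-pass optional, then SSR)."""
    cfg = config or PreprocessConfig(apply_bandpass=False)
    out = np.asarray(oxy, dtype=float)
    s = np.asarray(short_oxy, dtype=float)
    if cfg.apply_bandpass:
        lo, hi = cfg.band_hz
        out = bandpass(out, fs, lo, hi, cfg.filter_order)
        s = bandpass(s, fs, lo, hi, cfg.filter_order)
    if cfg.apply_ssr:
        out = short_separation_regression(out, s, pairing)
    return out
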