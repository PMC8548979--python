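"""Optical density, modified Beer-Lambert conversion, resampling, filtering.

The conversion chain mirrors standard continuous-wave fNIRS practice:

1. raw intensity -> change in optical density,
   ``dOD(t) = -log(I(t) / I_base)`` per channel and wavelength, with the
   baseline taken as the *geometric* temporal mean so that dOD is exactly
   zero-mean and exactly linear in the underlying chromophore signal;
2. dOD -> hemoglobin concentration change via the modified Beer-Lambert law:
   ``dOD_lambda = (eps_HbO,lambda dHbO + eps_HbR,lambda dHbR) * L * DPF_lambda``
   solved per time point as a 2x2 linear system for the 690/830 nm pair;
3. anti-aliased polyphase decimation to the analysis rates (2 Hz for
   activation, 4 Hz for connectivity);
4. zero-phase Butterworth band-pass filtering into the analysis bands
   (low 0.01-0.08 Hz, high 0.5-1 Hz, cardiac 0.01-2 Hz).

Hemoglobin concentration changes are in micromolar (uM); optical density is
unitless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from nirspain.probe import RawIntensityRecording

#: Molar extinction coefficients, OD / (uM * cm), rows = wavelength,
#: columns = (HbO, HbR).  Values from the standard compiled hemoglobin
#: spectra used across CW-fNIRS toolboxes.
EXTINCTION_UM_CM = {
    690.0: (2.7600e-4, 2.0520e-3),
    830.0: (9.7400e-4, 6.9304e-4),
}

#: Default differential pathlength factor, per wavelength (unitless).
DEFAULT_DPF = 6.0


@dataclass
class OpticalDensitySeries:
    """Change in optical density, (channels, wavelengths, times), unitless."""

    od: np.ndarray
    sampling_rate: float
    wavelengths: tuple[float, ...]

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3:
            raise ValueError("od must be (channels, wavelengths, times)")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.od.shape[0]


@dataclass
class HemoglobinTimeSeries:
    """HbO/HbR concentration change (uM), shape (channels, times)."""

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("HbO and HbR must have the same shape")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_times(self) -> int:
        return self.hbo.shape[1]

    def crop(self, start_s: float, stop_s: float) -> "HemoglobinTimeSeries":
        i0 = int(np.ceil(start_s * self.sampling_rate - 1e-9))
        i1 = min(int(np.ceil(stop_s * self.sampling_rate - 1e-9)), self.n_times)
        return HemoglobinTimeSeries(
            hbo=self.hbo[:, i0:i1],
            hbr=self.hbr[:, i0:i1],
            sampling_rate=self.sampling_rate,
            provenance=dict(self.provenance),
        )


def extinction_matrix(wavelengths: tuple[float, ...]) -> np.ndarray:
    """2x2 extinction matrix, rows = wavelengths, cols = (HbO, HbR)."""
    try:
        return np.array([EXTINCTION_UM_CM[float(w)] for w in wavelengths])
    except KeyError as exc:
        raise KeyError(
            f"no packaged extinction coefficients for wavelength {exc}; "
            "pass an explicit extinction table"
        ) from exc


def intensity_to_od(rec: RawIntensityRecording) -> OpticalDensitySeries:
    """Convert raw intensities to optical density change.

    The baseline is the geometric temporal mean of each channel/wavelength
    trace, which makes dOD exactly zero-mean (an arithmetic-mean baseline
    leaves a second-order offset through the exp nonlinearity).  Scaling all
    intensities of a trace by a constant gain leaves dOD unchanged.
    """
    intens = rec.intensities
    if np.any(intens <= 0):
        ch, wl, t = np.argwhere(intens <= 0)[0]
        raise ValueError(
            f"non-positive intensity at channel {ch + 1}, wavelength index "
            f"{wl}, sample {t}"
        )
    log_i = np.log(intens)
    od = -(log_i - log_i.mean(axis=2, keepdims=True))
    return OpticalDensitySeries(
        od=od,
        sampling_rate=rec.sampling_rate,
        wavelengths=tuple(rec.layout.wavelengths),
    )


def od_to_hemoglobin(
    od: OpticalDensitySeries,
    dpf: float | tuple[float, float] = DEFAULT_DPF,
    separation_cm: float = 3.0,
    extinction: np.ndarray | None = None,
) -> HemoglobinTimeSeries:
    """Invert the modified Beer-Lambert law for the two-wavelength pair.

    Parameters
    ----------
    dpf
        Differential pathlength factor, scalar or one value per wavelength.
    separation_cm
        Emitter-detector separation L in cm.
    extinction
        Optional 2x2 override, rows = wavelengths, cols = (HbO, HbR), in
        OD / (uM * cm); defaults to the packaged table for the recording's
        wavelengths.
    """
    if extinction is None:
        extinction = extinction_matrix(od.wavelengths)
    extinction = np.asarray(extinction, dtype=float)
    if extinction.shape != (2, 2):
        raise ValueError("extinction must be 2x2 (wavelengths x chromophores)")
    dpf_arr = np.broadcast_to(np.asarray(dpf, dtype=float), (2,))
    a = extinction * (separation_cm * dpf_arr[:, None])
    if abs(np.linalg.det(a)) < 1e-12:
        raise ValueError("extinction matrix is singular; cannot separate HbO/HbR")
    a_inv = np.linalg.inv(a)
    # od: (ch, 2, t) -> conc (ch, 2, t)
    conc = np.einsum("kw,cwt->ckt", a_inv, od.od)
    return HemoglobinTimeSeries(
        hbo=conc[:, 0, :],
        hbr=conc[:, 1, :],
        sampling_rate=od.sampling_rate,
        provenance={
            "dpf": tuple(map(float, dpf_arr)),
            "separation_cm": float(separation_cm),
            "extinction_um_cm": extinction.tolist(),
            "wavelengths_nm": tuple(map(float, od.wavelengths)),
        },
    )


def hemoglobin_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    dpf: float | tuple[float, float] = DEFAULT_DPF,
    separation_cm: float = 3.0,
    extinction: np.ndarray | None = None,
    wavelengths: tuple[float, float] = (690.0, 830.0),
) -> np.ndarray:
    """Forward modified Beer-Lambert projection, the inverse of
    :func:`od_to_hemoglobin`; returns (channels, wavelengths, times) dOD."""
    if extinction is None:
        extinction = extinction_matrix(wavelengths)
    extinction = np.asarray(extinction, dtype=float)
    dpf_arr = np.broadcast_to(np.asarray(dpf, dtype=float), (2,))
    a = extinction * (separation_cm * dpf_arr[:, None])
    conc = np.stack([np.atleast_2d(hbo), np.atleast_2d(hbr)], axis=1)
    return np.einsum("wk,ckt->cwt", a, conc)


def resample_array(x: np.ndarray, rate: float, target_hz: float) -> np.ndarray:
    """Anti-alias filtered polyphase decimation along the last axis."""
    if target_hz <= 0 or target_hz > rate:
        raise ValueError(
            f"target rate must be in (0, {rate}] Hz, got {target_hz}"
        )
    if np.isclose(target_hz, rate):
        return np.asarray(x, dtype=float)
    frac = Fraction(target_hz / rate).limit_denominator(10000)
    y = signal.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                             frac.denominator, axis=-1)
    n_out = int(np.floor(x.shape[-1] * target_hz / rate))
    return y[..., :n_out]


def resample(series: HemoglobinTimeSeries, target_hz: float) -> HemoglobinTimeSeries:
    """Down-sample a hemoglobin series to ``target_hz`` (anti-aliased)."""
    return HemoglobinTimeSeries(
        hbo=resample_array(series.hbo, series.sampling_rate, target_hz),
        hbr=resample_array(series.hbr, series.sampling_rate, target_hz),
        sampling_rate=float(target_hz),
        provenance={**series.provenance, "resampled_from_hz": series.sampling_rate},
    )


def bandpass(
    x: np.ndarray,
    rate: float,
    low_hz: float,
    high_hz: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    ``low_hz`` may be 0 for a pure low-pass.  Forward-backward filtering
    (sosfiltfilt) doubles the effective order and cancels phase delay, so
    event-locked responses are not shifted in time.
    """
    nyq = rate / 2.0
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"high edge {high_hz} Hz not below Nyquist {nyq} Hz at rate {rate}"
        )
    x = np.asarray(x, dtype=float)
    # separate high-pass/low-pass cascade keeps the full order-`order`
    # rolloff at each edge even for very wide bands (e.g. 0.01-2 Hz)
    sos_lp = signal.butter(order, high_hz / nyq, btype="lowpass", output="sos")
    y = signal.sosfiltfilt(sos_lp, x, axis=-1)
    if low_hz > 0:
        sos_hp = signal.butter(order, low_hz / nyq, btype="highpass",
                               output="sos")
        y = signal.sosfiltfilt(sos_hp, y, axis=-1)
    return y


class BeerLambertTransformer(BaseEstimator, TransformerMixin):
    """Recording -> hemoglobin series, as a composable transformer.

    ``transform`` accepts a :class:`~nirspain.probe.RawIntensityRecording`
    (or a list of them) and returns :class:`HemoglobinTimeSeries`.
    """

    def __init__(
        self,
        dpf: float | tuple[float, float] = DEFAULT_DPF,
        separation_cm: float = 3.0,
    ):
        self.dpf = dpf
        self.separation_cm = separation_cm

    def fit(self, X=None, y=None):  # stateless
        return self

    def transform(self, X):
        def _one(rec: RawIntensityRecording) -> HemoglobinTimeSeries:
            return od_to_hemoglobin(
                intensity_to_od(rec), dpf=self.dpf, separation_cm=self.separation_cm
            )

        if isinstance(X, RawIntensityRecording):
            return _one(X)
        return [_one(rec) for rec in X]


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth band-pass over (n_series, n_times) arrays."""

    def __init__(self, low_hz: float, high_hz: float, rate: float, order: int = 4):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.rate = rate
        self.order = order

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        return bandpass(X, self.rate, self.low_hz, self.high_hz, order=self.order)


class Resampler(BaseEstimator, TransformerMixin):
    """Polyphase decimation of (n_series, n_times) arrays to ``target_hz``."""

    def __init__(self, target_hz: float, rate: float):
        self.target_hz = target_hz
        self.rate = rate

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        return resample_array(X, self.rate, self.target_hz)
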