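"""Reporter-timeseries processing: detrending, wavelet periods, phases.

The raw input is a coarse-grained reporter intensity trace (one value per
sample per timepoint, e.g. a global-ROI average of a dynamic signaling
reporter).  The stages here turn it into quantities the entrainment
analysis consumes: a detrended oscillation (windowed-sinc high-pass), an
instantaneous period from the ridge of a continuous Morlet wavelet
spectrum, and an instantaneous phase with the convention that phase 0 sits
at oscillation peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
import scipy.signal

from .circstats import TWO_PI, wrap_2pi

OMEGA0 = 6.0  # Morlet time-frequency resolution parameter
_MORLET = f"cmor2.0-{OMEGA0 / TWO_PI:.12f}"  # bandwidth 2 <=> exp(-t^2/2)

__all__ = [
    "Timeseries",
    "PhaseSeries",
    "SpectrumGrid",
    "sinc_detrend",
    "wavelet_spectrum",
    "ridge_periods",
    "extract_phase",
    "mean_period_window",
]


@dataclass
class Timeseries:
    """One sample's uniformly sampled reporter intensity.

    ``t`` in minutes (strictly increasing, uniform within 1e-9 relative
    tolerance), ``y`` in arbitrary intensity units; at least 16 points.
    """

    sample_id: str
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) < 16:
            raise ValueError(
                f"sample {self.sample_id!r}: need >= 16 timepoints, got {len(self.t)}"
            )
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise ValueError(f"sample {self.sample_id!r}: time grid not increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > 1e-9 * max(abs(dt), 1.0)):
            raise ValueError(
                f"sample {self.sample_id!r}: non-uniform sampling "
                f"(dt varies from {steps.min():.6g} to {steps.max():.6g} min)"
            )

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class PhaseSeries:
    """Instantaneous phase / period / ridge power for one sample.

    ``phi`` is wrapped to [0, 2pi); ``period`` in minutes; ``mask`` is True
    at timepoints flagged unreliable (low ridge power, or undefined phase
    velocity) — masked points are excluded from means, never interpolated.
    """

    sample_id: str
    t: np.ndarray
    phi: np.ndarray
    period: np.ndarray
    power: np.ndarray
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.zeros(len(self.t), dtype=bool)


@dataclass
class SpectrumGrid:
    """Morlet wavelet power over a time x period grid (backing store for the ridge)."""

    sample_id: str
    t: np.ndarray
    periods: np.ndarray  # strictly increasing, minutes
    power: np.ndarray  # shape (len(t), len(periods)), >= 0
    coef: np.ndarray = None  # complex coefficients, same shape (optional)


def sinc_detrend(ts: Timeseries, cutoff_period: float = 240.0,
                 numtaps: int | None = None) -> Timeseries:
    """Subtract a windowed-sinc low-pass trend (cutoff frequency 1/cutoff_period).

    The trend is the convolution of the signal with a Kaiser-windowed sinc
    FIR kernel; edges are handled by reflection padding.  By default the
    kernel spans the whole series (largest odd length <= len(y)), which
    gives the sharpest attainable transition band.
    """
    dt = ts.dt
    if cutoff_period <= 2.0 * dt:
        raise ValueError(
            f"cutoff_period ({cutoff_period} min) must exceed 2*dt ({2 * dt} min)"
        )
    n = len(ts.y)
    if numtaps is None:
        numtaps = n if n % 2 == 1 else n - 1
    if numtaps % 2 == 0:
        raise ValueError("numtaps must be odd")
    if numtaps > 2 * n - 1:
        raise ValueError(
            f"series of length {n} too short for a {numtaps}-tap kernel"
        )
    kernel = scipy.signal.firwin(
        numtaps, cutoff=1.0 / cutoff_period, fs=1.0 / dt, window=("kaiser", 8.6)
    )
    pad = numtaps // 2
    padded = np.pad(ts.y, pad, mode="reflect")
    trend = np.convolve(padded, kernel, mode="valid")
    return replace(ts, y=ts.y - trend)


def wavelet_spectrum(ts: Timeseries, period_min: float = 100.0,
                     period_max: float = 350.0, n_periods: int = 200) -> SpectrumGrid:
    """Continuous Morlet wavelet power over a log-spaced period grid.

    Expects a detrended input.  The wavelet is the complex Morlet with
    omega0 = 6; the scanned instantaneous-period grid has ``n_periods``
    log-spaced steps between ``period_min`` and ``period_max``.
    """
    dt = ts.dt
    if period_min >= period_max:
        raise ValueError("period range inverted: period_min >= period_max")
    if period_min <= 2.0 * dt:
        raise ValueError(f"period_min ({period_min}) must exceed 2*dt ({2 * dt})")
    if period_max >= ts.span:
        raise ValueError(
            f"period_max ({period_max}) must be below the series span ({ts.span})"
        )
    if np.any(~np.isfinite(ts.y)):
        raise ValueError(f"sample {ts.sample_id!r}: NaN/inf in intensity")

    periods = np.geomspace(period_min, period_max, n_periods)
    centre = pywt.ContinuousWavelet(_MORLET).center_frequency
    scales = centre * periods / dt
    coef, _ = pywt.cwt(ts.y, scales, _MORLET, sampling_period=dt)
    coef = coef.T  # -> (n_times, n_periods)
    # bias-rectified power (|W|^2 / scale): without the 1/scale factor the
    # ridge of a pure sinusoid is displaced toward longer periods
    power = np.abs(coef) ** 2 / scales[None, :]
    return SpectrumGrid(
        sample_id=ts.sample_id, t=ts.t.copy(), periods=periods,
        power=power, coef=coef,
    )


def ridge_periods(spec: SpectrumGrid, power_floor: float = 0.0) -> PhaseSeries:
    """Instantaneous period from the wavelet ridge (argmax over periods).

    Timepoints whose ridge power falls below ``power_floor`` keep their
    period estimate but are flagged in the mask.
    """
    if spec.power.size == 0:
        raise ValueError("empty spectrum grid")
    idx = np.argmax(spec.power, axis=1)
    rows = np.arange(len(spec.t))
    period = spec.periods[idx]
    power = spec.power[rows, idx]
    if spec.coef is not None:
        phi = wrap_2pi(np.angle(spec.coef[rows, idx]))
    else:
        phi = np.full(len(spec.t), np.nan)
    return PhaseSeries(
        sample_id=spec.sample_id, t=spec.t.copy(), phi=phi,
        period=period, power=power, mask=power < power_floor,
    )


def extract_phase(ts: Timeseries, method: str = "hilbert", **spectrum_kw) -> PhaseSeries:
    """Instantaneous phase of a detrended oscillation, peak-referenced.

    Phase 0 is defined at oscillation peaks: for a pure cosine the returned
    phase is (2 pi t / T) mod 2 pi.  ``method="hilbert"`` uses the analytic
    signal angle of the amplitude-normalized trace; ``method="ridge"`` reads
    the complex wavelet coefficient angle along the ridge (and its period).
    """
    if method == "hilbert":
        y = ts.y - np.mean(ts.y)
        scale = np.std(y)
        if scale < 1e-12 * (abs(np.mean(ts.y)) + 1.0):
            raise ValueError(
                f"sample {ts.sample_id!r}: constant signal, phase undefined"
            )
        z = scipy.signal.hilbert(y / scale)
        phi = wrap_2pi(np.angle(z))
        power = np.abs(z) ** 2
        unwrapped = np.unwrap(np.angle(z))
        dphi = np.gradient(unwrapped, ts.t)
        mask = dphi <= 0
        with np.errstate(divide="ignore"):
            period = np.where(dphi > 0, TWO_PI / np.where(dphi > 0, dphi, 1.0), np.nan)
        return PhaseSeries(
            sample_id=ts.sample_id, t=ts.t.copy(), phi=phi,
            period=period, power=power, mask=mask,
        )
    if method == "ridge":
        if np.ptp(ts.y) == 0:
            raise ValueError(
                f"sample {ts.sample_id!r}: constant signal, phase undefined"
            )
        return ridge_periods(wavelet_spectrum(ts, **spectrum_kw))
    raise ValueError(f"unknown phase extraction method {method!r}")


def mean_period_window(ps: PhaseSeries, t0: float, t1: float) -> float:
    """Arithmetic mean of unmasked instantaneous periods over [t0, t1]."""
    if t1 <= t0:
        raise ValueError("empty window: t1 <= t0")
    sel = (ps.t >= t0) & (ps.t <= t1) & ~ps.mask & np.isfinite(ps.period)
    if np.count_nonzero(sel) < 3:
        raise ValueError(
            f"sample {ps.sample_id!r}: fewer than 3 usable timepoints in "
            f"[{t0}, {t1}] min"
        )
    return float(np.mean(ps.period[sel]))
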