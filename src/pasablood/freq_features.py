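"""Frequency-domain features and the full 31-feature extraction.

The power spectrum is a Welch estimate (Hamming windows of 1/8 the signal
length, 50% overlap, averaged periodograms) expressed in dB.  Band-limited
linear regressions of the dB spectrum give the PASA slope (dB/MHz), the
intercept (regression line at 0 MHz) and the midband fit (line at the band
center) for four bands; the most prominent spectral peak in each of six
half-MHz bands contributes a prominence (dB) and a full width at half
maximum (MHz, measured at half the prominence); the trapezoidal area under
the dB spectrum completes the 25 frequency-domain features.

Sampling-rate modes
-------------------
The nominal 0.002 ms sampling interval puts the Nyquist frequency at
0.25 MHz, while the band edges are conventionally quoted on a 0–3 MHz axis.
In ``paper_dims`` mode the quoted MHz edges are rescaled by nyquist/3 so the
four/six bands tile the available spectrum; in ``wideband`` mode the quoted
edges are used verbatim and the sampling interval must support them
(Nyquist >= 3 MHz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .prep import AveragedSignal
from .time_features import (
    TIME_FEATURE_NAMES,
    amplitude_features,
    detect_change_points,
    partition_windows,
    slope_features,
    time_domain_area,
)

__all__ = [
    "PowerSpectrum",
    "BandFit",
    "PeakFeature",
    "FeatureConfig",
    "welch_psd",
    "pasa_fit",
    "peak_features",
    "frequency_domain_area",
    "extract_all_features",
    "FEATURE_NAMES",
    "PASA_FEATURE_NAMES",
    "PEAK_FEATURE_NAMES",
]

_DB_FLOOR = 1e-300  # guards log10 of an exactly-zero spectral bin

DEFAULT_PASA_BANDS = ((0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (0.0, 3.0))
DEFAULT_PEAK_BANDS = (
    (0.0, 0.5), (0.5, 1.0), (1.0, 1.5), (1.5, 2.0), (2.0, 2.5), (2.5, 3.0),
)

PASA_FEATURE_NAMES = tuple(
    f"{kind}_b{i}" for kind in ("pasa_slope", "midband", "intercept") for i in range(1, 5)
)
PEAK_FEATURE_NAMES = tuple(
    f"{kind}_s{i}" for kind in ("fwhm", "prominence") for i in range(1, 7)
)
FEATURE_NAMES = TIME_FEATURE_NAMES + PASA_FEATURE_NAMES + PEAK_FEATURE_NAMES + ("freq_area",)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided Welch power spectral density in dB vs frequency in MHz."""

    f: np.ndarray
    p_db: np.ndarray
    segment_length: int
    overlap_fraction: float = 0.5
    window_kind: str = "hamming"
    nyquist: float = 0.0

    @property
    def df(self) -> float:
        return float(self.f[1] - self.f[0])


def welch_psd(
    signal,
    dt: float,
    n_segments_divisor: int = 8,
    nperseg: int | None = None,
    noverlap: int | None = None,
) -> PowerSpectrum:
    """Welch PSD with Hamming windows of length N/divisor and 50% overlap.

    ``dt`` is the sampling interval in ms, so frequencies come out in MHz.
    Power is 10*log10 of the averaged linear density.  ``nperseg``/``noverlap``
    override the divisor rule (e.g. a single full-length segment with zero
    overlap reduces Welch to a plain Hamming periodogram).
    """
    y = np.asarray(signal, dtype=float)
    n = len(y)
    if nperseg is None:
        nperseg = n // n_segments_divisor
    if nperseg < 2:
        raise ValueError("segment length below 2 samples; signal too short")
    if n < nperseg:
        raise ValueError(
            f"signal of {n} samples is shorter than one segment ({nperseg})"
        )
    if noverlap is None:
        noverlap = nperseg // 2
    fs_mhz = 1.0e-3 / dt  # 1/ms -> kHz -> but expressed directly: 0.002 ms -> 0.5 MHz
    f, pxx = sps.welch(
        y,
        fs=fs_mhz,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        return_onesided=True,
    )
    p_db = 10.0 * np.log10(np.maximum(pxx, _DB_FLOOR))
    return PowerSpectrum(
        f=f,
        p_db=p_db,
        segment_length=int(nperseg),
        overlap_fraction=noverlap / nperseg,
        nyquist=fs_mhz / 2.0,
    )


@dataclass(frozen=True)
class BandFit:
    """Band-limited straight-line fit of the dB spectrum (PASA)."""

    band: tuple
    slope: float      # dB/MHz
    intercept: float  # dB, regression line evaluated at 0 MHz
    midband_fit: float  # dB, regression line at the band center

    def __post_init__(self) -> None:
        center = 0.5 * (self.band[0] + self.band[1])
        expected = self.intercept + self.slope * center
        if not np.isclose(self.midband_fit, expected, rtol=1e-9, atol=1e-9):
            raise ValueError("midband_fit inconsistent with slope and intercept")


def pasa_fit(psd: PowerSpectrum, band) -> BandFit:
    """Ordinary least squares of p_db on f over bins with f_lo <= f < f_hi."""
    f_lo, f_hi = band
    mask = (psd.f >= f_lo) & (psd.f < f_hi)
    if mask.sum() < 2:
        raise ValueError(
            f"band ({f_lo:g}, {f_hi:g}) MHz holds {int(mask.sum())} spectral bins; "
            "at least 2 are required for a line fit"
        )
    x, p = psd.f[mask], psd.p_db[mask]
    b, a = np.polyfit(x, p, 1)
    center = 0.5 * (f_lo + f_hi)
    return BandFit(
        band=(float(f_lo), float(f_hi)),
        slope=float(b),
        intercept=float(a),
        midband_fit=float(a + b * center),
    )


@dataclass(frozen=True)
class PeakFeature:
    """Most prominent in-band spectral peak; absent fields encoded as NaN."""

    band: tuple
    prominence: float
    fwhm: float
    peak_freq: float

    @property
    def present(self) -> bool:
        return np.isfinite(self.prominence)


def peak_features(
    psd: PowerSpectrum, band, prominence_threshold: float = 10.0
) -> PeakFeature:
    """Max-prominence peak in a band, with FWHM at half-prominence height.

    Prominence is the height of a local maximum of the dB spectrum above the
    lowest contour enclosing only that peak (computed on the full spectrum,
    so contour bases may extend beyond the band).  Peaks with prominence <=
    threshold are discarded; the surviving peak's width is measured at half
    its prominence below the peak, linearly interpolated between bins, and
    converted to MHz.  If no peak survives, prominence and FWHM are NaN.
    """
    f_lo, f_hi = band
    if f_lo >= psd.f[-1] or f_hi <= psd.f[0]:
        raise ValueError(f"band ({f_lo:g}, {f_hi:g}) MHz does not intersect the spectrum")
    peaks, props = sps.find_peaks(psd.p_db, prominence=0.0)
    in_band = (psd.f[peaks] >= f_lo) & (psd.f[peaks] < f_hi)
    keep = in_band & (props["prominences"] > prominence_threshold)
    if not np.any(keep):
        return PeakFeature(
            band=(float(f_lo), float(f_hi)),
            prominence=float("nan"),
            fwhm=float("nan"),
            peak_freq=float("nan"),
        )
    idx = np.flatnonzero(keep)
    best = idx[np.argmax(props["prominences"][idx])]
    widths, _, _, _ = sps.peak_widths(
        psd.p_db,
        peaks[best:best + 1],
        rel_height=0.5,
        prominence_data=(
            props["prominences"][best:best + 1],
            props["left_bases"][best:best + 1],
            props["right_bases"][best:best + 1],
        ),
    )
    return PeakFeature(
        band=(float(f_lo), float(f_hi)),
        prominence=float(props["prominences"][best]),
        fwhm=float(widths[0] * psd.df),
        peak_freq=float(psd.f[peaks[best]]),
    )


def frequency_domain_area(psd: PowerSpectrum) -> float:
    """Trapezoidal area under the dB spectrum across the full axis (dB·MHz)."""
    if len(psd.f) < 2:
        raise ValueError("need at least two spectral bins to integrate")
    return float(np.trapezoid(psd.p_db, psd.f))


@dataclass(frozen=True)
class FeatureConfig:
    """Band layout and estimator settings for the 31-feature extraction."""

    pasa_bands: tuple = DEFAULT_PASA_BANDS
    peak_bands: tuple = DEFAULT_PEAK_BANDS
    prominence_threshold_db: float = 10.0
    welch_divisor: int = 8
    sampling_rate_mode: str = "paper_dims"
    changepoint_k: int = 10

    def __post_init__(self) -> None:
        if self.sampling_rate_mode not in ("paper_dims", "wideband"):
            raise ValueError(
                f"unknown sampling_rate_mode {self.sampling_rate_mode!r}; "
                "expected 'paper_dims' or 'wideband'"
            )

    def band_scale(self, nyquist: float) -> float:
        """Factor mapping the quoted MHz band edges onto the usable axis."""
        if self.sampling_rate_mode == "paper_dims":
            quoted_max = max(hi for _, hi in self.pasa_bands + self.peak_bands)
            return nyquist / quoted_max
        if nyquist < max(hi for _, hi in self.pasa_bands + self.peak_bands):
            raise ValueError(
                f"wideband mode needs Nyquist >= the highest band edge, got {nyquist:g} MHz"
            )
        return 1.0


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ValueError as exc:
        raise ValueError(f"{name}: {exc}") from exc


def extract_all_features(avg: AveragedSignal, config: FeatureConfig | None = None) -> pd.Series:
    """Extract the full named 31-feature vector from a prepared trace.

    6 time-domain features + 12 PASA (4 bands x slope/midband/intercept)
    + 6 FWHM + 6 prominence + 1 frequency-domain area.  Peak features with
    no sufficiently prominent peak are NaN.  Only the steady-state segment
    is used.
    """
    cfg = config or FeatureConfig()
    y = avg.steady_y
    t = avg.steady_t
    dt = avg.trace.dt

    cps = _stage("change_points", detect_change_points, y, cfg.changepoint_k)
    part = _stage("partition", partition_windows, y, cps)
    p2p, pos_amp, neg_amp = amplitude_features(y, part)
    pos_slope, neg_slope = _stage("slopes", slope_features, y, part, dt, t)
    area_t = _stage("time_area", time_domain_area, y, dt)

    psd = _stage("welch", welch_psd, y, dt, cfg.welch_divisor)
    scale = cfg.band_scale(psd.nyquist)

    out = {
        "p2p_amplitude": p2p,
        "pos_peak_amplitude": pos_amp,
        "neg_peak_amplitude": neg_amp,
        "positive_slope": pos_slope.b,
        "negative_slope": neg_slope.b,
        "time_area": area_t,
    }
    for i, (lo, hi) in enumerate(cfg.pasa_bands, start=1):
        fit = _stage("pasa", pasa_fit, psd, (lo * scale, hi * scale))
        out[f"pasa_slope_b{i}"] = fit.slope
        out[f"midband_b{i}"] = fit.midband_fit
        out[f"intercept_b{i}"] = fit.intercept
    for i, (lo, hi) in enumerate(cfg.peak_bands, start=1):
        pk = _stage(
            "peaks", peak_features, psd, (lo * scale, hi * scale),
            cfg.prominence_threshold_db,
        )
        out[f"fwhm_s{i}"] = pk.fwhm
        out[f"prominence_s{i}"] = pk.prominence
    out["freq_area"] = _stage("freq_area", frequency_domain_area, psd)

    return pd.Series(out, dtype=float).reindex(list(FEATURE_NAMES))
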