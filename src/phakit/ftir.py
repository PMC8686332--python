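"""Semi-quantitative PHA estimation from FT-IR spectra.

Intracellular polyhydroxyalkanoate shows up in an ATR FT-IR spectrum of
whole cells as a carbonyl-ester band near 1724 cm-1, while cellular
protein contributes the amide band I around 1650 cm-1.  The ratio of the
integrated carbonyl-ester region (1763–1705 cm-1) to the amide band I
region (1705–1580 cm-1) — the C:A 1 ratio — tracks PHA content and is a
valid linear proxy below roughly 44% PHA per cell dry weight.

Areas are trapezoidal integrals on the instrument grid, with linear
interpolation at region boundaries that fall between grid points.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "RegionDef",
    "CA1Result",
    "RatioTimeSeries",
    "CARBONYL_ESTER_REGION",
    "AMIDE_I_REGION",
    "read_spectrum",
    "baseline_correct",
    "integrate_region",
    "ca1_ratio",
    "ratio_rate",
    "calibrate_ratio_to_pha",
]


@dataclass(frozen=True)
class RegionDef:
    """A wavenumber window [lo, hi] in cm-1."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"region {self.name!r}: lo {self.lo} >= hi {self.hi}")


#: Carbonyl-ester region, diagnostic for PHA.
CARBONYL_ESTER_REGION = RegionDef(1705.0, 1763.0, "carbonyl_ester")
#: Amide band I region, the protein reference band.
AMIDE_I_REGION = RegionDef(1580.0, 1705.0, "amide_I")


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber/absorbance series, stored ascending in wavenumber."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    time_h: float | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1 or wn.size != ab.size:
            raise ValueError("wavenumbers and absorbance must be 1-D arrays "
                             "of equal length")
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(wn)
        if np.all(d < 0):  # descending input: store ascending
            wn, ab = wn[::-1], ab[::-1]
            d = -d
        if not np.all(d > 0):
            raise ValueError("wavenumbers must be strictly monotone")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavenumbers, self.absorbance * factor,
                        self.label, self.time_h)


@dataclass(frozen=True)
class CA1Result:
    """Carbonyl/amide region areas and their ratio for one spectrum."""

    carbonyl_area: float
    amide_area: float
    ratio: float
    carbonyl_peak_cm1: float
    pha_positive: bool


@dataclass(frozen=True)
class RatioTimeSeries:
    """C:A 1 results along a culture time course."""

    points: tuple[tuple[float, CA1Result], ...]
    stationary_onset_h: float | None = None
    ratio_per_h: float | None = None
    ratio_slope_per_h: float | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time points must be strictly increasing")


def read_spectrum(path: str | PathLike, label: str = "",
                  time_h: float | None = None) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) delimited text file.

    Comma, tab or whitespace delimited; lines starting with ``#`` are
    comments.  Descending instrument order is accepted and reversed.
    Raises on non-numeric rows, duplicate wavenumbers, or <2 points.
    """
    df = pd.read_csv(path, comment="#", header=None, sep=None,
                     engine="python", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    df = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: non-numeric value near data row {bad}")
    wn = df.iloc[:, 0].to_numpy(float)
    if np.unique(wn).size != wn.size:
        raise ValueError(f"{path}: duplicate wavenumbers")
    return Spectrum(wn, df.iloc[:, 1].to_numpy(float), label=label,
                    time_h=time_h)


def baseline_correct(spectrum: Spectrum,
                     window: tuple[float, float] = (1500.0, 1800.0),
                     method: str = "offset") -> Spectrum:
    """Remove baseline so the fingerprint window has no negative values.

    ``offset`` subtracts the minimum absorbance found inside ``window``
    from the whole spectrum, making the window minimum exactly zero.
    ``linear`` subtracts the straight line through the absorbance at the
    two window edges, then clips remaining negatives inside the window
    to zero.  The input spectrum is never modified.
    """
    lo, hi = window
    wn = spectrum.wavenumbers
    if lo < wn[0] or hi > wn[-1]:
        raise ValueError(
            f"window ({lo}, {hi}) outside spectrum range "
            f"({wn[0]:g}, {wn[-1]:g})")
    mask = (wn >= lo) & (wn <= hi)
    if not mask.any():
        raise ValueError(f"window ({lo}, {hi}) contains no data points")
    ab = spectrum.absorbance
    if method == "offset":
        corrected = ab - ab[mask].min()
    elif method == "linear":
        y_lo = float(np.interp(lo, wn, ab))
        y_hi = float(np.interp(hi, wn, ab))
        line = y_lo + (wn - lo) * (y_hi - y_lo) / (hi - lo)
        corrected = ab - line
        corrected = np.where(mask, np.maximum(corrected, 0.0), corrected)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return Spectrum(wn, corrected, spectrum.label, spectrum.time_h)


def integrate_region(spectrum: Spectrum, region: RegionDef) -> float:
    """Trapezoidal integral of absorbance over a wavenumber region.

    Region edges falling between grid points are handled by linear
    interpolation.  Units: absorbance * cm-1.
    """
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    lo = max(region.lo, wn[0])
    hi = min(region.hi, wn[-1])
    if lo >= hi:
        raise ValueError(
            f"region ({region.lo}, {region.hi}) does not overlap spectrum "
            f"range ({wn[0]:g}, {wn[-1]:g})")
    inner = (wn > lo) & (wn < hi)
    xs = np.concatenate(([lo], wn[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, wn, ab)], ab[inner],
                         [np.interp(hi, wn, ab)]))
    return float(np.trapezoid(ys, xs))


def ca1_ratio(spectrum: Spectrum,
              carbonyl: RegionDef = CARBONYL_ESTER_REGION,
              amide: RegionDef = AMIDE_I_REGION,
              baseline: str = "none",
              peak_window: tuple[float, float] = (1722.0, 1726.0),
              prominence: float = 0.01) -> CA1Result:
    """Compute the C:A 1 ratio for one spectrum.

    ``baseline`` is ``none`` (raw spectra, the default for liquid-culture
    measurements), ``offset`` or ``linear``.  ``pha_positive`` is true
    when the carbonyl-region maximum sits inside ``peak_window``
    (default 1722–1726 cm-1, i.e. 1724 +/- 2) and rises at least
    ``prominence`` absorbance units above the carbonyl-window minimum.
    """
    if baseline != "none":
        span = (min(amide.lo, carbonyl.lo), max(amide.hi, carbonyl.hi))
        spectrum = baseline_correct(spectrum, window=span, method=baseline)
    carbonyl_area = integrate_region(spectrum, carbonyl)
    amide_area = integrate_region(spectrum, amide)
    if amide_area <= 0:
        raise ValueError("amide band area is non-positive; "
                         "C:A 1 ratio undefined")
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    cmask = (wn >= carbonyl.lo) & (wn <= carbonyl.hi)
    peak_idx = np.argmax(ab[cmask])
    peak_cm1 = float(wn[cmask][peak_idx])
    peak_height = float(ab[cmask][peak_idx] - ab[cmask].min())
    positive = (peak_window[0] <= peak_cm1 <= peak_window[1]
                and peak_height > prominence)
    return CA1Result(carbonyl_area=carbonyl_area, amide_area=amide_area,
                     ratio=carbonyl_area / amide_area,
                     carbonyl_peak_cm1=peak_cm1, pha_positive=positive)


def ratio_rate(series: Sequence[tuple[float, CA1Result]],
               stationary_onset: float) -> RatioTimeSeries:
    """Normalize a C:A 1 time course to production per hour.

    Primary definition: the ratio at the first measurement taken at or
    after ``stationary_onset`` divided by the elapsed culture time of
    that measurement (``ratio_per_h``).  Because the text definition of
    "ratio per hour" is ambiguous, the finite-difference alternative —
    the slope over the last two measurements — is always co-reported as
    ``ratio_slope_per_h``.
    """
    pts = sorted(series, key=lambda p: p[0])
    post = [(t, r) for t, r in pts if t >= stationary_onset]
    if not post:
        raise ValueError(
            f"no measurement at or after stationary onset {stationary_onset} h")
    t0, r0 = post[0]
    if t0 <= 0:
        raise ValueError("first post-onset time point must be positive")
    per_h = r0.ratio / t0
    slope = None
    if len(pts) >= 2:
        (ta, ra), (tb, rb) = pts[-2], pts[-1]
        slope = (rb.ratio - ra.ratio) / (tb - ta)
    return RatioTimeSeries(points=tuple(pts), stationary_onset_h=stationary_onset,
                           ratio_per_h=per_h, ratio_slope_per_h=slope)


@dataclass(frozen=True)
class RatioCalibration:
    """User-supplied linear map from C:A 1 ratio to %PHA of CDW."""

    slope: float
    intercept: float = 0.0
    validity_max_pct: float = 44.0


def calibrate_ratio_to_pha(ratio: float,
                           calibration: RatioCalibration | None
                           ) -> tuple[float | None, bool]:
    """Convert a C:A 1 ratio to %PHA of CDW via a linear calibration.

    Returns ``(pct_pha, valid)``.  Without a calibration the result is
    ``(None, False)`` — explicitly uncalibrated, never a guessed value.
    The linear proxy holds only below 44% PHA/CDW, so results above the
    calibration's validity bound are returned with ``valid`` False.
    """
    if calibration is None:
        return None, False
    pct = calibration.slope * ratio + calibration.intercept
    return pct, pct <= calibration.validity_max_pct
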