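"""Growth kinetics and PHA productivity arithmetic.

The specific growth rate k (per hour) is the log-ratio of two optical
densities taken during exponential phase divided by the elapsed time:

    k = ln(OD600(t2) / OD600(t1)) / (t2 - t1)

Productivity bookkeeping converts cell dry weight (CDW, g/L) and the
monomer content measured by GC-FID (% of CDW per monomer, e.g. 3HB and
3HV) into a PHA titer in g/L.  Dispersion across replicates is reported
as the population standard deviation (divide-by-n) and the coefficient
of variation, matching spreadsheet STDEV.P conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GrowthCurve",
    "RateEstimate",
    "ProductivityRecord",
    "DispersionStat",
    "specific_growth_rate",
    "max_growth_rate",
    "stationary_onset",
    "pha_titer",
    "round_half_away",
    "dispersion",
]


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series; times in hours, strictly increasing."""

    times: np.ndarray
    od600: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.ndim != 1 or od.ndim != 1 or t.size != od.size:
            raise ValueError("times and od600 must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a growth curve needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(od)) or np.any(od < 0):
            raise ValueError("od600 values must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RateEstimate:
    """A specific-growth-rate estimate with its time window."""

    k: float
    window: tuple[float, float]
    method: str
    r2: float | None = None


@dataclass(frozen=True)
class ProductivityRecord:
    """One harvest: CDW plus per-monomer content as % of CDW."""

    strain: str
    substrate: str
    cdw_g_per_l: float
    monomer_fractions_pct: Mapping[str, float]
    od_harvest: float | None = None

    @property
    def pha_g_per_l(self) -> float:
        return pha_titer(self.cdw_g_per_l, self.monomer_fractions_pct)


@dataclass(frozen=True)
class DispersionStat:
    mean: float
    population_sd: float
    cv: float | None


def specific_growth_rate(od1: float, od2: float, t1: float, t2: float) -> float:
    """k = ln(od2/od1) / (t2 - t1), in per hours."""
    if od1 <= 0 or od2 <= 0:
        raise ValueError("optical densities must be positive")
    if t2 <= t1:
        raise ValueError(f"t2 ({t2}) must be greater than t1 ({t1})")
    return math.log(od2 / od1) / (t2 - t1)


def max_growth_rate(curve: GrowthCurve, method: str = "pairwise_max",
                    window_pts: int = 4) -> RateEstimate:
    """Maximum specific growth rate along a curve.

    ``pairwise_max`` applies the two-point log-ratio formula to every
    consecutive pair of positive-OD points and returns the largest k.
    ``regression`` fits ln(OD) against time in a sliding window of
    ``window_pts`` points (default 4, i.e. three 2-h sampling intervals)
    and returns the steepest slope with its r^2; it is the smoother
    choice for noisy curves.
    """
    t, od = curve.times, curve.od600
    pos = od > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 points with OD > 0")
    if method == "pairwise_max":
        best: RateEstimate | None = None
        for i in range(len(curve) - 1):
            if od[i] <= 0 or od[i + 1] <= 0:
                continue
            k = specific_growth_rate(od[i], od[i + 1], t[i], t[i + 1])
            if best is None or k > best.k:
                best = RateEstimate(k, (float(t[i]), float(t[i + 1])),
                                    "pairwise_max")
        assert best is not None
        return best
    if method == "regression":
        w = min(window_pts, int(pos.sum()))
        if w < 2:
            raise ValueError("regression window must cover >= 2 points")
        ti, yi = t[pos], np.log(od[pos])
        best = None
        for i in range(len(ti) - w + 1):
            fit = stats.linregress(ti[i:i + w], yi[i:i + w])
            if best is None or fit.slope > best.k:
                best = RateEstimate(float(fit.slope),
                                    (float(ti[i]), float(ti[i + w - 1])),
                                    "regression", r2=float(fit.rvalue ** 2))
        assert best is not None
        return best
    raise ValueError(f"unknown method {method!r}")


def stationary_onset(curve: GrowthCurve, frac: float = 0.95) -> float:
    """First time at which OD reaches ``frac`` of the curve maximum."""
    threshold = frac * curve.od600.max()
    idx = int(np.argmax(curve.od600 >= threshold))
    return float(curve.times[idx])


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (spreadsheet-style), e.g. 0.25 -> 0.3."""
    value = float(value)
    q = Decimal(10) ** -decimals
    d = Decimal(repr(value)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_sign(Decimal(repr(value))))


def pha_titer(cdw_g_per_l: float,
              fractions_pct: Mapping[str, float] | Sequence[float] | float,
              rounded: bool = True) -> float:
    """PHA titer in g/L from CDW and monomer content.

    titer = CDW * (sum of monomer %CDW fractions) / 100, reported rounded
    half-away-from-zero to one decimal (``rounded=False`` returns the
    exact product for downstream arithmetic).
    """
    if isinstance(fractions_pct, Mapping):
        fracs = list(fractions_pct.values())
    elif isinstance(fractions_pct, (int, float)):
        fracs = [float(fractions_pct)]
    else:
        fracs = list(fractions_pct)
    if cdw_g_per_l < 0 or any(f < 0 for f in fracs):
        raise ValueError("CDW and monomer fractions must be >= 0")
    exact = cdw_g_per_l * sum(fracs) / 100.0
    return round_half_away(exact, 1) if rounded else exact


def dispersion(values: Sequence[float]) -> DispersionStat:
    """Mean, population (divide-by-n) SD, and CV of replicate values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("dispersion of an empty sample is undefined")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=0))
    cv = sd / mean if mean != 0 else None
    return DispersionStat(mean=mean, population_sd=sd, cv=cv)
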