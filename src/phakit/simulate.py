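"""Seeded generators for proteins, FT-IR spectra and growth curves.

Each generator returns ``(object, ground_truth)`` where the ground truth
records every planted quantity so the corresponding analysis stage can
be tested for exact or toleranced recovery.  All randomness flows from
an integer seed through :func:`numpy.random.default_rng`, so output is
fully reproducible across platforms.

What is emulated, and what is not: synthetic proteins have the extended
PhaC architecture (a catalytic segment with a planted box motif and a
Lys/Arg-enriched low-complexity C-terminus) but uniform background
composition rather than a real proteome's; spectra are sums of Gaussian
bands with linear baseline drift and white noise, not instrument-true
ATR line shapes; growth curves are logistic with a lag and multiplicative
log-normal noise, without substrate effects.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from phakit.ftir import Spectrum
from phakit.growth import GrowthCurve
from phakit.proteins import (
    ProteinRecord,
    count_aakp,
    scan_phac_box,
)

__all__ = [
    "ProteinSpec",
    "SpectrumSpec",
    "GrowthSpec",
    "gen_protein",
    "gen_spectrum",
    "gen_growth_curve",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Linear map from simulated PHA fraction to carbonyl band amplitude.
#: The slope is a package convention (no published calibration exists);
#: analyses assert only monotonicity, never this constant.
PHA_TO_CARBONYL_AMPLITUDE = 2.5

#: Swiss-Prot-style average amino-acid frequencies, an optional
#: proteome-like alternative to the uniform background.
PROTEOME_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class ProteinSpec:
    """Blueprint for an extended-PhaC-like synthetic protein."""

    seed: int = 0
    catalytic_len: int = 613
    cterm_len: int = 380
    box_motif: str = "SYCIG"
    box_position: int = 310        # 1-based start within the catalytic segment
    n_aakp: int = 5                # AAKP motifs planted in the C-terminus
    cterm_kr_fraction: float = 0.20
    background_freqs: dict[str, float] | None = None  # default uniform

    def __post_init__(self) -> None:
        if self.box_position < 1 or (
                self.box_position + len(self.box_motif) - 1 > self.catalytic_len):
            raise ValueError("box motif does not fit in the catalytic segment")
        if self.n_aakp * 4 > self.cterm_len:
            raise ValueError("AAKP motifs do not fit in the C-terminus")
        if not 0.0 <= self.cterm_kr_fraction <= 1.0:
            raise ValueError("cterm_kr_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SpectrumSpec:
    """Blueprint for a whole-cell-like absorbance spectrum.

    Default bands: amide I (1650 cm-1), amide II (1540), CH-stretch
    region minor bands (2850–2960), and a carbonyl-ester band at 1724
    whose amplitude scales linearly with ``pha_fraction``.
    """

    seed: int = 0
    grid_lo: float = 650.0
    grid_hi: float = 4000.0
    grid_step: float = 1.9
    pha_fraction: float = 0.2      # PHA as fraction of CDW, in [0, 0.6]
    carbonyl_center: float = 1724.0
    carbonyl_sigma: float = 10.0
    extra_bands: tuple[tuple[float, float, float], ...] = (
        (1650.0, 18.0, 1.0),       # amide I
        (1540.0, 15.0, 0.6),       # amide II
        (2850.0, 10.0, 0.10),      # CH2 symmetric stretch
        (2925.0, 12.0, 0.15),      # CH2 asymmetric stretch
        (2960.0, 10.0, 0.08),      # CH3 asymmetric stretch
    )
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0    # absorbance per cm-1
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        if not 0.0 <= self.pha_fraction <= 0.6:
            raise ValueError("pha_fraction must be in [0, 0.6]")
        if self.grid_step <= 0 or self.grid_lo >= self.grid_hi:
            raise ValueError("invalid wavenumber grid")


@dataclass(frozen=True)
class GrowthSpec:
    """Blueprint for a logistic OD600 curve with known exponential rate."""

    seed: int = 0
    k: float = 0.4                 # intrinsic exponential rate, per h
    lag_h: float = 2.0
    od_start: float = 0.05
    capacity: float = 8.0          # carrying capacity, OD600 units
    interval_h: float = 2.0
    horizon_h: float = 32.0
    noise_sd: float = 0.0          # sd of multiplicative log-normal noise

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.capacity < self.od_start:
            raise ValueError("capacity must be >= start OD")


def _sample_background(rng: np.random.Generator, n: int,
                       freqs: dict[str, float] | None) -> np.ndarray:
    if freqs is None:
        return rng.choice(_AA, size=n)
    aas = np.array(sorted(freqs))
    p = np.array([freqs[a] for a in aas], dtype=float)
    p = p / p.sum()
    return rng.choice(aas, size=n, p=p)


def _scrub_accidental_motifs(seq: list[str], rng: np.random.Generator,
                             protected: set[int]) -> None:
    """Mutate chance PhaC-box / AAKP matches outside protected positions.

    The 5-position box pattern occurs by chance roughly every 4000
    residues of uniform background, which would break exact-recovery
    guarantees; breaking the catalytic Cys (or the AAKP Lys) at an
    unprotected site removes the match without touching planted motifs.
    """
    for _ in range(100):
        s = "".join(seq)
        dirty = False
        for hit in scan_phac_box(s):
            cys0 = hit.catalytic_cys_index - 1
            if cys0 not in protected:
                seq[cys0] = str(rng.choice([a for a in _AA if a != "C"]))
                dirty = True
        for i in range(len(seq) - 3):
            if "".join(seq[i:i + 4]) == "AAKP" and not any(
                    j in protected for j in range(i, i + 4)):
                seq[i + 2] = str(rng.choice([a for a in _AA if a != "K"]))
                dirty = True
        if not dirty:
            return
    raise RuntimeError("failed to scrub accidental motifs")


def gen_protein(spec: ProteinSpec) -> tuple[ProteinRecord, dict]:
    """Generate a protein with planted box, AAKP and K/R ground truth.

    The C-terminal segment hits the target K+R fraction exactly (to
    rounding at one residue): K/R positions are drawn without
    replacement, remaining positions are filled from the non-K/R
    background.  Planted motifs are guaranteed to be the only matches.
    """
    rng = np.random.default_rng(spec.seed)
    protected: set[int] = set()

    cat = list(_sample_background(rng, spec.catalytic_len,
                                  spec.background_freqs))
    b0 = spec.box_position - 1
    for i, aa in enumerate(spec.box_motif):
        cat[b0 + i] = aa
    protected.update(range(b0, b0 + len(spec.box_motif)))

    n_kr = int(round(spec.cterm_kr_fraction * spec.cterm_len))
    non_kr = [a for a in _AA if a not in "KR"]
    cterm = [str(rng.choice(non_kr)) for _ in range(spec.cterm_len)]
    if n_kr:
        for p in rng.choice(spec.cterm_len, size=n_kr, replace=False):
            cterm[p] = str(rng.choice(["K", "R"]))

    # plant AAKP motifs at non-overlapping C-terminal slots
    aakp_starts: list[int] = []
    if spec.n_aakp:
        slots = rng.permutation(spec.cterm_len - 3)
        for s in slots:
            if all(abs(s - t) >= 4 for t in aakp_starts):
                aakp_starts.append(int(s))
                if len(aakp_starts) == spec.n_aakp:
                    break
        aakp_starts.sort()
        for s in aakp_starts:
            cterm[s:s + 4] = list("AAKP")
            protected.update(range(spec.catalytic_len + s,
                                   spec.catalytic_len + s + 4))

    seq = cat + cterm
    _scrub_accidental_motifs(seq, rng, protected)
    sequence = "".join(seq)
    cterm_seq = sequence[spec.catalytic_len:]
    kr_fraction = ((cterm_seq.count("K") + cterm_seq.count("R"))
                   / spec.cterm_len if spec.cterm_len else 0.0)

    record = ProteinRecord(
        id=f"synthetic_phac2_{spec.seed}",
        sequence=sequence,
        description="synthetic extended-PhaC-like protein "
                    f"(seed {spec.seed})")
    truth = {
        "seed": spec.seed,
        "length_aa": len(sequence),
        "catalytic_len": spec.catalytic_len,
        "cterm_len": spec.cterm_len,
        "box_motif": spec.box_motif,
        "box_position": spec.box_position,
        "aakp_starts_cterm": [s + 1 for s in aakp_starts],  # 1-based
        "n_aakp": len(aakp_starts),
        "cterm_kr_fraction": kr_fraction,
    }
    assert count_aakp(cterm_seq) == truth["n_aakp"]
    return record, truth


def _gaussian(x: np.ndarray, center: float, sigma: float,
              amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gen_spectrum(spec: SpectrumSpec) -> tuple[Spectrum, dict]:
    """Generate an absorbance spectrum as Gaussian bands + drift + noise.

    The carbonyl amplitude is ``PHA_TO_CARBONYL_AMPLITUDE * pha_fraction``.
    Ground truth stores the noise-free analytic area of every band
    (amplitude * sigma * sqrt(2*pi)) and the simulated PHA fraction.
    """
    rng = np.random.default_rng(spec.seed)
    wn = np.arange(spec.grid_lo, spec.grid_hi + spec.grid_step / 2,
                   spec.grid_step)
    a_pha = PHA_TO_CARBONYL_AMPLITUDE * spec.pha_fraction
    bands = [(spec.carbonyl_center, spec.carbonyl_sigma, a_pha),
             *spec.extra_bands]
    ab = np.zeros_like(wn)
    for center, sigma, amp in bands:
        if amp > 0:
            ab += _gaussian(wn, center, sigma, amp)
    ab += spec.baseline_offset + spec.baseline_slope * (wn - spec.grid_lo)
    if spec.noise_sd > 0:
        ab += rng.normal(0.0, spec.noise_sd, size=wn.size)
    truth = {
        "seed": spec.seed,
        "pha_fraction": spec.pha_fraction,
        "carbonyl_amplitude": a_pha,
        "band_areas": {
            f"{center:g}": amp * sigma * np.sqrt(2.0 * np.pi)
            for center, sigma, amp in bands
        },
    }
    label = f"synthetic_pha{spec.pha_fraction:g}_seed{spec.seed}"
    return Spectrum(wn, ab, label=label), truth


def gen_growth_curve(spec: GrowthSpec) -> tuple[GrowthCurve, dict]:
    """Generate a logistic OD600 time series sampled at fixed intervals.

    OD stays at the inoculation density during the lag, then follows
    logistic growth with intrinsic rate ``k`` toward the carrying
    capacity; noise is multiplicative log-normal.  Ground truth stores
    the true rate and the time at which the noise-free curve reaches
    95% of capacity.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.horizon_h + spec.interval_h / 2, spec.interval_h)
    od0, cap, k = spec.od_start, spec.capacity, spec.k
    od = np.full_like(t, od0)
    if cap > od0:
        grow = t >= spec.lag_h
        ratio = (cap - od0) / od0
        od[grow] = cap / (1.0 + ratio * np.exp(-k * (t[grow] - spec.lag_h)))
        stationary_h = spec.lag_h + np.log(ratio * 0.95 / 0.05) / k
    else:
        stationary_h = 0.0
    if spec.noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, spec.noise_sd, size=t.size))
    curve = GrowthCurve(t, od, label=f"synthetic_logistic_seed{spec.seed}")
    truth = {
        "seed": spec.seed,
        "k": k,
        "lag_h": spec.lag_h,
        "capacity": cap,
        "stationary_h": float(stationary_h),
    }
    return curve, truth
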