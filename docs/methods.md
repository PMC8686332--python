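# Methods

## Protein profiling

**Molecular weight.** Average (not monoisotopic) residue masses, summed
over the chain plus one water (18.01524 Da), the convention of standard
physicochemical calculators. Reported in kDa to one decimal in tables.
Non-canonical letters (B, Z, X, U, O) are accepted by the FASTA reader
but are hard errors for MW/pI: imputing an ambiguous residue would
silently bias the very quantities the profile exists to report.

**Net charge and pI.** The charge model sums Henderson–Hasselbalch
terms for the free N- and C-terminus and the ionizable side chains
(D, E, C, Y acidic; H, K, R basic). The default pKa set is the
Bjellqvist/Expasy one (N-term 7.5, C-term 3.55, D 4.05, E 4.45, C 9.0,
Y 10.0, H 5.98, K 10.0, R 12.0), kept in `phakit.constants` so an
alternate set (EMBOSS values are bundled) can be swapped without
touching the model. Residue-specific terminal pKa adjustments (e.g.
N-terminal Ala 7.59, C-terminal Glu 4.75) are implemented but **off by
default** (`terminal_adjustments=True` enables them); they move pI by
up to ~0.3 pH units for affected termini and explain second-decimal
differences between calculators. The charge is strictly decreasing in
pH, so the pI is the unique zero crossing; it is found by bisection to
1e-10 pH precision rather than by stopping when |Q| < tol, because in
flat stretches of the charge curve a charge-based stop can sit ~0.1 pH
from the true crossing. After convergence |Q| < 1e-4 is verified. Tests
cross-check against both a dense-grid (1e-4 step) scan and Biopython's
independent implementation.

**Segmentation.** Profiles split at residue 613 (1-based, inclusive) —
the catalytic-region length of the extended PhaC variant — exposed as a
parameter. Sequences shorter than the boundary give a catalytic-only
profile (no C-segment pI) rather than an error. Coordinates are 1-based
inclusive throughout.

**Motif scanning.** Both the 6-position box pattern `[GS]xCx[GA]G` and
the 5-position pattern `[GS]xCxG` are scanned (the short form covers
the GYCLG/SYCIG/SYCVG motifs reported for class I enzymes); overlaps
are allowed and a 6-mer suppresses the 5-mer at the same start, with
pattern provenance kept in `motif_name`. AAKP occurrences are counted
with overlaps permitted — the conservative superset, since counting
conventions in the literature are not explicit — and only in the
C-terminal segment, where the enrichment is diagnostic.

**Variant call.** Size thresholds (box-positive and ≥90 kDa →
`phac2_extended`; box-positive and 55–80 kDa → `phac1_like`) bracket the
published ranges for the two classes (93.6–106.4 kDa vs ~64–72 kDa)
with margin; both are configurable.

**Composition groups.** Small nonpolar {G,A,V,L,I,P,M,F,W}, polar
{S,T,C,N,Q,Y,H}, positive {K,R}, negative {D,E}. The split of K+R and
D+E is fixed by the analysis (basic-tail diagnosis); histidine goes
with the polar group because it is mostly neutral above pH 7. The four
groups partition the alphabet, so grouped fractions sum to one.

## FT-IR quantification

Region areas are trapezoidal integrals on the instrument grid with
linear interpolation at region edges; no peak fitting or deconvolution
is attempted. The carbonyl-ester region is 1705–1763 cm⁻¹ and the amide
band I region 1580–1705 cm⁻¹; the shared 1705 cm⁻¹ ordinate belongs to
both closed intervals, which is consistent with exact additivity of the
two areas to the 1580–1763 cm⁻¹ total. The default is **no** baseline
correction (liquid-culture spectra are ratioed raw); `offset` (zero the
window minimum) and `linear` (subtract the chord through the window
edges, clip in-window negatives) are opt-in, aimed at agar-plate
spectra with drift. The PHA-positive call requires the carbonyl-region
maximum within 1722–1726 cm⁻¹ and at least 0.01 absorbance of
prominence above the window minimum; the prominence value is a package
convention, configurable, not a published constant.

"Ratio per hour" is ambiguous between cumulative ratio ÷ elapsed time
and a rate of increase; `ratio_rate` reports the first as the primary
value (`ratio_per_h`) and always co-reports the two-point slope
(`ratio_slope_per_h`). Conversion of a ratio to %PHA of CDW requires a
user-supplied linear calibration; none is bundled, and results above
the 44% validity bound of the linear proxy are flagged invalid.

## Growth and productivity

The two-point rate is exact arithmetic on the log-ratio. For curves,
`pairwise_max` takes the maximum two-point rate over consecutive
samples; `regression` fits ln(OD) vs time in a sliding window (default
4 points, mirroring 2-h sampling over three intervals) and returns the
steepest slope with r². On logistic curves both underestimate the
intrinsic rate slightly (curvature within the window); the regression
estimator's mean bias at the default settings is about −3%, well within
the 10% recovery target. Stationary onset is the first time OD reaches
95% of the curve maximum (threshold configurable; no published value
exists). Titers are rounded half-away-from-zero to one decimal, the
spreadsheet convention that reproduces the published table; the
unrounded product is available (`rounded=False`). Dispersion uses the
population (divide-by-n) SD to match STDEV.P-style reporting, even
though sample SD would be the textbook choice for n = 6 replicates.

Two published harvest rows (MC34 on acetate, DSM 4741 on glycerol)
cannot be reproduced from their printed rounded inputs (3.4 × 0.72 =
2.448 → 2.4 ≠ 2.5; 4.0 × 0.61 = 2.44 → 2.4 ≠ 2.5); the original
arithmetic evidently used unrounded values. The productivity report
flags them rather than absorbing the discrepancy.

## Synthetic data

The generators define the test conditions; all draw from
`numpy.random.default_rng(seed)` with no time-based entropy.

*Proteins*: a 613-residue catalytic segment with one planted box motif
(default SYCIG at position 310) plus a 380-residue C-terminus hitting a
target K+R fraction (default 0.20) exactly, with planted AAKP motifs
(default 5, the maximum reported per sequence). Background composition
is uniform over the 20 residues (a Swiss-Prot-like frequency table is
provided as an option). Chance box/AAKP matches in the background are
scrubbed by mutating their unprotected anchor residue, so the planted
layout is provably the only one the scanners can find — this is what
makes exact-recovery tests meaningful. A uniform background yields a
near-neutral catalytic segment (pI ~6.3), so the synthetic N/C pI
separation (>3 units) is smaller than the >5 units seen for real
extended PhaC, whose catalytic domain is strongly acidic; tests assert
only the generator-derivable separation.

*Spectra*: sums of Gaussian bands — carbonyl 1724/σ10 with amplitude
2.5 × PHA fraction (the slope is an arbitrary recorded convention; only
monotonicity is ever asserted), amide I 1650/σ18/1.0, amide II
1540/σ15/0.6, minor CH-stretch bands at 2850–2960 — on a 650–4000 cm⁻¹
grid with 1.9 cm⁻¹ step, plus optional linear drift and Gaussian noise
(default sd 0.002). Gaussian rather than Lorentzian/Voigt shapes are
adequate for exercising integration and ratio logic; real ATR line
shapes, scattering and water-vapor artifacts are not modeled.

*Growth curves*: logistic OD(t) with lag (default 2 h), intrinsic rate
0.4 h⁻¹ (the reported optimum for these strains), start OD 0.05,
carrying capacity 8, 2-h sampling over 32 h, multiplicative log-normal
noise. Substrate consumption, diauxie and death phase are not modeled,
so passing recovery tests demonstrates estimator correctness on clean
kinetics, not robustness to every real-culture artifact.

## Problem sizes

The default verification runs use 200 random sequences for the pI
oracle, 100 synthetic proteins for motif recovery, 50 spectra for
monotonicity, and 100 logistic curves for rate recovery; the full suite
and the summary script each complete in a few seconds.

## Known limitations

No homology or domain search, no secondary-structure prediction, no
spectral deconvolution or chemometrics, no ODE growth models. pI values
depend on the pKa set to ±0.05–0.3; comparisons across tools should fix
the set and the terminal-adjustment policy first.
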