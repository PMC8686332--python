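"""Physicochemical profiling of PhaC polymerase candidates.

Class I PHA polymerases (PhaC) are ~60–73 kDa proteins carrying the
catalytic "PhaC box" (G/S)XCX(G/A)G around the active-site cysteine.
Some halophilic *Cobetia*/*Halomonas* strains instead encode an extended
variant of ~93–106 kDa whose C-terminal extension beyond the catalytic
region (boundary at residue 613 by convention) is strongly basic and
enriched in Lys/Arg and in the histone-like AAKP tetrapeptide.  This
module computes the quantities used to recognize that architecture:
average molecular weight, per-segment isoelectric points, motif scans,
residue-composition summaries and a size-based variant call.

Coordinates are 1-based and inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from os import PathLike
from typing import Mapping

from Bio import SeqIO

from phakit.constants import (
    ACIDIC_SIDE_CHAINS,
    AVERAGE_RESIDUE_MASS_DA,
    BASIC_SIDE_CHAINS,
    CANONICAL_RESIDUES,
    COMPOSITION_GROUPS,
    PKA_BJELLQVIST,
    PKA_CTERM_BY_RESIDUE,
    PKA_NTERM_BY_RESIDUE,
    PKA_SETS,
    WATER_MASS_DA,
)

__all__ = [
    "ProteinRecord",
    "MotifHit",
    "SegmentedProfile",
    "AaComposition",
    "read_fasta",
    "compute_mw",
    "net_charge",
    "compute_pi",
    "scan_phac_box",
    "count_aakp",
    "segment_profile",
    "classify_phac",
    "aa_composition",
]

# Default N-terminal segment length: the class I catalytic region of the
# extended PhaC variant; residues beyond it form the basic C-terminal tail.
DEFAULT_BOUNDARY = 613

_PHAC_BOX_6 = re.compile(r"(?=([GS].C.[GA]G))")
_PHAC_BOX_5 = re.compile(r"(?=([GS].C.G))")
_AAKP = re.compile(r"(?=AAKP)")


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence, the unit of profiling."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; ``start`` is the 1-based residue index.

    For PhaC boxes ``catalytic_cys_index`` points at the conserved
    active-site cysteine (``start + 2``); it is ``None`` for AAKP hits.
    """

    motif_name: str  # "phac_box_5" | "phac_box_6" | "aakp"
    start: int
    matched_seq: str
    catalytic_cys_index: int | None = None


@dataclass(frozen=True)
class SegmentedProfile:
    """MW and per-segment pI values plus motif annotation for one record."""

    record_id: str
    length_aa: int
    boundary: int
    mw_kda: float
    pi_full: float
    pi_n_segment: float
    pi_c_segment: float | None
    cterm_length_aa: int
    phac_box_hits: tuple[MotifHit, ...]
    aakp_count_cterm: int
    variant_call: str = "unclassified"


@dataclass(frozen=True)
class AaComposition:
    """Per-residue and grouped residue-composition of a sequence region."""

    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    group_fractions: Mapping[str, float]
    length: int


def _validate_canonical(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {pos}; only the "
                "20 canonical amino acids are admitted to MW/pI computations"
            )


def read_fasta(path: str | PathLike) -> list[ProteinRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Sequences are uppercased and trailing ``*`` stop symbols stripped.
    Non-canonical letters (B, Z, X, ...) are accepted here and rejected
    later by the MW/pI computations, so annotation-only workflows still
    run on imperfect sequences.

    Raises
    ------
    ValueError
        If the file contains no records or a duplicate record id.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(id=rec.id, sequence=seq,
                                     description=rec.description))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def compute_mw(sequence: str) -> float:
    """Average molecular weight of a peptide chain in kDa.

    Sum of average residue masses plus one water (18.01524 Da), the same
    convention as the Expasy Compute pI/MW tool; report to one decimal
    in summaries.
    """
    _validate_canonical(sequence)
    mass = sum(AVERAGE_RESIDUE_MASS_DA[aa] for aa in sequence) + WATER_MASS_DA
    return mass / 1000.0


def _resolve_pka(pka_set: str | Mapping[str, float]) -> Mapping[str, float]:
    if isinstance(pka_set, str):
        try:
            return PKA_SETS[pka_set]
        except KeyError:
            raise ValueError(
                f"unknown pKa set {pka_set!r}; available: {sorted(PKA_SETS)}"
            ) from None
    return pka_set


def net_charge(
    sequence: str,
    ph: float,
    pka_set: str | Mapping[str, float] = PKA_BJELLQVIST,
    terminal_adjustments: bool = False,
) -> float:
    """Net charge of a peptide at a given pH.

    Henderson–Hasselbalch sum over the free termini and the ionizable
    side chains (D, E, C, Y negative; H, K, R positive).  Strictly
    decreasing in pH, which makes the isoelectric point unique.
    ``terminal_adjustments`` switches on the residue-specific terminal
    pKa values used by Expasy-style calculators (off by default).
    """
    _validate_canonical(sequence)
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    pka = _resolve_pka(pka_set)
    nterm_pk, cterm_pk = pka["Nterm"], pka["Cterm"]
    if terminal_adjustments:
        nterm_pk = PKA_NTERM_BY_RESIDUE.get(sequence[0], nterm_pk)
        cterm_pk = PKA_CTERM_BY_RESIDUE.get(sequence[-1], cterm_pk)

    def pos(pk: float, n: int = 1) -> float:
        return n / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float, n: int = 1) -> float:
        return -n / (1.0 + 10.0 ** (pk - ph))

    charge = pos(nterm_pk) + neg(cterm_pk)
    for aa in BASIC_SIDE_CHAINS:
        n = sequence.count(aa)
        if n:
            charge += pos(pka[aa], n)
    for aa in ACIDIC_SIDE_CHAINS:
        n = sequence.count(aa)
        if n:
            charge += neg(pka[aa], n)
    return charge


def compute_pi(
    sequence: str,
    pka_set: str | Mapping[str, float] = PKA_BJELLQVIST,
    tol: float = 1e-4,
    terminal_adjustments: bool = False,
) -> float:
    """Isoelectric point by bisection on the monotone charge curve.

    Returns the pH in [0, 14] where ``|net_charge| < tol``.  The termini
    are always ionizable, so a zero crossing exists for every sequence.
    """
    pka = _resolve_pka(pka_set)
    lo, hi = 0.0, 14.0
    # charge(lo) > 0 > charge(hi).  Bisect to fixed pH precision rather
    # than stopping at |charge| < tol: in flat stretches of the charge
    # curve an early charge-based stop can sit 0.1 pH away from the true
    # zero crossing.  At 1e-10 pH precision |net_charge| < tol holds for
    # any realistic sequence (the slope at pI is bounded by ~0.6 per
    # ionizable group).
    mid = 7.0
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka, terminal_adjustments) > 0:
            lo = mid
        else:
            hi = mid
    if abs(net_charge(sequence, mid, pka, terminal_adjustments)) >= tol:
        raise ArithmeticError(
            f"bisection converged to pH {mid:.6f} but |net charge| >= {tol}")
    return mid


def scan_phac_box(sequence: str) -> list[MotifHit]:
    """Scan for PhaC-box motifs.

    Both the canonical 6-position pattern ``[GS]xCx[GA]G`` and the
    5-position pattern ``[GS]xCxG`` (which covers the short motif forms
    GYCLG / SYCIG / SYCVG) are reported, overlaps allowed; when a 6-mer
    and a 5-mer start at the same residue only the 6-mer is kept.  The
    catalytic cysteine is always the third motif position.
    """
    if not sequence:
        raise ValueError("empty sequence")
    hits: list[MotifHit] = []
    six_starts: set[int] = set()
    for m in _PHAC_BOX_6.finditer(sequence):
        start = m.start() + 1
        six_starts.add(start)
        hits.append(MotifHit("phac_box_6", start, m.group(1),
                             catalytic_cys_index=start + 2))
    for m in _PHAC_BOX_5.finditer(sequence):
        start = m.start() + 1
        if start in six_starts:
            continue
        hits.append(MotifHit("phac_box_5", start, m.group(1),
                             catalytic_cys_index=start + 2))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def count_aakp(sequence_region: str) -> int:
    """Count (possibly overlapping) exact AAKP tetrapeptide occurrences."""
    return sum(1 for _ in _AAKP.finditer(sequence_region))


def find_aakp(sequence_region: str) -> list[MotifHit]:
    """AAKP occurrences with 1-based start positions."""
    return [MotifHit("aakp", m.start() + 1, "AAKP")
            for m in _AAKP.finditer(sequence_region)]


def segment_profile(
    record: ProteinRecord,
    boundary: int = DEFAULT_BOUNDARY,
    pka_set: str | Mapping[str, float] = PKA_BJELLQVIST,
    classify: bool = True,
) -> SegmentedProfile:
    """Profile a record split at ``boundary`` (1-based residue count).

    The N segment is residues 1..boundary, the C segment boundary+1..end.
    Sequences no longer than the boundary yield a catalytic-only profile
    (``pi_c_segment`` is None, ``cterm_length_aa`` 0).  AAKP motifs are
    counted on the C segment only, since that is where the histone-like
    enrichment is diagnostic.
    """
    if boundary < 1:
        raise ValueError(f"boundary must be >= 1, got {boundary}")
    seq = record.sequence
    length = len(seq)
    n_seg = seq[:boundary]
    c_seg = seq[boundary:]
    profile = SegmentedProfile(
        record_id=record.id,
        length_aa=length,
        boundary=boundary,
        mw_kda=compute_mw(seq),
        pi_full=compute_pi(seq, pka_set),
        pi_n_segment=compute_pi(n_seg, pka_set),
        pi_c_segment=compute_pi(c_seg, pka_set) if c_seg else None,
        cterm_length_aa=max(0, length - boundary),
        phac_box_hits=tuple(scan_phac_box(seq)),
        aakp_count_cterm=count_aakp(c_seg),
    )
    if classify:
        profile = classify_phac(profile)
    return profile


def classify_phac(
    profile: SegmentedProfile,
    phac1_mw_range: tuple[float, float] = (55.0, 80.0),
    phac2_min_mw: float = 90.0,
) -> SegmentedProfile:
    """Assign a size-based variant call to a profile.

    ``phac2_extended`` for PhaC-box-positive proteins at or above 90 kDa
    (the extended-C-terminus class, 93.6–106.4 kDa in known members);
    ``phac1_like`` for box-positive proteins in the ordinary class I
    55–80 kDa range; everything else ``unclassified``.
    """
    has_box = bool(profile.phac_box_hits)
    if has_box and profile.mw_kda >= phac2_min_mw:
        call = "phac2_extended"
    elif has_box and phac1_mw_range[0] <= profile.mw_kda <= phac1_mw_range[1]:
        call = "phac1_like"
    else:
        call = "unclassified"
    return replace(profile, variant_call=call)


def aa_composition(sequence_region: str) -> AaComposition:
    """Residue counts, fractions and grouped fractions for a region.

    Groups: small nonpolar (G,A,V,L,I,P,M,F,W), polar (S,T,C,N,Q,Y,H),
    positively charged K+R, negatively charged D+E; they partition the
    canonical alphabet so group fractions sum to 1.
    """
    _validate_canonical(sequence_region)
    length = len(sequence_region)
    counts = {aa: sequence_region.count(aa)
              for aa in sorted(CANONICAL_RESIDUES)}
    fractions = {aa: n / length for aa, n in counts.items()}
    group_fractions = {
        name: sum(counts[aa] for aa in members) / length
        for name, members in COMPOSITION_GROUPS.items()
    }
    return AaComposition(counts=counts, fractions=fractions,
                         group_fractions=group_fractions, length=length)
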