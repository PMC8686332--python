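"""Physicochemical constants: average residue masses and pKa sets.

All pKa sets live in this one module so an alternate set (EMBOSS, IPC)
can be swapped in without touching the charge model.
"""

from __future__ import annotations

from types import MappingProxyType

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Average residue (amino acid minus water) masses in Da, Expasy-style.
AVERAGE_RESIDUE_MASS_DA = MappingProxyType({
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
})

#: Mass of one water molecule in Da (added once per peptide chain).
WATER_MASS_DA = 18.01524

#: Bjellqvist pKa values as used by the Expasy Compute pI/MW tool.
#: Keys: "Nterm", "Cterm", and the ionizable side chains.
#: Acidic groups (negative when deprotonated): Cterm, D, E, C, Y.
#: Basic groups (positive when protonated): Nterm, H, K, R.
PKA_BJELLQVIST = MappingProxyType({
    "Nterm": 7.5,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
})

#: Residue-specific terminal pKa adjustments from the Bjellqvist data
#: (applied by the Expasy tool when the chain starts/ends with these
#: residues).  Off by default here; enable via ``terminal_adjustments``.
PKA_NTERM_BY_RESIDUE = MappingProxyType({
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
    "T": 6.82, "V": 7.44, "E": 7.7,
})
PKA_CTERM_BY_RESIDUE = MappingProxyType({"D": 4.55, "E": 4.75})

#: EMBOSS iep defaults, provided as an alternate set.
PKA_EMBOSS = MappingProxyType({
    "Nterm": 8.6,
    "Cterm": 3.6,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
})

PKA_SETS = MappingProxyType({
    "bjellqvist": PKA_BJELLQVIST,
    "emboss": PKA_EMBOSS,
})

ACIDIC_SIDE_CHAINS = ("D", "E", "C", "Y")
BASIC_SIDE_CHAINS = ("H", "K", "R")

# Residue groups for composition summaries. The four groups partition the
# 20 canonical residues: charged K/R and D/E are split out because the
# extended PhaC C-terminus is diagnosed by its K+R enrichment; histidine
# (mostly neutral above pH 7) is grouped with the polar residues.
COMPOSITION_GROUPS = MappingProxyType({
    "small_nonpolar": frozenset("GAVLIPMFW"),
    "polar": frozenset("STCNQYH"),
    "positive_kr": frozenset("KR"),
    "negative_de": frozenset("DE"),
})
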