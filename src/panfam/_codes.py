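"""Standard genetic code tables shared by the codon, simulation and Ka/Ks modules.

Everything here is derived once, at import, from Biopython's standard codon
table, so the degeneracy classes, synonymous-site fractions and neighbour
classifications are guaranteed mutually consistent.
"""
from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = ("A", "C", "G", "T")
CODONS = tuple("".join(c) for c in product(NUCLEOTIDES, repeat=3))
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)  # 61
CODON_TO_AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

# Wright's degeneracy classes for the standard code: Ile is the sole 3-fold
# amino acid; Leu/Ser/Arg are 6-fold; Met and Trp are single-codon.
DEGENERACY = {aa: len(codons) for aa, codons in AA_TO_CODONS.items()}
SINGLE_CODON_AAS = frozenset(aa for aa, k in DEGENERACY.items() if k == 1)  # {M, W}
DEGENERATE_SENSE_CODONS = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)  # 59

# Codons scored by CAI / RSCU: all sense codons of degenerate amino acids.
CAI_EXCLUDED = frozenset(c for c in SENSE_CODONS if CODON_TO_AA[c] in SINGLE_CODON_AAS)


def translate_codon(codon: str) -> str | None:
    """Amino-acid letter for a sense codon, None for a stop codon."""
    return CODON_TO_AA.get(codon)


def codon_neighbors(codon: str):
    """All single-nucleotide variants of a codon, with position and new base."""
    out = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            out.append((pos, base, codon[:pos] + base + codon[pos + 1 :]))
    return out


def _syn_site_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of synonymous changes, nonsense changes excluded."""
    aa = CODON_TO_AA[codon]
    fractions = []
    for pos in range(3):
        syn = 0
        valid = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        fractions.append(syn / valid if valid else 0.0)
    return tuple(fractions)


# Nei–Gojobori synonymous site counts per codon: s = sum of per-position
# synonymous fractions, n = 3 - s (nonsense mutations disregarded).
SYN_SITES = {c: sum(_syn_site_fractions(c)) for c in SENSE_CODONS}
NONSYN_SITES = {c: 3.0 - s for c, s in SYN_SITES.items()}

# Non-stop single-nucleotide neighbours of each sense codon, split by effect.
SYN_NEIGHBORS = {
    c: tuple(
        (pos, base, alt)
        for pos, base, alt in codon_neighbors(c)
        if alt not in STOP_CODONS and CODON_TO_AA[alt] == CODON_TO_AA[c]
    )
    for c in SENSE_CODONS
}
NONSYN_NEIGHBORS = {
    c: tuple(
        (pos, base, alt)
        for pos, base, alt in codon_neighbors(c)
        if alt not in STOP_CODONS and CODON_TO_AA[alt] != CODON_TO_AA[c]
    )
    for c in SENSE_CODONS
}
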