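"""Nucleotide-composition and protein-level metrics.

Composition (GC, GC1/2/3, GC3s, silent third-position base frequencies) is
computed from codon counts with the terminal stop excluded, so the identity
``gc == (gc1 + gc2 + gc3) / 3`` holds exactly. Protein metrics (GRAVY,
aromaticity, isoelectric point, molecular weight) use bundled, versioned
constant tables so results are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .codon_core import CodingSequence, CodonCountTable, count_codons, translate
from .errors import EmptyInputError, UndefinedMetricError
from .genetic_code import BASES, GeneticCode, standard_code

# Kyte & Doolittle hydropathy values, one per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")

# Average (isotope-abundance-weighted) residue masses in Da, ExPASy values.
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.0153

# Lehninger-style pKa set used for the isoelectric point; a single published
# table is bundled so pI values are reproducible (different tools ship
# different sets, so absolute pI values are tool-dependent).
PKA_N_TERMINUS = 9.69
PKA_C_TERMINUS = 2.34
PKA_POSITIVE = {"K": 10.53, "R": 12.48, "H": 6.00}
PKA_NEGATIVE = {"D": 3.86, "E": 4.25, "C": 8.33, "Y": 10.07}


@dataclass
class CompositionRecord:
    """Per-gene nucleotide composition over the stop-stripped CDS."""

    gene_id: str
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float
    base_fractions: dict[str, float]


@dataclass
class ProteinRecord:
    gene_id: str
    length_aa: int
    gravy: float
    aromo: float
    pi: float
    mw_kda: float


def _check_protein(protein: str) -> str:
    if not protein:
        raise EmptyInputError("empty protein sequence")
    p = protein.upper()
    bad = set(p) - set(KYTE_DOOLITTLE)
    if bad:
        raise UndefinedMetricError(f"unknown residue symbols: {sorted(bad)}")
    return p


def composition(counts: CodonCountTable, code: GeneticCode | None = None) -> CompositionRecord:
    """Positional GC content and silent third-position base frequencies.

    GC1/GC2/GC3 are computed over *all* sense codons (Met and Trp included)
    so that ``gc = (gc1+gc2+gc3)/3``; GC3s and the X3s frequencies are
    restricted to synonymous codons. Following CodonW semantics, the X3s
    denominator for base x is the number of synonymous codons whose family
    offers at least one x-ending codon (i.e. codons for which ending in x is
    a silent possibility), not the plain count of synonymous codons.
    """
    code = code or standard_code()
    if counts.n_codons < 1:
        raise UndefinedMetricError(f"{counts.gene_id}: no codons")

    pos_gc = [0, 0, 0]
    base_totals = {b: 0 for b in BASES}
    n_sense = 0
    for codon, n in counts.counts.items():
        if code.codon_to_aa[codon] == "*":
            continue  # internal stops (lenient data) carry no composition meaning here
        n_sense += n
        for i, b in enumerate(codon):
            base_totals[b] += n
            if b in "GC":
                pos_gc[i] += n
    if n_sense == 0:
        raise UndefinedMetricError(f"{counts.gene_id}: no sense codons")

    gc1, gc2, gc3 = (g / n_sense for g in pos_gc)
    gc = (gc1 + gc2 + gc3) / 3

    syn = set(code.synonymous_codons)
    syn_total = 0
    syn_gc3 = 0
    x3_num = {b: 0 for b in BASES}
    x3_den = {b: 0 for b in BASES}
    family_offers = {
        aa: {c[2] for c in fam} for aa, fam in code.degenerate_families.items()
    }
    for codon, n in counts.counts.items():
        if codon not in syn:
            continue
        syn_total += n
        third = codon[2]
        if third in "GC":
            syn_gc3 += n
        x3_num[third] += n
        offered = family_offers[code.codon_to_aa[codon]]
        for b in offered:
            x3_den[b] += n

    if syn_total == 0:
        raise UndefinedMetricError(f"{counts.gene_id}: no synonymous codons for GC3s")

    def _x3s(b: str) -> float:
        return x3_num[b] / x3_den[b] if x3_den[b] else 0.0

    return CompositionRecord(
        gene_id=counts.gene_id,
        gc=gc, gc1=gc1, gc2=gc2, gc3=gc3,
        gc12=(gc1 + gc2) / 2,
        gc3s=syn_gc3 / syn_total,
        a3s=_x3s("A"), t3s=_x3s("T"), g3s=_x3s("G"), c3s=_x3s("C"),
        base_fractions={b: base_totals[b] / (3 * n_sense) for b in BASES},
    )


def gravy(protein: str) -> float:
    """Grand average of hydropathy (Kyte-Doolittle); negative = hydrophilic."""
    p = _check_protein(protein)
    return sum(KYTE_DOOLITTLE[r] for r in p) / len(p)


def aromo(protein: str) -> float:
    """Aromaticity: fraction of Phe + Tyr + Trp residues."""
    p = _check_protein(protein)
    return sum(r in AROMATIC for r in p) / len(p)


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    p = _check_protein(protein)
    positive = 1.0 / (1.0 + 10 ** (ph - PKA_N_TERMINUS))
    negative = 1.0 / (1.0 + 10 ** (PKA_C_TERMINUS - ph))
    for r in p:
        if r in PKA_POSITIVE:
            positive += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[r]))
        elif r in PKA_NEGATIVE:
            negative += 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[r] - ph))
    return positive - negative


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The net-charge function is strictly decreasing in pH (every group only
    deprotonates), so the root exists and is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def molecular_weight(protein: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    p = _check_protein(protein)
    return (sum(RESIDUE_MASS_DA[r] for r in p) + WATER_MASS_DA) / 1000.0


def protein_record(cds: CodingSequence, code: GeneticCode | None = None) -> ProteinRecord:
    """All protein-level metrics for one CDS."""
    prot = translate(cds, code=code)
    return ProteinRecord(
        gene_id=cds.gene_id,
        length_aa=len(prot),
        gravy=gravy(prot),
        aromo=aromo(prot),
        pi=isoelectric_point(prot),
        mw_kda=molecular_weight(prot),
    )


def length_summary(cds_set: Sequence[CodingSequence]) -> dict[str, int]:
    """Extremes of CDS and protein length over a gene set.

    ``max_difference_nt`` is the spread of CDS lengths; protein lengths
    exclude the terminal stop.
    """
    if not cds_set:
        raise EmptyInputError("length_summary requires at least one CDS")
    nt = [len(c) for c in cds_set]
    aa = [len(translate(c, mode="lenient")) for c in cds_set]
    return {
        "min_nt": min(nt),
        "max_nt": max(nt),
        "max_difference_nt": max(nt) - min(nt),
        "min_aa": min(aa),
        "max_aa": max(aa),
    }
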