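"""Standard genetic code: codon tables, synonymous families, degeneracy classes.

All codons are DNA-alphabet, uppercase, in fixed lexicographic order
(AAA ... TTT) so that every vector and file output is reproducible.
RNA-style codon names (with U) are accepted anywhere a codon is passed in.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

from Bio.Data import CodonTable as _BioCodonTable

BASES = "ACGT"
#: The 64 trinucleotides in lexicographic order — the canonical indexing
#: order for every codon vector in the package.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

STOP_SYMBOL = "*"


def normalize_codon(codon: str) -> str:
    """Uppercase a codon and map RNA U to DNA T (``'uac'`` -> ``'TAC'``)."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in BASES for b in c):
        raise ValueError(f"not a codon: {codon!r}")
    return c


def to_rna(codon: str) -> str:
    """Render a DNA codon in the RNA alphabet (``'TAC'`` -> ``'UAC'``)."""
    return codon.upper().replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid mapping plus its synonymous-family structure.

    Attributes
    ----------
    table_id:
        NCBI translation-table identifier (only table 1 is shipped).
    codon_to_aa:
        Maps each of the 64 codons to a one-letter amino acid or ``'*'``.
    families:
        Partition of the sense codons into synonymous families, keyed by
        amino acid; codons within each family are sorted lexicographically.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]
    stop_codons: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        stops = frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP_SYMBOL)
        object.__setattr__(self, "stop_codons", stops)

    # -- structural views -------------------------------------------------
    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP_SYMBOL)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.families))

    def degeneracy(self, aa: str) -> int:
        return len(self.families[aa])

    @property
    def degenerate_families(self) -> Mapping[str, tuple[str, ...]]:
        """Families with at least two synonymous codons (18 amino acids)."""
        return {aa: cods for aa, cods in self.families.items() if len(cods) >= 2}

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """Sense codons belonging to a family of size >= 2 (59 codons)."""
        return tuple(
            c for c in CODONS
            if self.codon_to_aa[c] != STOP_SYMBOL
            and len(self.families[self.codon_to_aa[c]]) >= 2
        )

    @property
    def informative_codons(self) -> tuple[str, ...]:
        """The 59 codons carrying synonymous-usage information.

        Stops and the single-codon families (ATG/Met, TGG/Trp) are excluded;
        these are the coordinates of every RSCU vector.
        """
        return self.synonymous_codons

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def degeneracy_class_census(self) -> dict[int, int]:
        """Number of families per degeneracy class, e.g. ``{1: 2, 2: 9, ...}``."""
        census: dict[int, int] = {}
        for cods in self.families.values():
            census[len(cods)] = census.get(len(cods), 0) + 1
        return census

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]


@lru_cache(maxsize=None)
def standard_code(table_id: int = 1) -> GeneticCode:
    """Return the standard genetic code (NCBI table 1).

    A ``table_id`` parameter is reserved for alternative codes, but only the
    standard code is shipped; anything else raises ``NotImplementedError``.
    """
    if table_id != 1:
        raise NotImplementedError("only the standard genetic code (table 1) is available")
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = {c: bio.forward_table.get(c, STOP_SYMBOL) for c in CODONS}
    families: dict[str, tuple[str, ...]] = {}
    for codon in CODONS:
        aa = codon_to_aa[codon]
        if aa == STOP_SYMBOL:
            continue
        families.setdefault(aa, ())
        families[aa] = tuple(sorted(families[aa] + (codon,)))
    return GeneticCode(table_id=table_id, codon_to_aa=codon_to_aa, families=families)
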