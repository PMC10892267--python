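"""CDS ingestion, validation, codon counting and pooling.

This is the substrate layer: every downstream index consumes the
:class:`CodonCountTable` produced here. Sequences are uppercased on read,
RNA input (U) is mapped to T, and the fixed lexicographic codon order of
:mod:`cubkit.genetic_code` governs every emitted vector.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .errors import EmptyInputError, PrematureStopError, ValidationError
from .genetic_code import BASES, CODONS, GeneticCode, standard_code

log = logging.getLogger(__name__)

Validation = Literal["strict", "lenient"]


@dataclass
class CodingSequence:
    """A protein-coding nucleotide sequence (ATG ... stop, length % 3 == 0)."""

    gene_id: str
    nucleotides: str
    species: str | None = None
    valid_start: bool = True
    valid_stop: bool = True

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper().replace("U", "T")
        if len(seq) == 0:
            raise ValidationError(f"{self.gene_id}: empty sequence")
        if len(seq) % 3 != 0:
            raise ValidationError(f"{self.gene_id}: length {len(seq)} not divisible by 3")
        bad = set(seq) - set(BASES)
        if bad:
            raise ValidationError(f"{self.gene_id}: non-ACGT characters {sorted(bad)}")
        self.nucleotides = seq
        self.valid_start = seq[:3] == "ATG"
        self.valid_stop = seq[-3:] in ("TAA", "TAG", "TGA")

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i:i + 3] for i in range(0, len(s), 3)]

    @property
    def is_canonical(self) -> bool:
        return self.valid_start and self.valid_stop


@dataclass
class CodonCountTable:
    """Occurrence counts of the 64 codons for one gene (or a labelled pool)."""

    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for codon, n in self.counts.items():
            c = codon.upper().replace("U", "T")
            if c not in CODONS:
                raise ValidationError(f"unknown codon {codon!r}")
            if n < 0:
                raise ValidationError(f"negative count for {codon}")
            if n:
                clean[c] = clean.get(c, 0) + int(n)
        self.counts = clean

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon.upper().replace("U", "T"), 0)

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> list[int]:
        """Counts in fixed lexicographic order (AAA ... TTT)."""
        return [self.counts.get(c, 0) for c in CODONS]

    def family_total(self, family: Iterable[str]) -> int:
        return sum(self.counts.get(c, 0) for c in family)


def read_cds_fasta(
    path: str | Path,
    validation: Validation = "strict",
    species: str | None = None,
) -> list[CodingSequence]:
    """Read coding sequences from a (optionally gzipped) FASTA file.

    Records whose length is not a multiple of 3 or that contain non-ACGT
    characters (including ambiguity codes) are always rejected, with the
    reason logged. In ``strict`` mode records lacking an ATG start or a
    canonical stop are rejected too; in ``lenient`` mode they are kept and
    flagged (``valid_start`` / ``valid_stop``).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, str(rec.seq)))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")

    out: list[CodingSequence] = []
    for gene_id, seq in records:
        try:
            cds = CodingSequence(gene_id=gene_id, nucleotides=seq, species=species)
        except ValidationError as exc:
            log.warning("rejected %s: %s", gene_id, exc)
            continue
        if validation == "strict" and not cds.is_canonical:
            log.warning(
                "rejected %s: start=%s stop=%s (strict mode)",
                gene_id, cds.nucleotides[:3], cds.nucleotides[-3:],
            )
            continue
        out.append(cds)
    return out


def count_codons(
    cds: CodingSequence,
    include_stop: bool = False,
    code: GeneticCode | None = None,
) -> CodonCountTable:
    """Tally consecutive non-overlapping codons of a CDS.

    With ``include_stop=False`` (default) the *terminal* codon is dropped
    when it is a stop, so ``n_codons`` matches the protein length for a
    canonical CDS.
    """
    code = code or standard_code()
    codons = cds.codons
    if not include_stop and codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    return CodonCountTable(gene_id=cds.gene_id, counts=counts)


def translate(
    cds: CodingSequence,
    mode: Validation = "strict",
    code: GeneticCode | None = None,
) -> str:
    """Standard-code translation, excluding the terminal stop.

    An internal stop raises :class:`PrematureStopError` in strict mode; in
    lenient mode translation is truncated there with a logged warning.
    """
    code = code or standard_code()
    codons = cds.codons
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    residues: list[str] = []
    for i, c in enumerate(codons):
        aa = code.codon_to_aa[c]
        if aa == "*":
            if mode == "strict":
                raise PrematureStopError(f"{cds.gene_id}: internal stop {c} at codon {i + 1}")
            log.warning("%s: truncating at internal stop %s (codon %d)", cds.gene_id, c, i + 1)
            break
        residues.append(aa)
    return "".join(residues)


def pool_counts(tables: Iterable[CodonCountTable], label: str) -> CodonCountTable:
    """Element-wise sum of count tables, e.g. a species 'super-gene' pool."""
    tables = list(tables)
    if not tables:
        raise EmptyInputError("pool_counts requires at least one table")
    merged: dict[str, int] = {}
    for t in tables:
        for codon, n in t.counts.items():
            merged[codon] = merged.get(codon, 0) + n
    return CodonCountTable(gene_id=label, counts=merged)
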