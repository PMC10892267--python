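"""Codon usage bias indices: RSCU, Wright's ENc, CAI, CBI and Fop.

ENc (effective number of codons) is the paper-facing centrepiece: it runs
from 20 (one codon per degenerate amino acid, maximal bias) to 61 (all
synonymous codons used equally, no bias), with 35 the conventional
strong-bias threshold. CAI/CBI/Fop measure adaptation to a reference set of
preferred codons; because the reference organism behind published absolute
values is usually unstated, the default reference here is self-derived from
the most biased genes of the dataset itself (the low-ENc pool).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .codon_core import CodingSequence, CodonCountTable, count_codons, pool_counts
from .errors import EncUndefinedError, UndefinedMetricError
from .genetic_code import GeneticCode, normalize_codon, standard_code
from .seq_metrics import CompositionRecord, ProteinRecord, composition, protein_record

#: Value ENc is capped at (uniform-usage upper extreme).
ENC_MAX = 61.0

MISSING = float("nan")


@dataclass
class RSCUVector:
    """Relative synonymous codon usage over the 59 informative codons.

    ``values[c]`` is observed(c) / expected-under-uniform-family-usage; a
    family never observed in the gene is marked ``NaN`` (missing), never 0.
    """

    gene_id: str
    values: dict[str, float]
    observed_aa: frozenset[str]

    def __getitem__(self, codon: str) -> float:
        return self.values[normalize_codon(codon)]


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> RSCUVector:
    """RSCU(c) = observed(c) / (family_total / family_size), per family."""
    code = code or standard_code()
    if counts.n_codons < 1:
        raise UndefinedMetricError(f"{counts.gene_id}: no codons")
    values: dict[str, float] = {}
    observed: set[str] = set()
    for aa, family in code.degenerate_families.items():
        total = counts.family_total(family)
        if total == 0:
            for c in family:
                values[c] = MISSING
            continue
        observed.add(aa)
        expected = total / len(family)
        for c in family:
            values[c] = counts[c] / expected
    return RSCUVector(gene_id=counts.gene_id, values=values, observed_aa=frozenset(observed))


def enc(counts: CodonCountTable, code: GeneticCode | None = None, cap: float = ENC_MAX) -> float:
    """Wright's effective number of codons.

    Per degenerate family with n >= 2 observations the codon homozygosity is
    estimated as F = (n * sum(p_i^2) - 1) / (n - 1); families are averaged
    within their degeneracy class k in {2, 3, 4, 6} and
    ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at 61.

    Families with n < 2 or with F == 0 (no usage information; the estimator
    would diverge) are excluded from class means. If the single 3-fold
    family (Ile) is unobserved, F3 is imputed as (F2 + F4) / 2; a missing
    2-, 4- or 6-fold class makes ENc undefined.
    """
    code = code or standard_code()
    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.degenerate_families.items():
        n = counts.family_total(family)
        if n < 2:
            continue
        sum_p2 = sum((counts[c] / n) ** 2 for c in family)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        if f <= 0.0:
            continue
        class_F[len(family)].append(f)

    means: dict[int, float] = {}
    for k, fs in class_F.items():
        if fs:
            means[k] = sum(fs) / len(fs)
    if 2 not in means or 4 not in means or 6 not in means:
        raise EncUndefinedError(
            f"{counts.gene_id}: insufficient codon usage to estimate ENc "
            f"(classes observed: {sorted(means)})"
        )
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2.0

    value = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(value, cap)


@dataclass
class ReferenceWeights:
    """Relative adaptiveness w in (0, 1] per codon, for CAI/CBI/Fop.

    ``optimal_set`` designates exactly one codon per degenerate family (the
    lexicographically smallest among those with maximal usage, so ties are
    deterministic).
    """

    label: str
    w: dict[str, float]
    optimal_set: frozenset[str]

    #: Weight assigned to codons absent from the reference pool (CodonW's
    #: convention: rare but never impossible).
    RARE_WEIGHT = 0.01

    @classmethod
    def from_counts(
        cls,
        reference: CodonCountTable,
        label: str | None = None,
        code: GeneticCode | None = None,
    ) -> "ReferenceWeights":
        """Derive weights from a reference pool: w = count / max family count."""
        code = code or standard_code()
        w: dict[str, float] = {}
        optimal: set[str] = set()
        for aa, family in code.degenerate_families.items():
            best = max(reference[c] for c in family)
            if best == 0:
                # family absent from the reference: uninformative, all rare
                for c in family:
                    w[c] = cls.RARE_WEIGHT
                optimal.add(family[0])
                continue
            for c in family:
                w[c] = reference[c] / best if reference[c] > 0 else cls.RARE_WEIGHT
            optimal.add(min(c for c in family if reference[c] == best))
        return cls(label=label or reference.gene_id, w=w, optimal_set=frozenset(optimal))

    @classmethod
    def read_tsv(cls, path: str | Path, code: GeneticCode | None = None) -> "ReferenceWeights":
        code = code or standard_code()
        df = pd.read_csv(path, sep="\t", comment="#", names=["codon", "w"], header=None)
        w = {normalize_codon(c): float(v) for c, v in zip(df["codon"], df["w"])}
        optimal: set[str] = set()
        for family in code.degenerate_families.values():
            best = max(w.get(c, 0.0) for c in family)
            optimal.add(min(c for c in family if w.get(c, 0.0) == best))
        return cls(label=str(path), w=w, optimal_set=frozenset(optimal))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# reference weights: {self.label}\n")
            for codon in sorted(self.w):
                fh.write(f"{codon}\t{self.w[codon]:.6g}\n")


def cai(counts: CodonCountTable, ref: ReferenceWeights, code: GeneticCode | None = None) -> float:
    """Codon adaptation index (Sharp & Li): geometric mean of w over the
    codons of degenerate families (Met, Trp and stops excluded)."""
    code = code or standard_code()
    log_sum = 0.0
    n = 0
    for codon in code.synonymous_codons:
        c = counts[codon]
        if c == 0:
            continue
        if codon not in ref.w:
            raise UndefinedMetricError(f"reference weights missing codon {codon}")
        log_sum += c * math.log(ref.w[codon])
        n += c
    if n == 0:
        raise UndefinedMetricError(f"{counts.gene_id}: no synonymous codons for CAI")
    return math.exp(log_sum / n)


def fop(counts: CodonCountTable, ref: ReferenceWeights, code: GeneticCode | None = None) -> float:
    """Frequency of optimal codons among synonymous codons."""
    code = code or standard_code()
    n_syn = sum(counts[c] for c in code.synonymous_codons)
    if n_syn == 0:
        raise UndefinedMetricError(f"{counts.gene_id}: no synonymous codons for Fop")
    n_opt = sum(counts[c] for c in ref.optimal_set)
    return n_opt / n_syn


def cbi(counts: CodonCountTable, ref: ReferenceWeights, code: GeneticCode | None = None) -> float:
    """Codon bias index (Bennetzen & Hall).

    (N_opt - N_rand) / (N_tot - N_rand), with N_rand the optimal-codon count
    expected under uniform within-family usage; 0 = random usage, 1 = only
    optimal codons, negative = optimal codons avoided.
    """
    code = code or standard_code()
    n_tot = 0
    n_opt = 0
    n_rand = 0.0
    for aa, family in code.degenerate_families.items():
        fam_total = counts.family_total(family)
        if fam_total == 0:
            continue
        n_tot += fam_total
        n_opt += sum(counts[c] for c in family if c in ref.optimal_set)
        n_opt_codons = sum(c in ref.optimal_set for c in family)
        n_rand += fam_total * n_opt_codons / len(family)
    if n_tot == 0 or math.isclose(n_tot, n_rand):
        return MISSING
    return (n_opt - n_rand) / (n_tot - n_rand)


def high_frequency_codons(vec: RSCUVector) -> frozenset[str]:
    """Codons used more than expected under no bias (RSCU strictly > 1)."""
    return frozenset(c for c, v in vec.values.items() if not math.isnan(v) and v > 1.0)


# ---------------------------------------------------------------------------
# Per-gene profile assembly
# ---------------------------------------------------------------------------

@dataclass
class CUBProfile:
    """Every per-gene quantity the analyses downstream consume."""

    gene_id: str
    species: str | None
    enc: float
    cai: float
    cbi: float
    fop: float
    composition: CompositionRecord
    protein: ProteinRecord
    length_nt: int

    def to_row(self) -> dict[str, object]:
        c, p = self.composition, self.protein
        return {
            "gene_id": self.gene_id,
            "species": self.species,
            "enc": self.enc, "cai": self.cai, "cbi": self.cbi, "fop": self.fop,
            "gc": c.gc, "gc1": c.gc1, "gc2": c.gc2, "gc3": c.gc3,
            "gc12": c.gc12, "gc3s": c.gc3s,
            "a3s": c.a3s, "t3s": c.t3s, "g3s": c.g3s, "c3s": c.c3s,
            "gravy": p.gravy, "aromo": p.aromo, "pi": p.pi, "mw_kda": p.mw_kda,
            "l_nt": self.length_nt, "l_aa": p.length_aa,
        }


def default_reference(
    counts_by_gene: Mapping[str, CodonCountTable],
    enc_by_gene: Mapping[str, float],
    k: int = 5,
    code: GeneticCode | None = None,
) -> ReferenceWeights:
    """Self-derived reference: pool of the k lowest-ENc (most biased) genes."""
    defined = [g for g in enc_by_gene if not math.isnan(enc_by_gene[g])]
    if defined:
        ranked = sorted(defined, key=lambda g: (enc_by_gene[g], g))
        members = ranked[: min(k, len(ranked))]
        label = f"self:bottom-{len(members)}-ENc"
    else:
        # no gene has a defined ENc (tiny inputs): pool everything
        members = sorted(counts_by_gene)
        label = "self:all-genes"
    pool = pool_counts([counts_by_gene[g] for g in members], label="low-ENc pool")
    return ReferenceWeights.from_counts(pool, label=label, code=code)


def compute_profiles(
    cds_list: list[CodingSequence],
    reference: ReferenceWeights | None = None,
    k_reference: int = 5,
    code: GeneticCode | None = None,
) -> tuple[list[CUBProfile], ReferenceWeights]:
    """Compute a :class:`CUBProfile` for every gene.

    When ``reference`` is None the CAI/CBI/Fop reference weights are derived
    from the dataset's own bottom-``k_reference`` ENc genes. Genes whose ENc
    is undefined (too little synonymous usage) keep their profile with
    ``enc = NaN``; ENc-dependent analyses drop them.
    """
    code = code or standard_code()
    counts_by_gene = {c.gene_id: count_codons(c, code=code) for c in cds_list}
    enc_by_gene: dict[str, float] = {}
    for gid, tab in counts_by_gene.items():
        try:
            enc_by_gene[gid] = enc(tab, code=code)
        except EncUndefinedError:
            enc_by_gene[gid] = MISSING
    if reference is None:
        reference = default_reference(counts_by_gene, enc_by_gene, k=k_reference, code=code)

    profiles: list[CUBProfile] = []
    for cds in cds_list:
        gid = cds.gene_id
        tab = counts_by_gene[gid]
        profiles.append(CUBProfile(
            gene_id=gid,
            species=cds.species,
            enc=enc_by_gene[gid],
            cai=cai(tab, reference, code=code),
            cbi=cbi(tab, reference, code=code),
            fop=fop(tab, reference, code=code),
            composition=composition(tab, code=code),
            protein=protein_record(cds, code=code),
            length_nt=len(cds),
        ))
    return profiles, reference


def profile_frame(profiles: list[CUBProfile]) -> pd.DataFrame:
    """Tabulate profiles as a DataFrame indexed by gene_id."""
    df = pd.DataFrame([p.to_row() for p in profiles])
    return df.set_index("gene_id")
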