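"""Synthetic CDS sets with controllable codon bias, drift and expression.

The generator emulates the statistical structure of a small heat-shock
(HSP20-like) gene family in AT-rich dicot genomes, so that every pipeline
stage is testable without downloads: CDS lengths in 393-1116 nt, per-gene
selection strength with subfamily-specific preferred codons, an optional
GC drift term (third positions only, or all positions for a mutation-like
regime), and expression levels that rise with bias strength so that FPKM
correlates negatively with ENc.

Model per gene g:

* bias strength s_g = s0 + Uniform(0, S), where the baseline s0 is the
  genome-wide preference floor shared by every gene (real genomes keep
  preferred codons at RSCU > 1 even in weakly expressed genes, which is
  what makes the "RSCU > 1 in both pools" optimal-codon criterion workable);
* codon choice within a synonymous family is softmax-weighted by
  ``s_g * 1[c is the preferred codon]  +  gamma_g * nGC(c)`` where nGC
  counts G/C at the third position (``third_position_only``) or over the
  whole codon (``all_positions``, which also shifts amino-acid usage and
  hence GC12);
* log FPKM = a + b * s_g + condition offset + Normal(0, sigma).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_core import CodingSequence
from .genetic_code import GeneticCode, standard_code

DriftScope = Literal["third_position_only", "all_positions"]

#: Average amino-acid composition of proteins (UniProtKB-style frequencies).
DEFAULT_AA_FREQ: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

DEFAULT_CONDITIONS: dict[str, float] = {"normal": 0.0, "salinity": 0.2, "drought": 0.4}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic gene-family generator; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 140
    length_range: tuple[int, int] = (393, 1116)   # nt incl. start + stop, % 3 == 0
    n_species: int = 4
    n_subfamilies: int = 12
    bias_strength_max: float = 3.0                # S in s_g ~ baseline + U(0, S)
    bias_baseline: float = 0.5                    # genome-wide bias floor shared by all genes
    gamma: float = -0.2                           # global GC(3) drift (negative = AT-rich)
    gamma_gene_range: float = 0.0                 # per-gene drift amplitude around gamma
    drift_scope: DriftScope = "third_position_only"
    subfamily_divergence: float = 0.3             # P(subfamily re-draws a family's preference)
    preferred_codons: Mapping[str, str] | None = None   # aa -> codon base map (else drawn)
    aa_freq: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_FREQ))
    expression_intercept: float = 3.0             # a
    expression_slope: float = 0.8                 # b (per unit s_g)
    expression_sigma: float = 0.6
    conditions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CONDITIONS))

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything one generator run produced."""

    cds: list[CodingSequence]
    expression: pd.DataFrame            # genes x conditions, FPKM
    metadata: pd.DataFrame              # gene_id -> species, subfamily
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA / expression TSV / metadata TSV / truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genes.fasta",
            "expression": outdir / "expression.tsv",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["fasta"], "w") as fh:
            for c in self.cds:
                fh.write(f">{c.gene_id}\n")
                for i in range(0, len(c.nucleotides), 60):
                    fh.write(c.nucleotides[i:i + 60] + "\n")
        long = self.expression.reset_index().melt(
            id_vars="gene_id", var_name="condition", value_name="fpkm"
        )
        long.to_csv(paths["expression"], sep="\t", index=False)
        self.metadata.to_csv(paths["metadata"], sep="\t")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)
        return paths


def _draw_preferred(rng: np.random.Generator, code: GeneticCode) -> dict[str, str]:
    return {
        aa: fam[rng.integers(0, len(fam))]
        for aa, fam in code.degenerate_families.items()
    }


def _codon_weight(codon: str, preferred: str, s: float, gamma: float, scope: DriftScope) -> float:
    ngc = sum(b in "GC" for b in codon) if scope == "all_positions" else (codon[2] in "GC")
    return float(np.exp(s * (codon == preferred) + gamma * ngc))


def generate_cds_set(cfg: GeneratorConfig, code: GeneticCode | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset under one configuration.

    Same config (hence same seed) always yields byte-identical output.
    """
    code = code or standard_code()
    rng = np.random.default_rng(cfg.seed)
    aas = sorted(cfg.aa_freq)
    freqs = np.array([cfg.aa_freq[a] for a in aas], dtype=float)
    freqs = freqs / freqs.sum()

    base_pref = dict(cfg.preferred_codons) if cfg.preferred_codons else _draw_preferred(rng, code)
    for aa in code.degenerate_families:
        if aa not in base_pref:
            raise ValueError(f"preferred-codon map lacks family {aa}")
    subfam_pref: dict[int, dict[str, str]] = {}
    for sf in range(cfg.n_subfamilies):
        pref = dict(base_pref)
        for aa, fam in code.degenerate_families.items():
            if rng.random() < cfg.subfamily_divergence:
                pref[aa] = fam[rng.integers(0, len(fam))]
        subfam_pref[sf] = pref

    lo, hi = cfg.length_range
    n_lengths = (hi - lo) // 3 + 1
    sense = list(code.sense_codons)

    genes: list[CodingSequence] = []
    meta_rows = []
    s_values = np.empty(cfg.n_genes)
    gamma_values = np.empty(cfg.n_genes)
    width = len(str(cfg.n_genes))
    for g in range(cfg.n_genes):
        gene_id = f"g{g + 1:0{width}d}"
        species = f"species_{rng.integers(0, cfg.n_species) + 1}"
        subfam = int(rng.integers(0, cfg.n_subfamilies))
        s_g = cfg.bias_baseline + rng.uniform(0.0, cfg.bias_strength_max)
        gamma_g = cfg.gamma + (
            rng.uniform(-cfg.gamma_gene_range, cfg.gamma_gene_range)
            if cfg.gamma_gene_range else 0.0
        )
        length = lo + 3 * int(rng.integers(0, n_lengths))
        n_interior = length // 3 - 2
        pref = subfam_pref[subfam]

        if cfg.drift_scope == "all_positions":
            # joint codon draw: amino-acid frequency x within-family weight
            w = np.array([
                cfg.aa_freq[code.codon_to_aa[c]]
                / len(code.families[code.codon_to_aa[c]])
                * _codon_weight(c, pref.get(code.codon_to_aa[c], ""), s_g, gamma_g,
                                "all_positions")
                for c in sense
            ])
            w = w / w.sum()
            interior = [sense[i] for i in rng.choice(len(sense), size=n_interior, p=w)]
        else:
            aa_draw = rng.choice(len(aas), size=n_interior, p=freqs)
            interior = []
            for ai in aa_draw:
                fam = code.families[aas[ai]]
                if len(fam) == 1:
                    interior.append(fam[0])
                    continue
                w = np.array([
                    _codon_weight(c, pref[aas[ai]], s_g, gamma_g, "third_position_only")
                    for c in fam
                ])
                interior.append(fam[rng.choice(len(fam), p=w / w.sum())])

        seq = "ATG" + "".join(interior) + "TGA"
        genes.append(CodingSequence(gene_id=gene_id, nucleotides=seq, species=species))
        meta_rows.append({"gene_id": gene_id, "species": species, "subfamily": f"sf{subfam + 1}"})
        s_values[g] = s_g
        gamma_values[g] = gamma_g

    conditions = dict(cfg.conditions)
    expr = {}
    for cond, offset in conditions.items():
        noise = rng.normal(0.0, cfg.expression_sigma, size=cfg.n_genes)
        expr[cond] = np.exp(cfg.expression_intercept + cfg.expression_slope * s_values
                            + offset + noise)
    expression = pd.DataFrame(expr, index=[g.gene_id for g in genes])
    expression.index.name = "gene_id"
    metadata = pd.DataFrame(meta_rows).set_index("gene_id")

    truth = {
        "config": asdict(cfg),
        "base_preferred_codons": base_pref,
        "subfamily_preferred_codons": {f"sf{k + 1}": v for k, v in subfam_pref.items()},
        "s_g": {g.gene_id: float(s) for g, s in zip(genes, s_values)},
        "gamma_g": {g.gene_id: float(v) for g, v in zip(genes, gamma_values)},
    }
    return SyntheticDataset(cds=genes, expression=expression, metadata=metadata, truth=truth)


def generate_regime(
    cfg: GeneratorConfig,
    regime: Literal["mutation", "selection"],
) -> SyntheticDataset:
    """Generate a dataset under a mutation- or selection-dominated regime.

    ``mutation``: no preferred-codon selection (S = 0); a wide per-gene GC
    drift applied to all codon positions makes GC12 and GC3 co-vary, so the
    neutrality slope is high. ``selection``: per-gene preferred-codon bias at
    third positions only, no shared drift, so GC3 varies while GC12 does
    not and the slope is near zero.
    """
    from dataclasses import replace

    if regime == "mutation":
        cfg = replace(cfg, bias_strength_max=0.0, bias_baseline=0.0,
                      drift_scope="all_positions", gamma=0.0, gamma_gene_range=0.8)
    elif regime == "selection":
        cfg = replace(cfg, drift_scope="third_position_only",
                      gamma_gene_range=0.0)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    ds = generate_cds_set(cfg)
    ds.truth["regime"] = regime
    return ds


# ---------------------------------------------------------------------------
# Deterministic worked fixtures (published summary values for small tests)
# ---------------------------------------------------------------------------

#: Per-species optimal-codon sets as published for the four cruciferous
#: species (DNA alphabet). The sharing pattern and per-species counts
#: (6/6/3/1, union of 12) are as printed; assignment of the eight
#: species-unique codons to species is not fully printed and is fixed here
#: deterministically. TGA (a stop) appears verbatim in the published list.
PUBLISHED_OPTIMAL_SETS: dict[str, frozenset[str]] = {
    "A_thaliana": frozenset({"AAC", "GGT", "GCT", "CCA", "GAA", "TCT"}),
    "C_sativa": frozenset({"AAC", "GGT", "AGA", "GAG", "GTG", "AGG"}),
    "B_rapa": frozenset({"TAC", "AGA", "TGA"}),
    "B_napus": frozenset({"TAC"}),
}


@dataclass
class WorkedFixtures:
    """Small deterministic inputs mirroring published summary numbers."""

    cds_min: CodingSequence          # 393 nt -> 130-aa protein
    cds_max: CodingSequence          # 1116 nt -> 371-aa protein
    enc_values: np.ndarray           # 140 ENc values, 94 of them in [50, 61]
    optimal_sets: dict[str, frozenset[str]]


def _fixture_cds(rng: np.random.Generator, gene_id: str, length: int,
                 code: GeneticCode) -> CodingSequence:
    aas = sorted(DEFAULT_AA_FREQ)
    p = np.array([DEFAULT_AA_FREQ[a] for a in aas])
    p = p / p.sum()
    n_interior = length // 3 - 2
    interior = []
    for ai in rng.choice(len(aas), size=n_interior, p=p):
        fam = code.families[aas[ai]]
        interior.append(fam[rng.integers(0, len(fam))])
    return CodingSequence(gene_id=gene_id, nucleotides="ATG" + "".join(interior) + "TGA")


def paper_worked_fixtures(code: GeneticCode | None = None) -> WorkedFixtures:
    """Fixtures reproducing published worked numbers deterministically:

    * one 393-nt and one 1116-nt valid CDS (length spread 723 nt, proteins
      of 130 and 371 residues);
    * a 140-gene ENc vector with exactly 94 values in the weak-bias band
      [50, 61] and none at or below 35;
    * the four per-species optimal-codon sets whose union has 12 codons
      with third-base tally A:4, T:3, G:3, C:2.
    """
    code = code or standard_code()
    rng = np.random.default_rng(20240206)
    cds_min = _fixture_cds(rng, "fix_min", 393, code)
    cds_max = _fixture_cds(rng, "fix_max", 1116, code)
    enc_values = np.concatenate([
        np.round(np.linspace(50.5, 61.0, 94), 3),
        np.round(np.linspace(37.9, 49.5, 46), 3),
    ])
    return WorkedFixtures(
        cds_min=cds_min,
        cds_max=cds_max,
        enc_values=enc_values,
        optimal_sets=dict(PUBLISHED_OPTIMAL_SETS),
    )
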