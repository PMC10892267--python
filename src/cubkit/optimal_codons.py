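"""Optimal-codon determination via the two-criterion delta-RSCU procedure.

Because ENc tracks expression in highly expressed genes, the most biased
(lowest-ENc) genes stand in for a high-expression set and the least biased
for a low-expression set. A codon is *optimal* when its RSCU exceeds 1 in
both pools and the high-pool RSCU exceeds the low-pool RSCU by at least a
threshold (0.08 by default).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .codon_core import CodonCountTable, pool_counts
from .cub_indices import rscu
from .errors import EmptyInputError
from .genetic_code import GeneticCode, normalize_codon, standard_code

DELTA_RSCU_THRESHOLD = 0.08


@dataclass
class ExpressionDatabases:
    """ENc-extreme gene pools standing in for expression classes."""

    high_pool: CodonCountTable   # bottom-k ENc (most biased) genes
    low_pool: CodonCountTable    # top-k ENc (least biased) genes
    k: int
    high_members: tuple[str, ...]
    low_members: tuple[str, ...]


def build_databases(
    enc_by_gene: Mapping[str, float],
    counts_by_gene: Mapping[str, CodonCountTable],
    k: int = 5,
) -> ExpressionDatabases:
    """Pool the k lowest-ENc genes (high-expression database) and the k
    highest-ENc genes (low-expression database).

    Genes are ranked by (ENc, gene_id) so ties at the pool boundary resolve
    deterministically.
    """
    genes = [g for g in enc_by_gene
             if g in counts_by_gene and not math.isnan(enc_by_gene[g])]
    if len(genes) < 2 * k:
        raise EmptyInputError(f"need >= {2 * k} genes with defined ENc, got {len(genes)}")
    ranked = sorted(genes, key=lambda g: (enc_by_gene[g], g))
    high = tuple(ranked[:k])
    low = tuple(ranked[-k:])
    return ExpressionDatabases(
        high_pool=pool_counts([counts_by_gene[g] for g in high], label="high_expression"),
        low_pool=pool_counts([counts_by_gene[g] for g in low], label="low_expression"),
        k=k,
        high_members=high,
        low_members=low,
    )


@dataclass
class OptimalCodonResult:
    table: pd.DataFrame          # per-codon rscu_high, rscu_low, delta, flags
    optimal_set: frozenset[str]
    delta_threshold: float


def optimal_codon_scan(
    db: ExpressionDatabases,
    delta_threshold: float = DELTA_RSCU_THRESHOLD,
    inclusive: bool = True,
    code: GeneticCode | None = None,
) -> OptimalCodonResult:
    """Scan the 59 informative codons for optimal codons.

    Criteria: RSCU > 1 in *both* pools, and delta = RSCU_high - RSCU_low at
    least (``inclusive``, default) or strictly above ``delta_threshold``.
    Codons of families absent from either pool are marked non-evaluable.
    """
    code = code or standard_code()
    rscu_high = rscu(db.high_pool, code=code)
    rscu_low = rscu(db.low_pool, code=code)
    rows = []
    optimal: set[str] = set()
    for codon in code.informative_codons:
        hi = rscu_high.values[codon]
        lo = rscu_low.values[codon]
        evaluable = not (math.isnan(hi) or math.isnan(lo))
        delta = hi - lo if evaluable else float("nan")
        if evaluable:
            passes_delta = delta >= delta_threshold if inclusive else delta > delta_threshold
            is_opt = hi > 1.0 and lo > 1.0 and passes_delta
        else:
            is_opt = False
        if is_opt:
            optimal.add(codon)
        rows.append({
            "codon": codon,
            "aa": code.codon_to_aa[codon],
            "rscu_high": hi,
            "rscu_low": lo,
            "delta": delta,
            "evaluable": evaluable,
            "is_high_frequency": evaluable and hi > 1.0 and lo > 1.0,
            "is_optimal": is_opt,
        })
    table = pd.DataFrame(rows).set_index("codon")
    return OptimalCodonResult(
        table=table,
        optimal_set=frozenset(optimal),
        delta_threshold=delta_threshold,
    )


@dataclass
class CrossSpeciesSummary:
    union: frozenset[str]
    membership: pd.DataFrame     # codon x species booleans
    ending_base_tally: dict[str, int]


def cross_species_summary(
    results: Mapping[str, "OptimalCodonResult | Iterable[str]"],
) -> CrossSpeciesSummary:
    """Combine per-species optimal-codon sets: union, shared membership and
    the tally of third-position bases across the union.

    Accepts either :class:`OptimalCodonResult` values or plain codon sets
    (RNA- or DNA-alphabet), so externally reported sets can be summarised too.
    """
    if not results:
        raise EmptyInputError("cross_species_summary requires at least one species")
    sets: dict[str, frozenset[str]] = {}
    for species, res in results.items():
        codons = res.optimal_set if isinstance(res, OptimalCodonResult) else res
        sets[species] = frozenset(normalize_codon(c) for c in codons)
    union = frozenset().union(*sets.values())
    ordered = sorted(union)
    membership = pd.DataFrame(
        {sp: [c in s for c in ordered] for sp, s in sets.items()},
        index=ordered,
    )
    tally = {b: 0 for b in "ATGC"}
    for c in union:
        tally[c[2]] += 1
    return CrossSpeciesSummary(union=union, membership=membership, ending_base_tally=tally)
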