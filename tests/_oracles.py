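"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity along a different code path from the
package (plain loops over an independently derived codon table), so that
agreement is evidence of correctness rather than shared bugs.
"""
from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]

# families derived independently via Bio.Seq translation, 6-fold unified
_AA_OF = {c: str(Seq(c).translate()) for c in ALL_CODONS}
FAMILIES: dict[str, list[str]] = {}
for c, aa in _AA_OF.items():
    if aa != "*":
        FAMILIES.setdefault(aa, []).append(c)


def enc_brute(counts: dict[str, int]) -> float:
    """Wright's ENc by direct per-family evaluation (independent loop)."""
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in FAMILIES.items():
        k = len(fam)
        if k < 2:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        s = sum((counts.get(c, 0) / n) ** 2 for c in fam)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            per_class[k].append(f)
    fbar = {k: np.mean(v) for k, v in per_class.items() if v}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    val = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(val, 61.0)


def rscu_brute(counts: dict[str, int]) -> dict[str, float]:
    out = {}
    for aa, fam in FAMILIES.items():
        if len(fam) < 2:
            continue
        tot = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = counts.get(c, 0) / (tot / len(fam)) if tot else float("nan")
    return out


def gc_brute(sequence: str) -> float:
    """Per-nucleotide G+C fraction of a stop-stripped CDS string."""
    s = sequence.upper()
    if s[-3:] in ("TAA", "TAG", "TGA"):
        s = s[:-3]
    return sum(b in "GC" for b in s) / len(s)


def average_linkage_brute(X: np.ndarray) -> list[tuple[frozenset[int], frozenset[int], float]]:
    """O(n^3) between-groups average-linkage agglomeration on squared
    Euclidean distances; returns the merge sequence with heights."""
    n = X.shape[0]
    d2 = np.array([[np.sum((X[i] - X[j]) ** 2) for j in range(n)] for i in range(n)])
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([d2[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best_d - 1e-12:
                    best_d, best = d, (i, j)
        i, j = best
        merges.append((clusters[i], clusters[j], best_d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def random_counts(rng: np.random.Generator, n_codons: int = 300) -> dict[str, int]:
    """A random codon count table over sense codons (non-uniform usage)."""
    sense = [c for c in ALL_CODONS if _AA_OF[c] != "*"]
    w = rng.dirichlet(np.ones(len(sense)) * 0.5)
    draw = rng.choice(len(sense), size=n_codons, p=w)
    out: dict[str, int] = {}
    for i in draw:
        out[sense[i]] = out.get(sense[i], 0) + 1
    return out


def random_additive_matrix(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, set[frozenset[int]]]:
    """Distances generated by a random binary tree with positive branch
    lengths; also returns the tree's non-trivial splits (as leaf-index
    sets canonicalised to the side without leaf 0)."""
    D = np.zeros((n, n))
    nodes: list[tuple[dict[int, float], frozenset[int]]] = [
        ({i: 0.0}, frozenset([i])) for i in range(n)
    ]
    splits: set[frozenset[int]] = set()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (da, sa), (db, sb) = nodes[i], nodes[j]
        ea, eb = rng.uniform(0.1, 2.0, size=2)
        for x in da:
            for y in db:
                D[x, y] = D[y, x] = da[x] + ea + db[y] + eb
        merged = {k: v + ea for k, v in da.items()} | {k: v + eb for k, v in db.items()}
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((merged, sa | sb))
        for side in (sa, sb, sa | sb):
            if 2 <= len(side) <= n - 2:
                canon = side if 0 not in side else frozenset(range(n)) - side
                splits.add(canon)
    return D, splits
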