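"""Multivariate views of codon usage: RSCU matrices, PCA and clustering.

Each gene (or species 'super-gene' pool) becomes a 59-dimensional RSCU
vector; PCA projects the centered vectors onto their principal axes, and
agglomerative clustering with between-groups (average) linkage on squared
Euclidean distances groups rows by usage similarity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SKPCA

from .codon_core import CodingSequence, count_codons, pool_counts
from .cub_indices import RSCUVector, rscu
from .errors import EmptyInputError
from .genetic_code import GeneticCode, standard_code

log = logging.getLogger(__name__)

ImputePolicy = Literal["drop_rows", "family_mean", "zero"]


@dataclass
class RSCUMatrix:
    """Genes-by-codons RSCU table with an observed-value mask and metadata.

    Columns follow the fixed lexicographic order of the 59 informative
    codons; ``mask`` is True where the value was observed (not imputed).
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    metadata: pd.DataFrame | None = None
    impute: ImputePolicy = "family_mean"

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)


def build_rscu_matrix(
    vectors: Sequence[RSCUVector],
    impute: ImputePolicy = "family_mean",
    metadata: pd.DataFrame | None = None,
    code: GeneticCode | None = None,
) -> RSCUMatrix:
    """Align RSCU vectors into a matrix, handling missing families.

    Policies for families unobserved in a gene: ``drop_rows`` removes the
    gene, ``family_mean`` imputes each missing cell with its column mean over
    observed genes, ``zero`` imputes 0. Columns missing in every row are
    dropped with a warning.
    """
    if len(vectors) < 2:
        raise EmptyInputError("build_rscu_matrix requires at least 2 vectors")
    code = code or standard_code()
    cols = list(code.informative_codons)
    raw = pd.DataFrame(
        [[v.values.get(c, np.nan) for c in cols] for v in vectors],
        index=[v.gene_id for v in vectors],
        columns=cols,
    )
    mask = raw.notna()
    all_missing = [c for c in cols if not mask[c].any()]
    if all_missing:
        log.warning("dropping all-missing codon columns: %s", all_missing)
        raw = raw.drop(columns=all_missing)
        mask = mask.drop(columns=all_missing)

    if impute == "drop_rows":
        keep = mask.all(axis=1)
        raw, mask = raw.loc[keep], mask.loc[keep]
        if raw.empty:
            raise EmptyInputError("drop_rows imputation removed every gene")
    elif impute == "family_mean":
        raw = raw.fillna(raw.mean(axis=0))
    elif impute == "zero":
        raw = raw.fillna(0.0)
    else:
        raise ValueError(f"unknown impute policy {impute!r}")

    meta = None
    if metadata is not None:
        meta = metadata.reindex(raw.index)
    return RSCUMatrix(values=raw, mask=mask, metadata=meta, impute=impute)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # rows x components
    loadings: pd.DataFrame          # codons x components
    explained_variance_ratio: np.ndarray


def pca(
    matrix: RSCUMatrix,
    n_components: int = 2,
    scale: bool = False,
) -> PCAResult:
    """PCA of the RSCU matrix (centered; unscaled by default).

    RSCU is already normalised within codon families, so column scaling is
    off by default (it would inflate rare-family noise); ``scale=True``
    standardises columns first. Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is positive.
    """
    X = matrix.values.to_numpy(float)
    if X.shape[0] < 3:
        raise EmptyInputError("pca requires at least 3 rows")
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    n_components = min(n_components, min(X.shape) - 1) or 1
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T
    for j in range(loadings.shape[1]):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.values.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


@dataclass
class ClusterTree:
    """Agglomerative merge history over labelled rows.

    ``linkage_matrix`` is in scipy format; ``merges`` lists, in order, the
    two member sets joined at each step and the merge height.
    """

    ids: list[str]
    linkage_matrix: np.ndarray
    distance: str = "squared_euclidean"
    linkage: str = "average"

    @property
    def merges(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        n = len(self.ids)
        clusters: dict[int, frozenset[str]] = {i: frozenset([g]) for i, g in enumerate(self.ids)}
        out = []
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            ca, cb = clusters[int(a)], clusters[int(b)]
            out.append((ca, cb, float(h)))
            clusters[n + step] = ca | cb
        return out

    def to_newick(self) -> str:
        """Newick string with merge heights converted to branch lengths."""
        n = len(self.ids)
        heights = {i: 0.0 for i in range(n)}
        labels: dict[int, str] = {i: self.ids[i] for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            node = n + step
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            labels[node] = f"({labels[a]}:{la:.6g},{labels[b]}:{lb:.6g})"
            heights[node] = h
        return labels[n + len(self.linkage_matrix) - 1] + ";"


def hierarchical_cluster(matrix: RSCUMatrix) -> ClusterTree:
    """Between-groups average linkage on squared Euclidean RSCU distances.

    This is the SPSS "intergroup linkage / squared Euclidean" combination;
    with average linkage on a fixed dissimilarity the merge heights are
    non-decreasing. Duplicate rows (zero distances) are legal.
    """
    X = matrix.values.to_numpy(float)
    if X.shape[0] < 2:
        raise EmptyInputError("hierarchical_cluster requires at least 2 rows")
    d2 = pdist(X, metric="sqeuclidean")
    Z = hierarchy.linkage(d2, method="average")
    return ClusterTree(ids=list(matrix.values.index), linkage_matrix=Z)


def species_supergene_cluster(
    cds_by_species: Mapping[str, Sequence[CodingSequence]],
    impute: ImputePolicy = "family_mean",
    code: GeneticCode | None = None,
) -> ClusterTree:
    """Cluster species by the pooled codon usage of all their genes.

    Each species' gene counts are summed into one 'super-gene' count table;
    species with zero genes are excluded with a warning.
    """
    code = code or standard_code()
    vectors = []
    for species, cds_list in cds_by_species.items():
        if not cds_list:
            log.warning("species %s has no genes; excluded", species)
            continue
        pooled = pool_counts([count_codons(c, code=code) for c in cds_list], label=species)
        vectors.append(rscu(pooled, code=code))
    if len(vectors) < 2:
        raise EmptyInputError("species_supergene_cluster requires >= 2 non-empty species")
    return hierarchical_cluster(build_rscu_matrix(vectors, impute=impute, code=code))
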