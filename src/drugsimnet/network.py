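"""Drug/gene-set bipartite weighting and projection to a drug-drug network.

A drug ``D`` (target gene set) and a gene set ``G`` are linked when their
gene sets overlap; the edge weight couples a purely structural factor with a
disease-contextual one::

    J(D, G) = |D n G| / |D u G|            (Jaccard overlap)
    W(D, G) = J(D, G) * median{ DE(x) : x in D n G }

where DE(x) is the per-gene differential-expression score.  Arranging the
weights as a drugs-by-sets matrix ``W``, the drug-drug functional similarity
matrix is the one-mode projection ``A = W @ W.T`` with the diagonal zeroed
(no self-links); entry ``A[a, b]`` is the sum over shared gene sets of the
product of the two drugs' edge weights.

Overlap genes that are not measured in the expression data are excluded from
the median; a pair with no measured overlap gene gets weight 0.  The Jaccard
factor always uses the full, unrestricted set sizes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np

from .de import DEProfile
from .io import DrugTargetCatalog, GeneSetCollection


def jaccard(d: Iterable[str], g: Iterable[str]) -> float:
    """Jaccard index |d n g| / |d u g| of two gene sets."""
    d, g = set(d), set(g)
    if not d and not g:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(d & g) / len(d | g)


def edge_weight(d: Iterable[str], g: Iterable[str], de: DEProfile) -> float:
    """Contextual drug/gene-set edge weight J(d,g) * median DE over d n g.

    Returns 0 when the sets do not overlap or when no overlap gene has a
    measured DE score.
    """
    d, g = set(d), set(g)
    overlap = d & g
    if not overlap:
        return 0.0
    measured = [x for x in overlap if x in de.table.index]
    if not measured:
        return 0.0
    return jaccard(d, g) * float(np.median(de.table.loc[measured, "de_score"]))


@dataclasses.dataclass
class BipartiteStructure:
    """DE-independent skeleton of the drug/gene-set bipartite network.

    Holds, for every (drug, set) pair with at least one measured overlap
    gene, the Jaccard factor and the indices of the overlap genes in a fixed
    gene order.  Given a vector of per-gene DE scores in that order,
    :meth:`weights` rebuilds the full weight matrix; bootstrap replicates
    reuse the structure and swap only the scores.  Pairs are grouped by
    overlap size so the medians vectorize.
    """

    drug_ids: list[str]
    set_ids: list[str]
    gene_order: list[str]
    # overlap size -> (drug row idx, set col idx, jaccard, overlap-gene index matrix)
    groups: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def build(
        cls,
        cat: DrugTargetCatalog,
        sets: GeneSetCollection,
        gene_order: list[str],
    ) -> "BipartiteStructure":
        gene_pos = {g: i for i, g in enumerate(gene_order)}
        drug_ids = cat.drug_ids
        set_ids = sets.set_ids
        set_members = [sets.genes[s] for s in set_ids]

        buckets: dict[int, list[tuple[int, int, float, list[int]]]] = {}
        for a, drug in enumerate(drug_ids):
            targets = cat.targets[drug]
            for j, members in enumerate(set_members):
                overlap = targets & members
                if not overlap:
                    continue
                measured = [gene_pos[x] for x in overlap if x in gene_pos]
                if not measured:
                    continue
                jac = len(overlap) / len(targets | members)
                buckets.setdefault(len(measured), []).append((a, j, jac, measured))

        groups = {}
        for size, items in buckets.items():
            rows = np.array([it[0] for it in items], dtype=np.intp)
            cols = np.array([it[1] for it in items], dtype=np.intp)
            jac = np.array([it[2] for it in items], dtype=float)
            idx = np.array([it[3] for it in items], dtype=np.intp)
            groups[size] = (rows, cols, jac, idx)
        return cls(
            drug_ids=list(drug_ids),
            set_ids=list(set_ids),
            gene_order=list(gene_order),
            groups=groups,
        )

    def weights(self, scores: np.ndarray) -> np.ndarray:
        """Weight matrix W (drugs x sets) for per-gene DE ``scores``."""
        scores = np.asarray(scores, dtype=float)
        W = np.zeros((len(self.drug_ids), len(self.set_ids)))
        for rows, cols, jac, idx in self.groups.values():
            W[rows, cols] = jac * np.median(scores[idx], axis=1)
        return W


@dataclasses.dataclass
class BipartiteWeights:
    """Weighted drug/gene-set adjacency matrix (rows drugs, columns sets)."""

    drug_ids: list[str]
    set_ids: list[str]
    W: np.ndarray


@dataclasses.dataclass
class DrugSimilarityMatrix:
    """Symmetric drug-drug functional similarity matrix with zero diagonal."""

    drug_ids: list[str]
    A: np.ndarray

    def as_mapping(self) -> Mapping[str, np.ndarray]:
        return dict(zip(self.drug_ids, self.A))


def build_bipartite(
    cat: DrugTargetCatalog,
    sets: GeneSetCollection,
    de: DEProfile,
) -> BipartiteWeights:
    """Build the contextual drug/gene-set weight matrix from a DE profile."""
    gene_order = de.gene_ids
    structure = BipartiteStructure.build(cat, sets, gene_order)
    W = structure.weights(de.score_array(gene_order))
    return BipartiteWeights(
        drug_ids=structure.drug_ids, set_ids=structure.set_ids, W=W
    )


def project_similarity(bw: BipartiteWeights) -> DrugSimilarityMatrix:
    """One-mode projection A = W @ W.T with the diagonal set to zero."""
    if len(bw.drug_ids) < 2:
        raise ValueError("projection needs at least 2 drugs")
    A = bw.W @ bw.W.T
    np.fill_diagonal(A, 0.0)
    # enforce exact symmetry against floating-point asymmetry in the product
    A = np.maximum(A, A.T)
    return DrugSimilarityMatrix(drug_ids=list(bw.drug_ids), A=A)
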