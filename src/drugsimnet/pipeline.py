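"""End-to-end orchestration: DE scoring -> bipartite weighting -> projection
-> restart walk -> bootstrap significance -> ranked result table."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .de import DEProfile, compute_de_scores, zscore_normalize
from .io import DrugTargetCatalog, ExpressionDataset, GeneSetCollection
from .network import (
    BipartiteStructure,
    BipartiteWeights,
    DrugSimilarityMatrix,
    project_similarity,
)
from .propagation import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    CentralityVector,
    column_normalize,
    random_walk_restart,
)
from .significance import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_N_PERMUTATIONS,
    NullScores,
    bh_fdr,
    bootstrap_null,
    empirical_pvalues,
    rank_drugs,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    de_profile: DEProfile
    bipartite: BipartiteWeights
    similarity: DrugSimilarityMatrix
    centrality: CentralityVector
    isolated: list[str]
    null: NullScores | None
    table: pd.DataFrame
    counts: dict[str, int | bool]


def run_pipeline(
    expression: ExpressionDataset,
    catalog: DrugTargetCatalog,
    sets: GeneSetCollection,
    restart: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    welch: bool = True,
    symmetric_tails: bool = False,
    normalize: bool = True,
    pseudocount: bool = False,
) -> PipelineResult:
    """Run the full prioritization pipeline on in-memory inputs.

    With ``n_permutations=0`` the bootstrap and the p/FDR columns are
    skipped (a warning is logged) and only centrality ranks are returned.
    """
    ds = zscore_normalize(expression) if normalize else expression
    de = compute_de_scores(ds, welch=welch, symmetric=symmetric_tails)

    structure = BipartiteStructure.build(catalog, sets, de.gene_ids)
    W = structure.weights(de.score_array(structure.gene_order))
    bipartite = BipartiteWeights(
        drug_ids=structure.drug_ids, set_ids=structure.set_ids, W=W
    )
    similarity = project_similarity(bipartite)
    tm = column_normalize(similarity)
    centrality = random_walk_restart(tm, r=restart, tol=tol, max_iter=max_iter)

    null = None
    if n_permutations > 0:
        null = bootstrap_null(
            catalog,
            sets,
            de,
            B=n_permutations,
            seed=seed,
            r=restart,
            tol=tol,
            max_iter=max_iter,
            structure=structure,
        )
        p = empirical_pvalues(centrality, null, pseudocount=pseudocount)
        fdr = bh_fdr(p)
        table = rank_drugs(
            centrality,
            p,
            fdr,
            threshold=fdr_threshold,
            names=catalog.names,
            isolated=tm.isolated,
        )
        n_candidates = int(table["candidate"].sum())
    else:
        logger.warning("n_permutations=0: result table carries no p/FDR columns")
        table = rank_drugs(centrality, names=catalog.names, isolated=tm.isolated)
        n_candidates = 0

    counts = {
        "drugs": len(catalog),
        "gene_sets": len(sets),
        "genes_measured": len(de.gene_ids),
        "edges": int(np.count_nonzero(np.triu(similarity.A, k=1))),
        "isolated_drugs": len(tm.isolated),
        "iterations": centrality.iterations,
        "converged": centrality.converged,
        "candidates": n_candidates,
    }
    for key, val in counts.items():
        logger.info("%s: %s", key, val)
    return PipelineResult(
        de_profile=de,
        bipartite=bipartite,
        similarity=similarity,
        centrality=centrality,
        isolated=tm.isolated,
        null=null,
        table=table,
        counts=counts,
    )
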