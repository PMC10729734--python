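"""Bootstrap significance of drug centrality scores with BH FDR control.

The drug/gene-set overlap structure is held fixed while the per-gene DE
scores are bootstrap-resampled (drawn with replacement from the observed
pool and reassigned to genes); the bipartite weighting, projection and
random walk are then rerun from scratch.  Each replicate yields a vector of
null centrality scores, and a drug's empirical p-value is the fraction of
replicates whose score for that drug is at least the observed one (the
indicator count divided by the number of replicates, with ties counted).
p-values are adjusted with the Benjamini-Hochberg step-up procedure and
drugs with FDR strictly below the threshold are flagged as candidates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .de import DEProfile
from .io import DrugTargetCatalog, GeneSetCollection
from .network import BipartiteStructure, DrugSimilarityMatrix
from .propagation import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    CentralityVector,
    column_normalize,
    random_walk_restart,
)

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_FDR_THRESHOLD = 0.1


@dataclasses.dataclass
class NullScores:
    """Replicates x drugs matrix of bootstrap centrality scores."""

    drug_ids: list[str]
    scores: np.ndarray  # shape (B, n_drugs)

    @property
    def n_replicates(self) -> int:
        return self.scores.shape[0]


def _replicate_centrality(
    structure: BipartiteStructure,
    scores: np.ndarray,
    r: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Rebuild W -> A -> T -> v for one score vector; isolated drugs get 0."""
    W = structure.weights(scores)
    A = W @ W.T
    np.fill_diagonal(A, 0.0)
    A = np.maximum(A, A.T)
    v_full = np.zeros(len(structure.drug_ids))
    sim = DrugSimilarityMatrix(drug_ids=list(structure.drug_ids), A=A)
    try:
        tm = column_normalize(sim)
    except ValueError:
        return v_full  # every drug isolated in this replicate
    cv = random_walk_restart(tm, r=r, tol=tol, max_iter=max_iter)
    pos = {d: i for i, d in enumerate(structure.drug_ids)}
    for d, val in zip(cv.drug_ids, cv.v):
        v_full[pos[d]] = val
    return v_full


def bootstrap_null(
    cat: DrugTargetCatalog,
    sets: GeneSetCollection,
    de: DEProfile,
    B: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    structure: BipartiteStructure | None = None,
) -> NullScores:
    """Bootstrap the gene-level DE scores and recompute centrality B times.

    Each replicate draws, for every gene, a DE score uniformly with
    replacement from the observed pool of DE scores, keeps the drug/gene-set
    intersections fixed, and reruns weighting, projection and the restart
    walk with identical parameters.  Replicate RNG streams are spawned from
    the master seed, so results do not depend on execution order.  Drugs
    isolated within a replicate receive centrality 0 in that row.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    if structure is None:
        structure = BipartiteStructure.build(cat, sets, de.gene_ids)
    pool = de.score_array(structure.gene_order)
    pool = pool[~np.isnan(pool)]
    n_genes = len(structure.gene_order)

    streams = np.random.SeedSequence(seed).spawn(B)
    rows = np.empty((B, len(structure.drug_ids)))
    for k in range(B):
        rng = np.random.default_rng(streams[k])
        resampled = rng.choice(pool, size=n_genes, replace=True)
        rows[k] = _replicate_centrality(structure, resampled, r, tol, max_iter)
    return NullScores(drug_ids=list(structure.drug_ids), scores=rows)


def empirical_pvalues(
    observed: CentralityVector,
    null: NullScores,
    pseudocount: bool = False,
) -> pd.Series:
    """Per-drug empirical p: fraction of null replicates >= the observed score.

    ``pseudocount=True`` switches to the (k + 1) / (B + 1) variant, which
    avoids exact zeros; the default follows the plain counting formula.
    Drugs present in the null universe but absent from ``observed`` (e.g.
    isolated in the observed network) are not returned here.
    """
    pos = {d: i for i, d in enumerate(null.drug_ids)}
    missing = [d for d in observed.drug_ids if d not in pos]
    if missing:
        raise ValueError(f"drug '{missing[0]}' missing from the null score matrix")
    idx = [pos[d] for d in observed.drug_ids]
    counts = (null.scores[:, idx] >= observed.v[None, :]).sum(axis=0)
    B = null.n_replicates
    if pseudocount:
        p = (counts + 1) / (B + 1)
    else:
        p = counts / B
    return pd.Series(p, index=observed.drug_ids, name="p_value")


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted values, order-aligned with input."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(adjusted, index=p.index, name="fdr")
    return adjusted


def rank_drugs(
    centrality: CentralityVector,
    p: pd.Series | None = None,
    fdr: pd.Series | None = None,
    threshold: float = DEFAULT_FDR_THRESHOLD,
    names: dict[str, str] | None = None,
    isolated: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-drug result table, ranked by descending centrality.

    Ties in centrality are broken by drug id.  Isolated drugs, if given, are
    appended with centrality 0 and p-value 1.  The candidate flag is
    ``fdr < threshold`` (strict).
    """
    if p is not None and list(p.index) != list(centrality.drug_ids):
        raise ValueError("p-values are not aligned with the centrality vector")
    if fdr is not None and p is not None and list(fdr.index) != list(p.index):
        raise ValueError("FDR values are not aligned with the p-values")

    rows = pd.DataFrame({"drug_id": centrality.drug_ids, "centrality_score": centrality.v})
    if p is not None:
        rows["p_value"] = p.to_numpy()
        rows["fdr"] = fdr.to_numpy() if fdr is not None else bh_fdr(p).to_numpy()
    if isolated:
        extra = pd.DataFrame({"drug_id": sorted(isolated), "centrality_score": 0.0})
        if p is not None:
            extra["p_value"] = 1.0
            extra["fdr"] = 1.0
        rows = pd.concat([rows, extra], ignore_index=True)

    rows["drug_name"] = rows["drug_id"].map(lambda d: (names or {}).get(d, d))
    rows = rows.sort_values(
        ["centrality_score", "drug_id"], ascending=[False, True]
    ).reset_index(drop=True)
    rows["rank"] = np.arange(1, len(rows) + 1)
    if p is not None:
        rows["candidate"] = rows["fdr"] < threshold
        cols = ["drug_id", "drug_name", "centrality_score", "p_value", "fdr", "rank", "candidate"]
    else:
        cols = ["drug_id", "drug_name", "centrality_score", "rank"]
    return rows[cols]
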