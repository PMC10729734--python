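"""Random walk with restart over the drug similarity network.

The similarity matrix ``A`` is column-normalized into a transition matrix
``T`` (``T[a, b] = A[a, b] / sum_a A[a, b]``) and the walk

    v_{t+1} = (1 - r) * T @ v_t + r * v_0

is iterated from the uniform seed ``v_0 = 1/N`` until the L1 change drops
below tolerance.  The fixed point is the drugs' eigenvector-centrality-style
score: drugs embedded among strongly similar neighbours accumulate
probability mass.  With restart probability r the iteration is a contraction
with factor (1 - r), so convergence is geometric.

Isolated drugs (all-zero rows/columns of ``A``) are removed before
normalization — a zero column cannot be normalized and an unconnected drug
can receive no propagation evidence — and reported separately.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .network import DrugSimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_RESTART = 0.9
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000


@dataclasses.dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix over the connected drugs."""

    drug_ids: list[str]
    T: np.ndarray
    isolated: list[str]  # drugs dropped because they had no edges


@dataclasses.dataclass
class CentralityVector:
    drug_ids: list[str]
    v: np.ndarray
    iterations: int
    converged: bool

    def as_series(self):
        import pandas as pd

        return pd.Series(self.v, index=self.drug_ids, name="centrality")


def column_normalize(sim: DrugSimilarityMatrix) -> TransitionMatrix:
    """Column-normalize A after dropping isolated drugs.

    Raises if every drug is isolated (there is no network to walk on).
    """
    A = np.asarray(sim.A, dtype=float)
    colsums = A.sum(axis=0)
    connected = colsums > 0
    if not connected.any():
        raise ValueError("all drugs are isolated; no similarity network exists")
    isolated = [d for d, c in zip(sim.drug_ids, connected) if not c]
    if isolated:
        logger.info("dropping %d isolated drug(s) before normalization", len(isolated))
    kept = [d for d, c in zip(sim.drug_ids, connected) if c]
    sub = A[np.ix_(connected, connected)]
    T = sub / sub.sum(axis=0, keepdims=True)
    return TransitionMatrix(drug_ids=kept, T=T, isolated=isolated)


def random_walk_restart(
    tm: TransitionMatrix,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CentralityVector:
    """Iterate the restart walk from the uniform seed to its fixed point.

    Returns the final probability vector together with the iteration count
    and a convergence flag; non-convergence within ``max_iter`` is reported,
    not fatal.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("restart probability must be in (0, 1]")
    n = len(tm.drug_ids)
    v0 = np.full(n, 1.0 / n)
    v = v0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        v_next = (1.0 - r) * (tm.T @ v) + r * v0
        if np.abs(v_next - v).sum() < tol:
            v = v_next
            converged = True
            break
        v = v_next
    if not converged:
        logger.warning("random walk did not converge within %d iterations", max_iter)
    return CentralityVector(
        drug_ids=list(tm.drug_ids), v=v, iterations=iterations, converged=converged
    )


def closed_form_stationary(tm: TransitionMatrix, r: float) -> CentralityVector:
    """Exact fixed point v = r * (I - (1-r) T)^-1 v0 via a dense solve.

    Serves as an analytic cross-check for the iterative walk; for r > 0 and
    column-stochastic T the system is always nonsingular.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("restart probability must be in (0, 1]")
    n = len(tm.drug_ids)
    v0 = np.full(n, 1.0 / n)
    v = np.linalg.solve(np.eye(n) - (1.0 - r) * tm.T, r * v0)
    return CentralityVector(drug_ids=list(tm.drug_ids), v=v, iterations=0, converged=True)
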