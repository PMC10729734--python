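"""Per-gene differential-expression (DE) scoring between case and control.

Each gene is tested with a two-tailed t-test (Welch by default) and the
p-value is mapped to a z-score through the inverse normal CDF,
``z = PhiInv(1 - p)``; the DE score is ``|z|``.  Note the deliberate
asymmetry of this transform: genes with p near 1 receive a large negative z
and hence a large DE score.  This follows the printed definition of the
method; a symmetric two-tailed alternative ``z = PhiInv(1 - p/2)`` is
available behind ``symmetric=True``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset

#: p-values are clamped into this open interval before the quantile transform,
#: since PhiInv(1 - p) diverges at both endpoints.
P_CLAMP_LO = 1e-300
P_CLAMP_HI = 1.0 - 1e-16


@dataclasses.dataclass
class DEProfile:
    """Per-gene t-test p-value, z-score and DE score (``|z|``)."""

    table: pd.DataFrame  # index: gene; columns: p, z, de_score

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def scores(self) -> pd.Series:
        return self.table["de_score"]

    def score_array(self, gene_order: list[str]) -> np.ndarray:
        """DE scores for ``gene_order``; genes without a value get NaN."""
        return self.table["de_score"].reindex(gene_order).to_numpy(float)


def zscore_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize each gene row to mean 0, sd 1 (ddof=1) across all samples.

    Constant rows (zero variance) are mapped to all-zero rows.
    """
    values = ds.values.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return ExpressionDataset(
        values=pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns),
        group=ds.group,
    )


def p_to_z(p: np.ndarray | float, symmetric: bool = False) -> np.ndarray | float:
    """Map t-test p-values to z-scores via the inverse normal CDF.

    Default is ``PhiInv(1 - p)`` (one-sided form, as printed in the method's
    definition); ``symmetric=True`` uses ``PhiInv(1 - p/2)``.  Input is
    clamped to ``[P_CLAMP_LO, P_CLAMP_HI]`` to keep the transform finite.
    """
    p = np.clip(p, P_CLAMP_LO, P_CLAMP_HI)
    # norm.isf(q) computes PhiInv(1 - q) without the 1 - p cancellation
    return stats.norm.isf(p / 2 if symmetric else p)


def compute_de_scores(
    ds: ExpressionDataset,
    welch: bool = True,
    symmetric: bool = False,
) -> DEProfile:
    """Two-tailed t-test per gene, then DE score ``|PhiInv(1 - p)|``.

    Parameters
    ----------
    ds:
        Expression dataset; both groups must have at least two samples.
    welch:
        Use Welch's unequal-variance t-test (default); ``False`` selects the
        pooled-variance Student test.
    symmetric:
        Use the symmetric transform ``PhiInv(1 - p/2)`` instead of the
        default ``PhiInv(1 - p)``.
    """
    case = ds.case_matrix()
    control = ds.control_matrix()
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples for the t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: no evidence of dysregulation
    p = np.where(np.isnan(p), 1.0, p)
    z = p_to_z(p, symmetric=symmetric)
    table = pd.DataFrame(
        {"p": np.clip(p, P_CLAMP_LO, P_CLAMP_HI), "z": z, "de_score": np.abs(z)},
        index=ds.values.index,
    )
    return DEProfile(table=table)
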