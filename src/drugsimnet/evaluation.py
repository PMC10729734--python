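"""Ranking evaluation: AUROC against known positives, top-k overlap and
rank correlation between runs."""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EvaluationReport:
    auroc: float
    n_positives: int
    n_negatives: int
    topk_overlap: int | None = None
    topk_fraction: float | None = None
    k: int | None = None
    rank_correlation: float | None = None
    rank_correlation_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def auroc(scores: pd.Series, positives: Iterable[str]) -> float:
    """Area under the ROC curve of ``scores`` against a positive drug set.

    Uses the Mann-Whitney form P(score_pos > score_neg) + 0.5 P(tie).
    Positives absent from the scored universe are dropped (with a logged
    count); at least one positive and one negative must remain.
    """
    positives = set(positives)
    unknown = positives - set(scores.index)
    if unknown:
        logger.info("%d positive drug(s) not in the scored universe", len(unknown))
    labels = scores.index.isin(positives).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative drug")
    return float(roc_auc_score(labels, scores.to_numpy(float)))


def topk_overlap(
    ranking_a: Sequence[str], ranking_b: Sequence[str], k: int = 50
) -> int:
    """Size of the intersection of the two rankings' top-k drug sets."""
    universe = set(ranking_a)
    if set(ranking_b) != universe:
        raise ValueError("rankings must cover the same drug universe")
    if k > len(universe):
        raise ValueError(f"k={k} exceeds the {len(universe)}-drug universe")
    return len(set(ranking_a[:k]) & set(ranking_b[:k]))


def rank_correlation(
    scores_a: pd.Series, scores_b: pd.Series, method: str = "spearman"
) -> tuple[float, float]:
    """Spearman (default) or Pearson correlation of two aligned score lists."""
    if len(scores_a) != len(scores_b):
        raise ValueError("score vectors differ in length")
    if not scores_a.index.equals(scores_b.index):
        scores_b = scores_b.reindex(scores_a.index)
        if scores_b.isna().any():
            raise ValueError("score vectors are not over the same drugs")
    if len(scores_a) < 3:
        raise ValueError("need at least 3 drugs for a rank correlation")
    if method == "spearman":
        res = stats.spearmanr(scores_a, scores_b)
    elif method == "pearson":
        res = stats.pearsonr(scores_a, scores_b)
    else:
        raise ValueError(f"unknown correlation method '{method}'")
    return float(res.statistic), float(res.pvalue)


def evaluate_ranking(
    table: pd.DataFrame,
    positives: Iterable[str],
    k: int | None = None,
    reference: pd.DataFrame | None = None,
) -> EvaluationReport:
    """AUROC of a result table's centrality scores, with optional top-k
    overlap and rank correlation against a reference table."""
    scores = table.set_index("drug_id")["centrality_score"].astype(float)
    positives = set(positives) & set(scores.index)
    value = auroc(scores, positives)
    report = EvaluationReport(
        auroc=value, n_positives=len(positives), n_negatives=len(scores) - len(positives)
    )
    if reference is not None:
        ref_scores = reference.set_index("drug_id")["centrality_score"].astype(float)
        if k is not None:
            a = scores.sort_values(ascending=False).index.tolist()
            b = ref_scores.sort_values(ascending=False).index.tolist()
            report.k = k
            report.topk_overlap = topk_overlap(a, b, k)
            report.topk_fraction = report.topk_overlap / k
        rho, pval = rank_correlation(scores, ref_scores)
        report.rank_correlation = rho
        report.rank_correlation_p = pval
    return report
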