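"""Evaluate a drug ranking: AUROC against known positives and robustness
of the ranking to the restart probability."""

import pandas as pd

from drugsimnet import (
    BenchmarkSpec,
    auroc,
    build_bipartite,
    column_normalize,
    compute_de_scores,
    generate_benchmark,
    project_similarity,
    random_walk_restart,
    rank_correlation,
    run_pipeline,
    topk_overlap,
    zscore_normalize,
)

bundle = generate_benchmark(BenchmarkSpec(seed=1))
result = run_pipeline(bundle.expression, bundle.catalog, bundle.sets, n_permutations=0)
scores = result.table.set_index("drug_id")["centrality_score"].astype(float)
print(f"AUROC against planted true drugs: {auroc(scores, bundle.true_drugs):.3f}")

de = compute_de_scores(zscore_normalize(bundle.expression))
tm = column_normalize(project_similarity(build_bipartite(bundle.catalog, bundle.sets, de)))
ref = random_walk_restart(tm, r=0.9)
s_ref = pd.Series(ref.v, index=ref.drug_ids)
rank_ref = s_ref.sort_values(ascending=False).index.tolist()
print("restart-probability robustness (top-20 overlap with r=0.9):")
for r in (0.1, 0.3, 0.5, 0.7):
    cv = random_walk_restart(tm, r=r)
    s = pd.Series(cv.v, index=cv.drug_ids)
    ov = topk_overlap(s.sort_values(ascending=False).index.tolist(), rank_ref, 20)
    rho, _ = rank_correlation(s, s_ref)
    print(f"  r={r}: overlap {ov}/20, Spearman {rho:.3f}")
# An AUROC near 1 means the centrality ranking separates planted drugs from
# decoys; stable top-k across r shows the ranking is not an artifact of the
# restart parameter.
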