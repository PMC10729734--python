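# Methods

## Model and assumptions

`drugsimnet` scores drugs for repurposing potential in a specific disease
context. The underlying assumptions are: (i) a drug acts through its target
genes; (ii) two drugs are functionally related when their targets share
membership in functional gene sets; (iii) relatedness matters for a disease
only insofar as the shared genes are transcriptionally dysregulated in that
disease; and (iv) therapeutic evidence reinforces across functionally
similar drugs, so a diffusion process on the similarity network is an
appropriate aggregator.

The pipeline is: per-gene DE scores → weighted drug/gene-set bipartite
network → one-mode projection to a drug–drug similarity matrix →
column-normalized random walk with restart → gene-level bootstrap
significance with BH FDR control.

### DE scores

Expression is z-score normalized per gene across all samples (unbiased
sd, n−1; constant rows map to zero). Each gene is tested with a two-tailed
t-test between case and control; Welch's unequal-variance form is the
default because unpaired public cohorts are rarely homoscedastic, with the
pooled-variance Student test available as an option. The t-test is computed
on the normalized matrix by default (normalization is a global
preprocessing step); a flag allows testing raw values, which changes
nothing for the t statistic since it is scale- and location-invariant
per gene.

The p-value is mapped through the inverse normal CDF, `z = Φ⁻¹(1 − p)`,
and the DE score is `|z|`. This transform is deliberately one-sided and
asymmetric: genes with p near 1 receive a large *negative* z and hence a
large DE score. We keep that behaviour because it is the method's printed
definition; in practice p-values near 1 are rare under continuous data and
the affected scores sit in the null bulk. A symmetric variant
`z = Φ⁻¹(1 − p/2)` is available behind `symmetric=True` for users who
prefer a monotone map from evidence to score. p-values are clamped to
`[1e-300, 1 − 1e-16]` before the quantile transform, which diverges at both
endpoints; genes with zero variance in both groups get p = 1 (no evidence)
before clamping. The quantile is computed via `norm.isf(p)` to avoid the
catastrophic cancellation of literally evaluating `1 − p` at small p.

### Bipartite weights and projection

A drug D and gene set G are linked iff their gene sets overlap; the weight
is the Jaccard index times the median DE score of the overlap genes. The
median of an even-size overlap is the midpoint of the two central values
(standard convention). Overlap genes without a measured DE value are
excluded from the median; if no overlap gene is measured the edge is absent
(weight 0) — an unmeasurable contextual weight should not create contextual
edges. The Jaccard factor always uses the full set sizes.

The drug–drug similarity matrix is `A = W·Wᵀ` with the diagonal zeroed
(self-links removed). Edges exist wherever `A[a,b] > 0`; no additional
sparsification threshold is applied. Matrices are dense `numpy` arrays: at
the intended scale (10²–10³ drugs, 10²–10³ sets) dense algebra is faster
and simpler than sparse bookkeeping.

### Propagation

`A` is column-normalized into `T` (each column divided by its sum) and the
walk `v ← (1−r)·T·v + r·v⁰` is iterated from the uniform seed `v⁰ = 1/N`
until the L1 change is below `1e-10` (L1 pairs naturally with probability
vectors). Because the update is a contraction with factor (1−r),
convergence is geometric — about 11 iterations at the default r = 0.9 —
and the `max_iter` default of 10,000 is far above need; non-convergence is
flagged, not fatal. A closed-form solve `v = r(I − (1−r)T)⁻¹v⁰` is provided
as an independent cross-check and is used as the test oracle, never as the
production path.

Isolated drugs (zero row/column of `A`) are removed before normalization —
a zero column cannot be normalized and an unconnected drug can receive no
propagation evidence — and appear in the result table with centrality 0 and
p = 1.

### Significance

The drug/set intersection structure is held fixed while per-gene DE scores
are resampled with replacement from the observed score pool (gene-level
bootstrap); steps 2–4 rerun per replicate with identical parameters. The
empirical p-value is the fraction of replicates whose centrality reaches
the observed value (inclusive ≥; ties count). Exact zeros are allowed, as
the counting formula permits; a `(k+1)/(B+1)` pseudocount variant exists
behind a flag for users worried about degenerate FDR on zeros, and is off
by default. Replicate RNG streams are spawned from the master seed
(`numpy.random.SeedSequence`), so results are independent of execution
order. Drugs isolated within a replicate get centrality 0 in that row,
which is conservative for the p-value count. Resampled scores are used
as-is (they are already nonnegative finite reals); no re-clamping is
needed. BH adjustment is the standard step-up procedure; candidates are
called at FDR strictly below 0.1.

Bootstrap cost is kept low by precomputing, per (drug, set) pair, the
Jaccard factor and the overlap-gene indices, grouped by overlap size so all
medians of a given size vectorize into one `np.median(..., axis=1)` call.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `restart` (r) | 0.9 | restart probability of the walk; 0.1–0.8 give closely similar rankings |
| `tol` | 1e-10 | L1 convergence tolerance of the walk |
| `n_permutations` (B) | 1000 | bootstrap replicates for the null |
| `fdr_threshold` | 0.1 | strict candidate cutoff on BH-adjusted p |
| drug target filter | 4–499 | targets per retained drug (exclusive bounds 3/500) |
| gene-set filter | 6–99 | genes per retained set (exclusive bounds 5/100) |
| `welch` | True | Welch vs pooled-variance t-test |
| `symmetric` | False | symmetric `Φ⁻¹(1 − p/2)` transform |
| `pseudocount` | False | `(k+1)/(B+1)` empirical p variant |

## The synthetic benchmark

`BenchmarkSpec` defaults define the standard desk-scale study conditions:
2,000 genes in 20 case / 20 control samples, 100 drugs (5 planted true),
300 gene sets (15 disease sets), a 2.5-sd case-group mean shift on 10% of
genes, target sets of 4–30 genes and gene sets of 6–30 genes. Expression is
i.i.d. Gaussian noise plus the planted shift — Gaussian because the DE
layer is a t-test, which makes the null calibration interpretable.

Construction details that matter:

* Disease sets draw 60% of their members from the shifted genes and 40%
  from unshifted ones; background sets draw uniformly from **all** genes.
  Functional categories in real collections do not avoid disease genes, and
  this mixing is what routes the signal through the network: decoys acquire
  weak edges into disease terms, which true drugs then dominate once DE
  upweights them, and true drugs keep weak high-DE edges across the
  background so they compete in every column of the transition matrix.
* True drugs sample their targets from the union of two disease sets plus
  one random set, so recovery genuinely exercises the bipartite/projection
  path rather than injecting scores directly. Decoys sample targets from
  the unshifted members of three random sets (topping up from the unshifted
  pool), so with a zero effect size true and decoy drugs are statistically
  exchangeable in the DE layer.
* All randomness flows from a single master seed through named substreams
  (genes, sets, catalog, expression), so the same seed yields byte-identical
  bundles and components can be regenerated independently.

What the generator does **not** emulate: transcriptome covariance
structure, batch effects, heavy-tailed noise, dropout, and the
identifier-mapping mess of real catalogs. Passing the planted-recovery
tests therefore shows the machinery is correct and the contextual weighting
carries signal under the model's own assumptions; it does not certify
performance on any real disease dataset.

## Numerical choices and degenerate inputs

* Centrality ties in the result table break by drug id (deterministic
  ordering); ranks are 1-based.
* TSV outputs print 6 significant digits; full precision is kept in memory.
* Duplicate gene rows in expression input collapse by mean (deterministic,
  order-independent); gene identifiers match by exact string after
  whitespace trimming — no alias resolution.
* Catalog filters apply to the raw inputs before intersection with the
  expression universe.
* `A` is symmetrized exactly after the matrix product to eliminate
  floating-point asymmetry (`max(A, Aᵀ)`, a no-op up to rounding).
* All-isolated networks, empty catalogs after filtering, groups with fewer
  than two samples, and p-values outside [0, 1] raise hard errors naming
  the offending entity.

## Scale of the shipped analyses

The test suite and the acceptance script run everything at desk scale —
benchmarks of 50–100 drugs, 150–300 sets, 1,000–2,000 genes, bootstrap
depths of 200–1,000, ten seeds per summary — which the package completes in
well under a minute; these sizes are the package's chosen study conditions
for self-contained, reproducible verification, and all scale knobs are
plain parameters for larger runs.

## Known limitations

* The one-sided `Φ⁻¹(1 − p)` transform scores extreme concordance
  (p → 1) as dysregulation; kept by design, see above.
* Empirical p-values are bounded below by 1/B; FDR resolution is limited
  accordingly, and exact zeros make the smallest adjusted values depend on
  B.
* Column normalization makes centrality sensitive to local weight *shares*
  rather than absolute similarity; drugs in small, tight, disconnected
  cliques can score high without strong absolute evidence. Isolated-drug
  removal mitigates the degenerate end of this.
* No GO-hierarchy awareness: parent/child terms count as independent
  functions in the projection sum.
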