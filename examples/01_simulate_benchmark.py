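"""Generate a synthetic case/control benchmark and write it to disk.

The bundle contains an expression matrix (genes x samples), a phenotype
table, a drug-target catalog, a gene-set collection in GMT format and the
list of planted "true" drugs whose targets sit in disease-enriched sets.
"""

from drugsimnet import BenchmarkSpec, generate_benchmark, write_bundle

spec = BenchmarkSpec(seed=1)
bundle = generate_benchmark(spec)
paths = write_bundle(bundle, "scratch/example_bundle")

print(f"genes:        {len(bundle.expression.gene_ids)}")
print(f"samples:      {len(bundle.expression.sample_ids)} (20 case / 20 control)")
print(f"drugs:        {len(bundle.catalog)} ({len(bundle.true_drugs)} planted true)")
print(f"gene sets:    {len(bundle.sets)}")
print(f"dysregulated: {len(bundle.dysregulated_genes)} genes shifted by {spec.effect_size} sd in cases")
for name, path in paths.items():
    print(f"  {name}: {path}")
# The true drugs' targets concentrate in gene sets enriched for the shifted
# genes; decoy drugs target only unshifted genes.
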