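"""Synthetic case/control benchmarks with a planted disease-contextual signal.

The generator emulates the statistical structure the method exploits: a
subset of genes is transcriptionally shifted in the case group, a handful of
"disease" gene sets are enriched in those shifted genes, and a few "true"
drugs target genes inside those disease sets.  Decoy drugs draw their
targets exclusively from unshifted (null) genes, but through the shared
gene-set collection they still form a connected weak-similarity background,
so the planted drugs must win by capturing diffusion mass, not by being the
only connected nodes.  Disease sets deliberately contain a fraction of null
genes: that gives decoy drugs weak edges into disease terms, which the true
drugs then dominate once differential expression upweights them.

All randomness flows from one master seed through named substreams, so the
same seed always yields a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .io import DrugTargetCatalog, ExpressionDataset, GeneSetCollection


@dataclasses.dataclass
class BenchmarkSpec:
    """Parameters of a synthetic benchmark.

    Defaults give the standard desk-scale benchmark: 2,000 genes measured in
    20 case / 20 control samples, 100 drugs of which 5 are planted true
    drugs, 300 gene sets of which 15 are disease sets, and a case-group mean
    shift of 2.5 within-group standard deviations on 10% of genes.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 20
    n_drugs: int = 100
    n_gene_sets: int = 300
    n_true_drugs: int = 5
    effect_size: float = 2.5
    frac_dysregulated: float = 0.1
    target_set_size_range: tuple[int, int] = (4, 30)
    gene_set_size_range: tuple[int, int] = (6, 30)
    n_disease_sets: int = 15
    disease_set_purity: float = 0.6
    sets_per_drug: int = 3
    disease_sets_per_true: int = 2
    seed: int = 0

    def validate(self) -> None:
        lo_t, hi_t = self.target_set_size_range
        lo_g, hi_g = self.gene_set_size_range
        if not (dio.DRUG_MIN_TARGETS <= lo_t <= hi_t <= dio.DRUG_MAX_TARGETS):
            raise ValueError("target set size range outside the catalog filter bounds")
        if not (dio.SET_MIN_GENES <= lo_g <= hi_g <= dio.SET_MAX_GENES):
            raise ValueError("gene set size range outside the collection filter bounds")
        if self.n_true_drugs > self.n_drugs:
            raise ValueError("more true drugs than drugs")
        if self.n_disease_sets > self.n_gene_sets:
            raise ValueError("more disease sets than gene sets")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if not 0.0 <= self.frac_dysregulated < 1.0:
            raise ValueError("frac_dysregulated must lie in [0, 1)")
        n_dys = round(self.n_genes * self.frac_dysregulated)
        n_null = self.n_genes - n_dys
        if n_dys < max(1, round(self.disease_set_purity * hi_g)):
            raise ValueError("not enough dysregulated genes for the disease sets")
        if n_null < hi_g:
            raise ValueError("not enough null genes for the decoy gene sets")


@dataclasses.dataclass
class BenchmarkBundle:
    expression: ExpressionDataset
    catalog: DrugTargetCatalog
    sets: GeneSetCollection
    true_drugs: set[str]
    dysregulated_genes: set[str]


def _sample_set(rng: np.random.Generator, pool: np.ndarray, size: int) -> list[str]:
    return list(rng.choice(pool, size=size, replace=False))


def generate_benchmark(spec: BenchmarkSpec) -> BenchmarkBundle:
    """Generate a fully reproducible benchmark bundle from ``spec``."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_genes, rng_sets, rng_cat, rng_expr = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    width = max(4, len(str(spec.n_genes)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(spec.n_genes)])
    n_dys = round(spec.n_genes * spec.frac_dysregulated)
    dys_idx = rng_genes.choice(spec.n_genes, size=n_dys, replace=False)
    dys_mask = np.zeros(spec.n_genes, dtype=bool)
    dys_mask[dys_idx] = True
    dys_pool = gene_ids[dys_mask]
    null_pool = gene_ids[~dys_mask]
    dys_set = set(dys_pool)

    # --- gene sets: disease sets mix shifted and null genes, decoy sets are null-only
    lo_g, hi_g = spec.gene_set_size_range
    set_sizes = rng_sets.integers(lo_g, hi_g + 1, size=spec.n_gene_sets)
    set_genes: dict[str, frozenset[str]] = {}
    set_names: dict[str, str] = {}
    sw = max(3, len(str(spec.n_gene_sets)))
    for j in range(spec.n_gene_sets):
        sid = f"GS{j:0{sw}d}"
        size = int(set_sizes[j])
        if j < spec.n_disease_sets:
            k_dys = min(len(dys_pool), max(1, round(spec.disease_set_purity * size)))
            members = _sample_set(rng_sets, dys_pool, k_dys)
            members += _sample_set(rng_sets, null_pool, size - k_dys)
            set_names[sid] = "disease set"
        else:
            members = _sample_set(rng_sets, gene_ids, size)
            set_names[sid] = "background set"
        set_genes[sid] = frozenset(members)
    sets = GeneSetCollection(genes=set_genes, names=set_names)
    set_ids = [f"GS{j:0{sw}d}" for j in range(spec.n_gene_sets)]
    disease_set_ids = set_ids[: spec.n_disease_sets]

    # --- drugs: true drugs target disease sets, decoys target null genes only
    dw = max(3, len(str(spec.n_drugs)))
    drug_ids = [f"D{i:0{dw}d}" for i in range(spec.n_drugs)]
    true_ids = {
        drug_ids[i]
        for i in rng_cat.choice(spec.n_drugs, size=spec.n_true_drugs, replace=False)
    }
    lo_t, hi_t = spec.target_set_size_range
    targets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for drug in drug_ids:
        size = int(rng_cat.integers(lo_t, hi_t + 1))
        if drug in true_ids:
            n_dsets = min(spec.disease_sets_per_true, len(disease_set_ids))
            chosen = list(rng_cat.choice(disease_set_ids, size=n_dsets, replace=False))
            chosen += list(rng_cat.choice(set_ids, size=1))
            pool = sorted(set().union(*(set_genes[s] for s in chosen)))
            top_up = dys_pool
            names[drug] = "planted true drug"
        else:
            chosen = list(
                rng_cat.choice(set_ids, size=min(spec.sets_per_drug, len(set_ids)), replace=False)
            )
            union = set().union(*(set_genes[s] for s in chosen))
            pool = sorted(g for g in union if g not in dys_set)
            top_up = null_pool
            names[drug] = "decoy drug"
        if len(pool) < size:
            extra = [g for g in top_up if g not in pool]
            need = size - len(pool)
            pool = pool + _sample_set(rng_cat, np.array(extra), need)
        targets[drug] = frozenset(_sample_set(rng_cat, np.array(sorted(pool)), size))
    catalog = DrugTargetCatalog(targets=targets, names=names)

    # --- expression: N(0, 1) baseline, case-group mean shift on dysregulated genes
    n = spec.n_samples_per_group
    values = rng_expr.standard_normal((spec.n_genes, 2 * n))
    values[dys_mask, :n] += spec.effect_size
    sample_ids = [f"case{i:03d}" for i in range(n)] + [f"ctrl{i:03d}" for i in range(n)]
    group = pd.Series([dio.CASE] * n + [dio.CONTROL] * n, index=sample_ids, name="group")
    expression = ExpressionDataset(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids), group=group
    )

    return BenchmarkBundle(
        expression=expression,
        catalog=catalog,
        sets=sets,
        true_drugs=true_ids,
        dysregulated_genes=dys_set,
    )


def write_bundle(bundle: BenchmarkBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as the five plain-text files the readers consume.

    Emits ``expression.tsv``, ``phenotype.tsv``, ``drug_targets.tsv``,
    ``gene_sets.gmt`` and ``true_drugs.txt`` under ``out_dir`` and returns
    the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "phenotype": out / "phenotype.tsv",
        "targets": out / "drug_targets.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "true_drugs": out / "true_drugs.txt",
    }
    expr = bundle.expression.values.copy()
    expr.to_csv(paths["expression"], sep="\t", index_label="gene", float_format="%.6g")
    pheno = pd.DataFrame(
        {"sample": bundle.expression.sample_ids, "label": bundle.expression.group.to_numpy()}
    )
    pheno.to_csv(paths["phenotype"], sep="\t", index=False)

    rows = []
    for drug in sorted(bundle.catalog.targets):
        for gene in sorted(bundle.catalog.targets[drug]):
            rows.append((drug, bundle.catalog.name_of(drug), gene))
    pd.DataFrame(rows, columns=["drug_id", "drug_name", "target_gene"]).to_csv(
        paths["targets"], sep="\t", index=False
    )

    with open(paths["gene_sets"], "w", encoding="utf-8") as fh:
        for sid in sorted(bundle.sets.genes):
            members = "\t".join(sorted(bundle.sets.genes[sid]))
            fh.write(f"{sid}\t{bundle.sets.names.get(sid, sid)}\t{members}\n")

    with open(paths["true_drugs"], "w", encoding="utf-8") as fh:
        for drug in sorted(bundle.true_drugs):
            fh.write(drug + "\n")
    return paths
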