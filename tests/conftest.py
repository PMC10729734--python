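import numpy as np
import pandas as pd
import pytest

from drugsimnet.io import CASE, CONTROL, ExpressionDataset
from drugsimnet.synthetic import BenchmarkSpec, generate_benchmark


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully connected planted benchmark for pipeline tests."""
    spec = BenchmarkSpec(
        n_genes=300,
        n_samples_per_group=8,
        n_drugs=12,
        n_gene_sets=30,
        n_true_drugs=2,
        n_disease_sets=5,
        seed=11,
    )
    return generate_benchmark(spec)


@pytest.fixture()
def tiny_expression():
    """5 genes x 6 samples (3 case, 3 control) with one shifted gene."""
    rng = np.random.default_rng(3)
    values = rng.normal(size=(5, 6))
    values[0, :3] += 4.0
    genes = [f"g{i}" for i in range(5)]
    samples = [f"s{i}" for i in range(6)]
    group = pd.Series([CASE] * 3 + [CONTROL] * 3, index=samples)
    return ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples), group=group
    )


def write_expression_files(tmp_path, values, labels, name="expr"):
    """Helper: write a matrix TSV and phenotype TSV; returns the two paths."""
    mpath = tmp_path / f"{name}.tsv"
    ppath = tmp_path / f"{name}_pheno.tsv"
    values.to_csv(mpath, sep="\t", index_label="gene")
    pd.DataFrame({"sample": list(labels.index), "label": list(labels)}).to_csv(
        ppath, sep="\t", index=False
    )
    return mpath, ppath
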