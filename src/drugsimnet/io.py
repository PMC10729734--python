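"""Readers and writers for the pipeline's tabular inputs and outputs.

Three input kinds are supported: a gene x sample expression matrix with a
two-column phenotype table (TSV), a drug -> target-gene catalog (TSV, long
format), and a gene-set collection (GMT).  Size filters mirror the curation
applied to public drug-target and Gene Ontology sources: drugs are kept only
with more than 3 and fewer than 500 targets, gene sets only with more than 5
and fewer than 100 members.  Filters are applied to the raw catalogs before
any intersection with the expression universe.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

#: exclusive bounds on drug target-set size: keep n with 3 < n < 500
DRUG_MIN_TARGETS = 4
DRUG_MAX_TARGETS = 499
#: exclusive bounds on gene-set size: keep m with 5 < m < 100
SET_MIN_GENES = 6
SET_MAX_GENES = 99

#: significant digits used when writing numeric TSV columns
_TSV_PRECISION = 6


@dataclasses.dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with a binary case/control labelling.

    ``values`` is indexed by gene id (rows) and sample id (columns);
    ``group`` maps each sample id to :data:`CASE` or :data:`CONTROL`.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not self.group.index.equals(self.values.columns):
            raise ValueError("phenotype labels do not align with sample columns")
        counts = self.group.value_counts()
        for label in (CASE, CONTROL):
            if counts.get(label, 0) < 2:
                raise ValueError(
                    f"need at least 2 '{label}' samples, got {counts.get(label, 0)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def case_matrix(self) -> np.ndarray:
        return self.values.loc[:, self.group == CASE].to_numpy(float)

    def control_matrix(self) -> np.ndarray:
        return self.values.loc[:, self.group == CONTROL].to_numpy(float)


@dataclasses.dataclass
class DrugTargetCatalog:
    """Drug id -> target gene set mapping with optional display names."""

    targets: dict[str, frozenset[str]]
    names: dict[str, str]

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def name_of(self, drug_id: str) -> str:
        return self.names.get(drug_id, drug_id)


@dataclasses.dataclass
class GeneSetCollection:
    """Gene-set id -> member gene set mapping (e.g. GO Molecular Function)."""

    genes: dict[str, frozenset[str]]
    names: dict[str, str]

    @property
    def set_ids(self) -> list[str]:
        return sorted(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def read_expression(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    case_label: str = CASE,
    control_label: str = CONTROL,
) -> ExpressionDataset:
    """Read an expression TSV and phenotype TSV into an :class:`ExpressionDataset`.

    The matrix file has gene ids in the first column and a header row of
    sample ids.  The phenotype file is a two-column TSV (sample id, label)
    with a header row.  Samples whose label matches neither ``case_label``
    nor ``control_label`` are dropped; labels are recoded to
    ``case``/``control``.  Duplicate gene rows are collapsed by mean.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.strip()
    values.columns = values.columns.astype(str).str.strip()
    if values.index.has_duplicates:
        values = values.groupby(level=0, sort=False).mean()

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if pheno.shape[1] < 2:
        raise ValueError("phenotype file must have two columns (sample, label)")
    pheno = pheno.iloc[:, :2]
    pheno.columns = ["sample", "label"]
    pheno["sample"] = pheno["sample"].str.strip()
    pheno["label"] = pheno["label"].str.strip()
    labels = pheno.set_index("sample")["label"]

    missing = [s for s in values.columns if s not in labels.index]
    if missing:
        raise ValueError(
            f"sample '{missing[0]}' in expression matrix has no phenotype entry"
        )

    recode = {case_label: CASE, control_label: CONTROL}
    keep = [s for s in values.columns if labels[s] in recode]
    values = values[keep]
    group = pd.Series(
        [recode[labels[s]] for s in keep], index=values.columns, name="group"
    )
    return ExpressionDataset(values=values, group=group)


def read_drug_targets(
    path: str | Path,
    min_size: int = DRUG_MIN_TARGETS,
    max_size: int = DRUG_MAX_TARGETS,
) -> DrugTargetCatalog:
    """Read a long-format drug-target TSV and apply the size filter.

    Expected columns: ``drug_id``, optionally ``drug_name``, and
    ``target_gene`` (one row per drug-target pair).  Drugs whose
    deduplicated target set has fewer than ``min_size`` or more than
    ``max_size`` genes are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "drug_id" not in cols or "target_gene" not in cols:
        raise ValueError("drug target file needs 'drug_id' and 'target_gene' columns")
    df = df.rename(columns={v: k for k, v in cols.items()})
    df["drug_id"] = df["drug_id"].str.strip()
    df["target_gene"] = df["target_gene"].str.strip()

    names: dict[str, str] = {}
    if "drug_name" in df.columns:
        for drug_id, sub in df.groupby("drug_id"):
            name = sub["drug_name"].dropna()
            names[drug_id] = str(name.iloc[0]).strip() if len(name) else drug_id

    targets: dict[str, frozenset[str]] = {}
    for drug_id, sub in df.groupby("drug_id"):
        tset = frozenset(sub["target_gene"].dropna())
        if min_size <= len(tset) <= max_size:
            targets[drug_id] = tset
    if not targets:
        raise ValueError("no drugs remain after the target-set size filter")
    names = {d: names.get(d, d) for d in targets}
    return DrugTargetCatalog(targets=targets, names=names)


def read_gene_sets(
    path: str | Path,
    min_size: int = SET_MIN_GENES,
    max_size: int = SET_MAX_GENES,
) -> GeneSetCollection:
    """Read a GMT file (set id, description, member genes) with size filtering."""
    genes: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            set_id, description = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if min_size <= len(members) <= max_size:
                genes[set_id] = members
                names[set_id] = description
    if not genes:
        raise ValueError("no gene sets remain after the size filter")
    return GeneSetCollection(genes=genes, names=names)


def read_drug_list(path: str | Path) -> set[str]:
    """Read a plain-text drug list, one id per line (e.g. known positives)."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    return f"{x:.{_TSV_PRECISION}g}"


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a drug result table as TSV, sorted by descending centrality.

    Expects the columns produced by :func:`drugsimnet.significance.rank_drugs`
    (drug_id, drug_name, centrality_score, p_value, fdr, rank, ...).  Numeric
    columns are written with 6 significant digits; ties in centrality appear
    in drug-id order.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    out = table.sort_values(
        ["centrality_score", "drug_id"], ascending=[False, True]
    ).copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def write_edge_list(
    drug_ids: Iterable[str],
    similarity: np.ndarray,
    path: str | Path,
    min_weight: float = 0.0,
) -> int:
    """Write the upper triangle of a symmetric similarity matrix as an edge TSV.

    Emits rows (drug_a, drug_b, similarity) with drug_a < drug_b
    lexicographically, keeping only edges with similarity strictly greater
    than ``min_weight``.  Returns the number of edges written.
    """
    ids = list(drug_ids)
    sim = np.asarray(similarity, dtype=float)
    if sim.shape != (len(ids), len(ids)):
        raise ValueError("similarity matrix shape does not match drug ids")
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sorted((ids[i], ids[j]))
            w = sim[i, j]
            if w > min_weight:
                rows.append((a, b, w))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\tsimilarity\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{_fmt(w)}\n")
    return len(rows)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an edge-list TSV written by :func:`write_edge_list`."""
    return pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str})


def write_de_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene differential-expression table (gene, p, z, de_score)."""
    out = profile.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index_label="gene")
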