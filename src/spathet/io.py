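"""Readers, writers, and the shared data model.

Formats are the plain-text conventions of the single-cell/spatial field:
Matrix Market coordinate triples with gene/barcode id files (10x layout),
tab-separated tables for spot coordinates, labels and gene annotation,
and GMT for gene sets. Genomic coordinates are 1-based inclusive (GTF
convention); only gene start positions matter downstream, where genes are
ordered along the karyotype for CNV smoothing.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import KARYOTYPE, chrom_rank, logger, normalize_chrom

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_gmt",
    "write_gmt",
    "read_spots",
    "write_spots",
    "read_labels",
    "write_labels",
]


@dataclass
class CountMatrix:
    """Genes x observations matrix of non-negative integer counts.

    ``values`` may be dense (ndarray) or a scipy sparse matrix; rows are
    genes, columns are observations (spots or cells).
    """

    values: "np.ndarray | sp.spmatrix"
    gene_ids: list[str]
    obs_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        n_genes, n_obs = self.values.shape
        if n_genes != len(self.gene_ids) or n_obs != len(self.obs_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.obs_ids)} obs ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if len(set(self.obs_ids)) != n_obs:
            raise ValueError("obs_ids are not unique")
        if self.values.size and (self.values < 0).sum() > 0:
            raise ValueError("count matrix has negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        v = self.values
        return np.asarray(v.todense()) if sp.issparse(v) else np.asarray(v)

    def depths(self) -> np.ndarray:
        """Total counts per observation."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with nonzero counts per observation."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def subset_obs(self, obs_ids: "list[str]") -> "CountMatrix":
        oi = self._obs_index()
        idx = [oi[o] for o in obs_ids]
        v = self.values[:, idx] if not sp.issparse(self.values) else self.values.tocsc()[:, idx]
        return CountMatrix(v, list(self.gene_ids), list(obs_ids))

    def subset_genes(self, gene_ids: "list[str]") -> "CountMatrix":
        gi = self._gene_index()
        idx = [gi[g] for g in gene_ids]
        v = self.values[idx, :] if not sp.issparse(self.values) else self.values.tocsr()[idx, :]
        return CountMatrix(v, list(gene_ids), list(self.obs_ids))

    def _gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def _obs_index(self) -> dict[str, int]:
        return {o: i for i, o in enumerate(self.obs_ids)}

    def concat_obs(self, other: "CountMatrix") -> "CountMatrix":
        """Column-wise concatenation; gene ids must match exactly."""
        if self.gene_ids != other.gene_ids:
            raise ValueError("gene ids differ; cannot concatenate")
        a, b = self.dense(), other.dense()
        return CountMatrix(np.hstack([a, b]), list(self.gene_ids), self.obs_ids + other.obs_ids)


@dataclass
class ExpressionMatrix:
    """Genes x observations matrix of normalized (float) expression."""

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError("expression matrix shape does not match id lists")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_obs(self, obs_ids: "list[str]") -> "ExpressionMatrix":
        oi = {o: i for i, o in enumerate(self.obs_ids)}
        idx = [oi[o] for o in obs_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(obs_ids))

    def subset_genes(self, gene_ids: "list[str]") -> "ExpressionMatrix":
        gi = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [gi[g] for g in gene_ids]
        return ExpressionMatrix(self.values[idx, :], list(gene_ids), list(self.obs_ids))


class GeneSetCollection:
    """Ordered, named gene sets (GMT semantics).

    Set names are unique, sets are non-empty, and genes within a set are
    deduplicated preserving first occurrence.
    """

    def __init__(self, sets: "dict[str, list[str]] | None" = None):
        self._sets: dict[str, list[str]] = {}
        for name, genes in (sets or {}).items():
            self.add(name, genes)

    def add(self, name: str, genes: "list[str]") -> None:
        if name in self._sets:
            raise ValueError(f"duplicate gene set name: {name}")
        deduped = list(dict.fromkeys(str(g) for g in genes))
        if not deduped:
            raise ValueError(f"gene set {name!r} is empty")
        self._sets[name] = deduped

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)

    def items(self):
        return self._sets.items()


# ---------------------------------------------------------------------------
# counts


def _read_ids(path) -> list[str]:
    """One id per line; for multi-column TSVs (10x features file) take col 1."""
    ids = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_counts(matrix_path, genes_path, obs_path) -> CountMatrix:
    """Read a genes x observations count matrix.

    ``matrix_path`` is either Matrix Market coordinate format (10x triple
    layout, genes as rows) or a dense TSV with one gene per row. Duplicate
    gene ids are collapsed by summing their rows.
    """
    genes = _read_ids(genes_path)
    obs = _read_ids(obs_path)
    with open(matrix_path, "rt", encoding="utf-8") as fh:
        head = fh.read(14)
    if head.startswith("%%MatrixMarket"):
        m = scipy.io.mmread(matrix_path)
        values = np.asarray(sp.coo_matrix(m).todense())
    else:
        df = pd.read_csv(matrix_path, sep="\t", header=None)
        values = df.to_numpy()
    if values.shape != (len(genes), len(obs)):
        raise ValueError(
            f"matrix header claims {values.shape} but id files provide "
            f"{len(genes)} genes x {len(obs)} observations"
        )
    if (values < 0).any():
        raise ValueError("negative count entry in matrix")
    if not np.allclose(values, np.round(values)):
        raise ValueError("non-integer count entry in matrix")
    values = np.round(values).astype(np.int64)
    if len(set(genes)) != len(genes):
        # collapse duplicated gene rows by summation (deterministic, lossless)
        order = list(dict.fromkeys(genes))
        pos: dict[str, int] = {g: i for i, g in enumerate(order)}
        collapsed = np.zeros((len(order), values.shape[1]), dtype=np.int64)
        for row, g in zip(values, genes):
            collapsed[pos[g]] += row
        values, genes = collapsed, order
    return CountMatrix(values, genes, obs)


def write_counts(cm: CountMatrix, matrix_path, genes_path, obs_path) -> None:
    """Write a CountMatrix as a Matrix Market triple (integer field)."""
    coo = sp.coo_matrix(cm.dense())
    scipy.io.mmwrite(str(matrix_path), coo, field="integer")
    Path(genes_path).write_text("".join(g + "\n" for g in cm.gene_ids), encoding="utf-8")
    Path(obs_path).write_text("".join(o + "\n" for o in cm.obs_ids), encoding="utf-8")


# ---------------------------------------------------------------------------
# gene annotation

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end"]


def sort_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Karyotype sort: (chromosome in 1..22,X order, start, gene_id)."""
    if ann.empty:
        return ann.reset_index(drop=True)
    key = ann["chromosome"].map(chrom_rank)
    return (
        ann.assign(_k=key)
        .sort_values(["_k", "start", "gene_id"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


def read_gene_annotation(tsv_path) -> pd.DataFrame:
    """Read a gene position table (gene_id, chromosome, start, end).

    Coordinates are 1-based inclusive. Rows are returned sorted in
    karyotype order (chromosomes 1..22, X) by start position; genes on
    unlisted chromosomes (Y, chrM, scaffolds) are dropped with a logged
    count. An empty file yields an empty table.
    """
    try:
        df = pd.read_csv(tsv_path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    if df.shape[1] < 4:
        raise ValueError("gene annotation needs >= 4 columns (gene_id, chromosome, start, end)")
    # tolerate a header row
    if str(df.iloc[0, 0]).lower() in ("gene_id", "gene", "id"):
        df = df.iloc[1:]
    if df.empty:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    ann = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 0].astype(str),
            "chromosome": df.iloc[:, 1].map(normalize_chrom),
            "start": df.iloc[:, 2].astype(np.int64),
            "end": df.iloc[:, 3].astype(np.int64),
        }
    )
    if (ann["start"] > ann["end"]).any():
        bad = ann.loc[ann["start"] > ann["end"], "gene_id"].tolist()
        raise ValueError(f"start > end for genes: {bad[:5]}")
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene annotation records: {dup[:5]}")
    keep = ann["chromosome"].isin(KARYOTYPE)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d genes on unlisted chromosomes", n_drop)
    return sort_annotation(ann.loc[keep])


def write_gene_annotation(ann: pd.DataFrame, tsv_path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(tsv_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated gene ids.

    Set order is preserved; genes within a set are deduplicated.
    """
    coll = GeneSetCollection()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected name, description and >= 1 gene")
            coll.add(fields[0], fields[2:])
    return coll


def write_gmt(coll: GeneSetCollection, path, description: str = "spathet") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in coll.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# spot and label tables

SPOT_COLUMNS = ["obs_id", "section_id", "x", "y"]


def read_spots(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    df = df[SPOT_COLUMNS].copy()
    df["obs_id"] = df["obs_id"].astype(str)
    df["section_id"] = df["section_id"].astype(str)
    if df["obs_id"].duplicated().any():
        raise ValueError("duplicate obs_id in spot table")
    return df


def write_spots(spots: pd.DataFrame, tsv_path) -> None:
    spots[SPOT_COLUMNS].to_csv(tsv_path, sep="\t", index=False)


def read_labels(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if not {"obs_id", "label"}.issubset(df.columns):
        raise ValueError("label table needs obs_id and label columns")
    df = df[["obs_id", "label"]].copy()
    if df["obs_id"].duplicated().any():
        raise ValueError("observation labeled more than once")
    return df


def write_labels(labels: pd.DataFrame, tsv_path) -> None:
    labels[["obs_id", "label"]].to_csv(tsv_path, sep="\t", index=False)
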