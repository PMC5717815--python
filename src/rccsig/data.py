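"""Core data containers, readers/writers and the packaged 44-gene panel.

The pipeline works on gene-level expression matrices (genes x samples,
log2 scale by convention), per-sample annotation tables carrying the
histological subtype label, batch and cohort, and gene signatures — ordered
gene panels with optional per-class provenance (which one-vs-all ranking
contributed the gene, and at which rank).

Gene identity throughout the package is the uppercase HGNC-style symbol
string; no alias resolution is attempted.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the five histological classes handled by the pipeline
SUBTYPES = ("ccRCC", "pRCC", "chRCC", "oncocytoma", "normal")

PLATFORMS = ("microarray", "rnaseq", "qpcr", "synthetic")
SCALES = ("raw", "log2", "zscored")

_FIXTURE_NAME = "signature44.tsv"
_FIXTURE_SHA256 = "bb858fa1dce033b148529861fba7d9c2e8aa48a525c2d14b460334496f31ea7b"


class FormatError(ValueError):
    """Malformed input file (bad header, dimension mismatch, bad cell)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression table.

    Parameters
    ----------
    gene_symbols : list of str
        Unique uppercase gene symbols, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; log2 scale by pipeline convention.
    platform : str
        One of ``microarray``, ``rnaseq``, ``qpcr``, ``synthetic``.
    scale : str
        One of ``raw``, ``log2``, ``zscored``.
    """

    gene_symbols: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform: str = "synthetic"
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.gene_symbols = [str(g).upper() for g in self.gene_symbols]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_symbols), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_symbols)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("duplicate gene symbols")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise ValueError("NaN values are not allowed after ingestion")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_symbols, columns=self.sample_ids)

    def copy_with(self, *, values: np.ndarray | None = None, scale: str | None = None,
                  gene_symbols: list[str] | None = None,
                  sample_ids: list[str] | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            gene_symbols=list(self.gene_symbols if gene_symbols is None else gene_symbols),
            sample_ids=list(self.sample_ids if sample_ids is None else sample_ids),
            values=np.array(self.values if values is None else values, dtype=float),
            platform=self.platform,
            scale=self.scale if scale is None else scale,
        )

    def restrict_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Return the sub-matrix over `genes` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_symbols)}
        missing = [g for g in genes if g.upper() not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        rows = [index[g.upper()] for g in genes]
        return self.copy_with(values=self.values[rows], gene_symbols=[g.upper() for g in genes])


@dataclass
class SampleAnnotation:
    """Per-sample metadata table: subtype label, batch and cohort."""

    table: pd.DataFrame  # columns: sample_id, label, batch, cohort

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("label", "batch", "cohort"):
            if col not in df.columns:
                df[col] = ""
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in annotation")
        present = df["label"].fillna("").astype(str)
        bad = sorted(set(present) - set(SUBTYPES) - {""})
        if bad:
            raise ValueError(f"labels outside the subtype vocabulary: {bad}")
        self.table = df.reset_index(drop=True)

    def labels_for(self, sample_ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.table["sample_id"], self.table["label"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples missing from annotation: {missing[:5]}")
        return np.array([lookup[s] for s in sample_ids], dtype=object)

    def batches_for(self, sample_ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.table["sample_id"], self.table["batch"]))
        missing = [s for s in sample_ids if s not in lookup or lookup[s] in ("", None)
                   or (isinstance(lookup.get(s), float) and np.isnan(lookup[s]))]
        if missing:
            raise ValueError(f"batch label missing for samples: {missing[:5]}")
        return np.array([str(lookup[s]) for s in sample_ids], dtype=object)


@dataclass
class GeneSignature:
    """Ordered gene panel with optional per-class provenance.

    ``entries`` is an ordered list of ``(gene_symbol, source_class, rank)``
    tuples; ``rank`` is the within-class position (1 = best) of the gene in
    the one-vs-all ranking that contributed it. The packaged 44-gene panel
    ships without provenance (source_class/rank of None): the published
    table lists the genes but not which subtype's ranking produced each.
    """

    entries: list[tuple[str, str | None, int | None]]
    k: int = 10

    def __post_init__(self) -> None:
        norm = []
        for gene, cls, rank in self.entries:
            gene = str(gene).upper()
            if rank is not None:
                rank = int(rank)
                if not (1 <= rank <= self.k):
                    raise ValueError(f"rank {rank} outside 1..{self.k} for {gene}")
            norm.append((gene, cls, rank))
        if not norm:
            raise ValueError("empty signature")
        self.entries = norm

    @property
    def unique_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for gene, _, _ in self.entries:
            seen.setdefault(gene)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_symbol", "source_class", "rank"])


# ---------------------------------------------------------------------------
# readers / writers

def _frame_to_matrix(df: pd.DataFrame, platform: str, scale: str,
                     source: str) -> ExpressionMatrix:
    if df.columns.duplicated().any():
        raise FormatError(f"{source}: duplicate sample id in header")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().values)[0]
        raise FormatError(
            f"{source}: non-numeric value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    symbols = [str(g).upper() for g in df.index]
    numeric.index = symbols
    if len(set(symbols)) != len(symbols):
        # collapse duplicate symbols by per-gene maximum, keep first-seen order
        logger.info("collapsing %d duplicate gene symbols by per-gene maximum",
                    len(symbols) - len(set(symbols)))
        order = list(dict.fromkeys(symbols))
        numeric = numeric.groupby(level=0, sort=False).max().loc[order]
    return ExpressionMatrix(
        gene_symbols=list(numeric.index),
        sample_ids=[str(c) for c in numeric.columns],
        values=numeric.values,
        platform=platform,
        scale=scale,
    )


def _check_sample_header(sample_ids: list[str], path) -> None:
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample id(s) in header: {dupes[:5]}")


def read_expression_matrix(path, format: str = "tsv", *, platform: str = "synthetic",
                           scale: str = "log2") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    TSV dialect: first column gene symbols (header cell arbitrary, "gene"
    by convention), remaining header cells sample ids. GCT 1.2: "#1.2"
    version line, dims line, then Name/Description columns before samples.
    Duplicate gene symbols are collapsed by per-gene maximum.
    """
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        _check_sample_header(header[1:], path)
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no sample columns")
        return _frame_to_matrix(df, platform, scale, str(path))
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            header_line = fh.readline().rstrip("\n").split("\t")
            _check_sample_header(header_line[2:], path)
            df = pd.read_csv(fh, sep="\t", dtype=str, names=header_line)
        if df.shape[0] != n_genes or df.shape[1] - 2 != n_samples:
            raise FormatError(
                f"{path}: GCT dims line says {n_genes}x{n_samples} but file has "
                f"{df.shape[0]} rows x {df.shape[1] - 2} sample columns"
            )
        df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
        return _frame_to_matrix(df, platform, scale, str(path))
    raise ValueError(f"unknown format {format!r}")


def write_expression_matrix(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write a matrix as TSV or GCT 1.2; round-trips values to 1e-6."""
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValueError("refusing to write an empty matrix")
    df = matrix.to_frame()
    if format == "tsv":
        df.to_csv(path, sep="\t", index_label="gene", float_format="%.6f")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format="%.6f")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotation(path) -> SampleAnnotation:
    """Read a sample annotation TSV (columns sample_id, label, batch, cohort)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: annotation requires a sample_id column")
    return SampleAnnotation(df)


def write_annotation(ann: SampleAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_signature(path) -> GeneSignature:
    """Read a signature TSV (gene_symbol, source_class, rank; extras ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_symbol" not in df.columns:
        raise FormatError(f"{path}: signature requires a gene_symbol column")
    entries = []
    for _, row in df.iterrows():
        cls = row.get("source_class")
        rank = row.get("rank")
        cls = None if cls in (None, "") or pd.isna(cls) else str(cls)
        rank = None if rank in (None, "") or pd.isna(rank) else int(rank)
        entries.append((row["gene_symbol"], cls, rank))
    return GeneSignature(entries)


def write_signature(sig: GeneSignature, path) -> None:
    sig.to_frame().to_csv(path, sep="\t", index=False)


def load_signature_fixture() -> GeneSignature:
    """Load the packaged 44-gene renal-tumour classification panel.

    The panel was derived by one-vs-all SVM-RFE over five histological
    classes (top 10 per class, duplicates removed, 44 unique genes). The
    fixture file is integrity-checked against a stored SHA-256 digest.
    """
    resource = importlib.resources.files("rccsig") / "_fixtures" / _FIXTURE_NAME
    raw = resource.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"signature fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    df = pd.read_csv(io.StringIO(raw.decode()), sep="\t", dtype=str)
    entries = [(row["gene_symbol"], None, None) for _, row in df.iterrows()]
    return GeneSignature(entries)


def align_by_genes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the common gene set, in a shared order.

    The common set is the case-insensitive intersection of all symbol sets;
    output order is the first matrix's order restricted to the intersection.
    Dropped-gene counts per matrix are logged.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to align")
    common = set(matrices[0].gene_symbols)
    for m in matrices[1:]:
        common &= set(m.gene_symbols)
    if not common:
        raise ValueError("empty gene intersection across matrices")
    order = [g for g in matrices[0].gene_symbols if g in common]
    out = []
    for m in matrices:
        dropped = m.n_genes - len(order)
        if dropped:
            logger.info("align_by_genes: dropping %d genes from a %d-gene matrix",
                        dropped, m.n_genes)
        out.append(m.restrict_genes(order))
    return out
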