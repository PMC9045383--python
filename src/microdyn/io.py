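"""Readers, writers and containers for the pipeline's standard artifacts.

The pipeline's root input is an OTU count table in the classic QIIME TSV
dialect (OTUs as rows, first column ``#OTU ID``), accompanied by a sample
metadata table, a Greengenes/Silva-style taxonomy map, a rooted newick tree
and a cytokine concentration table. All readers accept gzip-compressed
input transparently (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

METADATA_COLUMNS = ("subject", "time_point", "phase", "environment", "gender")


class FormatError(ValueError):
    """Malformed input file (bad value, duplicate id, broken cross-reference)."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class OtuTable:
    """Integer OTU count matrix (OTUs x samples) with per-sample metadata.

    ``counts`` is a DataFrame indexed by OTU id with sample ids as columns;
    ``metadata`` is indexed by sample id with columns
    subject / time_point / phase / environment / gender.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts, meta = self.counts, self.metadata
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if (counts.values < 0).any():
            otu_i, samp_i = np.argwhere(counts.values < 0)[0]
            raise FormatError(
                f"negative count at OTU {counts.index[otu_i]!r}, "
                f"sample {counts.columns[samp_i]!r}"
            )
        missing = [s for s in counts.columns if s not in meta.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        absent_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if absent_cols:
            raise FormatError(f"metadata missing columns: {absent_cols}")
        zero = counts.sum(axis=0)
        zero = zero[zero <= 0]
        if len(zero):
            raise FormatError(f"samples with zero total count: {list(zero.index)}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, subject: str) -> pd.DataFrame:
        """Metadata rows of one subject, ordered by time point."""
        sub = self.metadata[self.metadata["subject"] == subject]
        if sub.empty:
            raise KeyError(f"unknown subject: {subject!r}")
        return sub.sort_values("time_point")

    def fractions(self) -> pd.DataFrame:
        """Per-sample fractional abundances (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)


@dataclass
class TaxonomyMap:
    """OTU id -> ordered lineage (kingdom..species, at most 7 ranks)."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            if len(lin) > len(RANKS):
                raise FormatError(f"lineage of {otu!r} has more than 7 ranks")

    def label(self, otu_id: str, rank: str) -> str | None:
        """Taxon label of ``otu_id`` at ``rank``, or None when unassigned."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if otu_id not in self.lineages:
            raise KeyError(f"OTU {otu_id!r} not in taxonomy")
        lin = self.lineages[otu_id]
        i = RANKS.index(rank)
        if i >= len(lin):
            return None
        name = lin[i]
        # strip the rank prefix; empty remainder means unassigned
        if name.startswith(RANK_PREFIXES[i]):
            name = name[len(RANK_PREFIXES[i]):]
        return name or None


@dataclass
class CytokineTable:
    """Sample x cytokine concentration matrix (assay units, nonnegative)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise FormatError("negative cytokine concentration")

    @property
    def cytokines(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# OTU table + metadata

def read_otu_table(path: str | Path, metadata_path: str | Path) -> OtuTable:
    """Read a QIIME-classic OTU TSV and its metadata TSV into an OtuTable."""
    with _open_text(path) as fh:
        counts = pd.read_csv(fh, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = None
    counts.columns = counts.columns.astype(str)
    for j, col in enumerate(counts.columns):
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            row = counts.index[vals.isna().to_numpy().argmax()]
            raise FormatError(f"non-numeric count at OTU {row!r}, sample {col!r}")
        counts[col] = vals
    if (counts.values < 0).any():
        otu_i, samp_i = np.argwhere(counts.values < 0)[0]
        raise FormatError(
            f"negative count at OTU {counts.index[otu_i]!r}, "
            f"sample {counts.columns[samp_i]!r}"
        )
    counts = counts.astype(np.int64)
    meta = read_metadata(metadata_path)
    table = OtuTable(counts, meta)
    logger.info(
        "read OTU table: %d OTUs x %d samples", len(table.otu_ids), len(table.sample_ids)
    )
    return table


def write_otu_table(table: OtuTable, path: str | Path, metadata_path: str | Path | None = None) -> None:
    with _open_text(path, "wt") as fh:
        out = table.counts.copy()
        out.index.name = "#OTU ID"
        out.to_csv(fh, sep="\t")
    if metadata_path is not None:
        write_metadata(table.metadata, metadata_path)


def read_metadata(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        meta = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    meta.index.name = None
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        out = meta.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy

def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a 2-column TSV (otu_id, semicolon-separated lineage)."""
    lineages: dict[str, tuple[str, ...]] = {}
    with _open_text(path) as fh:
        header = fh.readline()
        if not header:
            raise FormatError("empty taxonomy file")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"taxonomy line {line_no}: expected 2 columns")
            otu, lineage = parts
            if otu in lineages:
                raise FormatError(f"duplicate OTU {otu!r} in taxonomy")
            lineages[otu] = tuple(x.strip() for x in lineage.split(";"))
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, lin in tax.lineages.items():
            fh.write(f"{otu}\t{';'.join(lin)}\n")


# ---------------------------------------------------------------------------
# Tree

def read_tree(path: str | Path) -> TreeNode:
    """Parse a rooted newick tree; missing branch lengths default to 0."""
    with _open_text(path) as fh:
        text = fh.read()
    return parse_newick(text)


def parse_newick(text: str) -> TreeNode:
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in newick text")
    try:
        tree = TreeNode.read([text], format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"newick parse error: {exc}") from exc
    defaulted = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            defaulted += 1
    if tree.length is None:
        tree.length = 0.0
    if defaulted:
        logger.warning("defaulted %d missing branch lengths to 0", defaulted)
    labels = [t.name for t in tree.tips()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        tree.write(fh, format="newick")


# ---------------------------------------------------------------------------
# Cytokines

def read_cytokines(path: str | Path) -> CytokineTable:
    with _open_text(path) as fh:
        values = pd.read_csv(fh, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    return CytokineTable(values)


def write_cytokines(table: CytokineTable, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        out = table.values.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Rank aggregation

def aggregate_to_rank(table: OtuTable, taxonomy: TaxonomyMap, rank: str) -> OtuTable:
    """Sum counts over OTUs sharing a taxon label at ``rank``.

    OTUs without a label at the rank (or absent from the taxonomy) are pooled
    into an ``unclassified`` row, so per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = []
    for otu in table.otu_ids:
        try:
            lab = taxonomy.label(otu, rank)
        except KeyError:
            lab = None
        labels.append(lab if lab is not None else "unclassified")
    agg = table.counts.groupby(pd.Index(labels, name=rank)).sum()
    return OtuTable(agg, table.metadata)
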