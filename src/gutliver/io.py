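"""Readers and writers for the pipeline's TSV dialects.

All tables are tab-separated UTF-8 with a header row; missing values are
written as ``"."``. Feature tables are stored taxa-in-rows (first column the
taxon id, remaining columns samples) as is conventional for 16S count tables,
and transposed to samples x taxa on load. Taxonomy lineages accept both plain
semicolon-delimited strings and the ``d__;p__;c__;o__;f__;g__`` prefix dialect.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .tables import (
    META_COLUMNS,
    RANKS,
    UNCLASSIFIED_PREFIX,
    CompartmentTable,
    SchemaError,
)

NA_TOKEN = "."
_RANK_PREFIXES = {"d": "domain", "k": "domain", "p": "phylum", "c": "class",
                  "o": "order", "f": "family", "g": "genus"}


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load a taxa-in-rows count TSV into a samples x taxa integer frame."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicate taxon id(s): {dup}")
    if df.isna().any().any():
        raise SchemaError(f"{path}: missing values in count table")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.array_equal(vals, np.floor(vals)):
        raise SchemaError(f"{path}: counts must be integers")
    return df.T.astype(np.int64)


def write_feature_table(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a samples x taxa frame as a taxa-in-rows TSV."""
    out = counts.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN])
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: metadata must have a sample_id column")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: metadata missing required column(s): {missing}")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-delimited lineage, with or without rank prefixes.

    Labels missing at genus rank are replaced by ``unclassified:<parent>`` where
    ``<parent>`` is the nearest named ancestor; intermediate blanks become empty
    strings (they only matter if one aggregates to that rank).
    """
    fields = [f.strip() for f in str(lineage).split(";")]
    out: dict[str, str] = {}
    for i, f in enumerate(fields):
        if len(f) >= 3 and f[1:3] == "__" and f[0].lower() in _RANK_PREFIXES:
            rank, label = _RANK_PREFIXES[f[0].lower()], f[3:]
        else:
            rank = RANKS[i] if i < len(RANKS) else None
            label = f
        if rank is not None:
            out[rank] = label
    parent = ""
    for rank in RANKS:
        label = out.get(rank, "")
        if label:
            parent = label
        elif rank == "genus":
            out[rank] = f"{UNCLASSIFIED_PREFIX}{parent or 'root'}"
    return out


def read_taxonomy(path: str | os.PathLike) -> pd.DataFrame:
    """Load a two-column taxon id / lineage TSV into a taxon x rank frame."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: taxonomy needs taxon id and lineage columns")
    ids, lineages = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        raise SchemaError(f"{path}: duplicate taxon id(s) in taxonomy")
    rows = [parse_lineage(lin) for lin in lineages]
    out = pd.DataFrame(rows, index=pd.Index(ids, name="taxon_id"))
    return out.reindex(columns=list(RANKS)).fillna("")


def write_taxonomy(lineage: pd.DataFrame, path: str | os.PathLike) -> None:
    prefixes = {"domain": "d__", "phylum": "p__", "class": "c__",
                "order": "o__", "family": "f__", "genus": "g__"}
    parts = []
    for rank in lineage.columns:
        col = lineage[rank].astype(str).replace("nan", "")
        col = col.where(~col.str.startswith(UNCLASSIFIED_PREFIX), "")
        parts.append(prefixes.get(rank, "") + col)
    joined = parts[0].str.cat(parts[1:], sep=";")
    pd.DataFrame({"taxon_id": lineage.index, "lineage": joined}).to_csv(
        path, sep="\t", index=False)


def read_gene_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Load a genes x samples count TSV (first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.array_equal(vals, np.floor(vals)):
        raise SchemaError(f"{path}: gene counts must be integers")
    if (vals < 0).any():
        raise SchemaError(f"{path}: gene counts must be nonnegative")
    return df.astype(np.int64)


def write_gene_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def load_compartment_table(feature_path, metadata_path, taxonomy_path=None) -> CompartmentTable:
    """Assemble a :class:`CompartmentTable` from its three TSV files."""
    counts = read_feature_table(feature_path)
    meta = read_metadata(metadata_path)
    orphans = counts.index.difference(meta.index)
    if len(orphans):
        raise SchemaError(f"samples absent from metadata: {orphans.tolist()[:5]}")
    lineage = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    return CompartmentTable(counts=counts, meta=meta.loc[counts.index], lineage=lineage)


def write_distance_matrix(dm: pd.DataFrame, path: str | os.PathLike) -> None:
    out = dm.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_distance_matrix(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
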