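"""Readers and writers for the pipeline's interchange formats.

Conventions: tab-separated UTF-8 text, ``#`` comment lines, no quoting;
gene/sample ids are opaque strings. Gzipped files (``.gz``) are accepted
transparently by the expression reader. Networks round-trip through weighted
edge-list TSV or GraphML.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_expression", "write_expression",
    "read_matrix", "write_matrix",
    "read_network_tsv", "write_network_tsv",
    "read_network_graphml", "write_network_graphml",
    "read_clinical", "write_clinical",
    "read_mutations", "write_mutations",
    "read_drug_targets", "write_drug_targets",
    "read_ic50", "write_ic50",
    "write_gmt", "read_gmt",
]

_TSV = dict(sep="\t", comment="#", float_precision="round_trip")


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene ids, header sample ids."""
    df = pd.read_csv(path, index_col=0, **_TSV)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids: {dups[:10]}")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = body.columns[body.isna().any()].tolist()
        raise ValueError(f"non-numeric or missing cells in columns: {bad[:10]}")
    return body.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_matrix(path) -> pd.DataFrame:
    """Square gene x gene matrix with id header row and column."""
    df = pd.read_csv(path, index_col=0, **_TSV).astype(float)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix row and column ids differ")
    return df


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="gene")


def read_network_tsv(path) -> nx.Graph:
    """Edge-list TSV with columns gene_a, gene_b [, weight]."""
    df = pd.read_csv(path, **_TSV)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("edge list needs columns gene_a, gene_b")
    g = nx.Graph()
    dupes = 0
    for row in df.itertuples(index=False):
        u, v = str(row.gene_a), str(row.gene_b)
        if u == v:
            raise ValueError(f"self-loop on {u}")
        if g.has_edge(u, v):
            dupes += 1
        w = float(getattr(row, "weight", 1.0))
        g.add_edge(u, v, weight=w)
    if dupes:
        warnings.warn(f"{dupes} duplicate edge(s) collapsed", stacklevel=2)
    return g


def write_network_tsv(g: nx.Graph, path) -> None:
    rows = [(u, v, d.get("weight", 1.0)) for u, v, d in sorted(g.edges(data=True))]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(path, sep="\t", index=False)


def read_network_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop on {u}")
        h.add_edge(u, v, weight=float(d.get("weight", 1.0)))
    return h


def write_network_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def read_clinical(path) -> pd.DataFrame:
    """patient_id, tumour_id, time (days >= 0), event in {0, 1}."""
    df = pd.read_csv(path, **_TSV)
    need = {"patient_id", "tumour_id", "time", "event"}
    if not need <= set(df.columns):
        raise ValueError(f"clinical table needs columns {sorted(need)}")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient ids")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0/1")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mutations(path) -> pd.DataFrame:
    """Either tidy (cluster_id, gene, mutated) or MAF-lite (gene, sample, ...)."""
    df = pd.read_csv(path, **_TSV)
    if {"cluster_id", "gene", "mutated"} <= set(df.columns):
        df["mutated"] = df["mutated"].astype(bool)
        return df
    if "gene" in df.columns:
        out = pd.DataFrame({"cluster_id": 0, "gene": df["gene"].unique()})
        out["mutated"] = True
        return out
    raise ValueError("unrecognized mutation table format")


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_drug_targets(path) -> pd.DataFrame:
    p = Path(path)
    if p.suffix == ".gmt":
        rows = []
        for line in p.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                rows += [(parts[0], g) for g in parts[2:] if g]
        return pd.DataFrame(rows, columns=["drug_id", "gene"])
    df = pd.read_csv(path, **_TSV)
    if not {"drug_id", "gene"} <= set(df.columns):
        raise ValueError("drug target table needs columns drug_id, gene")
    return df


def write_drug_targets(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ic50(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_TSV)
    if not {"cell_line", "drug_id", "ic50"} <= set(df.columns):
        raise ValueError("IC50 table needs columns cell_line, drug_id, ic50")
    if (df["ic50"] <= 0).any():
        raise ValueError("IC50 values must be positive")
    if df.duplicated(["cell_line", "drug_id"]).any():
        raise ValueError("duplicate (cell_line, drug) pairs")
    return df


def write_ic50(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_gmt(sets: dict, path, description: str = "netsig") -> None:
    """Gene sets as GMT lines: name <tab> description <tab> genes..."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([str(name), description, *map(str, genes)]) + "\n")


def read_gmt(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            out[parts[0]] = list(parts[2:])
    return out
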