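"""Readers and writers for the tabular formats used across the pipeline.

All formats are strict tab-separated UTF-8 text; lines starting with ``#``
are comments; missing values are spelled ``NA``. Every writer/reader pair
round-trips (``read(write(x)) == x``).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO

NA = "NA"


# ---------------------------------------------------------------- expression

def write_expression(path, values: pd.DataFrame) -> None:
    """Write a genes x samples matrix; first column ``gene``."""
    values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path!s}: {dup}")
    return df


def write_metadata(path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", index_col="sample")
    required = {"condition", "timepoint", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


# ----------------------------------------------------------------- edge lists

def write_edgelist(path, graph: nx.Graph, weight: str = "confidence") -> None:
    with open(path, "w") as fh:
        fh.write(f"protein_a\tprotein_b\t{weight}\n")
        for u, v, d in sorted(graph.edges(data=True)):
            a, b = sorted((str(u), str(v)))
            fh.write(f"{a}\t{b}\t{d.get(weight, 1.0):.6g}\n")


def read_edgelist(path, weight: str = "confidence") -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path!s}: expected at least two columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            w = float(parts[2]) if len(parts) > 2 else 1.0
            if w <= 0:
                raise ValueError(f"{path!s}:{lineno}: non-positive confidence {w}")
            g.add_edge(parts[0], parts[1], **{weight: w})
    return g


def write_network(path, edges: pd.DataFrame) -> None:
    """GGM edge table: gene_a, gene_b, pcor, local_fdr."""
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_network(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ------------------------------------------------------------------------ GMT

def write_gmt(path, sets: dict[str, tuple[str, list[str]]]) -> None:
    """``sets`` maps name -> (description, members)."""
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path!s}:{lineno}: GMT line needs >=3 fields")
            name, desc, members = parts[0], parts[1], parts[2:]
            seen: list[str] = []
            for m in members:
                if m in seen:
                    warnings.warn(f"{path!s}:{lineno}: duplicate gene {m!r} "
                                  f"in set {name!r}; deduplicated")
                else:
                    seen.append(m)
            out[name] = (desc, seen)
    return out


# ---------------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


# ------------------------------------------------------------------ genotypes

def write_genotypes(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="subject", na_rep=NA)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="subject",
                     na_values=[NA], keep_default_na=False)
    bad = ~(df.isna() | df.isin([0, 1, 2]))
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        line = df.index.get_loc(row) + 2  # header line is 1
        raise ValueError(
            f"{path!s}:{line}: invalid genotype value {df.loc[row, col]!r} "
            f"for SNP {col} (expected 0/1/2/NA)")
    return df


def write_phenotype(path, pheno: pd.Series | pd.DataFrame) -> None:
    pheno.to_csv(path, sep="\t", index_label="subject", na_rep=NA)


def read_phenotype(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="subject",
                       na_values=[NA], keep_default_na=False)


# ------------------------------------------------------------ powergraph JSON

def write_powergraph(path, pg) -> None:
    Path(path).write_text(json.dumps(pg.to_dict(), indent=1, sort_keys=True))


def read_powergraph(path):
    from .powergraph import PowerGraph
    return PowerGraph.from_dict(json.loads(Path(path).read_text()))
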