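"""Readers and writers for every on-disk format the pipeline touches.

Expression matrices, clinical tables, drug tables and edge lists are plain
TSV; gene sets are GMT; result manifests are JSON.  All readers validate the
invariants of the containers they return (unique identifiers, non-negative
survival times, binary event flags) and all writer/reader pairs round-trip
losslessly.

Containers are deliberately plain: an expression matrix is a pandas
DataFrame indexed by gene with one column per sample, a clinical table is a
DataFrame with columns ``sample_id``/``time``/``event``, and a network is a
:class:`networkx.Graph`.  Gene identifiers are opaque strings; no symbol/ID
mapping is attempted.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_drugs",
    "write_drugs",
    "read_network",
    "write_network",
    "write_results",
]

CLINICAL_COLUMNS = ("sample_id", "time", "event")


@dataclasses.dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GO-BP style terms or any other annotation source).

    ``sets`` maps a unique term id to a frozen set of member gene ids and
    ``names`` maps the same ids to a human-readable description.
    """

    sets: dict[str, frozenset[str]]
    names: dict[str, str]

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]

    def items(self):
        return self.sets.items()


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise ValueError(f"duplicate {what}: {v!r}")
        seen.add(v)


def read_expression(path: str | Path, missing_policy: str = "drop-gene") -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    The file has a header row of sample ids; the first column holds gene ids.
    ``missing_policy`` is ``"drop-gene"`` (remove any gene with a missing
    value) or ``"impute-row-mean"``.  Row and column order follow the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    _check_unique(df.index, "gene id")
    _check_unique(df.columns, "sample id")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
    df = df.astype(float)
    if missing_policy == "drop-gene":
        df = df.loc[df.notna().all(axis=1)]
    elif missing_policy == "impute-row-mean":
        means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(means[row.name]), axis=1)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, time, event.

    ``time`` is a non-negative survival/censoring time (units are whatever
    the source used; the pipeline never converts them) and ``event`` is 1
    for an observed death and 0 for censoring.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    df = df[list(CLINICAL_COLUMNS)]
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    _check_unique(df["sample_id"], "sample id")
    if (df["time"] < 0).any():
        bad = df.loc[df["time"] < 0, "sample_id"].iloc[0]
        raise ValueError(f"negative survival time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "sample_id"].iloc[0]
        raise ValueError(f"event flag outside {{0,1}} for sample {bad!r}")
    df = df.copy()
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical[list(CLINICAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term id, description, then member genes, tab-separated."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: need term, description and >=1 gene")
            term, desc, members = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ValueError(f"duplicate term id: {term!r}")
            sets[term] = frozenset(m for m in members if m)
            names[term] = desc
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in collection.sets:
            genes = sorted(collection.sets[term])
            fh.write("\t".join([term, collection.names.get(term, "")] + genes) + "\n")


def read_drugs(targets_path: str | Path, indications_path: str | Path) -> pd.DataFrame:
    """Read drug target and indication tables into one drug table.

    ``targets_path`` is a two-column TSV (drug_id, target gene), one pair per
    row; the same pair may appear several times when several source databases
    list it — targets are the union across sources.  ``indications_path`` is
    a TSV with columns drug_id and is_cancer (0/1).  Drugs present in the
    indication table but with no listed target get an empty target set (they
    can never be selected by a screen).
    """
    tgt = pd.read_csv(targets_path, sep="\t", dtype=str)
    if list(tgt.columns[:2]) != ["drug_id", "target"]:
        raise ValueError("drug target table must have columns drug_id, target")
    ind = pd.read_csv(indications_path, sep="\t", dtype={"drug_id": str})
    if "drug_id" not in ind.columns or "is_cancer" not in ind.columns:
        raise ValueError("indication table must have columns drug_id, is_cancer")
    _check_unique(ind["drug_id"], "drug id")
    if not ind["is_cancer"].isin([0, 1]).all():
        raise ValueError("is_cancer must be 0 or 1")
    targets = tgt.groupby("drug_id")["target"].agg(lambda s: frozenset(s))
    table = ind.set_index("drug_id")
    table["targets"] = [targets.get(d, frozenset()) for d in table.index]
    table["is_cancer"] = table["is_cancer"].astype(int)
    return table[["targets", "is_cancer"]]


def write_drugs(drugs: pd.DataFrame, targets_path: str | Path, indications_path: str | Path) -> None:
    rows = [
        {"drug_id": drug, "target": gene}
        for drug, tset in drugs["targets"].items()
        for gene in sorted(tset)
    ]
    pd.DataFrame(rows, columns=["drug_id", "target"]).to_csv(targets_path, sep="\t", index=False)
    ind = drugs.reset_index()[["drug_id", "is_cancer"]]
    ind.to_csv(indications_path, sep="\t", index=False)


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write an undirected simple graph as a two-column TSV edge list.

    Each edge appears exactly once with lexicographically ordered endpoints;
    edges are sorted so output is deterministic.  Isolated nodes are not
    representable in an edge list and are dropped.
    """
    edges = sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges())
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_network(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    net = nx.Graph()
    net.add_edges_from(df.itertuples(index=False, name=None))
    return net


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj) if isinstance(obj, (list, tuple)) else sorted(obj, key=str)
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    return obj


def write_results(result, path: str | Path) -> None:
    """Serialize any pipeline result (dataclass, dict, DataFrame) to JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
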