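"""Kinase-substrate network export.

Maps differentially phosphorylated substrates to the kinase putatively
responsible for each phosphorylation event (from the chip annotation table)
and exports a typed edge list for downstream network tools. Annotations come
exclusively from the local layout file; no live database queries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import networkx as nx
import pandas as pd

from .containers import ChipLayout
from .differential import CLASS_DOWN, CLASS_UP, DifferentialRecord


@dataclass(frozen=True, order=True)
class KinaseEdge:
    source: str      # kinase gene name
    target: str      # substrate id
    direction: str   # up | down (the substrate's differential class)
    weight: float    # |log2 fold change|


def build_edges(
    records: Sequence[DifferentialRecord],
    layout: ChipLayout,
    include_classes: frozenset[str] | set[str] = frozenset({CLASS_UP, CLASS_DOWN}),
) -> tuple[list[KinaseEdge], list[str]]:
    """One deduplicated edge per (annotated kinase, selected substrate).

    Returns (edges, orphans): substrates in the selected classes that lack a
    kinase annotation are reported separately as orphans.
    """
    kinases = layout.kinase_map()
    edges: dict[tuple[str, str], KinaseEdge] = {}
    orphans: list[str] = []
    for r in records:
        if r.class_label not in include_classes:
            continue
        kin = kinases.get(r.substrate_id)
        if kin is None:
            orphans.append(r.substrate_id)
            continue
        key = (kin, r.substrate_id)
        if key not in edges:
            edges[key] = KinaseEdge(
                source=kin, target=r.substrate_id, direction=r.class_label,
                weight=abs(math.log2(r.fold_change)),
            )
    return list(edges.values()), orphans


def kinase_summary(edges: Sequence[KinaseEdge]) -> pd.DataFrame:
    """Per-kinase hit counts and mean |log2 FC|.

    Sorted by total targets descending, ties broken by kinase name ascending.
    """
    per: dict[str, dict] = {}
    for e in edges:
        d = per.setdefault(e.source, {"n_up": 0, "n_down": 0, "weights": []})
        d["n_up" if e.direction == CLASS_UP else "n_down"] += 1
        d["weights"].append(e.weight)
    rows = [
        {
            "kinase": k,
            "n_up": d["n_up"],
            "n_down": d["n_down"],
            "n_total": d["n_up"] + d["n_down"],
            "mean_abs_log2_fc": sum(d["weights"]) / len(d["weights"]),
        }
        for k, d in per.items()
    ]
    df = pd.DataFrame(rows, columns=["kinase", "n_up", "n_down", "n_total",
                                     "mean_abs_log2_fc"])
    if not df.empty:
        df = df.sort_values(
            ["n_total", "kinase"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def write_sif(edges: Iterable[KinaseEdge], path) -> None:
    """Write source<TAB>relation<TAB>target, relation = phosphorylation_{up,down}."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.source}\tphosphorylation_{e.direction}\t{e.target}\n")


def read_sif(path) -> list[KinaseEdge]:
    """Parse a SIF written by write_sif (weights are not stored in SIF)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            source, relation, target = line.split("\t")
            direction = relation.removeprefix("phosphorylation_")
            edges.append(KinaseEdge(source, target, direction, 0.0))
    return edges


def to_graph(edges: Iterable[KinaseEdge]) -> nx.DiGraph:
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.source, e.target, direction=e.direction, weight=e.weight)
    return g


def write_graphml(edges: Iterable[KinaseEdge], path) -> None:
    nx.write_graphml(to_graph(edges), path)


def read_graphml(path) -> list[KinaseEdge]:
    g = nx.read_graphml(path)
    return [
        KinaseEdge(u, v, data["direction"], float(data["weight"]))
        for u, v, data in g.edges(data=True)
    ]
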