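"""ceRNA triple assembly, the tripartite network, hubs and subnetworks.

A ceRNA triple (lncRNA, miRNA, mRNA) is emitted when the lncRNA-mRNA pair
passed the positive co-expression screen, both target-database edges exist
among DE features, and the shared miRNA is negatively correlated with both
the lncRNA and the mRNA (Pearson r below ``neg_max``, default 0.0).  The
triples induce an undirected tripartite graph with lncRNA-miRNA and
miRNA-mRNA edges only.

Hubs are the top fraction of nodes by degree (default 10%, k = ceil of the
fraction, expanded to include ties with the k-th degree).  The hub
subnetwork keeps every *whole* triple touching at least one hub — triple
closure, not the induced subgraph on hubs — so a hub miRNA brings its
sponge lncRNAs and target mRNAs along.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import pearson_with_p
from .errors import ValidationError
from .matrix import ExpressionMatrix

#: sort order used to break degree ties in reports (not in hub selection)
CLASS_ORDER = {"miRNA": 0, "lncRNA": 1, "mRNA": 2}


@dataclass(frozen=True)
class CeRNATriple:
    """One lncRNA-miRNA-mRNA association with its supporting correlations."""

    lncrna: str
    mirna: str
    mrna: str
    r_lnc_mrna: float = float("nan")
    r_mir_lnc: float = float("nan")
    r_mir_mrna: float = float("nan")

    @property
    def ids(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)


@dataclass
class CeRNANetwork:
    """Tripartite graph plus the triples it was built from."""

    graph: nx.Graph
    triples: tuple[CeRNATriple, ...]

    @property
    def nodes_by_class(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in CLASS_ORDER}
        for node, cls in self.graph.nodes(data="feature_class"):
            out[cls].append(node)
        return {c: sorted(v) for c, v in out.items()}

    def census(self) -> dict[str, int]:
        """Node and edge counts by class."""
        by_class = self.nodes_by_class
        return {
            "n_lncrna": len(by_class["lncRNA"]),
            "n_mirna": len(by_class["miRNA"]),
            "n_mrna": len(by_class["mRNA"]),
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_triples": len(self.triples),
        }


@dataclass
class HubRanking:
    """Degree ranking with the selected hub set."""

    ranking: pd.DataFrame  # columns: node, feature_class, degree
    fraction: float
    selected: list[str]


def assemble_triples(
    coexp_pairs: pd.DataFrame,
    lm_pairs: pd.DataFrame,
    mm_pairs: pd.DataFrame,
    lnc_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    neg_max: float = 0.0,
) -> list[CeRNATriple]:
    """Assemble ceRNA triples from the three pair screens.

    A triple (l, m, g) is emitted iff (l, g) is a co-expressed pair, the DB
    screens contain l->m and m->g, and Pearson r(m, l) < neg_max and
    r(m, g) < neg_max on log2 expression.  The miRNA matrix must already be
    on the log-CPM (intensity) scale.  All three matrices must share the
    same sample columns.
    """
    for other in (mirna_expr, mrna_expr):
        if list(other.sample_ids) != list(lnc_expr.sample_ids):
            raise ValidationError("expression matrices must share sample columns")

    mirs_of_lnc: dict[str, set[str]] = {}
    for l, m in zip(lm_pairs["source_id"], lm_pairs["target_id"]):
        mirs_of_lnc.setdefault(l, set()).add(m)
    mirs_of_mrna: dict[str, set[str]] = {}
    for m, g in zip(mm_pairs["source_id"], mm_pairs["target_id"]):
        mirs_of_mrna.setdefault(g, set()).add(m)

    def profile(expr: ExpressionMatrix, fid: str) -> np.ndarray:
        if fid not in expr.values.index:
            raise ValidationError(
                f"no expression for {expr.feature_class} {fid!r}"
            )
        vals = expr.as_log2().values if not expr.is_log2 else expr.values
        return vals.loc[fid].to_numpy(dtype=float)

    triples: list[CeRNATriple] = []
    for _, row in coexp_pairs.iterrows():
        l, g, r_lg = row["lncrna_id"], row["mrna_id"], float(row["r"])
        shared = mirs_of_lnc.get(l, set()) & mirs_of_mrna.get(g, set())
        for m in sorted(shared):
            r_ml, _ = pearson_with_p(profile(mirna_expr, m), profile(lnc_expr, l))
            if r_ml >= neg_max:
                continue
            r_mg, _ = pearson_with_p(profile(mirna_expr, m), profile(mrna_expr, g))
            if r_mg >= neg_max:
                continue
            triples.append(CeRNATriple(l, m, g, r_lg, r_ml, r_mg))
    return triples


def build_network(triples: Iterable[CeRNATriple]) -> CeRNANetwork:
    """Build the deduplicated tripartite graph from triples.

    Nodes carry a ``feature_class`` attribute; edges are lncRNA-miRNA and
    miRNA-mRNA only.  Duplicate triples (same three IDs) are collapsed.
    """
    seen: dict[tuple[str, str, str], CeRNATriple] = {}
    for t in triples:
        seen.setdefault(t.ids, t)
    g = nx.Graph()
    for t in seen.values():
        g.add_node(t.lncrna, feature_class="lncRNA")
        g.add_node(t.mirna, feature_class="miRNA")
        g.add_node(t.mrna, feature_class="mRNA")
        g.add_edge(t.lncrna, t.mirna)
        g.add_edge(t.mirna, t.mrna)
    return CeRNANetwork(graph=g, triples=tuple(seen.values()))


def node_degrees(net: CeRNANetwork) -> pd.DataFrame:
    """Per-node degree table, sorted for stable output.

    Sort key: degree descending, then class (miRNA < lncRNA < mRNA), then
    node ID.
    """
    rows = [
        (node, cls, net.graph.degree[node])
        for node, cls in net.graph.nodes(data="feature_class")
    ]
    df = pd.DataFrame(rows, columns=["node", "feature_class", "degree"])
    df["_c"] = df["feature_class"].map(CLASS_ORDER)
    df = (
        df.sort_values(["degree", "_c", "node"], ascending=[False, True, True])
        .drop(columns="_c")
        .reset_index(drop=True)
    )
    return df


def select_hubs(
    degree_table: pd.DataFrame, fraction: float = 0.10, include_ties: bool = True
) -> HubRanking:
    """Top-fraction hub selection on a degree table.

    k = ceil(fraction * n_nodes); the selected set is the k highest-degree
    nodes, expanded to every node tied with the k-th degree when
    ``include_ties`` (so the minimum selected degree is strictly above every
    unselected degree).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    if degree_table.empty:
        raise ValidationError("hub selection needs >= 1 node")
    df = degree_table.sort_values(
        ["degree", "node"], ascending=[False, True]
    ).reset_index(drop=True)
    k = math.ceil(fraction * len(df))
    if include_ties:
        cutoff = df["degree"].iloc[k - 1]
        selected = df.loc[df["degree"] >= cutoff, "node"].tolist()
    else:
        selected = df["node"].iloc[:k].tolist()
    return HubRanking(ranking=degree_table.reset_index(drop=True),
                      fraction=fraction, selected=selected)


def hub_nodes(
    net: CeRNANetwork, fraction: float = 0.10, include_ties: bool = True
) -> HubRanking:
    """Degree-ranked hub selection on a built network."""
    return select_hubs(node_degrees(net), fraction, include_ties)


def extract_subnetwork(net: CeRNANetwork, hubs: Iterable[str]) -> CeRNANetwork:
    """Triple-closure subnetwork around the hub set.

    Keeps every whole triple containing at least one hub node and rebuilds
    the network from those triples; an empty hub set gives an empty network.
    """
    hubs = set(hubs)
    unknown = sorted(hubs - set(net.graph.nodes))
    if unknown:
        raise ValidationError(f"unknown hub IDs: {unknown}")
    kept = [t for t in net.triples if hubs.intersection(t.ids)]
    return build_network(kept)


def export_network(net: CeRNANetwork, directory: str | Path) -> dict[str, Path]:
    """Write the network as an edge-list TSV, a GraphML file and a degree
    table TSV.  The edge list round-trips through :func:`read_edge_list`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": directory / "edges.tsv",
        "graphml": directory / "network.graphml",
        "degrees": directory / "degrees.tsv",
    }
    rows = []
    for a, b in net.graph.edges:
        ca = net.graph.nodes[a]["feature_class"]
        cb = net.graph.nodes[b]["feature_class"]
        # orient edges as lncRNA--miRNA and miRNA--mRNA for readability
        if (ca, cb) in (("miRNA", "lncRNA"), ("mRNA", "miRNA")):
            a, b, ca, cb = b, a, cb, ca
        rows.append((a, b, ca, cb))
    edges = pd.DataFrame(
        sorted(rows), columns=["node_a", "node_b", "class_a", "class_b"]
    )
    edges.to_csv(paths["edges"], sep="\t", index=False)
    nx.write_graphml(net.graph, paths["graphml"], named_key_ids=True)
    node_degrees(net).to_csv(paths["degrees"], sep="\t", index=False)
    return paths


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_node(row["node_a"], feature_class=row["class_a"])
        g.add_node(row["node_b"], feature_class=row["class_b"])
        g.add_edge(row["node_a"], row["node_b"])
    return g
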