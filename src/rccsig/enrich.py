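"""Over-representation analysis and minimal seed-connecting subnetworks.

Generic local counterparts of web-tool enrichment/network analyses:
exact upper-tail hypergeometric tests with Benjamini-Hochberg FDR control
over user-supplied gene-set collections (GMT), and a Steiner-tree
approximation that connects a seed gene panel through a user-supplied
protein-interaction edge list with the fewest extra nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import GeneSignature


@dataclass
class GeneSetCollection:
    """Named gene sets (symbols uppercased) with an optional background."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            members = {str(g).upper() for g in members}
            if not members:
                raise ValueError(f"empty gene set {name!r}")
            clean[name] = members
        self.sets = clean
        if self.universe is not None:
            self.universe = {str(g).upper() for g in self.universe}


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(filter(None, parts[2:]))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, source=source or str(path))


def read_edge_list(path) -> nx.Graph:
    """Read a SIF or 2-column TSV edge list into an undirected graph."""
    G = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                continue
            # 2 columns: plain TSV edge; >=3: SIF (relation in column 2)
            a = parts[0]
            rest = [parts[1]] if len(parts) == 2 else parts[2:]
            for b in rest:
                a_u, b_u = a.upper(), b.upper()
                if a_u != b_u:
                    G.add_edge(a_u, b_u)
    if G.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges found")
    return G


def hypergeom_enrich(query: list[str], sets: GeneSetCollection,
                     universe: list[str]) -> pd.DataFrame:
    """Exact upper-tail hypergeometric over-representation with BH FDR.

    For each set, p = P(X >= overlap) where X is hypergeometric with the
    universe as population, set members in the universe as successes, and
    the query as the draw. Query genes outside the universe are dropped
    with a warning. Results are sorted by p.
    """
    universe_set = {str(g).upper() for g in universe}
    query_set = {str(g).upper() for g in query}
    outside = sorted(query_set - universe_set)
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside universe dropped: "
                      f"{outside[:10]}")
    query_set &= universe_set
    if not query_set:
        raise ValueError("empty query after restricting to the universe")

    rows = []
    for name, members in sorted(sets.sets.items()):
        members_in = members & universe_set
        if len(members_in) > len(universe_set):
            raise ValueError(f"set {name!r} larger than the universe")
        overlap = sorted(query_set & members_in)
        x = len(overlap)
        p = float(hypergeom.sf(x - 1, len(universe_set), len(members_in),
                               len(query_set)))
        rows.append({"set": name, "overlap_genes": ",".join(overlap),
                     "overlap": x, "set_size": len(members_in),
                     "query_size": len(query_set),
                     "universe_size": len(universe_set), "p_value": p})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "set"]).reset_index(drop=True)


@dataclass
class Subnetwork:
    """Connected subgraph spanning the seed genes plus minimal connectors."""

    graph: nx.Graph
    seeds: list[str]
    connectors: list[str]
    missing_seeds: list[str] = field(default_factory=list)


def min_connected_subnetwork(graph: nx.Graph, seeds: list[str]) -> Subnetwork:
    """Connect the seeds through the fewest extra (non-seed) nodes.

    Classic metric-closure Steiner approximation: build the shortest-path
    distance closure over the seeds, take its minimum spanning tree,
    expand each closure edge back to an original shortest path, and prune
    non-seed leaves. Deterministic: all ties resolve by symbol order. If
    the seeds span several components of the input graph, each component's
    seeds are connected internally (the result is then a forest).
    """
    seed_set = sorted({str(s).upper() for s in seeds})
    present = [s for s in seed_set if s in graph]
    missing = [s for s in seed_set if s not in graph]
    if not present:
        raise ValueError("no seed present in the interaction graph")
    if missing:
        warnings.warn(f"seed(s) absent from graph: {missing[:10]}")

    sub = nx.Graph()
    sub.add_nodes_from(present)
    # group seeds by connected component; connect within each
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            comp_of[node] = ci
    groups: dict[int, list[str]] = {}
    for s in present:
        groups.setdefault(comp_of[s], []).append(s)

    for group in groups.values():
        if len(group) < 2:
            continue
        closure = nx.Graph()
        paths: dict[tuple[str, str], list[str]] = {}
        for a, b in combinations(sorted(group), 2):
            # BFS shortest path with deterministic neighbor order
            path = _shortest_path_det(graph, a, b)
            paths[(a, b)] = path
            closure.add_edge(a, b, weight=len(path) - 1)
        mst = nx.minimum_spanning_tree(
            closure, algorithm="kruskal",
            weight="weight")
        for a, b in sorted(mst.edges()):
            key = (a, b) if (a, b) in paths else (b, a)
            nx.add_path(sub, paths[key])

    # prune non-seed leaves (cannot be essential connectors)
    seed_lookup = set(present)
    changed = True
    while changed:
        changed = False
        for node in sorted(sub.nodes()):
            if node not in seed_lookup and sub.degree(node) <= 1:
                sub.remove_node(node)
                changed = True
    connectors = sorted(set(sub.nodes()) - seed_lookup)
    return Subnetwork(graph=sub, seeds=present, connectors=connectors,
                      missing_seeds=missing)


def _shortest_path_det(graph: nx.Graph, a: str, b: str) -> list[str]:
    """BFS shortest path expanding neighbors in sorted order (unit weights)."""
    from collections import deque

    prev = {a: None}
    queue = deque([a])
    while queue:
        node = queue.popleft()
        if node == b:
            break
        for nbr in sorted(graph.neighbors(node)):
            if nbr not in prev:
                prev[nbr] = node
                queue.append(nbr)
    if b not in prev:
        raise nx.NetworkXNoPath(f"no path between {a} and {b}")
    path = [b]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path[::-1]


def report_signature_overlap(signature: GeneSignature,
                             sets: GeneSetCollection) -> pd.DataFrame:
    """Set-by-set intersection of a signature with a gene-set collection."""
    genes = set(signature.unique_genes)
    rows = [{"set": name, "overlap_genes": ",".join(sorted(genes & members)),
             "overlap": len(genes & members)}
            for name, members in sorted(sets.sets.items())]
    return pd.DataFrame(rows, columns=["set", "overlap_genes", "overlap"])
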