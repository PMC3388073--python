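"""DEG-seeded interaction-network construction and regulator ranking.

The network model starts from a differentially-expressed seed set, expands
to its first neighbors in a protein-protein / protein-DNA interaction
graph, then prunes neighbors that do not help connect DEG nodes: a
non-DEG node survives only if it is adjacent to at least two DEG nodes.
Candidate regulators (transcription factors, signaling genes supplied as an
annotation) are ranked by degree centrality, counted over adjacent DEG
nodes in the pruned network — the number of DEG interactors a regulator
can reach directly.  Total degree is carried along for transparency.
Nodes are finally labeled with the most significant enriched functional
term containing them, giving the module grouping of the network.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .io import CholnetError, InteractionNetwork


def build_initial_network(degs: Iterable[str], interactions: InteractionNetwork,
                          ) -> InteractionNetwork:
    """First-neighbor expansion of the DEG seed set.

    Nodes are the seed DEGs plus every direct neighbor of a seed found in
    the interaction data; edges are all interaction edges with both
    endpoints inside that node set (including neighbor-neighbor edges).
    Seeds absent from the interaction data are kept as isolated nodes.
    """
    deg_set = set(degs)
    if not deg_set:
        raise CholnetError("empty DEG seed set")
    g = interactions.graph
    present = deg_set & set(g.nodes())
    if not present:
        raise CholnetError("no DEG appears in the interaction data")

    nodes = set(deg_set)
    for d in present:
        nodes.update(g.neighbors(d))

    out = InteractionNetwork()
    for n in sorted(nodes):
        out.graph.add_node(n, role="deg" if n in deg_set else "neighbor")
    for u, v, data in sorted(g.edges(data=True)):
        if u in nodes and v in nodes:
            out.add_edge(u, v, kind=data.get("kind", "ppi"))
            # re-adding endpoints must not clobber roles set above
    for n in nodes:
        out.graph.nodes[n]["role"] = "deg" if n in deg_set else "neighbor"
    return out


def prune_network(net: InteractionNetwork) -> InteractionNetwork:
    """Drop non-DEG nodes adjacent to fewer than two DEG nodes.

    A neighbor touching a single DEG bridges nothing, so it is removed
    along with its edges; DEG nodes are never removed.  The rule is a
    single pass and idempotent: removing non-DEG nodes cannot change any
    surviving node's count of DEG neighbors.
    """
    g = net.graph
    deg_nodes = {n for n, r in g.nodes(data="role") if r == "deg"}
    keep = set(deg_nodes)
    for n in g.nodes():
        if n in deg_nodes:
            continue
        if sum(1 for nb in g.neighbors(n) if nb in deg_nodes) >= 2:
            keep.add(n)
    out = InteractionNetwork(graph=g.subgraph(keep).copy())
    return out


def degree_centrality(net: InteractionNetwork, node: str) -> int:
    """Number of DEG nodes adjacent to ``node``."""
    g = net.graph
    if node not in g:
        raise CholnetError(f"node {node!r} not in network")
    return sum(1 for nb in g.neighbors(node) if g.nodes[nb].get("role") == "deg")


def rank_regulators(net: InteractionNetwork, regulators: Iterable[str]) -> pd.DataFrame:
    """Rank candidate regulators by DEG-neighbor degree centrality.

    Returns a DataFrame (gene, degree, total_degree, rank) sorted by degree
    descending with alphabetical tiebreak; ranks are 1..R.  Regulators not
    present in the network count as degree 0.
    """
    regs = sorted(set(regulators))
    if not regs:
        raise CholnetError("empty regulator set")
    g = net.graph
    rows = []
    for r in regs:
        if r in g:
            rows.append({"gene": r, "degree": degree_centrality(net, r),
                         "total_degree": g.degree(r)})
        else:
            rows.append({"gene": r, "degree": 0, "total_degree": 0})
    out = pd.DataFrame(rows).sort_values(
        ["degree", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    for r in regs:
        if r in g:
            g.nodes[r]["regulator"] = True
    return out


def assign_modules(
    net: InteractionNetwork,
    enrichment: pd.DataFrame,
    sets: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Label each node with its most significant enriched term.

    Terms with p < ``alpha`` in the enrichment table are eligible,
    considered in order of increasing p (ties by term id); a node gets the
    first eligible term containing it, or "unassigned".  Labels are also
    written onto the graph's ``module_label`` node attribute.
    """
    eligible = enrichment[enrichment["p"] < alpha].sort_values(
        ["p", "term"], kind="stable")
    term_order = list(eligible["term"])
    labels: dict[str, str] = {}
    for node in net.graph.nodes():
        label = "unassigned"
        for term in term_order:
            if node in set(sets.get(term, ())):
                label = term
                break
        labels[node] = label
        net.graph.nodes[node]["module_label"] = label
    return labels
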