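"""Combined-score-filtered PPI graph and MCODE dense-module detection.

MCODE (molecular complex detection) finds locally dense regions of a
protein-protein interaction graph in three stages: (1) every vertex is
weighted by its core-clustering coefficient — the density of the highest
k-core of its open neighborhood, scaled by k; (2) complexes are grown
greedily outward from the highest-weighted unassigned seed, admitting a
neighbor whose weight is within a vertex-weight-percentage (VWP) tolerance
of the seed's; (3) complexes lacking a 2-core are discarded, an optional
"haircut" prunes singly-connected members, and optional "fluff" adds
dense-neighborhood peripherals. Defaults match the common plugin settings
(vwp=0.2, degree cutoff 2, haircut on, fluff off).

The edge filter accepts STRING-style combined scores on either the 0-1000
or 0-1 scale and normalizes to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class ComplexResult:
    """One detected complex: member set, density*size score, seed, 1-based rank."""

    members: frozenset[str]
    score: float
    seed_node: str
    rank: int


@dataclass
class MCODEParams:
    vwp: float = 0.2
    degree_cutoff: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.5
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp <= 1.0:
            raise ValueError(f"vwp must be in [0, 1], got {self.vwp}")
        if self.degree_cutoff < 0 or self.max_depth < 0:
            raise ValueError("degree_cutoff and max_depth must be >= 0")


def build_ppi(edge_table: pd.DataFrame, cutoff: float,
              scale: str = "auto") -> nx.Graph:
    """Filter a (protein_a, protein_b, combined_score) table into a graph.

    ``scale='auto'`` divides all scores by 1000 when any exceeds 1 (the
    STRING 0-1000 convention); ``'thousand'`` always divides; ``'unit'``
    never does. Edges with normalized score strictly greater than ``cutoff``
    are retained; self-loops are dropped and duplicate rows (either
    orientation) collapse to a single edge keeping the maximum score.
    """
    if scale not in ("auto", "unit", "thousand"):
        raise ValueError(f"unknown scale {scale!r}")
    scores = edge_table["combined_score"].astype(float)
    if (scores < 0).any():
        raise ValueError("negative combined scores are not allowed")
    if scale == "thousand" or (scale == "auto" and (scores > 1).any()):
        scores = scores / 1000.0

    g = nx.Graph()
    for (a, b), s in zip(
        edge_table[["protein_a", "protein_b"]].itertuples(index=False),
        scores,
    ):
        a, b = str(a), str(b)
        if a == b or s <= cutoff:
            continue
        if g.has_edge(a, b):
            g[a][b]["combined_score"] = max(g[a][b]["combined_score"], float(s))
        else:
            g.add_edge(a, b, combined_score=float(s))
    return g


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph with all degrees >= k (empty graph allowed)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if graph.number_of_nodes() == 0:
        return graph.copy()
    return nx.k_core(graph, k)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weight(graph: nx.Graph, v) -> float:
    """Core-clustering coefficient of ``v``: k(H) * density(H) where H is the
    highest-k core of the induced subgraph on the open neighborhood N(v).
    Isolated and degree-1 vertices weigh 0.
    """
    if v not in graph:
        raise KeyError(v)
    nbrs = list(graph.neighbors(v))
    if len(nbrs) < 2:
        return 0.0
    sub = graph.subgraph(nbrs)
    core_num = nx.core_number(sub)
    k_max = max(core_num.values())
    h = sub.subgraph([u for u, c in core_num.items() if c >= k_max])
    return k_max * _density(h)


def mcode_find_complexes(graph: nx.Graph,
                         params: MCODEParams | None = None) -> list[ComplexResult]:
    """Run the three MCODE stages and return score-ranked complexes.

    Seeds are taken in descending weight order (ties broken by smaller node
    ID); vertices of degree below ``degree_cutoff``, or with weight 0, never
    seed — their expansion threshold would be 0 and would swallow whole
    components. Expansion admits an unassigned neighbor u iff
    weight(u) >= weight(seed)*(1-vwp) and, once the complex has two or more
    members, u attaches by at least two edges. This bridge guard keeps two
    dense regions joined by a single edge from collapsing into one complex
    (a known failure mode of pure threshold expansion) and is consistent
    with the 2-core semantics of the post-filter. Up to ``max_depth``
    expansion rounds are run, one frontier per round.

    Post-processing drops complexes lacking a 2-core, then optionally fluffs
    (adds neighbors whose closed-neighborhood density exceeds
    ``fluff_density``; fluffed nodes may repeat across complexes) and
    haircuts (restricts to the complex 2-core, so every member keeps degree
    >= 2 inside it; pruned nodes may be claimed by later complexes).
    Score = density * member count; ranking is by score descending, ties by
    smaller seed ID.
    """
    params = params or MCODEParams()
    weights = {v: (0.0 if graph.degree(v) < params.degree_cutoff
                   else vertex_weight(graph, v)) for v in graph}

    assigned: set = set()
    results: list[ComplexResult] = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.vwp)
        members = {seed}
        # expand to a fixed point, one frontier round per depth unit; once the
        # complex has >= 2 members a candidate must attach by >= 2 edges (the
        # bridge guard), so a single bridge edge cannot chain two dense
        # regions into one complex
        for _ in range(params.max_depth):
            candidates = sorted({u for v in members for u in graph.neighbors(v)
                                 if u not in members and u not in assigned},
                                key=str)
            added = False
            for u in candidates:
                if weights[u] < threshold:
                    continue
                attach = sum(1 for w in graph.neighbors(u) if w in members)
                if attach >= min(2, len(members)):
                    members.add(u)
                    added = True
            if not added:
                break
        assigned |= members

        sub = graph.subgraph(members)
        if nx.k_core(sub, 2).number_of_nodes() == 0:
            assigned -= members - {seed}  # not a complex; free the others
            continue
        final = set(members)
        if params.fluff:
            for v in sorted(members, key=str):
                for u in graph.neighbors(v):
                    if u in final:
                        continue
                    closed = list(graph.neighbors(u)) + [u]
                    if _density(graph.subgraph(closed)) > params.fluff_density:
                        final.add(u)
        if params.haircut:
            kept = set(nx.k_core(graph.subgraph(final), 2).nodes)
            assigned -= final - kept  # pruned nodes may join later complexes
            final = kept
            if not final:
                continue
        sub = graph.subgraph(final)
        results.append(ComplexResult(
            members=frozenset(final),
            score=_density(sub) * sub.number_of_nodes(),
            seed_node=str(seed),
            rank=0,
        ))

    results.sort(key=lambda c: (-c.score, c.seed_node))
    return [ComplexResult(c.members, c.score, c.seed_node, i + 1)
            for i, c in enumerate(results)]


def complexes_to_frame(results: list[ComplexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"rank": c.rank, "score": c.score, "size": len(c.members),
          "seed": c.seed_node, "members": ",".join(sorted(c.members))}
         for c in results],
        columns=["rank", "score", "size", "seed", "members"],
    )
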