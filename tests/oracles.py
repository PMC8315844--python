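"""Independent brute-force oracles shared by unit and acceptance tests.

Each oracle re-derives the expected result from the literal definition
(window comparison, repeated deletion, exhaustive enumeration) without using
the implementation under test.
"""

import itertools

import networkx as nx

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_seed_scan(mir: str, utr: str):
    """Naive window-by-window scan for the four canonical miRNA site types."""
    mir = mir.replace("T", "U").upper()
    utr = utr.replace("T", "U").upper()
    core = _rc(mir[1:7])
    m8core = _rc(mir[1:8])  # complement of position 8 followed by the core
    out = []
    for i in range(len(utr) - 5):
        if utr[i:i + 6] != core:
            continue
        if i >= 1 and utr[i - 1:i + 7] == m8core + "A":
            out.append(("8mer", i - 1, i + 7))
        elif i >= 1 and utr[i - 1:i + 6] == m8core:
            out.append(("7mer-m8", i - 1, i + 6))
        elif utr[i:i + 7] == core + "A":
            out.append(("7mer-A1", i, i + 7))
        else:
            out.append(("6mer", i, i + 6))
    return out


def brute_force_k_core(graph: nx.Graph, k: int) -> set:
    """Fixed point of repeatedly deleting any vertex of degree < k."""
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if g.degree(v) < k:
                g.remove_node(v)
                changed = True
    return set(g.nodes)


def enumeration_overlap_counts(K, n, N):
    """Count draws by overlap size over all C(N, n) draws from an N-item urn."""
    marked = set(range(K))
    counts = [0] * (min(K, n) + 1)
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        counts[len(marked.intersection(draw))] += 1
    return counts, total
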