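"""Competing-triplet construction and the tripartite ceRNA network.

A competing triplet (lncRNA, miRNA, mRNA) requires that all three members be
differentially expressed, that the lncRNA and the mRNA share the miRNA as a
predicted targeter, and that both partners be negatively coexpressed with
the miRNA. With the small replicate numbers typical of these designs a
correlation threshold is statistically meaningless, so two negativity modes
are offered: an opposite-DE-direction proxy (default) and a Pearson/Spearman
threshold for designs with >= 6 samples. The network is always derived from
triplets — never assembled directly from edges — so every node participates
in at least one triplet by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
from scipy import stats

from .diffexpr import DESets, compute_tpm
from .synthdata import ExpressionBundle
from .targetnet import ConsensusInteractions

ROLES = ("lncRNA", "miRNA", "mRNA")


@dataclass(frozen=True)
class Triplet:
    lnc_id: str
    mir_id: str
    mrna_id: str
    r_lnc_mir: float | None = None   # None in direction-proxy mode
    r_mir_mrna: float | None = None
    evidence: tuple[tuple[str, ...], tuple[str, ...]] = ((), ())  # provenance of both edges


@dataclass
class TripletParams:
    mode: str = "direction"          # direction | correlation
    method: str = "pearson"          # pearson | spearman (correlation mode)
    r_max: float = -0.7              # keep pair iff r < r_max
    min_samples: int = 6
    pseudocount: float = 1.0


@dataclass
class CeRNANetwork:
    """Tripartite graph induced by a triplet list.

    ``nodes`` maps id -> (role, direction); ``edges`` are
    (source_id, target_id, kind) with kind lnc_mir or mir_mrna.
    """

    nodes: dict[str, tuple[str, str]] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    triplets: list[Triplet] = field(default_factory=list)


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation; NaN when either vector is constant.

    The NaN signals an undefined correlation and always fails a negativity
    test of the form ``r < r_max``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def find_triplets(desets: DESets, consensus: ConsensusInteractions,
                  expr: ExpressionBundle | None = None,
                  params: TripletParams | None = None) -> list[Triplet]:
    """Enumerate competing triplets from DE sets, consensus edges, expression.

    A triplet (l, m, g) is emitted iff l, m, g are DE in their classes, the
    edges (l -> m) and (m -> g) are both in the consensus, and the negative
    coexpression criterion holds for both pairs under the active mode.
    Output is sorted by (lnc, mir, mrna).
    """
    params = params or TripletParams()
    if params.mode not in ("direction", "correlation"):
        raise ValueError(f"unknown mode {params.mode!r}")

    log_tpm: dict[str, "np.ndarray"] = {}
    if params.mode == "correlation":
        if expr is None:
            raise ValueError("correlation mode requires an expression bundle")
        n_samples = len(expr.sample_condition)
        if n_samples < params.min_samples:
            raise ValueError(
                f"correlation mode needs >= {params.min_samples} samples, got "
                f"{n_samples}; use mode='direction' for small designs"
            )
        order = list(expr.sample_condition.index)
        for cls in ROLES:
            tpm = compute_tpm(expr.counts[cls], expr.lengths[cls])[order]
            logv = np.log2(tpm.to_numpy() + params.pseudocount)
            for fid, row in zip(tpm.index, logv):
                log_tpm[fid] = row

    de_lnc = desets.members("lncRNA")
    de_mir = desets.members("miRNA")
    de_mrna = desets.members("mRNA")

    lnc_of_mir: dict[str, list[str]] = {}
    mrna_of_mir: dict[str, list[str]] = {}
    for typ, reg, tgt in consensus.edges:
        if typ == "lnc_mir" and reg in de_lnc and tgt in de_mir:
            lnc_of_mir.setdefault(tgt, []).append(reg)
        elif typ == "mir_mrna" and reg in de_mir and tgt in de_mrna:
            mrna_of_mir.setdefault(reg, []).append(tgt)

    def negativity(a: str, b: str) -> tuple[bool, float | None]:
        if params.mode == "direction":
            da = desets.direction_of(_class_of(desets, a), a)
            db = desets.direction_of(_class_of(desets, b), b)
            return ({da, db} == {"up", "down"}), None
        r = correlate(log_tpm[a], log_tpm[b], method=params.method)
        return (not np.isnan(r)) and r < params.r_max, r

    triplets: list[Triplet] = []
    for mir in sorted(set(lnc_of_mir) & set(mrna_of_mir)):
        for lnc in sorted(lnc_of_mir[mir]):
            ok_lm, r_lm = negativity(lnc, mir)
            if not ok_lm:
                continue
            for mrna in sorted(mrna_of_mir[mir]):
                ok_mg, r_mg = negativity(mir, mrna)
                if not ok_mg:
                    continue
                triplets.append(Triplet(
                    lnc_id=lnc, mir_id=mir, mrna_id=mrna,
                    r_lnc_mir=r_lm, r_mir_mrna=r_mg,
                    evidence=(consensus.provenance.get(("lnc_mir", lnc, mir), ()),
                              consensus.provenance.get(("mir_mrna", mir, mrna), ())),
                ))
    triplets.sort(key=lambda t: (t.lnc_id, t.mir_id, t.mrna_id))
    return triplets


def _class_of(desets: DESets, feature_id: str) -> str:
    for cls in ROLES:
        if feature_id in desets.up.get(cls, []) or feature_id in desets.down.get(cls, []):
            return cls
    return "mRNA"  # unknown ids resolve to ns anyway


def assemble_network(triplets: list[Triplet],
                     desets: DESets | None = None) -> CeRNANetwork:
    """Union of triplets, deduplicated, with roles and (optional) directions.

    Directions are looked up from ``desets`` when provided, else recorded as
    ``na``. An ID appearing under two different roles is rejected.
    """
    net = CeRNANetwork(triplets=list(triplets))
    edge_set: set[tuple[str, str, str]] = set()

    def add_node(fid: str, role: str) -> None:
        direction = desets.direction_of(role, fid) if desets is not None else "na"
        if fid in net.nodes and net.nodes[fid][0] != role:
            raise ValueError(
                f"ID {fid!r} appears as both {net.nodes[fid][0]} and {role}")
        net.nodes[fid] = (role, direction)

    for t in triplets:
        add_node(t.lnc_id, "lncRNA")
        add_node(t.mir_id, "miRNA")
        add_node(t.mrna_id, "mRNA")
        edge_set.add((t.lnc_id, t.mir_id, "lnc_mir"))
        edge_set.add((t.mir_id, t.mrna_id, "mir_mrna"))
    net.edges = sorted(edge_set)
    return net


def summarize_network(net: CeRNANetwork) -> dict:
    """Role/direction counts and a per-node degree table."""
    by_role = {r: 0 for r in ROLES}
    by_direction: dict[str, int] = {}
    for role, direction in net.nodes.values():
        by_role[role] += 1
        by_direction[direction] = by_direction.get(direction, 0) + 1
    degree: dict[str, int] = {fid: 0 for fid in net.nodes}
    for s, t, _ in net.edges:
        degree[s] += 1
        degree[t] += 1
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_triplets": len(net.triplets),
        "by_role": by_role,
        "by_direction": by_direction,
        "degree": dict(sorted(degree.items())),
    }


def to_networkx(net: CeRNANetwork) -> nx.Graph:
    g = nx.Graph()
    for fid, (role, direction) in net.nodes.items():
        g.add_node(fid, role=role, direction=direction)
    for s, t, kind in net.edges:
        g.add_edge(s, t, kind=kind)
    return g


_FORMATS = ("sif", "graphml", "tsv")


def export_network(net: CeRNANetwork, path: str | Path, fmt: str = "sif") -> Path:
    """Write the network as SIF, GraphML, or an edge TSV.

    SIF/TSV are line-oriented; node IDs containing tabs or newlines are
    rejected (sanitize IDs upstream). GraphML carries role/direction node
    attributes and round-trips exactly via :func:`import_network`.
    """
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    path = Path(path)
    if fmt in ("sif", "tsv"):
        for fid in net.nodes:
            if "\t" in fid or "\n" in fid:
                raise ValueError(
                    f"node ID {fid!r} contains a tab/newline; sanitize IDs before "
                    "exporting to a tab-separated format")
    if fmt == "sif":
        with open(path, "w") as fh:
            for s, t, kind in net.edges:
                fh.write(f"{s}\t{kind}\t{t}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tkind\n")
            for s, t, kind in net.edges:
                fh.write(f"{s}\t{t}\t{kind}\n")
    else:
        nx.write_graphml(to_networkx(net), path)
    return path


def import_network(path: str | Path, fmt: str = "graphml") -> CeRNANetwork:
    """Read a network written by :func:`export_network` (GraphML only).

    Triplets are not stored in the file, so the imported object carries the
    node/edge structure only.
    """
    if fmt.lower() != "graphml":
        raise ValueError("only GraphML carries enough attributes to round-trip")
    g = nx.read_graphml(Path(path))
    net = CeRNANetwork()
    for fid, data in g.nodes(data=True):
        net.nodes[fid] = (data["role"], data["direction"])
    edge_set = set()
    for u, v, data in g.edges(data=True):
        kind = data["kind"]
        if kind == "lnc_mir":
            s, t = (u, v) if net.nodes[u][0] == "lncRNA" else (v, u)
        else:
            s, t = (u, v) if net.nodes[u][0] == "miRNA" else (v, u)
        edge_set.add((s, t, kind))
    net.edges = sorted(edge_set)
    return net
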