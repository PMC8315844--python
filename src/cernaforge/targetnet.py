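"""miRNA-target interaction layer: seed-site scanning and source consensus.

Prediction databases disagree, so the standard practice is to integrate
several (sequence-scan predictors plus an experimentally validated resource)
under an explicit consensus rule. The built-in scanner implements canonical
seed matching only — Watson-Crick reverse-complement matches to miRNA
positions 2-7, classified into the four canonical site types — with no
wobble pairing and no context scoring, so it is exactly specifiable and
testable against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
SITE_RANK = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}


@dataclass(frozen=True)
class SeedSite:
    """One predicted miRNA binding site on a UTR (0-based half-open coords)."""

    mirna_id: str
    utr_id: str
    site_type: str  # 8mer / 7mer-m8 / 7mer-A1 / 6mer
    utr_start: int
    utr_end: int


@dataclass
class InteractionTable:
    """Typed directed edges from one prediction source."""

    source: str
    edges: list[tuple[str, str, str]]  # (type, regulator, target); type lnc_mir|mir_mrna
    validated: bool = False
    scores: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValueError(f"duplicate edges within source {self.source!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str | None = None) -> "InteractionTable":
        src = source if source is not None else (
            str(df["source"].iloc[0]) if len(df) else "unknown")
        validated = bool(df["validated"].any()) if "validated" in df else False
        edges, scores = [], {}
        seen = set()
        for _, row in df.iterrows():
            e = (str(row["type"]), str(row["regulator"]), str(row["target"]))
            if e in seen:
                continue
            seen.add(e)
            edges.append(e)
            if "score" in row and pd.notna(row["score"]):
                scores[e] = float(row["score"])
        return cls(source=src, edges=edges, validated=validated, scores=scores)


@dataclass
class ConsensusInteractions:
    """Consensus-filtered edges with per-edge source provenance."""

    edges: list[tuple[str, str, str]]
    provenance: dict[tuple[str, str, str], tuple[str, ...]]
    rule: str = "quorum2"

    def __contains__(self, edge: tuple[str, str, str]) -> bool:
        return edge in self.provenance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"type": t, "regulator": r, "target": g,
              "sources": ",".join(self.provenance[(t, r, g)])}
             for t, r, g in self.edges],
            columns=["type", "regulator", "target", "sources"],
        )


def _clean_rna(seq: str, name: str) -> str:
    out = []
    for i, ch in enumerate(seq.upper()):
        ch = "U" if ch == "T" else ch
        if ch not in _COMPLEMENT:
            raise ValueError(f"invalid character {ch!r} at position {i} of {name}")
        out.append(ch)
    return "".join(out)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def predict_seed_sites(mirna_seq: str, utr_seq: str, mirna_id: str = "mirna",
                       utr_id: str = "utr") -> list[SeedSite]:
    """Scan a UTR for canonical seed sites of one miRNA.

    The 6mer core is the reverse complement of miRNA positions 2-7 (1-based,
    from the 5' end). Because the duplex is antiparallel, on the UTR read
    5'->3' the position pairing miRNA nucleotide 8 lies immediately 5' of the
    core match and the position opposite miRNA nucleotide 1 immediately 3' of
    it. Site classes:

    - ``8mer``: core + WC match to position 8 + an A opposite position 1
    - ``7mer-m8``: core + WC match to position 8
    - ``7mer-A1``: core + an A opposite position 1
    - ``6mer``: core only

    The A of A1 sites is a literal adenosine, not a complement (recognized by
    Argonaute directly). Each core match is reported once with its strongest
    class; coordinates are 0-based half-open on the UTR.
    """
    mir = _clean_rna(mirna_seq, "miRNA")
    utr = _clean_rna(utr_seq, "UTR")
    if len(mir) < 8:
        raise ValueError(f"miRNA too short ({len(mir)} < 8 nt)")

    core = _revcomp(mir[1:7])       # pairs positions 2-7
    m8_nt = _COMPLEMENT[mir[7]]     # UTR nt pairing miRNA position 8
    sites: list[SeedSite] = []
    start = utr.find(core)
    while start != -1:
        m8 = start >= 1 and utr[start - 1] == m8_nt
        a1 = start + 6 < len(utr) and utr[start + 6] == "A"
        if m8 and a1:
            site = SeedSite(mirna_id, utr_id, "8mer", start - 1, start + 7)
        elif m8:
            site = SeedSite(mirna_id, utr_id, "7mer-m8", start - 1, start + 6)
        elif a1:
            site = SeedSite(mirna_id, utr_id, "7mer-A1", start, start + 7)
        else:
            site = SeedSite(mirna_id, utr_id, "6mer", start, start + 6)
        sites.append(site)
        start = utr.find(core, start + 1)
    return sites


_RULES = ("quorum2", "union", "intersection")


def combine_sources(tables: list[InteractionTable], rule: str = "quorum2") -> ConsensusInteractions:
    """Integrate per-source interaction tables under a consensus rule.

    ``quorum2`` (default): keep an edge present in >= 2 distinct sources, or
    in any source flagged validated. ``union`` / ``intersection`` are the
    obvious alternatives. Provenance (supporting sources) is retained per
    edge; output is sorted by (type, regulator, target).
    """
    if rule not in _RULES:
        raise ValueError(f"unknown consensus rule {rule!r}; choose from {_RULES}")
    if not tables:
        raise ValueError("need at least one interaction table")

    support: dict[tuple[str, str, str], set[str]] = {}
    validated_hit: set[tuple[str, str, str]] = set()
    for tab in tables:
        for e in tab.edges:
            support.setdefault(e, set()).add(tab.source)
            if tab.validated:
                validated_hit.add(e)

    n_sources = len({t.source for t in tables})
    kept = []
    for e, srcs in support.items():
        if rule == "union":
            ok = True
        elif rule == "intersection":
            ok = len(srcs) == n_sources
        else:  # quorum2
            ok = len(srcs) >= 2 or e in validated_hit
        if ok:
            kept.append(e)
    kept.sort()
    return ConsensusInteractions(
        edges=kept,
        provenance={e: tuple(sorted(support[e])) for e in kept},
        rule=rule,
    )
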