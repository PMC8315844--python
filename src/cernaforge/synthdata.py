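"""Synthetic fixtures with the statistical structure the ceRNA analysis assumes.

Real studies of this design (two conditions, a handful of replicates, three
RNA classes) rarely deposit raw data, so every downstream stage here is
exercised on generated inputs: negative-binomial count matrices with planted
differential features, noisy multi-source target-prediction tables with
planted competing triplets, a PPI graph with planted dense complexes, and
gene-set collections with one planted enriched set. Ground truth is carried
alongside each fixture so recovery can be scored exactly.

All generators are deterministic given ``SimConfig.seed``; each stage draws
from its own substream (``default_rng([seed, stage_offset])``) so stages can
be regenerated independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RNA_CLASSES = ("lncRNA", "miRNA", "mRNA")

# fixed substream offsets, one per generator stage
_STREAM_EXPR = 11
_STREAM_INTERACT = 23
_STREAM_PPI = 37
_STREAM_GENESETS = 53
_STREAM_SEQ = 67
_STREAM_CT = 79


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the stated synthetic world.

    Defaults emulate the study design this pipeline targets: 3 vs 3
    replicates, ~10% planted differential features at |log2FC| = 3,
    negative-binomial counts with moderate dispersion, three overlapping
    prediction sources, and a PPI graph with planted complexes.
    """

    seed: int = 0
    n_replicates: int = 3
    n_lnc: int = 300
    n_mir: int = 150
    n_mrna: int = 2000
    frac_de: float = 0.1
    planted_lfc: float = 3.0
    dispersion: float = 0.05
    mean_log_range: tuple[float, float] = (3.0, 9.0)
    n_triplets: int = 5
    source_recall: float = 0.9
    source_fpr: float = 0.2
    ppi_n_nodes: int = 100
    ppi_n_complexes: int = 2
    ppi_complex_size: int = 6
    ppi_bg_edge_prob: float = 0.05
    n_genesets: int = 50
    planted_set_de_frac: float = 0.8
    geneset_size_range: tuple[int, int] = (10, 40)

    def __post_init__(self) -> None:
        for name in ("frac_de", "source_recall", "source_fpr",
                     "ppi_bg_edge_prob", "planted_set_de_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_replicates", "n_lnc", "n_mir", "n_mrna", "n_triplets",
                     "ppi_n_nodes", "ppi_n_complexes", "ppi_complex_size",
                     "n_genesets"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.planted_lfc <= 0:
            raise ValueError("planted_lfc must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (the DE test is "
                             "undefined with a single replicate)")


@dataclass
class ExpressionBundle:
    """Count matrices per RNA class plus sample map and planted-DE truth."""

    counts: dict[str, pd.DataFrame]
    lengths: dict[str, pd.Series]
    sample_condition: pd.Series  # index: sample id, values: control/treated
    truth_de: dict[str, pd.Series]  # values: up/down/null

    def samples(self, condition: str) -> list[str]:
        return list(self.sample_condition.index[self.sample_condition == condition])


@dataclass
class InteractionTruth:
    """Planted target-interaction layer: true edges, triplets, noisy sources."""

    true_edges: set[tuple[str, str, str]]  # (type, regulator, target)
    planted_triplets: list[tuple[str, str, str]]  # (lnc, mir, mrna)
    source_tables: dict[str, "pd.DataFrame"]  # source -> interaction table


@dataclass
class PPITruth:
    """Scored PPI edge table with planted-complex memberships."""

    edges: pd.DataFrame  # protein_a, protein_b, combined_score
    complexes: list[set[str]]
    nodes: list[str]


@dataclass
class GeneSetTruth:
    """GMT-style gene-set collection with one planted DE-enriched set."""

    sets: dict[str, set[str]]
    planted_set: str | None


def _rng(config: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, offset])


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


def generate_expression(config: SimConfig) -> ExpressionBundle:
    """Draw negative-binomial count matrices with planted DE features.

    Per-feature baseline means are log2-uniform over ``mean_log_range``;
    counts have variance ``mu + dispersion * mu**2``. A fraction ``frac_de``
    of features per class is planted differential: the treated-condition
    mean is multiplied by ``2**(+-planted_lfc)``, sign chosen uniformly.
    """
    rng = _rng(config, _STREAM_EXPR)
    n_rep = config.n_replicates
    samples = [f"ctrl_{i+1}" for i in range(n_rep)] + [f"trt_{i+1}" for i in range(n_rep)]
    condition = pd.Series(
        ["control"] * n_rep + ["treated"] * n_rep,
        index=pd.Index(samples, name="sample"), name="condition",
    )

    class_sizes = {"lncRNA": config.n_lnc, "miRNA": config.n_mir, "mRNA": config.n_mrna}
    prefixes = {"lncRNA": "LNC", "miRNA": "MIR", "mRNA": "GENE"}
    counts: dict[str, pd.DataFrame] = {}
    lengths: dict[str, pd.Series] = {}
    truth: dict[str, pd.Series] = {}

    lo, hi = config.mean_log_range
    for cls in RNA_CLASSES:
        n_feat = class_sizes[cls]
        ids = _feature_ids(prefixes[cls], n_feat)
        base_mu = 2.0 ** rng.uniform(lo, hi, size=n_feat)

        n_de = int(round(config.frac_de * n_feat))
        de_idx = rng.choice(n_feat, size=n_de, replace=False) if n_de else np.array([], int)
        signs = rng.choice([1.0, -1.0], size=n_de)
        labels = np.array(["null"] * n_feat, dtype=object)
        labels[de_idx] = np.where(signs > 0, "up", "down")

        fold = np.ones(n_feat)
        fold[de_idx] = 2.0 ** (signs * config.planted_lfc)

        mu = np.column_stack(
            [base_mu] * n_rep + [base_mu * fold] * n_rep
        )  # features x samples
        # NB with var = mu + a*mu^2  =>  n = 1/a, p = n/(n+mu)
        n_param = 1.0 / config.dispersion
        p_param = n_param / (n_param + mu)
        mat = rng.negative_binomial(n_param, p_param)

        idx = pd.Index(ids, name="feature_id")
        counts[cls] = pd.DataFrame(mat, index=idx, columns=samples)
        if cls == "miRNA":
            feat_len = rng.integers(20, 25, size=n_feat)
        else:
            feat_len = rng.integers(200, 3000, size=n_feat)
        lengths[cls] = pd.Series(feat_len, index=idx, name="length")
        truth[cls] = pd.Series(labels, index=idx, name="truth")

    return ExpressionBundle(counts=counts, lengths=lengths,
                            sample_condition=condition, truth_de=truth)


SOURCE_NAMES = ("mirandish", "targetscannish", "mirtarbasish")
VALIDATED_SOURCES = frozenset({"mirtarbasish"})  # miRTarBase-like: experimentally validated


def generate_interactions(config: SimConfig, bundle: ExpressionBundle) -> InteractionTruth:
    """Plant competing triplets and emit noisy per-source interaction tables.

    Each planted triplet (lncRNA, miRNA, mRNA) uses distinct DE features with
    coherent directions (miRNA opposite to both partners) and contributes one
    lncRNA->miRNA and one miRNA->mRNA true edge. Each of the three sources
    contains each true edge with probability ``source_recall`` plus
    ``round(source_fpr * n_true)`` uniformly drawn false edges.
    """
    rng = _rng(config, _STREAM_INTERACT)
    t = bundle.truth_de

    def de_ids(cls: str, direction: str) -> list[str]:
        s = t[cls]
        return list(s.index[s == direction])

    triplets: list[tuple[str, str, str]] = []
    pools = {
        "up": (de_ids("lncRNA", "down"), de_ids("miRNA", "up"), de_ids("mRNA", "down")),
        "down": (de_ids("lncRNA", "up"), de_ids("miRNA", "down"), de_ids("mRNA", "up")),
    }
    capacity = sum(min(len(l), len(m), len(g)) for l, m, g in pools.values())
    if capacity < config.n_triplets:
        raise ValueError(
            f"cannot plant {config.n_triplets} direction-coherent triplets: only "
            f"{capacity} available from the DE features of this bundle "
            "(increase frac_de or class sizes)"
        )
    # alternate miRNA directions while capacity lasts, consuming without replacement
    pools = {k: [[str(x) for x in rng.permutation(p)] for p in v]
             for k, v in pools.items()}
    order = ["up", "down"]
    while len(triplets) < config.n_triplets:
        for d in order:
            l, m, g = pools[d]
            if l and m and g and len(triplets) < config.n_triplets:
                triplets.append((l.pop(), m.pop(), g.pop()))

    true_edges = set()
    for lnc, mir, mrna in triplets:
        true_edges.add(("lnc_mir", lnc, mir))
        true_edges.add(("mir_mrna", mir, mrna))

    all_lnc = list(t["lncRNA"].index)
    all_mir = list(t["miRNA"].index)
    all_mrna = list(t["mRNA"].index)

    def random_false_edges(n: int) -> set[tuple[str, str, str]]:
        out: set[tuple[str, str, str]] = set()
        guard = 0
        while len(out) < n and guard < 100 * (n + 1):
            guard += 1
            if rng.random() < 0.5:
                e = ("lnc_mir", all_lnc[rng.integers(len(all_lnc))],
                     all_mir[rng.integers(len(all_mir))])
            else:
                e = ("mir_mrna", all_mir[rng.integers(len(all_mir))],
                     all_mrna[rng.integers(len(all_mrna))])
            if e not in true_edges:
                out.add(e)
        return out

    sorted_true = sorted(true_edges)
    tables: dict[str, pd.DataFrame] = {}
    for source in SOURCE_NAMES:
        keep = [e for e in sorted_true if rng.random() < config.source_recall]
        false = sorted(random_false_edges(int(round(config.source_fpr * len(true_edges)))))
        rows = [
            {"source": source, "type": typ, "regulator": reg, "target": tgt,
             "score": float(np.round(rng.uniform(0.5, 1.0), 4)),
             "validated": source in VALIDATED_SOURCES}
            for typ, reg, tgt in keep + false
        ]
        tables[source] = pd.DataFrame(
            rows, columns=["source", "type", "regulator", "target", "score", "validated"]
        )

    return InteractionTruth(true_edges=true_edges, planted_triplets=triplets,
                            source_tables=tables)


def generate_ppi(config: SimConfig) -> PPITruth:
    """Erdős–Rényi background with planted clique complexes, STRING-like scores.

    Within-complex edges score uniform(0.7, 1.0) — above any usual cutoff;
    background edges score uniform(0.1, 0.9), straddling the 0.4 cutoff.
    """
    if config.ppi_n_complexes and config.ppi_complex_size < 3:
        raise ValueError("ppi_complex_size must be >= 3")
    if config.ppi_n_complexes * config.ppi_complex_size > config.ppi_n_nodes:
        raise ValueError(
            f"{config.ppi_n_complexes} complexes of size {config.ppi_complex_size} "
            f"do not fit in {config.ppi_n_nodes} nodes"
        )
    rng = _rng(config, _STREAM_PPI)
    nodes = _feature_ids("PROT", config.ppi_n_nodes)

    complexes: list[set[str]] = []
    edges: dict[tuple[str, str], float] = {}
    k = config.ppi_complex_size
    for c in range(config.ppi_n_complexes):
        members = nodes[c * k:(c + 1) * k]
        complexes.append(set(members))
        for i in range(k):
            for j in range(i + 1, k):
                edges[(members[i], members[j])] = float(np.round(rng.uniform(0.7, 1.0), 4))

    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            key = (nodes[i], nodes[j])
            if key in edges:
                continue
            if rng.random() < config.ppi_bg_edge_prob:
                edges[key] = float(np.round(rng.uniform(0.1, 0.9), 4))

    df = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["protein_a", "protein_b", "combined_score"],
    )
    return PPITruth(edges=df, complexes=complexes, nodes=nodes)


def generate_genesets(config: SimConfig, bundle: ExpressionBundle) -> GeneSetTruth:
    """Random gene sets over the mRNA universe, with one DE-enriched planted set.

    The planted set draws ``planted_set_de_frac`` of its members from
    truth-DE mRNAs (up or down); all other sets are uniform draws from the
    universe.
    """
    universe = list(bundle.truth_de["mRNA"].index)
    if not universe:
        raise ValueError("mRNA universe is empty")
    rng = _rng(config, _STREAM_GENESETS)
    lo, hi = config.geneset_size_range
    if lo < 1:
        raise ValueError("geneset sizes must be >= 1")

    de_pool = [g for g in universe if bundle.truth_de["mRNA"][g] != "null"]
    non_de_pool = [g for g in universe if bundle.truth_de["mRNA"][g] == "null"]

    sets: dict[str, set[str]] = {}
    planted_name: str | None = None
    for i in range(config.n_genesets):
        size = int(rng.integers(lo, hi + 1))
        if size > len(universe):
            raise ValueError(f"gene-set size {size} exceeds universe {len(universe)}")
        name = f"SET_{i+1:04d}"
        if i == 0 and de_pool:
            n_de = min(int(round(config.planted_set_de_frac * size)), len(de_pool))
            members = set(rng.choice(de_pool, size=n_de, replace=False))
            fill_pool = non_de_pool if len(non_de_pool) >= size - n_de else universe
            while len(members) < size:
                members.add(fill_pool[rng.integers(len(fill_pool))])
            planted_name = name
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        sets[name] = members
    return GeneSetTruth(sets=sets, planted_set=planted_name)


_NT = np.array(list("ACGU"))


def random_sequences(config: SimConfig, n_mirnas: int = 10, n_utrs: int = 10,
                     mirna_len: int = 22, utr_len: int = 300) -> tuple[dict[str, str], dict[str, str]]:
    """Random RNA sequences (miRNAs and 3'UTRs) for the seed-site scanner."""
    rng = _rng(config, _STREAM_SEQ)
    mirnas = {f"mir_{i+1}": "".join(rng.choice(_NT, size=mirna_len))
              for i in range(n_mirnas)}
    utrs = {f"utr_{i+1}": "".join(rng.choice(_NT, size=utr_len))
            for i in range(n_utrs)}
    return mirnas, utrs


def simulate_ct_table(config: SimConfig, gene_log2fc: dict[str, float],
                      reference_id: str = "GAPDH", ct_noise_sd: float = 0.1,
                      base_ct: float = 22.0, ref_ct: float = 16.0) -> pd.DataFrame:
    """Simulate a qPCR Ct table realizing known fold changes.

    Treated-condition target Ct is shifted by ``-log2fc`` cycles relative to
    control (one PCR cycle per 2-fold change, efficiency exactly 2);
    Gaussian well noise with ``ct_noise_sd`` cycles is added everywhere.
    """
    rng = _rng(config, _STREAM_CT)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for cond in ("control", "treated"):
            sample = f"{cond[:4]}_{rep}"
            rows.append({"sample_id": sample, "condition": cond,
                         "gene_id": reference_id, "reference_id": reference_id,
                         "ct": ref_ct + rng.normal(0, ct_noise_sd), "replicate": rep})
            for gene, lfc in gene_log2fc.items():
                ct = base_ct - (lfc if cond == "treated" else 0.0)
                rows.append({"sample_id": sample, "condition": cond,
                             "gene_id": gene, "reference_id": reference_id,
                             "ct": ct + rng.normal(0, ct_noise_sd), "replicate": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization


def write_bundle(bundle: ExpressionBundle, outdir: str | Path) -> dict[str, Path]:
    """Write counts/lengths/sample-map/truth TSVs; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cls in RNA_CLASSES:
        p = outdir / f"counts_{cls}.tsv"
        bundle.counts[cls].to_csv(p, sep="\t", index_label="feature_id")
        paths[f"counts_{cls}"] = p
        p = outdir / f"lengths_{cls}.tsv"
        bundle.lengths[cls].to_frame().to_csv(p, sep="\t", index_label="feature_id")
        paths[f"lengths_{cls}"] = p
        p = outdir / f"truth_de_{cls}.tsv"
        bundle.truth_de[cls].to_frame().to_csv(p, sep="\t", index_label="feature_id")
        paths[f"truth_de_{cls}"] = p
    p = outdir / "samples.tsv"
    bundle.sample_condition.to_frame().to_csv(p, sep="\t", index_label="sample")
    paths["samples"] = p
    return paths


def read_bundle(indir: str | Path) -> ExpressionBundle:
    indir = Path(indir)
    counts, lengths, truth = {}, {}, {}
    for cls in RNA_CLASSES:
        counts[cls] = pd.read_csv(indir / f"counts_{cls}.tsv", sep="\t", index_col="feature_id")
        lengths[cls] = pd.read_csv(indir / f"lengths_{cls}.tsv", sep="\t",
                                   index_col="feature_id")["length"]
        tp = indir / f"truth_de_{cls}.tsv"
        if tp.exists():
            truth[cls] = pd.read_csv(tp, sep="\t", index_col="feature_id")["truth"]
    cond = pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample")["condition"]
    return ExpressionBundle(counts=counts, lengths=lengths,
                            sample_condition=cond, truth_de=truth)


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (e.g. parsed YAML), tuple-ifying ranges."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    kwargs = {k: v for k, v in d.items() if k in known}
    for key in ("mean_log_range", "geneset_size_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return SimConfig(**kwargs)
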