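"""End-to-end orchestration: synth -> DE -> consensus -> ceRNA -> PPI/MCODE ->
ORA -> qPCR concordance, under one config, with a manifest of outputs.

Each stage writes its result to disk before the next consumes it, so any
stage can be rerun standalone on the manifest's intermediates. The whole run
is deterministic given the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import synthdata, diffexpr, targetnet, cerna, ppimcode, enrich, qpcr
from .synthdata import SimConfig

log = logging.getLogger("cernaforge.pipeline")


@dataclass
class PipelineConfig:
    """Fully-populated default profile mirroring the usual analysis thresholds:
    |log2FC| > 2 at p < 0.05 for screening, PPI combined score > 0.4,
    raw enrichment p < 0.05, direction-mode triplet negativity."""

    seed: int = 0
    outdir: str = "cernaforge_out"
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    lfc_cut: float = 2.0
    p_cut: float = 0.05
    pseudocount: float = 1.0
    consensus_rule: str = "quorum2"
    triplet_mode: str = "direction"
    triplet_r_max: float = -0.7
    ppi_cutoff: float = 0.4
    ppi_scale: str = "auto"
    mcode: dict = field(default_factory=dict)      # MCODEParams overrides
    enrich_p_cut: float = 0.05
    ct_noise_sd: float = 0.1

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sim_config(self) -> SimConfig:
        d = dict(self.sim)
        d["seed"] = self.seed
        return synthdata.config_from_dict(d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; return the manifest.

    The manifest maps each written file to its sha256 and carries a summary:
    DE counts per class/direction, consensus edge count, triplet count,
    network role counts, complex count, significant-set count, and the
    qPCR/sequencing concordance fraction. Any stage failure raises with the
    stage name; files written so far are left in place for debugging.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    summary: dict = {}

    def record(name: str, path: Path) -> None:
        files[name] = str(path.relative_to(outdir))

    stage = "synthdata"
    try:
        sim = config.sim_config()
        log.info("[%s] generating fixtures (seed=%d)", stage, sim.seed)
        bundle = synthdata.generate_expression(sim)
        for name, p in synthdata.write_bundle(bundle, outdir / "synth").items():
            record(f"synth/{name}", p)
        interactions = synthdata.generate_interactions(sim, bundle)
        for source, df in interactions.source_tables.items():
            p = outdir / "synth" / f"interactions_{source}.tsv"
            df.to_csv(p, sep="\t", index=False)
            record(f"synth/interactions_{source}", p)
        ppi_truth = synthdata.generate_ppi(sim)
        ppi_path = outdir / "synth" / "ppi.tsv"
        ppi_truth.edges.to_csv(ppi_path, sep="\t", index=False)
        record("synth/ppi", ppi_path)
        genesets = synthdata.generate_genesets(sim, bundle)
        gmt_path = outdir / "synth" / "genesets.gmt"
        synthdata.write_gmt(genesets.sets, gmt_path)
        record("synth/genesets", gmt_path)

        stage = "diffexpr"
        log.info("[%s] testing %d+%d+%d features", stage, sim.n_lnc, sim.n_mir, sim.n_mrna)
        records = diffexpr.test_differential(bundle, pseudocount=config.pseudocount)
        desets = diffexpr.screen_de(records, lfc_cut=config.lfc_cut, p_cut=config.p_cut)
        de_path = outdir / "de.tsv"
        diffexpr.records_to_frame(records).to_csv(de_path, sep="\t", index=False)
        record("de", de_path)
        summary["de_counts"] = {
            cls: {"up": len(desets.up.get(cls, [])), "down": len(desets.down.get(cls, []))}
            for cls in synthdata.RNA_CLASSES
        }

        stage = "targetnet"
        tables = [targetnet.InteractionTable.from_frame(df, source=s)
                  for s, df in interactions.source_tables.items()]
        consensus = targetnet.combine_sources(tables, rule=config.consensus_rule)
        cons_path = outdir / "consensus.tsv"
        consensus.to_frame().to_csv(cons_path, sep="\t", index=False)
        record("consensus", cons_path)
        summary["consensus_edges"] = len(consensus.edges)
        log.info("[%s] %d consensus edges (rule=%s)", stage,
                 len(consensus.edges), config.consensus_rule)

        stage = "cerna"
        params = cerna.TripletParams(mode=config.triplet_mode, r_max=config.triplet_r_max)
        triplets = cerna.find_triplets(desets, consensus, expr=bundle, params=params)
        net = cerna.assemble_network(triplets, desets=desets)
        trip_path = outdir / "triplets.tsv"
        pd.DataFrame(
            [{"lnc_id": t.lnc_id, "mir_id": t.mir_id, "mrna_id": t.mrna_id}
             for t in triplets],
            columns=["lnc_id", "mir_id", "mrna_id"],
        ).to_csv(trip_path, sep="\t", index=False)
        record("triplets", trip_path)
        record("network_sif", cerna.export_network(net, outdir / "cerna.sif", "sif"))
        record("network_graphml",
               cerna.export_network(net, outdir / "cerna.graphml", "graphml"))
        net_summary = cerna.summarize_network(net)
        summary["n_triplets"] = len(triplets)
        summary["network_roles"] = net_summary["by_role"]
        log.info("[%s] %d triplets, %d nodes", stage, len(triplets),
                 net_summary["n_nodes"])

        stage = "ppimcode"
        graph = ppimcode.build_ppi(ppi_truth.edges, cutoff=config.ppi_cutoff,
                                   scale=config.ppi_scale)
        mcode_params = ppimcode.MCODEParams(**config.mcode)
        complexes = ppimcode.mcode_find_complexes(graph, mcode_params)
        cx_path = outdir / "complexes.tsv"
        ppimcode.complexes_to_frame(complexes).to_csv(cx_path, sep="\t", index=False)
        record("complexes", cx_path)
        summary["n_complexes"] = len(complexes)
        log.info("[%s] %d nodes / %d edges above cutoff %.2f, %d complexes",
                 stage, graph.number_of_nodes(), graph.number_of_edges(),
                 config.ppi_cutoff, len(complexes))

        stage = "enrich"
        universe = set(bundle.truth_de["mRNA"].index)
        query = desets.members("mRNA")
        enr = enrich.ora(query, universe, genesets.sets, p_cut=config.enrich_p_cut)
        enr_path = outdir / "enrichment.tsv"
        enrich.records_to_frame(enr).to_csv(enr_path, sep="\t", index=False)
        record("enrichment", enr_path)
        summary["n_significant_sets"] = sum(r.significant for r in enr)

        stage = "qpcr"
        seq_lfc = {r.feature_id: r.log2fc for r in records
                   if r.feature_id in net.nodes}
        if seq_lfc:
            # validate network members: Ct tables realized from the planted truth
            truth_lfc = {}
            for fid in seq_lfc:
                role = net.nodes[fid][0]
                label = bundle.truth_de[role][fid]
                truth_lfc[fid] = {"up": sim.planted_lfc,
                                  "down": -sim.planted_lfc}.get(label, 0.0)
            ct = synthdata.simulate_ct_table(sim, truth_lfc,
                                             ct_noise_sd=config.ct_noise_sd)
            ct_path = outdir / "ct.tsv"
            ct.to_csv(ct_path, sep="\t", index=False)
            record("ct", ct_path)
            fc = {g: qpcr.ddct_fold_change(ct, g) for g in sorted(seq_lfc)}
            conc = qpcr.concordance(fc, seq_lfc)
            summary["concordance_fraction"] = conc["fraction"]
            summary["n_validated_genes"] = conc["n_genes"]
        else:
            summary["concordance_fraction"] = None
            summary["n_validated_genes"] = 0
        log.info("[%s] concordance=%s", stage, summary["concordance_fraction"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "files": {name: {"path": rel, "sha256": _sha256(outdir / rel)}
                  for name, rel in sorted(files.items())},
        "summary": summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return manifest
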