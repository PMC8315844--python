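# cernaforge

A tested, reusable implementation of the competing-endogenous-RNA (ceRNA)
network analysis used in two-condition transcriptome studies (e.g. a
drug-treated vs untreated cancer cell line profiled for lncRNA, miRNA and
mRNA expression). It is aimed at computational biologists who want the whole
chain — differential screening, target-prediction integration, triplet
construction, hub-module detection, enrichment, qPCR concordance — as
composable, deterministic library functions instead of a collage of web
tools.

## What it computes

- **Differential expression**: TPM quantification
  (`TPM_i = rate_i / Σ rate_j × 10⁶`, `rate_i = count_i/(length_i/1000)`),
  Welch t-test on log₂(TPM+1), screening at strict |log₂FC| > 2, p < 0.05.
- **Consensus miRNA targets**: edges from multiple prediction sources kept
  when supported by ≥2 sources or any validated source (configurable), plus
  a built-in canonical seed-site scanner (8mer / 7mer-m8 / 7mer-A1 / 6mer,
  Watson–Crick only).
- **Competing triplets**: (lncRNA, miRNA, mRNA) with all three
  differentially expressed, both consensus edges present, and the miRNA
  negatively coexpressed with both partners (opposite-direction proxy by
  default; Pearson/Spearman r < −0.7 for designs with ≥6 samples). The
  tripartite ceRNA network is derived from the triplets and exported as
  SIF/GraphML/TSV.
- **PPI hub modules**: combined-score filtering (0–1000 or 0–1 scales) and a
  from-scratch MCODE (core-clustering vertex weights `k(H)·density(H)`,
  VWP-thresholded seeded expansion, 2-core filter, haircut/fluff).
- **Over-representation**: exact upper-tail hypergeometric p-values
  `P(X ≥ k)` against a GMT collection with Benjamini–Hochberg q-values.
- **qPCR concordance**: Livak 2^−ΔΔCt fold changes and sign agreement with
  sequencing log₂FC.
- **Synthetic data**: a negative-binomial expression generator with planted
  differential features, planted triplets behind noisy prediction sources,
  planted PPI complexes, and a planted enriched gene set — ground truth
  recorded, everything seeded.

See `docs/methods.md` for models, parameter defaults, numerical choices, and
known limitations.

## Worked example

Run the whole pipeline on its synthetic world:

```bash
cerna-forge run --seed 1 --out out/
```

which prints the run summary (identical for identical seeds):

```json
{
  "concordance_fraction": 1.0,
  "consensus_edges": 12,
  "de_counts": {
    "lncRNA": {"down": 16, "up": 13},
    "mRNA": {"down": 91, "up": 100},
    "miRNA": {"down": 8, "up": 7}
  },
  "n_complexes": 6,
  "n_significant_sets": 2,
  "n_triplets": 3,
  "n_validated_genes": 9,
  "network_roles": {"lncRNA": 3, "mRNA": 3, "miRNA": 3}
}
```

Reading it: of 2450 simulated features, 235 pass the |log₂FC| > 2, p < 0.05
screen (the world plants 10% at |log₂FC| = 3); 12 lncRNA→miRNA /
miRNA→mRNA edges survive the two-source consensus; they support 3 competing
triplets whose 9 member RNAs form the ceRNA network; MCODE finds 6 dense
modules in the 100-protein PPI graph (the two top-ranked are the planted
complexes); 2 gene sets are enriched at raw p < 0.05 (one is planted); and
the simulated qPCR fold changes of all 9 network members agree in sign with
the sequencing estimates. `out/` holds every intermediate (counts, DE table,
consensus, triplets, SIF/GraphML network, complexes, enrichment, Ct table)
plus `manifest.json` with sha256 hashes.

The same stages are available piecewise (`cerna-forge synth|de|targets|
seedscan|cerna|mcode|ora|qpcr`) and as plain functions:

```python
from cernaforge import SimConfig, synthdata, test_differential, screen_de

cfg = SimConfig(seed=1)
bundle = synthdata.generate_expression(cfg)
desets = screen_de(test_differential(bundle))
print(len(desets.up["mRNA"]), len(desets.down["mRNA"]))  # 100 91
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on the synthetic world for the given
seed and echoes the run summary.
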