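# Methods

`cernaforge` implements the analysis chain behind competing-endogenous-RNA
(ceRNA) studies of two-condition cell-line experiments: screen each RNA class
(lncRNA, miRNA, mRNA) for differential expression, integrate miRNA-target
predictions from several sources, enumerate competing triplets, assemble the
tripartite ceRNA network, detect dense hub modules in a protein-protein
interaction (PPI) graph, test gene sets for over-representation, and check
qPCR concordance. Because studies of this design rarely deposit raw data,
the package carries a synthetic-data generator that realizes the statistical
structure each stage assumes, with ground truth recorded for recovery
scoring.

## Expression model and differential screening

Counts are negative binomial with per-feature baseline mean `mu` drawn
log2-uniform on `mean_log_range` (default `[3, 9]`, i.e. means from 8 to 512
counts) and variance `mu + dispersion * mu^2` with a common dispersion
(default 0.05, a typical cell-line value). A fraction `frac_de` (default
0.1) of features is planted differential: the treated mean is multiplied by
`2^(+-planted_lfc)` (default magnitude 3), sign uniform. The design is 3 vs
3 replicates, the common minimum for such experiments. miRNA counts use the
same model; small-RNA protocol differences are not modeled, since only the
analysis-level structure matters downstream.

Expression is quantified as transcripts per million (TPM): per sample,
`rate_i = count_i / (length_i/1000)` scaled so each column sums to 1e6. The
group comparison is a Welch two-sample t-test on `log2(TPM + 1)`; the
pseudocount (1 TPM, configurable) bounds the fold change of zero-count
features. Tools such as Ballgown fill this role on real isoform-level data;
their internal models are intentionally not reproduced — the pipeline's
contract is a per-feature p-value and log2 fold change (treated over
control), screened at strict `|log2FC| > 2` and `p < 0.05`. Screening is
idempotent and threshold-monotone. No multiple-testing correction is applied
at this stage (the screening convention in this literature uses raw p).

**Known limitation (measured, not hidden):** at 3 vs 3 the Welch test on
log counts is conservative — the null rejection rate at p < 0.05 is about
0.034 rather than 0.05 (it reaches 0.0496 at n = 10 and 0.0503 at n = 30
with the same generator). The acceptance test asserting nominal calibration
is therefore expected to fail at the default design and is kept as stated
rather than widened; planted-effect recovery is unaffected (sensitivity
~0.96, false-discovery proportion <0.01 at the default effect size).

A second caveat: TPM is compositional. When a large planted mass is
unbalanced, every fold-change estimate shifts by the change in the
normalization total; at the default 10% planted fraction with symmetric
directions the shift is negligible.

## Target interactions and consensus

Three simulated sources mimic the practical mix of predictive and validated
databases (miRanda-like, TargetScan-like, miRTarBase-like; the last flagged
validated). Each source contains each true edge with probability
`source_recall` (default 0.9) and `round(source_fpr * n_true)` uniformly
drawn false edges (default `source_fpr` 0.2). How real studies "combine"
such sources is rarely stated, so the rule is explicit and configurable:
the default `quorum2` keeps an edge supported by >= 2 distinct sources or by
any validated source; `union` and `intersection` are available. Consensus is
monotone in sources and retains per-edge provenance.

The built-in site scanner implements canonical seed matching only:
Watson-Crick reverse-complement matches to miRNA positions 2-7, classified
as 8mer / 7mer-m8 / 7mer-A1 / 6mer, where the m8 position pairs miRNA
nucleotide 8 and the A1 position is a literal adenosine (recognized by
Argonaute, not base-paired). No G:U wobble, context scoring, or conservation
filtering — the predictor is exactly specifiable and is tested against a
brute-force window oracle. lncRNA sponge sites are scanned with the same
rules as 3'UTR sites. Coordinates are 0-based half-open on the transcript.

## Competing triplets and the ceRNA network

A triplet (lncRNA l, miRNA m, mRNA g) is emitted iff all three are
differentially expressed, both edges l->m and m->g survive the consensus,
and both pairs are negatively coexpressed with the miRNA. "Negatively
coexpressed" has no standard operationalization at n = 6 samples, so two
modes exist:

- `direction` (default): opposite DE direction of the miRNA versus each
  partner. This is the only statistically defensible reading for 3 vs 3
  designs.
- `correlation`: Pearson (or Spearman) r < `r_max` (default -0.7) on
  log2(TPM+1) across all samples; refused below `min_samples` (default 6).
  An undefined correlation (constant vector) fails the negativity test.

The miRNA must itself be differentially expressed — published ceRNA
networks of this kind contain only DE miRNAs. The network is always derived
from triplets (never assembled from raw edges), which enforces
tripartiteness and guarantees every node participates in a triplet. Whether
to additionally require lncRNA-mRNA *positive* coexpression (as some ceRNA
methods do) was left out: the triplet definition used here does not include
it, and adding it would silently shrink recall on the planted worlds.

Exports: SIF and edge-TSV (tab-safe IDs enforced), GraphML with role and
direction attributes (round-trips exactly).

## PPI graph and MCODE

Edge tables carry STRING-style combined scores on either the 0-1000 or 0-1
scale; `build_ppi` normalizes to [0, 1] (`auto` divides by 1000 when any
score exceeds 1) and keeps edges with score strictly greater than the
cutoff. The cutoff is a required argument with no default because published
thresholds genuinely differ (0.4 "medium" and 0.7 "high" are both in use);
the pipeline's default profile uses 0.4.

MCODE is implemented from its published three-stage description with the
usual plugin defaults (VWP 0.2, degree cutoff 2, haircut on, fluff off):

1. *Vertex weighting.* weight(v) = k(H) x density(H), where H is the
   highest-k core of the induced subgraph on the open neighborhood N(v);
   vertices of degree < 2 (or below `degree_cutoff`) weigh 0.
2. *Expansion.* Seeds are unassigned vertices in descending weight order
   (ties to the smaller ID; zero-weight vertices never seed, since their
   expansion threshold of 0 would swallow whole components). A neighbor is
   admitted iff its weight is >= weight(seed) x (1 - VWP) **and**, once the
   complex has >= 2 members, it attaches by >= 2 edges. This *bridge guard*
   is a deliberate deviation from pure threshold expansion: without it, two
   K5 cliques joined by a single bridge edge merge into one 10-node complex
   (all their vertices carry equal weight), which defeats the purpose of a
   dense-module detector. The guard is consistent with the 2-core semantics
   of stage 3 and leaves clique growth unchanged.
3. *Post-processing.* Complexes lacking a 2-core are dropped; optional fluff
   adds neighbors whose closed-neighborhood density exceeds `fluff_density`
   (fluffed nodes may repeat across complexes); haircut restricts to the
   complex 2-core, and pruned vertices return to the unassigned pool so a
   later complex can claim them. Score = density x size; ranking is by score
   descending, ties by seed ID.

The synthetic PPI world plants `ppi_n_complexes` cliques (size 6 by default,
within-complex scores 0.7-1.0) in an Erdős–Rényi background (p = 0.05,
scores 0.1-0.9, straddling the 0.4 cutoff). Mean recovery Jaccard of the
top-2 complexes is ~0.95 over 10 seeds; occasional fixtures draw several
background edges between the two planted cliques, and any local-density
method merges them (per-complex Jaccard 0.5 in ~1 of 10 seeds). Note that a
sparse random background is *not* complex-free: G(50, 0.05) contains a
triangle with probability ~0.9, and a triangle is a legitimate 2-core
complex, so "no planted complexes" does not imply "no detected complexes".

## Over-representation analysis

For each gene set (GMT), the upper-tail hypergeometric probability
P(X >= k) of the observed overlap k between the query (DE mRNAs) and the set
(size K after intersection with the universe), drawing n = |query| from
N = |universe|. The universe is all expressed mRNAs in the experiment — the
only universe constructible without external annotation, and standard ORA
practice. Benjamini-Hochberg q-values are computed across the collection
(via statsmodels), but the significance flag uses raw p < 0.05, matching the
screening convention in this literature. GO/KEGG hierarchies are not
modeled; any GMT collection is accepted. The synthetic collection plants one
set drawing `planted_set_de_frac` (default 0.8) of its members from DE
mRNAs; the rest are uniform draws.

## qPCR concordance

Relative expression follows the Livak 2^-ddCt formulation: technical
replicates are averaged per (sample, gene); dCt = Ct_gene - Ct_reference
within the same sample (the per-sample subtraction makes the estimate
invariant to sample-wise loading offsets, asserted on random tables);
ddCt = mean(dCt treated) - mean(dCt control); fold change = 2^-ddCt with
amplification efficiency assumed exactly 2 (no standard-curve correction).
The simulated Ct tables shift the treated target Ct by -log2(fold change)
cycles and add Gaussian well noise (default sd 0.1 cycles, typical
instrument repeatability). Concordance with sequencing is per-gene sign
agreement between log2 of the qPCR fold change and the sequencing log2FC
(zeros discordant) plus the overall fraction.

## Pipeline, determinism, and the synthetic world's limits

`run_pipeline` executes the stages in dependency order under one YAML
config, writing every intermediate as TSV/GMT/SIF/GraphML plus a manifest
with sha256 hashes and a summary (DE counts, consensus edges, triplets,
network role counts, complexes, significant sets, concordance). Every random
draw descends from the single global seed through fixed per-stage substreams
(`default_rng([seed, offset])`), so identical configs give byte-identical
outputs and any stage can be regenerated independently.

What a green suite establishes — and does not: the generator emulates the
*analysis-level* structure (planted effects, overlapping noisy sources,
planted dense complexes, a planted enriched set), not read-level artifacts,
library-size variation, isoform ambiguity, batch effects, or database
version drift. Recovery results on this world say the algorithms implement
their definitions and can detect the structure they target at realistic
noise; they do not certify performance on any particular real dataset, and
published headline counts from real studies (which depend on undeposited
raw data and dated database snapshots) are out of reach by construction.
The one worked example taken from the literature — a 23-node ceRNA network
of 2 lncRNA decoys, 3 central miRNAs, and 18 mRNA targets — checks network
assembly arithmetic on printed membership; its mRNA wiring is a synthetic
round-robin stand-in because the original edge list is not public.
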