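# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Co-occurrence network

Input is a fixed-depth OTU count table (samples × OTUs) with one
lineage label per OTU and a set of lineage labels flagged as
methanogens.

**Core filter.** An OTU is "core" when its pooled count across all
samples, divided by the table's grand total, strictly exceeds
`min_pooled_rel_abundance` (default 1e-5, i.e. 0.001%) *and* it is
non-zero in at least `min_occurrence` samples (default 2). The
abundance criterion is read as a pooled quantity; a per-sample variant
can be had by pre-filtering, but pooled is the default because the
threshold is defined against "total sequences". The filter is
idempotent and preserves sample set and OTU order.

**Edges.** Spearman's ρ is computed on per-sample relative abundances
for every OTU pair, with average ranks for ties and two-sided p-values
from the large-sample t approximation (`scipy.stats.spearmanr`). Rank
correlation is invariant to the per-sample normalisation, but relative
abundances are used so the documented substrate matches compositional
intuition. Benjamini–Hochberg adjustment is applied jointly across
*all* tested pairs — one family, not per-OTU families. An edge is kept
iff ρ > `rho_min` (default 0.6), adjusted p < `q_max` (default 0.01),
and, with `positive_only` (default), ρ > 0. Constant (all-tied) OTU
vectors have undefined rank correlation; their pairs are excluded from
testing *and* from the FDR family (a ρ = 0 placeholder would dilute the
adjustment), with a logged warning. Isolated OTUs remain nodes.

`q_max=None` disables the FDR gate entirely. This exists for null
calibration studies — under a global null, BH-adjusted p-values
concentrate near 1, so any FDR-gated network of association-free data
is empty and there is nothing to calibrate against. It is not intended
for inference.

## Observed/random incidence ratio

For lineage groups A and B in a network with N nodes and m edges, the
observed statistic is the number of edges with one endpoint in each
group. Three null models give the expected count:

- `analytic_er` (default): `m · n_A·n_B / C(N,2)` — the mean over all
  graphs with the same N and m, exact by pair-exchangeability.
- `permutation_er`: Monte-Carlo mean over uniformly random simple
  graphs with the same N and m. Implemented by sampling uniform
  m-subsets of the C(N,2) node pairs (vectorised and chunked), which is
  distributionally exact for the cross-edge count. Also returns
  `perm_p = (1 + #{null ≥ observed}) / (1 + n_permutations)`.
- `degree_preserving`: the same Monte-Carlo scheme over
  double-edge-swap rewirings that preserve the degree sequence
  (networkx), for when hub structure should be held fixed.

O/R = observed/expected; O/R > 1 marks a non-random association, and
the screening operation retains exactly those partners. The original
definition of "random incidence" is not pinned down in the source
methodology, hence the configurable null; the analytic and permutation
nulls agree to Monte-Carlo precision by construction, and the
degree-preserving null is the conservative alternative when degree
heterogeneity is itself the confounder. With m = 0 the ratio is
undefined and flagged (NaN), never coerced to 0 or 1.

The permutation p is a discrete statistic: with few edges the null
cross-edge count takes few values and the test is conservative (the
achievable rejection rate at nominal 5% falls below 0.05 by roughly
`0.1/sd(null)`). Calibration checks should therefore be run on graphs
with enough chance edges (null sd ≳ 5); the shipped calibration uses a
ρ > 0.1 threshold network (~440 chance edges on 60 association-free
OTUs) where the measured rejection rate is 0.04 and mean O/R is 1.00.

## Pathway calls

A pathway is an ordered list of required steps; each step lists
acceptable marker groups (`any_of`), where synonyms are ORed (fwd or
fmd) and complex subunits ANDed (hdrA∧hdrB∧hdrC∧mvhA∧mvhD∧mvhG).
Completeness is the unweighted fraction of satisfied steps — no
weighting scheme is defensible from gene lists alone — and `complete`
requires completeness = 1.0 exactly. A configurable soft threshold
exists for exploratory use and is off by default; the strict rule is
what makes "no complete pathway in a bin lacking mcr" a theorem rather
than a tendency, since mcr is a required step of all three pathways.

The default marker config defines the three pathways plus four
auxiliary modules reported as flags: `hdr_mvh` (H₂ oxidation coupled to
CoB-S-S-CoM reduction), `ech_eha_ehb` (membrane-bound energy-conserving
hydrogenases), `fpo_hdrD` (F₄₂₀H₂ dehydrogenase/heterodisulfide
reductase coupling), and `rhp` (reductive hexulose-phosphate carbon
fixation; step granularity for this module is provisional and entirely
config-driven). The `h2_dependent_methylotrophic` flag requires a
complete methylotrophic pathway, absence of mtr, and the hdr_mvh
module — the diagnostic combination for methylotrophs that reduce
methyl compounds with H₂ rather than running the membrane-bound MTR
step.

Marker labels are a controlled vocabulary, not KO numbers, so any
annotation tool can feed the module after label mapping. One vocabulary
choice is worth noting: the methylotrophic step accepts mtm as a
methyltransferase synonym (the general methylamine set), while the
shipped Methanofastidiosa *template* omits mtm, matching the narrower
substrate range described for that lineage. Transporter/osmolyte genes
are recorded in the vocabulary for bookkeeping but never count toward
pathway steps.

## Quantification and ranking

RPKM and FPKM share one formula —
`mapped / ((length_bp/10³) · (library_size/10⁶))` — differing only in
the unit counted (reads vs fragments). The library size is, by
default, total mapped reads within the layer's library; whether
denominators should instead be total QC-passed reads is left to the
caller, who controls the `library_size` column. MAG-level values use
total MAG length, treating the MAG as one feature. Values are
invariant to jointly scaling counts and library sizes (depth
invariance, exact to floating point).

Absent (feature, layer) records are NaN, never 0: a layer with no RNA
library (as happens when deep-sediment RNA fails QC) is representable
without inventing zeros. Pathway aggregation sums member-gene FPKM
(sum, not mean, because stacked pathway-level magnitudes are the
quantity of interest; mean is available). Markers shared between
pathways (mcr, mtr) are attributed to the first pathway in config
order for gene-to-pathway aggregation. Lineage ranking sums RPKM per
lineage per layer, separately for the metagenome (abundance) and
metatranscriptome (activity); each role is ranked over its own layers,
and a consensus is reported when all layers agree. Gene-count
differences between lineages bias summed activity mildly; planted
effect sizes ≥ 2× dominate this in practice, but mean-based
aggregation is the robust alternative when gene inventories differ
wildly.

## Synthetic communities

The generator produces the three input kinds with planted,
recoverable truth. It emulates *counts*, not sequences: no FASTQ, no
chimeras, no OTU picking.

**OTU tables.** Per-sample latent log-abundances are
`μ_i + σ·z_{s,i}`: μ_i ~ N(0, 0.5) is the across-OTU base spread,
σ (`base_abundance_dispersion`, default 1.0) scales i.i.d. standard
normal per-sample factors, and counts are multinomial at fixed
`depth_per_sample` (default 1e5) on the softmax of the latents —
fixed-depth compositional data. A planted pair (a, b, strength) gives
both OTUs loading √strength on a shared per-sample factor, so their
latent correlation equals `strength` and the sample Spearman ρ rises
monotonically with it (≈0.79 latent Spearman at strength 0.8, safely
above the 0.6 edge threshold at 50 samples). The across-OTU spread is
deliberately *not* tied to σ: if single OTUs dominate the per-sample
softmax denominator, compositional closure correlates every other
pair and unplanted pairs are no longer conditionally independent —
with sd 0.5 the largest OTU holds a modest share and the closure
artifact is negligible at the scales used here. Real amplicon data
have heavier taxon-abundance tails, overdispersion, and zero
inflation than this model; passing tests show the *chain* recovers
planted structure under compositional noise, not that the generator
reproduces mangrove OTU statistics.

**MAG annotations.** Each lineage template lists intended markers;
each is dropped independently with `dropout_rate`, emulating genome
incompleteness (the shipped templates at dropout 0 reproduce the
four-lineage truth table exactly: MM hydrogenotrophic; MS all three
pathways; MF/MMA H₂-dependent methylotrophic; MB/MC mcr-less and never
complete). Gene lengths are uniform on 300–3000 bp — the typical
prokaryotic CDS range; nothing downstream is sensitive to this choice.

**Count tables.** DNA reads per layer are multinomial over MAGs with
weights abundance × MAG length; RNA fragments are multinomial over
genes with weights abundance × activity multiplier × gene length. The
activity multiplier decouples transcription from abundance, so one
lineage can be planted most abundant and another most active; because
RPKM divides length back out, length never confounds the ranking.
Default library sizes are 1e6 per layer and RNA libraries may cover a
subset of layers.

All generators run from one integer seed through a single numpy
Generator stream per call; identical spec + seed is bit-identical. The
pipeline derives stage seeds from the master seed via
`SeedSequence.spawn`.

## Pipeline

Plain-file orchestration, no workflow engine: every stage writes
TSV/JSON intermediates and `report.json` carries SHA-256 digests of
all artifacts plus in/out record counts for every filter. Identical
config + seed reproduces identical digests, and downstream stages
rerun from persisted intermediates reproduce the same downstream
digests. Config validation fills defaults (0.001% / >1 sample /
ρ > 0.6 / q < 0.01 / O/R > 1) and reports all schema violations at
once. The spec'd per-module command-line entry points are provided as
subcommands of one `methanonet` executable.

## Problem sizes and limitations

The validation experiments use 40–60 OTUs × 50–78 samples, 100-seed
replication, 999–100 000 permutation draws, and 1e6-read libraries —
sizes at which every documented property is measurable in seconds to
tens of seconds on one CPU. Field-scale quantities (thousands of
network nodes, real OTU inventories, wet-lab gene-copy numbers) depend
on sequencing data this package deliberately does not ship; nothing in
the validation claims to reproduce them. Known limitations: the
Spearman p-value uses the t approximation (an exact permutation option
is provided for very small sample counts); the degree-preserving null
relies on finite edge-swap mixing; the generator's noise model is
log-normal/multinomial, not fitted to any real dataset; and
gene-to-pathway attribution for shared markers is first-match by
config order.
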