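# Methods

## Scope and inputs

`rbprofiler` analyzes already-summarized microarray data: a probeset ×
sample intensity table with a parallel detection-p table (MAS5-style
detection calls are an input, never recomputed), a probeset→gene
annotation, a sample→group table, a curated regulator census (one symbol
per line), and optionally GMT pathway sets.  Gene symbols are matched
case-insensitively after uppercasing, because census lists and array
annotations mix cases.  Probesets without gene annotation are carried
through all probe-level stages and dropped only at gene aggregation, with
their count recorded in the run manifest.

## Differential pipeline

**Detection filter.**  A probeset is kept when, *within each group
separately*, at least one sample has detection p < α (default 0.05).  The
alternative reading — one detected sample anywhere — would make the
per-group qualifier vacuous, so the per-group rule is used.

**Normalization.**  Each array (column) is divided by its own median
intensity; after the step every column has median 1.  The operation is
idempotent and fails loudly on non-positive medians.

**Per-probe test.**  Welch's two-sample t on log₂ normalized intensities.
The original studies this pipeline is modeled on do not name their test
statistic, so the assumption-light default was chosen and the test is
injectable (`probe_differential(..., test=...)`) for moderated-t
variants.  p-values are corrected by Benjamini–Hochberg across **all**
detection-filtered probes of the contrast; the census is intersected with
the finished table afterwards and therefore never shrinks the
multiple-testing family.

**Fold change.**  FC is the ratio of linear-scale group means, displayed
with the signed-ratio convention (r if r ≥ 1 else −1/r), so |FC| ≥ 1
always and "halved" prints as −2.  At exactly equal means both directions
print +1; this is the one point where swapping case and control does not
negate the FC.

**Tiers.**  DEG ⇔ FDR ≤ 0.05; SDEG ⇔ DEG and |FC| ≥ 1.5.  Both
thresholds inclusive and configurable.

**Gene aggregation.**  Only significant (tier ≥ DEG) probes vote;
non-significant probes of a gene carry no directional information at this
point because the FDR filter precedes consistency in the pipeline order.
Consistency = (majority-direction probes)/(significant probes); genes
below 2/3 are flagged discordant and excluded from final counts.  The
2/3 threshold is applied with a 1e-12 tolerance so an exact 2-of-3 gene
passes (a "67%" rule is treated as rounded 2/3).  Gene FC is the median
of majority-direction probe FCs; the gene is SDEG if any
majority-direction probe is SDEG.

**Report arithmetic.**  All percentages are whole numbers rounded
half-up, and every report line carries its numerator/denominator so the
percentage is recomputable by inspection.

## Venn partitioning

Two or three named SDEG gene sets are split into all 2^k − 1 disjoint
regions (exclusive intersections).  The partition property — regions
disjoint, union preserved, inclusion–exclusion identity — is enforced by
construction and asserted in tests.

## Clustering and admixture

**Distances.**  Pearson distance 1 − r (constant items have undefined r
and are assigned the maximal distance 2, and flagged) or Euclidean, on a
per-probe signature: each probe divided by its median across all samples,
then log₂, so rows are relative fold changes with median 0.

**Agglomeration.**  Complete linkage is implemented in-package rather
than delegated so tie-breaking is deterministic across platforms: among
minimal-distance pairs, the lexicographically lowest cluster-id pair
merges first (leaves 0..n−1, merged clusters numbered in creation
order).  An independent library implementation serves as the test oracle
for merge heights.

**Co-expression clusters.**  The probe tree is cut at height 1 − r_min
(default r_min = 0.70).  Under complete linkage every pair inside a
resulting group is within that height, which *guarantees* min pairwise
r ≥ r_min; the guarantee is still re-verified directly on every emitted
cluster.  Groups below `size_min` (default 2) are dropped; clusters are
reported in decreasing size.  The cluster count is data-dependent, never
hard-coded.

**Admixture detection.**  The qualitative readout — control subjects
clustering inside the disease branch — is formalized without inventing a
cluster count k.  Starting from the smallest subtree containing every
disease-group sample, the detector widens to the *disease clade*: the
ancestor of that subtree with the largest jump between its own merge
height and its parent's.  The widening step matters because the minimal
enclosing subtree excludes, by construction, any admixed control that
happens to be the clade's single most peripheral member — a coin-flip
event under exchangeability that the maximal-gap rule removes.  Ties
resolve toward the higher ancestor, so a tree of identical samples
degenerates, documentedly, to the whole cohort.  Non-disease leaves
inside the clade are returned with the clade height.

## Enrichment

Over-representation is the right-tailed hypergeometric tail
P(X ≥ k) for an overlap of k selected genes with a pathway of K genes in
a universe of U, with n genes selected.  The default universe is the set
of census genes surviving detection filtering in the contrast;
enrichment runs on DEG-level calls by default (more genes, more power for
a set-level test) with an SDEG option.  Discordance-excluded genes never
vote.

The activation z-score summarizes overlap directionality:
z = (n_up − n_down)/√N, reported to two decimals, with prediction
Activation (z > 0), Inhibition (z < 0) or "0".  A plain-N denominator
(z = (n_up − n_down)/N) is selectable by flag; the √N form is the default
because reference tables of this statistic score an all-down pair −1.41
and an all-down quartet −2, values only consistent with the square-root
denominator.  |z| ≤ √N with equality iff all directions agree.

## Synthetic cohorts

The generator's defaults are the study conditions the pipeline targets,
chosen once and frozen:

| parameter | default | meaning |
|---|---|---|
| group_sizes | NS 12, S 12, COPD 6 | three-group brushing cohort |
| n_admixed_controls | 4 | smokers carrying the disease signature |
| n_census_genes / n_background_genes | 250 / 600 | census vs array background |
| n_regulated_census_genes | 120 | planted disease-regulated census genes |
| fraction_down | 0.75 | downward share of planted directions |
| effect_log2 | 3.0 | planted effect magnitude (8-fold) |
| within_group_sd_log2 | 0.5 | per-observation log₂ noise |
| biological_factor_sd | 1.0 | per-gene per-sample biological variation |
| n_modules × module_size | 5 × 10 | planted co-expression modules |
| module_latent_sd | 1.0 | module latent-factor scale |
| probes_per_gene_law | uniform 1–4 | multi-probe genes |
| discordant_probe_rate | 0.15 | chance a multi-probe gene gets one flipped probe |
| detection_background | 8.0 | intensity scale of the detection squash |

Log₂ intensities are baseline(gene) + offset(probe) ± effect·disease(s)
+ factor(gene, s) + noise, exponentiated to the linear scale.  Baselines
are N(8, 1.5²); probe offsets N(0, 0.25²).  The effect magnitude 8-fold
sits inside the wide range reported for strongly regulated RBPs in
airway epithelium (top changes exceed 30-fold) and is a free parameter —
no quantitative effect-size distribution is published for this setting.
Every gene gets an independent per-sample biological factor except module
members, which share their module's latent factor: this is what separates
planted modules (pairwise r ≈ 0.93 in expectation) from the
disease-driven background correlation among co-directional regulated
genes (r ≈ 0.6), keeping the latter below the 0.70 extraction threshold.
Modules are direction-homogeneous by construction (members drawn from
genes whose i.i.d. direction draws agree), so the shared factor produces
positive correlation; directions remain i.i.d. marginally, preserving the
binomial law of the down-fraction.

Detection p-values come from a monotone squash p = 1/(1 + (I/bg)³) plus
small additive noise, clipped to [0, 1] — near 0 well above background,
near 1 below it.  The array's actual detection-call machinery (Wilcoxon
on probe pairs) is out of scope, so the squash is a stand-in with the
right monotonicity, not a calibrated model.

Randomness is split into a *biology* stream (regulated set, directions,
modules, baselines, probe layout, discordant flips) and a *cohort* stream
(subjects, admixture assignment, factors, noise).  Two configs sharing
`biology_seed` but differing in `seed` emulate a test cohort and an
independent validation cohort of the same disease, which is how the
cross-cohort fold-change concordance check is exercised.

**What the generator does not emulate:** batch effects, probe-level
PM/MM structure, intensity-dependent variance, a smoking-only expression
program (the smoker-vs-non-smoker contrast is therefore nearly empty in
synthetic data, unlike in real cohorts where smoking itself regulates
genes), and realistic annotation errors.  Passing tests demonstrate that
the pipeline recovers the structure it is designed for, not that it
reproduces any specific real cohort's counts.

A consequence of planting the *identical* effect in admixed smokers is
that the disease-vs-smoker contrast loses power sharply: the admixed
subjects inflate the smoker group's variance by (4/12)(8/12)·effect² per
gene, so that contrast's call counts vary widely across seeds.  Recovery
properties (recall, FDR, admixture, modules) are therefore evaluated on
the disease-vs-non-smoker contrast, whose signature probes carry the
admixed signal equally well.

**Frozen property bounds** (chosen by pilot simulation at the defaults,
then fixed): mean gene-level SDEG recall ≥ 0.8, mean observed FDR ≤ 0.1
and mean direction accuracy ≥ 0.95 over 20 seeds; exact recovery of the
planted admixed smokers per seed; mean best-match Jaccard ≥ 0.8 between
planted modules and recovered clusters over 12 seeds, scored against the
genes actually present in the clustered signature (clustering is judged
on what it could see, not on upstream selection losses).

## Numerical choices and degenerate inputs

- BH correction via the standard step-up implementation; verified against
  a brute-force oracle.
- Hypergeometric tails via the survival function at k − 1; verified
  against exact rational enumeration for all universes ≤ 25.
- Consistency threshold comparison carries 1e-12 slack (2-of-3 passes).
- Zero/negative medians, empty groups, single-sample groups (no variance
  estimate), empty censuses (as files), malformed GMT lines and
  misaligned detection tables are hard errors with labeled messages; an
  empty census *set* passed programmatically yields zero gene calls
  without error.
- Observed FDR with zero positive calls is defined as 0.
- Constant rows under Pearson distance are flagged and set to the maximal
  distance 2 rather than erroring, so one dead probe cannot abort a run.

## Problem sizes

Default synthetic cohorts are ~850 genes / ~2100 probes × 30 samples,
small enough that the full pipeline (three contrasts, Venn, clustering,
enrichment) completes in well under a second, and multi-seed property
checks run in seconds.  All sizes are configurable upward.

## Known limitations

- The per-probe test is Welch's t, not a moderated/empirical-Bayes
  variance model; with 6 disease samples the variance estimates are
  noisy, and real-data counts will differ from pipelines using limma-like
  statistics.  The test hook exists precisely to swap this.
- The admixture detector assumes the disease group dominates one branch;
  in data where disease samples scatter, the maximal-gap clade can be
  large and the flagged list correspondingly permissive (by design, the
  flagged set is always reported with the clade height).
- Pathway enrichment treats gene sets as flat lists; no curated edge
  signs or causal network structure are used in the activation score.
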