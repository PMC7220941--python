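# Methods

## Problem and approach

Bulk tissue expression profiles — for instance inflamed synovial tissue in
rheumatoid arthritis compared against osteoarthritis tissue — mix the
contributions of many infiltrating and resident cell types, each possibly in a
different activation state. `refpattern` asks which *reference* condition
(a purified cell type, with or without a defined stimulus) best explains the
genes that distinguish two tissue groups, in three stages:

1. **All-pairs differential selection.** Every experimental sample is compared
   with every baseline sample (n_exp × n_base ordered pairs). Each pair yields a
   signal log ratio per probe-set, SLR = log2(x_i) − log2(y_j), and a change
   call by a symmetric SLR threshold. A probe-set is selected when the calls
   agree in at least 50% of pairs (major criterion), or in at least 30% of
   pairs while the experimental group is the more homogeneous of the two
   (minor criterion), and in either case the one-sample t-test of the pairwise
   SLRs against zero survives Bonferroni correction over all probe-sets tested.
2. **Co-expression pattern discovery.** Reference arrays are merged onto their
   shared probe-set universe and quantile-normalised. The gene×gene Pearson
   correlation matrix over all distinct reference arrays is clustered
   hierarchically (Euclidean distance between correlation rows, average
   linkage); cutting the tree yields gene modules, and each module is aligned
   with the condition whose arrays show the highest mean z-score over the
   module's genes.
3. **Cumulative-score quantification.** Genes are scored per contrast
   (`score = mean SLR × change-call frequency`, see below), collapsed to one
   representative probe-set per gene and ranked. Walking down the target
   contrast's top-N ranking, the running sum of each reference comparison's
   scores is divided by the target's own running sum; the maximum of that
   ratio over ranks ("up to X% of the target score") and its final-rank value
   summarise how fully the reference pattern reproduces the target signature.
   The reverse analysis accumulates target scores over each reference's own
   top-N ranking, and top-N set overlaps and gene-set filters (e.g. GO
   "extracellular space"/"extracellular exosome" for secreted proteins)
   complement the curves.

## The gene score

Per probe-set and contrast the score is

    score = mean_SLR × (n_increase + n_decrease) / n_pairs

i.e. the average pairwise log2 effect weighted by the fraction of pairs that
called any change. The mean SLR carries sign and magnitude; the change
frequency discounts effects that only a few sample pairs support. The score is
bounded by the largest |SLR|, is zero when nothing changes, and negates
exactly when the two groups are swapped — a property we treat as definitional,
since a score that is symmetric in the groups could not distinguish a pattern
from its inverse in the cumulative curves. (A variant using the *net* call
frequency, n_inc − n_dec, loses this antisymmetry because both factors flip
sign together.) Collapsing keeps, per gene, the probe-set with maximal
|score|; ties break by lexicographic probe-set ID so runs are reproducible.

## Selection details and numerical choices

* **Change calls.** Calls are derived from probe-set-level SLRs with a
  threshold of 0.5 log2 (~1.4-fold), configurable. Probe-level detection
  p-values of the original array software are not modelled; the pipeline
  starts from probe-set signals.
* **Homogeneity (minor criterion).** "More homogeneous" is the coefficient of
  variation of log2 signals in the experimental group being strictly smaller
  than in the baseline group (`sd_log2` available as an alternative). The
  dispersion measure is a design choice of this package.
* **SLR t-test.** A two-sided one-sample t over the n_exp × n_base pairwise
  SLRs. The pairs share samples and are therefore not independent, which makes
  the test anticonservative; it acts as a gate on top of the frequency
  criteria (which carry the real specificity) rather than as a calibrated
  p-value. The t-test gates both the major and the minor criterion. Bonferroni
  divisor = number of probe-sets entering testing. Degenerate rows (zero SLR
  variance) get p = 1 if the common SLR is 0, else p = 0.
* **Signal floor.** Signals are clipped at a configurable floor (default 1.0)
  before any log, so SLRs are always finite. Flooring is an explicit step;
  the expression container itself rejects non-positive values.
* **Direction ties.** If both directions satisfy the criteria at exactly equal
  frequencies the probe-set stays unselected rather than receiving an
  arbitrary direction.
* **Quantile normalisation.** Rank-wise column means, with tied input values
  receiving the mean of their tied-rank targets; this makes the transform
  idempotent. Arrays reused as controls for several stimulated arms are
  stored and normalised once; any repeated display is presentation only.
* **Constant genes.** In co-expression, zero-variance genes get correlation 0
  to everything (diagonal kept at 1) and are flagged; clusters consisting only
  of such genes are labelled "unassigned".
* **PCA.** Performed by SVD on per-gene z-normalised log2 signals (samples as
  observations); percent variance of component i is its eigenvalue over the
  eigenvalue total. z-normalisation is stated for heatmap display in the
  source protocol only; we adopt it for PCA and pattern scoring as well, for
  scale invariance across probe-sets. Requests beyond the matrix rank are
  truncated with a warning.
* **Tree cut.** k has no canonical value; the pipeline defaults to the number
  of distinct cell classes in the compendium metadata, which is admittedly
  arbitrary and user-overridable.
* **Curves.** "Up to X%" is the maximum cumulative ratio over ranks 1..N; the
  final-rank ratio is always reported alongside. Negative reference scores
  enter the cumulative sums signed by default (they can depress a curve); a
  `clip_negative` switch floors them at zero. Genes missing from a reference's
  universe contribute 0 and are flagged. Equal scores rank by lexicographic
  probe-set ID.

## Synthetic data: what it emulates and what it does not

The generator produces (i) a reference compendium — per cell type a control
arm of replicate arrays, per stimulus a stimulated arm linked to its base cell
type's control arm — and (ii) bulk-tissue cohorts in which each sample is a
simplex mixture of cell-type profiles, with stimuli acting multiplicatively
on the contributing cell type's component only (mirroring the premise that
tissue patterns are borne by specific cell types). Per-gene log2 signal =
global baseline + marker offset + stimulus effect + Gaussian log2 noise;
zero-noise mixtures are exact linear combinations of the signatures on the
linear scale.

Default scales: global baseline 7.0 log2 units, marker offsets graded over
2–5 log2, stimulus effects graded over 1–4 log2 with every fourth response
gene down-regulated, 3 replicate arrays per reference arm, cohorts of 10 vs
10 samples, and the stimulated cell type holding half of the tissue. The
default log2 noise sd is 0.15 — replicate-level variability typical of
expression arrays for well-expressed transcripts. This matters: the pairwise
frequency criterion's specificity is governed by the chance that the group
means drift apart by about `slr_threshold − z(f_minor)·√2·σ`; at σ = 0.15 a
10 vs 10 null cohort of 1000 probe-sets selects nothing essentially always,
while at σ = 0.3 the (anticonservative) t-test no longer protects the
frequency rule and a few spurious probe-sets per thousand appear. In other
words, the published selection procedure is calibrated for replicate-scale
noise, and the defaults reflect the regime it was designed for; power checks
at σ = 0.3 still recover ≥ 90% of effects of at least 1 log2.

The generator does **not** emulate: probe-level (PM/MM) structure, batch or
platform effects beyond what quantile normalisation removes, correlated
biological heterogeneity between patients (per-sample variation enters only
through the noise term and any user-supplied variation in mixing fractions),
gene–gene correlation beyond the block structure, or realistic
mRNA-abundance distributions. Passing tests therefore demonstrate the
*internal* correctness and calibration of the pipeline under its stated
model, not that real cohorts with patient-level heterogeneity would yield
the same sensitivity or specificity.

## Problem sizes used in validation

The test suite and the acceptance script run on deliberately small instances:
200-gene universes (3 cell types × 40 markers + 80 background genes; 1000
probe-sets for the null-calibration runs), 18-array compendia, 10 vs 10
cohorts, and 10–20 seeded replicates per stochastic claim. These sizes keep
every quantity exactly checkable against brute-force oracles while exercising
all code paths; all generators scale to larger designs through their
parameters.

## Known limitations

* Headline counts from any specific clinical dataset (e.g. how many
  probe-sets a 10 vs 10 synovial cohort yields) depend on raw-data
  preprocessing (MAS5.0 condensing, platform, annotation version) that is out
  of scope here; the pipeline ingests probe-set-level signal matrices.
* The t-test treats pairwise SLRs as independent (by design, matching the
  original selection procedure); do not interpret its p-values as calibrated.
* Pattern labels come from a max-mean-z rule; visually curated assignments of
  the original heatmaps may differ near ties.
* Gene-set filtering relies on user-supplied GMT files; no annotation
  retrieval is performed, so counts depend on the annotation version used.
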