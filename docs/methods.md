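# Methods

`rumiprox` implements a staged association analysis between rumen
microbial gene abundances and cattle feed-efficiency traits, together
with a synthetic-study generator that reproduces the statistical
structure such analyses assume. This note records the models, the
defaults and why they are set where they are, and what the synthetic
experiments do and do not demonstrate.

## Traits

Four performance traits are derived per animal:

* **ADG** (average daily gain, kg/day): the OLS slope of weekly body
  weight on test day. Mid-test body weight is the fitted value at the
  midpoint of the date range (the record gives no formula for "mid-test
  BW"; the fitted midpoint is deterministic and robust to uneven
  weighing dates), and metabolic body weight is MBW = mid-BW^0.75.
* **DFI** (daily feed intake, kg DM/day): the mean of daily dry-matter
  intake records.
* **FCR** = DFI / ADG (kg intake per kg gain; lower is better). Animals
  with non-positive ADG are excluded with a warning rather than given
  negative ratios.
* **RFI** (residual feed intake, kg/day): the residual of DFI regressed
  on ADG, MBW and rib fat depth. By OLS construction RFI has mean zero
  and is orthogonal to each predictor; both identities are asserted in
  tests at 1e-10. The regression is pooled across the whole study;
  class covariates can be added via `extra_covariates`.

High/low groups per trait come from a stratified median split within
the combined breed x diet x year class (six levels): above the stratum
median is "high", at or below is "low" (the tie rule is fixed so the
split is deterministic; group sizes differ by at most one per stratum).

## Abundance model

Features are KEGG Orthologues (KOs). A read counts toward a KO only
when all best-quality alignment hits agree on a single KO; ambiguous
reads are dropped (assignment conservation is tested). Counts are
closed per animal to relative abundances. The gene filter removes a
gene when it is absent (exactly zero) from more than `max_absent = 2`
animals **or** its mean relative abundance is below `min_mean = 1e-5`
(0.001% as a fraction). This both-rules-required-to-stay reading is the
standard prevalence + abundance filter and the stricter of the two
readings of the rule; the literal conjunctive-removal alternative is
selectable (`filter_mode="conjunctive"`). "Absent" means exactly zero;
the filter is idempotent.

## Per-gene prescreen

For each gene, abundance is the response in a fixed-effect linear model
with the six-level class factor plus a trait term — the two-level FCR
group factor for FCR, the continuous trait value otherwise. The partial
F-test of the trait term (equal to the squared t for these 1-df terms)
decides retention at raw α = 0.1; no multiplicity correction is applied
because the screen exists only to discard clearly unassociated genes
before the multivariate stage. All genes share one design matrix, so
the screen runs as two QR projections on the whole matrix at once; a
per-gene statsmodels OLS is the cross-check in tests. Constant genes
get p = 1. Options: `transform="log10"` (log10 of abundance plus half
the smallest nonzero value) and `reverse=True` (trait as response; for
1-df continuous terms the p-values are identical either way).

## PLS with VIP-based sequential selection

The core model is univariate-response PLS fitted by NIPALS with
response deflation on autoscaled X and y. Per-factor percent variance
is reported for both blocks: X as 100·‖t_a p_aᵀ‖²_F/‖X₀‖²_F, y from
successive deflation. The weight-vector sign is fixed by making the
largest-magnitude element positive, so results do not depend on the
linear-algebra backend. Scores are orthogonal (asserted at 1e-8
relative), coefficients are back-transformed to the input scale, and at
full rank the fit reproduces OLS (asserted at 1e-6). VIP is

  VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),

whose squared values average exactly 1 (asserted at 1e-8). The number
of factors is chosen by leave-one-out cross-validation minimizing
PRESS, with centering and scaling recomputed inside each fold and
zero-variance fold columns dropped; the factor search is capped at 10.

Selection is two-stage:

1. **Elimination loop.** Fit PLS (factors by LOO-CV) on the retained
   genes plus p−1 reference-coded class dummies (autoscaled like genes,
   never ranked or dropped); compute VIP; drop genes with
   VIP < 1.0, but at most the bottom 20% per iteration; record each
   candidate set; stop below 2 genes or when nothing falls below the
   threshold. Because mean squared VIP is identically 1, the threshold
   1.0 reads as "below average importance" and the loop traces a full
   trajectory of nested candidate sets (sizes strictly decreasing). A
   threshold of 0 disables elimination entirely.
2. **Evaluation.** Refit every candidate set with three factors and
   score it by the product of the X-block and response explained
   variances (both on the 0–100 scale, product divided by 100). The
   combined score is the default because noise genes leave the X block
   incoherent: a small correlated set of truly associated genes
   explains most of both blocks at three factors, whereas a response-
   only score is maximized by the largest candidate set (training fit
   grows with column count). The smallest set scoring within
   `rsq_tolerance = 3` points of the best is returned — nearly
   equivalent smaller sets win. The chosen set is refitted without the
   class dummies to report the no-fixed-effect explained variance.
   A response-only criterion (`criterion="dependent"`) is available.

The elimination cutoff, per-iteration cap, evaluation factor count,
criterion and tolerance are all configurable; the defaults above were
chosen because the evaluation score must trade parsimony against fit on
its own (the source analysis reports final sets of 14–20 genes but not
its cutoff), and they produce selections in exactly that size range on
synthetic studies.

## Linear discriminant analysis

Two-class Fisher/Gaussian LDA with pooled within-class covariance; the
discriminant direction is normalized to unit norm under the pooled
metric, and the threshold includes the empirical-prior log-odds term.
With as many selected genes as animals the pooled covariance is
near-singular, so a diagonal shrinkage (1−γ)S + γ·diag(S) is applied
with the smallest γ from a fixed grid {0, 0.01, 0.05, 0.1, 0.2, 0.5,
0.9} that keeps the condition number below 1e8; the intensity is
logged. Both resubstitution accuracy (the figure comparable to
published density-plot accuracies, which mention no cross-validation)
and leave-one-out accuracy (refit per fold; the honest out-of-sample
figure) are always reported. Predictions are invariant to positive
per-feature rescaling (tested), and LD1 score tables are emitted as
numbers, not images.

## Coabundance networks and Markov clustering

Edges connect gene pairs with Pearson correlation ≥ t across animals;
only positive correlations form edges (coabundance semantics; an |r|
mode and Spearman correlations are available). The covering threshold
t* is the largest grid value (step 0.01) at which no gene is isolated;
one step higher at least one gene drops out (tested).

MCL is implemented from scratch on scipy sparse matrices: edge weights
are raised to the pre-inflation power; each node receives a self-loop
equal to its maximum incident weight (isolated nodes get 1 and end as
singletons); then the column-stochastic flow matrix alternates
expansion (matrix square) and inflation (element-wise power + column
renormalization), pruning entries below 1e-5 and capping columns at
their top 100 entries, until the column-wise change falls below 1e-8
(cap 200 iterations; non-convergence returns the current interpretation
with a warning). Columns sum to 1 after every normalization (tested at
1e-9). Clusters are read from attractor rows; a node attracted by
several attractors joins the lowest-indexed one, and cluster ids are
relabelled 1..K by decreasing size (ties by smallest member index). The
originating graph tool's "scheme 6" pruning knob is not publicly
specified; the prune-threshold + top-k mapping is an approximation and
both knobs are exposed. The first-stage clustering uses inflation and
pre-inflation 6 as printed in the source description of its tool
defaults (unusually sharp, producing fine clusters — possibly a UI
label rather than a true inflation; it is configurable), the second
stage 2 and 2.

Cluster enrichment of the per-trait selections (plus the union sets
FCR&ADG and RFI&DFI and the intersection set FCR+ADG) uses the
one-sided hypergeometric upper tail with the second-stage network's
nodes as the default universe; raw p at 0.05 drives the significance
flag, with Benjamini–Hochberg values reported alongside. Singleton
clusters are excluded from enrichment by default.

## Synthetic-study generator

The generator reproduces the design of the emulated study: six breed x
diet x year cells of sizes 6, 6, 6, 6, 9, 9 (42 animals), each cell's
animals chosen as within-cell FCR extremes from a three-fold
oversampled pool (selection is on by default and switchable off).

**Traits.** log ADG and log DFI are jointly normal with small
deterministic class shifts; FCR is the exact ratio DFI/ADG; fat depth
loads on part of the ADG-independent DFI noise so that the RFI
regression (run through the same `derive_rfi` as real data) leaves the
intended residual share. Because FCR is an exact ratio, the four target
correlations (FCR↔ADG −0.80, FCR↔RFI 0.32, DFI↔RFI 0.77, DFI↔ADG 0.53)
cannot all be achieved exactly, and the extreme-FCR selection distorts
every pair further; the three latent parameters (ADG/DFI log-variance
ratio, latent ADG–DFI correlation, RFI noise share) are therefore
calibrated by a deterministic common-random-numbers pilot simulation
(Nelder–Mead on 25-fold enlarged classes, fixed internal seed, cached
per configuration). Realized correlations match the targets within
about ±0.08 in the median across seeds (tested against a ±0.15 band).

**Genes.** Pre-closure log-abundances are per-gene baseline (SD 1.5
across genes, giving the heavy right tail of KO tables) + a shared
within-block latent factor (30 blocks; per-gene loadings uniform in
2.2–3.2 times the noise SD, within-block correlations ≈ 0.83–0.91) +
independent noise (SD 0.3) + the planted signal; the softmax closure
then yields compositional rows summing to 1 within 1e-12. A 5% "rare"
subset is shifted 3–6 log units down and given dropout zeros in 1–6
animals to exercise the prevalence/abundance filter. Signal genes carry
a linear term in their designated trait's standardized value, scaled by
`effect_size` in units of the gene's non-signal log-SD; the default 0.8
gives per-gene log-scale correlations near 0.6 — strong enough to be
detected reliably at n = 42 (per-gene power well above 0.9 at α = 0.1)
but weak enough that selection has real work to do. Each trait plants
17 genes (the published sets hold 14–20); mirroring the published
overlap structure, 6 genes are planted for both FCR and ADG (opposite
signs, consistent with their negative correlation) and 3 for both RFI
and DFI (equal signs). Signal genes open their trait's block, so
trait-associated genes are also coabundant — the property the network
stage is meant to recover.

**What the generator does not emulate.** Sequencing noise, taxonomic
composition, true KO annotations, non-normal abundance shapes beyond
the log-normal, diet-dependent covariance changes, and any real
biological pathway structure. Passing recovery tests therefore shows
the pipeline recovers planted structure under its own assumptions, not
that the published biological findings are correct.

## Evaluation experiments and their readings

* **Null calibration.** With `effect_size = 0`, prescreen retention at
  α = 0.1 is compared to the exact binomial 99% interval. The
  calibration config uses zero block loading (independent genes)
  because the binomial reference presumes independent tests; block
  correlation would not bias the rate but would invalidate the
  interval. The FCR-group screen is used: a balanced two-sample
  comparison is robust to the mild log-normal skew of the response.
* **Recovery.** Across replicate default-condition studies and all four
  traits, recall counts the designated trait's planted genes recovered
  and precision counts selected genes planted for *any* trait. The
  asymmetry is deliberate: with traits correlated at 0.77–0.88, a gene
  planted for a neighbouring trait is genuinely associated with the
  focal trait (the published analysis itself reports such shared
  genes), so only non-planted genes count as false selections.
* **Block recovery.** MCL at r ≥ 0.80 versus the planted block
  partition, summarized by the adjusted Rand index over the network's
  nodes (singletons included as their own clusters).

Problem sizes: the acceptance test suite uses 30 null seeds, 20
recovery seeds (80 trait-runs) and 10 network seeds; the acceptance
script uses 25/12/8, keeping a full run near 15 seconds.

## Numerical choices and degenerate inputs

Zero-variance predictors are rejected at fit time and dropped inside
LOO folds; constant genes get p = 1 in the prescreen; a constant gene
in network construction is an error directing the user to filter
first; an empty candidate drop set ends the elimination loop; selection
collapsing below two genes stops the loop at the last valid set; LDA
classes with fewer than two members are errors. All randomness flows
from one `numpy` Generator per study seed; identical configurations
give bitwise-identical studies and byte-identical pipeline reports.

## Known limitations

* The VIP elimination cutoff, iteration cap and stage-2 tolerance have
  no published reference values; the defaults are this package's own
  design choices, supported by the synthetic experiments only.
* Resubstitution accuracy with 15–20 genes on 42 animals is optimistic
  by construction; the LOO figures (typically 10–25 points lower) are
  the better generalization estimates.
* The first-stage MCL inflation of 6 follows a printed tool default
  that may be a mislabel; with it, first-stage clusters are very fine,
  which mainly affects how many genes the carry-forward step keeps.
* Hypergeometric enrichment treats genes as exchangeable; coabundant
  genes violate that assumption, so enrichment p-values on blocky data
  are anti-conservative and are best read as ranking scores.
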