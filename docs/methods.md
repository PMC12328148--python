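# Methods

This note documents the statistical model behind each stage of the screen,
the defaults and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical conventions adopted where the design
was genuinely open.

## Differential expression

For each feature *g* and two disjoint sample groups A and B, the statistic
is the pooled-variance two-sample *t* on log2 abundances:

    log2FC_g = mean_A(g) − mean_B(g)
    s_g² = [(n_A−1) s_A² + (n_B−1) s_B²] / d_g ,   d_g = n_A + n_B − 2
    t_g = log2FC_g / sqrt(s_g² (1/n_A + 1/n_B))

with a two-sided p from the t distribution on d_g degrees of freedom.  The
effect size is a *difference of means of log2 values*, not the log2 of a
ratio of raw means — all inputs are assumed log2-transformed (a reader
flag applies log2(x+1) to raw-scale files).

Calls: `up` iff p < p_cut and log2FC > fc_cut; `down` iff p < p_cut and
log2FC < −fc_cut; otherwise `ns`.  Defaults are raw p < 0.05 with
fc_cut = 0.585 (1.5-fold) for proteome and 1.0 (2-fold) for transcriptome
features.  No multiple-testing correction is applied to these calls; the
screen's thresholds are deliberately on raw p.  Missing values are never
imputed: a feature with fewer than `min_obs_per_group` (default 3)
observations in either group is `skipped`, with an undefined p.

Degenerate variance: when the pooled variance is exactly zero, p is
defined as 1 if the group means agree (no evidence) and 0 if they differ
(the t statistic diverges).  This keeps downstream counting total.

### Empirical-Bayes moderation (opt-in)

With `moderation=True`, per-feature variances are shrunk toward a prior
(s0², d0) estimated by moment-matching the log variances against the
scaled-F model: writing e_g = log s_g² − digamma(d_g/2) + log(d_g/2), the
excess of var(e) over mean(trigamma(d_g/2)) equals trigamma(d0/2), solved
by Newton iteration; s0² follows from mean(e) with the digamma bias
correction.  The posterior variance is
s̃_g² = (d0 s0² + d_g s_g²)/(d0 + d_g) and the moderated t carries
d0 + d_g degrees of freedom (normal reference when d0 = ∞, which is
returned whenever the variances show no excess dispersion).  d0 = 0
reduces exactly to the ordinary t.  The unmoderated test is the default
because it is exactly reproducible against a textbook oracle; moderation
is provided for fidelity to common proteomics practice.

## Membrane annotation

Raw GO cellular-component terms are collapsed into a fixed vocabulary
{cytosol, membrane, nucleus, cytoskeleton, mitochondria, golgi, lysosome,
other}.  The shipped term map is a coarse stand-in for testing; real
analyses should supply their own table, since the exact term set defining
"membrane" is a modelling choice.  Multi-label features contribute to
every matching compartment row of the breakdown; fractions are normalized
by the number of called features per direction, so they may sum above 1.
The candidate pool for scoring is the up-called features carrying the
`membrane` label.

## Target prioritization

Components, each in [0, 1]:

* **Tumor expression** — tumor-vs-normal log2 fold-changes, negatives
  clamped to 0, divided by the maximum over candidates.  Clamping (rather
  than erroring) accommodates genuine candidates that are
  metastasis-associated without tumor-vs-normal enrichment.
* **Metastasis significance** — −log10 of the LN+ vs LN− p-value (floored
  at 1e-300), max-scaled over candidates.  Base 10 is the p-value
  convention; any base rescales before max-normalization, so ranks are
  unaffected.
* **Off-tumor** — from the healthy-tissue profile (arbitrary units, AU):
  1 when the maximum abundance is 0, else clamp(−log10(max_AU/10), 0, 1).
  Under this reading the component is continuous at zero abundance
  (values ≤ 1 AU score 1) and hits 0 at ≥ 10 AU.  The alternative reading
  −log10(max_AU)/10 is available as `off_rule="scaled_log"` for
  sensitivity analysis but is not the default, because it is
  discontinuous against the stated zero-abundance case and compresses the
  useful range to abundances below 1 AU.  c_off is *not* re-scaled across
  candidates: it is already defined on a [0, 1] scale.

Score: min(‖(c_expr, c_sig, c_off)‖₂, √3), the cap implemented exactly at
√3.  Ties are broken by ascending metastasis p, then lexicographic feature
id, making the ranking a deterministic total order.  The score is
monotone in each raw input (improving one candidate's input never lowers
its score) and the ranking is invariant to positive rescaling of the raw
fold-changes; both properties are tested on randomized candidate sets.

## Survival and mutation gates

* **Kaplan–Meier**: product-limit estimator with tied events handled by a
  single (1 − d/n) factor per distinct event time.
* **Log-rank**: k-group observed-minus-expected statistic with the
  hypergeometric variance (factor d(n−d)/(n−1) at tied times), chi-square
  on k−1 df via the pseudo-inverse of the covariance of the first k−1
  groups.
* **Cox (univariate)**: Newton–Raphson maximization of the Breslow
  partial likelihood, step-halving to enforce monotone ascent,
  convergence at |Δβ| < 1e-8 or 50 iterations; perfectly separating
  covariates are flagged `converged=False` instead of raising.  Breslow
  tie handling was chosen as the simplest rule adequate for the
  continuous simulated times; Efron weights are not implemented.  The
  score test at β = 0 is exposed and, for a binary covariate without tied
  event times, coincides with the log-rank chi-square — a cross-check the
  tests exploit.
* **Mutation association**: genes ranked by mutation frequency among
  tumor samples with known LN status (top 20 by default), each tested on
  its 2×2 mutated/wild-type × LN+/LN− table by Pearson chi-square without
  continuity correction; Fisher's exact test is available behind
  `method="fisher"`.  Zero-margin tables are flagged degenerate with an
  undefined p rather than erroring.
* **Median split**: high/low expression groups split at the median with
  ties assigned to the low group; used by the per-feature survival view.

## Synthetic cohort generator

The generator emulates a CPTAC-like proteogenomic cohort:

* **Samples** — 24 LN+ and 23 LN− tumors (a 47-tumor proteome cohort)
  plus 20 adjacent normals.  Sample ids are the join key everywhere.
* **Expression** — feature baselines Uniform(4, 10) (proteome) /
  Uniform(2, 8) (transcriptome) on log2 scale, Gaussian residual noise
  (sd 1.0).  Planted membrane targets (15 by default, matching a
  screen-sized candidate pool) carry +1.0 log2 in LN+ tumors and +1.5
  log2 in tumors vs normals.  Decoy membrane proteins (matched count)
  carry the metastasis effect only: they emulate broadly expressed
  surface proteins that survive the differential and membrane gates but
  should be eliminated by the off-tumor component.  Background features
  carry no effect and are annotated with 1–2 random compartments
  (membrane with probability 0.2).
* **Missingness** — completely at random at rate 0.10, proteome only;
  the simplest mechanism consistent with sparse label-based proteomes.
* **Off-tumor profile** — planted: silent with probability 0.5, else
  below 1 AU (component 1 either way); decoys: Uniform(10, 100) AU
  (component 0); background: Uniform(0.5, 50) AU.
* **Survival** — exponential event times with log-hazard
  log(1/1500 per day) + log(2)·1[LN+], administratively censored at five
  years; the OS hazard is 0.6× the PFS hazard so OS runs longer.
  Constant-hazard proportional hazards with a single binary covariate is
  the minimal generator for which KM/log-rank/Cox are the correct
  analyses; any planted-target–survival association arises indirectly
  through the targets' LN+ enrichment.
* **Mutations** — Bernoulli(0.15) per gene and tumor sample; 5 of 50
  genes are enriched in the LN− group at odds ratio 4, mirroring screens
  where mutation burden anti-correlates with nodal spread.
* **Determinism** — one `numpy.random.default_rng(seed)` stream consumed
  in a fixed order; identical configs give bit-identical cohorts across
  platforms.

What the generator does **not** emulate: between-feature correlation,
batch or platform effects, informative missingness, isoform structure,
non-proportional hazards, or co-mutation patterns.  Passing recovery
tests therefore demonstrate correctness of the pipeline's logic and
calibration of its statistics under the stated model — not robustness to
the full messiness of real proteogenomic data.

## Problem sizes in the test suite

The simulation-based tests use cohorts the analysis can process in
seconds: 1,000 features at the default sample sizes for the end-to-end
recovery replicates, 10,000 features for type-I calibration, n = 500 with
100 replicates for Cox recovery, and 5,000 simulated variances for the
moderation estimator — sizes at which the Monte-Carlo error is safely
inside each test's tolerance.

## Known limitations

* The unmoderated t with raw-p thresholds is intentionally liberal; the
  screen's guard against false positives is the conjunction of gates, not
  per-test stringency.
* The membrane vocabulary is flat: no GO DAG traversal or term
  propagation.
* Cox regression is univariate only; no covariate adjustment or
  multivariable models.
* The off-tumor rule treats AU thresholds (1 and 10 AU) as universal;
  real tissue atlases would require platform-specific calibration.
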