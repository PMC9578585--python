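# Methods

This note documents the statistical procedures implemented in `achnet`,
the assumptions behind them, the synthetic study conditions, and the
numerical choices that were genuinely open.

## Data model

The unit of observation is the **dyad**: an unordered pair of organizations
within one coalition site. A roster survey yields directed *tie reports*
(reporter, target, collaboration types, strength 1–3, evolution, expected
sustainment), which are aggregated to dyads:

- **Union rule.** A dyad is tied if either endpoint reports it in either
  direction. Roster surveys under-report (forgotten or skipped ties) far
  more often than they invent ties, so a single positive report is treated
  as evidence of a tie and a respondent's silence about a partner is
  treated as evidence of absence.
- **Missing dyads.** If neither organization responded, nothing is known
  about the pair; the dyad enters the missing mask and is imputed.
- **Conflict resolution.** At most two reports describe one dyad.
  Strength is averaged; types are unioned; evolution is `preexisting` if
  *any* reporter says so (a tie one partner knew before the grant cannot
  have been created by it); sustainment expectation defaults to the
  optimistic "any reporter expects it" rule, with a strict "all reporters"
  variant exposed as `sustain_rule="all"`.
- **Layers.** Three nested edge sets per site: `preexisting ⊆ grant` and
  `sustained ⊆ grant`, with `stimulated = grant \ preexisting`. Networks
  are undirected: the survey asks about collaboration, a mutual relation,
  and density denominators are `n(n−1)/2`.

## Missing-dyad imputation

An ERGM with `edges` and `triangles` statistics is fitted per site to the
observed (non-missing) dyads of the grant layer by **maximum
pseudolikelihood** (MPLE): logistic regression of each dyad's state on its
change statistics — 1 for the edge term, the number of common neighbors
for the triangle term. MPLE is fast, deterministic, and adequate at
coalition scale (11–36 nodes); full MCMC maximum likelihood is out of
scope. A layer whose observed dyads are all ties or all non-ties is
flagged degenerate and falls back to an edges-only empirical logit capped
at |20|.

Each of `m = 10` completions (default) draws every missing dyad from the
fitted conditional `logistic(θ_edges + θ_triangles · common neighbors)`.
**The triangle statistic is evaluated on the observed structure**
(`triangle_update="observed"`), making the draws independent — this is the
MPLE predictive distribution. The textbook alternative, Gibbs sweeps that
recompute the statistic on the current completion
(`triangle_update="sequential"`, `k = 20` sweeps), is implemented but not
the default: the edge–triangle ERGM is near-degenerate, and because every
dyad among the non-respondents is missing, the missing mask contains a
contiguous block in which live triangle feedback avalanches toward a
near-complete subgraph (in experiments at ~30–38% missing, imputed-dyad
density reached 0.99 against observed densities of 0.16–0.51). The frozen
scaffold keeps imputed density consistent with the observed layer while
still letting transitive pressure raise the tie probability of dyads with
many observed common neighbors. Curved alternatives (GWESP) are a
non-goal.

An imputed tie then receives nested-layer memberships and attributes from
the site's observed empirical distributions: preexisting membership
Bernoulli(observed preexisting fraction of grant ties), sustainment
Bernoulli(observed sustained fraction), strength resampled from observed
strengths, types from observed per-type marginals. Nesting therefore holds
in every completion by construction, and observed dyads are never altered.
Completion seeds are `master_seed + completion_index`; per-site master
seeds derive from the pipeline seed.

## Logistic network regression

Both models maximize the Bernoulli likelihood over dyad rows by
iteratively reweighted least squares (convergence when the maximum
absolute score < 1e-8, at most 100 iterations), with covariance from the
inverse observed information, Wald 95% CIs `exp(β ± 1.96·SE)`, and
two-sided normal p-values.

- **Stimulated model.** Risk set = dyads *without* a preexisting tie
  (stimulation is only possible where no tie existed; `risk_set="all"` is
  available). Outcome: the dyad is a stimulated grant tie. Degree sums and
  harmonic-closeness differences are computed on the preexisting layer.
- **Sustained model.** One row per grant tie; outcome: expected
  sustainment. Centralities are recomputed on the grant layer; mean
  strength, a stimulated indicator, and the four type indicators join the
  design.
- **Site effects.** One fixed-effect indicator per site and *no* global
  intercept (the dummies span it), so sites with different baseline tie
  production pool into a single model.
- **Closeness.** Harmonic (Σ 1/d over other nodes, 1/∞ = 0), not Freeman
  closeness — coalition layers are frequently disconnected and the
  harmonic form needs no special-casing. It is left unnormalized (no
  division by n−1), so the closeness-difference coefficient is
  scale-sensitive to site size; comparisons of its magnitude across
  studies should keep that in mind.
- **Separation.** Complete or quasi-separation (typical case: a small
  site contributes no stimulated tie, driving its intercept to −∞) caps
  the affected coefficients at |20|, flags the fit non-converged, and
  leaves the remaining coordinates at their conditional optimum. The
  pipeline additionally drops covariate columns with no variation in any
  completion (so pooled coefficient sets stay aligned) and degrades to a
  capped degenerate fit if an outcome is single-class.
- **Pooling.** Rubin's rules across completions: pooled estimate = mean;
  total variance = mean within-completion covariance plus
  `(1 + 1/m) ×` between-completion covariance.
- **Prediction.** Sustainment-probability curves sweep strength over
  [1, 3] with all other covariates at their site-specific design means and
  the site's own intercept active.

## Collaboration-type comparisons

Grant ties pooled across sites are cross-tabulated as evolution
(preexisting vs stimulated) × presence of each type. Pearson chi-square
without continuity correction (tables here are large; the correction is a
small-sample device), cross-product odds ratio oriented
preexisting:stimulated, Woolf CI `exp(log OR ± 1.96·√Σ 1/cell)`, and the
Haldane–Anscombe 0.5 addition only when a cell is empty.

## Synthetic study conditions

The generator's defaults emulate a seven-site Iowa-style ACH coalition:
site sizes (28, 23, 36, 11, 29, 16, 26), response rates (53.6%, 43.5%,
38.9%, 45.5%, 37.9%, 43.8%, 57.7%), steering-committee sizes (6, 4, 9, 2,
4, 2, 10), one public-health integrator per site. Respondents are drawn as
a **fixed count** `round(rate·n)` without replacement rather than i.i.d.
Bernoulli: published response rates are exact per-site fractions, and the
fixed count makes missing-dyad fractions (e.g. C(6,2)/C(11,2) = 27.3% at
an 11-node site with 5 respondents) reproducible rather than random.

The preexisting layer is a Bernoulli graph with baseline log-odds −2.3,
same-sector homophily +0.7, and a +1.0 closure bonus per shared neighbor
applied in a single Gibbs pass — a modeling convenience that induces
realistic transitivity (~0.33) without full ERGM simulation. Stimulated
ties and sustainment labels are drawn from exactly the logistic models the
package fits, so the LNRMs are well-specified and parameter recovery is a
meaningful check. The slope coefficients default to published
coalition-study effect sizes (odds ratios 1.157 per unit degree sum, 2.715
for integrator dyads, 13.86 for steering pairs; 1.881 per strength level,
2.129 / 2.164 for data / resource sharing); the intercepts (−5.3
stimulated, −3.2 sustained) were calibrated once so that edge counts,
densities, and the sustained fraction fall in the ranges coalition studies
report (~167 stimulated ties study-wide, 64% of grant ties sustained).
Strengths and types are drawn independently of topology — no dependence is
assumed — so type-composition contrasts are null under the defaults and
are planted explicitly where a contrast is under test.

Reports are emitted only for true incident ties by responding
organizations: the asymmetric-error assumption behind the union rule
(false negatives, not false positives). An optional false-negative
reporting rate exists (default 0). Recall error is modeled at the edge
level: a stated fraction of preexisting ties is misreported as stimulated,
consistently by both reporters; the `recall_error_sensitivity` analysis
perturbs, refits the full pipeline, and reports per-coefficient deviations
and sign agreement. The perturbation design (5% default rate) is a
stand-in — no canonical design exists for this check.

**What the generator does not emulate:** within-organization multiple
respondents and their aggregation, respondent-specific reporting styles or
strength disagreement between partners, cross-site ties, longitudinal
re-surveys, and any dependence of tie attributes on topology. Passing
recovery tests therefore show the estimators are correct *under the stated
generating process*, not that real coalition data meet its assumptions.

## Test scale and tolerances

Oracle tests compare density/transitivity/closeness to O(n³) enumeration
and hand BFS on 200 random graphs (n ≤ 20), and the IRLS fitter to an
independent likelihood maximizer on 50 random designs (agreement 1e-5;
intercept-only MLE exact). Parameter recovery uses 200 replicates at full
response and the seven default site sizes: 95% CI coverage is required in
[0.90, 0.99] for every coefficient and mean |bias| < 0.1 log-odds for the
shared effect coefficients — site intercepts are excluded from the bias
bound because the smallest sites occasionally produce zero events, making
their (capped) MLE infinite by construction. Imputation checks use m = 200
completions against a 3-Monte-Carlo-SE band. Rubin's rules are checked
against the hand example {0, 1}/{1, 1} → 0.5, 1.75 at 1e-12. These
problem sizes keep the default suite under a minute while leaving binomial
error well below the asserted bands.
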