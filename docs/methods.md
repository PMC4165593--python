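# Methods

## Demographic rates

All rates are annualized and computed over a fixed multi-year window
(default 1992–2003, i.e. `T = 11` yearly intervals) on trees at or above
the 10 cm DBH census threshold.

* **Population change rate λ** — geometric annual rate
  `(N_T/N_0)^(1/T) − 1` by default (zero when the population is unchanged);
  a log-ratio alternative `ln(N_T/N_0)/T` is available via
  `convention="log"`. The two agree to first order for the small rates
  typical of tree populations; the geometric form is the common demographic
  convention and is defined at `N_T = 0`.
* **Recruitment and mortality rates** — mean of annual ratios
  `(1/T) Σ n_t/N_t` by default, which weights each yearly survey equally;
  the pooled ratio `Σn_t / ΣN_t` (which weights years by population size)
  is available via `pooling="pooled"`. The two coincide exactly when the
  yearly ratios are constant.
* **Exclusion rule** — deaths of trees flagged as wounded or poisoned by
  silvicultural operations are dropped from the mortality numerator; the
  trees themselves still count among the living. This is the only reading
  under which a census whose every death is flagged yields mortality zero.
  It slightly understates mortality when flagged trees would also have died
  naturally; with realistic flagged fractions (a few percent) the bias is
  well inside Monte-Carlo error at the tested census sizes.
* **Recruitment detection** — a tree recruits in the first year it is
  recorded at ≥ 10 cm DBH; trees present in the window's first census year
  are the initial cohort, not recruits. An event in calendar year `y` is
  attributed to the interval starting at `y − 1`, with denominator
  `N_{y−1}`.

Derived traits: **Dm** is the 95th percentile of the left-truncated DBH
distribution (diameters above 10% of the species' absolute maximum —
truncation suppresses the juvenile bulk so the percentile reflects adult
stature); **SV** is the ellipsoid volume `(π/6)·L·W·D` on the measured seed
dimensions (any constant factor becomes an additive shift after the log
transform and cannot affect the network analysis); **RDIR** is the 95th
percentile of per-interval relative diameter increments
`(D_{t+1} − D_t)/(D_t Δt)` pooled over trees and one-year intervals within
a window (per-tree averaging first is available via `per_tree=True`). All
95th percentiles use linear interpolation between order statistics; at
n ≈ 50 the choice of quantile convention moves Dm by less than one diameter
class.

## Transformation

Right-skewed variables (defaults: rec, mort, Dm, SV) are natural-logged so
their distributions approach the normality the Gaussian network assumes.
A mortality rate of exactly zero (a species with no observed deaths) makes
the log undefined; the default policy adds half the smallest positive
observed value of that column before logging, only when a zero is present.
An explicit per-variable offset map can override this. Already-Gaussian
inputs (e.g. tables from the SEM generator) run with `log_vars=()`.

## Network model and scores

Each node is a Gaussian linear model in its parents; the joint likelihood
is the product over parent–child clusters, so any decomposable score is a
sum of family scores computed from the sample size, means and covariance
alone. Two scores are provided:

* **BIC** (default): `loglik − (k+2)/2 · ln n` per family, with the
  maximum-likelihood residual variance (divisor `n`) inside the likelihood.
  Summaries report the unbiased `n − k − 1` variance instead, matching the
  usual regression convention.
* **bayes_cg**: the Bayesian Gaussian (BGe-form) marginal likelihood under
  a conjugate normal-Wishart prior centred on the sample mean, with
  imaginary sample size `prior_ess` (default 4, a weakly informative
  prior), Wishart dof `prior_ess + d + 1`, and identity-proportional prior
  scatter. The subset-size-adjusted dof makes the score decomposable and
  identical across Markov-equivalent DAGs, which the tests assert.

Both scores therefore identify structure only up to Markov equivalence;
orientation information comes from the tier constraints, which ban every
edge out of the performance tier (λ), every demographic → trait edge, and
every direct trait → performance edge. Within-tier edges (e.g. rec ↔ mort)
are allowed: the hierarchy bans only downward arrows.

## Structure search

Greedy hill climbing from the empty graph over single-edge add / delete /
reverse moves, accepting the best strictly-improving legal move
(improvement threshold 1e-10 guards floating-point ties; candidate moves
are enumerated in a fixed node order, so ties break deterministically).
After local convergence the incumbent is perturbed by `perturb_moves`
(default 10) random legal moves and re-climbed, for `restarts` (default 20)
rounds — enough to saturate the ten-node space, where the search matches
exhaustive enumeration on every three-node problem tested. Family scores
are cached by (node, parent-set) across the whole search, so a 20-restart
run on ten nodes takes well under a second. The search is deterministic
given its seed.

## Validation and pruning

* **Basis set**: for every non-adjacent pair in a fixed (lexicographic)
  topological order, the claim `x ⟂ y | pa(x) ∪ pa(y)`. Every emitted claim
  is d-separated in the DAG (asserted against a graphical oracle in tests).
* **Partial correlations** are computed by the classical recursion
  `r_xy·Zw = (r_xy·Z − r_xw·Z r_yw·Z)/√((1−r²_xw·Z)(1−r²_yw·Z))`, memoized
  over subproblems; the precision-matrix expression serves as an
  independent oracle in tests, never as the implementation path. Spearman
  partials run the same recursion on rank-transformed data.
* **P-values** use Fisher's z: `z = atanh(r)·√(n − |Z| − 3)`, two-sided
  normal. At n = 53 this is an approximation; its type-I error and the
  resulting uniformity of Fisher's C under the true model are verified by
  simulation (rejection rate within [0.03, 0.07] at α = 0.05; KS test on
  1000 null replicates).
* **Fisher's C** is computed over the Pearson basis-set p-values (the
  coefficient consistent with the model's linearity assumption).
* **Pruning**: each edge `u → v` is tested as `u ~ v | pa(v) \ {u}` — the
  conditioning set under which the edge's regression coefficient is the
  association being claimed. The edge is removed iff BOTH corrected
  p-values are ≥ α (default 0.05). Corrections (Holm by default, chosen as
  the conservative option; Benjamini–Hochberg available) are applied
  separately per coefficient and per claim kind. Pruning only deletes
  edges; the pruned DAG is refit before reporting. Note the direction of
  the α dependence: a smaller α makes significance harder, so it removes
  *more* edges.

## Synthetic data

`default_paracou_like_spec()` defines the reference ten-node SEM:
exogenous SV, WD, LNC, Dm; LPC ← WD(−0.45), LNC(+0.55);
δ13C ← LPC(+0.45), Dm(+0.40); SLA ← LNC(+0.50), δ13C(−0.35);
rec ← LPC(+0.50), WD(−0.40), SV(−0.30); mort ← Dm(−0.50);
λ ← rec(+0.60), mort(−0.35). Coefficients are standardized (every node has
unit marginal variance; residual variances are solved from the implied
parent covariance) with magnitudes 0.3–0.6 — strong enough to be
detectable at n ≈ 2000, realistic for interspecific trait correlations,
and matching the qualitative sign pattern of the trait–demography
literature; they are defaults of this package, not estimates from any
dataset. The `include_rdir` variant replaces the direct WD → rec edge with
the mediated path WD → RDIR(−0.55) → rec(+0.50), so mediation recovery can
be tested where it is true by construction. Default n = 53 mirrors the
scale of a realistic species table; structure-recovery tests deliberately
use n = 2000 because learning at n = 53 is noisy by design.

What the generator does *not* emulate: non-Gaussian trait distributions
beyond what the log transform induces, measurement error, interactions
among traits (the per-node models are purely additive), phylogenetic
non-independence among species, and spatial or competitive structure in the
censuses. Passing tests therefore certify the estimators and the inference
machinery under the model's own assumptions, not robustness to their
violation on field data.

The census simulator draws yearly Bernoulli deaths (probability 0.01 by
default), binomial recruitment at the threshold (0.05), lognormal initial
diameters above 10 cm and Gaussian relative growth (2% ± 1% yr⁻¹) for a
stand of 1000 trees over 1992–2003; these magnitudes match disturbed
tropical-plot dynamics. Flagged ("excluded") trees default to none and are
enabled per test.

## Numerical choices and degenerate inputs

* Family scores raise on zero residual variance (infinite likelihood) and
  on collinear parent sets.
* The partial-correlation recursion raises when a conditioning variable is
  perfectly collinear with a claim variable (zero denominator); `ci_test`
  clamps |r| ≤ 1 against rounding and returns p = 0 at exact |r| = 1.
* `fisher_c` rejects p = 0 (infinite statistic); the pipeline floors
  p-values at 1e-300 before combining.
* Census rates require a positive living count in every interval; a
  species absent at the period start is reported as not analyzable rather
  than given a rate.
* All stochastic components take explicit seeds; pipeline exports are
  byte-identical across reruns with the same config and seed.

## Problem sizes used in checks

Oracle comparisons use 200 random positive-definite correlation matrices
(|Z| ≤ 4) and every 3-node DAG (25); calibration uses 2000 null
replicates (n = 500) for the type-I rate and 1000 replicates (n = 53, a
five-node SEM) for Fisher's C uniformity; recovery uses 20 fresh draws at
n = 2000 with 20 restarts; the pipeline demonstration runs at the
53-species study scale. These sizes give Monte-Carlo error comfortably
below the asserted tolerances while keeping the whole suite fast.

## Known limitations

* The search returns a single DAG, not its Markov-equivalence class;
  within-tier edge orientations at small n should be read as one member of
  the class.
* Fisher-z p-values and the χ² null of Fisher's C are asymptotic; both are
  simulation-verified at n = 53 but smaller samples are untested.
* No support for missing trait values, latent variables, interventional
  data, or mixed discrete–continuous networks.
* The species-level analysis treats species as independent replicates;
  phylogenetic signal in traits would violate this.
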