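# Methods

## Circuit ensemble model

A regulatory network is a set of named nodes with signed directed edges
(activation or inhibition). Node dynamics follow

    dx_i/dt = g_i * prod_{j in reg(i)} H(x_j; B0_ji, n_ji, lambda_ji) - k_i * x_i

with the shifted Hill multiplier `H(B) = lambda + (1 - lambda) / (1 + (B/B0)^n)`:
1 at zero regulator, `(1 + lambda)/2` at the threshold, saturating at the
fold change `lambda`. Inhibition stores the reciprocal of the sampled
fold-change magnitude, so activation edges have `lambda > 1` and inhibition
edges `0 < lambda < 1`. The model assumes deterministic mass-action-like
kinetics with multiplicative, independent regulation per edge; transcription
and translation are collapsed into a single production term, and there is no
explicit noise, delay or dilution term.

Cell-to-cell variability is represented by parameters, not by stochastic
dynamics: each simulated cell is one parameter set drawn uniformly from the
configured ranges, and the population readout is the set of stable steady
states across all sampled cells.

### Sampling defaults

| parameter | default | units | rationale |
|---|---|---|---|
| production g | U(1, 100) | molecules/time | two-decade span of expression capacity |
| degradation k | U(0.1, 1) | 1/time | lifetimes between 1 and 10 time units |
| Hill coefficient n | integer U(1, 6) | — | non-cooperative to strongly cooperative binding |
| fold-change magnitude | U(1, 100) | — | weak to essentially switch-like regulation |
| threshold B0 | U(0.02·M, 1.98·M) | molecules | half-functional rule, below |
| parameter sets | 10,000 | — | working default of the ensemble convention |
| initial conditions | 100 | — | per parameter set |

`M` is the median unregulated level g/k under the configured ranges,
estimated once by a fixed-seed Monte Carlo of 10,000 draws (the internal
seed is a constant, deliberately outside the user-visible random stream, so
the threshold rule is part of the model rather than of a particular run).
Spreading thresholds symmetrically around `M` makes each link functional in
roughly half of the sampled cells, which is what lets a finite ensemble
exercise both the "edge on" and "edge off" regimes of every interaction.

### Steady-state search

Initial conditions are log-uniform per coordinate on
`[1e-2 * g_min/k_max, (g_i/k_i) * prod_j max(1, lambda_ji)]` — the upper end
is the attainable-range bound (production fully activated), and the log
scale covers near-zero states that a linear draw would almost never visit.

Integration is forward Euler with step 0.05 time units up to a horizon of
200. A trajectory stops as soon as the per-node relative rate
`|f_i| / max(|x_i|, 1)` falls below the tolerance (default 1e-3) on every
node simultaneously. The per-node criterion matters: a sup-norm criterion
normalized by the largest coordinate certifies endpoints that are still
5–15% off their root on weakly expressed nodes, which then fail to merge
with their basin siblings and inflate the state census.

Endpoints are deduplicated by Chebyshev distance in log2 space (merge
tolerance 0.05, i.e. ~3.5% in linear scale) and each cluster representative
is refined by a damped Newton iteration on the analytic Jacobian:

* a polished root whose Jacobian spectrum has only negative real parts is
  kept (exact to ~1e-12 relative residual);
* a polish that lands on an *unstable* root exposes the endpoint as a
  saddle-node ghost — a trajectory crawling through a region of tiny |f|
  that satisfies the rate criterion without being near any stable state —
  and the cluster is discarded;
* if the polish fails outright the raw endpoint is kept (it still satisfies
  the convergence criterion).

Trajectories that exhaust the horizon are offered the same Newton rescue
with the same stability gate; this recovers stable states whose local
relaxation rate exceeds the explicit-Euler stability limit `2/dt` for the
configured step. Overflowing trajectories are counted as divergent and
excluded; a parameter set with no surviving state is flagged and excluded
from statistics, and an ensemble in which *every* set fails raises a hard
error. Reported states are re-verified against the convergence criterion
and sorted lexicographically, which fixes the state order deterministically.

Each multistable parameter set contributes one ensemble row per distinct
stable state, unweighted — no basin-size weighting is attempted, since the
random-initial-condition counts are a poor estimator of basin volume at the
default 100 starts.

A structural note on the built-in circuit: the positive BubR1/p53 and
BubR1/γH2AX co-variation is encoded as two activation edges out of BUBR1 (a
common upstream node produces the observed positive co-variation without
asserting a mechanism). With that encoding the six-node circuit is acyclic,
and an acyclic network of this form has exactly one stable state per
parameter set; multistability in this package is exercised by the
mutual-inhibition toggle fixtures. Users who want to test other
orientations of the co-variation supply their own topology file.

### Ensemble statistics

Steady states are log2-transformed (no z-scoring; the transform refuses to
run twice) and pairs are summarized by the Pearson product-moment
coefficient, a two-sided p-value from the t-distribution with n−2 degrees
of freedom, and an ordinary-least-squares line of y on x. The default
readout pairs are (TWIST1, CDH1), (TWIST1, VIM), (TWIST1, BUBR1).

## Cohort screen

For each cohort and each target (a gene-set member's expression, or a
covariate), the driver and target series are robustly standardized — median
center, scale 1.4826·MAD (consistent for the standard deviation at the
normal) — and the slope of `y = b·x` is fitted by iteratively reweighted
least squares with Huber weights (tuning constant 1.345, MAD residual
scale, at most 50 iterations, coefficient tolerance 1e-8; statsmodels RLM
underneath). The coefficient is `b` clipped to [−1, 1]; the p-value is the
two-sided tail of the robust t-statistic at n−2 degrees of freedom. A
numerically perfect fit short-circuits to p = 0; a non-converged fit is
flagged and reported with p = 1.

Robust standardization is load-bearing, not cosmetic: with moment
standardization, symmetric 10-sigma contamination of 5% of samples inflates
the variance roughly six-fold, and the deflated denominator attenuates the
robust slope exactly as much as the Pearson coefficient — the robust fit
then wins the head-to-head error comparison only ~56% of the time. With MAD
standardization it wins essentially always, at the cost of O(0.05)
sampling-level disagreement with Pearson on noisy (but clean) Gaussian data.

Multiple testing is controlled per gene set with Bonferroni
`q = min(1, p·m)`, `m` = (targets in the set) × (cohorts screened) — the
most conservative plausible scope — and flags are set at q < 0.01. Each
covariate forms its own single-target set. Mutation counts are associated
on the log10(count+1) scale (burden is heavy-tailed); CNA fraction is used
raw. Cohorts below 20 samples are skipped, never imputed; gene-set members
absent from the matrix are dropped with a warning count, and a set with no
member present is an error.

The default EMT list is CDH1, OCLN, TJP1, CDH2, FN1, SNAI1, VIM. The CIN
and DSB defaults combine the spindle-checkpoint genes highlighted by the
circuit work (MAD2L1, AURKC, BUB1, BUB1B, MAD1L1, AURKB) and canonical
double-strand-break genes (H2AX, TP53BP1, BRCA1, BRCA2, RAD51, ATM); both
are plain data intended to be replaced by the caller's curated lists.

Stage stratification reports per-stage n, median and quartiles of one
gene's expression in one cohort, with missing-stage samples counted
separately rather than dropped silently.

## Synthetic cohorts

The generator emulates the statistical structure the screen consumes, with
exactly known truth: per cohort a latent driver level z ~ N(0,1) per
sample; driver log2 expression affine in z plus an optional per-stage mean
shift; each target `a·z + sqrt(1−a²)·ε` on the standardized scale, then
shifted to per-gene baselines drawn on [4, 10] log2 units — so the true
driver–target correlation is exactly the requested `a`, which makes
recovery tests sharp. Mutation counts are negative-binomial (dispersion
1.0) with log-mean linked to z; CNA fractions are logit-normal (spread 1.0)
linked likewise; both links are attenuated by their own sampling noise, so
covariate recoveries are sign tests, not point tests.

What the generator does *not* emulate: gene–gene correlation beyond the
single driver factor, cohort-specific library or batch effects, missing
values, the empirical size distribution of real tumor cohorts, or any
relationship between stage and the covariates. Passing screens on this
generator therefore demonstrate calibration, power and robustness of the
statistics under the stated model — not performance on any real compendium.
The screen accepts real matrices in the same tab-delimited format if
supplied.

## Problem sizes used by the tests and the acceptance script

The shipped checks run the ensemble at 2,000 parameter sets × 50 initial
conditions per seed (20 seeds in the sign-reproducibility test, 10 in the
acceptance script), the closed-form check at 1,000 single-node sets, the
oracle comparison at 100 toggle + 20 six-node-circuit sets, and the screen
calibration at 50 replicates of 30 cohorts × 100 samples, with 100–200
replicates for power, recovery and robustness. These sizes give stable
pass/fail behavior (sign tests at these scales have p-values far below the
0.01 line) while keeping the full suite in the minutes range on one CPU.

## Known limitations

* Oscillatory dynamics are out of scope: a limit cycle never satisfies the
  convergence criterion and is counted as non-converged.
* Euler with a fixed step can fail to settle into stable states whose local
  relaxation is faster than 2/dt; the Newton rescue recovers these, but a
  pathological configuration (tolerances too loose, horizon too short) is
  reported through warning counts rather than repaired.
* The IRLS p-value relies on the asymptotic normality of the robust slope;
  at the minimum n of 10 it is approximate.
* Bonferroni at the chosen scope is deliberately conservative; with many
  cohorts and large sets, true weak associations will be missed.
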