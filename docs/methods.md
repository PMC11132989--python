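# Methods

## The diffusion model

`socdiff` models the spread of a discrete skill through animal groups as a
multiplicative-hazard process. At any time *t* a naive, untrained
individual *i* acquires the skill with hazard

λ(i, t) = λ₀(t) · [ s_g(i) · E(i, t) · exp(γ'xᵢ) + exp(β'xᵢ) ]

* **λ₀(t)** — a baseline hazard shared by everyone. It cancels from the
  order-of-acquisition likelihood and is never estimated; it exists only in
  the synthetic generator (as a config constant, per hour).
* **s_g** — social-transmission strength in group *g*: the increase in
  acquisition rate per unit network connection to informed individuals,
  relative to the asocial rate of the reference individual. `s = 0` is
  purely asocial learning.
* **E(i, t)** — exposure on the chosen network (below).
* **xᵢ** — individual-level variables (ILVs): sex (0 female, 1 male), age
  (years, centred at the sample mean) and rank (ordinal-averaged score,
  centred at the sample median). With this centring exp(β'x) = exp(γ'x) = 1
  for a female of average age and middle rank, so s reads directly as a
  rate multiplier for that reference individual (`relative_rate(s, n) =
  1 + n·s` on the absolute network). β acts on the asocial rate, γ on the
  social rate; in the "unconstrained" form used here each included ILV gets
  independent coefficients on both rates.

Because only the *order* of first solves enters the likelihood
(order-of-acquisition variant), each acquisition event k contributes
log r(a_k) − log Σ_{i∈R_k} r(i) over the naive risk set R_k. This
conditional probability is exact for arbitrarily time-varying exposures as
long as exposures are evaluated at the event instant, which is what
`exposure_at_events` does. The two study groups form one pooled diffusion
(a common order axis with the risk set spanning both groups); this is what
makes the static group network a meaningful comparison model for "the
diffusion merely reflects between-group timing differences".

### Networks

Four connection structures, all queried with a strictly-before-t
convention (an observation time-stamped exactly at an acquisition does not
contribute to that acquisition's exposure — the causal direction is
unknowable at the instant itself; the source studies state no rule):

| variant | exposure E(i, t) |
|---|---|
| `absolute_observation` | number of solves i has watched |
| `individuals_observed` | number of distinct solvers i has watched |
| `single_observation` | 1 if i has watched any solve, else 0 |
| `group` | number of informed same-group individuals (static ties) |

Trained demonstrators are informed from t = 0 and never appear in a risk
set. Observation counts are uncapped.

## Model selection

Candidate sets are enumerated as network × hypothesis × ILV pattern. The
transmission hypotheses: s₁ ≠ s₂, s₁ = s₂, s₂ = 0, s₁ = 0, and purely
asocial; the group network is fitted only under s₁ = s₂ (it exists as a
null for the observation networks). Two ILV enumeration schemes are
available: the default **joint** scheme (each ILV in or out of the model
as a whole, 2³ = 8 patterns) and an **independent** scheme (asocial and
social inclusion varied separately, 4³ = 64). The source analysis quotes a
"16 models per set" count that matches neither; the scheme is therefore
config-driven and the default is the smaller, more conventional one.

Models are ranked by AICc, −2ℓ + 2k + 2k(k+1)/(n−k−1), with **n = the
number of acquisition events** (the likelihood's independent
contributions; the cited multi-model framework leaves n to the analyst).
Support for a hypothesis or network is its summed Akaike weight,
renormalised within the compared set; because the asocial set is much
smaller than the social sets, evidence against purely asocial learning is
judged by the profile CI for s, not by total weight. Model-averaged
estimates treat a parameter fixed at 0 by constraint as contributing 0.

## Inference for s

* **Fitting** — bounded L-BFGS-B with a 5-point multi-start over
  s ∈ {0.01, 0.1, 1, 10, 100} (coefficients start at 0), convergence
  tolerance 1e-12 on the objective. Non-convergence is flagged on the
  result, never silent. Ties in acquisition order (identical timestamps)
  are broken by event-log order and reported as a diagnostic.
* **Profile CI** — bounds solve 2(ℓ_max − ℓ_profile(s)) = χ²₁(0.95), with
  all other parameters re-optimised at each pinned s, roots found by
  Brent's method. The upper bound is +∞ when the profile deviance never
  reaches the threshold below a ceiling of 10⁶ × ŝ (10⁶ if ŝ = 0). A flat
  likelihood (all exposures zero) yields (0, ∞).
* **Boundary caveat** — s = 0 lies on the parameter boundary, so the
  χ²₁-threshold CI is conservative there: the large-sample probability
  that a 95% CI excludes 0 under a true s = 0 is ≈ 2.5% (the ½χ²₀ + ½χ²₁
  mixture), not 5%. The calibration experiments show exactly this.
* **%ST** — event-wise attribution: the mean over acquisition events of
  the social share s·E·exp(γ'x) / r of the acquirer's rate, × 100. (The
  alternative — forward simulation from the fitted model — is not
  implemented; the output metadata records the method.) Interval endpoints
  re-optimise nuisance parameters at the s profile bounds; an infinite
  upper bound is evaluated in the limit, where every event whose acquirer
  had positive exposure becomes fully social.

## Multistate extension

Two transitions — naive → interacting (first manipulation) and
interacting → informed (first solve) — each carry their own
order-likelihood with its own s-by-group and ILV coefficients, both using
the absolute observation network (observations of *successful* solves
only; unsuccessful attempts are not modelled). The stages share no
parameters, so the joint maximum factorises and the fit is implemented
stage-wise. Stage-1 events condition on the naive risk set, stage-2 events
on the interacting risk set; the interleaved sequence is globally
time-ordered with manipulations sorting before solves at ties. A solve
with no prior recorded manipulation is coerced to both transitions at the
solve instant, with a diagnostic. The stage-1 between-group ratio s₂/s₁ is
profiled directly (s₂ = ρ·s₁, maximising over s₁ and coefficients at each
ρ); an estimate with ŝ₁ = 0 is reported unbounded with a diagnostic.

## Observation-network GLMM

Who watches whom is modelled as Bernoulli with logit link on the expanded
opportunity table (one row per solve event × same-group candidate other
than the manipulator):

logit p = α_g + κ_g·kin + a_g·age_diff + r_g·rank_diff + φ_g·prev + u_obs + v_manip

with maternal kinship 0/1, age and rank differences coded manipulator
minus observer (a positive a_g means a bias towards watching older
manipulators), prev = 1 if the candidate watched the previous manipulation
in its group, group-specific fixed effects, and crossed random effects for
observer and manipulator propensities (pooled across groups, since each
individual belongs to one group). Presence at the apparatus is
unobservable and not modelled: every living same-group individual is a
candidate at every event.

Priors: fixed effects Normal(0, 2.5²) — weakly informative on the logit
scale; random-effect SDs half-Normal(1); both config-overridable. The
sampler is an adaptive Metropolis-within-Gibbs scheme written for this
model: scalar random-walk updates for fixed effects and log-SDs
(Robbins–Monro adaptation to 0.44 acceptance during burn-in), and exact
*parallel* single-site updates for the random-effect vectors — valid
because the likelihood factorises over observers (and over manipulators),
so per-component acceptance ratios can be computed simultaneously with one
vectorised pass. Chains are seeded independently and reproducibly.
Reported effects are odds ratios (back-transformed posterior means) with
95% highest-posterior-density intervals (narrowest-window, via arviz), and
between-group ratios from per-draw coefficient differences; reporting is
gated on rank-normalised split R-hat < 1.05 (note this statistic plateaus
near 1.8 even for completely separated chains). Defaults: 2 chains × 3000
iterations, 1000 burn-in.

## Synthetic generator

`simulate_diffusion` emulates the target study design: two groups with one
trained mid/high-rank female demonstrator each, 39 two-hour sessions
concatenated on a cumulative experimental-time axis, informed individuals
solving as Poisson processes, each solve independently watched by each
same-group individual with a per-individual attendance propensity
(Beta-distributed, concentrating observation on a watchful subset), and
naive individuals acquiring with the hazard above. All hazards are
piecewise-constant between events, so the simulation draws competing
exponentials exactly — no time discretisation — which makes it a valid
generator for the order likelihood and the recovery experiments internally
consistent. A two-stage mode adds first-manipulation events with
stage-specific parameters.

What it does **not** emulate: ball logistics and spatial structure
(attendance probabilities stand in for "being near the apparatus"),
session gaps (time is cumulative), observation of unsuccessful attempts,
coding error, and demography. Passing recovery tests therefore show the
estimators are correct *for this generating process*, not that any real
dataset satisfies it.

### Canonical recovery design

`recovery_config`: 2 × 15 individuals (one demonstrator each), stop after
20 acquisitions; demonstrators solve 1/h, attendance Beta(1, 9), λ₀ =
0.05/h. The rates are chosen so exposures at acquisition times are of
order units: if observation is much denser, the social term saturates the
likelihood, the data only bound s from below, and ŝ's upper tail is
unbounded (the same phenomenon that produces s CIs with infinite upper
limits in real open-diffusion data). For the same reason,
estimation error is *not* monotone in observation density; it is monotone
in the number of acquisition events, which is what the property tests
assert. At truth s = 2 this design gives a median ŝ within a few percent
of 2 and ~93% profile-CI coverage over 200 replicates; at truth s = 0 the
CI excludes 0 in ~2–3% of replicates (the boundary effect above).

## Numerical and degenerate-case choices

* Report rounding (rates, 2 dp) is half-even and applied once at output;
  all internal computation is unrounded.
* Stable sorts preserve input order of simultaneous events everywhere.
* Akaike weights use max-subtraction before exponentiation.
* An empty stage (no events of one transition) contributes 0 to the
  multistate likelihood, with a diagnostic; an empty risk set is an error.
* AICc is undefined (NaN) when events ≤ parameters + 1; the pipeline drops
  such over-parameterised candidates with a warning.
* Individuals absent from the event log get zero-count summaries over the
  full observation window.

## Known limitations

* No time-of-acquisition (TADA) variant; inference is order-only.
* No Hessian-based standard errors; profile CIs are the contract.
* %ST is event-wise attribution only.
* The GLMM's candidate set ignores presence/absence at the apparatus.
* Two-group designs are assumed wherever group-specific s constraints
  (s₁ ≠ s₂, s₁ = 0, s₂ = 0) are requested.
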