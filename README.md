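# socdiff

Network-based diffusion analysis (NBDA) for **open-diffusion social-learning
experiments**: studies in which a skill is seeded in animal groups (here, two
chimpanzee communities, one trained demonstrator each) and the analyst asks
whether its spread through the group follows the social network of learning
opportunities — evidence of social transmission — or is explained by asocial
learning alone.

The package is aimed at behavioural ecologists and comparative psychologists
who have event logs of *who solved the task when* and *who watched whom
solve it*, and want the full inferential pipeline: dynamic observation
networks, order-of-acquisition likelihood, AICc multi-model inference,
profile-likelihood confidence intervals, %ST, a multistate (two-transition)
extension, and a Bayesian GLMM for the structure of the observation network
itself.

## The model

Immediately before the k-th acquisition event, each naive (untrained,
not-yet-skilled) individual *i* has relative acquisition rate

```
r_k(i) = s_g(i) · E_k(i) · exp(γ'x_i) + exp(β'x_i)
```

where `E_k(i)` is *i*'s exposure on the chosen network (e.g. the number of
solves it has watched), `s_g` the social-transmission strength in *i*'s
group (rate of learning per unit connection to informed individuals,
relative to the asocial baseline), and `x_i` individual-level variables
(sex, age, rank) with separate asocial (β) and social (γ) coefficients.
The order-of-acquisition likelihood uses only the order of first solves —
the shared baseline hazard cancels:

```
ℓ = Σ_k [ log r_k(a_k) − log Σ_{i ∈ R_k} r_k(i) ]
```

with `a_k` the acquirer and `R_k` the naive risk set. Candidate models
(network variant × transmission hypothesis × ILV pattern) are compared by
AICc with Akaike-weight support shares; `s` gets a profile-likelihood CI
(upper bound may be +∞) and is converted to %ST, the estimated percentage
of acquisition events due to social transmission. See `docs/methods.md`.

## Worked example

```python
import socdiff as sd

# the packaged observation-record table of the two-group chimpanzee study
summaries = sd.table1_summaries()
print(sd.count_learners(summaries))                      # 14
print(sd.min_observations_among_learners(summaries))     # 9
print(sd.format_rate(summaries["Renate"].rate_of_observation))  # 5.69

# with a lower 95% bound s = 0.461 on the absolute-observation network,
# ten observed solves make a baseline individual at least
print(sd.relative_rate(0.461, 10))                       # 5.61  (x faster)

# a synthetic diffusion with known truth, refitted end to end
study = sd.simulate_diffusion(sd.recovery_config(truth_s=2.0, seed=5))
data = sd.build_diffusion_data(study.log, study.ilv, "absolute_observation")
fit = sd.fit_oada(sd.OADAModelSpec(s_constraint="s1_eq_s2"), data)
print(round(fit.s_by_group[0], 2))                       # 0.82
print(tuple(round(b, 2) for b in sd.profile_ci_s(fit, data)))  # (0.06, 3.98)
```

`14` is the number of untrained individuals that acquired the skill, `9`
the fewest solves any of them had watched before first solving, `5.69`
observations per hour for the most watchful non-learner, and `5.61` the
rate multiplier `1 + 10 × 0.461`. In this particular synthetic replicate
the generating strength s = 2 is estimated at 0.82 with 95% profile CI
(0.06, 3.98) — a single 20-event diffusion carries limited information
about s; across 200 replicates the median estimate sits within a few
percent of the truth (see the acceptance script below).

A command-line interface mirrors the library
(`socdiff simulate|validate|fit|model-select|multistate|obsnet|recover|report`).

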