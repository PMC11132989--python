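"""Bayesian logistic mixed model for observation-network structure.

Who watches whom? Every solve event is expanded into one binary row per
potential observer (same-group individuals other than the manipulator):
y = 1 if that individual was recorded observing the solve. The linear
predictor, per group g,

    logit p = alpha_g + kappa_g * kin + a_g * age_diff + r_g * rank_diff
              + phi_g * prev + u_observer + v_manipulator

tests for biases towards watching maternal kin, older/younger and
higher/lower-ranked manipulators (differences coded manipulator minus
observer) and for carryover (prev = 1 if the candidate observed the
previous manipulation in the group), with crossed random effects for
observer and manipulator propensities.

Inference is a self-contained adaptive Metropolis-within-Gibbs sampler:
scalar random-walk updates for fixed effects and random-effect SDs, and
exact parallel single-site updates for the random-effect vectors (valid
because rows factorise over observers / manipulators). Priors: fixed
effects Normal(0, 2.5^2); SDs half-Normal(1). Effects are reported as odds
ratios (back-transformed posterior means) with highest-posterior-density
intervals, gated on rank-normalised split R-hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .data_model import DomainError, EventLog, ILVTable

__all__ = [
    "GLMMPriors",
    "build_obs_design",
    "glmm_log_posterior",
    "PosteriorSample",
    "mcmc_sample",
    "rhat",
    "hpd_interval",
    "odds_ratios_hpd",
    "simulate_design",
]

EFFECTS = ("intercept", "kin", "age_diff", "rank_diff", "prev")


@dataclass(frozen=True)
class GLMMPriors:
    fixed_sd: float = 2.5
    sd_scale: float = 1.0  # half-Normal scale for random-effect SDs


# ---------------------------------------------------------------------------
# design expansion
# ---------------------------------------------------------------------------


def build_obs_design(log: EventLog, ilv: ILVTable) -> pd.DataFrame:
    """Expand the event log into the binary observation-opportunity table.

    One row per (solve event, same-group candidate != manipulator). Columns:
    event, group, manipulator, observer, y, kin, age_diff, rank_diff, prev.
    """
    observed: dict[tuple[float, str], set[str]] = {}
    for t, o, s in log.observations:
        observed.setdefault((t, s), set()).add(o)

    by_group: dict[int, list[str]] = {}
    for ind in ilv.individuals.values():
        by_group.setdefault(ind.group, []).append(ind.id)

    rows = []
    prev_observers: dict[int, set[str]] = {}
    event_counter = 0
    for t, solver in log.solves:
        g = ilv[solver].group
        watchers = observed.get((t, solver), set())
        prev = prev_observers.get(g, set())
        for cand in by_group[g]:
            if cand == solver:
                continue
            rows.append(
                {
                    "event": event_counter,
                    "group": g,
                    "manipulator": solver,
                    "observer": cand,
                    "y": int(cand in watchers),
                    "kin": int(ilv.is_kin(cand, solver)),
                    "age_diff": ilv[solver].age - ilv[cand].age,
                    "rank_diff": ilv[solver].rank - ilv[cand].rank,
                    "prev": int(cand in prev),
                }
            )
        prev_observers[g] = watchers
        event_counter += 1
    return pd.DataFrame(
        rows,
        columns=["event", "group", "manipulator", "observer", "y", "kin", "age_diff", "rank_diff", "prev"],
    )


# ---------------------------------------------------------------------------
# posterior density
# ---------------------------------------------------------------------------


def _design_arrays(design: pd.DataFrame):
    groups = sorted(design["group"].unique()) if len(design) else []
    g_idx = (
        design["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
        if len(design)
        else np.zeros(0, dtype=int)
    )
    C = (
        np.column_stack(
            [
                np.ones(len(design)),
                design["kin"].to_numpy(float),
                design["age_diff"].to_numpy(float),
                design["rank_diff"].to_numpy(float),
                design["prev"].to_numpy(float),
            ]
        )
        if len(design)
        else np.zeros((0, 5))
    )
    obs_ids = sorted(design["observer"].unique()) if len(design) else []
    man_ids = sorted(design["manipulator"].unique()) if len(design) else []
    obs_idx = (
        design["observer"].map({o: i for i, o in enumerate(obs_ids)}).to_numpy()
        if len(design)
        else np.zeros(0, dtype=int)
    )
    man_idx = (
        design["manipulator"].map({m: i for i, m in enumerate(man_ids)}).to_numpy()
        if len(design)
        else np.zeros(0, dtype=int)
    )
    y = design["y"].to_numpy(float) if len(design) else np.zeros(0)
    return groups, g_idx, C, obs_ids, obs_idx, man_ids, man_idx, y


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def glmm_log_posterior(
    params: dict,
    design: pd.DataFrame,
    priors: GLMMPriors = GLMMPriors(),
    include_priors: bool = True,
) -> float:
    """Log posterior density (up to a constant) at a parameter dictionary.

    ``params``: "fixed" (n_groups x 5 array, columns ordered as EFFECTS),
    "u" (observer effects), "v" (manipulator effects), "sigma_u", "sigma_v".
    """
    fixed = np.atleast_2d(np.asarray(params["fixed"], dtype=float))
    u = np.asarray(params.get("u", np.zeros(0)), dtype=float)
    v = np.asarray(params.get("v", np.zeros(0)), dtype=float)
    sigma_u = float(params.get("sigma_u", 1.0))
    sigma_v = float(params.get("sigma_v", 1.0))
    if not np.all(np.isfinite(fixed)) or not np.isfinite(sigma_u) or not np.isfinite(sigma_v):
        raise DomainError("non-finite parameter value")
    if sigma_u <= 0 or sigma_v <= 0:
        return -np.inf
    _, g_idx, C, _, obs_idx, _, man_idx, y = _design_arrays(design)
    eta = (C * fixed[g_idx]).sum(axis=1)
    if len(u):
        eta = eta + u[obs_idx]
    if len(v):
        eta = eta + v[man_idx]
    lp = _bernoulli_loglik(eta, y)
    if include_priors:
        lp += float(-0.5 * np.sum(fixed**2) / priors.fixed_sd**2)
        lp += float(-0.5 * np.sum(u**2) / sigma_u**2 - len(u) * np.log(sigma_u))
        lp += float(-0.5 * np.sum(v**2) / sigma_v**2 - len(v) * np.log(sigma_v))
        lp += float(-0.5 * (sigma_u**2 + sigma_v**2) / priors.sd_scale**2)
    return lp


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSample:
    """Posterior draws: {parameter name: array of shape (n_chains, n_draws)}."""

    draws: dict[str, np.ndarray]
    groups: list[int]
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for name, arr in self.draws.items():
            for c in range(arr.shape[0]):
                for i, val in enumerate(arr[c]):
                    recs.append((c, i, name, val))
        return pd.DataFrame(recs, columns=["chain", "iter", "parameter", "value"])


def _run_chain(
    design_arrays, priors: GLMMPriors, n_iter: int, n_burn: int, rng: np.random.Generator
):
    groups, g_idx, C, obs_ids, obs_idx, man_ids, man_idx, y = design_arrays
    n_g = max(len(groups), 1)
    n_u, n_v, n_rows = len(obs_ids), len(man_ids), len(y)

    fixed = np.zeros((n_g, 5))
    u = np.zeros(n_u)
    v = np.zeros(n_v)
    ls_u, ls_v = 0.0, 0.0  # log SDs

    eta = (C * fixed[g_idx]).sum(axis=1) if n_rows else np.zeros(0)
    if n_u:
        eta = eta + u[obs_idx]
    if n_v:
        eta = eta + v[man_idx]
    row_ll = y * eta - np.logaddexp(0.0, eta) if n_rows else np.zeros(0)

    scales_fixed = np.full((n_g, 5), 0.5)
    scale_u = np.full(n_u, 0.5)
    scale_v = np.full(n_v, 0.5)
    scale_ls = np.array([0.5, 0.5])

    acc = {"fixed": [0, 0], "u": [0, 0], "v": [0, 0], "sigma": [0, 0]}
    kept = {
        **{f"{e}[{g}]": np.empty(n_iter - n_burn) for g in (groups or [1]) for e in EFFECTS},
        "sigma_observer": np.empty(n_iter - n_burn),
        "sigma_manipulator": np.empty(n_iter - n_burn),
    }

    def adapt(scale, rate_obs, target, t):
        # Robbins-Monro scale adaptation towards the target acceptance rate
        return scale * np.exp((rate_obs - target) / (t + 1) ** 0.6)

    for it in range(n_iter):
        # fixed effects, one scalar at a time
        for gi in range(n_g):
            rows = g_idx == gi if n_rows else np.zeros(0, dtype=bool)
            for p in range(5):
                step = rng.normal(0.0, scales_fixed[gi, p])
                d_lp = -((fixed[gi, p] + step) ** 2 - fixed[gi, p] ** 2) / (2 * priors.fixed_sd**2)
                if n_rows:
                    d_eta = np.where(rows, step * C[:, p], 0.0)
                    eta_new = eta + d_eta
                    row_ll_new = y * eta_new - np.logaddexp(0.0, eta_new)
                    d_lp += float(row_ll_new.sum() - row_ll.sum())
                accept = np.log(rng.uniform()) < d_lp
                acc["fixed"][1] += 1
                if accept:
                    acc["fixed"][0] += 1
                    fixed[gi, p] += step
                    if n_rows:
                        eta, row_ll = eta_new, row_ll_new
                if it < n_burn:
                    scales_fixed[gi, p] = adapt(scales_fixed[gi, p], float(accept), 0.44, it)

        # observer effects: parallel single-site updates (rows factorise)
        if n_u:
            su = np.exp(ls_u)
            eps = rng.normal(0.0, scale_u)
            eta_new = eta + eps[obs_idx]
            row_ll_new = y * eta_new - np.logaddexp(0.0, eta_new)
            d_ll = np.bincount(obs_idx, weights=row_ll_new - row_ll, minlength=n_u)
            d_prior = -((u + eps) ** 2 - u**2) / (2 * su**2)
            accept = np.log(rng.uniform(size=n_u)) < d_ll + d_prior
            u = np.where(accept, u + eps, u)
            applied = np.where(accept, eps, 0.0)
            eta = eta + applied[obs_idx]
            row_ll = y * eta - np.logaddexp(0.0, eta)
            acc["u"][0] += int(accept.sum())
            acc["u"][1] += n_u
            if it < n_burn:
                scale_u = adapt(scale_u, accept.astype(float), 0.44, it)

        # manipulator effects
        if n_v:
            sv = np.exp(ls_v)
            eps = rng.normal(0.0, scale_v)
            eta_new = eta + eps[man_idx]
            row_ll_new = y * eta_new - np.logaddexp(0.0, eta_new)
            d_ll = np.bincount(man_idx, weights=row_ll_new - row_ll, minlength=n_v)
            d_prior = -((v + eps) ** 2 - v**2) / (2 * sv**2)
            accept = np.log(rng.uniform(size=n_v)) < d_ll + d_prior
            v = np.where(accept, v + eps, v)
            applied = np.where(accept, eps, 0.0)
            eta = eta + applied[man_idx]
            row_ll = y * eta - np.logaddexp(0.0, eta)
            acc["v"][0] += int(accept.sum())
            acc["v"][1] += n_v
            if it < n_burn:
                scale_v = adapt(scale_v, accept.astype(float), 0.44, it)

        # log-SD updates (half-Normal hyperprior, log-scale Jacobian)
        for which in (0, 1):
            ls = ls_u if which == 0 else ls_v
            x = u if which == 0 else v
            step = rng.normal(0.0, scale_ls[which])
            ls_new = ls + step

            def sd_target(lsig: float) -> float:
                sig = np.exp(lsig)
                return (
                    -len(x) * lsig
                    - 0.5 * float(np.sum(x**2)) / sig**2
                    - 0.5 * sig**2 / priors.sd_scale**2
                    + lsig  # Jacobian of the log transform
                )

            accept = np.log(rng.uniform()) < sd_target(ls_new) - sd_target(ls)
            acc["sigma"][1] += 1
            if accept:
                acc["sigma"][0] += 1
                if which == 0:
                    ls_u = ls_new
                else:
                    ls_v = ls_new
            if it < n_burn:
                scale_ls[which] = adapt(scale_ls[which], float(accept), 0.30, it)

        if it >= n_burn:
            j = it - n_burn
            for gi, g in enumerate(groups or [1]):
                for p, e in enumerate(EFFECTS):
                    kept[f"{e}[{g}]"][j] = fixed[gi, p]
            kept["sigma_observer"][j] = np.exp(ls_u)
            kept["sigma_manipulator"][j] = np.exp(ls_v)

    rates = {k: (a / t if t else 0.0) for k, (a, t) in acc.items()}
    return kept, rates


def mcmc_sample(
    design: pd.DataFrame,
    priors: GLMMPriors = GLMMPriors(),
    n_chains: int = 2,
    n_iter: int = 3000,
    n_burn: int = 1000,
    seed: int = 0,
) -> PosteriorSample:
    """Draw a posterior sample with the adaptive Metropolis-within-Gibbs sampler.

    Chains are independent and reproducible: chain c uses a generator
    seeded with (seed, c), so the draws are a pure function of the seed.
    """
    if n_chains < 2:
        raise DomainError("at least 2 chains are required for convergence diagnostics")
    if n_iter - n_burn < 1:
        raise DomainError("n_iter must exceed n_burn")
    arrays = _design_arrays(design)
    groups = arrays[0]
    all_kept: list[dict[str, np.ndarray]] = []
    rates_acc: dict[str, float] = {}
    for c in range(n_chains):
        rng = np.random.default_rng([seed, c])
        kept, rates = _run_chain(arrays, priors, n_iter, n_burn, rng)
        all_kept.append(kept)
        for k, r in rates.items():
            rates_acc[k] = rates_acc.get(k, 0.0) + r / n_chains
    draws = {
        name: np.stack([kept[name] for kept in all_kept]) for name in all_kept[0]
    }
    return PosteriorSample(draws=draws, groups=groups or [1], accept_rates=rates_acc)


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def rhat(sample: PosteriorSample) -> dict[str, float]:
    """Rank-normalised split R-hat per parameter (requires >= 2 chains)."""
    if sample.n_chains < 2:
        raise DomainError("R-hat requires at least 2 chains")
    idata = az.from_dict(posterior={k: v for k, v in sample.draws.items()})
    ds = az.rhat(idata, method="rank")
    return {k: float(ds[k].values) for k in sample.draws}


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing `level` posterior mass (HPD)."""
    arr = np.asarray(draws, dtype=float).reshape(-1)
    lo, hi = az.hdi(arr, hdi_prob=level)
    return float(lo), float(hi)


def odds_ratios_hpd(
    sample: PosteriorSample,
    level: float = 0.95,
    force: bool = False,
    rhat_limit: float = 1.05,
) -> dict:
    """Odds ratios (back-transformed posterior means) with HPD intervals.

    For each non-intercept effect and group: OR = exp(mean of draws), HPD of
    exp(draws); with two groups, additionally the between-group ratio from
    the per-draw coefficient difference. Refuses on R-hat > rhat_limit
    unless forced.
    """
    diags = rhat(sample)
    bad = {k: v for k, v in diags.items() if np.isfinite(v) and v > rhat_limit}
    if bad and not force:
        raise DomainError(f"chains not converged (R-hat > {rhat_limit}): {bad}")
    out: dict = {"rhat": diags, "effects": {}}
    for e in EFFECTS:
        if e == "intercept":
            continue
        per_group = {}
        for g in sample.groups:
            d = sample.stacked(f"{e}[{g}]")
            per_group[str(g)] = {
                "odds_ratio": float(np.exp(np.mean(d))),
                "hpd": list(hpd_interval(np.exp(d), level)),
            }
        entry = {"groups": per_group}
        if len(sample.groups) == 2:
            g1, g2 = sample.groups
            diff = sample.stacked(f"{e}[{g1}]") - sample.stacked(f"{e}[{g2}]")
            entry["group_ratio"] = {
                "odds_ratio": float(np.exp(np.mean(diff))),
                "hpd": list(hpd_interval(np.exp(diff), level)),
            }
        out["effects"][e] = entry
    return out


# ---------------------------------------------------------------------------
# synthetic designs for recovery checks
# ---------------------------------------------------------------------------


def simulate_design(
    n_events: int,
    n_candidates: int,
    truth: dict[str, float],
    seed: int = 0,
    sigma_u: float = 0.5,
    sigma_v: float = 0.5,
    kin_prob: float = 0.2,
    group: int = 1,
) -> pd.DataFrame:
    """Synthetic observation-opportunity table drawn from the GLMM itself.

    ``truth`` maps effect names (EFFECTS) to coefficients; unset effects are
    0. Candidates and manipulators are labelled individuals with random
    covariate differences; y is Bernoulli(logit^-1(eta)).
    """
    rng = np.random.default_rng(seed)
    coef = np.array([truth.get(e, 0.0) for e in EFFECTS])
    cands = [f"C{i}" for i in range(n_candidates)]
    mans = [f"M{i}" for i in range(max(2, n_candidates // 3))]
    u = rng.normal(0.0, sigma_u, size=len(cands))
    v = rng.normal(0.0, sigma_v, size=len(mans))
    rows = []
    prev_watch: set[str] = set()
    for ev in range(n_events):
        m_i = int(rng.integers(len(mans)))
        age_d = rng.normal(0.0, 8.0, size=len(cands))
        rank_d = rng.normal(0.0, 5.0, size=len(cands))
        kin = rng.uniform(size=len(cands)) < kin_prob
        watchers: set[str] = set()
        for ci, cand in enumerate(cands):
            x = np.array([1.0, float(kin[ci]), age_d[ci], rank_d[ci], float(cand in prev_watch)])
            eta = float(x @ coef) + u[ci] + v[m_i]
            yv = int(rng.uniform() < 1.0 / (1.0 + np.exp(-eta)))
            if yv:
                watchers.add(cand)
            rows.append(
                {
                    "event": ev, "group": group, "manipulator": mans[m_i], "observer": cand,
                    "y": yv, "kin": int(kin[ci]), "age_diff": age_d[ci],
                    "rank_diff": rank_d[ci], "prev": int(cand in prev_watch),
                }
            )
        prev_watch = watchers
    return pd.DataFrame(rows)
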