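"""Two-transition (multistate) extension of the diffusion analysis.

Individuals move naive -> interacting (first manipulation of the task) ->
informed (first successful solve). Each transition is modelled with its own
order-of-acquisition likelihood: stage-1 events are first manipulations
conditioned on the naive risk set, stage-2 events are first solves
conditioned on the interacting risk set, and the two stages share no
parameters, so the joint maximum factorises into the two stage-wise
maxima. Exposure for both stages counts observations of successful solves
(the absolute observation network by default).

A solve recorded without a prior manipulation is coerced to both
transitions at the solve instant, with a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import DomainError, EventLog, ILVTable
from .networks import ExposureMatrix, build_network
from .oada import (
    ILV_NAMES,
    DiffusionData,
    FitResult,
    OADAModelSpec,
    fit_oada,
    oada_loglik,
    percent_st,
    percent_st_ci,
    profile_ci_s,
)
from scipy import optimize, stats

__all__ = [
    "StateHistory",
    "build_state_histories",
    "MultistateData",
    "build_multistate_data",
    "multistate_loglik",
    "MultistateFit",
    "fit_multistate",
    "profile_ci_ratio",
    "stage_model_table",
]

_CHI2_1 = stats.chi2(df=1)


@dataclass
class StateHistory:
    """First-transition times of one individual (None = never)."""

    id: str
    t_interact: float | None  # first manipulation
    t_informed: float | None  # first solve
    trained: bool = False
    coerced: bool = False  # solve observed without a prior manipulation record

    def state_at(self, t: float) -> str:
        """State at time t (right-continuous; trained are informed from 0)."""
        if self.trained:
            return "informed"
        if self.t_informed is not None and t >= self.t_informed:
            return "informed"
        if self.t_interact is not None and t >= self.t_interact:
            return "interacting"
        return "naive"


def build_state_histories(log: EventLog, ilv: ILVTable) -> dict[str, StateHistory]:
    """Derive each individual's transition times from the event log."""
    first_manip: dict[str, float] = {}
    for t, i in log.first_manipulations:
        first_manip.setdefault(i, t)
    out: dict[str, StateHistory] = {}
    for ind in ilv.individuals.values():
        if ind.trained:
            out[ind.id] = StateHistory(id=ind.id, t_interact=0.0, t_informed=0.0, trained=True)
            continue
        t_solve = log.first_solve(ind.id)
        t_manip = first_manip.get(ind.id)
        coerced = False
        if t_solve is not None and (t_manip is None or t_manip > t_solve):
            t_manip = t_solve
            coerced = True
        out[ind.id] = StateHistory(
            id=ind.id, t_interact=t_manip, t_informed=t_solve, coerced=coerced
        )
    return out


@dataclass
class MultistateData:
    """Likelihood-ready stage-wise bundles sharing one ILV design."""

    stage1: DiffusionData  # naive -> interacting
    stage2: DiffusionData  # interacting -> informed
    diagnostics: list[str] = field(default_factory=list)


def build_multistate_data(
    log: EventLog, ilv: ILVTable, network_variant: str = "absolute_observation"
) -> MultistateData:
    """Interleave both transition streams and build per-stage exposure data."""
    if network_variant == "group":
        raise DomainError("the static group network is not defined for the multistate model")
    histories = build_state_histories(log, ilv)
    diagnostics = [
        f"solve without prior manipulation coerced for {h.id}"
        for h in histories.values()
        if h.coerced
    ]
    ids = ilv.untrained_ids()
    idx = {i: n for n, i in enumerate(ids)}
    net = build_network(log, ilv, network_variant)

    # globally time-ordered event sequence; manipulation sorts before solve at ties
    events: list[tuple[float, int, str]] = []  # (time, stage, id)
    for h in histories.values():
        if h.trained:
            continue
        if h.t_interact is not None:
            events.append((h.t_interact, 1, h.id))
        if h.t_informed is not None:
            events.append((h.t_informed, 2, h.id))
    events.sort(key=lambda e: (e[0], e[1]))

    naive = set(ids)
    interacting: set[str] = set()
    stage_rows: dict[int, list[tuple[float, str, list[str]]]] = {1: [], 2: []}
    for t, stage, a in events:
        if stage == 1:
            stage_rows[1].append((t, a, sorted(naive, key=idx.get)))
            naive.discard(a)
            interacting.add(a)
        else:
            stage_rows[2].append((t, a, sorted(interacting, key=idx.get)))
            interacting.discard(a)

    def stage_data(rows) -> DiffusionData:
        K = len(rows)
        matrix = np.zeros((K, len(ids)))
        risk = np.zeros((K, len(ids)), dtype=bool)
        acquirer = np.zeros(K, dtype=int)
        times = np.zeros(K)
        for k, (t, a, risk_ids) in enumerate(rows):
            times[k] = t
            acquirer[k] = idx[a]
            for i in risk_ids:
                risk[k, idx[i]] = True
            for i in ids:
                matrix[k, idx[i]] = net.exposure(i, t)
        exp_mat = ExposureMatrix(
            ids=ids, times=times, acquirer=acquirer, matrix=matrix, risk=risk,
            variant=network_variant,
        )
        all_inds = list(ilv.individuals.values())
        age_mean = float(np.mean([a.age for a in all_inds]))
        rank_med = float(np.median([a.rank for a in all_inds]))
        X = np.array(
            [[ilv[i].sex, ilv[i].age - age_mean, ilv[i].rank - rank_med] for i in ids],
            dtype=float,
        )
        groups = np.array([ilv[i].group for i in ids], dtype=int)
        return DiffusionData(
            exposures=exp_mat, groups=groups, group_levels=ilv.groups, X=X, ids=ids
        )

    d1 = stage_data(stage_rows[1])
    d2 = stage_data(stage_rows[2])
    if d1.n_events == 0:
        diagnostics.append("no naive->interacting events; stage 1 contributes 0")
    if d2.n_events == 0:
        diagnostics.append("no interacting->informed events; stage 2 contributes 0")
    return MultistateData(stage1=d1, stage2=d2, diagnostics=diagnostics)


def multistate_loglik(
    theta1, spec1: OADAModelSpec, theta2, spec2: OADAModelSpec, data: MultistateData
) -> float:
    """Sum of the two stage-wise order log-likelihoods (disjoint parameters)."""
    ll = 0.0
    if data.stage1.n_events:
        ll += oada_loglik(theta1, spec1, data.stage1)
    if data.stage2.n_events:
        ll += oada_loglik(theta2, spec2, data.stage2)
    return ll


# ---------------------------------------------------------------------------
# fitting and ratio inference
# ---------------------------------------------------------------------------


@dataclass
class MultistateFit:
    """Stage-wise fits plus the stage-1 between-group ratio inference."""

    fit1: FitResult
    fit2: FitResult
    loglik: float
    ratio_s2_s1: float | None = None  # stage-1 group-2 s over group-1 s
    ratio_ci: tuple[float, float] | None = None
    diagnostics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage1": self.fit1.to_dict(),
            "stage2": self.fit2.to_dict(),
            "loglik": self.loglik,
            "ratio_s2_s1": self.ratio_s2_s1,
            "ratio_ci": list(self.ratio_ci) if self.ratio_ci else None,
            "diagnostics": self.diagnostics,
        }


def profile_ci_ratio(
    fit: FitResult,
    data: DiffusionData,
    level: float = 0.95,
    floor: float = 1e-8,
    ceiling: float = 1e8,
) -> tuple[float, float]:
    """Profile-likelihood CI for the group ratio s2/s1 of an s1 != s2 fit.

    The ratio rho is profiled directly: for each pinned rho the likelihood
    is re-maximised over s1 >= 0 (with s2 = rho * s1) and all coefficients.
    Unreachable thresholds are reported as 0 / +inf.
    """
    spec = fit.spec
    if spec.s_constraint != "s1_ne_s2":
        raise DomainError("ratio CI requires the s1 != s2 hypothesis")
    n_b, n_g = len(spec.ilvs_asocial), len(spec.ilvs_social)
    thresh = _CHI2_1.ppf(level)
    llmax = fit.loglik

    def pll(rho: float) -> float:
        def negll(theta_opt):
            s1 = theta_opt[0]
            full = np.concatenate([[s1, rho * s1], theta_opt[1:]])
            return -oada_loglik(full, spec, data)

        best = None
        for s0 in (0.01, 0.1, 1.0, 10.0):
            x0 = np.concatenate([[s0], np.zeros(n_b + n_g)])
            res = optimize.minimize(
                negll, x0, method="L-BFGS-B",
                bounds=[(0.0, None)] + [(None, None)] * (n_b + n_g),
                options={"ftol": 1e-12, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        return -float(best.fun)

    def deviance(rho: float) -> float:
        return 2.0 * (llmax - pll(rho))

    s1_hat, s2_hat = float(fit.theta[0]), float(fit.theta[1])
    rho_hat = s2_hat / s1_hat if s1_hat > 0 else np.inf
    anchor = rho_hat if np.isfinite(rho_hat) and rho_hat > 0 else 1.0

    lower = 0.0
    rho = anchor
    while rho > floor:
        rho /= 10.0
        if deviance(rho) > thresh:
            lower = float(optimize.brentq(lambda r: deviance(r) - thresh, rho, rho * 10.0))
            break
    upper = np.inf
    rho = anchor
    while rho < ceiling:
        rho *= 10.0
        if deviance(rho) > thresh:
            upper = float(optimize.brentq(lambda r: deviance(r) - thresh, rho / 10.0, rho))
            break
    return (lower, upper)


def fit_multistate(
    data: MultistateData,
    spec1: OADAModelSpec | None = None,
    spec2: OADAModelSpec | None = None,
    level: float = 0.95,
    with_ratio: bool = True,
) -> MultistateFit:
    """Fit both transitions and, for a stage-1 group contrast, the s2/s1 ratio.

    Defaults: stage 1 with group-specific s (s1 != s2), stage 2 with a
    common s, both on the absolute observation network without ILVs.
    """
    two_groups = len(data.stage1.group_levels) == 2
    spec1 = spec1 or OADAModelSpec(s_constraint="s1_ne_s2" if two_groups else "s1_eq_s2")
    spec2 = spec2 or OADAModelSpec(s_constraint="s1_eq_s2")
    diagnostics: list[str] = list(data.diagnostics)

    def stage_fit(spec: OADAModelSpec, d: DiffusionData) -> FitResult:
        fit = fit_oada(spec, d)
        if spec.n_free_s and d.n_events:
            for w in range(spec.n_free_s):
                ci = profile_ci_s(fit, d, which=w, level=level)
                fit.profile_ci[f"s[{w}]"] = ci
            fit.percent_st = percent_st(fit, data=d)
            fit.percent_st_interval = percent_st_ci(fit, d, fit.profile_ci["s[0]"], which=0)
        return fit

    fit1 = stage_fit(spec1, data.stage1)
    fit2 = stage_fit(spec2, data.stage2)
    ms = MultistateFit(
        fit1=fit1, fit2=fit2, loglik=fit1.loglik + fit2.loglik, diagnostics=diagnostics
    )
    if with_ratio and spec1.s_constraint == "s1_ne_s2" and data.stage1.n_events:
        s1, s2 = float(fit1.theta[0]), float(fit1.theta[1])
        ms.ratio_s2_s1 = s2 / s1 if s1 > 0 else float("inf")
        if s1 == 0:
            ms.diagnostics.append("stage-1 group-1 s estimated at 0; ratio unbounded")
        ms.ratio_ci = profile_ci_ratio(fit1, data.stage1, level=level)
    return ms


def stage_model_table(stage_data: DiffusionData, ilvs=ILV_NAMES, scheme: str = "joint"):
    """AICc model table for one transition, absolute network fixed."""
    from .model_selection import enumerate_model_set, fit_model_set

    specs = enumerate_model_set(
        networks=("absolute_observation",), ilvs=ilvs, scheme=scheme,
        include_group_network=False, include_asocial=True,
    )
    return fit_model_set(specs, {"absolute_observation": stage_data})
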