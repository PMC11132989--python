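"""Order-of-acquisition diffusion analysis (OADA).

The model: immediately before acquisition event k, every untrained
still-naive individual i has relative acquisition rate

    r_k(i) = s_{g(i)} * E_k(i) * exp(gamma' x_i) + exp(beta' x_i)

where E_k(i) is i's network exposure just before the event, g(i) its group,
x_i its (centred) individual-level variables, beta the asocial and gamma
the social ILV coefficients. The shared baseline time-hazard cancels, so
only the acquisition *order* matters and each event contributes

    log r_k(a_k) - log sum_{i in R_k} r_k(i)

with a_k the acquirer and R_k the naive risk set. The social-transmission
strength s is the rate of learning per unit connection to informed
individuals relative to the asocial baseline rate; with the ILV centring
used here (sex as coded, age at its sample mean, rank at its sample
median) the baseline individual is a female of average age and middle
rank, so s reads directly as a rate multiplier per unit exposure.

Inference: bounded quasi-Newton maximisation with a multi-start schedule
in s, profile-likelihood confidence intervals for s (upper bound reported
as +inf when the profile deviance never reaches the chi-square threshold
below a search ceiling), and conversion of a fit into %ST — the estimated
percentage of acquisition events attributable to social transmission.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data_model import DomainError, EventLog, ILVTable, UndefinedResultError
from .networks import ExposureMatrix, build_network, exposure_at_events

__all__ = [
    "ILV_NAMES",
    "S_CONSTRAINTS",
    "OADAModelSpec",
    "DiffusionData",
    "build_diffusion_data",
    "oada_loglik",
    "FitResult",
    "fit_oada",
    "profile_ci_s",
    "percent_st",
    "percent_st_ci",
    "relative_rate",
    "uniform_order_loglik",
]

ILV_NAMES = ("sex", "age", "rank")
S_CONSTRAINTS = ("s1_ne_s2", "s1_eq_s2", "s1_zero", "s2_zero", "asocial")

_CHI2_1 = stats.chi2(df=1)
S_MULTISTARTS = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class OADAModelSpec:
    """One candidate model: network x s-constraint x ILV inclusion pattern."""

    network_variant: str = "absolute_observation"
    s_constraint: str = "s1_eq_s2"
    ilvs_asocial: tuple[str, ...] = ()
    ilvs_social: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.s_constraint not in S_CONSTRAINTS:
            raise DomainError(f"unknown s constraint {self.s_constraint!r}")
        for name in (*self.ilvs_asocial, *self.ilvs_social):
            if name not in ILV_NAMES:
                raise DomainError(f"unknown ILV {name!r}")
        if self.s_constraint == "asocial" and self.ilvs_social:
            raise DomainError("asocial models carry no social (gamma) coefficients")
        if self.network_variant == "group" and self.s_constraint not in ("s1_eq_s2", "asocial"):
            raise DomainError("the static group network is only fitted with s1 = s2")

    @property
    def n_free_s(self) -> int:
        return {"s1_ne_s2": 2, "s1_eq_s2": 1, "s1_zero": 1, "s2_zero": 1, "asocial": 0}[
            self.s_constraint
        ]

    @property
    def n_params(self) -> int:
        return self.n_free_s + len(self.ilvs_asocial) + len(self.ilvs_social)

    def label(self) -> str:
        a = "+".join(self.ilvs_asocial) or "none"
        g = "+".join(self.ilvs_social) or "none"
        return f"{self.network_variant}|{self.s_constraint}|asoc:{a}|soc:{g}"


@dataclass
class DiffusionData:
    """Likelihood-ready bundle: exposures, risk sets and centred ILVs."""

    exposures: ExposureMatrix
    groups: np.ndarray  # (N,) int group labels of untrained individuals
    group_levels: list[int]
    X: np.ndarray  # (N, 3) centred ILV matrix, columns = ILV_NAMES
    ids: list[str]

    @property
    def n_events(self) -> int:
        return self.exposures.n_events

    def ilv_columns(self, names: tuple[str, ...]) -> np.ndarray:
        cols = [ILV_NAMES.index(n) for n in names]
        return self.X[:, cols]


def build_diffusion_data(log: EventLog, ilv: ILVTable, network_variant: str) -> DiffusionData:
    """Derive exposures, risk sets and the centred ILV design from raw data.

    Centring: sex enters as coded (0 female / 1 male); age is centred at the
    sample mean and rank at the sample median, over all individuals, so the
    reference individual with exp(beta'x) = exp(gamma'x) = 1 is a female of
    average age and middle rank.
    """
    net = build_network(log, ilv, network_variant)
    exp_mat = exposure_at_events(net, log, ilv)
    ids = exp_mat.ids
    all_inds = list(ilv.individuals.values())
    age_mean = float(np.mean([a.age for a in all_inds]))
    rank_med = float(np.median([a.rank for a in all_inds]))
    X = np.array(
        [[ilv[i].sex, ilv[i].age - age_mean, ilv[i].rank - rank_med] for i in ids], dtype=float
    )
    groups = np.array([ilv[i].group for i in ids], dtype=int)
    return DiffusionData(
        exposures=exp_mat, groups=groups, group_levels=ilv.groups, X=X, ids=ids
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _s_vector(spec: OADAModelSpec, s_free: np.ndarray, group_levels: list[int]) -> np.ndarray:
    """Map free s parameters onto the per-group s vector (length = n groups)."""
    n_g = len(group_levels)
    if spec.s_constraint == "asocial":
        return np.zeros(n_g)
    if spec.s_constraint == "s1_eq_s2":
        return np.full(n_g, s_free[0])
    if n_g != 2:
        raise DomainError(f"{spec.s_constraint} requires exactly 2 groups, found {n_g}")
    if spec.s_constraint == "s1_ne_s2":
        return np.array([s_free[0], s_free[1]])
    if spec.s_constraint == "s1_zero":
        return np.array([0.0, s_free[0]])
    return np.array([s_free[0], 0.0])  # s2_zero


def _rates(
    spec: OADAModelSpec,
    s_free: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    data: DiffusionData,
) -> np.ndarray:
    """(K, N) matrix of relative rates r_k(i)."""
    if np.any(s_free < 0):
        raise DomainError("s must be non-negative")
    s_by_group = _s_vector(spec, s_free, data.group_levels)
    gidx = np.searchsorted(np.array(data.group_levels), data.groups)
    s_i = s_by_group[gidx]  # (N,)
    asocial = np.exp(data.ilv_columns(spec.ilvs_asocial) @ beta) if len(beta) else np.ones(len(data.ids))
    social_mult = (
        np.exp(data.ilv_columns(spec.ilvs_social) @ gamma) if len(gamma) else np.ones(len(data.ids))
    )
    return s_i * social_mult * data.exposures.matrix + asocial[None, :]


def oada_loglik(
    theta: np.ndarray | list[float],
    spec: OADAModelSpec,
    data: DiffusionData,
) -> float:
    """Order-of-acquisition log partial likelihood at parameter vector theta.

    ``theta`` concatenates the free s parameters (order: s1 then s2 where
    both are free), the asocial coefficients beta and the social
    coefficients gamma, in the order declared on the model specification.
    """
    theta = np.asarray(theta, dtype=float)
    n_s = spec.n_free_s
    n_b = len(spec.ilvs_asocial)
    s_free = theta[:n_s]
    beta = theta[n_s : n_s + n_b]
    gamma = theta[n_s + n_b :]
    r = _rates(spec, s_free, beta, gamma, data)
    risk = data.exposures.risk
    if not risk.any(axis=1).all():
        raise UndefinedResultError("empty risk set at an acquisition event")
    num = r[np.arange(data.n_events), data.exposures.acquirer]
    den = np.where(risk, r, 0.0).sum(axis=1)
    if np.any(num <= 0):
        return -np.inf
    return float(np.sum(np.log(num) - np.log(den)))


def uniform_order_loglik(data: DiffusionData) -> float:
    """Null log-likelihood when all rates are equal: sum_k log(1 / |R_k|)."""
    sizes = data.exposures.risk.sum(axis=1)
    return float(-np.sum(np.log(sizes)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model."""

    spec: OADAModelSpec
    theta: np.ndarray
    s_by_group: np.ndarray
    beta: dict[str, float]
    gamma: dict[str, float]
    loglik: float
    n_params: int
    n_events: int
    aicc: float
    converged: bool
    profile_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    percent_st: float | None = None
    percent_st_interval: tuple[float, float] | None = None
    diagnostics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "network": self.spec.network_variant,
                "s_constraint": self.spec.s_constraint,
                "ilvs_asocial": list(self.spec.ilvs_asocial),
                "ilvs_social": list(self.spec.ilvs_social),
            },
            "s_by_group": list(map(float, self.s_by_group)),
            "beta": self.beta,
            "gamma": self.gamma,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_events": self.n_events,
            "aicc": self.aicc,
            "converged": self.converged,
            "profile_ci": {k: [v[0], v[1]] for k, v in self.profile_ci.items()},
            "percent_st": self.percent_st,
            "percent_st_interval": list(self.percent_st_interval)
            if self.percent_st_interval
            else None,
            "percent_st_method": "event-wise attribution",
            "diagnostics": self.diagnostics,
        }


def _maximize(
    spec: OADAModelSpec,
    data: DiffusionData,
    fixed_s: dict[int, float] | None = None,
    s_starts: tuple[float, ...] = S_MULTISTARTS,
) -> tuple[np.ndarray, float, bool]:
    """Maximize the log-likelihood; optionally pin some free-s entries.

    Returns (theta_full, loglik, converged) where theta_full includes the
    pinned entries at their fixed values.
    """
    n_s, n_b, n_g = spec.n_free_s, len(spec.ilvs_asocial), len(spec.ilvs_social)
    fixed_s = fixed_s or {}
    free_s_idx = [i for i in range(n_s) if i not in fixed_s]

    def pack_full(theta_opt: np.ndarray) -> np.ndarray:
        full = np.empty(n_s + n_b + n_g)
        for i, v in fixed_s.items():
            full[i] = v
        full[free_s_idx] = theta_opt[: len(free_s_idx)]
        full[n_s:] = theta_opt[len(free_s_idx) :]
        return full

    def negll(theta_opt: np.ndarray) -> float:
        return -oada_loglik(pack_full(theta_opt), spec, data)

    n_opt = len(free_s_idx) + n_b + n_g
    if n_opt == 0:
        theta = pack_full(np.empty(0))
        return theta, oada_loglik(theta, spec, data), True

    bounds = [(0.0, None)] * len(free_s_idx) + [(None, None)] * (n_b + n_g)
    best = None
    starts = s_starts if free_s_idx else (0.0,)
    for s0 in starts:
        x0 = np.concatenate([np.full(len(free_s_idx), s0), np.zeros(n_b + n_g)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                negll, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
            )
        if best is None or res.fun < best.fun - 0.0:
            best = res
    assert best is not None
    return pack_full(best.x), -float(best.fun), bool(best.success)


def fit_oada(spec: OADAModelSpec, data: DiffusionData) -> FitResult:
    """Fit one candidate model by maximum likelihood (multi-start in s)."""
    from .model_selection import aicc  # local import: model_selection imports this module

    theta, ll, converged = _maximize(spec, data)
    n_s = spec.n_free_s
    n_b = len(spec.ilvs_asocial)
    s_by_group = _s_vector(spec, theta[:n_s], data.group_levels)
    beta = dict(zip(spec.ilvs_asocial, map(float, theta[n_s : n_s + n_b])))
    gamma = dict(zip(spec.ilvs_social, map(float, theta[n_s + n_b :])))
    K = data.n_events
    try:
        aicc_val = aicc(ll, spec.n_params, K)
    except DomainError:
        aicc_val = float("nan")  # too few events for the correction; ranking undefined
    fit = FitResult(
        spec=spec, theta=theta, s_by_group=s_by_group, beta=beta, gamma=gamma,
        loglik=ll, n_params=spec.n_params, n_events=K,
        aicc=aicc_val, converged=converged,
    )
    if not converged:
        fit.diagnostics.append("optimizer did not report convergence")
    blocks = data.exposures.tied_blocks()
    if blocks:
        fit.diagnostics.append(f"tied acquisition times broken by log order: events {blocks}")
    return fit


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


def _profile_loglik(spec: OADAModelSpec, data: DiffusionData, which: int, s_value: float) -> float:
    """Max log-likelihood with the which-th free s pinned at s_value."""
    _, ll, _ = _maximize(spec, data, fixed_s={which: s_value})
    return ll


def profile_ci_s(
    fit: FitResult,
    data: DiffusionData,
    which: int = 0,
    level: float = 0.95,
    ceiling_factor: float = 1e6,
) -> tuple[float, float]:
    """Profile-likelihood CI for one free s parameter.

    Bounds solve 2*(llmax - profile(s)) = chi2_1 quantile, re-optimising all
    other parameters at each pinned s. The upper bound is reported as +inf
    when the profile deviance stays below the threshold up to the search
    ceiling (ceiling_factor x the estimate, or ceiling_factor when the
    estimate is 0).
    """
    spec = fit.spec
    if spec.n_free_s == 0:
        raise DomainError("asocial model has no s parameter to profile")
    thresh = _CHI2_1.ppf(level)
    llmax = fit.loglik
    s_hat = float(fit.theta[which])

    def deviance(s: float) -> float:
        return 2.0 * (llmax - _profile_loglik(spec, data, which, s))

    # lower bound
    d0 = deviance(0.0)
    if d0 <= thresh + 1e-9:
        lower = 0.0
    else:
        lo = max(s_hat, 1e-8)
        lower = float(optimize.brentq(lambda s: deviance(s) - thresh, 1e-12, lo, xtol=1e-8, rtol=1e-8))
    # upper bound
    ceiling = ceiling_factor * s_hat if s_hat > 0 else ceiling_factor
    s_hi = max(s_hat * 2, 1.0)
    upper = np.inf
    prev = max(s_hat, 1e-8)
    while s_hi <= ceiling:
        if deviance(s_hi) > thresh:
            upper = float(
                optimize.brentq(lambda s: deviance(s) - thresh, prev, s_hi, xtol=1e-8, rtol=1e-8)
            )
            break
        prev = s_hi
        s_hi *= 10.0
    return (lower, upper)


# ---------------------------------------------------------------------------
# %ST and derived report quantities
# ---------------------------------------------------------------------------


def _social_fractions(theta: np.ndarray, spec: OADAModelSpec, data: DiffusionData) -> np.ndarray:
    """Per-event fraction of the acquirer's rate due to social transmission."""
    n_s, n_b = spec.n_free_s, len(spec.ilvs_asocial)
    s_free, beta, gamma = theta[:n_s], theta[n_s : n_s + n_b], theta[n_s + n_b :]
    r = _rates(spec, s_free, beta, gamma, data)
    asocial = (
        np.exp(data.ilv_columns(spec.ilvs_asocial) @ beta) if n_b else np.ones(len(data.ids))
    )
    k_idx = np.arange(data.n_events)
    a = data.exposures.acquirer
    total = r[k_idx, a]
    return (total - asocial[a]) / total


def percent_st(fit_or_theta, spec: OADAModelSpec | None = None, data: DiffusionData | None = None) -> float:
    """Estimated percentage of acquisition events due to social transmission.

    Event-wise attribution: the mean over acquisition events of the social
    share of the acquirer's rate, times 100.
    """
    if isinstance(fit_or_theta, FitResult):
        theta, spec = fit_or_theta.theta, fit_or_theta.spec
    else:
        theta = np.asarray(fit_or_theta, dtype=float)
        assert spec is not None
    assert data is not None
    if data.n_events == 0:
        raise UndefinedResultError("no acquisition events; %ST undefined")
    return float(100.0 * np.mean(_social_fractions(theta, spec, data)))


def percent_st_ci(
    fit: FitResult, data: DiffusionData, s_interval: tuple[float, float], which: int = 0
) -> tuple[float, float]:
    """%ST evaluated at the s profile bounds with nuisance re-optimisation.

    An infinite upper s bound is handled in the limit: events whose acquirer
    has positive exposure (in a group with free s) become fully social.
    """
    spec = fit.spec
    lo_s, hi_s = s_interval
    theta_lo, _, _ = _maximize(spec, data, fixed_s={which: lo_s})
    lo = percent_st(theta_lo, spec, data)
    if np.isinf(hi_s):
        # limit s -> inf with other parameters finite
        s_free = np.zeros(spec.n_free_s)
        s_free[which] = 1.0
        s_by_group = _s_vector(spec, s_free, data.group_levels)
        gidx = np.searchsorted(np.array(data.group_levels), data.groups)
        social_possible = (s_by_group[gidx] > 0)[data.exposures.acquirer] & (
            data.exposures.matrix[np.arange(data.n_events), data.exposures.acquirer] > 0
        )
        hi = float(100.0 * np.mean(social_possible))
    else:
        theta_hi, _, _ = _maximize(spec, data, fixed_s={which: hi_s})
        hi = percent_st(theta_hi, spec, data)
    return (min(lo, hi), max(lo, hi))


def relative_rate(s: float, n_observations: int) -> float:
    """Rate multiplier 1 + n*s for a baseline individual after n observed solves.

    Applies to the absolute-observation network, whose exposure equals the
    number of solves watched.
    """
    if s < 0 or n_observations < 0:
        raise DomainError("s and n_observations must be non-negative")
    return 1.0 + n_observations * s
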