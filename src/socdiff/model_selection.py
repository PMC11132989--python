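"""Multi-model inference over the candidate OADA model sets.

Candidate models are enumerated as network variant x transmission
hypothesis x ILV inclusion pattern, fitted by maximum likelihood, ranked by
AICc (sample size = number of acquisition events) and aggregated with
Akaike weights. Support for a hypothesis or a network is the summed weight
of its models within the compared set; because the asocial set is much
smaller than the social sets, evidence against purely asocial learning is
assessed with the profile-likelihood CI for s rather than by total weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .data_model import DomainError
from .oada import ILV_NAMES, DiffusionData, FitResult, OADAModelSpec, fit_oada

__all__ = [
    "aicc",
    "akaike_weights",
    "enumerate_model_set",
    "ModelTable",
    "fit_model_set",
    "total_support",
    "support_ratio",
    "model_average",
]

SOCIAL_HYPOTHESES = ("s1_ne_s2", "s1_eq_s2", "s2_zero", "s1_zero")
OBSERVATION_NETWORKS = ("absolute_observation", "individuals_observed", "single_observation")


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction.

    n is the number of independent likelihood contributions (acquisition
    events); requires n > k + 1 for the correction term to be defined.
    """
    if n <= k + 1:
        raise DomainError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """Akaike weights exp(-delta/2) normalised over the compared set."""
    aiccs = np.asarray(list(aiccs), dtype=float)
    if aiccs.size == 0:
        raise DomainError("cannot compute Akaike weights of an empty model set")
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def enumerate_model_set(
    networks=OBSERVATION_NETWORKS,
    hypotheses=SOCIAL_HYPOTHESES,
    ilvs: tuple[str, ...] = ILV_NAMES,
    scheme: str = "joint",
    include_group_network: bool = True,
    include_asocial: bool = True,
) -> list[OADAModelSpec]:
    """Deterministic, duplicate-free list of candidate model specs.

    ILV enumeration schemes:

    * ``"joint"`` (default): each ILV is in or out of the model as a whole,
      entering both the asocial and the social rate when in (2^m patterns);
    * ``"independent"``: each ILV independently in/out of the asocial and
      the social rate (4^m patterns).

    The static group network is only combined with the s1 = s2 hypothesis;
    asocial models carry no social coefficients.
    """
    if scheme not in ("joint", "independent"):
        raise DomainError(f"unknown ILV enumeration scheme {scheme!r}")

    def patterns():
        if scheme == "joint":
            for mask in product((False, True), repeat=len(ilvs)):
                included = tuple(v for v, m in zip(ilvs, mask) if m)
                yield included, included
        else:
            for amask, gmask in product(
                product((False, True), repeat=len(ilvs)), repeat=2
            ):
                yield (
                    tuple(v for v, m in zip(ilvs, amask) if m),
                    tuple(v for v, m in zip(ilvs, gmask) if m),
                )

    specs: list[OADAModelSpec] = []
    for net in networks:
        for hyp in hypotheses:
            for asoc, soc in patterns():
                specs.append(
                    OADAModelSpec(
                        network_variant=net, s_constraint=hyp,
                        ilvs_asocial=asoc, ilvs_social=soc,
                    )
                )
    if include_group_network:
        for asoc, soc in patterns():
            specs.append(
                OADAModelSpec(
                    network_variant="group", s_constraint="s1_eq_s2",
                    ilvs_asocial=asoc, ilvs_social=soc,
                )
            )
    if include_asocial:
        seen_asoc = set()
        for asoc, _ in patterns():
            if asoc not in seen_asoc:
                seen_asoc.add(asoc)
                specs.append(
                    OADAModelSpec(
                        network_variant="absolute_observation", s_constraint="asocial",
                        ilvs_asocial=asoc, ilvs_social=(),
                    )
                )
    assert len(set(specs)) == len(specs)
    return specs


@dataclass
class ModelTable:
    """Fitted candidate set with AICc ranking and Akaike weights."""

    fits: list[FitResult]
    table: pd.DataFrame  # one row per fit: spec fields, loglik, aicc, delta, weight

    @classmethod
    def from_fits(cls, fits: list[FitResult]) -> "ModelTable":
        aiccs = np.array([f.aicc for f in fits])
        weights = akaike_weights(aiccs)
        rows = []
        for f, w in zip(fits, weights):
            rows.append(
                {
                    "network": f.spec.network_variant,
                    "hypothesis": f.spec.s_constraint,
                    "ilvs_asocial": "+".join(f.spec.ilvs_asocial),
                    "ilvs_social": "+".join(f.spec.ilvs_social),
                    "n_params": f.n_params,
                    "loglik": f.loglik,
                    "aicc": f.aicc,
                    "delta_aicc": f.aicc - aiccs.min(),
                    "akaike_weight": w,
                    "converged": f.converged,
                }
            )
        df = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
        return cls(fits=fits, table=df)

    def best(self) -> FitResult:
        return min(self.fits, key=lambda f: f.aicc)


def fit_model_set(specs: list[OADAModelSpec], data_by_network: dict[str, DiffusionData]) -> ModelTable:
    """Fit every spec against the diffusion data for its network variant."""
    fits = [fit_oada(spec, data_by_network[spec.network_variant]) for spec in specs]
    return ModelTable.from_fits(fits)


def total_support(table: ModelTable | pd.DataFrame, by: str) -> dict[str, float]:
    """Summed Akaike weight per category, as percentages over the table's rows.

    ``by`` is "hypothesis" or "network". Weights are renormalised within the
    rows passed in, so shares always sum to 100 over the compared set.
    """
    df = table.table if isinstance(table, ModelTable) else table
    if by not in ("hypothesis", "network"):
        raise DomainError(f"unknown support grouping {by!r}")
    w = df["akaike_weight"].to_numpy()
    shares = df.groupby(by)["akaike_weight"].sum() / w.sum() * 100.0
    return {str(k): float(v) for k, v in shares.items()}


def support_ratio(table: ModelTable | pd.DataFrame, column: str, cat_a: str, cat_b: str) -> float:
    """Ratio of summed Akaike weights between two categories of a column."""
    df = table.table if isinstance(table, ModelTable) else table
    wa = float(df.loc[df[column] == cat_a, "akaike_weight"].sum())
    wb = float(df.loc[df[column] == cat_b, "akaike_weight"].sum())
    if wa == 0 and wb == 0:
        raise DomainError(f"no weight in either category {cat_a!r}, {cat_b!r}")
    if wb == 0:
        return float("inf")
    return wa / wb


def model_average(table: ModelTable, quantity: str = "s", group: int | None = None) -> float:
    """Akaike-weight-averaged estimate across the table's models.

    ``quantity`` is "s" (optionally for one group label) or the name of an
    ILV coefficient prefixed "beta:" / "gamma:". Models in which the
    parameter is fixed to 0 (or absent by constraint) contribute 0.
    """
    weights = akaike_weights([f.aicc for f in table.fits])
    vals = []
    for f in table.fits:
        if quantity == "s":
            if group is None:
                vals.append(float(np.mean(f.s_by_group)))
            else:
                vals.append(float(f.s_by_group[group - 1]))
        elif quantity.startswith("beta:"):
            vals.append(f.beta.get(quantity[5:], 0.0))
        elif quantity.startswith("gamma:"):
            vals.append(f.gamma.get(quantity[6:], 0.0))
        else:
            raise DomainError(f"unknown quantity {quantity!r}")
    return float(np.dot(weights, vals))
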