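"""Dynamic observation networks and exposure pre-computation.

Four connection structures can drive the diffusion model:

* ``absolute_observation`` — connection(i, j, t) is the number of times i
  has watched j solve the task strictly before t; exposure is the total
  count of solves watched.
* ``individuals_observed`` — connection is the 0/1 indicator that i has
  watched j solve at least once; exposure counts distinct solvers watched.
* ``single_observation`` — exposure is the 0/1 indicator that i has watched
  at least one solve by anyone.
* ``group`` — static same-group network; exposure is the number of informed
  same-group individuals.

The boundary convention everywhere is *strictly before t*: an observation
time-stamped exactly at an acquisition instant does not contribute to that
acquisition's exposure. Trained demonstrators are informed from t = 0 and
never appear in any risk set.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DomainError, EventLog, ILVTable

__all__ = [
    "VARIANTS",
    "DynamicNetwork",
    "build_network",
    "acquisition_events",
    "ExposureMatrix",
    "exposure_at_events",
]

VARIANTS = ("absolute_observation", "individuals_observed", "single_observation", "group")


class DynamicNetwork:
    """Queryable connection/exposure structure for one network variant."""

    def __init__(self, log: EventLog, ilv: ILVTable, variant: str):
        if variant not in VARIANTS:
            raise DomainError(f"unknown network variant {variant!r}")
        self.variant = variant
        self.ilv = ilv
        self.log = log
        # observation times keyed by observer then solver, sorted
        self._pair_times: dict[str, dict[str, list[float]]] = {}
        # all observation times per observer, sorted
        self._obs_times: dict[str, list[float]] = {}
        for t, o, s in log.observations:
            self._pair_times.setdefault(o, {}).setdefault(s, []).append(t)
            self._obs_times.setdefault(o, []).append(t)
        for d in self._pair_times.values():
            for v in d.values():
                v.sort()
        for v in self._obs_times.values():
            v.sort()
        # first solve per individual (informed-from time); trained informed at 0
        self._first_solve: dict[str, float] = {}
        for ind_id in ilv.trained_ids():
            self._first_solve[ind_id] = 0.0
        for t, s in log.solves:
            if s not in self._first_solve:
                self._first_solve[s] = t

    # -- connection ---------------------------------------------------------

    def connection(self, i: str, j: str, t: float) -> float:
        """Edge weight from observer i to solver j just before time t."""
        if i == j:
            return 0.0
        if self.variant == "group":
            return 1.0 if self.ilv[i].group == self.ilv[j].group else 0.0
        times = self._pair_times.get(i, {}).get(j, [])
        count = bisect_left(times, t)  # observations strictly before t
        if self.variant == "absolute_observation":
            return float(count)
        return 1.0 if count > 0 else 0.0  # individuals_observed / single_observation

    # -- exposure -----------------------------------------------------------

    def exposure(self, i: str, t: float) -> float:
        """Total connection of i to informed individuals just before t."""
        if self.variant == "absolute_observation":
            times = self._obs_times.get(i, [])
            return float(bisect_left(times, t))
        if self.variant == "individuals_observed":
            per_solver = self._pair_times.get(i, {})
            return float(sum(1 for times in per_solver.values() if bisect_left(times, t) > 0))
        if self.variant == "single_observation":
            times = self._obs_times.get(i, [])
            return 1.0 if bisect_left(times, t) > 0 else 0.0
        # group: informed same-group individuals strictly before t
        g = self.ilv[i].group
        return float(
            sum(
                1
                for j, ft in self._first_solve.items()
                if j != i and ft < t and self.ilv[j].group == g
            )
        )


def build_network(log: EventLog, ilv: ILVTable, variant: str) -> DynamicNetwork:
    """Construct the requested dynamic (or static group) network."""
    return DynamicNetwork(log, ilv, variant)


def network_to_frame(net: DynamicNetwork, times: list[float]) -> pd.DataFrame:
    """Long-format dump (t, i, j, weight) of non-zero edges at the given times."""
    rows = []
    ids = net.ilv.ids
    for t in times:
        for i in ids:
            for j in ids:
                w = net.connection(i, j, t)
                if w:
                    rows.append((t, i, j, w))
    return pd.DataFrame(rows, columns=["t", "i", "j", "weight"])


# ---------------------------------------------------------------------------
# acquisition events and exposure matrices
# ---------------------------------------------------------------------------


def acquisition_events(log: EventLog, ilv: ILVTable) -> list[tuple[float, str]]:
    """First solves of untrained individuals, in diffusion order.

    Ties in time keep event-log order (stable); trained demonstrators are
    informed at t = 0 and contribute no acquisition event.
    """
    seen: set[str] = set(ilv.trained_ids())
    events = []
    for t, s in log.solves:
        if s not in seen:
            events.append((t, s))
            seen.add(s)
    return events


@dataclass
class ExposureMatrix:
    """Exposures of every untrained individual immediately before each event.

    ``matrix[k, i]`` is the exposure of individual ``ids[i]`` just before
    acquisition event k; ``risk[k, i]`` marks membership of the naive risk
    set at that instant; ``acquirer[k]`` indexes the acquiring individual.
    """

    ids: list[str]
    times: np.ndarray  # (K,)
    acquirer: np.ndarray  # (K,) int indices into ids
    matrix: np.ndarray  # (K, N)
    risk: np.ndarray  # (K, N) bool
    variant: str

    @property
    def n_events(self) -> int:
        return len(self.times)

    def tied_blocks(self) -> list[list[int]]:
        """Indices of events sharing a timestamp (order broken by log order)."""
        blocks: list[list[int]] = []
        k = 0
        while k < self.n_events:
            j = k
            while j + 1 < self.n_events and self.times[j + 1] == self.times[k]:
                j += 1
            if j > k:
                blocks.append(list(range(k, j + 1)))
            k = j + 1
        return blocks


def exposure_at_events(net: DynamicNetwork, log: EventLog, ilv: ILVTable | None = None) -> ExposureMatrix:
    """Pre-compute the exposure and risk-set structure the likelihood needs.

    The informed-status vector is updated after each event, so for the group
    network (and only there) exposures change with the event *sequence*, not
    just with clock time: the k-th row counts demonstrators plus the k-1
    earlier acquirers.
    """
    ilv = ilv or net.ilv
    events = acquisition_events(log, ilv)
    ids = ilv.untrained_ids()
    idx = {i: n for n, i in enumerate(ids)}
    K, N = len(events), len(ids)
    matrix = np.zeros((K, N))
    risk = np.zeros((K, N), dtype=bool)
    acquirer = np.zeros(K, dtype=int)
    times = np.array([t for t, _ in events])

    informed: set[str] = set(ilv.trained_ids())  # sequence-based informed status
    still_naive = set(ids)
    for k, (t, a) in enumerate(events):
        acquirer[k] = idx[a]
        for i in still_naive:
            risk[k, idx[i]] = True
        if net.variant == "group":
            for i in ids:
                g = ilv[i].group
                matrix[k, idx[i]] = sum(1 for j in informed if j != i and ilv[j].group == g)
        else:
            for i in ids:
                matrix[k, idx[i]] = net.exposure(i, t)
        informed.add(a)
        still_naive.discard(a)
    return ExposureMatrix(ids=ids, times=times, acquirer=acquirer, matrix=matrix, risk=risk, variant=net.variant)
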