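"""Data structures for open-diffusion social-learning experiments.

An experiment is described by two tables:

* an *event log* of time-stamped solve events (an individual successfully
  operates the task), observation events (an individual watches a solver at
  the moment of a solve) and first-manipulation events (an individual first
  touches the task), all on a cumulative experimental-time axis in hours
  from the start of the social-learning phase;
* an *individual-level-variable (ILV) table* giving, per individual, group
  membership, sex (0 female / 1 male), age in years, an ordinal-averaged
  rank score and a trained-demonstrator flag, plus a symmetric set of
  maternal-kin pairs.

This module loads and validates both, and computes the per-individual
observation summaries (count of observations before the relevant solve,
observation time, rate of observation, solve count) that the study reports.
A transcription of the published per-individual summary table ships as a
packaged fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DataFormatError",
    "UnknownIdentifierError",
    "DomainError",
    "UndefinedResultError",
    "Individual",
    "ILVTable",
    "EventLog",
    "IndividualSummary",
    "load_event_log",
    "write_event_log",
    "load_ilv_table",
    "summarize_individuals",
    "count_learners",
    "min_observations_among_learners",
    "baseline_exposure_hours",
    "load_table1",
    "table1_summaries",
    "format_rate",
]


class DataFormatError(ValueError):
    """A file or table violates the declared column/row format."""


class UnknownIdentifierError(ValueError):
    """An event or kin pair references an individual that does not exist."""


class DomainError(ValueError):
    """An argument is outside the mathematically valid domain."""


class UndefinedResultError(ValueError):
    """The requested quantity is undefined for the given data (e.g. no learners)."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Individual:
    """One study subject with its individual-level variables."""

    id: str
    group: int
    sex: int  # 0 female, 1 male
    age: float  # years
    rank: float  # ordinal-averaged score
    trained: bool = False


class ILVTable:
    """Collection of :class:`Individual` plus a symmetric kin relation."""

    def __init__(self, individuals: Iterable[Individual], kin_pairs: Iterable[tuple[str, str]] = ()):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise DataFormatError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self.kin: set[frozenset[str]] = set()
        for a, b in kin_pairs:
            for x in (a, b):
                if x not in self.individuals:
                    raise UnknownIdentifierError(f"kin pair references unknown id {x!r}")
            if a == b:
                raise DataFormatError(f"kin pair with identical ids {a!r}")
            self.kin.add(frozenset((a, b)))

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.individuals

    @property
    def ids(self) -> list[str]:
        return list(self.individuals)

    @property
    def groups(self) -> list[int]:
        return sorted({ind.group for ind in self.individuals.values()})

    def is_kin(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.kin

    def untrained_ids(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if not ind.trained]

    def trained_ids(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.trained]


@dataclass
class EventLog:
    """Time-ordered solve / observation / first-manipulation streams.

    Times are hours from the start of the social phase; each stream is kept
    sorted by time with a stable sort, so events that share a timestamp keep
    their input order.
    """

    solves: list[tuple[float, str]] = field(default_factory=list)
    observations: list[tuple[float, str, str]] = field(default_factory=list)  # (t, observer, solver)
    first_manipulations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.solves = sorted(self.solves, key=lambda e: e[0])
        self.observations = sorted(self.observations, key=lambda e: e[0])
        self.first_manipulations = sorted(self.first_manipulations, key=lambda e: e[0])

    def validate(self, ilv: ILVTable | None = None) -> None:
        solve_keys = {(t, s) for t, s in self.solves}
        for t, obs, solver in self.observations:
            if obs == solver:
                raise UnknownIdentifierError(
                    f"observer {obs!r} recorded as observing their own solve at t={t}"
                )
            if (t, solver) not in solve_keys:
                raise DataFormatError(
                    f"observation of {solver!r} at t={t} has no matching solve event"
                )
        if ilv is not None:
            for t, s in self.solves:
                if s not in ilv:
                    raise UnknownIdentifierError(f"unknown solver id {s!r}")
            for t, o, s in self.observations:
                if o not in ilv:
                    raise UnknownIdentifierError(f"unknown observer id {o!r}")
            for t, i in self.first_manipulations:
                if i not in ilv:
                    raise UnknownIdentifierError(f"unknown manipulator id {i!r}")

    def first_solve(self, ind_id: str) -> float | None:
        for t, s in self.solves:
            if s == ind_id:
                return t
        return None

    def n_solves(self, ind_id: str) -> int:
        return sum(1 for _, s in self.solves if s == ind_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, s in self.solves:
            rows.append(("social", t, "solve", s, ""))
        for t, o, s in self.observations:
            rows.append(("social", t, "observe", o, s))
        for t, i in self.first_manipulations:
            rows.append(("social", t, "first_manipulation", i, ""))
        df = pd.DataFrame(rows, columns=["phase", "time_h", "event_type", "actor_id", "target_id"])
        return df.sort_values("time_h", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["phase", "time_h", "event_type", "actor_id", "target_id"]


def load_event_log(path: str | Path, ilv: ILVTable | None = None) -> EventLog:
    """Read an events.csv file into a validated :class:`EventLog`.

    Expected columns: phase, time_h, event_type in {solve, observe,
    first_manipulation}, actor_id, target_id (solver id for observe rows,
    empty otherwise).
    """
    df = pd.read_csv(path, dtype={"actor_id": str, "target_id": str}, keep_default_na=False)
    for col in _EVENT_COLUMNS:
        if col not in df.columns:
            raise DataFormatError(f"events file missing required column {col!r}")
    solves, observations, manips = [], [], []
    for row in df.itertuples(index=False):
        t = float(row.time_h)
        kind = row.event_type
        if kind == "solve":
            solves.append((t, row.actor_id))
        elif kind == "observe":
            if not row.target_id:
                raise DataFormatError("observe row with empty target_id")
            observations.append((t, row.actor_id, row.target_id))
        elif kind == "first_manipulation":
            manips.append((t, row.actor_id))
        else:
            raise DataFormatError(f"unknown event_type {kind!r}")
    log = EventLog(solves=solves, observations=observations, first_manipulations=manips)
    log.validate(ilv)
    return log


def write_event_log(log: EventLog, path: str | Path) -> None:
    log.to_frame().to_csv(path, index=False)


def load_ilv_table(ilv_path: str | Path, kin_path: str | Path | None = None) -> ILVTable:
    """Read ilv.csv (id, group, sex, age_years, rank, trained) and optional kin.csv."""
    df = pd.read_csv(ilv_path, dtype={"id": str})
    required = ["id", "group", "sex", "age_years", "rank", "trained"]
    for col in required:
        if col not in df.columns:
            raise DataFormatError(f"ILV file missing required column {col!r}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise DataFormatError(f"duplicate individual id {dup!r}")
    individuals = [
        Individual(
            id=r.id,
            group=int(r.group),
            sex=int(r.sex),
            age=float(r.age_years),
            rank=float(r.rank),
            trained=bool(int(r.trained)),
        )
        for r in df.itertuples(index=False)
    ]
    kin_pairs: list[tuple[str, str]] = []
    if kin_path is not None:
        kdf = pd.read_csv(kin_path, dtype=str)
        for col in ("id_a", "id_b"):
            if col not in kdf.columns:
                raise DataFormatError(f"kin file missing required column {col!r}")
        kin_pairs = [(r.id_a, r.id_b) for r in kdf.itertuples(index=False)]
    return ILVTable(individuals, kin_pairs)


def write_ilv_table(ilv: ILVTable, ilv_path: str | Path, kin_path: str | Path | None = None) -> None:
    rows = [
        (ind.id, ind.group, ind.sex, ind.age, ind.rank, int(ind.trained))
        for ind in ilv.individuals.values()
    ]
    pd.DataFrame(rows, columns=["id", "group", "sex", "age_years", "rank", "trained"]).to_csv(
        ilv_path, index=False
    )
    if kin_path is not None:
        krows = [tuple(sorted(p)) for p in sorted(ilv.kin, key=lambda p: tuple(sorted(p)))]
        pd.DataFrame(krows, columns=["id_a", "id_b"]).to_csv(kin_path, index=False)


# ---------------------------------------------------------------------------
# per-individual summaries (published-table semantics)
# ---------------------------------------------------------------------------


@dataclass
class IndividualSummary:
    """Observation record of one individual, published-table style.

    ``n_observations_pre`` counts observations before the individual's own
    first solve (learners) or up to the group's final solve (non-learners);
    ``observation_time`` is the corresponding window length in hours.
    Trained demonstrators carry ``None`` in the observation fields.
    """

    id: str
    group: int
    trained: bool
    n_observations_pre: int | None
    acquired: int | None
    observation_time: float | None
    rate_of_observation: float | None
    n_solves: int


def format_rate(rate: float | None, decimals: int = 2) -> float | None:
    """Round a rate for report output (half-even, internal values stay unrounded)."""
    if rate is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(rate)).quantize(q, rounding=ROUND_HALF_EVEN))


def summarize_individuals(log: EventLog, ilv: ILVTable) -> dict[str, IndividualSummary]:
    """Per-individual observation counts, windows, rates and solve counts.

    Learners (untrained with >=1 solve): observations strictly before their
    own first solve. Non-learners: observations up to and including the
    final solve event in their group. Individuals absent from the log get a
    zero count over the full window.
    """
    last_solve_by_group: dict[int, float] = {}
    for t, s in log.solves:
        g = ilv[s].group
        last_solve_by_group[g] = max(last_solve_by_group.get(g, 0.0), t)

    obs_times: dict[str, list[float]] = {}
    for t, o, _s in log.observations:
        obs_times.setdefault(o, []).append(t)

    out: dict[str, IndividualSummary] = {}
    for ind in ilv.individuals.values():
        n_solves = log.n_solves(ind.id)
        if ind.trained:
            out[ind.id] = IndividualSummary(
                id=ind.id, group=ind.group, trained=True,
                n_observations_pre=None, acquired=None,
                observation_time=None, rate_of_observation=None,
                n_solves=n_solves,
            )
            continue
        first = log.first_solve(ind.id)
        times = obs_times.get(ind.id, [])
        if first is not None:
            window = first
            n_pre = sum(1 for t in times if t < first)  # strictly before own first solve
            acquired = 1
        else:
            window = last_solve_by_group.get(ind.group, 0.0)
            n_pre = sum(1 for t in times if t <= window)  # inclusive at the closing solve
            acquired = 0
        rate = n_pre / window if window > 0 else 0.0
        out[ind.id] = IndividualSummary(
            id=ind.id, group=ind.group, trained=False,
            n_observations_pre=n_pre, acquired=acquired,
            observation_time=window, rate_of_observation=rate,
            n_solves=n_solves,
        )
    return out


def count_learners(summaries: Mapping[str, IndividualSummary] | Iterable[IndividualSummary]) -> int:
    """Number of untrained individuals that acquired the skill."""
    vals = summaries.values() if isinstance(summaries, Mapping) else summaries
    return sum(1 for s in vals if not s.trained and s.acquired == 1)


def min_observations_among_learners(
    summaries: Mapping[str, IndividualSummary] | Iterable[IndividualSummary],
) -> int:
    """Minimum pre-acquisition observation count over untrained learners."""
    vals = summaries.values() if isinstance(summaries, Mapping) else summaries
    counts = [s.n_observations_pre for s in vals if not s.trained and s.acquired == 1]
    if not counts:
        raise UndefinedResultError("no learners in the study; minimum undefined")
    return min(c for c in counts if c is not None)


def baseline_exposure_hours(months: int, days_per_month: int, hours_per_day: float, n_groups: int) -> float:
    """Total baseline exposure: months x days/month x hours/day x groups."""
    for name, v in (
        ("months", months), ("days_per_month", days_per_month),
        ("hours_per_day", hours_per_day), ("n_groups", n_groups),
    ):
        if v <= 0:
            raise DomainError(f"{name} must be positive, got {v}")
    return months * days_per_month * hours_per_day * n_groups


# ---------------------------------------------------------------------------
# packaged fixture: published per-individual summary table
# ---------------------------------------------------------------------------


def load_table1() -> pd.DataFrame:
    """Load the packaged transcription of the published observation-record table."""
    with resources.files("socdiff.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def table1_summaries() -> dict[str, IndividualSummary]:
    """The published table as :class:`IndividualSummary` records.

    The published rate column is a rounded report value; the summaries carry
    the unrounded ratio n_observations / observation_time instead, so report
    rounding is applied exactly once (by the caller, via :func:`format_rate`).
    """
    df = load_table1()
    out: dict[str, IndividualSummary] = {}
    for r in df.itertuples(index=False):
        trained = bool(r.trained)
        if trained or (isinstance(r.n_observations, float) and math.isnan(r.n_observations)):
            out[r.chimpanzee] = IndividualSummary(
                id=r.chimpanzee, group=int(r.group), trained=trained,
                n_observations_pre=None, acquired=None,
                observation_time=None, rate_of_observation=None,
                n_solves=int(r.n_solves),
            )
            continue
        n_obs = int(r.n_observations)
        window = float(r.observation_time_h)
        rate = n_obs / window if window > 0 else 0.0
        out[r.chimpanzee] = IndividualSummary(
            id=r.chimpanzee, group=int(r.group), trained=False,
            n_observations_pre=n_obs, acquired=int(r.acquired),
            observation_time=window, rate_of_observation=rate,
            n_solves=int(r.n_solves),
        )
    return out
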