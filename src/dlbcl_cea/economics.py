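"""Discounted cost / QALY / life-year accumulation and incremental analysis.

Rewards follow the usual cohort-model conventions: each cycle contributes
``occupancy x reward x cycle length`` (half-cycle corrected by averaging the
occupancy at the cycle's two boundaries), discounted at an annual rate
compounded per cycle.  One-time costs (transplant, CAR-T infusion, adverse
events) are booked at state entry and discounted at the entry cycle.

All monetary amounts are 2022 Canadian dollars.  ``CURRENCY_NOTE`` records
the source conversion used by the underlying cost inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import ALIVE_STATES, DEAD, S_IDX, CohortTrace
from .transitions import ConfigurationError, CycleSchedule

CURRENCY = "CAD"
CURRENCY_NOTE = "2022 CAD; source unit costs quoted at CAD 1 = USD 0.78"


@dataclass
class CostTable:
    """Per-state per-cycle costs plus one-time state-entry costs (2022 CAD).

    ``per_cycle`` must cover every alive state; ``one_time`` entries are
    charged once on arrival in the state.  ``ae_cost`` is the one-time cost of
    front-line adverse events (febrile neutropenia, nausea/vomiting), applied
    in expectation at treatment start.
    """

    per_cycle: dict[str, float]
    one_time: dict[str, float] = field(default_factory=dict)
    ae_cost: float = 0.0

    def validate(self) -> None:
        missing = [s for s in ALIVE_STATES if s not in self.per_cycle]
        if missing:
            raise ConfigurationError(f"cost table missing state(s): {missing}")
        bad = {k: v for k, v in {**self.per_cycle, **self.one_time}.items() if v < 0}
        if bad or self.ae_cost < 0:
            raise ConfigurationError(f"negative cost entries: {bad or self.ae_cost}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"state": s, "cost_per_cycle": self.per_cycle[s],
             "one_time_cost": self.one_time.get(s, 0.0)}
            for s in ALIVE_STATES
        ]
        rows.append({"state": "adverse_event", "cost_per_cycle": 0.0,
                     "one_time_cost": self.ae_cost})
        return pd.DataFrame(rows)


@dataclass
class UtilityTable:
    """Per-state utilities on the 0 (death) to 1 (perfect health) scale.

    ``ae_decrement`` is the one-cycle utility loss applied, in expectation,
    to patients experiencing front-line adverse events.
    """

    utility: dict[str, float]
    ae_decrement: float = 0.0

    def validate(self) -> None:
        missing = [s for s in ALIVE_STATES if s not in self.utility]
        if missing:
            raise ConfigurationError(f"utility table missing state(s): {missing}")
        bad = {s: u for s, u in self.utility.items() if not 0.0 <= u <= 1.0}
        if bad:
            raise ConfigurationError(f"utilities outside [0, 1]: {bad}")
        if self.utility.get(DEAD, 0.0) != 0.0:
            raise ConfigurationError("dead state utility must be 0")
        if self.ae_decrement < 0:
            raise ConfigurationError("ae_decrement must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"state": s, "utility": self.utility[s]} for s in ALIVE_STATES]
            + [{"state": "ae_decrement", "utility": self.ae_decrement}]
        )


def discount_factor(cycle, annual_rate: float, schedule: CycleSchedule):
    """(1 + r)^(-t) with t in years at the start of ``cycle``; 1 at cycle 0."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    t_years = np.asarray(cycle, dtype=float) * schedule.cycle_years
    out = (1.0 + annual_rate) ** (-t_years)
    return float(out) if np.ndim(cycle) == 0 else out


@dataclass(frozen=True)
class RewardLoadings:
    """Linear coefficients mapping unit rewards to discounted totals.

    For a fixed trace, QALYs are linear in the state utilities and costs are
    linear in the cost entries.  ``time_years[s]`` converts a unit utility in
    state ``s`` to discounted QALYs; ``cycles_disc[s]`` converts a per-cycle
    cost; ``entries_disc[s]`` converts a one-time entry cost; ``ae_exposure``
    is the expected adverse-event mass at treatment start (discount 1).
    Exposing the loadings keeps accumulation and calibration numerically
    identical by construction.
    """

    time_years: dict[str, float]
    cycles_disc: dict[str, float]
    entries_disc: dict[str, float]
    ae_exposure: float
    cycle_years: float


def reward_loadings(
    trace: CohortTrace, annual_rate: float, half_cycle: bool = True
) -> RewardLoadings:
    sched = trace.schedule
    n = sched.n_cycles
    disc = discount_factor(np.arange(n), annual_rate, sched)
    disc_b = discount_factor(np.arange(n + 1), annual_rate, sched)
    occ = trace.occupancy
    occ_c = 0.5 * (occ[:, :-1] + occ[:, 1:]) if half_cycle else occ[:, :-1]
    time_years = {}
    cycles_disc = {}
    entries_disc = {}
    for s, i in S_IDX.items():
        w = float((occ_c[i] * disc).sum())
        time_years[s] = w * sched.cycle_years
        cycles_disc[s] = w
        entries_disc[s] = float((trace.entries[i] * disc_b).sum())
    return RewardLoadings(
        time_years=time_years,
        cycles_disc=cycles_disc,
        entries_disc=entries_disc,
        ae_exposure=trace.ae_probability,
        cycle_years=sched.cycle_years,
    )


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one strategy."""

    strategy: str
    cost: float
    qaly: float
    ly: float


def accumulate(
    trace: CohortTrace,
    costs: CostTable,
    utilities: UtilityTable,
    annual_rate: float,
    half_cycle: bool = True,
) -> StrategyOutcome:
    """Discounted (cost, QALY, LY) for one strategy's trace.

    QALY = sum over cycles of discount x occupancy x utility x cycle length
    (half-cycle corrected); LY is the same with utility 1 in every alive
    state.  Costs add per-cycle state costs, one-time entry costs, and the
    expected adverse-event cost at treatment start.  The adverse-event
    utility decrement is applied for one cycle at treatment start.
    """
    costs.validate()
    utilities.validate()
    lo = reward_loadings(trace, annual_rate, half_cycle)
    ly = sum(lo.time_years[s] for s in ALIVE_STATES)
    qaly = sum(utilities.utility[s] * lo.time_years[s] for s in ALIVE_STATES)
    qaly -= lo.ae_exposure * utilities.ae_decrement * lo.cycle_years
    cost = sum(costs.per_cycle[s] * lo.cycles_disc[s] for s in ALIVE_STATES)
    cost += sum(costs.one_time.get(s, 0.0) * lo.entries_disc[s] for s in ALIVE_STATES)
    cost += lo.ae_exposure * costs.ae_cost
    return StrategyOutcome(strategy=trace.strategy, cost=cost, qaly=qaly, ly=ly)


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = WTP x QALY - cost, in CAD."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return wtp * qaly - cost


UNDOMINATED = "undominated"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


@dataclass
class CEEntry:
    name: str
    cost: float
    qaly: float
    status: str = UNDOMINATED
    icer: float | None = None  # vs previous frontier strategy; None for cheapest
    tie: bool = False


@dataclass
class CEResult:
    """Efficiency frontier with dominance statuses and pairwise ICERs."""

    entries: list[CEEntry]
    frontier: list[str]

    def entry(self, name: str) -> CEEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def icer_of(self, name: str) -> float | None:
        return self.entry(name).icer

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"strategy": e.name, "cost": e.cost, "qaly": e.qaly,
                 "status": e.status, "icer": e.icer, "tie": e.tie}
                for e in self.entries
            ]
        )


def _as_entries(results) -> list[CEEntry]:
    entries = []
    for r in results:
        if isinstance(r, StrategyOutcome):
            entries.append(CEEntry(r.strategy, r.cost, r.qaly))
        elif isinstance(r, CEEntry):
            entries.append(CEEntry(r.name, r.cost, r.qaly))
        else:
            name, cost, qaly = r
            entries.append(CEEntry(name, float(cost), float(qaly)))
    return entries


def compute_icer(results) -> CEResult:
    """Dominance-aware incremental cost-effectiveness analysis.

    Strategies are sorted by cost; strictly dominated ones (at least as
    costly and no more effective than some alternative) are flagged, extended
    dominance removes strategies less efficient than a blend of neighbors,
    and ICERs are reported between consecutive frontier strategies.  A
    strategy with identical cost and QALY to a frontier member is flagged as
    a tie (ICER 0 by convention).  Undefined ratios are reported as
    dominance, never as numbers.  The result is invariant to input order.
    """
    entries = _as_entries(results)
    if len(entries) < 2:
        raise ValueError("need at least two strategies")
    order = sorted(entries, key=lambda e: (e.cost, -e.qaly, e.name))

    for e in order:
        for o in order:
            if o is e:
                continue
            if (
                o.cost <= e.cost
                and o.qaly >= e.qaly
                and (o.cost < e.cost or o.qaly > e.qaly)
            ):
                e.status = DOMINATED
                break

    candidates = [e for e in order if e.status != DOMINATED]
    stack: list[CEEntry] = []
    for e in candidates:
        if stack and e.cost == stack[-1].cost and e.qaly == stack[-1].qaly:
            e.tie = True
            e.icer = 0.0
            continue
        while stack:
            dq = e.qaly - stack[-1].qaly
            dc = e.cost - stack[-1].cost
            # dq > 0 here: equal-or-lower QALY at higher cost is strict dominance.
            icer = dc / dq
            if len(stack) >= 2 and icer <= stack[-1].icer:
                stack[-1].status = EXTENDED_DOMINATED
                stack[-1].icer = None
                stack.pop()
                continue
            e.icer = icer
            break
        stack.append(e)

    return CEResult(entries=order, frontier=[e.name for e in stack])


def summary_frame(
    outcomes: list[StrategyOutcome],
    ce: CEResult,
    sds: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Human-readable per-strategy summary (LY, QALY, cost, ICER columns)."""
    rows = []
    for o in sorted(outcomes, key=lambda o: o.cost):
        e = ce.entry(o.strategy)
        row = {
            "strategy": o.strategy,
            "ly": o.ly,
            "qaly": o.qaly,
            f"cost_{CURRENCY.lower()}": o.cost,
            "status": e.status,
            "icer": e.icer if not math.isnan(e.icer or 0.0) else None,
        }
        if sds and o.strategy in sds:
            for k, v in sds[o.strategy].items():
                row[f"sd_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
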