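"""Strategy state graphs and the deterministic cohort simulation.

Two treatment strategies are modeled for newly diagnosed ABC-type DLBCL in
patients 60 or younger: R-CHOP chemoimmunotherapy alone, and R-CHOP with
front-line ibrutinib (I-RCHOP).  Both share the same downstream pathway:

    front_line -> disease_free -> (relapse) salvage GDP chemotherapy
        responders      -> autologous stem-cell transplant -> remission
        non-responders  -> CAR-T therapy or palliative care
    palliative care lasts exactly two cycles (six months) and ends in death.

Front-line event-free and overall survival are Weibull curves in model time;
per-cycle death comes from the OS curve, per-cycle events from the EFS curve,
and relapse is the excess of events over deaths (clamped at zero).  Salvage,
CAR-T and the post-treatment remission states run Weibull or point hazards on
a time-in-state clock, because each source fit starts at that state's entry.
Background mortality from a life table acts on every alive state as a
competing hazard (hazards add: within a cycle the survival fractions
multiply).  After five years of sustained remission the relapse hazard
plateaus at zero.

The simulation is a semi-Markov cohort: occupancy is tracked per (state,
time-in-state) so tunnel states (front line, CAR-T delivery, palliation) can
force exits after a fixed number of cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transitions import (
    ConfigurationError,
    CycleSchedule,
    TransitionSpec,
    apply_plateau,
    per_cycle_prob,
    point_prob_to_cycle,
)

logger = logging.getLogger(__name__)

# State names, in trace order.
FRONT_LINE = "front_line"
DISEASE_FREE = "disease_free"
SALVAGE_GDP = "salvage_gdp"
AUTO_SCT = "auto_sct"
POST_SCT_DF = "post_sct_disease_free"
CAR_T = "car_t"
POST_CART_DF = "post_cart_disease_free"
PALLIATIVE = "palliative"
DEAD = "dead"

STATES: list[str] = [
    FRONT_LINE,
    DISEASE_FREE,
    SALVAGE_GDP,
    AUTO_SCT,
    POST_SCT_DF,
    CAR_T,
    POST_CART_DF,
    PALLIATIVE,
    DEAD,
]
S_IDX = {name: i for i, name in enumerate(STATES)}
ALIVE_STATES: list[str] = STATES[:-1]
N_STATES = len(STATES)


@dataclass(frozen=True)
class HealthState:
    name: str
    is_absorbing: bool = False
    is_tunnel: bool = False
    tags: frozenset = field(default_factory=frozenset)


class NumericalError(RuntimeError):
    """NaN or conservation failure during the cohort recursion."""


_ARM_KEYS = {"I-RCHOP": "irchop", "RCHOP": "rchop", "irchop": "irchop", "rchop": "rchop"}

_SHARED_ROWS = [
    "os_gdp",
    "pfs_gdp",
    "salvage_response",
    "sct_to_cart",
    "sct_to_df",
    "sct_to_relapse",
    "relapse_to_palliation",
    "df_to_persistent",
    "os_cart",
    "pfs_cart",
    "cart_df_death",
    "cart_df_relapse",
]


@dataclass
class StrategyModel:
    """One arm's state graph plus references into the parameter table.

    ``mortality_mode`` selects how disease-specific death is attributed:

    * ``"pathway"`` (default): each pathway state carries the death hazard
      of its own source fit (GDP OS in salvage, CAR-T OS during CAR-T
      delivery, the post-CAR-T death probability in that remission state),
      on a time-in-state clock -- literal per-state sourcing.
    * ``"os_anchored"``: the arm's intention-to-treat OS curve drives
      disease death in every non-palliative alive state (it was fit on the
      whole randomized cohort, so it already contains deaths occurring
      after relapse); the salvage-pathway fits then only shape movement
      through the pathway, avoiding double counting at the price of using
      a front-line curve in downstream states.
    """

    name: str
    arm_key: str
    states: list[HealthState]
    transitions: dict[str, TransitionSpec]
    ae_probability: float
    front_line_cycles: int = 2
    car_t_cycles: int = 2
    palliative_cycles: int = 2
    mortality_mode: str = "pathway"

    def state(self, name: str) -> HealthState:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)


def build_strategy(
    arm: str,
    params: dict[str, TransitionSpec],
    schedule: CycleSchedule,
    mortality_mode: str = "pathway",
) -> StrategyModel:
    """Wire one arm's state graph from the parameter table.

    Raises :class:`ConfigurationError` naming any missing parameter row.
    """
    if arm not in _ARM_KEYS:
        raise ConfigurationError(f"unknown arm {arm!r}; expected I-RCHOP or RCHOP")
    if mortality_mode not in ("os_anchored", "pathway"):
        raise ConfigurationError(f"unknown mortality_mode {mortality_mode!r}")
    key = _ARM_KEYS[arm]
    required = [f"os_{key}", f"efs_{key}", f"ae_{key}", *_SHARED_ROWS]
    missing = [r for r in required if r not in params]
    if missing:
        raise ConfigurationError(f"missing parameter row(s) for arm {arm}: {missing}")

    states = [
        HealthState(FRONT_LINE, is_tunnel=True, tags=frozenset({"front_line"})),
        HealthState(DISEASE_FREE, tags=frozenset({"disease_free"})),
        HealthState(SALVAGE_GDP, tags=frozenset({"salvage"})),
        HealthState(AUTO_SCT, tags=frozenset({"auto_sct"})),
        HealthState(POST_SCT_DF, tags=frozenset({"disease_free"})),
        HealthState(CAR_T, is_tunnel=True, tags=frozenset({"car_t"})),
        HealthState(POST_CART_DF, tags=frozenset({"disease_free"})),
        HealthState(PALLIATIVE, is_tunnel=True, tags=frozenset({"palliative"})),
        HealthState(DEAD, is_absorbing=True, tags=frozenset({"dead"})),
    ]
    return StrategyModel(
        name="I-RCHOP" if key == "irchop" else "RCHOP",
        arm_key=key,
        states=states,
        transitions=params,
        ae_probability=params[f"ae_{key}"].point.value,
        mortality_mode=mortality_mode,
    )


@dataclass
class _Precomputed:
    """Per-cycle / per-age transition probabilities for one model run."""

    mode: str  # mortality mode, see StrategyModel
    p_death_fl: np.ndarray  # model-time disease death (OS curve)
    p_relapse_fl: np.ndarray  # model-time relapse (EFS excess, plateau applied)
    p_death_sv: np.ndarray  # by age-in-state
    p_prog_sv: np.ndarray
    p_resp: float
    w_cart: float  # CAR-T weight among progressors / relapsers (raw 0.201)
    w_pall: float  # palliation weight (raw 0.393); residual keeps progressing
    p_sct_df: float
    p_sct_rel: float
    p_rel_ps: np.ndarray  # post-SCT remission relapse by age (plateau applied)
    w_cart_df: float  # renormalized CAR-T share for relapse out of remission
    w_pall_df: float
    p_death_ct: np.ndarray
    p_prog_ct: np.ndarray
    p_death_pc: float
    p_rel_pc: np.ndarray  # post-CAR-T remission relapse by age (plateau applied)
    q_bg: np.ndarray  # background mortality per cycle (model time)


def _precompute(
    model: StrategyModel,
    schedule: CycleSchedule,
    life_table,
    start_age: float,
) -> _Precomputed:
    tr = model.transitions
    n = schedule.n_cycles
    cycles = np.arange(n)
    ages = np.arange(n + 1)

    p_os = per_cycle_prob(tr[f"os_{model.arm_key}"].weibull, cycles, schedule)
    p_efs = per_cycle_prob(tr[f"efs_{model.arm_key}"].weibull, cycles, schedule)
    if np.any(p_efs < p_os - 1e-12):
        logger.warning(
            "%s: OS event probability exceeds EFS in %d cycle(s); "
            "relapse clamped to 0 there",
            model.name,
            int(np.sum(p_efs < p_os - 1e-12)),
        )
    p_rel = np.clip(p_efs - p_os, 0.0, 1.0)
    p_rel = apply_plateau(p_rel, cycles, schedule, is_relapse_hazard=True)

    p_death_sv = per_cycle_prob(tr["os_gdp"].weibull, ages, schedule)
    p_prog_sv = np.clip(
        per_cycle_prob(tr["pfs_gdp"].weibull, ages, schedule) - p_death_sv, 0.0, 1.0
    )

    w_cart = tr["sct_to_cart"].point.value
    w_pall = tr["relapse_to_palliation"].point.value
    if w_cart + w_pall > 1.0:
        raise ConfigurationError("CAR-T and palliation shares exceed 1")
    p_sct_df = point_prob_to_cycle(tr["sct_to_df"].point, schedule)
    p_sct_rel = point_prob_to_cycle(tr["sct_to_relapse"].point, schedule)
    if p_sct_df + p_sct_rel > 1.0:
        raise ConfigurationError(
            "transplant branch probabilities (disease-free + relapse) exceed 1"
        )
    # Relapse out of a remission state cannot stay put: the printed share
    # (0.393) goes to palliation and the complement proceeds to CAR-T.
    # Progression inside a treatment state keeps its residual share in
    # continued progression (the 0.201 / 0.393 split applied directly).
    w_cart_df = 1.0 - w_pall
    w_pall_df = w_pall

    p_rel_ps = np.full(
        n + 1, point_prob_to_cycle(tr["df_to_persistent"].point, schedule)
    )
    p_rel_ps = apply_plateau(p_rel_ps, ages, schedule, is_relapse_hazard=True)

    p_death_ct = per_cycle_prob(tr["os_cart"].weibull, ages, schedule)
    p_prog_ct = np.clip(
        per_cycle_prob(tr["pfs_cart"].weibull, ages, schedule) - p_death_ct, 0.0, 1.0
    )

    p_rel_pc = per_cycle_prob(tr["cart_df_relapse"].weibull, ages, schedule)
    p_rel_pc = apply_plateau(p_rel_pc, ages, schedule, is_relapse_hazard=True)

    if life_table is None:
        q_bg = np.zeros(n)
    else:
        mid_ages = start_age + cycles * schedule.cycle_years
        q_bg = life_table.cycle_prob(mid_ages, schedule.cycle_years)

    return _Precomputed(
        mode=model.mortality_mode,
        p_death_fl=p_os,
        p_relapse_fl=p_rel,
        p_death_sv=p_death_sv,
        p_prog_sv=p_prog_sv,
        p_resp=point_prob_to_cycle(tr["salvage_response"].point, schedule),
        w_cart=w_cart,
        w_pall=w_pall,
        p_sct_df=p_sct_df,
        p_sct_rel=p_sct_rel,
        p_rel_ps=p_rel_ps,
        w_cart_df=w_cart_df,
        w_pall_df=w_pall_df,
        p_death_ct=p_death_ct,
        p_prog_ct=p_prog_ct,
        p_death_pc=point_prob_to_cycle(tr["cart_df_death"].point, schedule),
        p_rel_pc=p_rel_pc,
        q_bg=q_bg,
    )


def _outflows(
    pre: _Precomputed, state_idx: int, cycle: int, ages: np.ndarray
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Outflow probabilities from one state for each time-in-state age.

    Background mortality is applied first within the cycle; survivors then
    face the disease-specific transitions, so combined death equals
    ``1 - (1 - q_bg)(1 - p_disease)`` -- additive hazards for competing
    exponential risks.  Returns (target -> probability array, stay array).
    """
    q = pre.q_bg[cycle]
    ones = np.ones_like(ages, dtype=float)
    out: dict[int, np.ndarray] = {}

    if state_idx in (S_IDX[FRONT_LINE], S_IDX[DISEASE_FREE]):
        pd_ = pre.p_death_fl[cycle]
        pr = pre.p_relapse_fl[cycle]
        out[S_IDX[DEAD]] = (q + (1.0 - q) * pd_) * ones
        out[S_IDX[SALVAGE_GDP]] = (1.0 - q) * pr * ones
    elif state_idx == S_IDX[SALVAGE_GDP]:
        if pre.mode == "os_anchored":
            pd_ = pre.p_death_fl[cycle] * ones
        else:
            pd_ = pre.p_death_sv[ages]
        alive = (1.0 - q) * (1.0 - pd_)
        prog = alive * (1.0 - pre.p_resp) * pre.p_prog_sv[ages]
        out[S_IDX[DEAD]] = q + (1.0 - q) * pd_
        out[S_IDX[AUTO_SCT]] = alive * pre.p_resp
        out[S_IDX[CAR_T]] = prog * pre.w_cart
        out[S_IDX[PALLIATIVE]] = prog * pre.w_pall
    elif state_idx == S_IDX[AUTO_SCT]:
        pd_ = pre.p_death_fl[cycle] if pre.mode == "os_anchored" else 0.0
        rel = (1.0 - q) * (1.0 - pd_) * pre.p_sct_rel
        out[S_IDX[DEAD]] = (q + (1.0 - q) * pd_) * ones
        out[S_IDX[POST_SCT_DF]] = (1.0 - q) * (1.0 - pd_) * pre.p_sct_df * ones
        out[S_IDX[CAR_T]] = rel * pre.w_cart * ones
        out[S_IDX[PALLIATIVE]] = rel * pre.w_pall * ones
    elif state_idx == S_IDX[POST_SCT_DF]:
        pd_ = pre.p_death_fl[cycle] if pre.mode == "os_anchored" else 0.0
        rel = (1.0 - q) * (1.0 - pd_) * pre.p_rel_ps[ages]
        out[S_IDX[DEAD]] = (q + (1.0 - q) * pd_) * ones
        out[S_IDX[CAR_T]] = rel * pre.w_cart_df
        out[S_IDX[PALLIATIVE]] = rel * pre.w_pall_df
    elif state_idx == S_IDX[CAR_T]:
        if pre.mode == "os_anchored":
            pd_ = pre.p_death_fl[cycle] * ones
        else:
            pd_ = pre.p_death_ct[ages]
        out[S_IDX[DEAD]] = q + (1.0 - q) * pd_
        out[S_IDX[PALLIATIVE]] = (1.0 - q) * (1.0 - pd_) * pre.p_prog_ct[ages]
    elif state_idx == S_IDX[POST_CART_DF]:
        dd = pre.p_death_pc
        out[S_IDX[DEAD]] = (q + (1.0 - q) * dd) * ones
        out[S_IDX[PALLIATIVE]] = (1.0 - q) * (1.0 - dd) * pre.p_rel_pc[ages]
    elif state_idx == S_IDX[PALLIATIVE]:
        out[S_IDX[DEAD]] = q * ones
    elif state_idx == S_IDX[DEAD]:
        return {}, ones
    else:  # pragma: no cover
        raise KeyError(state_idx)

    stay = ones.copy()
    for p in out.values():
        stay = stay - p
    return out, np.clip(stay, 0.0, 1.0)


def _forced_exits(model: StrategyModel) -> dict[int, tuple[int, int]]:
    """Tunnel rules: state -> (max cycles in state, forced destination)."""
    return {
        S_IDX[FRONT_LINE]: (model.front_line_cycles, S_IDX[DISEASE_FREE]),
        S_IDX[CAR_T]: (model.car_t_cycles, S_IDX[POST_CART_DF]),
        S_IDX[PALLIATIVE]: (model.palliative_cycles, S_IDX[DEAD]),
    }


@dataclass
class CohortTrace:
    """State occupancy at every cycle boundary plus state-entry flows.

    ``occupancy[s, c]`` is the cohort fraction in state ``s`` at the start of
    cycle ``c`` (column 0 is the initial distribution; the last column is the
    end of the horizon).  ``entries[s, c]`` is the fraction newly arriving in
    ``s`` at boundary ``c`` -- the hook for one-time costs.
    """

    states: list[str]
    occupancy: np.ndarray
    entries: np.ndarray
    schedule: CycleSchedule
    ae_probability: float
    start_age: float
    strategy: str

    def validate(self, atol: float = 1e-9) -> None:
        if np.isnan(self.occupancy).any():
            cyc = int(np.argwhere(np.isnan(self.occupancy))[0][1])
            raise NumericalError(f"NaN occupancy at cycle {cyc}")
        sums = self.occupancy.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=atol):
            cyc = int(np.argmax(np.abs(sums - 1.0)))
            raise NumericalError(
                f"occupancy not conserved at cycle {cyc}: sum={sums[cyc]!r}"
            )
        if np.any(self.occupancy < -atol) or np.any(self.occupancy > 1 + atol):
            raise NumericalError("occupancy outside [0, 1]")
        dead = self.occupancy[S_IDX[DEAD]]
        if np.any(np.diff(dead) < -atol):
            raise NumericalError("dead occupancy decreased")

    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[S_IDX[DEAD]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, state, occupancy) table."""
        n = self.occupancy.shape[1]
        return pd.DataFrame(
            {
                "cycle": np.repeat(np.arange(n), len(self.states)),
                "state": np.tile(self.states, n),
                "occupancy": self.occupancy.T.reshape(-1),
            }
        )


def run_cohort(
    model: StrategyModel,
    schedule: CycleSchedule,
    life_table=None,
    start_age: float = 55.0,
    validate: bool = True,
) -> CohortTrace:
    """Propagate the whole cohort from front-line treatment over the horizon.

    The cohort starts with occupancy 1 in ``front_line``.  Occupancy is
    resolved per (state, time-in-state); tunnel states force exits once their
    dwell limit is reached (front line -> remission after 2 cycles, CAR-T
    delivery -> post-CAR-T remission after 2 cycles, palliation -> death
    after 2 cycles, i.e. six months).
    """
    pre = _precompute(model, schedule, life_table, start_age)
    n = schedule.n_cycles
    nb = n + 1
    ages = np.arange(nb)
    forced = _forced_exits(model)
    dead_i = S_IDX[DEAD]

    occ = np.zeros((N_STATES, nb))
    occ[S_IDX[FRONT_LINE], 0] = 1.0
    occupancy = np.zeros((N_STATES, nb))
    occupancy[S_IDX[FRONT_LINE], 0] = 1.0
    entries = np.zeros((N_STATES, nb))
    entries[S_IDX[FRONT_LINE], 0] = 1.0

    for c in range(n):
        new = np.zeros_like(occ)
        new[dead_i, 0] = occ[dead_i, 0]
        for s in range(N_STATES):
            if s == dead_i:
                continue
            m = occ[s]
            if not m.any():
                continue
            out, stay = _outflows(pre, s, c, ages)
            for tgt, p in out.items():
                amt = float((m * p).sum())
                if amt == 0.0:
                    continue
                new[tgt, 0] += amt
                if tgt != dead_i:
                    entries[tgt, c + 1] += amt
            stayed = m * stay
            if s in forced:
                limit, tgt2 = forced[s]
                moved = float(stayed[limit - 1 :].sum())
                if moved > 0.0:
                    new[tgt2, 0] += moved
                    if tgt2 != dead_i:
                        entries[tgt2, c + 1] += moved
                new[s, 1:limit] += stayed[: limit - 1]
            else:
                new[s, 1:] += stayed[:-1]
                new[s, -1] += stayed[-1]
        occ = new
        occupancy[:, c + 1] = occ.sum(axis=1)
        if np.isnan(occupancy[:, c + 1]).any():
            raise NumericalError(f"NaN occupancy produced at cycle {c}")

    trace = CohortTrace(
        states=list(STATES),
        occupancy=occupancy,
        entries=entries,
        schedule=schedule,
        ae_probability=model.ae_probability,
        start_age=start_age,
        strategy=model.name,
    )
    if validate:
        trace.validate()
    return trace


def resolve_cycle_matrix(
    model: StrategyModel,
    schedule: CycleSchedule,
    cycle: int,
    state_clocks: dict[str, int] | None = None,
    life_table=None,
    start_age: float = 55.0,
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix over the 9 states.

    ``state_clocks`` gives the time-in-state (cycles since entry) used for
    states on a state-time clock; model-time states use ``cycle`` directly.
    Tunnel forcing is folded into the stay probability's destination.
    """
    if cycle >= schedule.n_cycles:
        raise ValueError("cycle must be below n_cycles")
    clocks = state_clocks or {}
    pre = _precompute(model, schedule, life_table, start_age)
    forced = _forced_exits(model)
    mat = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        age = int(clocks.get(STATES[s], 0))
        out, stay = _outflows(pre, s, cycle, np.array([min(age, schedule.n_cycles)]))
        for tgt, p in out.items():
            mat[s, tgt] += float(p[0])
        st = float(stay[0])
        if s in forced and age + 1 >= forced[s][0]:
            mat[s, forced[s][1]] += st
        else:
            mat[s, s] += st
    return mat


def to_dot(model: StrategyModel) -> str:
    """Strategy graph in DOT format for visual audit."""
    edges = [
        (FRONT_LINE, DISEASE_FREE, "end of front line"),
        (FRONT_LINE, SALVAGE_GDP, "relapse (EFS - OS)"),
        (FRONT_LINE, DEAD, "OS / background"),
        (DISEASE_FREE, SALVAGE_GDP, "relapse (plateau at 5 y)"),
        (DISEASE_FREE, DEAD, "OS / background"),
        (SALVAGE_GDP, AUTO_SCT, "response"),
        (SALVAGE_GDP, CAR_T, "progression -> CAR-T"),
        (SALVAGE_GDP, PALLIATIVE, "progression -> palliation"),
        (SALVAGE_GDP, DEAD, "GDP OS / background"),
        (AUTO_SCT, POST_SCT_DF, "disease-free"),
        (AUTO_SCT, CAR_T, "relapse -> CAR-T"),
        (AUTO_SCT, PALLIATIVE, "relapse -> palliation"),
        (AUTO_SCT, DEAD, "background"),
        (POST_SCT_DF, CAR_T, "relapse -> CAR-T"),
        (POST_SCT_DF, PALLIATIVE, "relapse -> palliation"),
        (POST_SCT_DF, DEAD, "background"),
        (CAR_T, POST_CART_DF, "response (2 cycles)"),
        (CAR_T, PALLIATIVE, "progression"),
        (CAR_T, DEAD, "CAR-T OS / background"),
        (POST_CART_DF, PALLIATIVE, "relapse"),
        (POST_CART_DF, DEAD, "death / background"),
        (PALLIATIVE, DEAD, "after 6 months"),
    ]
    lines = [f"digraph {model.arm_key} {{", "  rankdir=LR;"]
    for a, b, lbl in edges:
        lines.append(f'  {a} -> {b} [label="{lbl}"];')
    lines.append("}")
    return "\n".join(lines)
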