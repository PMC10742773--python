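"""Discounted reward accumulation, dominance and incremental ratios."""

import numpy as np
import pytest

from dlbcl_cea.cohort_model import (
    ALIVE_STATES,
    DISEASE_FREE,
    S_IDX,
    STATES,
    CohortTrace,
)
from dlbcl_cea.economics import (
    CostTable,
    UtilityTable,
    accumulate,
    compute_icer,
    discount_factor,
    net_monetary_benefit,
)
from dlbcl_cea.transitions import ConfigurationError, CycleSchedule


def flat_costs(per_cycle=0.0, **kw):
    return CostTable(per_cycle={s: per_cycle for s in ALIVE_STATES}, **kw)


def flat_utilities(u=1.0, **kw):
    return UtilityTable(utility={s: u for s in ALIVE_STATES}, **kw)


def immortal_trace(schedule, state=DISEASE_FREE):
    """Whole cohort parked in one alive state forever."""
    occ = np.zeros((len(STATES), schedule.n_cycles + 1))
    occ[S_IDX[state]] = 1.0
    entries = np.zeros_like(occ)
    entries[S_IDX[state], 0] = 1.0
    return CohortTrace(
        states=list(STATES),
        occupancy=occ,
        entries=entries,
        schedule=schedule,
        ae_probability=0.0,
        start_age=55.0,
        strategy="toy",
    )


@pytest.mark.parametrize(
    "cycle, rate, expected",
    [
        (0, 0.015, 1.0),
        (4, 0.015, 0.9852216748768474),  # exactly one year elapsed
        (77, 0.0, 1.0),
    ],
)
def test_discount_factor(cycle, rate, expected, schedule):
    assert discount_factor(cycle, rate, schedule) == pytest.approx(expected, rel=1e-12)


def test_discount_factor_rejects_negative_rate(schedule):
    with pytest.raises(ValueError):
        discount_factor(1, -0.01, schedule)


def test_perfect_health_makes_qaly_equal_ly(traces):
    for trace in traces.values():
        out = accumulate(trace, flat_costs(), flat_utilities(1.0), 0.0)
        assert out.qaly == pytest.approx(out.ly, rel=1e-12)


def test_uniform_half_utility_scales_linearly(traces):
    trace = traces["RCHOP"]
    full = accumulate(trace, flat_costs(), flat_utilities(1.0), 0.0)
    half = accumulate(trace, flat_costs(), flat_utilities(0.5), 0.0)
    assert half.qaly == pytest.approx(full.ly / 2.0, rel=1e-12)


def test_immortal_annuity_matches_geometric_sum(schedule):
    """Discounted QALYs of an immortal cohort equal the closed-form annuity
    u * sum_c (1+r)^(-c/4) / 4, computed here independently."""
    r, u = 0.015, 0.82
    trace = immortal_trace(schedule)
    out = accumulate(trace, flat_costs(), flat_utilities(u), r, half_cycle=True)
    v = (1.0 + r) ** (-0.25)
    annuity = 0.25 * (1.0 - v**schedule.n_cycles) / (1.0 - v)
    assert out.qaly == pytest.approx(u * annuity, abs=1e-10)
    assert out.ly == pytest.approx(annuity, abs=1e-10)


def test_discounting_never_increases_totals(traces):
    for trace in traces.values():
        costs = flat_costs(100.0, one_time={"auto_sct": 5_000.0}, ae_cost=1_000.0)
        utils = flat_utilities(0.8, ae_decrement=0.1)
        disc = accumulate(trace, costs, utils, 0.03)
        undisc = accumulate(trace, costs, utils, 0.0)
        assert disc.cost <= undisc.cost
        assert disc.qaly <= undisc.qaly
        assert disc.qaly <= disc.ly


def test_missing_state_is_named(traces):
    costs = flat_costs()
    del costs.per_cycle[DISEASE_FREE]
    with pytest.raises(ConfigurationError, match=DISEASE_FREE):
        accumulate(traces["RCHOP"], costs, flat_utilities(), 0.015)


def test_utilities_outside_unit_interval_rejected():
    with pytest.raises(ConfigurationError):
        flat_utilities(1.2).validate()


def test_one_time_costs_booked_at_entry(schedule):
    trace = immortal_trace(schedule)
    costs = flat_costs(one_time={DISEASE_FREE: 10_000.0})
    out = accumulate(trace, costs, flat_utilities(), 0.10)
    assert out.cost == pytest.approx(10_000.0)  # entry at cycle 0, discount 1


def test_adverse_event_cost_and_disutility(schedule):
    trace = immortal_trace(schedule)
    trace.ae_probability = 0.642
    costs = flat_costs(ae_cost=8_000.0)
    utils = flat_utilities(1.0, ae_decrement=0.2)
    base = accumulate(trace, flat_costs(), flat_utilities(), 0.0)
    out = accumulate(trace, costs, utils, 0.0)
    assert out.cost == pytest.approx(0.642 * 8_000.0)
    assert base.qaly - out.qaly == pytest.approx(0.642 * 0.2 * 0.25, rel=1e-12)


# --------------------------------------------------------------- incremental


def test_cheaper_and_better_dominates():
    res = compute_icer([("A", 100.0, 10.0), ("B", 90.0, 11.0)])
    assert res.entry("A").status == "dominated"
    assert res.frontier == ["B"]


def test_extended_dominance_frontier_matches_enumeration():
    """A (0, 0), B (50, 1), C (40, 2): C beats B outright, leaving the
    frontier A -> C with ICER 40/2 = 20."""
    res = compute_icer([("A", 0.0, 0.0), ("B", 50.0, 1.0), ("C", 40.0, 2.0)])
    assert res.frontier == ["A", "C"]
    assert res.entry("C").icer == pytest.approx(20.0)
    assert res.entry("B").status in ("dominated", "extended_dominated")


def test_extended_dominance_removes_inefficient_middle():
    # B's ICER vs A (100) exceeds C's ICER vs B (50): B extended-dominated
    res = compute_icer([("A", 0.0, 0.0), ("B", 100.0, 1.0), ("C", 150.0, 2.0)])
    assert res.entry("B").status == "extended_dominated"
    assert res.frontier == ["A", "C"]
    assert res.entry("C").icer == pytest.approx(75.0)


def test_icer_is_input_order_invariant():
    strategies = [("A", 0.0, 0.0), ("B", 100.0, 1.0), ("C", 150.0, 2.0)]
    a = compute_icer(strategies).to_frame()
    b = compute_icer(strategies[::-1]).to_frame()
    assert a.equals(b)


def test_exact_tie_is_flagged_not_divided():
    res = compute_icer([("A", 10.0, 1.0), ("B", 10.0, 1.0)])
    tied = [e for e in res.entries if e.tie]
    assert len(tied) == 1 and tied[0].icer == 0.0


def test_icer_requires_two_strategies():
    with pytest.raises(ValueError):
        compute_icer([("A", 1.0, 1.0)])


@pytest.mark.parametrize(
    "cost, qaly, wtp, expected",
    [
        (0.0, 0.0, 50_000.0, 0.0),
        (32_520.82, 14.245, 100_000.0, 1_391_979.18),
        (5_000.0, 2.0, 0.0, -5_000.0),
    ],
)
def test_net_monetary_benefit(cost, qaly, wtp, expected):
    assert net_monetary_benefit(cost, qaly, wtp) == pytest.approx(expected, rel=1e-12)


def test_nmb_indifference_at_the_icer():
    """At a WTP exactly equal to the frontier ICER, the two frontier
    strategies have equal net monetary benefit."""
    res = compute_icer([("A", 1_000.0, 1.0), ("B", 3_000.0, 1.5)])
    icer = res.entry("B").icer
    nmb_a = net_monetary_benefit(1_000.0, 1.0, icer)
    nmb_b = net_monetary_benefit(3_000.0, 1.5, icer)
    assert abs(nmb_a - nmb_b) < 1e-6 * max(abs(nmb_a), 1.0)
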