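"""Strategy wiring and the semi-Markov cohort recursion."""

import numpy as np
import pytest

from dlbcl_cea.cohort_model import (
    ALIVE_STATES,
    CAR_T,
    DEAD,
    DISEASE_FREE,
    FRONT_LINE,
    PALLIATIVE,
    SALVAGE_GDP,
    S_IDX,
    STATES,
    build_strategy,
    resolve_cycle_matrix,
    run_cohort,
    to_dot,
)
from dlbcl_cea.economics import reward_loadings
from dlbcl_cea.transitions import (
    ConfigurationError,
    CycleSchedule,
    TransitionSpec,
    WeibullSpec,
    per_cycle_prob,
)


def _with_weibull(params, name, lam, k):
    out = dict(params)
    out[name] = TransitionSpec(name=name, kind="weibull", weibull=WeibullSpec(lam, k, "years"))
    return out


def test_build_strategy_uses_arm_specific_survival(params, schedule):
    model = build_strategy("I-RCHOP", params, schedule)
    assert model.ae_probability == 0.642
    efs = model.transitions["efs_irchop"].weibull
    os_ = model.transitions["os_irchop"].weibull
    assert (efs.rate_lambda, efs.shape_k) == (0.181, 1.350)
    assert (os_.rate_lambda, os_.shape_k) == (0.016, 0.493)
    rchop = build_strategy("RCHOP", params, schedule)
    assert rchop.ae_probability == 0.303


def test_build_strategy_missing_row_is_named(params, schedule):
    broken = dict(params)
    del broken["salvage_response"]
    with pytest.raises(ConfigurationError, match="salvage_response"):
        build_strategy("RCHOP", broken, schedule)


def test_unknown_arm_rejected(params, schedule):
    with pytest.raises(ConfigurationError):
        build_strategy("R-CVP", params, schedule)


def test_dead_state_is_absorbing(params, schedule, life_table):
    model = build_strategy("RCHOP", params, schedule)
    mat = resolve_cycle_matrix(model, schedule, cycle=5, life_table=life_table)
    dead = S_IDX[DEAD]
    assert mat[dead, dead] == 1.0
    assert mat[dead].sum() == 1.0
    # dead is reachable from every alive state
    assert np.all(mat[: dead, dead] > 0)


@pytest.mark.parametrize("cycle", [0, 1, 19, 20, 60, 119])
def test_cycle_matrix_rows_are_stochastic(params, schedule, life_table, cycle):
    model = build_strategy("I-RCHOP", params, schedule)
    clocks = {SALVAGE_GDP: 3, CAR_T: 1, PALLIATIVE: 1, "post_sct_disease_free": 7}
    mat = resolve_cycle_matrix(model, schedule, cycle, clocks, life_table)
    assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(mat >= 0)


def test_zero_background_limit_death_equals_disease_death(params, schedule):
    """With no background mortality the front-line death probability is the
    OS-curve conditional probability exactly."""
    model = build_strategy("RCHOP", params, schedule)
    mat = resolve_cycle_matrix(model, schedule, cycle=4, life_table=None)
    expected = per_cycle_prob(model.transitions["os_rchop"].weibull, 4, schedule)
    assert mat[S_IDX[FRONT_LINE], S_IDX[DEAD]] == pytest.approx(expected, rel=1e-12)


def test_trace_invariants_base_fixture(traces):
    for trace in traces.values():
        trace.validate(atol=1e-9)
        dead = trace.occupancy[S_IDX[DEAD]]
        assert np.all(np.diff(dead) >= -1e-12)


def test_immortal_cohort_accrues_full_horizon(params, schedule):
    """Negligible hazards everywhere: undiscounted life years equal the
    30-year horizon."""
    p = params
    for name in ("os_rchop", "efs_rchop"):
        p = _with_weibull(p, name, 1e-12, 1.0)
    model = build_strategy("RCHOP", p, schedule)
    trace = run_cohort(model, schedule, life_table=None)
    ly = sum(reward_loadings(trace, 0.0).time_years[s] for s in ALIVE_STATES)
    assert ly == pytest.approx(30.0, abs=1e-6)


def test_immediate_death_leaves_half_cycle(params, schedule):
    """Certain death in cycle 0 contributes exactly the half-cycle credit."""
    p = _with_weibull(params, "os_rchop", 1e9, 1.0)
    p = _with_weibull(p, "efs_rchop", 1e9, 1.0)
    model = build_strategy("RCHOP", p, schedule)
    trace = run_cohort(model, schedule, life_table=None)
    ly = sum(reward_loadings(trace, 0.0).time_years[s] for s in ALIVE_STATES)
    assert ly == pytest.approx(0.125, abs=1e-9)


def test_two_state_collapse_oracle(params, schedule, life_table):
    """With relapse switched off (EFS identical to OS) the model collapses to
    alive/dead, so dead occupancy must equal 1 minus the product of per-cycle
    survival -- computed here independently of the engine."""
    p = _with_weibull(params, "efs_rchop", 0.081, 0.769)  # EFS == OS, no excess events
    model = build_strategy("RCHOP", p, schedule)
    trace = run_cohort(model, schedule, life_table, 55.0)
    p_dis = per_cycle_prob(model.transitions["os_rchop"].weibull, np.arange(10), schedule)
    ages = 55.0 + np.arange(10) * schedule.cycle_years
    q_bg = life_table.cycle_prob(ages, schedule.cycle_years)
    survival = np.cumprod((1.0 - q_bg) * (1.0 - p_dis))
    dead = trace.occupancy[S_IDX[DEAD], 1:11]
    assert np.allclose(dead, 1.0 - survival, atol=1e-9)
    # and nobody ever reaches the salvage pathway
    assert trace.occupancy[S_IDX[SALVAGE_GDP]].max() == 0.0


def test_relapse_plateau_stops_salvage_entries(traces, schedule):
    """After five years of front-line remission no one newly enters salvage
    from the remission pool (the only source of salvage entries)."""
    for trace in traces.values():
        assert np.all(trace.entries[S_IDX[SALVAGE_GDP], schedule.plateau_cycle + 1 :] == 0.0)
        assert trace.entries[S_IDX[SALVAGE_GDP], 1 : schedule.plateau_cycle].sum() > 0


def test_palliative_tunnel_holds_at_most_two_cycles(traces):
    """Occupancy in palliation never exceeds the last two boundaries' entries:
    the six-month terminal window."""
    for trace in traces.values():
        pall = trace.occupancy[S_IDX[PALLIATIVE]]
        ent = trace.entries[S_IDX[PALLIATIVE]]
        for c in range(2, trace.schedule.n_cycles):
            assert pall[c] <= ent[c] + ent[c - 1] + 1e-12


def test_strategy_symmetry(params, schedule, life_table):
    """Giving the experimental arm the comparator's parameters produces an
    identical trace."""
    p = dict(params)
    for row in ("os", "efs", "ae"):
        p[f"{row}_irchop"] = p[f"{row}_rchop"]
    a = run_cohort(build_strategy("RCHOP", p, schedule), schedule, life_table)
    b = run_cohort(build_strategy("I-RCHOP", p, schedule), schedule, life_table)
    assert np.array_equal(a.occupancy, b.occupancy)
    assert np.array_equal(a.entries, b.entries)


def test_front_line_is_a_two_cycle_tunnel(traces):
    for trace in traces.values():
        assert trace.occupancy[S_IDX[FRONT_LINE], 0] == 1.0
        # after two cycles the front-line state is empty for good
        assert np.all(trace.occupancy[S_IDX[FRONT_LINE], 2:] == 0.0)
        assert trace.occupancy[S_IDX[DISEASE_FREE], 2] > 0.5


def test_trace_frame_and_dot_export(traces, params, schedule):
    frame = traces["RCHOP"].to_frame()
    assert set(frame.columns) == {"cycle", "state", "occupancy"}
    assert len(frame) == (schedule.n_cycles + 1) * len(STATES)
    dot = to_dot(build_strategy("RCHOP", params, schedule))
    assert dot.startswith("digraph") and "palliative -> dead" in dot
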