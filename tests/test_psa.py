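"""Parameter distributions, probabilistic runs and the acceptability curve."""

import json
import math

import numpy as np
import pytest

from dlbcl_cea.economics import StrategyOutcome
from dlbcl_cea.psa import (
    CEACCurve,
    ParameterDistribution,
    PSARun,
    ceac,
    default_distributions,
    infer_family,
    run_psa,
    sample_parameters,
)
from dlbcl_cea.transitions import ConfigurationError

RNG = lambda: np.random.default_rng(20230)


@pytest.mark.parametrize(
    "name, family",
    [
        ("efs_irchop.lambda", "lognormal"),
        ("os_rchop.k", "lognormal"),
        ("cost.car_t.one_time", "gamma"),
        ("salvage_response", "beta"),
        ("utility.disease_free", "beta"),
    ],
)
def test_family_inference(name, family):
    assert infer_family(name) == family


@pytest.mark.parametrize(
    "family, mean, se",
    [("beta", 0.642, 0.05), ("gamma", 10_000.0, 1_000.0), ("lognormal", 0.181, 0.018)],
)
def test_moment_matching_recovers_mean_and_sd(family, mean, se):
    d = ParameterDistribution("x", family, mean, se)
    draws = d.sample(RNG(), size=200_000)
    assert np.mean(draws) == pytest.approx(mean, abs=4 * se / math.sqrt(200_000))
    assert np.std(draws) == pytest.approx(se, rel=0.03)


def test_gamma_cost_draws_are_positive():
    d = ParameterDistribution("cost", "gamma", 10_000.0, 1_000.0)
    assert np.all(d.sample(RNG(), size=10_000) > 0)


def test_beta_respects_unit_interval_and_bounds():
    d = ParameterDistribution("p", "beta", 0.3755, 0.05, low=0.300, high=0.451)
    draws = d.sample(RNG(), size=5_000)
    assert draws.min() >= 0.300 and draws.max() <= 0.451


def test_infeasible_beta_se_names_the_parameter():
    with pytest.raises(ConfigurationError, match="salvage_response"):
        ParameterDistribution("salvage_response", "beta", 0.5, 0.6)


def test_zero_se_collapses_to_the_mean():
    d = ParameterDistribution("x", "beta", 0.642, 0.0)
    assert d.sample(RNG()) == 0.642


def test_sample_parameters_is_a_complete_draw():
    dists = default_distributions({"a": 0.4, "cost.b": 5.0, "w.lambda": 0.2})
    draw = sample_parameters(dists, RNG())
    assert set(draw) == {"a", "cost.b", "w.lambda"}


# ------------------------------------------------------------------ psa runs


def _toy_evaluator(k_years=10.0):
    """Two-strategy toy with outcomes linear in the drawn parameters, so the
    expected cost/QALY are available in closed form."""

    def evaluate(draw):
        return {
            "A": StrategyOutcome("A", draw["cost.a"], draw["utility.a"] * k_years, k_years),
            "B": StrategyOutcome("B", 0.5 * draw["cost.a"], 0.6 * k_years, k_years),
        }

    return evaluate


def test_psa_mean_matches_analytic_toy_model():
    """With cost ~ gamma(mean 10,000) and utility ~ beta(mean 0.7), the toy
    outcome means are E[cost] = 10,000 and E[QALY] = 7 exactly; the PSA mean
    must agree within 3 standard errors."""
    dists = [
        ParameterDistribution("cost.a", "gamma", 10_000.0, 1_000.0),
        ParameterDistribution("utility.a", "beta", 0.7, 0.05),
    ]
    run = run_psa(_toy_evaluator(), dists, n_sims=100_000, seed=11)
    s = run.summary().set_index("strategy")
    assert s.loc["A", "mean_cost"] == pytest.approx(10_000.0, abs=3 * s.loc["A", "se_cost"])
    assert s.loc["A", "mean_qaly"] == pytest.approx(7.0, abs=3 * s.loc["A", "se_qaly"])


def test_psa_zero_spread_collapses_to_base_case():
    dists = [
        ParameterDistribution("cost.a", "gamma", 10_000.0, 0.0),
        ParameterDistribution("utility.a", "beta", 0.7, 0.0),
    ]
    run = run_psa(_toy_evaluator(), dists, n_sims=10, seed=3)
    assert np.all(run.cost["A"] == 10_000.0)
    assert np.all(run.qaly["A"] == 7.0)


def test_psa_seed_determinism_byte_identical():
    dists = [
        ParameterDistribution("cost.a", "gamma", 10_000.0, 1_000.0),
        ParameterDistribution("utility.a", "beta", 0.7, 0.05),
    ]
    a = run_psa(_toy_evaluator(), dists, n_sims=64, seed=42)
    b = run_psa(_toy_evaluator(), dists, n_sims=64, seed=42)
    assert a.summary().to_json() == b.summary().to_json()
    assert json.dumps(a.cost["A"].tolist()) == json.dumps(b.cost["A"].tolist())


def test_failed_draws_are_counted_not_propagated():
    calls = {"n": 0}

    def flaky(draw):
        calls["n"] += 1
        if calls["n"] % 3 == 0:
            return {"A": StrategyOutcome("A", float("nan"), 1.0, 1.0),
                    "B": StrategyOutcome("B", 1.0, 1.0, 1.0)}
        return _toy_evaluator()(draw)

    dists = [
        ParameterDistribution("cost.a", "gamma", 10_000.0, 1_000.0),
        ParameterDistribution("utility.a", "beta", 0.7, 0.05),
    ]
    run = run_psa(flaky, dists, n_sims=30, seed=1)
    assert run.n_failed == 10
    assert run.n_sims == 20
    assert np.all(np.isfinite(run.cost["A"]))


# --------------------------------------------------------------------- ceac


def _run_from_arrays(cost_a, qaly_a, cost_b, qaly_b):
    return PSARun(
        strategies=["A", "B"],
        cost={"A": np.asarray(cost_a, float), "B": np.asarray(cost_b, float)},
        qaly={"A": np.asarray(qaly_a, float), "B": np.asarray(qaly_b, float)},
        ly={"A": np.asarray(qaly_a, float), "B": np.asarray(qaly_b, float)},
        seed=0,
    )


def test_ceac_matches_exhaustive_enumeration_of_four_draws():
    """Hand enumeration at WTP 10: NMB_A = 10q - c.  Draw-by-draw winners:
    (A: 10*1-5=5 vs B: 10*0.5-1=4 -> A), (A: -5+10*0.2=-3 vs B: 3 -> B),
    (A: 15 vs B: 4 -> A), (tie 5 vs 5 -> split)."""
    run = _run_from_arrays(
        cost_a=[5.0, 5.0, 5.0, 5.0],
        qaly_a=[1.0, 0.2, 2.0, 1.0],
        cost_b=[1.0, 2.0, 1.0, 5.0],
        qaly_b=[0.5, 0.5, 0.5, 1.0],
    )
    curve = ceac(run, [10.0])
    assert curve.at("A", 10.0) == pytest.approx((1 + 0 + 1 + 0.5) / 4)
    assert curve.at("B", 10.0) == pytest.approx((0 + 1 + 0 + 0.5) / 4)


def test_ceac_probabilities_partition_unity():
    rng = np.random.default_rng(5)
    run = _run_from_arrays(
        rng.uniform(0, 10, 50), rng.uniform(0, 2, 50),
        rng.uniform(0, 10, 50), rng.uniform(0, 2, 50),
    )
    curve = ceac(run, np.linspace(0.0, 20.0, 9))
    total = np.sum([curve.prob[s] for s in run.strategies], axis=0)
    assert np.allclose(total, 1.0, atol=1e-12)
    for s in run.strategies:
        assert np.all((curve.prob[s] >= 0) & (curve.prob[s] <= 1))


def test_ceac_at_zero_wtp_reduces_to_cost_comparison():
    run = _run_from_arrays([5.0, 1.0, 3.0], [1, 1, 1], [4.0, 2.0, 3.5], [9, 9, 9])
    curve = ceac(run, [0.0])
    assert curve.at("A", 0.0) == pytest.approx(2 / 3)  # cheaper in draws 2 and 3


def test_ceac_rejects_empty_grid():
    run = _run_from_arrays([1.0], [1.0], [2.0], [2.0])
    with pytest.raises(ValueError):
        ceac(run, [])


def test_ceac_frame_is_tidy():
    run = _run_from_arrays([1.0], [1.0], [2.0], [2.0])
    frame = ceac(run, [0.0, 1.0]).to_frame()
    assert list(frame.columns) == ["wtp", "strategy", "probability"]
    assert len(frame) == 4
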