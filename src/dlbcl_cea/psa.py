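"""Probabilistic sensitivity analysis and the acceptability curve.

Each PSA iteration draws every uncertain parameter jointly from a
moment-matched distribution (beta for probabilities and utilities, gamma for
costs, lognormal for Weibull shape/rate parameters -- the conventional
health-economics choices), evaluates the full deterministic model for both
strategies under the common draw, and records discounted cost/QALY/LY.
Because both strategies share one draw, strategy contrasts are paired and
the Monte-Carlo variance of incremental quantities is reduced.

The cost-effectiveness acceptability curve (CEAC) reports, for each
willingness-to-pay value, the fraction of draws in which each strategy has
the maximal net monetary benefit; exact ties are split equally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .economics import StrategyOutcome
from .transitions import ConfigurationError

Family = str  # "beta" | "gamma" | "lognormal" | "degenerate"


def infer_family(name: str) -> Family:
    """Conventional family by parameter kind, inferred from the flat name."""
    if name.endswith(".lambda") or name.endswith(".k"):
        return "lognormal"
    if name.startswith("cost."):
        return "gamma"
    # probabilities and utilities (incl. the AE decrement) live on [0, 1]
    return "beta"


@dataclass
class ParameterDistribution:
    """One uncertain parameter, moment-matched from (mean, se).

    ``low``/``high`` optionally clip the support (used for ranged
    probabilities whose published bounds are known).
    """

    name: str
    family: Family
    mean: float
    se: float
    low: float | None = None
    high: float | None = None
    _hyper: tuple = field(default=(), repr=False)

    def __post_init__(self) -> None:
        m, v = self.mean, self.se**2
        if not math.isfinite(m) or not math.isfinite(v):
            raise ConfigurationError(f"{self.name}: non-finite moments")
        if self.se == 0.0 or m == 0.0:
            self.family = "degenerate"
            self._hyper = ()
            return
        if self.family == "beta":
            if not 0.0 < m < 1.0:
                raise ConfigurationError(
                    f"{self.name}: beta mean must be inside (0, 1), got {m}"
                )
            if v >= m * (1.0 - m):
                raise ConfigurationError(
                    f"{self.name}: se {self.se} too large for a beta with mean {m}"
                )
            nu = m * (1.0 - m) / v - 1.0
            self._hyper = (m * nu, (1.0 - m) * nu)
        elif self.family == "gamma":
            self._hyper = (m * m / v, v / m)  # shape, scale
        elif self.family == "lognormal":
            sigma2 = math.log1p(v / (m * m))
            self._hyper = (math.log(m) - 0.5 * sigma2, math.sqrt(sigma2))
        elif self.family != "degenerate":
            raise ConfigurationError(f"{self.name}: unknown family {self.family}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "degenerate":
            out = np.full(size, self.mean) if size else self.mean
            return out
        if self.family == "beta":
            out = rng.beta(*self._hyper, size=size)
        elif self.family == "gamma":
            out = rng.gamma(shape=self._hyper[0], scale=self._hyper[1], size=size)
        else:
            out = rng.lognormal(mean=self._hyper[0], sigma=self._hyper[1], size=size)
        if self.low is not None or self.high is not None:
            out = np.clip(out, self.low, self.high)
        return float(out) if size is None else out


def default_distributions(
    flat: dict[str, float],
    se_frac: float = 0.10,
    se_overrides: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> list[ParameterDistribution]:
    """One distribution per flat parameter, with se defaulting to 10% of mean.

    The published tables report uncertainty for outcomes only, so the input
    spread is a stand-in consistent with the +/-10% one-way interrogation.
    """
    se_overrides = se_overrides or {}
    bounds = bounds or {}
    dists = []
    for name, mean in flat.items():
        se = se_overrides.get(name, abs(mean) * se_frac)
        fam = infer_family(name)
        if fam == "beta" and mean > 0:
            # keep the stand-in spread feasible near the [0, 1] edges
            se = min(se, 0.9 * math.sqrt(mean * (1.0 - mean))) if mean < 1.0 else 0.0
        lo, hi = bounds.get(name, (None, None))
        dists.append(
            ParameterDistribution(name=name, family=fam, mean=mean, se=se, low=lo, high=hi)
        )
    return dists


def sample_parameters(
    distributions: Sequence[ParameterDistribution], rng: np.random.Generator
) -> dict[str, float]:
    """One coherent joint draw (independent across parameters)."""
    return {d.name: float(d.sample(rng)) for d in distributions}


@dataclass
class PSARun:
    """Per-draw outcomes of a probabilistic analysis."""

    strategies: list[str]
    cost: dict[str, np.ndarray]
    qaly: dict[str, np.ndarray]
    ly: dict[str, np.ndarray]
    seed: int
    n_failed: int = 0

    @property
    def n_sims(self) -> int:
        return len(next(iter(self.cost.values())))

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in self.strategies:
            n = len(self.cost[s])
            rows.append(
                {
                    "strategy": s,
                    "n_sims": n,
                    "mean_cost": float(np.mean(self.cost[s])),
                    "sd_cost": float(np.std(self.cost[s], ddof=1)) if n > 1 else 0.0,
                    "se_cost": float(np.std(self.cost[s], ddof=1) / math.sqrt(n))
                    if n > 1
                    else 0.0,
                    "mean_qaly": float(np.mean(self.qaly[s])),
                    "sd_qaly": float(np.std(self.qaly[s], ddof=1)) if n > 1 else 0.0,
                    "se_qaly": float(np.std(self.qaly[s], ddof=1) / math.sqrt(n))
                    if n > 1
                    else 0.0,
                    "mean_ly": float(np.mean(self.ly[s])),
                    "sd_ly": float(np.std(self.ly[s], ddof=1)) if n > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def scatter_frame(self) -> pd.DataFrame:
        """(draw, strategy, cost, qaly) for cost-effectiveness-plane plots."""
        frames = []
        for s in self.strategies:
            frames.append(
                pd.DataFrame(
                    {
                        "draw": np.arange(len(self.cost[s])),
                        "strategy": s,
                        "cost": self.cost[s],
                        "qaly": self.qaly[s],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run_psa(
    evaluate: Callable[[dict[str, float]], dict[str, StrategyOutcome]],
    distributions: Sequence[ParameterDistribution],
    n_sims: int,
    seed: int,
) -> PSARun:
    """Joint parameter draws -> per-draw model outcomes for every strategy.

    Deterministic under a fixed seed.  Draws producing NaN outcomes are
    excluded and counted in ``n_failed`` rather than poisoning the summary.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    rng = np.random.default_rng(seed)
    cost: dict[str, list[float]] = {}
    qaly: dict[str, list[float]] = {}
    ly: dict[str, list[float]] = {}
    strategies: list[str] = []
    n_failed = 0
    for _ in range(n_sims):
        draw = sample_parameters(distributions, rng)
        try:
            out = evaluate(draw)
        except (ValueError, FloatingPointError, ConfigurationError):
            n_failed += 1
            continue
        if not strategies:
            strategies = list(out)
            for s in strategies:
                cost[s], qaly[s], ly[s] = [], [], []
        if any(
            not math.isfinite(o.cost) or not math.isfinite(o.qaly) for o in out.values()
        ):
            n_failed += 1
            continue
        for s in strategies:
            cost[s].append(out[s].cost)
            qaly[s].append(out[s].qaly)
            ly[s].append(out[s].ly)
    if not strategies:
        raise RuntimeError(f"all {n_sims} draws failed")
    return PSARun(
        strategies=strategies,
        cost={s: np.asarray(v) for s, v in cost.items()},
        qaly={s: np.asarray(v) for s, v in qaly.items()},
        ly={s: np.asarray(v) for s, v in ly.items()},
        seed=seed,
        n_failed=n_failed,
    )


@dataclass
class CEACCurve:
    """Probability each strategy is cost-effective across a WTP grid."""

    wtp: np.ndarray
    prob: dict[str, np.ndarray]

    def at(self, strategy: str, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        if not math.isclose(self.wtp[idx], wtp, rel_tol=1e-9, abs_tol=1e-9):
            raise KeyError(f"wtp {wtp} not on the grid")
        return float(self.prob[strategy][idx])

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for s, p in self.prob.items():
            frames.append(pd.DataFrame({"wtp": self.wtp, "strategy": s, "probability": p}))
        return pd.concat(frames, ignore_index=True)


def ceac(run: PSARun, wtp_grid: Iterable[float]) -> CEACCurve:
    """Fraction of draws where each strategy maximizes NMB, per WTP value.

    Exact ties split equally among the tied strategies, so the fractions
    partition 1 at every grid point.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if run.n_sims == 0:
        raise ValueError("empty PSA run")
    # vectorized net_monetary_benefit over (strategy, wtp, draw)
    nmb = np.stack(
        [
            wtp[:, None] * run.qaly[s][None, :] - run.cost[s][None, :]
            for s in run.strategies
        ]
    )
    best = nmb.max(axis=0, keepdims=True)
    is_best = nmb >= best - 1e-12 * np.maximum(1.0, np.abs(best))
    weights = is_best / is_best.sum(axis=0, keepdims=True)
    prob = {s: weights[i].mean(axis=1) for i, s in enumerate(run.strategies)}
    return CEACCurve(wtp=wtp, prob=prob)
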