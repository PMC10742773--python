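"""One-way deterministic sensitivity analysis and the tornado ordering.

Each parameter is perturbed to value x (1 +/- delta) with everything else at
base case (probabilities and utilities clamped to [0, 1]); the full
deterministic model is re-run at both bounds and the incremental
cost-effectiveness ratio recorded.  Entries sorted by descending ICER range
form the tornado diagram; a threshold check flags any entry whose ICER
crosses the willingness-to-pay ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

from .economics import StrategyOutcome, compute_icer
from .psa import infer_family


@dataclass
class TornadoEntry:
    """One parameter's ICER excursion under the +/- perturbation."""

    parameter: str
    low_value: float
    high_value: float
    icer_low: float  # ICER with the parameter at its low value
    icer_high: float
    base_icer: float
    flagged: bool = False  # a bound made the comparison degenerate (dominance)

    @property
    def range(self) -> float:
        if math.isnan(self.icer_low) or math.isnan(self.icer_high):
            return math.nan
        return abs(self.icer_high - self.icer_low)


def icer_between(
    outcomes: dict[str, StrategyOutcome],
    comparator: str = "I-RCHOP",
) -> float:
    """ICER of ``comparator`` on the frontier; NaN when dominance removes it."""
    ce = compute_icer(list(outcomes.values()))
    entry = ce.entry(comparator)
    if entry.status != "undominated" or entry.icer is None:
        return math.nan
    return float(entry.icer)


def _try_icer(evaluate, overrides, comparator) -> float:
    """NaN (flagged downstream) when a perturbation makes the model infeasible."""
    from .transitions import ConfigurationError

    try:
        return icer_between(evaluate(overrides), comparator)
    except (ConfigurationError, ValueError):
        return math.nan


def _clamp(name: str, value: float) -> float:
    fam = infer_family(name)
    if fam == "beta":
        return min(max(value, 0.0), 1.0)
    if fam == "gamma":
        return max(value, 0.0)
    return max(value, 1e-12)  # Weibull parameters stay positive


def one_way(
    evaluate: Callable[[dict[str, float]], dict[str, StrategyOutcome]],
    base_params: dict[str, float],
    parameter: str,
    delta: float = 0.10,
    comparator: str = "I-RCHOP",
    base_icer: float | None = None,
) -> TornadoEntry:
    """Re-run the full model at parameter x (1 +/- delta); record both ICERs.

    ``delta=0`` reproduces the base-case ICER exactly.  If a perturbation
    makes the incremental comparison degenerate (dominance), the entry is
    flagged rather than silently dropped.
    """
    if parameter not in base_params:
        raise KeyError(f"unknown parameter {parameter!r}")
    base = base_params[parameter]
    low = _clamp(parameter, base * (1.0 - delta))
    high = _clamp(parameter, base * (1.0 + delta))
    if base_icer is None:
        base_icer = icer_between(evaluate({}), comparator)
    icer_low = _try_icer(evaluate, {parameter: low}, comparator)
    icer_high = _try_icer(evaluate, {parameter: high}, comparator)
    return TornadoEntry(
        parameter=parameter,
        low_value=low,
        high_value=high,
        icer_low=icer_low,
        icer_high=icer_high,
        base_icer=base_icer,
        flagged=math.isnan(icer_low) or math.isnan(icer_high),
    )


def tornado(entries: Iterable[TornadoEntry]) -> list[TornadoEntry]:
    """Sort by descending ICER range; ties (and NaNs) break alphabetically."""
    entries = list(entries)
    if not entries:
        raise ValueError("no tornado entries")
    return sorted(
        entries,
        key=lambda e: (-(e.range if not math.isnan(e.range) else -math.inf), e.parameter),
    )


def threshold_check(
    entries: Iterable[TornadoEntry], wtp: float
) -> list[tuple[str, str, float]]:
    """(parameter, bound, icer) for every excursion beyond the WTP ceiling."""
    if not wtp > 0:
        raise ValueError("wtp must be positive")
    flags = []
    for e in entries:
        if not math.isnan(e.icer_low) and e.icer_low > wtp:
            flags.append((e.parameter, "low", e.icer_low))
        if not math.isnan(e.icer_high) and e.icer_high > wtp:
            flags.append((e.parameter, "high", e.icer_high))
    return flags


def default_dsa_parameters(flat: dict[str, float]) -> list[str]:
    """The conventional one-way set: point probabilities, costs, utilities.

    Weibull shape/rate pairs are excluded -- a +/-10% move of a shape
    parameter is not a 10% move of any probability -- matching the usual
    presentation of probability/cost/utility bars only.
    """
    names = []
    for name in flat:
        if name.endswith(".lambda") or name.endswith(".k"):
            continue
        names.append(name)
    return sorted(names)


def run_dsa(
    evaluate,
    base_params: dict[str, float],
    parameters: Sequence[str] | None = None,
    delta: float = 0.10,
    comparator: str = "I-RCHOP",
) -> list[TornadoEntry]:
    """One-way analysis over a parameter set, tornado-ordered."""
    parameters = (
        list(parameters) if parameters is not None else default_dsa_parameters(base_params)
    )
    base = icer_between(evaluate({}), comparator)
    entries = [
        one_way(evaluate, base_params, p, delta=delta, comparator=comparator, base_icer=base)
        for p in parameters
    ]
    return tornado(entries)


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    """CSV-ready (parameter, low, high, icer_low, icer_high, range), sorted."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "range": e.range,
                "flagged": e.flagged,
            }
            for e in entries
        ]
    )
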