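"""Per-cycle transition probabilities from published survival parameterizations.

Disease-history inputs arrive in two forms: Weibull survival fits
``S(t) = exp(-lambda * t**k)`` (rate parameterization, with ``lambda`` the rate
scale and ``k`` the shape) and point probabilities quoted over some period.
A Markov cohort engine needs conditional per-cycle probabilities on a fixed
three-month grid, so this module performs the conversions:

* Weibull -> per-cycle:  ``p_c = 1 - S(t + dt) / S(t)`` with ``t = c * dt``,
  the probability of the event during cycle ``c`` conditional on being
  event-free at its start.
* point -> per-cycle:    constant-rate rescaling
  ``p_cycle = 1 - (1 - p) ** (dt / period)``.

It also applies the relapse-hazard plateau: after five years of sustained
remission the relapse hazard is set to zero, while background and
disease-specific mortality continue to act.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np

logger = logging.getLogger(__name__)

TimeUnit = Literal["years", "months", "cycles"]


class ConfigurationError(Exception):
    """An input table is missing or inconsistent; the message names the culprit."""


@dataclass(frozen=True)
class WeibullSpec:
    """Weibull survival curve in rate form, S(t) = exp(-lambda * t**k).

    ``rate_lambda`` has units of 1/time_unit**k; ``shape_k`` is dimensionless.
    ``shape_k > 1`` means an increasing hazard, ``< 1`` a decreasing one, and
    ``== 1`` reduces to the exponential (constant-hazard) distribution.
    """

    rate_lambda: float
    shape_k: float
    time_unit: TimeUnit = "years"

    def __post_init__(self) -> None:
        if not self.rate_lambda > 0:
            raise ValueError(f"rate_lambda must be positive, got {self.rate_lambda}")
        if not self.shape_k > 0:
            raise ValueError(f"shape_k must be positive, got {self.shape_k}")
        if self.time_unit not in ("years", "months", "cycles"):
            raise ValueError(f"unknown time unit {self.time_unit!r}")

    def survival(self, t):
        return weibull_survival(self, t)


@dataclass(frozen=True)
class PointProbSpec:
    """A probability quoted over a fixed period (default: one model cycle).

    Ranged table entries (e.g. 0.200-0.500) carry their bounds in
    ``range_low``/``range_high``; the ``value`` is the base case.
    """

    value: float
    over_period_cycles: float = 1.0
    range_low: float | None = None
    range_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability must lie in [0, 1], got {self.value}")
        if self.over_period_cycles <= 0:
            raise ValueError("over_period_cycles must be positive")
        if (self.range_low is None) != (self.range_high is None):
            raise ValueError("range_low and range_high must be given together")
        if self.range_low is not None:
            if not (0.0 <= self.range_low <= self.value <= self.range_high <= 1.0):
                raise ValueError(
                    f"range [{self.range_low}, {self.range_high}] must bracket "
                    f"value {self.value} within [0, 1]"
                )


@dataclass(frozen=True)
class CycleSchedule:
    """The discrete time grid: 3-month cycles over a 30-year horizon by default.

    ``plateau_cycle`` is the cycle index (20 = five years) from which the
    relapse hazard out of sustained remission is treated as zero.
    """

    cycle_months: float = 3.0
    n_cycles: int = 120
    plateau_cycle: int = 20

    def __post_init__(self) -> None:
        if self.cycle_months <= 0 or self.n_cycles <= 0:
            raise ValueError("cycle_months and n_cycles must be positive")
        if self.plateau_cycle > self.n_cycles:
            raise ValueError("plateau_cycle cannot exceed n_cycles")

    @property
    def cycle_years(self) -> float:
        return self.cycle_months / 12.0

    @property
    def horizon_years(self) -> float:
        return self.n_cycles * self.cycle_years

    def cycle_in(self, unit: TimeUnit) -> float:
        """Length of one cycle expressed in ``unit``."""
        if unit == "years":
            return self.cycle_months / 12.0
        if unit == "months":
            return self.cycle_months
        if unit == "cycles":
            return 1.0
        raise ValueError(f"unknown time unit {unit!r}")


@dataclass(frozen=True)
class TransitionSpec:
    """One parameter-table row: either a Weibull curve or a point probability."""

    name: str
    kind: Literal["weibull", "point"]
    weibull: WeibullSpec | None = None
    point: PointProbSpec | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind == "weibull" and self.weibull is None:
            raise ValueError(f"{self.name}: weibull row without parameters")
        if self.kind == "point" and self.point is None:
            raise ValueError(f"{self.name}: point row without a value")


def weibull_survival(spec: WeibullSpec, t):
    """S(t) = exp(-lambda * t**k), with t in spec.time_unit. S(0) == 1."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("survival time must be non-negative")
    out = np.exp(-spec.rate_lambda * np.power(arr, spec.shape_k))
    return float(out) if np.ndim(t) == 0 else out


def per_cycle_prob(spec: WeibullSpec, cycle_index, schedule: CycleSchedule):
    """Conditional probability of the event during a cycle.

    ``1 - S(t + dt) / S(t)`` with ``t = cycle_index * dt`` and ``dt`` the cycle
    length converted to the spec's time unit.  If S(t) has underflowed to zero
    the event is certain for anyone still at risk, so 1 is returned (with a
    warning, since occupancy there should be negligible).
    """
    idx = np.asarray(cycle_index, dtype=float)
    if np.any(idx < 0):
        raise ValueError("cycle_index must be non-negative")
    dt = schedule.cycle_in(spec.time_unit)
    s0 = np.exp(-spec.rate_lambda * np.power(idx * dt, spec.shape_k))
    s1 = np.exp(-spec.rate_lambda * np.power((idx + 1.0) * dt, spec.shape_k))
    underflow = s0 <= 0.0
    if np.any(underflow):
        logger.warning(
            "Weibull survival underflowed to 0 (lambda=%g, k=%g); "
            "returning per-cycle probability 1",
            spec.rate_lambda,
            spec.shape_k,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(underflow, 1.0, 1.0 - s1 / np.where(underflow, 1.0, s0))
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.ndim(cycle_index) == 0 else p


def point_prob_to_cycle(spec: PointProbSpec, schedule: CycleSchedule) -> float:
    """Rescale a probability quoted over ``over_period_cycles`` to one cycle.

    Constant-rate conversion: p_cycle = 1 - (1 - p) ** (1 / period_in_cycles).
    Identity when the period is one cycle; returns 1 when p == 1.
    """
    if spec.value >= 1.0:
        return 1.0
    return float(1.0 - (1.0 - spec.value) ** (1.0 / spec.over_period_cycles))


def apply_plateau(p, cycle_index, schedule: CycleSchedule, is_relapse_hazard: bool = True):
    """Zero the relapse hazard from the plateau cycle onward.

    Non-relapse hazards (death, background mortality) pass through unchanged.
    ``cycle_index`` is the clock the hazard runs on: model time for front-line
    remission, time-in-state for post-salvage remission states.
    """
    if not is_relapse_hazard:
        return p
    idx = np.asarray(cycle_index)
    out = np.where(idx >= schedule.plateau_cycle, 0.0, p)
    if np.ndim(p) == 0 and np.ndim(cycle_index) == 0:
        return float(out)
    return out


_DATA_PACKAGE = "dlbcl_cea.data"
PARAMETER_TABLE_FILE = "transition_probabilities.csv"


def load_parameter_table(
    path=None, time_unit: TimeUnit | None = None
) -> dict[str, TransitionSpec]:
    """Read the transition-parameter CSV into named :class:`TransitionSpec`.

    Columns: name, kind {weibull, point}, lambda, k, value, range_low,
    range_high, time_unit, over_period_cycles, source.  With ``path=None`` the
    packaged table of published trial parameterizations is used.
    ``time_unit`` overrides the per-row unit of every Weibull row (the
    published fits do not state their unit; years is the packaged default).
    """
    if path is None:
        ref = resources.files(_DATA_PACKAGE).joinpath(PARAMETER_TABLE_FILE)
        with ref.open("r", newline="") as fh:
            return _parse_rows(csv.DictReader(fh), time_unit)
    with open(path, newline="") as fh:
        return _parse_rows(csv.DictReader(fh), time_unit)


def _parse_rows(reader, time_unit: TimeUnit | None) -> dict[str, TransitionSpec]:
    table: dict[str, TransitionSpec] = {}
    for row in reader:
        name = row["name"].strip()
        kind = row["kind"].strip()
        source = (row.get("source") or "").strip()
        if kind == "weibull":
            spec = TransitionSpec(
                name=name,
                kind="weibull",
                weibull=WeibullSpec(
                    rate_lambda=float(row["lambda"]),
                    shape_k=float(row["k"]),
                    time_unit=time_unit or (row.get("time_unit") or "years").strip(),
                ),
                source=source,
            )
        elif kind == "point":
            low = row.get("range_low") or None
            high = row.get("range_high") or None
            spec = TransitionSpec(
                name=name,
                kind="point",
                point=PointProbSpec(
                    value=float(row["value"]),
                    over_period_cycles=float(row.get("over_period_cycles") or 1.0),
                    range_low=float(low) if low else None,
                    range_high=float(high) if high else None,
                ),
                source=source,
            )
        else:
            raise ConfigurationError(f"row {name!r}: unknown kind {kind!r}")
        if name in table:
            raise ConfigurationError(f"duplicate parameter row {name!r}")
        table[name] = spec
    return table
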