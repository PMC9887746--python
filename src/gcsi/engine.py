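"""Original INFORM/GCSI severity-score aggregation.

The published index combines ordinal sub-indicators (0-5) into three pillar
scores and then a final severity value:

* **impact** — weighted sum of a human-impact composite (weight 0.7, the
  mean of up to four sub-indicators, missing ones ignored) and a
  geographic-impact composite (weight 0.3, the mean of two sub-indicators);
* **complexity** — geometric mean of a society-and-safety composite (mean of
  its available sub-indicators) and an operating-environment composite
  (average of a scaled sub-indicator sum and a direct data input);
* **conditions** — arithmetic mean of two sub-indicators derived from the
  distribution of the population over five levels of humanitarian
  conditions: a ranked count of people in levels 3-5, and the highest level
  containing more than 5% of the affected population.

The final severity score is the weighted mean of the three pillar values
with default weights (0.2, 0.3, 0.5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConditionsDistribution",
    "PillarInputs",
    "GcsiScore",
    "ConfigError",
    "impact_pillar",
    "complexity_pillar",
    "conditions_affected_level",
    "conditions_total_score",
    "conditions_pillar",
    "severity_score",
    "DEFAULT_WEIGHTS",
    "DEFAULT_CONDITION_BINS",
    "DEFAULT_CATEGORY_BANDS",
]

DEFAULT_WEIGHTS = (0.2, 0.3, 0.5)

#: Ascending people-count thresholds mapping the levels-3-5 population sum to
#: an ordinal 0-5 score.  The published methodology does not print its ladder
#: in the main text; this powers-of-ten style default is configuration and
#: every worked example passes bins explicitly.
DEFAULT_CONDITION_BINS = (1e4, 1e5, 1e6, 5e6, 2e7)

#: severity -> label bands at 1-unit steps (upper bound inclusive).
DEFAULT_CATEGORY_BANDS = (
    (1.0, "Very Low Severity"),
    (2.0, "Low Severity"),
    (3.0, "Medium Severity"),
    (4.0, "High Severity"),
    (5.0, "Very High Severity"),
)


class ConfigError(ValueError):
    """Invalid aggregation configuration (weights, bins, bands)."""


def _available(values: Sequence[float | None]) -> list[float]:
    return [float(v) for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]


@dataclass(frozen=True)
class ConditionsDistribution:
    """Population distribution over the five humanitarian-conditions levels.

    ``shares[l]`` is the fraction of the population at level ``l`` (1-5,
    level 1 = none/minor need, level 5 = extreme need).  ``counts`` holds
    absolute numbers per level when known.  Shares may sum to less than one
    (unclassified remainder).
    """

    shares: dict[int, float] = field(default_factory=dict)
    counts: dict[int, float] | None = None
    population_total: float | None = None

    def __post_init__(self) -> None:
        for lvl, s in self.shares.items():
            if lvl not in (1, 2, 3, 4, 5):
                raise ValueError(f"level {lvl} outside 1-5")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"share {s} for level {lvl} outside [0, 1]")
        if sum(self.shares.values()) > 1.0 + 1e-9:
            raise ValueError("shares sum to more than 1")
        if self.counts is not None and self.population_total:
            for lvl, c in self.counts.items():
                s = self.shares.get(lvl)
                if s is not None and abs(c - s * self.population_total) > 0.5 + 1e-6 * self.population_total:
                    raise ValueError(f"count for level {lvl} inconsistent with share x total")


@dataclass(frozen=True)
class PillarInputs:
    """Raw sub-indicator values feeding one crisis's three pillar scores.

    Missing sub-indicators are ``None`` (or NaN) and are ignored during
    aggregation, mirroring the published treatment of unavailable inputs.
    """

    human_impact_subs: Sequence[float | None] = ()
    geographic_subs: Sequence[float | None] = ()
    society_safety_subs: Sequence[float | None] = ()
    operating_env_subs: Sequence[float | None] = ()
    operating_env_data_input: float | None = None
    conditions_total_dist: ConditionsDistribution | None = None
    conditions_affected_dist: ConditionsDistribution | None = None

    def __post_init__(self) -> None:
        for group in (self.human_impact_subs, self.geographic_subs, self.society_safety_subs):
            for v in _available(group):
                if not 0.0 <= v <= 5.0:
                    raise ValueError(f"sub-indicator value {v} outside [0, 5]")


@dataclass(frozen=True)
class GcsiScore:
    """Pillar values, weights and the aggregated severity score."""

    impact: float
    complexity: float
    conditions: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    severity: float = float("nan")
    category: str | None = None


# ---------------------------------------------------------------------------
# pillar aggregations


def impact_pillar(inputs: PillarInputs) -> float:
    """Impact of the crisis: 0.7 x human composite + 0.3 x geographic composite.

    Each composite is the mean of its available sub-indicators; missing
    values are ignored.
    """
    human = _available(inputs.human_impact_subs)
    if not human:
        raise ValueError("no human-impact sub-indicator available")
    geo = _available(inputs.geographic_subs)
    if not geo:
        raise ValueError("no geographic-impact sub-indicator available")
    return 0.7 * float(np.mean(human)) + 0.3 * float(np.mean(geo))


def operating_environment_composite(
    subs: Sequence[float | None],
    data_input: float | None,
    *,
    sub_scale_max: float = 3.0,
) -> float:
    """Operating-environment composite: average of a sub-indicator aggregate
    and a direct data input.

    The sub-indicator aggregate is a plain sum for up to two contributing
    variables and a sum rescaled linearly to 0-5 — ``sum / (k * scale_max) * 5``
    for ``k`` contributing variables — when more than two contribute.
    """
    vals = _available(subs)
    if not vals and data_input is None:
        raise ValueError("operating environment has no available components")
    parts: list[float] = []
    if vals:
        total = float(sum(vals))
        if len(vals) > 2:
            total = total / (len(vals) * sub_scale_max) * 5.0
        parts.append(min(total, 5.0))
    if data_input is not None:
        parts.append(float(data_input))
    return float(np.mean(parts))


def complexity_pillar(inputs: PillarInputs) -> float:
    """Complexity of the crisis: geometric mean of the society-and-safety and
    operating-environment composites.

    A zero composite yields 0 with a warning (the geometric mean collapses).
    """
    ss_vals = _available(inputs.society_safety_subs)
    if not ss_vals:
        raise ValueError("no society-and-safety sub-indicator available")
    ss = float(np.mean(ss_vals))
    oe = operating_environment_composite(inputs.operating_env_subs, inputs.operating_env_data_input)
    return geometric_mean_pair(ss, oe)


def geometric_mean_pair(a: float, b: float) -> float:
    if a < 0 or b < 0:
        raise ValueError("composites must be non-negative")
    if (a == 0) != (b == 0):
        warnings.warn("geometric mean degenerate: one composite is zero", stacklevel=2)
    return math.sqrt(a * b)


def conditions_affected_level(
    dist: ConditionsDistribution, threshold: float = 0.05
) -> int:
    """Highest humanitarian-conditions level holding strictly more than
    ``threshold`` of the affected population (default 5%); 1 if none does."""
    if not dist.shares or all(s == 0 for s in dist.shares.values()):
        raise ValueError("distribution has no positive share")
    qualifying = [lvl for lvl, s in dist.shares.items() if s > threshold]
    return max(qualifying) if qualifying else 1


def conditions_total_score(
    dist: ConditionsDistribution,
    bins: Sequence[float] = DEFAULT_CONDITION_BINS,
) -> int:
    """Ordinal 0-5 rank of the number of people in levels 3-5.

    The sum enters bin ``b`` only when it strictly exceeds the ``b``-th
    threshold, so a sum exactly on a threshold stays in the lower bin.
    """
    bins = tuple(bins)
    if list(bins) != sorted(bins) or len(set(bins)) != len(bins):
        raise ConfigError("bins must be strictly ascending")
    if dist.counts is None:
        raise ValueError("distribution lacks absolute counts")
    try:
        total = sum(float(dist.counts[lvl]) for lvl in (3, 4, 5))
    except KeyError as e:
        raise ValueError(f"missing count for level {e.args[0]}") from e
    return int(sum(total > b for b in bins))


def conditions_pillar(inputs: PillarInputs, *, bins: Sequence[float] = DEFAULT_CONDITION_BINS,
                      threshold: float = 0.05) -> float:
    """Conditions of the people: mean of the ranked total-population count and
    the >5%-rule level of the affected population."""
    if inputs.conditions_total_dist is None or inputs.conditions_affected_dist is None:
        raise ValueError("both conditions distributions are required")
    total = conditions_total_score(inputs.conditions_total_dist, bins)
    affected = conditions_affected_level(inputs.conditions_affected_dist, threshold)
    return (total + affected) / 2.0


def severity_score(
    impact: float,
    complexity: float,
    conditions: float,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    *,
    category_bands: Sequence[tuple[float, str]] | None = DEFAULT_CATEGORY_BANDS,
) -> GcsiScore:
    """Weighted mean of the three pillar values (weights must sum to 1)."""
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigError(f"weights {weights} do not sum to 1")
    sev = weights[0] * impact + weights[1] * complexity + weights[2] * conditions
    category = None
    if category_bands is not None:
        for upper, label in category_bands:
            if sev <= upper + 1e-12:
                category = label
                break
        else:
            category = category_bands[-1][1]
    return GcsiScore(impact, complexity, conditions, tuple(weights), sev, category)
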