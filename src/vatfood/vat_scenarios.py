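"""VAT schedules, policy scenarios and tax-to-price conversion.

A :class:`VATSchedule` holds one country's value-added-tax rates per food
group together with the country's maximum (standard) rate.  Policy scenarios
rewrite group rates — zero-rating fruits and vegetables, raising meat and
dairy to the maximum rate, or both — and :func:`price_change` converts a rate
change into a relative consumer-price change under a configurable degree of
tax pass-through.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CATEGORIES",
    "SCENARIOS",
    "VATSchedule",
    "ScenarioSpec",
    "aggregate_item_rates",
    "build_scenario",
    "price_change",
]

#: Primary food-category labels.  ``red_meat`` and ``meat`` are sub-groupings
#: of ``MD`` used by the sensitivity scenarios and are tracked separately on
#: the schedule, so every group carries exactly one primary label.
CATEGORIES = frozenset({"MD", "FV", "other"})

SCENARIOS = (
    "baseline",
    "zero_fv",
    "max_md",
    "combo",
    "max_meat_combo",
    "max_redmeat_combo",
)

# Conventional group membership used when a schedule does not specify its own.
DEFAULT_RED_MEAT = frozenset({"beef", "lamb", "pork"})
DEFAULT_MEAT = DEFAULT_RED_MEAT | {"poultry"}


@dataclass(frozen=True)
class VATSchedule:
    """Per-country VAT rates by food group.

    Parameters
    ----------
    country:
        Country identifier.
    group_rates:
        Mapping food group -> VAT rate as a fraction (0.21 for 21%).
    max_rate:
        The country's standard/maximum VAT rate (fraction).
    category_map:
        Mapping food group -> primary category in ``{"MD", "FV", "other"}``.
    red_meat_groups, meat_groups:
        Sub-groupings of MD targeted by the sensitivity scenarios.  Default
        to the conventional memberships intersected with the schedule's
        groups.
    """

    country: str
    group_rates: dict[str, float]
    max_rate: float
    category_map: dict[str, str]
    red_meat_groups: frozenset[str] = field(default=None)  # type: ignore[assignment]
    meat_groups: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.max_rate < 0:
            raise ValueError(f"{self.country}: max_rate must be >= 0")
        for g, t in self.group_rates.items():
            if t < 0:
                raise ValueError(f"{self.country}/{g}: negative VAT rate {t}")
            if t > self.max_rate + 1e-12:
                raise ValueError(
                    f"{self.country}/{g}: rate {t} exceeds max_rate {self.max_rate}"
                )
        for g in self.group_rates:
            cat = self.category_map.get(g)
            if cat is None:
                raise ValueError(f"{self.country}/{g}: missing category label")
            if cat not in CATEGORIES:
                raise ValueError(f"{self.country}/{g}: unknown category {cat!r}")
        groups = frozenset(self.group_rates)
        if self.red_meat_groups is None:
            object.__setattr__(self, "red_meat_groups", DEFAULT_RED_MEAT & groups)
        if self.meat_groups is None:
            object.__setattr__(self, "meat_groups", DEFAULT_MEAT & groups)

    def groups_in_category(self, category: str) -> list[str]:
        return [g for g in self.group_rates if self.category_map[g] == category]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named VAT policy scenario with a tax pass-through fraction."""

    name: str
    passthrough: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIOS}"
            )
        if not 0.0 <= self.passthrough <= 1.0:
            raise ValueError("passthrough must lie in [0, 1]")


def aggregate_item_rates(
    item_rates: list[tuple[str, float, float]],
    mapping: dict[str, str],
) -> dict[str, float]:
    """Aggregate item-level VAT rates to food-group rates.

    Each group's rate is the weight-weighted mean of its member items' rates
    (weights are consumption or expenditure weights).  Groups that no item
    maps to are simply absent from the result.

    Raises
    ------
    ValueError
        If an item id is missing from ``mapping``, a rate is outside [0, 1],
        a weight is negative, or a group's weights sum to zero.
    """
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for item, rate, weight in item_rates:
        if item not in mapping:
            raise ValueError(f"item {item!r} has no food-group mapping")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"item {item!r}: rate {rate} outside [0, 1]")
        if weight < 0:
            raise ValueError(f"item {item!r}: negative weight {weight}")
        g = mapping[item]
        num[g] = num.get(g, 0.0) + weight * rate
        den[g] = den.get(g, 0.0) + weight
    out: dict[str, float] = {}
    for g in num:
        if den[g] == 0.0:
            raise ValueError(f"group {g!r}: all member item weights are zero")
        out[g] = num[g] / den[g]
    return out


def build_scenario(schedule: VATSchedule, spec: ScenarioSpec) -> VATSchedule:
    """Apply a policy scenario to a schedule, returning a new schedule.

    ``zero_fv`` zero-rates the FV category; ``max_md`` raises the MD category
    to the country maximum; ``combo`` does both; ``max_meat_combo`` and
    ``max_redmeat_combo`` restrict the rate increase to the meat / red-meat
    groups while still zero-rating FV.  ``baseline`` returns an identical
    copy.  The operation is idempotent.
    """
    rates = dict(schedule.group_rates)
    name = spec.name
    if name == "baseline":
        return replace(schedule, group_rates=rates)

    zero_fv = name in {"zero_fv", "combo", "max_meat_combo", "max_redmeat_combo"}
    if name == "max_md":
        raised = set(schedule.groups_in_category("MD"))
    elif name == "combo":
        raised = set(schedule.groups_in_category("MD"))
    elif name == "max_meat_combo":
        raised = set(schedule.meat_groups)
    elif name == "max_redmeat_combo":
        raised = set(schedule.red_meat_groups)
    else:
        raised = set()

    for g in rates:
        if g in raised:
            rates[g] = schedule.max_rate
        elif zero_fv and schedule.category_map[g] == "FV":
            rates[g] = 0.0
    return replace(schedule, group_rates=rates)


def price_change(t_old: float, t_new: float, passthrough: float = 1.0) -> float:
    """Relative consumer-price change implied by a VAT rate change.

    With the tax-exclusive price held fixed, the gross price moves from
    ``1 + t_old`` to ``1 + t_old + passthrough * (t_new - t_old)``; the
    return value is the relative change of the gross price.  Full
    pass-through (the default) and a zero baseline rate give a price change
    equal to the rate change itself.
    """
    if t_old < 0 or t_new < 0:
        raise ValueError("VAT rates must be >= 0")
    if not 0.0 <= passthrough <= 1.0:
        raise ValueError("passthrough must lie in [0, 1]")
    return (1.0 + t_old + passthrough * (t_new - t_old)) / (1.0 + t_old) - 1.0
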