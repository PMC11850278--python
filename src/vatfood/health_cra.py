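"""Comparative risk assessment (CRA) for diet- and weight-related mortality.

Demand changes are converted to intake changes via food-waste shares, intake
changes shift relative risks for dietary risk factors (red meat harmful;
fruits, vegetables, nuts and legumes protective, each with a theoretical
minimum-risk exposure level, TMREL), and energy-intake changes shift the
population BMI distribution across the underweight / normal / overweight /
obese categories.  Per cause, the mortality ratio (MR) is the product of the
risk-factor MRs; averted deaths are ``mortality * (1 - MR)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "CAUSES",
    "BMI_CATEGORIES",
    "BMIDistribution",
    "intake_from_demand",
    "mortality_ratio",
    "weight_category_shift",
    "bmi_mortality_ratio",
    "combine_mortality_ratios",
    "averted_deaths",
]

#: The five disease endpoints: coronary heart disease, stroke, type-2
#: diabetes mellitus, cancer (aggregate) and respiratory disease.
CAUSES = ("CHD", "stroke", "T2DM", "cancer", "respiratory")

BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")


@dataclass(frozen=True)
class BMIDistribution:
    """Normal approximation of a population's BMI distribution.

    ``cutoffs`` are the category boundaries (under/normal, normal/over,
    over/obese) in kg m^-2; ``mean_height`` converts weight changes to BMI
    changes.
    """

    mean_bmi: float
    sd_bmi: float
    mean_height: float
    cutoffs: tuple[float, float, float] = (18.5, 25.0, 30.0)

    def __post_init__(self) -> None:
        if self.sd_bmi <= 0:
            raise ValueError("sd_bmi must be > 0")
        if self.mean_height <= 0:
            raise ValueError("mean_height must be > 0")
        c = self.cutoffs
        if not (c[0] < c[1] < c[2]):
            raise ValueError("cutoffs must be strictly increasing")

    def prevalences(self, shift: float = 0.0) -> np.ndarray:
        """Category prevalences after shifting the mean by ``shift`` kg m^-2."""
        cdf = norm.cdf(np.asarray(self.cutoffs), self.mean_bmi + shift, self.sd_bmi)
        return np.array([cdf[0], cdf[1] - cdf[0], cdf[2] - cdf[1], 1.0 - cdf[2]])


def intake_from_demand(q: np.ndarray, waste_share: np.ndarray) -> np.ndarray:
    """Food intake from demand, discounting the share wasted: q*(1-waste)."""
    q = np.asarray(q, dtype=float)
    waste = np.asarray(waste_share, dtype=float)
    if np.any(waste < 0) or np.any(waste >= 1):
        raise ValueError("waste shares must lie in [0, 1)")
    return q * (1.0 - waste)


def mortality_ratio(
    rr_unit: float,
    unit_size: float,
    x_base: float,
    x_scen: float,
    tmrel: float,
    harmful: bool | None = None,
) -> float:
    """Mortality ratio from an intake change under a log-linear dose-response.

    ``rr_unit`` is the relative risk per ``unit_size`` g d^-1 of intake.  For
    protective factors (RR < 1) intake is capped at the TMREL from above
    (``min(x, tmrel)``: no extra credit beyond it); for harmful factors
    (RR > 1) intake is floored at the TMREL (``max(x, tmrel)``: no risk
    credited below it).  MR = rr_unit ** ((clip(x_scen) - clip(x_base)) /
    unit_size); equal clipped intakes give MR = 1 exactly.
    """
    if rr_unit <= 0:
        raise ValueError("relative risk must be > 0")
    if unit_size <= 0:
        raise ValueError("unit_size must be > 0")
    if x_base < 0 or x_scen < 0:
        raise ValueError("intakes must be >= 0")
    if harmful is None:
        harmful = rr_unit > 1.0
    clip = (lambda x: max(x, tmrel)) if harmful else (lambda x: min(x, tmrel))
    delta = clip(x_scen) - clip(x_base)
    if delta == 0.0:
        return 1.0
    return float(rr_unit ** (delta / unit_size))


def weight_category_shift(
    delta_kcal: float,
    k: float,
    dist: BMIDistribution,
) -> tuple[np.ndarray, np.ndarray]:
    """BMI-category prevalences before and after an energy-intake change.

    A sustained change of ``delta_kcal`` kcal d^-1 moves steady-state body
    weight by ``k * delta_kcal`` kg, hence mean BMI by ``k * delta_kcal /
    height^2``; the distribution is shifted with its spread unchanged.

    Returns ``(prev_base, prev_scen)`` over the four BMI categories.
    """
    d_bmi = k * delta_kcal / dist.mean_height**2
    return dist.prevalences(0.0), dist.prevalences(d_bmi)


def bmi_mortality_ratio(
    prev_base: np.ndarray,
    prev_scen: np.ndarray,
    rr_by_category: np.ndarray,
) -> float:
    """MR contribution of the BMI shift for one cause.

    Ratio of RR-weighted prevalences, scenario over baseline; the normal
    category carries RR = 1 by convention.
    """
    prev_base = np.asarray(prev_base, dtype=float)
    prev_scen = np.asarray(prev_scen, dtype=float)
    rr = np.asarray(rr_by_category, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("BMI-category relative risks must be > 0")
    return float((prev_scen @ rr) / (prev_base @ rr))


def combine_mortality_ratios(mrs: list[float] | np.ndarray) -> float:
    """Combined MR across independent risk factors: the product of the MRs."""
    mrs = np.asarray(mrs, dtype=float)
    if mrs.size == 0:
        return 1.0
    if np.any(mrs <= 0):
        raise ValueError("mortality ratios must be > 0")
    return float(np.prod(mrs))


def averted_deaths(
    mortality: dict[str, float],
    combined_mr: dict[str, float],
    population: float,
) -> tuple[dict[str, float], float, float]:
    """Averted deaths by cause, in total, and per million people.

    ``averted_c = mortality_c * (1 - MR_c)``; negative values (added deaths)
    are allowed and propagate into the total.
    """
    if population <= 0:
        raise ValueError("population must be > 0")
    by_cause = {}
    for cause, deaths in mortality.items():
        if deaths < 0:
            raise ValueError(f"negative mortality for {cause}")
        mr = combined_mr[cause]
        if mr <= 0:
            raise ValueError(f"non-positive MR for {cause}")
        by_cause[cause] = deaths * (1.0 - mr)
    total = float(sum(by_cause.values()))
    return by_cause, total, total * 1e6 / population
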