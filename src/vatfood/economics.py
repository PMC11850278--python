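"""Diet costs, VAT revenue and monetized social costs.

Producer (tax-exclusive) prices are held fixed across scenarios — no
supply-side response — so all consumer-price movement comes from the tax.
Climate damages are valued at the social cost of carbon (default US$185 per
t CO2e) and mortality changes at cause-specific cost-of-illness estimates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DEFAULT_SCC",
    "diet_cost",
    "vat_revenue",
    "climate_damage_savings",
    "health_cost_savings",
    "net_economic_benefit",
]

#: Default social cost of carbon, currency per t CO2e.
DEFAULT_SCC = 185.0


def diet_cost(
    q: np.ndarray, prices_net: np.ndarray, rates: np.ndarray
) -> float:
    """Consumer cost of the diet, currency per person per day.

    ``sum_i q_i[g/d] * 1e-3 * p_net_i[per kg] * (1 + t_i)``.
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(prices_net, dtype=float)
    t = np.asarray(rates, dtype=float)
    if not (q.shape == p.shape == t.shape):
        raise ValueError("q, prices_net and rates must have equal length")
    return float((q * 1e-3 * p * (1.0 + t)).sum())


def vat_revenue(
    q: np.ndarray,
    prices_net: np.ndarray,
    rates: np.ndarray,
    population: float,
    gdp: float | None = None,
    days: float = 365.0,
) -> tuple[float, float | None]:
    """National annual VAT revenue from food, and optionally % of GDP.

    Revenue is the tax wedge on consumer expenditure:
    ``sum_i q_i * 1e-3 * p_net_i * t_i * population * days``.
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(prices_net, dtype=float)
    t = np.asarray(rates, dtype=float)
    if np.any(t < 0):
        raise ValueError("VAT rates must be >= 0")
    revenue = float((q * 1e-3 * p * t).sum() * population * days)
    if gdp is None:
        return revenue, None
    if gdp <= 0:
        raise ValueError("gdp must be > 0")
    return revenue, 100.0 * revenue / gdp


def climate_damage_savings(delta_ghg_t: float, scc: float = DEFAULT_SCC) -> float:
    """Avoided climate damages, currency per year.

    ``delta_ghg_t`` is the emissions change in t CO2e per year; a fall in
    emissions (negative delta) yields positive savings.
    """
    if scc < 0:
        raise ValueError("social cost of carbon must be >= 0")
    return -delta_ghg_t * scc


def health_cost_savings(
    averted_by_cause: dict[str, float], coi: dict[str, float]
) -> float:
    """Avoided cost of illness: sum over causes of averted deaths x unit cost."""
    total = 0.0
    for cause, averted in averted_by_cause.items():
        if averted != 0.0 and cause not in coi:
            raise ValueError(f"missing cost-of-illness estimate for {cause!r}")
        total += averted * coi.get(cause, 0.0)
    return total


def net_economic_benefit(
    delta_revenue: float, climate_savings: float, health_savings: float
) -> dict[str, float]:
    """Net benefit and its breakdown: revenue + climate + health components."""
    return {
        "revenue": delta_revenue,
        "climate": climate_savings,
        "health": health_savings,
        "net": delta_revenue + climate_savings + health_savings,
    }
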