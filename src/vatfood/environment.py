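"""Environmental footprint accounting and carbon-price equivalence.

Per-capita demand is coupled to per-kg footprints for four endpoints —
greenhouse-gas emissions (kg CO2e kg^-1), land use (m^2 kg^-1), freshwater
use (L kg^-1) and eutrophication potential (g PO4^3- e kg^-1) — and scaled
to national annual totals.  Totals are reported in Mt CO2e, km^2, km^3 and
t PO4^3- e respectively.  The carbon-price equivalence search finds the
ad valorem-equivalent carbon price whose demand response reproduces a given
percentage reduction in total GHG emissions.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = [
    "ENDPOINTS",
    "ENDPOINT_UNITS",
    "total_impact",
    "impact_change",
    "carbon_price_equivalent",
]

ENDPOINTS = ("ghg", "land", "water", "eutrophication")

#: Output units and the conversion from the per-kg footprint unit scaled by
#: kg of food:  GHG kg -> Mt (1e-9), land m^2 -> km^2 (1e-6),
#: water L -> km^3 (1e-12), eutrophication g -> t (1e-6).
ENDPOINT_UNITS = {
    "ghg": ("Mt CO2e", 1e-9),
    "land": ("km2", 1e-6),
    "water": ("km3", 1e-12),
    "eutrophication": ("t PO4e", 1e-6),
}


def total_impact(
    q: np.ndarray,
    footprints: dict[str, np.ndarray],
    population: float,
    days: float = 365.0,
) -> dict[str, float]:
    """National annual impact per endpoint from per-capita daily demand.

    ``impact_e = sum_i q_i[g/d] * 1e-3 [kg/g] * f_ie * population * days``,
    converted to the endpoint's reporting unit.

    Raises if any endpoint's footprint vector is missing, misaligned or
    negative where demand is positive.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("demand must be >= 0")
    out: dict[str, float] = {}
    for e in ENDPOINTS:
        if e not in footprints:
            raise ValueError(f"missing footprint endpoint {e!r}")
        f = np.asarray(footprints[e], dtype=float)
        if f.shape != q.shape:
            raise ValueError(f"footprint vector for {e!r} misaligned with demand")
        if np.any(~np.isfinite(f) & (q > 0)) or np.any(np.isnan(f) & (q > 0)):
            raise ValueError(f"missing footprint value for a demanded group ({e})")
        _, scale = ENDPOINT_UNITS[e]
        out[e] = float((q * 1e-3 * f).sum() * population * days * scale)
    return out


def impact_change(
    base: dict[str, float], scen: dict[str, float]
) -> dict[str, tuple[float, float]]:
    """Absolute and percentage change per endpoint: (scen - base, 100*Δ/base).

    A zero baseline with a non-zero scenario value yields ``nan`` percent,
    flagging the undefined ratio without hiding the absolute change.
    """
    out = {}
    for e, b in base.items():
        d = scen[e] - b
        if b != 0.0:
            pct = 100.0 * d / b
        else:
            pct = 0.0 if d == 0.0 else float("nan")
        out[e] = (d, pct)
    return out


def carbon_price_equivalent(
    target_pct_reduction: float,
    reduction_fn: Callable[[float], float],
    bracket: tuple[float, float] = (0.0, 1000.0),
    rel_tol: float = 1e-3,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Carbon price reproducing a target percentage reduction in emissions.

    ``reduction_fn(tau)`` must return the percentage reduction in total GHG
    emissions (positive = lower emissions) achieved by a carbon price of
    ``tau`` currency per t CO2e applied to consumer prices.  The price is
    found by bisection on ``bracket`` until the achieved reduction is within
    ``rel_tol`` (relative) of the target.

    Returns ``(tau, achieved_reduction_pct)``.
    """
    lo, hi = bracket
    if target_pct_reduction < 0:
        raise ValueError("target reduction must be >= 0")
    if target_pct_reduction == 0.0:
        return 0.0, float(reduction_fn(0.0))
    r_hi = reduction_fn(hi)
    r_lo = reduction_fn(lo)
    if not (r_lo <= target_pct_reduction <= r_hi):
        raise ValueError(
            f"target {target_pct_reduction}% not bracketed: achievable range "
            f"[{r_lo:.4g}%, {r_hi:.4g}%] on tau in [{lo}, {hi}]"
        )
    tau = 0.5 * (lo + hi)
    achieved = reduction_fn(tau)
    for _ in range(max_iter):
        if abs(achieved - target_pct_reduction) <= rel_tol * target_pct_reduction:
            return tau, achieved
        if achieved < target_pct_reduction:
            lo = tau
        else:
            hi = tau
        tau = 0.5 * (lo + hi)
        achieved = reduction_fn(tau)
    return tau, achieved
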