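"""Scenario orchestration: per-country runs and European aggregation.

``run_scenario`` executes, for every country, the full chain

    build_scenario -> price changes -> calibrated demand response ->
    intake / energy changes -> comparative risk assessment ->
    environmental footprints -> costs and revenues

and appends a population-aggregated ``EU`` row.  National totals (deaths,
emissions, currency per year) aggregate by summation; per-capita levels and
percentage changes aggregate as population-weighted means.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import economics, environment, health_cra
from .datasets import Dataset
from .demand_system import (
    ElasticityMatrix,
    calibrate_elasticities,
    demand_response,
    energy_and_mass_changes,
)
from .environment import ENDPOINTS
from .health_cra import CAUSES
from .vat_scenarios import ScenarioSpec, build_scenario, price_change

__all__ = [
    "run_scenario",
    "calibrate_all",
    "population_weighted_average",
    "carbon_price_for_reduction",
    "share_of_change",
]

log = logging.getLogger("vatfood")

EU_KEY = "EU"

#: Columns that aggregate by summation (national totals per year, deaths).
_ADDITIVE = [
    "averted_total",
    *(f"averted_{c}" for c in CAUSES),
    "d_revenue",
    "revenue_base",
    "climate_savings",
    "health_savings",
    "net_benefit",
    "population",
]


def population_weighted_average(values, populations) -> float:
    """Population-weighted mean: sum(v_c * pop_c) / sum(pop_c)."""
    v = np.asarray(values, dtype=float)
    p = np.asarray(populations, dtype=float)
    if v.shape != p.shape:
        raise ValueError("values and populations differ in length")
    if np.any(p <= 0):
        raise ValueError("populations must be > 0")
    return float((v * p).sum() / p.sum())


def calibrate_all(
    dataset: Dataset, method: str = "projection"
) -> dict[str, ElasticityMatrix]:
    """Calibrated elasticity matrices per country, cached on the dataset."""
    cache = getattr(dataset, "_calibration_cache", None)
    if cache is None:
        cache = {}
        dataset._calibration_cache = cache
    if method not in cache:
        out = {}
        for c in dataset.countries:
            t0 = time.perf_counter()
            out[c] = calibrate_elasticities(dataset.elasticity_prior(c), method=method)
            log.debug(
                "calibrated %s method=%s in %.1f ms",
                c, method, 1e3 * (time.perf_counter() - t0),
            )
        cache[method] = out
    return cache[method]


def _category_mask(dataset: Dataset, category: str) -> np.ndarray:
    return np.array([dataset.category_map[g] == category for g in dataset.groups])


def run_scenario(
    dataset: Dataset,
    spec: ScenarioSpec,
    method: str = "projection",
    response_form: str = "loglinear",
) -> pd.DataFrame:
    """Run one policy scenario for every country and aggregate to EU level.

    Returns a results table indexed by country (plus an ``EU`` row) with
    demand, energy, environmental, health and economic deltas.  The
    ``baseline`` scenario yields exactly zero in every delta column.
    """
    dataset.validate()
    calibrated = calibrate_all(dataset, method=method)
    md_mask = _category_mask(dataset, "MD")
    fv_mask = _category_mask(dataset, "FV")
    fp_vectors = dataset.footprint_vectors()
    groups = dataset.groups

    rows = {}
    for c in dataset.countries:
        t_start = time.perf_counter()
        sched0 = dataset.schedule_for(c)
        sched1 = build_scenario(sched0, spec)
        t0 = np.array([sched0.group_rates[g] for g in groups])
        t1 = np.array([sched1.group_rates[g] for g in groups])
        pc = np.array(
            [price_change(a, b, spec.passthrough) for a, b in zip(t0, t1)]
        )
        dlnp = np.log1p(pc)

        E = calibrated[c]
        q0 = dataset.demand.loc[c, groups].to_numpy(float)
        q1 = demand_response(q0, dlnp, E, form=response_form)
        dmass, dkcal_demand = energy_and_mass_changes(
            q0, q1, dataset.kcal_per_g[groups].to_numpy(float)
        )

        waste = dataset.waste_share[groups].to_numpy(float)
        intake0 = health_cra.intake_from_demand(q0, waste)
        intake1 = health_cra.intake_from_demand(q1, waste)
        _, dkcal_intake = energy_and_mass_changes(
            intake0, intake1, dataset.kcal_per_g[groups].to_numpy(float)
        )

        # --- comparative risk assessment
        risk = dataset.risk
        gidx = {g: i for i, g in enumerate(groups)}
        mr_by_factor: dict[str, dict[str, float]] = {}
        for f in risk.factors:
            idx = [gidx[g] for g in risk.factor_groups[f]]
            x0, x1 = float(intake0[idx].sum()), float(intake1[idx].sum())
            mr_by_factor[f] = {
                cause: health_cra.mortality_ratio(
                    float(risk.rr_unit.loc[f, cause]),
                    float(risk.unit_size[f]),
                    x0,
                    x1,
                    float(risk.tmrel[f]),
                    harmful=bool(risk.harmful[f]),
                )
                for cause in CAUSES
            }
        prev0, prev1 = health_cra.weight_category_shift(
            dkcal_intake, risk.k_kcal, dataset.bmi_distribution(c)
        )
        mr_by_factor["bmi"] = {
            cause: health_cra.bmi_mortality_ratio(
                prev0, prev1, risk.bmi_rr[cause].to_numpy(float)
            )
            for cause in CAUSES
        }
        combined = {
            cause: health_cra.combine_mortality_ratios(
                [mr_by_factor[f][cause] for f in mr_by_factor]
            )
            for cause in CAUSES
        }
        mortality_c = {
            cause: float(dataset.mortality.loc[c, cause]) for cause in CAUSES
        }
        pop = float(dataset.population[c])
        by_cause, total_averted, per_million = health_cra.averted_deaths(
            mortality_c, combined, pop
        )
        # single-factor attribution (factor alone, others at baseline)
        averted_by_factor = {
            f: sum(
                mortality_c[cause] * (1.0 - mr_by_factor[f][cause])
                for cause in CAUSES
            )
            for f in mr_by_factor
        }

        # --- environment
        imp0 = environment.total_impact(q0, fp_vectors, pop)
        imp1 = environment.total_impact(q1, fp_vectors, pop)
        dimp = environment.impact_change(imp0, imp1)

        # --- economics (producer prices fixed; consumer price reflects
        # pass-through, the statutory rate defines the tax wedge)
        p_net = dataset.prices_net.loc[c, groups].to_numpy(float)
        gross0 = 1.0 + t0
        gross1 = 1.0 + t0 + spec.passthrough * (t1 - t0)
        cost0 = economics.diet_cost(q0, p_net, gross0 - 1.0)
        cost1 = economics.diet_cost(q1, p_net, gross1 - 1.0)
        gdp = float(dataset.gdp[c])
        # ratio first so an unchanged schedule leaves producer prices exact
        p_prod1 = p_net * (gross1 / (1.0 + t1))
        rev0, _ = economics.vat_revenue(q0, p_net, t0, pop, gdp)
        rev1, _ = economics.vat_revenue(q1, p_prod1, t1, pop, gdp)
        d_rev = rev1 - rev0

        d_ghg_t = dimp["ghg"][0] * 1e6  # Mt -> t
        climate = economics.climate_damage_savings(d_ghg_t, dataset.scc)
        health = economics.health_cost_savings(
            by_cause, {k: float(v) for k, v in dataset.coi.loc[c].items()}
        )
        benefit = economics.net_economic_benefit(d_rev, climate, health)

        spend0 = q0 * p_net * gross0
        row = {"population": pop}
        for label, mask in (("md", md_mask), ("fv", fv_mask)):
            w_spend = spend0[mask]
            base = q0[mask].sum()
            row[f"demand_{label}_base"] = base
            row[f"d_demand_{label}_g"] = dmass[mask].sum()
            row[f"d_demand_{label}_pct"] = 100.0 * dmass[mask].sum() / base
            row[f"d_vat_{label}_pp"] = 100.0 * float(
                (t1 - t0)[mask] @ w_spend / w_spend.sum()
            )
            row[f"d_price_{label}_pct"] = 100.0 * float(
                pc[mask] @ w_spend / w_spend.sum()
            )
        row["d_kcal_demand"] = dkcal_demand
        row["d_kcal_intake"] = dkcal_intake
        for e in ENDPOINTS:
            row[f"{e}_base"] = imp0[e]
            row[f"d_{e}"] = dimp[e][0]
            row[f"d_{e}_pct"] = dimp[e][1]
        row["averted_total"] = total_averted
        row["averted_per_million"] = per_million
        for cause in CAUSES:
            row[f"averted_{cause}"] = by_cause[cause]
        for f, v in averted_by_factor.items():
            row[f"averted_factor_{f}"] = v
        row["diet_cost_base"] = cost0
        row["d_diet_cost"] = cost1 - cost0
        row["d_diet_cost_pct"] = 100.0 * (cost1 - cost0) / cost0
        row["revenue_base"] = rev0
        row["d_revenue"] = d_rev
        if rev0 > 0:
            row["d_revenue_pct"] = 100.0 * d_rev / rev0
        else:  # zero tax base: no change is 0%, any change is undefined
            row["d_revenue_pct"] = 0.0 if d_rev == 0.0 else float("nan")
        row["d_revenue_pct_gdp"] = 100.0 * d_rev / gdp
        row["climate_savings"] = climate
        row["health_savings"] = health
        row["net_benefit"] = benefit["net"]
        rows[c] = row
        log.debug(
            "%s scenario=%s done in %.1f ms", c, spec.name,
            1e3 * (time.perf_counter() - t_start),
        )

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "country"

    pops = table["population"].to_numpy(float)
    eu = {}
    for col in table.columns:
        if col in _ADDITIVE:
            eu[col] = float(table[col].sum())
        else:
            eu[col] = population_weighted_average(table[col].to_numpy(float), pops)
    # ratio quantities recomputed from EU totals rather than averaged
    eu["averted_per_million"] = eu["averted_total"] * 1e6 / eu["population"]
    for e in ENDPOINTS:
        eu[f"{e}_base"] = float(table[f"{e}_base"].sum())
        eu[f"d_{e}"] = float(table[f"d_{e}"].sum())
        eu[f"d_{e}_pct"] = 100.0 * eu[f"d_{e}"] / eu[f"{e}_base"]
    eu["d_revenue_pct"] = 100.0 * eu["d_revenue"] / eu["revenue_base"]
    eu["d_revenue_pct_gdp"] = 100.0 * eu["d_revenue"] / float(dataset.gdp.sum())
    for f in list(dataset.risk.factors) + ["bmi"]:
        eu[f"averted_factor_{f}"] = float(table[f"averted_factor_{f}"].sum())
    table.loc[EU_KEY] = pd.Series(eu)
    table.insert(0, "scenario", spec.name)
    return table


def carbon_price_for_reduction(
    dataset: Dataset,
    target_pct_reduction: float,
    method: str = "projection",
    bracket: tuple[float, float] = (0.0, 1000.0),
    rel_tol: float = 1e-3,
) -> tuple[float, float]:
    """European carbon price equivalent to a target % GHG reduction.

    The carbon price ``tau`` (currency per t CO2e) is passed through to
    consumer prices ad valorem-equivalently (``dlnp_i = ln(1 + tau * f_i *
    1e-3 / p_gross_i)``), demand responds through each country's calibrated
    elasticities, and total European food-related GHG emissions are compared
    with baseline.
    """
    calibrated = calibrate_all(dataset, method=method)
    groups = dataset.groups
    fghg = dataset.footprints.loc[groups, "ghg"].to_numpy(float)
    per_country = []
    base_total = 0.0
    for c in dataset.countries:
        q0 = dataset.demand.loc[c, groups].to_numpy(float)
        p_gross = dataset.prices_gross(c)
        pop = float(dataset.population[c])
        base = float((q0 * 1e-3 * fghg).sum() * pop * 365.0)
        per_country.append((q0, p_gross, calibrated[c], pop))
        base_total += base

    def reduction_fn(tau: float) -> float:
        scen_total = 0.0
        for q0, p_gross, E, pop in per_country:
            dlnp = np.log1p(tau * fghg * 1e-3 / p_gross)
            q1 = demand_response(q0, dlnp, E)
            scen_total += float((q1 * 1e-3 * fghg).sum() * pop * 365.0)
        return 100.0 * (base_total - scen_total) / base_total

    return environment.carbon_price_equivalent(
        target_pct_reduction, reduction_fn, bracket=bracket, rel_tol=rel_tol
    )


def share_of_change(part: float, total: float) -> float:
    """Percentage contribution of one component to a total change."""
    if total == 0.0:
        raise ValueError("total change is zero; share undefined")
    return 100.0 * part / total
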