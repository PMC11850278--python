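"""Seeded generator of a synthetic-Europe input dataset.

The generator emulates the statistical structure of a Europe-wide food-VAT
analysis — roughly 28 countries and 24 food groups, VAT rates spanning 0%
to the high twenties with a mixture of zero-rate, reduced-rate and full-rate
countries, meat-and-dairy (M&D) demand near 745 g person^-1 d^-1 and
fruit-and-vegetable (F&V) demand near 560 g d^-1 on the EU average,
inelastic own-price elasticities, and per-kg greenhouse-gas footprints much
larger for M&D than for F&V.  Two boundary countries are always included:
a "UK-like" country with zero food VAT but a high maximum rate, and a
"DK-like" country that already taxes all foods at its maximum rate.

All draws come from one :class:`numpy.random.Generator` seeded from the
config, so identical configs give byte-identical datasets.  The numbers are
plausible in structure and magnitude but are synthetic throughout; they do
not reproduce any national statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import Dataset, RiskParams
from .health_cra import BMI_CATEGORIES, CAUSES

__all__ = ["SyntheticConfig", "generate_dataset", "generate_elasticity_prior"]

# Ordered so any prefix of >= 10 groups keeps the full M&D and F&V categories.
# Columns: group, category, demand g/d, kcal/g, price /kg, waste share,
#          ghg kgCO2e/kg, land m2/kg, water L/kg, eutrophication gPO4e/kg
_GROUP_TABLE = [
    ("beef", "MD", 50, 2.5, 10.0, 0.12, 30.0, 160.0, 1450.0, 300.0),
    ("lamb", "MD", 10, 2.8, 11.0, 0.12, 25.0, 180.0, 1800.0, 250.0),
    ("pork", "MD", 105, 2.4, 7.0, 0.12, 7.5, 11.0, 600.0, 75.0),
    ("poultry", "MD", 70, 1.7, 6.5, 0.12, 5.5, 7.5, 450.0, 50.0),
    ("milk_dairy", "MD", 510, 0.65, 1.6, 0.10, 2.4, 9.0, 630.0, 11.0),
    ("fruits", "FV", 225, 0.55, 2.2, 0.20, 0.9, 0.9, 950.0, 2.0),
    ("vegetables", "FV", 295, 0.30, 2.4, 0.22, 0.7, 0.4, 330.0, 3.0),
    ("legumes", "FV", 25, 1.1, 2.6, 0.12, 0.9, 7.5, 430.0, 6.0),
    ("nuts", "FV", 15, 6.1, 9.0, 0.08, 2.5, 9.0, 4100.0, 20.0),
    ("roots", "other", 180, 0.80, 1.2, 0.20, 0.45, 0.35, 30.0, 1.5),
    ("wheat", "other", 250, 2.9, 1.5, 0.15, 1.5, 2.7, 650.0, 5.0),
    ("rice", "other", 30, 3.6, 1.8, 0.10, 4.0, 2.8, 2250.0, 35.0),
    ("other_grains", "other", 40, 3.4, 1.6, 0.12, 1.3, 2.5, 500.0, 4.0),
    ("sugar", "other", 90, 4.0, 1.1, 0.08, 1.8, 2.0, 200.0, 4.0),
    ("sweets", "other", 45, 4.6, 5.0, 0.08, 3.0, 3.5, 700.0, 8.0),
    ("vegetable_oils", "other", 40, 8.8, 3.0, 0.05, 3.3, 10.0, 350.0, 12.0),
    ("animal_fats", "other", 15, 7.2, 4.5, 0.05, 9.0, 25.0, 700.0, 40.0),
    ("eggs", "other", 35, 1.4, 3.2, 0.10, 4.2, 5.7, 580.0, 20.0),
    ("fish", "other", 40, 1.3, 8.0, 0.15, 5.0, 3.5, 700.0, 100.0),
    ("beverages", "other", 480, 0.25, 1.0, 0.05, 0.6, 0.5, 150.0, 2.0),
    ("alcohol", "other", 150, 0.55, 3.0, 0.05, 1.2, 1.1, 300.0, 3.0),
    ("coffee_tea", "other", 15, 0.20, 8.0, 0.05, 8.0, 4.0, 600.0, 30.0),
    ("spices", "other", 5, 3.0, 12.0, 0.05, 3.0, 3.5, 500.0, 10.0),
    ("other_foods", "other", 50, 2.0, 3.5, 0.10, 2.0, 2.5, 400.0, 8.0),
]

# Baseline cause-specific diet-related death rates, deaths per person per
# year; CHD-dominant among the five endpoints.
_DEATH_RATES = {
    "CHD": 0.0045,
    "stroke": 0.0017,
    "T2DM": 0.0004,
    "cancer": 0.0028,
    "respiratory": 0.0006,
}

# Cost of illness per death by cause, currency (direct + indirect).
_COI = {
    "CHD": 250_000.0,
    "stroke": 300_000.0,
    "T2DM": 400_000.0,
    "cancer": 350_000.0,
    "respiratory": 150_000.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic-Europe generator.

    ``vat_profile`` gives the mixture weights of zero-rate, reduced-rate and
    full-rate countries (the first two countries are always the UK-like and
    DK-like boundary cases); ``anchors`` are the targeted EU-mean M&D and F&V
    demand levels in g d^-1; ``footprint_ratio`` is the targeted ratio of
    mean per-kg GHG footprints of M&D versus F&V.
    """

    n_countries: int = 28
    n_groups: int = 24
    seed: int = 0
    # One in ~28 European countries zero-rates food outright and about four
    # tax all foods at the maximum rate; the rest apply reduced rates.
    vat_profile: tuple[float, float, float] = (0.04, 0.82, 0.14)
    anchors: dict = field(
        default_factory=lambda: {"md_demand": 745.0, "fv_demand": 560.0}
    )
    footprint_ratio: float = 8.0

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ValueError("need at least 2 countries")
        if not 10 <= self.n_groups <= 24:
            raise ValueError("n_groups must lie in [10, 24]")
        if abs(sum(self.vat_profile) - 1.0) > 1e-9 or min(self.vat_profile) < 0:
            raise ValueError("vat_profile weights must be >= 0 and sum to 1")
        if self.footprint_ratio <= 1:
            raise ValueError("footprint_ratio must exceed 1")


def generate_elasticity_prior(
    n: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random uncalibrated elasticity prior for ``n`` goods.

    Own-price elasticities are negative and inelastic (uniform on
    [-1.2, -0.2]); cross-price priors are small and centred slightly below
    zero, reflecting the income-effect component of uncompensated
    elasticities; income elasticities are positive and below 1.2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(-0.015, 0.012, size=(n, n))
    eps[np.diag_indices(n)] = rng.uniform(-1.2, -0.2, size=n)
    eta = rng.uniform(0.3, 1.1, size=n)
    return eps, eta


def _default_risk_params(groups: list[str]) -> RiskParams:
    """Illustrative relative-risk configuration.

    The values are plausible in sign and magnitude for the listed factors
    and causes but are an illustrative default; study-grade analyses must
    supply their own risk_model.yaml.
    """
    factors = ["red_meat", "fruits", "vegetables", "nuts", "legumes"]
    # Dietary dose-responses are the dominant channel; the BMI-category
    # gradient is kept mild so that weight-mediated effects contribute on
    # the order of a tenth of the total, with fruit and vegetable intake
    # contributing the bulk — the balance the assessment framework assumes.
    rr = pd.DataFrame(
        {
            "CHD": [1.15, 0.92, 0.89, 0.95, 0.96],
            "stroke": [1.12, 0.89, 0.89, 0.97, 0.99],
            "T2DM": [1.20, 0.97, 0.95, 0.96, 0.97],
            "cancer": [1.12, 0.96, 0.94, 0.98, 0.98],
            "respiratory": [1.00, 0.92, 1.00, 1.00, 1.00],
        },
        index=factors,
    )
    bmi_rr = pd.DataFrame(
        {
            "CHD": [1.10, 1.0, 1.06, 1.15],
            "stroke": [1.10, 1.0, 1.05, 1.12],
            "T2DM": [0.95, 1.0, 1.40, 2.00],
            "cancer": [1.05, 1.0, 1.02, 1.08],
            "respiratory": [1.30, 1.0, 1.02, 1.10],
        },
        index=list(BMI_CATEGORIES),
    )
    return RiskParams(
        rr_unit=rr,
        unit_size=pd.Series([100.0, 100.0, 100.0, 28.0, 50.0], index=factors),
        # Protective TMRELs sit above typical European intakes, as in
        # GBD-style risk assessment, so marginal intake increases are credited.
        tmrel=pd.Series([14.0, 325.0, 450.0, 25.0, 90.0], index=factors),
        harmful=pd.Series([True, False, False, False, False], index=factors),
        factor_groups={
            "red_meat": [g for g in ("beef", "lamb", "pork") if g in groups],
            "fruits": ["fruits"],
            "vegetables": ["vegetables"],
            "nuts": ["nuts"],
            "legumes": ["legumes"],
        },
        bmi_rr=bmi_rr,
        k_kcal=0.0454,
    )


def generate_dataset(config: SyntheticConfig | None = None) -> Dataset:
    """Generate a complete, schema-valid synthetic-Europe dataset."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    table = _GROUP_TABLE[: cfg.n_groups]
    groups = [r[0] for r in table]
    category_map = {r[0]: r[1] for r in table}
    md = [g for g in groups if category_map[g] == "MD"]
    fv = [g for g in groups if category_map[g] == "FV"]

    mean_demand = pd.Series({r[0]: float(r[2]) for r in table})
    # soft anchoring of category means to the configured EU levels
    mean_demand[md] *= cfg.anchors["md_demand"] / mean_demand[md].sum()
    mean_demand[fv] *= cfg.anchors["fv_demand"] / mean_demand[fv].sum()
    kcal = pd.Series({r[0]: float(r[3]) for r in table})
    mean_price = pd.Series({r[0]: float(r[4]) for r in table})
    waste = pd.Series({r[0]: float(r[5]) for r in table})

    fp = pd.DataFrame(
        {
            "ghg": [r[6] for r in table],
            "land": [r[7] for r in table],
            "water": [r[8] for r in table],
            "eutrophication": [r[9] for r in table],
        },
        index=groups,
    )
    # rescale M&D GHG footprints to hit the configured M&D:F&V per-kg ratio
    current = fp.loc[md, "ghg"].mean() / fp.loc[fv, "ghg"].mean()
    fp.loc[md, "ghg"] *= cfg.footprint_ratio / current
    fp *= rng.lognormal(0.0, 0.08, size=fp.shape)  # regional sampling noise

    countries = ["UK-like", "DK-like"] + [
        f"C{i:02d}" for i in range(3, cfg.n_countries + 1)
    ]
    profiles = ["zero", "full"] + list(
        rng.choice(["zero", "reduced", "full"], size=cfg.n_countries - 2,
                   p=list(cfg.vat_profile))
    )

    max_rate = pd.Series(
        np.round(rng.uniform(0.17, 0.27, size=cfg.n_countries), 2), index=countries
    )
    max_rate["UK-like"] = 0.20
    max_rate["DK-like"] = 0.25

    vat = pd.DataFrame(0.0, index=countries, columns=groups)
    for c, prof in zip(countries, profiles):
        if prof == "zero":
            continue
        if prof == "full":
            vat.loc[c] = max_rate[c]
            continue
        # reduced-rate country: category-level reduced rates with group jitter
        for cat in ("MD", "FV", "other"):
            level = rng.uniform(0.05, 0.60 * max_rate[c])
            members = [g for g in groups if category_map[g] == cat]
            jitter = rng.uniform(-0.01, 0.01, size=len(members))
            vat.loc[c, members] = np.clip(level + jitter, 0.05, max_rate[c])

    demand = pd.DataFrame(
        mean_demand.to_numpy()
        * rng.lognormal(0.0, 0.15, size=(cfg.n_countries, cfg.n_groups)),
        index=countries,
        columns=groups,
    )
    price_level = rng.lognormal(0.0, 0.10, size=cfg.n_countries)
    prices = pd.DataFrame(
        mean_price.to_numpy()
        * price_level[:, None]
        * rng.lognormal(0.0, 0.08, size=(cfg.n_countries, cfg.n_groups)),
        index=countries,
        columns=groups,
    )

    eps_prior, eta_prior = {}, {}
    for c in countries:
        eps_prior[c], eta_prior[c] = generate_elasticity_prior(cfg.n_groups, rng)

    population = pd.Series(
        np.round(rng.lognormal(np.log(8e6), 1.0, size=cfg.n_countries)),
        index=countries,
    ).clip(lower=4e5)
    gdp_per_capita = rng.uniform(25_000, 55_000, size=cfg.n_countries)
    gdp = population * gdp_per_capita

    mortality = pd.DataFrame(
        {
            cause: _DEATH_RATES[cause]
            * population.to_numpy()
            * rng.lognormal(0.0, 0.15, size=cfg.n_countries)
            for cause in CAUSES
        },
        index=countries,
    )

    bmi = pd.DataFrame(
        {
            "mean_bmi": rng.uniform(25.0, 27.0, size=cfg.n_countries),
            "sd_bmi": rng.uniform(3.8, 4.5, size=cfg.n_countries),
            "mean_height": rng.uniform(1.65, 1.78, size=cfg.n_countries),
        },
        index=countries,
    )

    income_factor = gdp_per_capita / 40_000.0
    coi = pd.DataFrame(
        {cause: _COI[cause] * income_factor for cause in CAUSES}, index=countries
    )

    ds = Dataset(
        groups=groups,
        countries=countries,
        category_map=category_map,
        vat=vat,
        max_rate=max_rate,
        demand=demand,
        prices_net=prices,
        kcal_per_g=kcal,
        waste_share=waste,
        eps_prior=eps_prior,
        eta_prior=eta_prior,
        footprints=fp,
        mortality=mortality,
        population=population,
        gdp=gdp,
        bmi=bmi,
        coi=coi,
        risk=_default_risk_params(groups),
    )
    ds.validate()
    return ds
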