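"""In-memory dataset container and the CSV/YAML on-disk dialect.

A :class:`Dataset` bundles every input table the pipeline needs for a set of
countries sharing one food-group list: VAT schedules, demand, producer
prices, energy densities, waste shares, elasticity priors, regional
footprints, mortality, population, GDP, BMI distributions, cost-of-illness
and risk-model parameters.  ``to_dir``/``from_dir`` round-trip the dataset
through plain delimited text plus two YAML configs so a run can be driven
entirely from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demand_system import ElasticityMatrix
from .environment import ENDPOINTS
from .health_cra import BMI_CATEGORIES, CAUSES, BMIDistribution
from .vat_scenarios import VATSchedule

__all__ = ["RiskParams", "Dataset"]

_INCOME_KEY = "_income"


@dataclass
class RiskParams:
    """Relative-risk parameterization of the comparative risk assessment.

    ``rr_unit`` holds the RR per ``unit_size`` g d^-1 for each dietary risk
    factor and cause; ``factor_groups`` maps each factor to the food groups
    whose intake it tracks; ``bmi_rr`` holds BMI-category RRs versus normal
    weight; ``k_kcal`` is the steady-state body-weight response in kg per
    kcal d^-1 of sustained energy-intake change.
    """

    rr_unit: pd.DataFrame
    unit_size: pd.Series
    tmrel: pd.Series
    harmful: pd.Series
    factor_groups: dict[str, list[str]]
    bmi_rr: pd.DataFrame
    k_kcal: float = 0.0454

    def __post_init__(self) -> None:
        factors = list(self.rr_unit.index)
        for s in (self.unit_size, self.tmrel, self.harmful):
            if list(s.index) != factors:
                raise ValueError("risk-factor indices are misaligned")
        if set(self.rr_unit.columns) != set(CAUSES):
            raise ValueError(f"rr_unit columns must be {CAUSES}")
        if list(self.bmi_rr.index) != list(BMI_CATEGORIES):
            raise ValueError(f"bmi_rr rows must be {BMI_CATEGORIES}")
        for f in factors:
            if f not in self.factor_groups:
                raise ValueError(f"factor {f!r} has no food-group mapping")

    @property
    def factors(self) -> list[str]:
        return list(self.rr_unit.index)


@dataclass
class Dataset:
    """All pipeline inputs for one region of countries."""

    groups: list[str]
    countries: list[str]
    category_map: dict[str, str]
    vat: pd.DataFrame  # country x group, rate fractions
    max_rate: pd.Series  # per country
    demand: pd.DataFrame  # country x group, g person^-1 d^-1
    prices_net: pd.DataFrame  # country x group, currency kg^-1 (tax-exclusive)
    kcal_per_g: pd.Series  # per group
    waste_share: pd.Series  # per group
    eps_prior: dict[str, np.ndarray]  # country -> (n, n)
    eta_prior: dict[str, np.ndarray]  # country -> (n,)
    footprints: pd.DataFrame  # group x endpoint (regional European set)
    mortality: pd.DataFrame  # country x cause, deaths yr^-1
    population: pd.Series
    gdp: pd.Series
    bmi: pd.DataFrame  # country: mean_bmi, sd_bmi, mean_height
    coi: pd.DataFrame  # country x cause, currency per death
    risk: RiskParams
    scc: float = 185.0
    currency: str = "USD-PPP"
    region: str = "Europe"

    # ------------------------------------------------------------------ views
    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def schedule_for(self, country: str) -> VATSchedule:
        return VATSchedule(
            country=country,
            group_rates={g: float(self.vat.loc[country, g]) for g in self.groups},
            max_rate=float(self.max_rate[country]),
            category_map=dict(self.category_map),
        )

    def prices_gross(self, country: str, rates: np.ndarray | None = None) -> np.ndarray:
        """Consumer prices: net prices marked up by the (given) VAT rates."""
        p = self.prices_net.loc[country, self.groups].to_numpy(float)
        t = (
            self.vat.loc[country, self.groups].to_numpy(float)
            if rates is None
            else np.asarray(rates, float)
        )
        return p * (1.0 + t)

    def budget_shares(self, country: str) -> np.ndarray:
        """Food budget shares from baseline demand and gross consumer prices."""
        q = self.demand.loc[country, self.groups].to_numpy(float)
        spend = q * self.prices_gross(country)
        return spend / spend.sum()

    def elasticity_prior(self, country: str) -> ElasticityMatrix:
        return ElasticityMatrix(
            eps=self.eps_prior[country],
            eta=self.eta_prior[country],
            w=self.budget_shares(country),
            group_ids=tuple(self.groups),
        )

    def bmi_distribution(self, country: str) -> BMIDistribution:
        row = self.bmi.loc[country]
        return BMIDistribution(
            mean_bmi=float(row["mean_bmi"]),
            sd_bmi=float(row["sd_bmi"]),
            mean_height=float(row["mean_height"]),
        )

    def footprint_vectors(self) -> dict[str, np.ndarray]:
        return {
            e: self.footprints.loc[self.groups, e].to_numpy(float) for e in ENDPOINTS
        }

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Schema validation; raises ValueError naming country/group context."""
        problems: list[str] = []
        n = self.n_groups
        for c in self.countries:
            for frame, name in ((self.vat, "vat"), (self.demand, "demand"),
                                (self.prices_net, "prices"), (self.mortality, "mortality")):
                if c not in frame.index:
                    problems.append(f"{name}: missing country {c}")
            if c in self.vat.index:
                try:
                    self.schedule_for(c)
                except ValueError as exc:
                    problems.append(str(exc))
            if c not in self.eps_prior or self.eps_prior[c].shape != (n, n):
                problems.append(f"elasticities: bad prior for {c}")
            if c in self.population.index and self.population[c] <= 0:
                problems.append(f"macro: non-positive population for {c}")
        for g in self.groups:
            if g not in self.category_map:
                problems.append(f"category_map: missing group {g}")
            if g not in self.footprints.index:
                problems.append(f"footprints: missing group {g}")
            elif self.footprints.loc[g, list(ENDPOINTS)].isna().any():
                problems.append(f"footprints: incomplete endpoints for {g}")
        if (self.demand.reindex(index=self.countries, columns=self.groups) < 0).any().any():
            problems.append("demand: negative values")
        if problems:
            raise ValueError("dataset validation failed:\n  " + "\n  ".join(problems))

    # --------------------------------------------------------------------- IO
    def to_dir(self, path: str | Path) -> None:
        """Write the dataset as the pipeline's CSV/YAML dialect."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        long_vat = (
            self.vat.loc[self.countries, self.groups]
            .rename_axis("country")
            .reset_index()
            .melt("country", var_name="food_group", value_name="rate")
        )
        long_vat["max_rate"] = long_vat["country"].map(self.max_rate)
        long_vat.to_csv(path / "vat_rates.csv", index=False)

        cat: dict[str, list[str]] = {}
        for g, c in self.category_map.items():
            cat.setdefault(c, []).append(g)
        cat["red_meat"] = [g for g in ("beef", "lamb", "pork") if g in self.groups]
        cat["meat"] = cat["red_meat"] + (["poultry"] if "poultry" in self.groups else [])
        (path / "category_map.yaml").write_text(yaml.safe_dump(cat, sort_keys=True))

        for frame, fname, value in (
            (self.demand, "demand.csv", "demand_g_per_day"),
            (self.prices_net, "prices.csv", "price_net_per_kg"),
        ):
            (
                frame.loc[self.countries, self.groups]
                .rename_axis("country")
                .reset_index()
                .melt("country", var_name="food_group", value_name=value)
                .to_csv(path / fname, index=False)
            )

        pd.DataFrame(
            {
                "food_group": self.groups,
                "kcal_per_g": self.kcal_per_g[self.groups].to_numpy(),
                "waste_share": self.waste_share[self.groups].to_numpy(),
            }
        ).to_csv(path / "food_properties.csv", index=False)

        rows = []
        for c in self.countries:
            eps = self.eps_prior[c]
            for i, gi in enumerate(self.groups):
                for j, gj in enumerate(self.groups):
                    rows.append((c, gi, gj, eps[i, j]))
                rows.append((c, gi, _INCOME_KEY, self.eta_prior[c][i]))
        pd.DataFrame(
            rows, columns=["country", "group_i", "group_j", "eps_prior"]
        ).to_csv(path / "elasticities.csv", index=False)

        unit_by_endpoint = {"ghg": "kgCO2e/kg", "land": "m2/kg",
                            "water": "L/kg", "eutrophication": "gPO4e/kg"}
        (
            self.footprints.loc[self.groups, list(ENDPOINTS)]
            .rename_axis("food_group")
            .reset_index()
            .melt("food_group", var_name="endpoint", value_name="value")
            .assign(
                region=self.region,
                unit=lambda d: d["endpoint"].map(unit_by_endpoint),
            )[["region", "food_group", "endpoint", "value", "unit"]]
            .to_csv(path / "footprints.csv", index=False)
        )

        for frame, fname, value in (
            (self.mortality, "mortality.csv", "deaths_per_year"),
            (self.coi, "coi.csv", "cost_per_death"),
        ):
            (
                frame.loc[self.countries, list(CAUSES)]
                .rename_axis("country")
                .reset_index()
                .melt("country", var_name="cause", value_name=value)
                .to_csv(path / fname, index=False)
            )

        pd.DataFrame(
            {
                "country": self.countries,
                "population": self.population[self.countries].to_numpy(),
                "gdp": self.gdp[self.countries].to_numpy(),
            }
        ).to_csv(path / "macro.csv", index=False)
        self.bmi.loc[self.countries].rename_axis("country").reset_index().to_csv(
            path / "bmi.csv", index=False
        )

        risk = {
            "k_kcal": float(self.risk.k_kcal),
            "factors": {
                f: {
                    "groups": list(self.risk.factor_groups[f]),
                    "unit_size": float(self.risk.unit_size[f]),
                    "tmrel": float(self.risk.tmrel[f]),
                    "harmful": bool(self.risk.harmful[f]),
                    "rr": {c: float(self.risk.rr_unit.loc[f, c]) for c in CAUSES},
                }
                for f in self.risk.factors
            },
            "bmi_rr": {
                cat: {c: float(self.risk.bmi_rr.loc[cat, c]) for c in CAUSES}
                for cat in BMI_CATEGORIES
            },
        }
        (path / "risk_model.yaml").write_text(yaml.safe_dump(risk, sort_keys=True))
        (path / "config.yaml").write_text(
            yaml.safe_dump(
                {"scc": float(self.scc), "currency": self.currency,
                 "region": self.region},
                sort_keys=True,
            )
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "Dataset":
        """Read a dataset previously written with :meth:`to_dir`."""
        path = Path(path)
        vat_long = pd.read_csv(path / "vat_rates.csv")
        countries = list(pd.unique(vat_long["country"]))
        cat_yaml = yaml.safe_load((path / "category_map.yaml").read_text())
        category_map = {
            g: c for c in ("MD", "FV", "other") for g in cat_yaml.get(c, [])
        }
        props = pd.read_csv(path / "food_properties.csv").set_index("food_group")
        groups = list(props.index)

        def wide(fname: str, value: str) -> pd.DataFrame:
            long = pd.read_csv(path / fname)
            return long.pivot(index="country", columns="food_group", values=value)[
                groups
            ]

        vat = vat_long.pivot(index="country", columns="food_group", values="rate")[groups]
        max_rate = vat_long.groupby("country")["max_rate"].first()
        demand = wide("demand.csv", "demand_g_per_day")
        prices = wide("prices.csv", "price_net_per_kg")

        el = pd.read_csv(path / "elasticities.csv")
        gidx = {g: i for i, g in enumerate(groups)}
        eps_prior, eta_prior = {}, {}
        for c, sub in el.groupby("country"):
            eps = np.zeros((len(groups), len(groups)))
            eta = np.zeros(len(groups))
            for _, r in sub.iterrows():
                if r["group_j"] == _INCOME_KEY:
                    eta[gidx[r["group_i"]]] = r["eps_prior"]
                else:
                    eps[gidx[r["group_i"]], gidx[r["group_j"]]] = r["eps_prior"]
            eps_prior[c], eta_prior[c] = eps, eta

        fp = pd.read_csv(path / "footprints.csv").pivot(
            index="food_group", columns="endpoint", values="value"
        )[list(ENDPOINTS)]

        mort = pd.read_csv(path / "mortality.csv").pivot(
            index="country", columns="cause", values="deaths_per_year"
        )[list(CAUSES)]
        coi = pd.read_csv(path / "coi.csv").pivot(
            index="country", columns="cause", values="cost_per_death"
        )[list(CAUSES)]
        macro = pd.read_csv(path / "macro.csv").set_index("country")
        bmi = pd.read_csv(path / "bmi.csv").set_index("country")

        ry = yaml.safe_load((path / "risk_model.yaml").read_text())
        factors = list(ry["factors"])
        risk = RiskParams(
            rr_unit=pd.DataFrame(
                {c: [ry["factors"][f]["rr"][c] for f in factors] for c in CAUSES},
                index=factors,
            ),
            unit_size=pd.Series(
                {f: ry["factors"][f]["unit_size"] for f in factors}
            ).loc[factors],
            tmrel=pd.Series({f: ry["factors"][f]["tmrel"] for f in factors}).loc[factors],
            harmful=pd.Series(
                {f: ry["factors"][f]["harmful"] for f in factors}
            ).loc[factors],
            factor_groups={f: ry["factors"][f]["groups"] for f in factors},
            bmi_rr=pd.DataFrame(
                {c: [ry["bmi_rr"][cat][c] for cat in BMI_CATEGORIES] for c in CAUSES},
                index=list(BMI_CATEGORIES),
            ),
            k_kcal=float(ry["k_kcal"]),
        )
        cfg = yaml.safe_load((path / "config.yaml").read_text())

        ds = cls(
            groups=groups,
            countries=countries,
            category_map=category_map,
            vat=vat,
            max_rate=max_rate,
            demand=demand,
            prices_net=prices,
            kcal_per_g=props["kcal_per_g"],
            waste_share=props["waste_share"],
            eps_prior=eps_prior,
            eta_prior=eta_prior,
            footprints=fp,
            mortality=mort,
            population=macro["population"],
            gdp=macro["gdp"],
            bmi=bmi,
            coi=coi,
            risk=risk,
            scc=float(cfg["scc"]),
            currency=cfg["currency"],
            region=cfg.get("region", "Europe"),
        )
        return ds
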