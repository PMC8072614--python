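"""The experiment layer: economic values, the scenario catalog, and runners.

Selection pressure on feed efficiency enters a ten-trait index in three ways
per novel trait (DMI or RFI): holding its genetic gain at zero (C), positive
(favorable) pressure (P) and negative pressure (N), each additionally run
with conservative correlations shrunk toward zero by one standard error
(_SD), plus a no-pressure baseline (BASE / BASE_SD) — 14 scenarios — and
four more that double to quintuple the RFI economic weight (RFI_P2..P5).

Economic values follow v = R - C with C = C1 * DMP1 for production traits
(revenue per kg minus feed cost of producing the kg) and, for the intake
traits, the feed cost of a 1 kg/day change over a 305-day lactation
(C1 * 305 = 88.45 CAD at C1 = 0.29). Health and fertility traits carry
literature values with negative sign; stature is held at zero response in
every scenario by optimising its economic value.

Each scenario builds its breeding goal, solves the GEBV index, converts
per-round responses to annual responses through the four selection pathways,
and prices the annual monetary gain with discounted gene-flow expressions.
Absolute monetary outputs are model-relative (the synthetic core-trait
correlations and this package's own discounting define them); printed-table
contrasts run against the embedded published report fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gene_flow as gf
from . import selection_index as si
from .params import (
    NOVEL_TRAITS,
    TRAIT_ORDER,
    CorrelationSet,
    ParameterError,
    TraitParams,
    shrink_toward_zero,
)
from .synthetic_data import generate_core_correlations

LACTATION_DAYS = 305

#: literature economic values (CAD per trait unit), applied with negative
#: sign because the goal reduces disease incidence and fertility intervals
HEALTH_FERTILITY_VALUES = {"AFS": 2.57, "FSTC": 6.86, "CK": 233.00, "DA": 707.00}

#: traits whose economic value is optimised to zero response in every run
HELD_TYPE_TRAITS = ("STAT",)

SDU_HOLD_TOL = 0.005

REPORT_COLUMNS = list(TRAIT_ORDER) + ["total_cad"]


@dataclass(frozen=True)
class EconomicValueSpec:
    """Revenue/cost constants for one production trait."""

    revenue: float           # CAD per kg product
    dm_cost: float           # CAD per kg DM (C1)
    dm_per_kg: float         # kg DM per kg product (DMP1)
    lactation_days: int = LACTATION_DAYS

    def __post_init__(self) -> None:
        if min(self.revenue, self.dm_cost, self.dm_per_kg,
               self.lactation_days) < 0:
            raise ParameterError("economic constants must be >= 0")


FAT_SPEC = EconomicValueSpec(revenue=10.76, dm_cost=0.29, dm_per_kg=6.00)
PROTEIN_SPEC = EconomicValueSpec(revenue=8.23, dm_cost=0.29, dm_per_kg=3.70)


def production_economic_value(spec: EconomicValueSpec) -> float:
    """v = R - C1 * DMP1 (CAD per kg)."""
    return spec.revenue - spec.dm_cost * spec.dm_per_kg


def intake_economic_value(dm_cost: float = 0.29,
                          lactation_days: int = LACTATION_DAYS) -> float:
    """Feed cost of a 1 kg/day intake change over a lactation (magnitude);
    the scenario assigns the sign (+ on DMI, - on RFI for favorable
    pressure, reversed for unfavorable)."""
    return dm_cost * lactation_days


@dataclass(frozen=True)
class Scenario:
    """One entry of the catalog."""

    name: str
    novel_trait: str | None          # "DMI", "RFI" or None (BASE)
    treatment: str                   # "none" | "hold" | "positive" | "negative"
    correlations: str = "estimated"  # "estimated" | "se-shrunk"
    multiplier: int = 1

    def __post_init__(self) -> None:
        if self.novel_trait not in (None, *NOVEL_TRAITS):
            raise ParameterError(f"unknown novel trait {self.novel_trait!r}")
        if self.treatment not in ("none", "hold", "positive", "negative"):
            raise ParameterError(f"unknown treatment {self.treatment!r}")
        if self.correlations not in ("estimated", "se-shrunk"):
            raise ParameterError(f"unknown correlation variant {self.correlations!r}")
        if self.multiplier < 1:
            raise ParameterError("multiplier must be >= 1")

    def novel_economic_value(self, dm_cost: float = 0.29) -> float:
        """Signed economic value this scenario puts on its novel trait."""
        if self.novel_trait is None or self.treatment in ("none", "hold"):
            return 0.0
        mag = intake_economic_value(dm_cost) * self.multiplier
        favorable = +1.0 if self.novel_trait == "DMI" else -1.0
        return favorable * mag if self.treatment == "positive" else -favorable * mag

    @property
    def held_traits(self) -> tuple[str, ...]:
        held = list(HELD_TYPE_TRAITS)
        if self.treatment == "hold" and self.novel_trait is not None:
            held.append(self.novel_trait)
        return tuple(held)


def scenario_catalog(config: dict | None = None) -> list[Scenario]:
    """The 14 published scenarios plus the four RFI weight multiples."""
    cat: list[Scenario] = []
    for variant, tag in (("estimated", ""), ("se-shrunk", "_SD")):
        cat.append(Scenario(f"BASE{tag}", None, "none", variant))
        for trait in NOVEL_TRAITS:
            for code, treatment in (("C", "hold"), ("P", "positive"),
                                    ("N", "negative")):
                cat.append(Scenario(f"{trait}_{code}{tag}", trait, treatment,
                                    variant))
    for k in (2, 3, 4, 5):
        cat.append(Scenario(f"RFI_P{k}", "RFI", "positive", "estimated",
                            multiplier=k))
    names = [s.name for s in cat]
    if len(names) != len(set(names)):
        raise ParameterError("duplicate scenario names in catalog")
    return cat


@dataclass
class ScenarioResult:
    """Annual responses and the total monetary index response."""

    scenario: Scenario
    traits: tuple[str, ...]
    annual_units: np.ndarray        # trait units per year
    annual_sdu: np.ndarray          # genetic-SD units per year
    monetary_total: float           # CAD, model-relative
    goal_values: np.ndarray         # economic values actually used
    index_accuracy: float
    held: tuple[str, ...]

    def as_series(self) -> pd.Series:
        s = pd.Series(self.annual_sdu, index=list(self.traits))
        s["total_cad"] = self.monetary_total
        s.name = self.scenario.name
        return s


def default_goal_values(spec_overrides: dict | None = None) -> dict[str, float]:
    """Baseline economic values (CAD per trait unit) before scenario logic."""
    values = {t: 0.0 for t in TRAIT_ORDER}
    values["FY"] = production_economic_value(FAT_SPEC)
    values["PY"] = production_economic_value(PROTEIN_SPEC)
    for trait, mag in HEALTH_FERTILITY_VALUES.items():
        values[trait] = -mag
    if spec_overrides:
        values.update(spec_overrides)
    return values


def default_config() -> dict:
    """Config sections: economics, gene_flow, population, report."""
    return {
        "economics": {
            "dm_cost": 0.29,
            "goal_overrides": {},
        },
        "gene_flow": {
            "discount_rate": 0.05,
            "horizon_years": 15,
            "expressing_classes": ["C2", "C3", "C4"],
        },
        "correlations": {
            "seed": 2021,
            "magnitude_bounds": [0.0, 0.30],
        },
        "report": {"decimals": 2},
    }


def load_config(path) -> dict:
    """YAML config merged over :func:`default_config`."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for section, content in user.items():
        if isinstance(content, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(content)
        else:
            cfg[section] = content
    return cfg


def run_scenario(
    s: Scenario,
    params: list[TraitParams],
    corr: CorrelationSet,
    flow: gf.AlleleFlowMatrix | None = None,
    pathways: gf.PathwaySpec | None = None,
    config: dict | None = None,
) -> ScenarioResult:
    """Solve one scenario end to end.

    ``corr`` must be a complete correlation set (synthetic core block filled)
    on the estimated scale; the scenario's SE-shrunk variant is derived here.
    Held traits (stature, plus the novel trait in hold scenarios) get their
    economic values from the joint zero-response solve.
    """
    if not corr.is_complete():
        raise ParameterError(
            f"scenario {s.name}: correlation set still has unfilled cells; "
            "run generate_core_correlations first")
    cfg = config or default_config()
    flow = flow or gf.build_flow_matrix()
    pathways = pathways or gf.default_pathways()

    used_corr = corr if s.correlations == "estimated" else shrink_toward_zero(corr)
    rg = used_corr.rg

    dm_cost = cfg["economics"]["dm_cost"]
    values = default_goal_values(cfg["economics"].get("goal_overrides"))
    if s.novel_trait is not None:
        values[s.novel_trait] = s.novel_economic_value(dm_cost)
    goal = si.BreedingGoal(tuple(TRAIT_ORDER),
                           np.array([values[t] for t in TRAIT_ORDER]))

    matrices = si.build_gebv_index_matrices(params, rg)
    goal = si.solve_holding_economic_values(matrices, goal, s.held_traits)
    sol = si.solve_index_weights(matrices, goal)

    sigma_g = np.array([p.sigma_g for p in params])
    per_round = {
        k: si.selection_intensity(pathways.proportions[k]) * sol.response_per_intensity
        for k in gf.PATHWAYS
    }
    annual = gf.aggregate_annual_response(per_round, pathways.intervals)

    gfc = cfg["gene_flow"]
    expressions = gf.discounted_expressions(
        flow, gfc["expressing_classes"], gfc["discount_rate"],
        gfc["horizon_years"])
    monetary = float(np.sum(goal.values * annual) * expressions)

    return ScenarioResult(
        scenario=s,
        traits=tuple(TRAIT_ORDER),
        annual_units=annual,
        annual_sdu=annual / sigma_g,
        monetary_total=monetary,
        goal_values=goal.values.copy(),
        index_accuracy=sol.accuracy,
        held=s.held_traits,
    )


def run_catalog(
    params: list[TraitParams],
    corr: CorrelationSet,
    scenarios: list[Scenario] | None = None,
    config: dict | None = None,
) -> list[ScenarioResult]:
    """Run every scenario of the catalog on one correlation structure."""
    scenarios = scenarios if scenarios is not None else scenario_catalog()
    flow = gf.build_flow_matrix()
    pathways = gf.default_pathways()
    return [run_scenario(s, params, corr, flow, pathways, config)
            for s in scenarios]


def weight_scaling_experiment(
    params: list[TraitParams],
    corr: CorrelationSet,
    multipliers: tuple[int, ...] = (1, 2, 3, 4, 5),
    config: dict | None = None,
) -> pd.DataFrame:
    """Responses under increasing positive pressure on RFI (RFI_P..RFI_P5).

    Returns one row per multiplier with per-trait annual SDU responses, the
    RFI economic value used, and the monetary total.
    """
    rows = []
    for k in multipliers:
        name = "RFI_P" if k == 1 else f"RFI_P{k}"
        s = Scenario(name, "RFI", "positive", "estimated", multiplier=k)
        res = run_scenario(s, params, corr, config=config)
        row = res.as_series()
        row["multiplier"] = k
        row["rfi_economic_value"] = s.novel_economic_value()
        rows.append(row)
    return pd.DataFrame(rows)


def cumulative_response(
    annual_response: float,
    generations: int,
    mode: str = "compound",
    base_mean: float = 23.0,
) -> float:
    """Cumulative per-day intake change after ``generations`` rounds.

    Linear mode accumulates the same absolute gain each round; compound mode
    applies the per-round relative gain to the compounded base (kg DM/day on
    a base mean intake). Multiply by 305 for the per-lactation total (see
    :func:`dm_per_lactation`).
    """
    if generations < 0:
        raise ParameterError("generations must be >= 0")
    if mode == "linear":
        return float(generations * annual_response)
    if mode == "compound":
        rate = annual_response / base_mean
        return float(base_mean * ((1.0 + rate) ** generations - 1.0))
    raise ParameterError(f"unknown mode {mode!r}")


def dm_per_lactation(per_day: float, days: int = LACTATION_DAYS) -> float:
    """Convert a per-day DM change to a per-lactation total (kg DM/305 d)."""
    return per_day * days


def load_reported_responses() -> pd.DataFrame:
    """The published per-scenario response table (SDU and CAD), embedded as a
    fixture for contrast operations."""
    path = Path(str(resources.files("feedsel").joinpath(
        "data", "reported_responses.csv")))
    return pd.read_csv(path, index_col="scenario")


def table_contrasts(report: pd.DataFrame, a: str, b: str) -> pd.Series:
    """Element-wise differences (scenario a minus scenario b), rounded to
    the report's 2-decimal precision."""
    for name in (a, b):
        if name not in report.index:
            raise ParameterError(f"unknown scenario {name!r} in report")
    diff = report.loc[a] - report.loc[b]
    return diff.round(2)


def results_to_report(results: list[ScenarioResult],
                      decimals: int = 2) -> pd.DataFrame:
    if not results:
        raise ParameterError("need at least one scenario result")
    df = pd.DataFrame([r.as_series() for r in results])
    df.index.name = "scenario"
    return df.loc[:, REPORT_COLUMNS].round(decimals)


def write_report(results: list[ScenarioResult] | pd.DataFrame, path,
                 decimals: int = 2) -> pd.DataFrame:
    """Write the per-scenario report CSV (trait SDU columns + total CAD)."""
    if isinstance(results, pd.DataFrame):
        df = results.loc[:, REPORT_COLUMNS].round(decimals)
    else:
        df = results_to_report(results, decimals)
    df.to_csv(path, float_format=f"%.{decimals}f")
    return df


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="scenario")
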