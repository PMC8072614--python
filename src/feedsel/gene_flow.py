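"""Gene flow through the sex-by-age class structure of the breeding program.

The population is tracked in ten classes — bulls of ages 1-5 (B1..B5) and
cows of ages 1-5 (C1..C5) — with a yearly transition matrix whose entry
p_ij is the proportion of alleles in class i at time t that come from class
j at time t-1. Newborn rows mix half sire-source and half dam-source genes;
every other row is pure ageing (a single unit entry one class younger).

The default structure mirrors a large genomically driven dairy program:
30,000 genotyped bull calves of which 2,100 (7%) become genomic bulls used
for three years; 100 of those (5%) graduate to proven bulls with 100
daughter records, active two further years; 500,000 heifer calves of which
425,000 (85%) enter the milking herd for three lactations and 50,000 (10%)
become elite bull dams. Elite dams are mated exclusively to genomic bulls;
the milking herd 70% to genomic and 30% to proven bulls.

Gene-flow propagation, discounted trait expressions and the classic
four-pathway (Rendel-Robertson) aggregation of per-round responses into
annual responses live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ParameterError

CLASS_LABELS: tuple[str, ...] = (
    "B1", "B2", "B3", "B4", "B5", "C1", "C2", "C3", "C4", "C5",
)

PATHWAYS: tuple[str, ...] = (
    "sires_of_sires", "sires_of_dams", "dams_of_sires", "dams_of_dams",
)


@dataclass(frozen=True)
class PopulationStructure:
    """Counts and retention rules of the modelled breeding program."""

    n_bull_calves: int = 30_000
    n_genomic_bulls: int = 2_100
    n_proven_bulls: int = 100
    daughter_records_per_proven: int = 100
    genomic_bull_years: tuple[int, ...] = (2, 3, 4)   # bull age classes in use
    proven_bull_years: tuple[int, ...] = (4, 5)
    n_heifer_calves: int = 500_000
    n_milking: int = 425_000
    n_lactations: int = 3
    n_elite_females: int = 50_000
    cow_parent_years: tuple[int, ...] = (2, 3, 4, 5)  # cow age classes as dams
    frac_elite_to_genomic: float = 1.0
    frac_herd_to_genomic: float = 0.70

    def __post_init__(self) -> None:
        for frac in (self.frac_elite_to_genomic, self.frac_herd_to_genomic):
            if not 0 < frac <= 1:
                raise ParameterError("mating fractions must lie in (0, 1]")
        for p in (self.p_genomic, self.p_proven, self.p_elite, self.p_milking):
            if not 0 < p <= 1:
                raise ParameterError("derived proportions must lie in (0, 1]")

    @property
    def p_genomic(self) -> float:
        """Selected proportion bull calves -> genomic bulls (printed 7%)."""
        return self.n_genomic_bulls / self.n_bull_calves

    @property
    def p_proven(self) -> float:
        """Selected proportion genomic -> proven bulls (printed 5%)."""
        return self.n_proven_bulls / self.n_genomic_bulls

    @property
    def p_elite(self) -> float:
        """Selected proportion heifer calves -> elite bull dams (10%)."""
        return self.n_elite_females / self.n_heifer_calves

    @property
    def p_milking(self) -> float:
        """Proportion of heifer calves entering the milking herd (85%)."""
        return self.n_milking / self.n_heifer_calves


@dataclass
class AlleleFlowMatrix:
    """Row-stochastic 10x10 transition over (bull, cow) x age classes."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.values
        if tuple(m.index) != CLASS_LABELS or tuple(m.columns) != CLASS_LABELS:
            raise ParameterError(f"classes must be labelled {CLASS_LABELS}")
        a = m.to_numpy(dtype=float)
        if a.min() < 0 or a.max() > 1:
            raise ParameterError("flow entries must lie in [0, 1]")
        rows = a.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 0.005):
            raise ParameterError(
                f"rows must sum to 1 within 0.005, got {rows}")

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def unit_vector(self, cls: str) -> np.ndarray:
        v = np.zeros(len(CLASS_LABELS))
        v[CLASS_LABELS.index(cls)] = 1.0
        return v


def load_printed_flow_matrix() -> AlleleFlowMatrix:
    """The published allele-flow matrix (rounded to 3 decimals)."""
    path = Path(str(resources.files("feedsel").joinpath("data", "allele_flow.csv")))
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    return AlleleFlowMatrix(values=df.astype(float))


def build_flow_matrix(
    structure: PopulationStructure | None = None,
) -> AlleleFlowMatrix:
    """Construct the allele-flow matrix from the population structure.

    Newborn bulls (B1): sired entirely by genomic bulls (elite-dam matings),
    0.5 split equally over the genomic bull age classes; dams are the elite
    cows, 0.5 split equally over the cow parent classes. Newborn cows (C1):
    sires mix genomic and proven bulls by the herd mating fractions; dams
    are milking cows over the same parent classes. Ageing rows carry a unit
    entry from the class one year younger. Rows sum to exactly 1.
    """
    s = structure or PopulationStructure()
    idx = list(CLASS_LABELS)
    m = pd.DataFrame(0.0, index=idx, columns=idx)

    # B1: sires-of-sires and dams-of-sires
    for age in s.genomic_bull_years:
        m.loc["B1", f"B{age}"] += 0.5 * s.frac_elite_to_genomic / len(s.genomic_bull_years)
    if s.frac_elite_to_genomic < 1.0:
        for age in s.proven_bull_years:
            m.loc["B1", f"B{age}"] += 0.5 * (1 - s.frac_elite_to_genomic) / len(s.proven_bull_years)
    for age in s.cow_parent_years:
        m.loc["B1", f"C{age}"] += 0.5 / len(s.cow_parent_years)

    # C1: sires-of-dams (genomic/proven mix) and dams-of-dams
    for age in s.genomic_bull_years:
        m.loc["C1", f"B{age}"] += 0.5 * s.frac_herd_to_genomic / len(s.genomic_bull_years)
    for age in s.proven_bull_years:
        m.loc["C1", f"B{age}"] += 0.5 * (1 - s.frac_herd_to_genomic) / len(s.proven_bull_years)
    for age in s.cow_parent_years:
        m.loc["C1", f"C{age}"] += 0.5 / len(s.cow_parent_years)

    for sex in "BC":
        sire_cols = [c for c in idx if c.startswith("B")]
        got = m.loc[f"{sex}1", sire_cols].sum()
        if abs(got - 0.5) > 1e-9:
            raise ParameterError(
                f"{sex}1 sire-side weights sum to {got:.6f}, expected 0.5")

    # ageing rows
    for sex in "BC":
        for age in range(2, 6):
            m.loc[f"{sex}{age}", f"{sex}{age - 1}"] = 1.0

    return AlleleFlowMatrix(values=m)


def propagate_gene_flow(
    flow: AlleleFlowMatrix, m0: np.ndarray, t: int
) -> np.ndarray:
    """Apply the flow matrix ``t`` times: m_t tracks, per class, the fraction
    of genes descending from the genes marked in ``m0``."""
    if t < 0:
        raise ParameterError("t must be >= 0")
    m0 = np.asarray(m0, dtype=float)
    if m0.shape != (len(CLASS_LABELS),):
        raise ParameterError(f"m0 must have length {len(CLASS_LABELS)}")
    if m0.min() < 0 or m0.max() > 1:
        raise ParameterError("m0 entries must lie in [0, 1]")
    out = m0.copy()
    p = flow.matrix
    for _ in range(t):
        out = p @ out
    return out


def discounted_expressions(
    flow: AlleleFlowMatrix,
    expressing_classes,
    rate: float,
    horizon: int,
    m0: np.ndarray | None = None,
) -> float:
    """Discounted number of trait expressions per selection round.

    Sums, over years u = 0..horizon, the fraction of the marked genes sitting
    in the expressing classes at year u, discounted by (1+rate)^-u. ``m0``
    marks the genes of the newly selected group (default: a newborn female,
    class C1). At rate 0 this is the plain total of expressions within the
    horizon.
    """
    if rate < 0:
        raise ParameterError("discount rate must be >= 0")
    if horizon < 1:
        raise ParameterError("horizon must be >= 1")
    expressing_classes = list(expressing_classes)
    if not expressing_classes:
        warnings.warn("empty expressing class set; returning 0", stacklevel=2)
        return 0.0
    unknown = set(expressing_classes) - set(CLASS_LABELS)
    if unknown:
        raise ParameterError(f"unknown classes {sorted(unknown)}")
    if m0 is None:
        m0 = flow.unit_vector("C1")
    h = np.isin(CLASS_LABELS, expressing_classes).astype(float)
    total = 0.0
    state = np.asarray(m0, dtype=float)
    for u in range(horizon + 1):
        total += float(h @ state) / (1.0 + rate) ** u
        state = flow.matrix @ state
    return total


@dataclass(frozen=True)
class PathwaySpec:
    """Selection criteria of the four classic pathways.

    ``proportion`` is the selected fraction (drives intensity),
    ``interval_years`` the generation interval L of the pathway.
    """

    proportions: dict = field(default_factory=dict)
    intervals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(PATHWAYS) - set(self.proportions) | set(PATHWAYS) - set(self.intervals)
        if missing:
            raise ParameterError(f"pathway spec incomplete: missing {sorted(missing)}")
        for k in PATHWAYS:
            if not 0 < self.proportions[k] <= 1:
                raise ParameterError(f"{k}: proportion must lie in (0, 1]")
            if self.intervals[k] <= 0:
                raise ParameterError(f"{k}: interval must be > 0")


def default_pathways(structure: PopulationStructure | None = None) -> PathwaySpec:
    """Pathway proportions from the printed counts; intervals from the age
    classes (genomic bulls used at ages 2-4 -> mean parent age 3; proven
    bulls at 4-5 -> 4.5; cows calving at ages 2-4 -> 3)."""
    s = structure or PopulationStructure()
    mean = lambda xs: sum(xs) / len(xs)
    l_genomic = mean(s.genomic_bull_years)
    l_proven = mean(s.proven_bull_years)
    l_cow = mean([a for a in s.cow_parent_years][: s.n_lactations])
    return PathwaySpec(
        proportions={
            "sires_of_sires": s.p_genomic,
            "sires_of_dams": s.p_genomic,
            "dams_of_sires": s.p_elite,
            "dams_of_dams": s.p_milking,
        },
        intervals={
            "sires_of_sires": l_genomic,
            "sires_of_dams": (s.frac_herd_to_genomic * l_genomic
                              + (1 - s.frac_herd_to_genomic) * l_proven),
            "dams_of_sires": l_cow,
            "dams_of_dams": l_cow,
        },
    )


def aggregate_annual_response(
    pathway_responses: dict, intervals: dict
) -> np.ndarray:
    """Four-pathway annual response: sum of per-round responses over the sum
    of generation intervals (Rendel-Robertson)."""
    keys = list(pathway_responses)
    if set(keys) != set(PATHWAYS):
        raise ParameterError(f"expected pathways {PATHWAYS}")
    total_l = float(sum(intervals[k] for k in keys))
    if total_l <= 0:
        raise ParameterError("total generation interval must be > 0")
    num = np.sum([np.asarray(pathway_responses[k], dtype=float) for k in keys],
                 axis=0)
    return num / total_l
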