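"""Domain types for the HTD decision pipeline: the 37-variable catalog, the
seven-region map, the directed influence pathway, and the country-year panel.

The pipeline studies high temperature-related diseases (HTDs): disease burden
attributable to high ambient temperature, split into five causes
(cardiovascular, infectious respiratory, injuries, metabolic, non-infectious
respiratory) whose sum is the total HTD burden. Thirty-one input variables
(11 influence factors, 8 key variables, 12 intervention measures) drive the
five cause-specific burdens through a directed acyclic influence pathway.
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

# ---------------------------------------------------------------------------
# Constants: roles, causes, regions
# ---------------------------------------------------------------------------

ROLE_INFLUENCE = "influence_factor"
ROLE_KEY = "key_variable"
ROLE_INTERVENTION = "intervention"
ROLE_INTERMEDIATE = "intermediate_outcome"
ROLE_FINAL = "final_outcome"
ROLES = (ROLE_INFLUENCE, ROLE_KEY, ROLE_INTERVENTION, ROLE_INTERMEDIATE, ROLE_FINAL)

#: The five cause-specific HTD burdens (intermediate outcomes).
CAUSES = (
    "cardiovascular_burden",
    "infectious_respiratory_burden",
    "injuries_burden",
    "metabolic_burden",
    "non_infectious_respiratory_burden",
)

#: The final outcome: the sum of the five cause-specific burdens.
TOTAL_BURDEN = "total_htd_burden"

#: Targets accepted by the optimizer: each cause or the total.
TARGETS = CAUSES + (TOTAL_BURDEN,)

#: The seven World Bank regions used to segment every optimization result.
REGIONS = (
    "East Asia and Pacific",
    "Europe and Central Asia",
    "Latin America and The Caribbean",
    "Middle East and North Africa",
    "North America",
    "South Asia",
    "Sub-Saharan Africa",
)

YEAR_MIN, YEAR_MAX = 2010, 2019


# ---------------------------------------------------------------------------
# VariableSpec / VariableCatalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """One variable of the panel.

    ``benefit_direction`` is only meaningful for interventions: +1 means the
    measure is applied by increasing the variable, -1 by decreasing it, in
    the direction anticipated to reduce the disease burden. ``disease_mask``
    is the subset of the five causes the intervention may affect; it shrinks
    the valid package space for cause-specific searches.
    """

    name: str
    role: str
    units: str = ""
    benefit_direction: int = 0  # +1 / -1 for interventions, 0 otherwise
    category: str = "none"  # mitigation | adaptation | none
    subcategory: str = ""
    disease_mask: frozenset[str] = field(default_factory=lambda: frozenset(CAUSES))

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.role == ROLE_INTERVENTION:
            if self.benefit_direction not in (-1, 1):
                raise ValueError(f"intervention {self.name!r} needs benefit_direction ±1")
            if not self.disease_mask:
                raise ValueError(f"intervention {self.name!r} needs a nonempty disease_mask")
        if not self.disease_mask <= set(CAUSES):
            raise ValueError(f"disease_mask of {self.name!r} contains unknown causes")


class VariableCatalog:
    """Ordered collection of :class:`VariableSpec` with role-based access."""

    def __init__(self, specs: Iterable[VariableSpec]):
        self._specs = list(specs)
        names = [s.name for s in self._specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in catalog")
        self._by_name = {s.name: s for s in self._specs}

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSpec:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs]

    def by_role(self, role: str) -> list[str]:
        return [s.name for s in self._specs if s.role == role]

    @property
    def influence_factors(self) -> list[str]:
        return self.by_role(ROLE_INFLUENCE)

    @property
    def key_variables(self) -> list[str]:
        return self.by_role(ROLE_KEY)

    @property
    def interventions(self) -> list[str]:
        return self.by_role(ROLE_INTERVENTION)

    @property
    def intermediate_outcomes(self) -> list[str]:
        return self.by_role(ROLE_INTERMEDIATE)

    @property
    def final_outcome(self) -> str:
        (name,) = self.by_role(ROLE_FINAL)
        return name

    @property
    def inputs(self) -> list[str]:
        """The 31 model inputs: influence factors + key variables + interventions."""
        return [
            s.name
            for s in self._specs
            if s.role in (ROLE_INFLUENCE, ROLE_KEY, ROLE_INTERVENTION)
        ]

    @property
    def normalized_variables(self) -> list[str]:
        """Variables subject to min-max rescaling: the 31 inputs plus the 5
        intermediate outcomes (the final outcome is left on its raw scale)."""
        return self.inputs + self.intermediate_outcomes

    def mask_valid(self, target: str) -> list[str]:
        """Interventions allowed in a package for ``target`` (cause or total)."""
        if target == TOTAL_BURDEN:
            return list(self.interventions)
        if target not in CAUSES:
            raise ValueError(f"unknown target {target!r}")
        return [
            s.name
            for s in self._specs
            if s.role == ROLE_INTERVENTION and target in s.disease_mask
        ]

    def validate(self) -> None:
        counts = {role: len(self.by_role(role)) for role in ROLES}
        expected = {
            ROLE_INFLUENCE: 11,
            ROLE_KEY: 8,
            ROLE_INTERVENTION: 12,
            ROLE_INTERMEDIATE: 5,
            ROLE_FINAL: 1,
        }
        if counts != expected:
            raise ValueError(f"catalog role counts {counts} != expected {expected}")

    def with_overrides(
        self,
        *,
        benefit_directions: Mapping[str, int] | None = None,
        disease_masks: Mapping[str, Iterable[str]] | None = None,
    ) -> "VariableCatalog":
        """Return a copy with intervention directions / masks replaced."""
        specs = []
        for s in self._specs:
            changes = {}
            if benefit_directions and s.name in benefit_directions:
                changes["benefit_direction"] = benefit_directions[s.name]
            if disease_masks and s.name in disease_masks:
                changes["disease_mask"] = frozenset(disease_masks[s.name])
            specs.append(dataclasses.replace(s, **changes) if changes else s)
        return VariableCatalog(specs)


def default_catalog() -> VariableCatalog:
    """The default 37-variable catalog.

    The 12 intervention measures, their categories and subcategories follow
    the published intervention taxonomy. The identities of the 11 influence
    factors and 8 key variables are documented placeholders consistent with
    the influence pathway narrative (sectoral GHG emissions, temperature,
    urbanization, geography, demography, obesity, education, ...); users with
    real panels can override them, only the role counts are enforced.
    """
    influence = [
        VariableSpec("ghg_agriculture", ROLE_INFLUENCE, "Mt CO2eq/yr"),
        VariableSpec("ghg_energy", ROLE_INFLUENCE, "Mt CO2eq/yr"),
        VariableSpec("ghg_industry", ROLE_INFLUENCE, "Mt CO2eq/yr"),
        VariableSpec("ghg_land_use", ROLE_INFLUENCE, "Mt CO2eq/yr"),
        VariableSpec("mean_temperature", ROLE_INFLUENCE, "deg C"),
        VariableSpec("urbanization", ROLE_INFLUENCE, "% urban population"),
        VariableSpec("latitude", ROLE_INFLUENCE, "abs degrees"),
        VariableSpec("altitude", ROLE_INFLUENCE, "m above sea level"),
        VariableSpec("population_density", ROLE_INFLUENCE, "people/km2"),
        VariableSpec("obesity_prevalence", ROLE_INFLUENCE, "% adults"),
        VariableSpec("population_over_65", ROLE_INFLUENCE, "% population"),
    ]
    key = [
        VariableSpec("education_index", ROLE_KEY, "index 0-1"),
        VariableSpec("gdp_per_capita", ROLE_KEY, "intl USD"),
        VariableSpec("extreme_heat_days", ROLE_KEY, "days/yr"),
        VariableSpec("relative_humidity", ROLE_KEY, "%"),
        VariableSpec("electricity_access", ROLE_KEY, "% population"),
        VariableSpec("hospital_beds", ROLE_KEY, "beds/1000"),
        VariableSpec("physicians_density", ROLE_KEY, "physicians/1000"),
        VariableSpec("safe_water_access", ROLE_KEY, "% population"),
    ]
    all_causes = frozenset(CAUSES)
    infectious = frozenset({"infectious_respiratory_burden"})
    interventions = [
        VariableSpec("fertilizer_use", ROLE_INTERVENTION, "kg/ha", -1,
                     "mitigation", "agricultural sector", all_causes),
        VariableSpec("livestock_feed", ROLE_INTERVENTION, "feed quality index", +1,
                     "mitigation", "agricultural sector", all_causes),
        VariableSpec("manure_management", ROLE_INTERVENTION, "% managed", +1,
                     "mitigation", "agricultural sector", all_causes),
        VariableSpec("energy_intensity", ROLE_INTERVENTION, "MJ/USD output", +1,
                     "mitigation", "energy sector", all_causes),
        VariableSpec("low_carbon_energy_production", ROLE_INTERVENTION, "% of energy", +1,
                     "mitigation", "energy sector", all_causes),
        VariableSpec("plant_cover", ROLE_INTERVENTION, "% land area", +1,
                     "mitigation", "land use change and forestry", all_causes),
        VariableSpec("air_pollution", ROLE_INTERVENTION, "PM2.5 ug/m3", -1,
                     "adaptation", "ecosystem resilience", all_causes),
        VariableSpec("road_infrastructure_construction", ROLE_INTERVENTION,
                     "paved km/1000 km2", +1, "adaptation", "infrastructure & community",
                     frozenset({"injuries_burden"})),
        VariableSpec("health_care_delivery", ROLE_INTERVENTION, "UHC index", +1,
                     "adaptation", "health system capacity", all_causes),
        VariableSpec("health_financing", ROLE_INTERVENTION, "% GDP on health", +1,
                     "adaptation", "health system capacity", all_causes),
        VariableSpec("pneumococcal_vaccines", ROLE_INTERVENTION, "% coverage", +1,
                     "adaptation", "health system capacity", infectious),
        VariableSpec("sanitation", ROLE_INTERVENTION, "% safely managed", +1,
                     "adaptation", "health system capacity", infectious),
    ]
    outcomes = [VariableSpec(c, ROLE_INTERMEDIATE, "DALY rate") for c in CAUSES]
    final = [VariableSpec(TOTAL_BURDEN, ROLE_FINAL, "DALY rate")]
    cat = VariableCatalog(influence + key + interventions + outcomes + final)
    cat.validate()
    return cat


# ---------------------------------------------------------------------------
# RegionMap
# ---------------------------------------------------------------------------

class RegionMap:
    """country -> one of the seven World Bank regions."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = {r for r in mapping.values() if r not in REGIONS}
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")
        self._map = dict(mapping)

    def __getitem__(self, country: str) -> str:
        return self._map[country]

    def __contains__(self, country: str) -> bool:
        return country in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def countries(self) -> list[str]:
        return sorted(self._map)

    def countries_in(self, region: str) -> list[str]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return sorted(c for c, r in self._map.items() if r == region)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"country": self.countries, "region": [self._map[c] for c in self.countries]}
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "RegionMap":
        df = pd.read_csv(path_or_buf)
        return cls(dict(zip(df["country"], df["region"])))

    @classmethod
    def default(cls) -> "RegionMap":
        """The shipped World Bank mapping of 92 real countries (for use with
        real panels; synthetic panels carry their own generated mapping)."""
        from importlib.resources import files

        path = files("heatburden.data").joinpath("world_bank_regions.csv")
        with path.open() as fh:
            return cls.from_csv(fh)


# ---------------------------------------------------------------------------
# PathwayGraph
# ---------------------------------------------------------------------------

class PathwayGraph:
    """Directed acyclic influence graph over the catalog's variables.

    Used twice: the synthetic generator evaluates structural equations along
    it, and the graph neural predictor passes messages along its edges.
    """

    def __init__(self, catalog: VariableCatalog, edges: Iterable[tuple[str, str]]):
        self.catalog = catalog
        g = nx.DiGraph()
        g.add_nodes_from(catalog.names)
        for u, v in edges:
            if u not in catalog or v not in catalog:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown variable")
            g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("pathway graph is cyclic")
        self.graph = g

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges())

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def parents(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    def ancestors(self, node: str) -> set[str]:
        return set(nx.ancestors(self.graph, node))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    def validate(self) -> None:
        for cause in CAUSES:
            if self.graph.in_degree(cause) < 1:
                raise ValueError(f"intermediate outcome {cause!r} has no incoming edge")
        if set(self.parents(TOTAL_BURDEN)) != set(CAUSES):
            raise ValueError("final outcome's parents must be exactly the 5 causes")

    def with_edges(self, extra: Iterable[tuple[str, str]]) -> "PathwayGraph":
        return PathwayGraph(self.catalog, list(self.graph.edges()) + list(extra))

    # -- I/O ----------------------------------------------------------------
    def to_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in self.edges:
                fh.write(f"{u}\t{v}\n")

    @classmethod
    def from_edgelist(cls, catalog: VariableCatalog, path) -> "PathwayGraph":
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    u, v = line.split("\t")
                    edges.append((u, v))
        return cls(catalog, edges)

    def to_dot(self) -> str:
        buf = io.StringIO()
        buf.write("digraph pathway {\n")
        for u, v in self.edges:
            buf.write(f'  "{u}" -> "{v}";\n')
        buf.write("}\n")
        return buf.getvalue()


def default_pathway(catalog: VariableCatalog) -> PathwayGraph:
    """The default influence pathway.

    Sectoral GHG emissions (with the mitigation measures acting on their
    sectors) drive temperature together with urbanization, population and
    geography; temperature raises all five cause-specific burdens and air
    pollution; air pollution, demography and geography modify specific
    causes; health-system measures and education act on all five causes; the
    total burden is the sum of the five causes.
    """
    edges: list[tuple[str, str]] = []
    # mitigation measures act on their sector's emissions
    edges += [
        ("fertilizer_use", "ghg_agriculture"),
        ("livestock_feed", "ghg_agriculture"),
        ("manure_management", "ghg_agriculture"),
        ("energy_intensity", "ghg_energy"),
        ("low_carbon_energy_production", "ghg_energy"),
        ("plant_cover", "ghg_land_use"),
    ]
    # emissions + context -> temperature
    for src in ("ghg_agriculture", "ghg_energy", "ghg_industry", "ghg_land_use",
                "urbanization", "population_density", "latitude", "altitude"):
        edges.append((src, "mean_temperature"))
    # temperature -> all causes and air pollution
    for cause in CAUSES:
        edges.append(("mean_temperature", cause))
    edges.append(("mean_temperature", "air_pollution"))
    # air pollution -> four causes (not injuries in the pathway diagram)
    for cause in ("metabolic_burden", "cardiovascular_burden",
                  "infectious_respiratory_burden", "non_infectious_respiratory_burden"):
        edges.append(("air_pollution", cause))
    # modifiers
    edges += [
        ("latitude", "infectious_respiratory_burden"),
        ("population_density", "infectious_respiratory_burden"),
        ("obesity_prevalence", "metabolic_burden"),
        ("obesity_prevalence", "cardiovascular_burden"),
        ("population_over_65", "metabolic_burden"),
        ("population_over_65", "cardiovascular_burden"),
        ("population_over_65", "infectious_respiratory_burden"),
        ("population_over_65", "non_infectious_respiratory_burden"),
        ("pneumococcal_vaccines", "infectious_respiratory_burden"),
        ("sanitation", "infectious_respiratory_burden"),
        ("road_infrastructure_construction", "injuries_burden"),
    ]
    # health system capacity + education -> all five causes
    for src in ("health_care_delivery", "health_financing", "education_index"):
        for cause in CAUSES:
            edges.append((src, cause))
    # the total burden is the cumulative measure of the five causes
    for cause in CAUSES:
        edges.append((cause, TOTAL_BURDEN))
    pathway = PathwayGraph(catalog, edges)
    pathway.validate()
    return pathway


# ---------------------------------------------------------------------------
# PanelDataset
# ---------------------------------------------------------------------------

@dataclass
class PanelDataset:
    """Country-year rows of variable values; the single currency of all stages.

    ``frame`` has columns ``country``, ``year``, then one column per catalog
    variable (missing cells are NaN). ``normalized`` marks panels whose input
    and intermediate-outcome columns are on the min-max [0, 1] scale, and
    ``counterfactual`` marks panels already adjusted by an intervention
    schedule (the engine refuses to adjust them twice).
    """

    frame: pd.DataFrame
    catalog: VariableCatalog
    region_map: RegionMap
    normalized: bool = False
    counterfactual: bool = False
    norm_params: "object | None" = None  # NormalizationParams once applied

    def __post_init__(self) -> None:
        for col in ("country", "year"):
            if col not in self.frame.columns:
                raise ValueError(f"panel frame lacks {col!r} column")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def countries(self) -> list[str]:
        return sorted(self.frame["country"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique())

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            self.frame.copy(), self.catalog, self.region_map,
            normalized=self.normalized, counterfactual=self.counterfactual,
            norm_params=self.norm_params,
        )

    def subset(self, countries: Iterable[str]) -> "PanelDataset":
        keep = set(countries)
        out = self.copy()
        out.frame = out.frame[out.frame["country"].isin(keep)].reset_index(drop=True)
        return out

    def year_rows(self, year: int) -> pd.DataFrame:
        return self.frame[self.frame["year"] == year]

    def values(self, variables: list[str]):
        return self.frame[variables].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, catalog: VariableCatalog, region_map: RegionMap,
                 **flags) -> "PanelDataset":
        return cls(pd.read_csv(path), catalog, region_map, **flags)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        return "valid panel" if self.ok else "\n".join(self.violations)


def validate_panel(panel: PanelDataset) -> ValidationReport:
    """Report duplicate (country, year) keys, out-of-range years, negative
    burdens, and countries absent from the region map. Empty report iff valid."""
    report = ValidationReport()
    df = panel.frame
    dup = df.duplicated(subset=["country", "year"])
    if dup.any():
        pairs = df.loc[dup, ["country", "year"]].itertuples(index=False)
        for c, y in pairs:
            report.violations.append(f"duplicate (country, year): ({c}, {y})")
    bad_years = sorted(set(df.loc[(df["year"] < YEAR_MIN) | (df["year"] > YEAR_MAX), "year"]))
    for y in bad_years:
        report.violations.append(f"year {y} outside [{YEAR_MIN}, {YEAR_MAX}]")
    burden_cols = [c for c in CAUSES + (TOTAL_BURDEN,) if c in df.columns]
    for col in burden_cols:
        neg = df[col].dropna() < 0
        if neg.any():
            report.violations.append(f"negative burden values in {col!r} ({int(neg.sum())} rows)")
    for c in df["country"].unique():
        if c not in panel.region_map:
            report.violations.append(f"country {c!r} not in region map")
    return report
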