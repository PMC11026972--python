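"""Synthetic country-year panels with known causal structure.

The study's real panel (WHO / FAO / GHDx / Our World in Data extracts for 93
countries, 2010-2019) is not publicly released, so this module generates
panels with the statistical structure the analysis assumes: exogenous
variables follow a per-country latent level plus an AR(1) year deviation;
endogenous variables are computed in topological order along the influence
pathway as ``intercept + sum(coeff * parent) + noise`` (optionally with a
monotone tanh saturation on the cause nodes); burdens are floored at zero
and the total HTD burden is the exact sum of the five causes.

The structural graph augments the analysis pathway with direct
intervention -> cause edges (one per entry of each intervention's disease
mask, signed so that the beneficial direction reduces burden in truth).
These proximal effects are what make intervention effects identifiable to a
reduced-form predictor whose counterfactuals move only the intervention
variables; mediated effects through sectoral emissions and temperature are
retained on top. Ground truth for recovery tests is computed by direct
structural re-evaluation of the 2019 counterfactual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import (
    CAUSES,
    REGIONS,
    TOTAL_BURDEN,
    PanelDataset,
    PathwayGraph,
    RegionMap,
    VariableCatalog,
)

#: Default number of countries per region (sums to 93, the study's panel size).
DEFAULT_REGION_SIZES: dict[str, int] = {
    "East Asia and Pacific": 13,
    "Europe and Central Asia": 21,
    "Latin America and The Caribbean": 16,
    "Middle East and North Africa": 10,
    "North America": 2,
    "South Asia": 5,
    "Sub-Saharan Africa": 26,
}

GLOBAL = "All regions"  # pseudo-region key for world-level ground truth

# ---------------------------------------------------------------------------
# Exogenous variable configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExogSpec:
    """Per-country latent level ~ Normal(mean, between_sd); the year series is
    level + AR(1) deviation with autocorrelation ``rho`` and innovation sd
    ``ar_sd`` (``ar_sd = 0`` gives a time-constant variable)."""

    mean: float
    between_sd: float
    ar_sd: float
    rho: float = 0.7
    floor: float | None = 0.0  # clip latent levels below this


#: Plausible raw scales for the placeholder variables; none of the analysis
#: depends on the absolute units, only on there being distinct scales so the
#: min-max rescaling step is non-trivial.
DEFAULT_EXOG: dict[str, ExogSpec] = {
    "ghg_industry": ExogSpec(120, 60, 8),
    "urbanization": ExogSpec(55, 20, 1),
    "latitude": ExogSpec(30, 15, 0),
    "altitude": ExogSpec(600, 500, 0),
    "population_density": ExogSpec(150, 120, 3),
    "obesity_prevalence": ExogSpec(18, 8, 0.5),
    "population_over_65": ExogSpec(9, 5, 0.2),
    "education_index": ExogSpec(0.65, 0.15, 0.01, floor=0.05),
    "gdp_per_capita": ExogSpec(20000, 15000, 600),
    "extreme_heat_days": ExogSpec(25, 15, 5),
    "relative_humidity": ExogSpec(65, 12, 2),
    "electricity_access": ExogSpec(85, 18, 1),
    "hospital_beds": ExogSpec(3, 2, 0.1),
    "physicians_density": ExogSpec(1.8, 1.2, 0.05),
    "safe_water_access": ExogSpec(75, 20, 1),
    # intervention variables (exogenous policy levers)
    "fertilizer_use": ExogSpec(120, 60, 5),
    "livestock_feed": ExogSpec(50, 20, 2),
    "manure_management": ExogSpec(40, 20, 2),
    "energy_intensity": ExogSpec(5, 2, 0.15),
    "low_carbon_energy_production": ExogSpec(25, 15, 1.5),
    "plant_cover": ExogSpec(35, 15, 0.5),
    "road_infrastructure_construction": ExogSpec(200, 120, 5),
    "health_care_delivery": ExogSpec(60, 15, 1),
    "health_financing": ExogSpec(6, 2.5, 0.15),
    "pneumococcal_vaccines": ExogSpec(45, 25, 3),
    "sanitation": ExogSpec(55, 25, 1.5),
}

#: Designed full-schedule (cumulative 20% of range) effect of each
#: intervention on each cause it affects, in raw burden units. Distinct
#: magnitudes give an unambiguous true contribution ranking.
DEFAULT_INTERVENTION_EFFECT: dict[str, float] = {
    "air_pollution": 12.0,
    "low_carbon_energy_production": 10.0,
    "health_care_delivery": 9.0,
    "pneumococcal_vaccines": 9.0,
    "road_infrastructure_construction": 8.0,
    "health_financing": 7.0,
    "energy_intensity": 6.0,
    "sanitation": 6.0,
    "livestock_feed": 5.0,
    "plant_cover": 4.0,
    "manure_management": 3.0,
    "fertilizer_use": 2.0,
}

#: Target mean level of each endogenous node (raw units); the intercept is
#: solved from these so generated burdens stay comfortably positive.
DEFAULT_NODE_LEVELS: dict[str, float] = {
    "ghg_agriculture": 60.0,
    "ghg_energy": 150.0,
    "ghg_land_use": 60.0,
    "mean_temperature": 14.0,
    "air_pollution": 40.0,
    "cardiovascular_burden": 400.0,
    "infectious_respiratory_burden": 500.0,
    "injuries_burden": 250.0,
    "metabolic_burden": 200.0,
    "non_infectious_respiratory_burden": 300.0,
}

#: Additive noise sd per endogenous node.
DEFAULT_NOISE: dict[str, float] = {
    "ghg_agriculture": 10.0,
    "ghg_energy": 20.0,
    "ghg_land_use": 12.0,
    "mean_temperature": 0.4,
    "air_pollution": 4.0,
    "cardiovascular_burden": 20.0,
    "infectious_respiratory_burden": 25.0,
    "injuries_burden": 15.0,
    "metabolic_burden": 12.0,
    "non_infectious_respiratory_burden": 15.0,
}


# ---------------------------------------------------------------------------
# StructuralModel
# ---------------------------------------------------------------------------

@dataclass
class StructuralModel:
    """Linear(-with-saturation) structural equations over a DAG.

    ``graph`` is the structural DAG (the analysis pathway augmented with the
    direct intervention -> cause edges). ``coefficients`` maps each edge to
    its effect per raw unit of the parent; ``intercepts`` and
    ``noise_scales`` are per endogenous node. With ``form =
    "linear_saturation"`` the cause nodes pass their linear predictor through
    a centered tanh (strength ``saturation_strength``), a monotone
    diminishing-returns response that a purely linear predictor cannot
    capture.
    """

    graph: PathwayGraph
    coefficients: dict[tuple[str, str], float]
    intercepts: dict[str, float]
    noise_scales: dict[str, float]
    exog: dict[str, ExogSpec]
    form: str = "linear"
    saturation_strength: float = 2.0
    designed_center: dict[str, float] = field(default_factory=dict)
    designed_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in ("linear", "linear_saturation"):
            raise ValueError("form must be 'linear' or 'linear_saturation'")

    @property
    def endogenous(self) -> list[str]:
        return [n for n in self.graph.topological_order()
                if self.graph.graph.in_degree(n) > 0]

    def with_noise_scales(self, scale: float, nodes: list[str] | None = None) -> "StructuralModel":
        """Copy with noise sd replaced by ``scale`` on ``nodes`` (default all)."""
        ns = dict(self.noise_scales)
        for n in (nodes if nodes is not None else list(ns)):
            ns[n] = scale
        return replace(self, noise_scales=ns)

    def node_equation(self, node: str):
        """(parents, coefficients, intercept) of one endogenous node."""
        parents = self.graph.parents(node)
        return parents, [self.coefficients[(p, node)] for p in parents], self.intercepts[node]


def default_structural_model(
    catalog: VariableCatalog,
    pathway: PathwayGraph,
    form: str = "linear",
    intervention_effects: dict[str, float] | None = None,
    saturation_strength: float = 2.0,
) -> StructuralModel:
    """Build the default structural model over the augmented pathway.

    Every intervention receives direct edges to the causes in its disease
    mask (beyond any edges the analysis pathway already carries), with the
    coefficient solved so that a full five-year schedule (cumulative 20% of
    the variable's designed range) shifts each affected cause by the
    intervention's designed effect, in the burden-reducing direction.
    """
    effects = dict(DEFAULT_INTERVENTION_EFFECT)
    if intervention_effects:
        effects.update(intervention_effects)

    coef: dict[tuple[str, str], float] = {}
    # -- mediated chain: mitigation -> sector emissions -> temperature ------
    coef[("fertilizer_use", "ghg_agriculture")] = 0.15
    coef[("livestock_feed", "ghg_agriculture")] = -0.30
    coef[("manure_management", "ghg_agriculture")] = -0.30
    coef[("energy_intensity", "ghg_energy")] = -8.0
    coef[("low_carbon_energy_production", "ghg_energy")] = -1.2
    coef[("plant_cover", "ghg_land_use")] = -0.8
    for sector in ("ghg_agriculture", "ghg_energy", "ghg_industry", "ghg_land_use"):
        coef[(sector, "mean_temperature")] = 0.008
    coef[("urbanization", "mean_temperature")] = 0.05
    coef[("population_density", "mean_temperature")] = 0.002
    coef[("latitude", "mean_temperature")] = -0.15
    coef[("altitude", "mean_temperature")] = -0.004
    coef[("mean_temperature", "air_pollution")] = 2.2
    # -- temperature and modifiers -> causes --------------------------------
    temp_effect = {
        "cardiovascular_burden": 12.0,
        "infectious_respiratory_burden": 14.0,
        "injuries_burden": 8.0,
        "metabolic_burden": 9.0,
        "non_infectious_respiratory_burden": 10.0,
    }
    for cause, c in temp_effect.items():
        coef[("mean_temperature", cause)] = c
    for cause, c in {
        "cardiovascular_burden": 1.2,
        "infectious_respiratory_burden": 1.4,
        "metabolic_burden": 0.8,
        "non_infectious_respiratory_burden": 1.6,
    }.items():
        coef[("air_pollution", cause)] = c
    coef[("obesity_prevalence", "cardiovascular_burden")] = 2.0
    coef[("obesity_prevalence", "metabolic_burden")] = 3.0
    coef[("population_over_65", "cardiovascular_burden")] = 4.0
    coef[("population_over_65", "metabolic_burden")] = 2.5
    coef[("population_over_65", "infectious_respiratory_burden")] = 3.0
    coef[("population_over_65", "non_infectious_respiratory_burden")] = 4.0
    coef[("latitude", "infectious_respiratory_burden")] = -1.2
    coef[("population_density", "infectious_respiratory_burden")] = 0.05
    for cause, c in {
        "cardiovascular_burden": -60.0,
        "infectious_respiratory_burden": -90.0,
        "injuries_burden": -50.0,
        "metabolic_burden": -40.0,
        "non_infectious_respiratory_burden": -60.0,
    }.items():
        coef[("education_index", cause)] = c
    # -- direct intervention effects (solved from designed effect sizes) ----
    extra_edges: list[tuple[str, str]] = []
    for name in catalog.interventions:
        spec = catalog[name]
        if name == "air_pollution":
            # pathway already carries four of its edges at the coefficients
            # above; only the injuries edge comes from the designed effect
            masked = [c for c in sorted(spec.disease_mask)
                      if (name, c) not in coef]
        else:
            masked = sorted(spec.disease_mask)
        # full-schedule raw shift: 20% of the designed range (~4.3 sd);
        # air pollution is endogenous, its designed sd comes from propagation
        # of its temperature parent (~8.3 in the default configuration)
        sd = DEFAULT_EXOG[name].between_sd if name in DEFAULT_EXOG else 8.3
        delta = 0.2 * 4.3 * sd
        for cause in masked:
            coef[(name, cause)] = -spec.benefit_direction * effects[name] / delta
            if (name, cause) not in pathway.graph.edges():
                extra_edges.append((name, cause))
    for cause in CAUSES:
        coef[(cause, TOTAL_BURDEN)] = 1.0

    graph = pathway.with_edges(e for e in extra_edges
                               if e not in set(pathway.graph.edges()))
    missing = [e for e in graph.edges if e not in coef]
    if missing:
        raise ValueError(f"edges without coefficients: {missing}")

    # -- solve intercepts from designed node levels; propagate designed sds -
    intercepts: dict[str, float] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for node in graph.topological_order():
        parents = graph.parents(node)
        if not parents:
            means[node] = DEFAULT_EXOG[node].mean
            s = DEFAULT_EXOG[node]
            sds[node] = math.hypot(s.between_sd,
                                   s.ar_sd / math.sqrt(1 - s.rho**2) if s.ar_sd else 0.0)
            continue
        lin_mean = sum(coef[(p, node)] * means[p] for p in parents)
        level = DEFAULT_NODE_LEVELS.get(node, 0.0)
        intercepts[node] = level - lin_mean if node != TOTAL_BURDEN else 0.0
        means[node] = level if node != TOTAL_BURDEN else lin_mean
        var = sum((coef[(p, node)] * sds[p]) ** 2 for p in parents)
        var += DEFAULT_NOISE.get(node, 0.0) ** 2
        sds[node] = math.sqrt(var)

    noise = {n: DEFAULT_NOISE.get(n, 0.0) for n in graph.topological_order()
             if graph.graph.in_degree(n) > 0}
    noise[TOTAL_BURDEN] = 0.0  # the total is always the exact sum

    return StructuralModel(
        graph=graph,
        coefficients=coef,
        intercepts=intercepts,
        noise_scales=noise,
        exog=dict(DEFAULT_EXOG),
        form=form,
        saturation_strength=saturation_strength,
        designed_center=means,
        designed_sd=sds,
    )


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def _propagate(
    model: StructuralModel,
    frame: pd.DataFrame,
    noise: pd.DataFrame,
    clamped: set[str] = frozenset(),
) -> pd.DataFrame:
    """Evaluate the endogenous nodes in topological order on ``frame``.

    ``clamped`` nodes keep the values already present in ``frame`` (used to
    hold package members at their scheduled values in counterfactuals).
    """
    out = frame.copy()
    for node in model.endogenous:
        if node in clamped:
            continue
        parents, coefs, intercept = model.node_equation(node)
        lin = intercept + sum(c * out[p].to_numpy() for p, c in zip(parents, coefs))
        if model.form == "linear_saturation" and node in CAUSES:
            lam = model.saturation_strength
            center, sd = model.designed_center[node], model.designed_sd[node]
            lin = center + (sd / lam) * np.tanh(lam * (lin - center) / sd)
        if node in noise.columns:
            lin = lin + noise[node].to_numpy()
        if node in CAUSES:
            lin = np.maximum(lin, 0.0)
        out[node] = lin
    out[TOTAL_BURDEN] = sum(out[c].to_numpy() for c in CAUSES)
    return out


@dataclass
class GroundTruth:
    """True full-schedule marginal effects, by region x target x intervention.

    ``baseline``: 2019 regional burden per (region, target); ``deltas``:
    burden reduction achieved by a singleton full schedule of each
    intervention, from direct structural re-evaluation of the counterfactual.
    The pseudo-region ``"All regions"`` aggregates every country.
    """

    baseline: pd.DataFrame  # index (region, target) -> burden
    deltas: pd.DataFrame    # index (region, target, intervention) -> reduction

    def marginal_effects(self, region: str, target: str) -> pd.Series:
        return self.deltas.xs((region, target), level=("region", "target"))["delta"]


def true_optimal_package(
    ground_truth: GroundTruth,
    region: str,
    target: str,
    mask_valid: list[str],
    tol: float = 1e-9,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """The mask-valid interventions with true burden-reducing effect.

    Under the additive monotone truth this package minimizes the 2019
    burden. Returns (package, ties) where ``ties`` lists interventions whose
    true effect is zero to within ``tol`` (their inclusion is indifferent).
    """
    eff = ground_truth.marginal_effects(region, target)
    package = tuple(sorted(i for i in mask_valid if eff.get(i, 0.0) > tol))
    ties = tuple(sorted(i for i in mask_valid if abs(eff.get(i, 0.0)) <= tol))
    return package, ties


def generate_panel(
    catalog: VariableCatalog,
    pathway: PathwayGraph,
    structural_model: StructuralModel | None = None,
    n_countries: int = 93,
    years: range = range(2010, 2020),
    region_sizes: dict[str, int] | None = None,
    seed: int = 0,
    schedule_intensity: float = 0.04,
    schedule_years: int = 5,
) -> tuple[PanelDataset, GroundTruth]:
    """Generate a country-year panel and its intervention ground truth.

    Exogenous nodes follow per-country latent levels with AR(1) year
    deviations; endogenous nodes are evaluated along the structural DAG;
    burdens are floored at zero and the total burden is the exact sum of the
    five causes. Ground truth evaluates, for each intervention, the 2019
    regional burden under a singleton schedule accumulating to
    ``schedule_intensity * schedule_years`` of the variable's observed raw
    range (the same semantics the intervention engine applies on the
    normalized scale).
    """
    model = structural_model or default_structural_model(catalog, pathway)
    for edge in pathway.graph.edges():
        if edge not in model.coefficients:
            raise ValueError(f"pathway edge {edge} lacks a structural coefficient")

    sizes = dict(region_sizes or DEFAULT_REGION_SIZES)
    if set(sizes) - set(REGIONS):
        raise ValueError("region_sizes contains unknown regions")
    if sum(sizes.values()) != n_countries:
        raise ValueError(f"region sizes sum to {sum(sizes.values())}, not {n_countries}")

    rng = np.random.default_rng(seed)
    countries, region_of = [], {}
    i = 1
    for region in REGIONS:
        for _ in range(sizes.get(region, 0)):
            name = f"C{i:03d}"
            countries.append(name)
            region_of[name] = region
            i += 1
    region_map = RegionMap(region_of)

    years = list(years)
    n_years = len(years)
    rows = pd.DataFrame(
        {"country": np.repeat(countries, n_years), "year": years * len(countries)}
    )

    # exogenous nodes: latent country level + AR(1) deviation
    exog_nodes = [n for n in model.graph.topological_order()
                  if model.graph.graph.in_degree(n) == 0]
    for node in exog_nodes:
        s = model.exog[node]
        levels = rng.normal(s.mean, s.between_sd, size=len(countries))
        if s.floor is not None:
            levels = np.maximum(levels, s.floor)
        values = np.empty((len(countries), n_years))
        if s.ar_sd > 0:
            stat_sd = s.ar_sd / math.sqrt(1 - s.rho**2)
            dev = rng.normal(0, stat_sd, size=len(countries))
            for t in range(n_years):
                if t > 0:
                    dev = s.rho * dev + rng.normal(0, s.ar_sd, size=len(countries))
                values[:, t] = levels + dev
        else:
            values[:] = levels[:, None]
        rows[node] = values.reshape(-1)

    # noise draws for endogenous nodes (stored for counterfactual truth)
    noise = pd.DataFrame(index=rows.index)
    for node in model.endogenous:
        scale = model.noise_scales.get(node, 0.0)
        noise[node] = rng.normal(0, scale, size=len(rows)) if scale > 0 else 0.0

    frame = _propagate(model, rows, noise)
    frame = frame[["country", "year"] + catalog.names]
    panel = PanelDataset(frame, catalog, region_map)

    truth = _ground_truth(
        model, catalog, panel, noise,
        cumulative=schedule_intensity * schedule_years,
    )
    return panel, truth


def _ground_truth(
    model: StructuralModel,
    catalog: VariableCatalog,
    panel: PanelDataset,
    noise: pd.DataFrame,
    cumulative: float,
    year: int = 2019,
) -> GroundTruth:
    df = panel.frame
    mask_year = (df["year"] == year).to_numpy()
    regions = list(REGIONS) + [GLOBAL]

    def regional(frame: pd.DataFrame) -> pd.DataFrame:
        sub = frame.loc[mask_year, ["country"] + list(CAUSES) + [TOTAL_BURDEN]].copy()
        sub["region"] = sub["country"].map(lambda c: panel.region_map[c])
        agg = sub.groupby("region")[list(CAUSES) + [TOTAL_BURDEN]].sum()
        agg.loc[GLOBAL] = sub[list(CAUSES) + [TOTAL_BURDEN]].sum()
        return agg

    base = regional(df)
    baseline_rows = [
        {"region": r, "target": t, "burden": float(base.loc[r, t])}
        for r in regions for t in list(CAUSES) + [TOTAL_BURDEN]
    ]

    ranges = {i: (float(df[i].min()), float(df[i].max())) for i in catalog.interventions}
    delta_rows = []
    for name in catalog.interventions:
        d = catalog[name].benefit_direction
        lo, hi = ranges[name]
        cf = df.copy()
        shifted = cf[name].to_numpy() + d * cumulative * (hi - lo)
        cf.loc[mask_year, name] = np.clip(shifted, lo, hi)[mask_year]
        cf = _propagate(model, cf, noise, clamped={name})
        agg = regional(cf)
        for r in regions:
            for t in list(CAUSES) + [TOTAL_BURDEN]:
                delta_rows.append(
                    {"region": r, "target": t, "intervention": name,
                     "delta": float(base.loc[r, t] - agg.loc[r, t])}
                )
    baseline = pd.DataFrame(baseline_rows).set_index(["region", "target"])
    deltas = pd.DataFrame(delta_rows).set_index(["region", "target", "intervention"])
    return GroundTruth(baseline, deltas)


# ---------------------------------------------------------------------------
# Missingness injection
# ---------------------------------------------------------------------------

def inject_missingness(
    panel: PanelDataset,
    interior_rate: float = 0.0,
    boundary_rate: float = 0.0,
    seed: int = 0,
    variables: list[str] | None = None,
    protect_outcome: bool = True,
) -> tuple[PanelDataset, pd.DataFrame]:
    """Blank cells to exercise the imputation rules; returns (panel, log).

    The number of interior (resp. boundary) gaps is Binomial(n_cells, rate)
    where n_cells counts every (country, year, variable) cell of the chosen
    variables; gap positions are then sampled uniformly among eligible cells
    (interior: not the first or last year of the series; boundary: first or
    last year). The log tags each removed cell ``interior`` or ``boundary``.
    """
    if not (0 <= interior_rate < 1 and 0 <= boundary_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    if variables is None:
        variables = list(panel.catalog.inputs)
        if not protect_outcome:
            variables += list(panel.catalog.intermediate_outcomes) + [TOTAL_BURDEN]
    out = panel.copy()
    df = out.frame.sort_values(["country", "year"]).reset_index(drop=True)
    rng = np.random.default_rng(seed)

    n_countries = df["country"].nunique()
    years = sorted(df["year"].unique())
    n_years = len(years)
    n_cells = len(df) * len(variables)

    # eligible cell indices as (row, variable) pairs
    first_last = df["year"].isin([years[0], years[-1]]).to_numpy()
    interior_rows = np.flatnonzero(~first_last)
    boundary_rows = np.flatnonzero(first_last)

    log_rows = []
    for kind, rate, eligible_rows in (
        ("interior", interior_rate, interior_rows),
        ("boundary", boundary_rate, boundary_rows),
    ):
        if rate <= 0 or n_years < 3:
            continue
        n_gaps = min(rng.binomial(n_cells, rate), len(eligible_rows) * len(variables))
        flat = rng.choice(len(eligible_rows) * len(variables), size=n_gaps, replace=False)
        for f in flat:
            r = eligible_rows[f // len(variables)]
            v = variables[f % len(variables)]
            df.loc[r, v] = np.nan
            log_rows.append(
                {"country": df.loc[r, "country"], "year": int(df.loc[r, "year"]),
                 "variable": v, "kind": kind}
            )
    out.frame = df
    log = pd.DataFrame(log_rows, columns=["country", "year", "variable", "kind"])
    return out, log
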