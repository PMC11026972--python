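"""End-to-end orchestration: simulate/load -> preprocess -> screen ->
optimize -> sensitivity, with every artifact and seed written to a fresh run
directory so a rerun with the same configuration reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    CAUSES,
    REGIONS,
    TOTAL_BURDEN,
    PanelDataset,
    RegionMap,
    default_catalog,
    default_pathway,
    validate_panel,
)
from .interventions import InterventionSchedule
from .models import PredictorSpec, screen
from .optimizer import OptimizationReport, PackageSweep, optimize_all, sensitivity
from .preprocessing import (
    apply_minmax,
    exclude_countries,
    fit_minmax,
    impute,
    split_train_test,
)
from .synthetic import default_structural_model, generate_panel, inject_missingness

logger = logging.getLogger(__name__)

MODEL_SUBSET_FAST = ("linear_regression", "random_forest", "gnn")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; the seed is mandatory."""

    seed: int
    out_dir: str = "runs"
    panel_csv: str | None = None      # load a real panel instead of simulating
    regions_csv: str | None = None    # required with panel_csv
    n_countries: int = 93
    region_sizes: dict[str, int] | None = None
    structural_form: str = "linear"
    interior_missing: float = 0.01
    boundary_missing: float = 0.005
    threshold: float = 0.15
    train_fraction: float = 0.7
    split_unit: str = "row"
    models: tuple[str, ...] = MODEL_SUBSET_FAST
    annual_intensity: float = 0.04
    window: tuple[int, int] = (2015, 2019)
    sensitivity_intensities: tuple[float, ...] = (0.02, 0.04, 0.06)
    targets: tuple[str, ...] = CAUSES + (TOTAL_BURDEN,)
    regions: tuple[str, ...] = REGIONS

    def validate(self) -> None:
        if self.panel_csv is not None:
            for p in (self.panel_csv, self.regions_csv):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"configured path missing: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models", "window", "sensitivity_intensities", "targets", "regions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _next_run_dir(base: Path) -> Path:
    base.mkdir(parents=True, exist_ok=True)
    n = 1
    while (base / f"run-{n:04d}").exists():
        n += 1
    path = base / f"run-{n:04d}"
    path.mkdir()
    return path


def export_contribution_table(
    report: OptimizationReport,
    regions: tuple[str, ...] = REGIONS,
    interventions: list[str] | None = None,
) -> pd.DataFrame:
    """Regions as columns, the 12 interventions as rows, normalized shares
    as percentage strings; interventions absent from a region's optimal
    total-burden package render as "/"."""
    if not any(t == TOTAL_BURDEN for (_, t) in report.cells):
        raise ValueError("report contains no total-burden cells")
    if interventions is None:
        interventions = sorted(default_catalog().interventions)
    table = {}
    for region in regions:
        key = (region, TOTAL_BURDEN)
        if key in report.cells:
            _, contrib = report.cells[key]
            col = {i: f"{contrib.shares[i] * 100:.2f}%" if i in contrib.shares else "/"
                   for i in interventions}
        else:
            col = {i: "/" for i in interventions}
        table[region] = col
    df = pd.DataFrame(table).loc[sorted(interventions)]
    df.index.name = "intervention"
    return df


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages: generate or load the panel; validate; screen missingness and
    exclude; impute; min-max normalize; 70/30 split; screen the configured
    models; optimize every (region, target) cell with the best model; run
    the intensity sensitivity analysis. Every stage writes its artifact
    before the next begins.
    """
    config.validate()
    run_dir = _next_run_dir(Path(config.out_dir))
    manifest: dict = {"config": dataclasses.asdict(config), "version": __version__,
                      "seeds": {"master": config.seed}}
    catalog = default_catalog()
    pathway = default_pathway(catalog)

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("data")
        if config.panel_csv:
            region_map = RegionMap.from_csv(config.regions_csv)
            panel = PanelDataset.from_csv(config.panel_csv, catalog, region_map)
            truth = None
        else:
            model = default_structural_model(catalog, pathway, form=config.structural_form)
            panel, truth = generate_panel(
                catalog, pathway, model, n_countries=config.n_countries,
                region_sizes=config.region_sizes, seed=config.seed,
            )
            if config.interior_missing or config.boundary_missing:
                panel, miss_log = inject_missingness(
                    panel, config.interior_missing, config.boundary_missing,
                    seed=config.seed + 1,
                )
                miss_log.to_csv(run_dir / "missingness_log.csv", index=False)
        panel.to_csv(run_dir / "panel.csv")
        panel.region_map.to_frame().to_csv(run_dir / "regions.csv", index=False)

        _stage("validate")
        report = validate_panel(panel)
        if not report.ok:
            raise ValueError(f"invalid panel:\n{report}")

        _stage("preprocess")
        panel, dropped = exclude_countries(panel, threshold=config.threshold)
        panel, imp_log = impute(panel)
        imp_log.to_csv(run_dir / "imputation_log.csv", index=False)
        params = fit_minmax(panel)
        params.to_json(run_dir / "norm_params.json")
        normalized = apply_minmax(panel, params)
        train, test = split_train_test(
            normalized, config.train_fraction, unit=config.split_unit,
            seed=config.seed + 2,
        )
        manifest["seeds"]["split"] = config.seed + 2
        manifest["dropped_countries"] = dropped
        manifest["n_rows"] = {"panel": panel.n_rows, "train": train.n_rows,
                              "test": test.n_rows}

        _stage("screen")
        specs = [PredictorSpec(name, seed=config.seed + 3) for name in config.models]
        manifest["seeds"]["models"] = config.seed + 3
        screened = screen(specs, train, test, pathway=pathway)
        screened.table().to_csv(run_dir / "metrics.csv", index=False)
        with open(run_dir / "metrics.json", "w") as fh:
            json.dump({s.name: ev.as_dict() for s, ev in screened.ranking}, fh, indent=1)
        best_spec, best_eval = screened.best
        best_model = screened.fitted[best_spec.name]
        manifest["selected_model"] = best_spec.name

        _stage("optimize")
        template = InterventionSchedule(
            package=tuple(catalog.interventions),
            start_year=config.window[0], end_year=config.window[1],
            annual_intensity=config.annual_intensity,
        )
        sweep = PackageSweep(best_model, normalized, template)
        opt = optimize_all(best_model, normalized, template,
                           targets=config.targets, regions=config.regions,
                           sweep=sweep)
        cells_json = {
            f"{region}|{target}": {
                "package": list(res.package),
                "baseline": res.baseline,
                "post": res.post,
                "reduction": res.reduction,
                "shares": contrib.shares,
            }
            for (region, target), (res, contrib) in sorted(opt.cells.items())
        }
        with open(run_dir / "optimal_packages.json", "w") as fh:
            json.dump(cells_json, fh, indent=1)
        opt.size_curve.to_csv(run_dir / "size_curve.csv", index=False)
        if TOTAL_BURDEN in config.targets:
            export_contribution_table(opt, config.regions).to_csv(
                run_dir / "contribution_table.csv"
            )

        _stage("sensitivity")
        sens = sensitivity(best_model, normalized, template,
                           intensities=config.sensitivity_intensities,
                           regions=config.regions)
        sens.to_csv(run_dir / "sensitivity.csv")

        _stage("summary")
        lines = [
            f"heatburden pipeline run (seed {config.seed})",
            f"panel: {panel.n_rows} rows, {len(panel.countries)} countries "
            f"({len(dropped)} dropped), years {panel.years[0]}-{panel.years[-1]}",
            f"selected model: {best_spec.name} "
            f"(RMSE {best_eval.rmse:.4f}, R2 {best_eval.r2:.4f})",
            f"optimization cells: {len(opt.cells)} "
            f"({len(opt.failures)} failures)",
        ]
        for region, res, contrib in opt.total_rows():
            top = next(iter(contrib.shares))
            lines.append(
                f"  {region}: reduction {res.reduction * 100:.2f}% with "
                f"{len(res.package)} interventions; top contributor {top} "
                f"({contrib.shares[top] * 100:.2f}%)"
            )
        summary = "\n".join(lines) + "\n"
        (run_dir / "summary.txt").write_text(summary)
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    except Exception:
        (run_dir / "FAILED").touch()
        raise
    return run_dir
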