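"""Missingness screening, country exclusion, imputation, min-max
normalization and train/test splitting for country-year panels.

The rules mirror the study protocol: countries lacking the HTD outcome are
excluded outright; a 15% per-country-variable missingness threshold decides
exclusion vs imputation; interior gaps (observed values on both sides) are
filled by linear interpolation in year, boundary gaps by the country's (or
optionally the region's) observed mean; the 31 inputs and the 5 intermediate
outcomes are min-max rescaled to [0, 1] while the final outcome keeps its raw
scale; modeling uses a 70/30 train/test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CAUSES, TOTAL_BURDEN, PanelDataset


# ---------------------------------------------------------------------------
# Missingness profile and exclusion
# ---------------------------------------------------------------------------

@dataclass
class MissingnessProfile:
    """Fraction of missing years per (country, variable), each in [0, 1]."""

    table: pd.DataFrame  # index: country, columns: variables, values: fractions

    def fraction(self, country: str, variable: str) -> float:
        return float(self.table.loc[country, variable])


def missingness(panel: PanelDataset, variables: list[str] | None = None) -> MissingnessProfile:
    if variables is None:
        variables = [v for v in panel.catalog.names if v in panel.frame.columns]
    df = panel.frame
    frac = df.groupby("country")[variables].apply(lambda g: g.isna().mean())
    return MissingnessProfile(frac)


def exclude_countries(
    panel: PanelDataset,
    profile: MissingnessProfile | None = None,
    threshold: float = 0.15,
    require_outcome: bool = True,
) -> tuple[PanelDataset, list[str]]:
    """Drop countries beyond the missing-data threshold.

    A country is dropped if (a) it lacks the HTD outcome entirely (when
    ``require_outcome``) or (b) any of the 31 input variables exceeds
    ``threshold`` missingness. Returns the filtered panel and the list of
    dropped countries. Raises if no country survives.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    inputs = [v for v in panel.catalog.inputs if v in panel.frame.columns]
    if profile is None:
        profile = missingness(panel, inputs + [TOTAL_BURDEN]
                              if TOTAL_BURDEN in panel.frame.columns else inputs)
    dropped: list[str] = []
    for country in panel.countries:
        if require_outcome and TOTAL_BURDEN in profile.table.columns:
            if profile.fraction(country, TOTAL_BURDEN) >= 1.0:
                dropped.append(country)
                continue
        if any(profile.fraction(country, v) > threshold for v in inputs):
            dropped.append(country)
    kept = [c for c in panel.countries if c not in set(dropped)]
    if not kept:
        raise ValueError("no countries survive the missingness threshold")
    return panel.subset(kept), dropped


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute(panel: PanelDataset, fallback: str = "country") -> tuple[PanelDataset, pd.DataFrame]:
    """Fill every missing cell; returns (imputed panel, provenance log).

    Interior gaps — missing runs with observed values on both sides — are
    filled by linear interpolation in year. Boundary gaps — runs touching the
    start or end of a country's series — are filled with the country's
    observed mean for that variable (``fallback="region"`` uses the region's
    observed mean instead). Raises on an all-missing country-variable series.
    """
    if fallback not in ("country", "region"):
        raise ValueError("fallback must be 'country' or 'region'")
    out = panel.copy()
    df = out.frame.sort_values(["country", "year"]).reset_index(drop=True)
    variables = [v for v in panel.catalog.names if v in df.columns]
    log_rows: list[dict] = []

    if fallback == "region":
        region_of = {c: panel.region_map[c] for c in df["country"].unique()}
        df["_region"] = df["country"].map(region_of)

    for country, grp in df.groupby("country", sort=False):
        idx = grp.index
        years = grp["year"].to_numpy()
        for var in variables:
            s = grp[var]
            miss = s.isna()
            if not miss.any():
                continue
            if miss.all():
                raise ValueError(f"all-missing series: country={country!r} variable={var!r}")
            obs_pos = np.flatnonzero(~miss.to_numpy())
            first, last = obs_pos[0], obs_pos[-1]
            # interior: interpolate linearly in year between flanking observations
            interp = np.interp(years, years[obs_pos], s.to_numpy()[obs_pos])
            if fallback == "country":
                fill_value = float(s.mean())
            else:
                region = region_of[country]
                mask = (df["_region"] == region)
                fill_value = float(df.loc[mask, var].mean())
            for k, pos in enumerate(np.flatnonzero(miss.to_numpy())):
                if first < pos < last:
                    df.loc[idx[pos], var] = interp[pos]
                    method = "linear_interpolation"
                else:
                    df.loc[idx[pos], var] = fill_value
                    method = f"{fallback}_mean"
                log_rows.append(
                    {"country": country, "year": int(years[pos]), "variable": var,
                     "method": method, "value": float(df.loc[idx[pos], var])}
                )
    if fallback == "region":
        df = df.drop(columns="_region")
    out.frame = df
    log = pd.DataFrame(log_rows, columns=["country", "year", "variable", "method", "value"])
    return out, log


# ---------------------------------------------------------------------------
# Min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-variable (min, max) fitted on the reference panel."""

    params: dict[str, tuple[float, float]]
    degenerate: list[str] = field(default_factory=list)

    def __contains__(self, variable: str) -> bool:
        return variable in self.params

    def range_width(self, variable: str) -> float:
        lo, hi = self.params[variable]
        return hi - lo

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"params": self.params, "degenerate": self.degenerate}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls({k: tuple(v) for k, v in d["params"].items()}, d["degenerate"])


def fit_minmax(panel: PanelDataset, variables: list[str] | None = None) -> NormalizationParams:
    """Fit (min, max) per variable over all rows; constant columns are flagged
    degenerate. By default covers the 31 inputs and 5 intermediate outcomes,
    never the final outcome."""
    if variables is None:
        variables = [v for v in panel.catalog.normalized_variables if v in panel.frame.columns]
    params, degenerate = {}, []
    for v in variables:
        col = panel.frame[v].astype(float)
        lo, hi = float(col.min()), float(col.max())
        if not np.isfinite(lo) or not np.isfinite(hi):
            raise ValueError(f"variable {v!r} has no finite values to fit")
        if hi <= lo:
            degenerate.append(v)
        params[v] = (lo, hi)
    return NormalizationParams(params, degenerate)


def apply_minmax(panel: PanelDataset, params: NormalizationParams) -> PanelDataset:
    """x' = (x - min)/(max - min), clipped to [0, 1]; degenerate columns -> 0."""
    out = panel.copy()
    for v, (lo, hi) in params.params.items():
        if v not in out.frame.columns:
            raise KeyError(f"unknown variable {v!r} in panel")
        col = out.frame[v].astype(float)
        if hi <= lo:
            out.frame[v] = np.where(col.notna(), 0.0, np.nan)
        else:
            out.frame[v] = ((col - lo) / (hi - lo)).clip(0.0, 1.0)
    out.normalized = True
    out.norm_params = params
    return out


def invert_minmax(panel: PanelDataset, params: NormalizationParams) -> PanelDataset:
    """Map normalized values back to the raw scale (degenerate columns -> min)."""
    out = panel.copy()
    for v, (lo, hi) in params.params.items():
        if v not in out.frame.columns:
            raise KeyError(f"unknown variable {v!r} in panel")
        out.frame[v] = panel.frame[v].astype(float) * (hi - lo) + lo
    out.normalized = False
    out.norm_params = None
    return out


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def split_train_test(
    panel: PanelDataset,
    train_fraction: float = 0.7,
    unit: str = "row",
    seed: int | None = None,
) -> tuple[PanelDataset, PanelDataset]:
    """Disjoint, exhaustive 70/30-style split, reproducible given ``seed``.

    ``unit="row"`` splits country-year rows; ``unit="country"`` keeps each
    country wholly on one side. Train size is floor(n * train_fraction).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if seed is None:
        raise ValueError("seed is mandatory for a reproducible split")
    rng = np.random.default_rng(seed)
    if unit == "row":
        n = panel.n_rows
        n_train = int(np.floor(n * train_fraction))
        perm = rng.permutation(n)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        train, test = panel.copy(), panel.copy()
        train.frame = panel.frame.iloc[train_idx].reset_index(drop=True)
        test.frame = panel.frame.iloc[test_idx].reset_index(drop=True)
    elif unit == "country":
        countries = panel.countries
        n_train = int(np.floor(len(countries) * train_fraction))
        perm = rng.permutation(len(countries))
        train_c = [countries[i] for i in np.sort(perm[:n_train])]
        test_c = [countries[i] for i in np.sort(perm[n_train:])]
        train, test = panel.subset(train_c), panel.subset(test_c)
    else:
        raise ValueError("unit must be 'row' or 'country'")
    if train.n_rows == 0 or test.n_rows == 0:
        raise ValueError("split leaves one side empty")
    return train, test
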