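"""Counterfactual intervention schedules and package enumeration.

An intervention schedule applies a subset ("package") of the 12 measures over
2015-2019, moving each member's normalized value by ``annual_intensity`` of
the [0, 1] range per year in its beneficial direction, accumulating
additively (4%/yr -> 20% cumulative over the five-year window) and clipping
to [0, 1]. Disease-specific interventions (air pollution, pneumococcal
vaccines, sanitation, road infrastructure) restrict the valid package space
for cause-specific searches.
"""

from __future__ import annotations

import itertools
import json
from collections.abc import Iterator
from dataclasses import dataclass, replace

import numpy as np

from .catalog import TOTAL_BURDEN, PanelDataset, VariableCatalog


@dataclass(frozen=True)
class InterventionSchedule:
    """Package membership + window + annual intensity.

    The cumulative fraction of the normalized range applied in year ``t`` is
    ``annual_intensity * (t - start_year + 1)``; at the defaults (4%/yr,
    2015-2019) the 2019 adjustment is 20% of the range.
    """

    package: tuple[str, ...]
    start_year: int = 2015
    end_year: int = 2019
    annual_intensity: float = 0.04
    mode: str = "normalized"  # or "raw_relative": v * (1 ± intensity·k)

    def __post_init__(self) -> None:
        object.__setattr__(self, "package", tuple(sorted(set(self.package))))
        if not self.package:
            raise ValueError("package must be nonempty")
        if self.start_year > self.end_year:
            raise ValueError("start_year must not exceed end_year")
        if self.annual_intensity <= 0:
            raise ValueError("annual_intensity must be positive")
        if self.mode not in ("normalized", "raw_relative"):
            raise ValueError("mode must be 'normalized' or 'raw_relative'")

    def cumulative(self, year: int) -> float:
        """Cumulative adjustment fraction in ``year`` (0 outside the window;
        the end-of-window level persists after ``end_year``)."""
        if year < self.start_year:
            return 0.0
        k = min(year, self.end_year) - self.start_year + 1
        return self.annual_intensity * k

    def with_package(self, package: tuple[str, ...]) -> "InterventionSchedule":
        return replace(self, package=tuple(package))

    def with_intensity(self, intensity: float) -> "InterventionSchedule":
        return replace(self, annual_intensity=intensity)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"package": list(self.package),
                       "window": [self.start_year, self.end_year],
                       "intensity": self.annual_intensity,
                       "mode": self.mode}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "InterventionSchedule":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["package"]), d["window"][0], d["window"][1],
                   d.get("intensity", 0.04), d.get("mode", "normalized"))


def apply_schedule(panel: PanelDataset, schedule: InterventionSchedule) -> PanelDataset:
    """Return the counterfactual panel under ``schedule``.

    Requires a normalized panel; every package member's value in each window
    year is shifted by ``direction * annual_intensity * years_elapsed`` of
    the normalized range (or scaled multiplicatively in ``raw_relative``
    mode) and clipped to [0, 1]. All other cells are untouched and the input
    panel is never modified. Counterfactual panels are tagged and refuse a
    second application.
    """
    if not panel.normalized:
        raise ValueError("apply_schedule requires a normalized panel")
    if panel.counterfactual:
        raise ValueError("panel is already counterfactual; refusing double application")
    catalog = panel.catalog
    unknown = [i for i in schedule.package if i not in set(catalog.interventions)]
    if unknown:
        raise KeyError(f"unknown interventions in package: {unknown}")
    out = panel.copy()
    years = out.frame["year"].to_numpy()
    cum = np.array([schedule.cumulative(int(y)) for y in years])
    active = cum > 0
    for name in schedule.package:
        d = catalog[name].benefit_direction
        v = out.frame[name].to_numpy(dtype=float)
        if schedule.mode == "normalized":
            shifted = v + d * cum
        else:
            shifted = v * (1.0 + d * cum)
        out.frame[name] = np.where(active, np.clip(shifted, 0.0, 1.0), v)
    out.counterfactual = True
    return out


def valid_packages(catalog: VariableCatalog, target: str) -> Iterator[tuple[str, ...]]:
    """All non-empty packages valid for ``target`` (a cause or the total).

    For the total burden this is every non-empty subset of the 12
    interventions (4095 packages); for a cause it is every non-empty subset
    of the interventions whose disease mask covers that cause (2^m - 1).
    Iteration order is deterministic: by size, then lexicographic.
    """
    valid = sorted(catalog.mask_valid(target))
    if not valid:
        raise ValueError(f"no valid interventions for target {target!r}")
    for size in range(1, len(valid) + 1):
        yield from itertools.combinations(valid, size)


def count_valid_packages(catalog: VariableCatalog, target: str) -> int:
    m = len(catalog.mask_valid(target))
    if m == 0:
        raise ValueError(f"no valid interventions for target {target!r}")
    return 2**m - 1
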