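"""Synthetic sex-age incidence panels with known ground-truth dynamics.

Generates GBD-shaped panels (2 sexes x 12 five-year age bands x 32 annual
observations by default) whose trends are analytic -- linear, logistic, or
piecewise-linear with one change-point -- so downstream stages can be tested
for parameter recovery without any restricted data download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .io import TimeSeriesPanel, PanelValidationError

__all__ = ["SyntheticSpec", "generate_panel", "write_gbd_csv", "default_age_bands"]

TREND_KINDS = ("linear", "logistic", "piecewise")


def default_age_bands(n: int = 12, start: int = 40, width: int = 5) -> list:
    """GBD-style labels '40-44' ... '90-94', '95+' (last band open-ended)."""
    bands = []
    for i in range(n):
        lo = start + i * width
        if i == n - 1:
            bands.append(f"{lo}+")
        else:
            bands.append(f"{lo}-{lo + width - 1}")
    return bands


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic panel; deterministic given ``seed``."""

    n_age_bands: int = 12
    sexes: tuple = ("Male", "Female")
    year_start: int = 1990
    year_end: int = 2021
    trend_kind: str = "logistic"
    changepoint_year: int | None = None
    noise_sd: float = 5.0
    sex_offset: float = 25.0
    seed: int = 0
    age_bands: list = field(default_factory=list)

    def __post_init__(self):
        if self.year_end - self.year_start + 1 < 12:
            raise PanelValidationError(
                "year range must span at least 12 years (window length + horizon)")
        if self.noise_sd < 0:
            raise PanelValidationError("noise_sd must be non-negative")
        if self.trend_kind not in TREND_KINDS:
            raise PanelValidationError(f"trend_kind must be one of {TREND_KINDS}")
        if self.n_age_bands < 1:
            raise PanelValidationError("need at least one age band")
        if not self.age_bands:
            self.age_bands = default_age_bands(self.n_age_bands)
        if len(self.age_bands) != self.n_age_bands:
            raise PanelValidationError("age_bands length disagrees with n_age_bands")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


def _trend_values(spec: SyntheticSpec, params: dict, years: np.ndarray) -> np.ndarray:
    t = years - spec.year_start
    if spec.trend_kind == "linear":
        return params["base"] + params["slope"] * t
    if spec.trend_kind == "logistic":
        mid = params["mid_year"] - spec.year_start
        return params["base"] + params["amplitude"] / (1.0 + np.exp(-params["rate"] * (t - mid)))
    # piecewise: one change-point, independent slopes before/after
    cp = params["changepoint_year"] - spec.year_start
    before = params["base"] + params["slope1"] * t
    after = params["base"] + params["slope1"] * cp + params["slope2"] * (t - cp)
    return np.where(t <= cp, before, after)


def _draw_band_params(spec: SyntheticSpec, rng: np.random.Generator, band_index: int) -> dict:
    """Male-series trend parameters for one age band; level rises with age."""
    span = spec.year_end - spec.year_start
    base = 120.0 + 90.0 * band_index + rng.uniform(-20.0, 20.0)
    if spec.trend_kind == "linear":
        return {"base": base, "slope": rng.uniform(2.0, 9.0)}
    if spec.trend_kind == "logistic":
        return {
            "base": base,
            "amplitude": rng.uniform(80.0, 220.0),
            "rate": rng.uniform(0.15, 0.4),
            "mid_year": spec.year_start + rng.uniform(0.35, 0.65) * span,
        }
    cp = spec.changepoint_year
    if cp is None:
        cp = spec.year_start + int(round(0.55 * span))
    return {
        "base": base,
        "slope1": rng.uniform(2.0, 8.0),
        "slope2": rng.uniform(-8.0, -2.0),
        "changepoint_year": cp,
    }


def generate_panel(spec: SyntheticSpec) -> TimeSeriesPanel:
    """Build a complete panel; ground truth is retained in ``panel.truth``.

    Each age band gets one analytic male trend; the female series is the
    male trend minus ``sex_offset`` (the systematic male-female gap).
    Independent Gaussian noise is added per (series, year) and values are
    clipped at zero, since incidence rates cannot be negative.
    """
    rng = np.random.default_rng(spec.seed)
    years = spec.years
    series: dict = {}
    truth: dict = {"spec": spec, "params": {}}
    for j, band in enumerate(spec.age_bands):
        params = _draw_band_params(spec, rng, j)
        male_trend = _trend_values(spec, params, years)
        for sex in spec.sexes:
            trend = male_trend if sex == spec.sexes[0] else male_trend - spec.sex_offset
            noise = rng.normal(0.0, spec.noise_sd, size=years.shape) if spec.noise_sd > 0 else 0.0
            series[(sex, band)] = np.clip(trend + noise, 0.0, None)
            truth["params"][(sex, band)] = dict(params)
    return TimeSeriesPanel(years=years, series=series, truth=truth)


def write_gbd_csv(panel: TimeSeriesPanel, path) -> None:
    """Write the panel as long-format CSV: year,sex,age_group,value[,lower,upper]."""
    has_bounds = bool(panel.bounds)
    header = ["year", "sex", "age_group", "value"]
    if has_bounds:
        header += ["lower", "upper"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for sex, band in panel.keys:
            values = panel.series[(sex, band)]
            for i, year in enumerate(panel.years):
                row = [int(year), sex, band, repr(float(values[i]))]
                if has_bounds:
                    lo, hi = panel.bounds[(sex, band)]
                    row += [repr(float(lo[i])), repr(float(hi[i]))]
                writer.writerow(row)
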