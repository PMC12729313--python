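"""Panel ingestion and per-series Z-score standardization.

A :class:`TimeSeriesPanel` holds one annual incidence series per
(sex, age band) cell on a shared, gap-free year grid.  Standardization is
per series, with statistics fitted on an explicit year range so that a
train-only fit never sees hold-out values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelValidationError",
    "DegenerateScaleError",
    "TimeSeriesPanel",
    "ScalerParams",
    "read_gbd_csv",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
]

REQUIRED_COLUMNS = ("year", "sex", "age_group", "value")
SEX_LABELS = ("Male", "Female")


class PanelValidationError(ValueError):
    """Raised when a panel or CSV violates the panel invariants."""


class DegenerateScaleError(ValueError):
    """Raised when a series is constant on the scaler fit window."""


def _canonical_sex(label: str) -> str:
    low = str(label).strip().lower()
    for canon in SEX_LABELS:
        if low == canon.lower():
            return canon
    raise PanelValidationError(f"unrecognized sex label {label!r}; expected one of {SEX_LABELS}")


def _band_sort_key(band: str):
    """Order age bands by their lower bound ('40-44' < '95+')."""
    token = str(band).split("-")[0].rstrip("+")
    try:
        return (0, float(token), str(band))
    except ValueError:
        return (1, 0.0, str(band))


@dataclass
class TimeSeriesPanel:
    """Sex x age-band x year grid of incidence rates (per 100,000)."""

    years: np.ndarray
    series: dict  # (sex, age_band) -> np.ndarray of rates, aligned with years
    bounds: dict = field(default_factory=dict)  # optional (sex, band) -> (lower, upper) arrays
    truth: dict = field(default_factory=dict)  # ground-truth generator parameters, if synthetic

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def sexes(self) -> tuple:
        seen = []
        for sex, _ in self.series:
            if sex not in seen:
                seen.append(sex)
        return tuple(sorted(seen, key=lambda s: SEX_LABELS.index(s) if s in SEX_LABELS else 99))

    @property
    def age_bands(self) -> tuple:
        seen = []
        for _, band in self.series:
            if band not in seen:
                seen.append(band)
        return tuple(sorted(seen, key=_band_sort_key))

    @property
    def keys(self) -> list:
        """Canonical series order: sex-major, age bands by lower bound."""
        return [(sex, band) for sex in self.sexes for band in self.age_bands]

    def validate(self) -> None:
        if self.n_years == 0:
            if self.series:
                raise PanelValidationError("panel has series but no years")
            return
        diffs = np.diff(self.years)
        if np.any(diffs != 1):
            raise PanelValidationError("year grid must be contiguous with step 1")
        for key, values in self.series.items():
            values = np.asarray(values, dtype=float)
            self.series[key] = values
            if values.shape != (self.n_years,):
                raise PanelValidationError(
                    f"series {key} has {values.shape[0]} values for {self.n_years} years")
            if np.any(~np.isfinite(values)):
                raise PanelValidationError(f"series {key} contains non-finite values")
            if np.any(values < 0):
                raise PanelValidationError(f"series {key} contains negative rates")
        bands = self.age_bands
        for sex in self.sexes:
            for band in bands:
                if (sex, band) not in self.series:
                    raise PanelValidationError(f"missing series for ({sex}, {band})")

    def matrix(self) -> np.ndarray:
        """(n_years, n_series) array in canonical key order."""
        return np.column_stack([self.series[k] for k in self.keys])

    def with_values(self, values: Mapping) -> "TimeSeriesPanel":
        return TimeSeriesPanel(years=self.years.copy(),
                               series={k: np.asarray(v, dtype=float) for k, v in values.items()},
                               truth=dict(self.truth))


def read_gbd_csv(path) -> TimeSeriesPanel:
    """Parse a long-format incidence CSV into a validated panel.

    The file must carry a header with at least ``year,sex,age_group,value``
    (any column order); ``lower``/``upper`` columns are kept as optional
    uncertainty bounds.  Duplicate (year, sex, age_group) rows, year gaps
    and negative rates are rejected with an error naming the offender.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"missing required column(s) {missing} in {path}")
    if len(df) == 0:
        return TimeSeriesPanel(years=np.array([], dtype=int), series={})
    df = df.copy()
    df["sex"] = df["sex"].map(_canonical_sex)
    df["age_group"] = df["age_group"].astype(str)
    df["year"] = df["year"].astype(int)

    dup = df.duplicated(subset=["year", "sex", "age_group"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate row for year={row['year']}, sex={row['sex']}, age_group={row['age_group']}")

    neg = df["value"] < 0
    if neg.any():
        row = df[neg].iloc[0]
        raise PanelValidationError(
            f"negative value for year={row['year']}, sex={row['sex']}, age_group={row['age_group']}")

    years = np.arange(df["year"].min(), df["year"].max() + 1)
    series: dict = {}
    bounds: dict = {}
    has_bounds = "lower" in df.columns and "upper" in df.columns
    for (sex, band), grp in df.groupby(["sex", "age_group"], sort=False):
        grp = grp.sort_values("year")
        if len(grp) != len(years) or not np.array_equal(grp["year"].to_numpy(), years):
            present = set(grp["year"])
            gap = sorted(set(years.tolist()) - present)
            raise PanelValidationError(
                f"series ({sex}, {band}) is missing year(s) {gap[:5]} on grid "
                f"{years[0]}-{years[-1]}")
        series[(sex, band)] = grp["value"].to_numpy(dtype=float)
        if has_bounds:
            bounds[(sex, band)] = (grp["lower"].to_numpy(dtype=float),
                                   grp["upper"].to_numpy(dtype=float))
    return TimeSeriesPanel(years=years, series=series, bounds=bounds)


# -- standardization -------------------------------------------------------


def _series_json_key(key) -> str:
    return f"{key[0]}|{key[1]}"


@dataclass
class ScalerParams:
    """Per-series mean/SD fitted on a stated year range (population SD)."""

    mean: dict
    sd: dict
    fit_years: tuple  # inclusive (start, end)

    def transform_value(self, key, x):
        return (np.asarray(x, dtype=float) - self.mean[key]) / self.sd[key]

    def invert_value(self, key, z):
        return np.asarray(z, dtype=float) * self.sd[key] + self.mean[key]

    def to_json(self) -> str:
        return json.dumps({
            "fit_years": list(self.fit_years),
            "mean": {_series_json_key(k): v for k, v in self.mean.items()},
            "sd": {_series_json_key(k): v for k, v in self.sd.items()},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScalerParams":
        obj = json.loads(text)

        def parse(d):
            out = {}
            for k, v in d.items():
                sex, band = k.split("|", 1)
                out[(sex, band)] = float(v)
            return out

        return cls(mean=parse(obj["mean"]), sd=parse(obj["sd"]),
                   fit_years=tuple(obj["fit_years"]))


def fit_standardizer(panel: TimeSeriesPanel, fit_years: Sequence[int] | None = None) -> ScalerParams:
    """Fit per-series mean/SD on ``fit_years`` only (population formula).

    ``fit_years`` is an inclusive (start, end) pair; ``None`` fits on the
    full year range.  Constant series raise :class:`DegenerateScaleError`.
    """
    if fit_years is None:
        fit_years = (int(panel.years[0]), int(panel.years[-1]))
    start, end = int(fit_years[0]), int(fit_years[-1])
    if start < panel.years[0] or end > panel.years[-1] or start > end:
        raise PanelValidationError(
            f"fit range {start}-{end} not within panel years {panel.years[0]}-{panel.years[-1]}")
    sel = (panel.years >= start) & (panel.years <= end)
    mean, sd = {}, {}
    for key, values in panel.series.items():
        seg = values[sel]
        mu = float(seg.mean())
        sigma = float(seg.std(ddof=0))
        if sigma == 0.0:
            raise DegenerateScaleError(f"series {key} is constant on fit range {start}-{end}")
        mean[key] = mu
        sd[key] = sigma
    return ScalerParams(mean=mean, sd=sd, fit_years=(start, end))


def apply_standardizer(panel: TimeSeriesPanel, scaler: ScalerParams) -> TimeSeriesPanel:
    missing = [k for k in panel.series if k not in scaler.mean]
    if missing:
        raise PanelValidationError(f"scaler does not cover series {missing[:3]}")
    values = {k: (v - scaler.mean[k]) / scaler.sd[k] for k, v in panel.series.items()}
    out = TimeSeriesPanel.__new__(TimeSeriesPanel)
    out.years = panel.years.copy()
    out.series = values
    out.bounds = {}
    out.truth = dict(panel.truth)
    return out  # standardized values may be negative: skip rate-scale validation


def invert_standardizer(values, scaler: ScalerParams, keys: Sequence | None = None):
    """Map standardized values back to the rate scale.

    ``values`` is (..., n_series) in the order of ``keys`` (defaults to the
    scaler's own sorted key order).
    """
    if keys is None:
        keys = sorted(scaler.mean)
    values = np.asarray(values, dtype=float)
    mu = np.array([scaler.mean[k] for k in keys])
    sd = np.array([scaler.sd[k] for k in keys])
    return values * sd + mu
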