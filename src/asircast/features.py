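"""Feature expansion and sliding-window framing.

Each standardized series contributes six model-input columns: the original
value plus five derived ones (3-year trailing mean, residual from that mean,
3-year trailing SD, male-female gap for its age band, EWMA).  A 24-series
panel therefore yields a 144-column matrix.  All rolling operators are
right-aligned with expanding warm-up, so the feature at year y depends only
on years <= y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TimeSeriesPanel, PanelValidationError

__all__ = [
    "moving_average",
    "residual_feature",
    "volatility",
    "sex_difference",
    "ewma",
    "build_feature_matrix",
    "make_windows",
    "split_sequential",
    "FeatureMatrix",
    "WindowedDataset",
    "SplitResult",
    "BLOCKS",
]

BLOCKS = ("original", "trend", "residual", "volatility", "sex_difference", "ewma")


def moving_average(series, k: int) -> np.ndarray:
    """Trailing k-year mean; the first k-1 years use the expanding mean."""
    if k < 1:
        raise ValueError("window length k must be >= 1")
    x = np.asarray(series, dtype=float)
    if k > len(x):
        raise ValueError(f"k={k} exceeds series length {len(x)}")
    out = np.empty_like(x)
    csum = np.cumsum(x)
    for i in range(len(x)):
        lo = max(0, i - k + 1)
        total = csum[i] - (csum[lo - 1] if lo > 0 else 0.0)
        out[i] = total / (i - lo + 1)
    return out


def residual_feature(series) -> np.ndarray:
    """Original value minus its 3-year trailing mean (short-term deviation)."""
    x = np.asarray(series, dtype=float)
    return x - moving_average(x, min(3, len(x)))


def volatility(series, k: int = 3) -> np.ndarray:
    """Trailing k-year population SD; expanding warm-up (first value 0)."""
    x = np.asarray(series, dtype=float)
    k = min(k, len(x))
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - k + 1)
        out[i] = x[lo:i + 1].std(ddof=0)
    return out


def ewma(series, decay: float = 0.3) -> np.ndarray:
    """Exponentially weighted moving average: s_t = decay*x_t + (1-decay)*s_{t-1}."""
    if not 0.0 < decay < 1.0:
        raise ValueError("decay must lie strictly between 0 and 1")
    x = np.asarray(series, dtype=float)
    out = np.empty_like(x)
    s = x[0]
    out[0] = s
    for i in range(1, len(x)):
        s = decay * x[i] + (1.0 - decay) * s
        out[i] = s
    return out


def sex_difference(panel: TimeSeriesPanel) -> dict:
    """Male_i - Female_i per age band, assigned to both sexes' feature slots.

    Returns a map (sex, age_band) -> column; the male and female columns for
    the same band are the identical array.
    """
    sexes = panel.sexes
    if len(sexes) != 2:
        raise PanelValidationError("sex_difference requires exactly two sexes")
    male, female = sexes
    out = {}
    for band in panel.age_bands:
        if (male, band) not in panel.series or (female, band) not in panel.series:
            raise PanelValidationError(f"both sexes required for age band {band}")
        diff = panel.series[(male, band)] - panel.series[(female, band)]
        out[(male, band)] = diff
        out[(female, band)] = diff
    return out


@dataclass
class FeatureMatrix:
    """(n_years, D) model-input matrix with a column manifest.

    ``manifest[j]`` is a dict with keys ``block``, ``sex``, ``age_band``;
    block order is fixed (original, trend, residual, volatility,
    sex_difference, ewma) and is part of the on-disk contract.
    """

    years: np.ndarray
    values: np.ndarray
    manifest: list
    diagnostics: dict | None = None  # optional 5-/7-year MA columns, not model input

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_names(self) -> list:
        return [f"{m['block']}|{m['sex']}|{m['age_band']}" for m in self.manifest]

    def columns_for_group(self, sex: str, age_band: str) -> list:
        return [j for j, m in enumerate(self.manifest)
                if m["sex"] == sex and m["age_band"] == age_band]


def build_feature_matrix(panel: TimeSeriesPanel, include_diagnostics: bool = False) -> FeatureMatrix:
    """Expand a standardized panel into the 6-block feature matrix.

    D = 6 x n_series (144 for the canonical 24-series panel).  The trend
    block is the 3-year trailing mean only -- the same reference used by the
    residual block -- so the dimension count closes; 5- and 7-year means are
    exported as diagnostics when requested, never as model input.
    """
    keys = panel.keys
    sexdiff = sex_difference(panel)
    blocks = {
        "original": {k: panel.series[k] for k in keys},
        "trend": {k: moving_average(panel.series[k], min(3, panel.n_years)) for k in keys},
        "residual": {k: residual_feature(panel.series[k]) for k in keys},
        "volatility": {k: volatility(panel.series[k]) for k in keys},
        "sex_difference": sexdiff,
        "ewma": {k: ewma(panel.series[k]) for k in keys},
    }
    columns, manifest = [], []
    for block in BLOCKS:
        for sex, band in keys:
            columns.append(blocks[block][(sex, band)])
            manifest.append({"block": block, "sex": sex, "age_band": band})
    values = np.column_stack(columns)
    if np.any(~np.isfinite(values)):
        raise PanelValidationError("feature matrix contains non-finite values")
    diagnostics = None
    if include_diagnostics:
        diagnostics = {}
        for k_ma in (5, 7):
            if k_ma <= panel.n_years:
                diagnostics[f"ma{k_ma}"] = {k: moving_average(panel.series[k], k_ma) for k in keys}
    return FeatureMatrix(years=panel.years.copy(), values=values,
                         manifest=manifest, diagnostics=diagnostics)


@dataclass
class WindowedDataset:
    """Supervised samples: (B, T, D) inputs and (B, G) next-year targets."""

    inputs: np.ndarray
    targets: np.ndarray
    target_years: np.ndarray
    group_keys: list  # G (sex, age_band) pairs, target column order
    window: int

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    def subset(self, mask) -> "WindowedDataset":
        mask = np.asarray(mask)
        return WindowedDataset(inputs=self.inputs[mask], targets=self.targets[mask],
                               target_years=self.target_years[mask],
                               group_keys=list(self.group_keys), window=self.window)


def make_windows(fm: FeatureMatrix, target_panel: TimeSeriesPanel,
                 window: int = 10, horizon: int = 1) -> WindowedDataset:
    """Frame supervised samples with a ``window``-year input per target year.

    The input for target year y covers exactly years [y-window, y-1]; the
    target is the standardized value at y for every group.
    """
    if horizon != 1:
        raise ValueError("only a 1-year prediction step is supported")
    if not np.array_equal(fm.years, target_panel.years):
        raise PanelValidationError("feature matrix and target panel must share the year index")
    n_years = len(fm.years)
    n_samples = n_years - window
    if n_samples < 1:
        raise PanelValidationError(
            f"need more than window={window} years, got {n_years}")
    keys = target_panel.keys
    target_matrix = target_panel.matrix()
    inputs = np.stack([fm.values[i:i + window] for i in range(n_samples)])
    targets = target_matrix[window:]
    target_years = fm.years[window:]
    return WindowedDataset(inputs=inputs, targets=targets, target_years=target_years,
                           group_keys=keys, window=window)


@dataclass
class SplitResult:
    train: WindowedDataset
    test: WindowedDataset
    boundary_year: int
    train_period: tuple  # inclusive calendar span of all years touching training
    test_period: tuple  # inclusive calendar span of test target years

    @property
    def n_train_period_years(self) -> int:
        return self.train_period[1] - self.train_period[0] + 1

    @property
    def n_test_period_years(self) -> int:
        return self.test_period[1] - self.test_period[0] + 1


def split_sequential(ds: WindowedDataset, boundary_year: int = 2016) -> SplitResult:
    """Walk-forward split: train targets <= boundary_year < test targets.

    Training samples (inputs and targets) touch only years up to the
    boundary; only test-sample windows may span it.
    """
    years = ds.target_years
    if boundary_year < years[0] or boundary_year >= years[-1]:
        raise PanelValidationError(
            f"boundary {boundary_year} must leave both partitions non-empty "
            f"(target years {years[0]}-{years[-1]})")
    train_mask = years <= boundary_year
    train, test = ds.subset(train_mask), ds.subset(~train_mask)
    first_input_year = int(years[0]) - ds.window
    return SplitResult(train=train, test=test, boundary_year=boundary_year,
                       train_period=(first_input_year, boundary_year),
                       test_period=(int(years[~train_mask][0]), int(years[-1])))
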