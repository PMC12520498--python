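"""Directional brain-heart coupling via windowed ARX models.

Four coefficient time series are estimated on a sliding window (default
15 s window, 1 s step) from the midline beta-power series and the HRV
LF/HF power series (the latter taken from the full-record time-frequency
surface, not re-estimated per window):

* heart->brain (``hf2b``, ``lf2b``): ARX fit of the standardized beta
  power on its own past plus lagged standardized HRV power; the
  coefficient is the net exogenous gain (sum of the exogenous weights).
* brain->heart (``b2hf``, ``b2lf``): the standardized beta series drives
  a deterministic generative heart model -- an oscillator whose
  modulation amplitude is ``1 + c * beta~(t - delay)``, whose
  instantaneous band power is the squared amplitude -- and the observed
  HRV power is regressed on that synthetic predictor plus its own past.

The model/results pair follows the statsmodels convention:
``BrainHeartModel(beta, hrv, config).fit()`` returns
:class:`BrainHeartResults` carrying the :class:`CouplingSeries`,
condition means and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate

from .datatypes import BandPowerSeries, CouplingSeries, HrvMetricSeries

__all__ = [
    "CouplingConfig",
    "BrainHeartModel",
    "BrainHeartResults",
    "align_series",
    "estimate_h2b",
    "estimate_b2h",
    "postprocess_coupling",
    "condition_mean_coupling",
    "exclude_coupling_outliers",
]


@dataclass(frozen=True)
class CouplingConfig:
    """Sliding-window and lag structure for the ARX coupling estimates."""

    window: float = 15.0  # s
    step: float = 1.0  # s
    na: int = 2  # autoregressive order (heart->brain fits)
    na_b2h: int = 0  # autoregressive order of the brain->heart fits (see notes)
    nb: int = 2  # exogenous order
    delay: int = 2  # samples at grid_rate (~ the 2 s coupling delay)
    grid_rate: float = 1.0  # Hz, common resampling grid
    predictor_gain: float = 0.5  # c in the generative brain->heart predictor
    standardize: bool = True

    def __post_init__(self):
        min_span = (max(self.na, self.na_b2h) + self.nb + self.delay + 3) / self.grid_rate
        if self.window <= min_span:
            raise ValueError(f"window {self.window}s too short for lag structure (needs > {min_span}s)")
        if self.step > self.window:
            raise ValueError("step must not exceed window")


def align_series(
    beta: BandPowerSeries, hrv: HrvMetricSeries, grid_rate: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Linear resampling of beta power and HRV LF/HF onto a common grid.

    Returns ``(t, beta, lf, hf)`` on a ``grid_rate`` grid covering the
    intersection of supports.
    """
    t0 = max(beta.times[0], hrv.times[0])
    t1 = min(beta.times[-1], hrv.times[-1])
    if t1 - t0 < 1.0 / grid_rate:
        raise ValueError("overlap between beta and HRV series too short")
    t = np.arange(np.ceil(t0 * grid_rate), np.floor(t1 * grid_rate) + 1) / grid_rate
    b = np.interp(t, beta.times, beta.band("beta"))
    lf = np.interp(t, hrv.times, hrv.lf)
    hf = np.interp(t, hrv.times, hrv.hf)
    return t, b, lf, hf


def _arx_fit(y: np.ndarray, u: np.ndarray, na: int, nb: int, delay: int) -> float:
    """Least-squares ARX fit; returns the net exogenous gain sum(b_j).

    ``na = 0`` drops the autoregressive terms (pure exogenous fit).
    Returns NaN on rank deficiency or constant regressors.
    """
    p = max(na, delay + nb - 1)
    n = y.size
    if n - p < na + nb + 2:
        return np.nan
    rows = []
    for i in range(1, na + 1):
        rows.append(y[p - i : n - i])
    for j in range(nb):
        lag = delay + j
        rows.append(u[p - lag : n - lag])
    X = np.column_stack(rows)
    target = y[p:]
    if np.any(X.std(axis=0) == 0):
        return np.nan
    coef, _, rank, _ = np.linalg.lstsq(X, target, rcond=None)
    if rank < X.shape[1]:
        return np.nan
    return float(coef[na:].sum())


def _zscore(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def _windowed_coefficients(
    t: np.ndarray,
    y: np.ndarray,
    u: np.ndarray,
    config: CouplingConfig,
    synthetic_predictor: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slide the ARX fit over windows; returns (centers, coeffs, flags)."""
    dt = 1.0 / config.grid_rate
    wlen = int(round(config.window / dt))
    step = int(round(config.step / dt))
    centers, coeffs, flags = [], [], []
    for start in range(0, t.size - wlen + 1, step):
        sl = slice(start, start + wlen)
        yy, uu = y[sl], u[sl]
        centers.append(t[start] + config.window / 2.0)
        if config.standardize:
            yz, uz = _zscore(yy), _zscore(uu)
        else:
            yz, uz = yy, uu
        if yz is None or uz is None:
            coeffs.append(np.nan)
            flags.append("constant")
            continue
        na = config.na
        if synthetic_predictor:
            uz2 = _predictor_from_beta(uz, config)
            if uz2 is None:
                coeffs.append(np.nan)
                flags.append("constant")
                continue
            uz = uz2
            na = config.na_b2h
        c = _arx_fit(yz, uz, na, config.nb, config.delay)
        coeffs.append(c)
        flags.append("ok" if np.isfinite(c) else "rank_deficient")
    return np.asarray(centers), np.asarray(coeffs), np.asarray(flags)


def _predictor_from_beta(beta_z: np.ndarray, config: CouplingConfig) -> np.ndarray | None:
    """Deterministic generative-heart predictor from the standardized beta.

    The oscillator amplitude is 1 + c * beta~ (floored at 0.05 to keep the
    rate admissible); its instantaneous band power is the squared
    amplitude, which is what the observed HRV power is regressed on.
    """
    amp = np.clip(1.0 + config.predictor_gain * beta_z, 0.05, None)
    p = amp**2
    return _zscore(p)


def estimate_h2b(
    t: np.ndarray, beta: np.ndarray, hrv_power: np.ndarray, config: CouplingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Heart->brain: beta regressed on its own past + lagged HRV power."""
    return _windowed_coefficients(t, beta, hrv_power, config, synthetic_predictor=False)


def estimate_b2h(
    t: np.ndarray, beta: np.ndarray, hrv_power: np.ndarray, config: CouplingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brain->heart: HRV power regressed on the beta-driven synthetic predictor."""
    return _windowed_coefficients(t, hrv_power, beta, config, synthetic_predictor=True)


def postprocess_coupling(series: CouplingSeries, eeg_times: np.ndarray) -> CouplingSeries:
    """Cubic-spline interpolation of the coefficients onto the EEG frame grid.

    Flagged (NaN) windows are excluded from the spline support; at least
    four valid windows are required.  Evaluation is restricted to the
    window-time support (no extrapolation).
    """
    eeg_times = np.asarray(eeg_times, dtype=float)
    splines = {}
    lo, hi = -np.inf, np.inf
    for name in CouplingSeries.COEFFICIENTS:
        vals = getattr(series, name)
        ok = np.isfinite(vals)
        if ok.sum() < 4:
            raise ValueError(f"fewer than 4 valid windows for {name}")
        splines[name] = interpolate.CubicSpline(series.times[ok], vals[ok])
        lo = max(lo, series.times[ok][0])
        hi = min(hi, series.times[ok][-1])
    t_out = eeg_times[(eeg_times >= lo) & (eeg_times <= hi)]
    vals = {name: splines[name](t_out) for name in splines}
    return CouplingSeries(t_out, vals["b2hf"], vals["b2lf"], vals["hf2b"], vals["lf2b"])


def condition_mean_coupling(
    series: CouplingSeries, condition: str, exclusion: float = 188.0
) -> dict[str, float]:
    cutoff = exclusion if condition == "zen" else -np.inf
    mask = series.times > cutoff
    if not mask.any():
        raise ValueError("no coupling samples remain after exclusion")
    out = {}
    for name in CouplingSeries.COEFFICIENTS:
        vals = getattr(series, name)[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no valid {name} samples remain")
        out[name] = float(vals.mean())
    return out


def exclude_coupling_outliers(
    means: pd.DataFrame, column: str = "hf2b", group_col: str = "group"
) -> tuple[pd.DataFrame, list[str]]:
    """Drop participants whose averaged HF2B falls outside their group's
    5th-95th percentile range (coupling statistics only).

    ``means`` needs columns ``participant``, ``group`` and ``column``
    (one row per participant).  Returns (filtered, excluded ids).
    """
    excluded: list[str] = []
    keep_idx = []
    for g, sub in means.groupby(group_col):
        if len(sub) < 5:
            keep_idx.extend(sub.index)
            continue
        lo, hi = np.percentile(sub[column], [5, 95])
        inside = (sub[column] >= lo) & (sub[column] <= hi)
        keep_idx.extend(sub.index[inside])
        excluded.extend(sub.loc[~inside, "participant"].tolist())
    return means.loc[sorted(keep_idx)].reset_index(drop=True), excluded


class BrainHeartModel:
    """Windowed ARX model of directional coupling between midline beta
    power and HRV LF/HF power.

    Parameters
    ----------
    beta : BandPowerSeries
        Relative beta power (electrode-group averaged).
    hrv : HrvMetricSeries
        LF/HF power series from the full-record spectrogram (15 s / 1 s
        windows for the coupling branch).
    config : CouplingConfig
    """

    def __init__(self, beta: BandPowerSeries, hrv: HrvMetricSeries,
                 config: CouplingConfig = CouplingConfig()):
        self.beta = beta
        self.hrv = hrv
        self.config = config

    def fit(self) -> "BrainHeartResults":
        cfg = self.config
        t, b, lf, hf = align_series(self.beta, self.hrv, cfg.grid_rate)
        if t[-1] - t[0] < cfg.window:
            raise ValueError("overlap shorter than one coupling window")
        centers, b2hf, f_b2hf = estimate_b2h(t, b, hf, cfg)
        _, b2lf, f_b2lf = estimate_b2h(t, b, lf, cfg)
        _, hf2b, f_hf2b = estimate_h2b(t, b, hf, cfg)
        _, lf2b, f_lf2b = estimate_h2b(t, b, lf, cfg)
        flags = np.where(
            (f_b2hf == "ok") & (f_b2lf == "ok") & (f_hf2b == "ok") & (f_lf2b == "ok"),
            "ok", "flagged",
        )
        series = CouplingSeries(centers, b2hf, b2lf, hf2b, lf2b, flags)
        return BrainHeartResults(self, series)


class BrainHeartResults:
    """Fitted coupling coefficient series with summaries and interpolation."""

    def __init__(self, model: BrainHeartModel, series: CouplingSeries):
        self.model = model
        self.series = series

    @property
    def n_windows(self) -> int:
        return int(self.series.times.size)

    def interpolated(self, eeg_times: np.ndarray) -> CouplingSeries:
        return postprocess_coupling(self.series, eeg_times)

    def condition_mean(self, condition: str, exclusion: float = 188.0,
                       eeg_times: np.ndarray | None = None) -> dict[str, float]:
        series = self.series if eeg_times is None else self.interpolated(eeg_times)
        return condition_mean_coupling(series, condition, exclusion)

    def to_frame(self) -> pd.DataFrame:
        s = self.series
        return pd.DataFrame(
            {"time_s": s.times, "b2hf": s.b2hf, "b2lf": s.b2lf,
             "hf2b": s.hf2b, "lf2b": s.lf2b, "flag": s.quality_flags}
        )

    def summary(self) -> str:
        s = self.series
        cfg = self.model.config
        lines = [
            "Brain-heart coupling (windowed ARX)",
            f"  windows: {self.n_windows} ({cfg.window:.0f} s window, {cfg.step:.0f} s step, "
            f"na={cfg.na}, nb={cfg.nb}, delay={cfg.delay})",
        ]
        for name in CouplingSeries.COEFFICIENTS:
            vals = getattr(s, name)
            vals = vals[np.isfinite(vals)]
            lines.append(
                f"  {name:>5}: mean {vals.mean():+.4f}  sd {vals.std():.4f}  (n={vals.size})"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Coefficient time courses on one axis (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        for name in CouplingSeries.COEFFICIENTS:
            ax.plot(self.series.times, getattr(self.series, name), label=name.upper())
        ax.set_xlabel("time (s)")
        ax.set_ylabel("coupling coefficient")
        ax.legend(ncol=4, fontsize=8)
        return ax
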