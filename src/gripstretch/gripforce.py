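"""Grip-force decomposition analyses.

Four complementary views of predictive grip-force control during probing of
an elastic field:

* the peak grip force / peak load force ratio per probe;
* an ordinary least-squares regression in the grip-load plane per probe,
  whose intercept estimates the baseline (safety margin) and whose slope
  estimates the anticipatory modulation;
* the between-probe grip-force baseline, read from the quiescent epoch
  between consecutive movements;
* the intended-peak decomposition: a multivariate regression trained on
  stretch-catch probes predicts the peak grip force a participant intended
  from the grip force and its rate at first contact
  (``peak = a*GF_contact + b*dGF/dt + c``); the grip-force modulation is
  that intended peak minus the grip force at contact.

Because stretch-catch probes deliver the load but omit the stretch, their
grip traces contain only the predictive component, which is why they train
the intended-peak model and anchor the decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .preprocess import Probe

logger = logging.getLogger(__name__)

__all__ = [
    "GFLFRegression",
    "GripDecomposition",
    "IntendedPeakRegressor",
    "peak_ratio",
    "gf_lf_regression",
    "baseline_between_probes",
    "baseline_before_probe",
    "contact_features",
    "fit_intended_peak_model",
    "predict_intended_peak",
    "decompose",
    "delta_vs_zero_gain",
    "first_last_ratio_analysis",
]


@dataclass(frozen=True)
class GFLFRegression:
    """OLS of grip on load over one probe's contact interval."""

    slope: float  # dimensionless grip per load
    intercept: float  # N
    r2: float
    n_samples: int
    excluded: bool  # negative slope: large grip/load phase shift


@dataclass(frozen=True)
class GripDecomposition:
    """Predictive grip-force components of one probing movement."""

    baseline: float  # N (nan if no quiescent epoch qualified)
    gf_contact: float  # N
    gf_rate_contact: float  # N/s
    intended_peak: float  # N
    modulation: float  # N, == intended_peak - gf_contact
    probe_number: int
    gain: float  # mm/m


def peak_ratio(probe: Probe) -> float:
    """Peak grip force / peak load force of one probe."""
    if not probe.peak_load > 0:
        raise ValueError("peak load must be positive")
    return probe.peak_grip / probe.peak_load


def gf_lf_regression(
    probe: Probe, load: np.ndarray, grip: np.ndarray
) -> GFLFRegression:
    """Two-degrees-of-freedom regression line in the grip-load plane.

    Fit over the probe's in-contact samples.  A negative slope marks a large
    phase shift between the two signals and flags the probe for exclusion.
    """
    sl = slice(probe.contact_idx, probe.contact_end)
    x = np.asarray(load, dtype=float)[sl]
    g = np.asarray(grip, dtype=float)[sl]
    if x.size < 3:
        raise ValueError("need at least 3 in-contact samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate probe: constant load")
    slope, intercept = np.polyfit(x, g, 1)
    resid = g - (slope * x + intercept)
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return GFLFRegression(
        slope=float(slope),
        intercept=float(intercept),
        r2=min(max(r2, 0.0), 1.0),
        n_samples=int(x.size),
        excluded=bool(slope < 0),
    )


def _baseline_in_gap(
    grip: np.ndarray,
    fs: float,
    gap_start: int,
    gap_end: int,
    rate_thresh: float = 0.1,
    window: float = 0.200,
) -> float:
    """First quiescent instant in an out-of-contact gap, averaged backwards.

    Scans from ``gap_start + window`` for the first sample whose
    backward-difference grip rate is below ``rate_thresh`` (N/s) and returns
    the mean grip over the trailing ``window`` seconds.  Returns NaN when no
    instant qualifies (the trial's baseline is then undefined).
    """
    grip = np.asarray(grip, dtype=float)
    win = int(round(window * fs))
    if gap_end - gap_start < win:
        logger.warning("gap shorter than the averaging window; baseline undefined")
        return np.nan
    rate = np.empty_like(grip)
    rate[0] = 0.0
    rate[1:] = np.diff(grip) * fs
    for i in range(gap_start + win, gap_end):
        if abs(rate[i]) < rate_thresh:
            return float(np.mean(grip[i - win + 1 : i + 1]))
    logger.warning("no quiescent instant in gap [%d, %d)", gap_start, gap_end)
    return np.nan


def baseline_between_probes(
    grip: np.ndarray,
    fs: float,
    probe_i: Probe,
    probe_j: Probe,
    rate_thresh: float = 0.1,
    window: float = 0.200,
) -> float:
    """Grip-force baseline in the gap between two consecutive probes, N."""
    if probe_j.probe_number != probe_i.probe_number + 1:
        raise ValueError("probes must be consecutive")
    return _baseline_in_gap(
        grip, fs, probe_i.contact_end, probe_j.contact_idx, rate_thresh, window
    )


def baseline_before_probe(
    grip: np.ndarray,
    fs: float,
    probe: Probe,
    rate_thresh: float = 0.1,
    window: float = 0.200,
) -> float:
    """Baseline in the out-of-contact epoch preceding one probe, N.

    For the first probe this is the initial rest epoch; for later probes it
    is the gap after the previous probe's contact (``start_idx`` already
    points at the end of the previous contact run).
    """
    return _baseline_in_gap(
        grip, fs, probe.start_idx, probe.contact_idx, rate_thresh, window
    )


def contact_features(
    probe: Probe, grip: np.ndarray, fs: float
) -> tuple[float, float]:
    """(grip force, backward-difference grip-force rate) at first contact."""
    i = probe.contact_idx
    if i < 1:
        raise ValueError("contact at the first sample: no backward difference")
    grip = np.asarray(grip, dtype=float)
    return float(grip[i]), float((grip[i] - grip[i - 1]) * fs)


class IntendedPeakRegressor(RegressorMixin, BaseEstimator):
    """Multivariate regression for the intended peak grip force.

    Least squares of ``peak = a*gf_contact + b*gf_rate_contact + c`` on
    stretch-catch probe features.  Since catch probes omit the stretch, the
    observed peak there is purely predictive, and the fitted map recovers
    the peak a participant *intended* on any probe from information available
    before the stretch stimulus can act.

    Fitted attributes: ``a_`` (dimensionless), ``b_`` (s), ``c_`` (N),
    ``coef_``, ``intercept_``, ``r2_``.
    """

    def fit(self, X, y) -> "IntendedPeakRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_probes, 2): contact grip and rate")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 stretch-catch probes")
        design = np.column_stack([X, np.ones(len(X))])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("collinear design: coefficients not identifiable")
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        self.a_, self.b_, self.c_ = (float(v) for v in coef)
        self.coef_ = np.array([self.a_, self.b_])
        self.intercept_ = self.c_
        pred = design @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = (
            1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
        )
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "a_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    @classmethod
    def from_coefficients(
        cls, a: float, b: float, c: float
    ) -> "IntendedPeakRegressor":
        """Build an already-'fitted' model from known coefficients."""
        model = cls()
        model.a_, model.b_, model.c_ = float(a), float(b), float(c)
        model.coef_ = np.array([model.a_, model.b_])
        model.intercept_ = model.c_
        model.r2_ = np.nan
        model.n_features_in_ = 2
        return model


def fit_intended_peak_model(
    catch_features: pd.DataFrame | np.ndarray,
) -> IntendedPeakRegressor:
    """Fit the intended-peak model on stretch-catch probe features.

    Accepts a table with columns (gf_contact, gf_rate_contact, peak_grip)
    or an (n, 3) array in that column order.
    """
    if isinstance(catch_features, pd.DataFrame):
        X = catch_features[["gf_contact", "gf_rate_contact"]].to_numpy()
        y = catch_features["peak_grip"].to_numpy()
    else:
        arr = np.asarray(catch_features, dtype=float)
        X, y = arr[:, :2], arr[:, 2]
    return IntendedPeakRegressor().fit(X, y)


def predict_intended_peak(
    model: IntendedPeakRegressor, gf_contact, gf_rate_contact
):
    """Intended peak grip force for given contact features, N."""
    X = np.column_stack(
        [np.atleast_1d(gf_contact), np.atleast_1d(gf_rate_contact)]
    )
    out = model.predict(X)
    return float(out[0]) if np.isscalar(gf_contact) else out


def decompose(
    probe: Probe,
    grip: np.ndarray,
    fs: float,
    model: IntendedPeakRegressor,
    baseline: float,
    gain: float = 0.0,
) -> GripDecomposition:
    """Assemble the predictive grip-force components of one probe."""
    gf_contact, rate = contact_features(probe, grip, fs)
    intended = predict_intended_peak(model, gf_contact, rate)
    return GripDecomposition(
        baseline=baseline,
        gf_contact=gf_contact,
        gf_rate_contact=rate,
        intended_peak=intended,
        modulation=intended - gf_contact,
        probe_number=probe.probe_number,
        gain=gain,
    )


def delta_vs_zero_gain(
    table: pd.DataFrame,
    value: str = "value",
    participant: str = "participant",
    probe: str = "probe_number",
    gain: str = "gain",
) -> pd.DataFrame:
    """Subtract each cell's zero-gain value within (participant, probe).

    Isolates the effect of the stretch: after differencing, the gain-0
    column is exactly zero and every other entry is the change caused by
    that gain.  Raises if any (participant, probe) cell lacks a gain-0 entry.
    """
    out = table.copy()
    zero = (
        table[table[gain] == 0]
        .set_index([participant, probe])[value]
        .rename("_zero")
    )
    missing = (
        out.set_index([participant, probe]).index.unique().difference(zero.index)
    )
    if len(missing):
        raise ValueError(f"missing gain-0 cells for {list(missing)[:10]}")
    merged = out.join(zero, on=[participant, probe])
    out[value] = merged[value] - merged["_zero"]
    return out


def first_last_ratio_analysis(probe_table: pd.DataFrame) -> pd.DataFrame:
    """Paired first/last peak-ratio per free-exploration trial.

    ``probe_table`` needs columns (trial, probe_number, peak_grip,
    peak_load) and optionally gain.  Trials with a single probe are dropped
    (no first/last pair to compare).
    """
    rows = []
    for trial, g in probe_table.groupby("trial"):
        g = g.sort_values("probe_number")
        if len(g) < 2:
            continue  # probed only once: excluded
        first, last = g.iloc[0], g.iloc[-1]
        row = dict(
            trial=trial,
            first_ratio=first["peak_grip"] / first["peak_load"],
            last_ratio=last["peak_grip"] / last["peak_load"],
            n_probes=len(g),
        )
        if "gain" in g.columns:
            row["gain"] = first["gain"]
        rows.append(row)
    return pd.DataFrame(rows)
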