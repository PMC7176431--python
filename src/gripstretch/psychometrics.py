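"""Psychometric-curve fitting: PSE and JND versus stretch gain.

Each participant's 2AFC responses ("the comparison field was stiffer") are
modelled, separately per tactor displacement gain, as a cumulative-Gaussian
function of the stiffness difference dk between the comparison and standard
fields:

    P(choose comparison | dk) = lapse/2 + (1 - lapse) * F((dk - mu) / sigma)

with F the standard normal CDF (a logistic link is available).  The point of
subjective equality (PSE) is the dk at which the curve crosses 0.5 — for a
symmetric lapse this equals ``mu`` — and the just-noticeable difference
(JND) is half the dk span between the 0.25 and 0.75 points, which for a
lapse-free Gaussian equals ``0.6745*sigma``.  A positive PSE means the
stretch-augmented standard field was perceived as stiffer than it is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.stats import logistic as logistic_dist
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PsychometricCurve",
    "fit_psychometric",
    "pse",
    "jnd",
    "pse_vs_gain",
]

_LINKS = {"probit": norm, "logit": logistic_dist}
_Z75 = float(norm.ppf(0.75))  # 0.6744897...


class PsychometricCurve(BaseEstimator):
    """Maximum-likelihood psychometric function for 2AFC responses.

    Parameters
    ----------
    link : {"probit", "logit"}
        Shape of the underlying sigmoid (cumulative Gaussian by default).
    lapse : float
        Fixed symmetric lapse/guess rate in [0, 0.5); 0 by default.

    max_sigma_factor : float
        Identifiability guard: a fitted spread of at least this fraction of
        the sampled stimulus span flags the fit as non-converged.

    Fitted attributes: ``mu_`` (location, N/m), ``sigma_`` (spread, N/m),
    ``pse_``, ``jnd_``, ``n_trials_``, ``converged_``.  Degenerate data
    (a single response category, perfectly separated responses, or a spread
    too large to identify within the sampled range) yield
    ``converged_ = False`` rather than an exception.
    """

    def __init__(
        self, link: str = "probit", lapse: float = 0.0, max_sigma_factor: float = 0.5
    ):
        self.link = link
        self.lapse = lapse
        self.max_sigma_factor = max_sigma_factor

    def _dist(self):
        try:
            return _LINKS[self.link]
        except KeyError:
            raise ValueError(f"unknown link {self.link!r}") from None

    def _prob(self, x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
        f = self._dist().cdf((x - mu) / sigma)
        return self.lapse / 2 + (1 - self.lapse) * f

    def fit(self, X, y) -> "PsychometricCurve":
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")
        self._dist()  # validate the link early
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(x).size < 2:
            raise ValueError("need responses at >= 2 distinct stimulus levels")
        self.n_trials_ = int(x.size)

        # aggregate to (level, n, k) for a cheap likelihood
        levels, inverse = np.unique(x, return_inverse=True)
        n = np.bincount(inverse).astype(float)
        k = np.bincount(inverse, weights=y)
        span = float(levels[-1] - levels[0])

        frac_by_level = k / n
        degenerate = k.sum() == 0 or k.sum() == n.sum()
        # perfectly separated responses (all 0s below a threshold, all 1s
        # above) fit exactly for any sufficiently small spread: flag early
        separated_data = (
            np.all((frac_by_level == 0) | (frac_by_level == 1))
            and np.all(np.diff(frac_by_level) >= 0)
        )
        if degenerate or separated_data:
            self.mu_, self.sigma_ = np.nan, np.nan
            self.pse_, self.jnd_ = np.nan, np.nan
            self.converged_ = False
            return self

        def nll(theta: np.ndarray) -> float:
            mu, log_sigma = theta
            p = np.clip(
                self._prob(levels, mu, np.exp(log_sigma)), 1e-9, 1 - 1e-9
            )
            return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

        # moment-style start: weighted mean/sd of levels by response flips
        frac = k / n
        w = np.abs(np.gradient(frac, levels)) + 1e-9
        mu0 = float(np.sum(levels * w) / np.sum(w))
        sigma0 = max(span / 4, 1e-3)
        res = minimize(
            nll,
            x0=np.array([mu0, np.log(sigma0)]),
            method="Nelder-Mead",
            options=dict(xatol=1e-6, fatol=1e-9, maxiter=2000),
        )
        self.mu_ = float(res.x[0])
        self.sigma_ = float(np.exp(res.x[1]))
        # perfectly separated responses drive sigma to 0; conversely a spread
        # approaching the sampled span means the sigmoid is near-linear over
        # the data and location/spread are no longer jointly identified.
        # Both cases are flagged rather than raised.
        separated = self.sigma_ < 1e-3 * span
        unidentified = self.sigma_ >= self.max_sigma_factor * span
        self.converged_ = bool(res.success and not separated and not unidentified)
        self.pse_ = self._quantile(0.5)
        self.jnd_ = (self._quantile(0.75) - self._quantile(0.25)) / 2
        return self

    def _quantile(self, q: float) -> float:
        """dk at which the (lapse-adjusted) curve reaches probability q."""
        lo, hi = self.lapse / 2, 1 - self.lapse / 2
        if not lo < q < hi:
            return np.nan
        inner = (q - self.lapse / 2) / (1 - self.lapse)
        return self.mu_ + self.sigma_ * float(self._dist().ppf(inner))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "mu_")
        return self._prob(np.asarray(X, dtype=float).reshape(-1), self.mu_, self.sigma_)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= 0.5

    def quantile(self, q: float) -> float:
        check_is_fitted(self, "mu_")
        return self._quantile(q)


def fit_psychometric(
    responses, link: str = "probit", lapse: float = 0.0
) -> PsychometricCurve:
    """Fit a psychometric curve to (delta_k, chose_comparison) pairs.

    ``responses`` may be an iterable of 2-tuples or a DataFrame with
    ``delta_k`` and ``chose_comparison`` columns.
    """
    if isinstance(responses, pd.DataFrame):
        x = responses["delta_k"].to_numpy()
        y = responses["chose_comparison"].to_numpy()
    else:
        arr = np.asarray(list(responses), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    return PsychometricCurve(link=link, lapse=lapse).fit(x, y)


def pse(fit: PsychometricCurve) -> float:
    """Point of subjective equality: dk where P(choose comparison) = 0.5."""
    if not getattr(fit, "converged_", False):
        raise ValueError("psychometric fit did not converge")
    return fit.pse_


def jnd(fit: PsychometricCurve) -> float:
    """Just-noticeable difference: half the 0.25-0.75 probability span."""
    if not getattr(fit, "converged_", False):
        raise ValueError("psychometric fit did not converge")
    return fit.jnd_


def pse_vs_gain(
    fits: pd.DataFrame,
    gains: tuple[float, ...] = (0.0, 33.0, 66.0, 100.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant regression of PSE (and JND) on stretch gain.

    ``fits`` needs columns (participant, gain, pse, jnd).  Every participant
    must contribute all requested gains; participants with any non-converged
    fit (``converged`` column, if present) are dropped first.  Returns
    (per-participant lines, group summary); slopes are in N/m per (mm/m).
    """
    if "converged" in fits.columns:
        ok = fits.groupby("participant")["converged"].transform("all")
        fits = fits[ok]
        if fits.empty:
            raise ValueError("no participant has converged fits at every gain")
    lines = []
    for participant, g in fits.groupby("participant"):
        have = set(g["gain"])
        missing = [gn for gn in gains if gn not in have]
        if missing:
            raise ValueError(
                f"participant {participant!r} missing gains {missing}"
            )
        g = g.sort_values("gain")
        x = g["gain"].to_numpy(dtype=float)
        row: dict = {"participant": participant}
        for metric in ("pse", "jnd"):
            slope, intercept = np.polyfit(x, g[metric].to_numpy(dtype=float), 1)
            row[f"{metric}_slope"] = slope
            row[f"{metric}_intercept"] = intercept
        lines.append(row)
    per_participant = pd.DataFrame(lines)
    group = (
        per_participant.drop(columns="participant")
        .agg(["mean", "sem"])
        .T.rename(columns={"mean": "mean", "sem": "sem"})
        .reset_index(names="coefficient")
    )
    return per_participant, group
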