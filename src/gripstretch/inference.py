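"""Repeated-measures general-linear-model F-tests.

The designs analyzed here are fully balanced within participant: every
participant contributes one value per (gain, probe-number) cell, gain enters
as a continuous regressor (1 numerator df), probe number as a categorical
factor, and participant as a random factor.  Following the classical
repeated-measures convention, each fixed effect is tested against the mean
square of its interaction with the participant factor, which reproduces the
familiar F(1, N-1) pattern for the gain effect with N participants.  The
gain x probe interaction is tested against the gain x probe x participant
term.  No sphericity correction is applied.

Sums of squares are computed in closed form from the balanced cell-mean
layout (equivalent to the sequential decomposition of an orthogonal design;
cross-checked against a full OLS + ANOVA decomposition in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = ["GLMResult", "rm_glm", "rm_regression"]


@dataclass(frozen=True)
class GLMResult:
    """One F-test of a repeated-measures general linear model."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.effect}: F{self.df_num},{self.df_den}="
            f"{self.F:.2f}, p={self.p:.4f}"
        )


def _balanced_cube(
    table: pd.DataFrame,
    value: str,
    participant: str,
    gain: str,
    probe: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a tidy table to a (participant, probe, gain) cell-mean cube.

    Raises with an explicit cell report when the design is unbalanced
    (missing or duplicated cells).
    """
    cols = [participant, gain] + ([probe] if probe else [])
    counts = table.groupby(cols, sort=True).size()
    participants = sorted(table[participant].unique())
    gains = np.array(sorted(table[gain].unique()), dtype=float)
    probes = sorted(table[probe].unique()) if probe else [None]
    expected = len(participants) * len(gains) * len(probes)
    if len(counts) != expected or counts.nunique() != 1:
        full = pd.MultiIndex.from_product(
            [participants, sorted(table[gain].unique())]
            + ([probes] if probe else []),
            names=cols,
        )
        missing = full.difference(counts.index)
        dup = counts[counts != counts.iloc[0]].index if len(counts) else []
        raise ValueError(
            "unbalanced design: "
            f"missing cells {list(missing)[:10]}, uneven cells {list(dup)[:10]}"
        )
    wide = table.groupby(cols, sort=True)[value].mean()
    cube = wide.to_numpy().reshape(
        len(participants),
        len(gains),
        len(probes) if probe else 1,
    )
    # reorder to (participant, probe, gain)
    return np.transpose(cube, (0, 2, 1)), gains


def rm_glm(
    table: pd.DataFrame,
    value: str = "value",
    participant: str = "participant",
    gain: str = "gain",
    probe: str = "probe_number",
) -> list[GLMResult]:
    """Repeated-measures GLM: continuous gain, categorical probe, random
    participant, and the gain x probe interaction.

    Requires a balanced design (one value, or an equal number of replicates
    averaged to cell means, per participant x gain x probe cell).
    """
    V, gains = _balanced_cube(table, value, participant, gain, probe)
    n, m, q = V.shape
    if n < 2 or m < 2 or q < 2:
        raise ValueError("need >= 2 participants, probe levels and gain levels")
    x = gains - gains.mean()
    sxx = float(np.sum(x**2))

    grand = V.mean()
    mean_p = V.mean(axis=(1, 2))  # participant means
    mean_j = V.mean(axis=(0, 2))  # probe means
    # regression slopes of cell means on centered gain
    beta = float(np.tensordot(V.mean(axis=(0, 1)), x, axes=1) / sxx)
    beta_i = V.mean(axis=1) @ x / sxx  # per participant
    beta_j = V.mean(axis=0) @ x / sxx  # per probe
    beta_ij = V @ x / sxx  # per cell

    ss_gain = n * m * sxx * beta**2
    ss_gain_p = m * sxx * float(np.sum((beta_i - beta) ** 2))
    ss_probe = n * q * float(np.sum((mean_j - grand) ** 2))
    cell_pj = V.mean(axis=2)
    ss_probe_p = q * float(
        np.sum((cell_pj - mean_p[:, None] - mean_j[None, :] + grand) ** 2)
    )
    ss_gp = n * sxx * float(np.sum((beta_j - beta) ** 2))
    ss_gp_p = sxx * float(
        np.sum((beta_ij - beta_i[:, None] - beta_j[None, :] + beta) ** 2)
    )

    tol = 1e-10 * max(1.0, float(np.sum((V - grand) ** 2)))

    def test(name, ss_eff, df_eff, ss_err, df_err):
        ms_eff = 0.0 if ss_eff < tol else ss_eff / df_eff
        ms_err = 0.0 if ss_err < tol else ss_err / df_err
        if ms_err == 0:
            F = np.inf if ms_eff > 0 else 0.0
        else:
            F = ms_eff / ms_err
        p = 0.0 if np.isinf(F) else float(f_dist.sf(F, df_eff, df_err))
        return GLMResult(name, float(F), df_eff, df_err, p)

    return [
        test("gain", ss_gain, 1, ss_gain_p, n - 1),
        test("probe", ss_probe, m - 1, ss_probe_p, (m - 1) * (n - 1)),
        test("gain:probe", ss_gp, m - 1, ss_gp_p, (m - 1) * (n - 1)),
    ]


def rm_regression(
    table: pd.DataFrame,
    value: str = "value",
    participant: str = "participant",
    x: str = "gain",
) -> GLMResult:
    """Repeated-measures regression on one continuous factor.

    Tests the common slope of ``value`` on ``x`` against the
    participant-by-slope interaction: F(1, N-1) for N participants.
    """
    V, xs = _balanced_cube(table, value, participant, x, probe=None)
    n, _, q = V.shape
    if n < 2 or q < 2:
        raise ValueError("need >= 2 participants and >= 2 x levels")
    xc = xs - xs.mean()
    sxx = float(np.sum(xc**2))
    beta_i = V[:, 0, :] @ xc / sxx
    beta = float(beta_i.mean())
    ss_x = n * sxx * beta**2
    ss_x_p = sxx * float(np.sum((beta_i - beta) ** 2))
    tol = 1e-10 * max(1.0, float(np.sum((V - V.mean()) ** 2)))
    ms_err = 0.0 if ss_x_p < tol else ss_x_p / (n - 1)
    if ms_err == 0:
        F = np.inf if ss_x > tol else 0.0
    else:
        F = ss_x / ms_err
    p = 0.0 if np.isinf(F) else float(f_dist.sf(F, 1, n - 1))
    return GLMResult(x, float(F), 1, n - 1, p)
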