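"""Synthetic apparatus and participant models.

The simulated task: a hand holding a tactile stimulation device makes
discrete vertical probing movements into a virtual elastic force field.
While the penetration depth ``y`` is negative (inside the field) the haptic
device renders a load force proportional to penetration, ``LF = -k*y``, and
a tactor stretches the finger-pad skin by ``-g*y`` millimetres (gain ``g``
in mm per m of penetration).  On stretch-catch probes the load force is
kept but the stretch is omitted.

The participant model has two parts.  A grip-force controller produces
``GF(t) = B(gain, probe) + S(gain, probe) * LF(t)`` during contact, where
the baseline ``B`` jumps immediately after the first exposure to stretch
and the modulation slope ``S`` builds up linearly over a few probing
movements — the qualitative structure reported for real participants.  The
approach ramp before contact is shaped so that the grip force and its
backward-difference rate at the contact sample map onto the realized peak
grip force through the intended-peak affine model (coefficients
``a*GF_contact + b*dGF/dt + c``), making the feature-level analyses exactly
self-consistent on noiseless data.  A psychometric observer answers the
two-alternative forced-choice question "was the comparison stiffer?" with
probability ``lapse/2 + (1-lapse) * Phi((dk - pse_per_gain*gain) / sigma)``,
so its point of subjective equality grows linearly with the stretch gain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import substream
from .schedule import EXP1_PROBES_PER_FIELD, TrialSpec

__all__ = [
    "EnvironmentParams",
    "ControllerParams",
    "ObserverParams",
    "probe_kinematics",
    "apply_force_field",
    "apply_tactor",
    "simulate_grip",
    "response_probability",
    "simulate_response",
    "simulate_responses",
    "generate_trial_trajectory",
    "generate_dataset",
    "eq3_catch_features",
    "sample_participants",
    "device_inertia_force",
]

#: Default coefficients (a, b [s], c [N]) of the intended-peak model used by
#: the generator: intended peak = a*GF_contact + b*dGF_contact/dt + c.
DEFAULT_EQ3_COEFFS = (1.14, 0.06, 0.1)


@dataclass(frozen=True)
class EnvironmentParams:
    """Virtual elastic field and skin-stretch apparatus for one interaction."""

    stiffness_k: float  # N/m
    gain_g: float = 0.0  # mm/m
    tactor_limit_mm: float = 5.0  # saturation clip of the tactor excursion
    catch: bool = False  # stretch omitted, load kept

    def __post_init__(self) -> None:
        if self.stiffness_k <= 0:
            raise ValueError("stiffness_k must be positive")
        if self.gain_g < 0:
            raise ValueError("gain_g must be nonnegative")
        if self.tactor_limit_mm <= 0:
            raise ValueError("tactor_limit_mm must be positive")


@dataclass(frozen=True)
class ControllerParams:
    """Parameters of the predictive grip-force controller.

    baseline0
        Grip force held between probes before any stretch exposure, N.
    baseline_gain_slope
        Immediate increase of the baseline per unit of expected stretch
        gain, N per (mm/m); applied from the second probe onward.
    modulation0
        Grip/load modulation slope on the first probe (dimensionless).
    modulation_gain_slope
        Asymptotic increase of the modulation slope per unit gain,
        1 per (mm/m), reached after ``modulation_buildup_probes`` probes.
    modulation_buildup_probes
        Number of probe-to-probe increments over which the modulation ramps
        to its plateau.
    noise_sd
        Gaussian measurement noise added to the grip channel, N.
    eq3_coeffs
        (a, b, c) of the intended-peak map enforced at contact.
    """

    baseline0: float = 1.0
    baseline_gain_slope: float = 0.002
    modulation0: float = 0.2
    modulation_gain_slope: float = 0.001
    modulation_buildup_probes: int = 4
    noise_sd: float = 0.02
    eq3_coeffs: tuple[float, float, float] = DEFAULT_EQ3_COEFFS

    def __post_init__(self) -> None:
        if self.modulation_buildup_probes < 1:
            raise ValueError("modulation_buildup_probes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def baseline(self, gain: float, probe_number: int) -> float:
        """Baseline grip force before probe ``probe_number`` (1-based), N."""
        if probe_number < 1:
            raise ValueError("probe_number must be >= 1")
        bump = self.baseline_gain_slope * gain if probe_number >= 2 else 0.0
        return self.baseline0 + bump

    def slope(self, gain: float, probe_number: int) -> float:
        """Grip/load modulation slope on probe ``probe_number``."""
        if probe_number < 1:
            raise ValueError("probe_number must be >= 1")
        frac = min((probe_number - 1) / self.modulation_buildup_probes, 1.0)
        return self.modulation0 + self.modulation_gain_slope * gain * frac


@dataclass(frozen=True)
class ObserverParams:
    """Cumulative-Gaussian 2AFC observer whose PSE is linear in gain.

    ``pse_per_gain`` is the stiffness-overestimation rate in N/m per mm/m of
    tactor displacement gain; ``sigma`` sets discrimination sensitivity
    (JND = 0.6745*sigma for a lapse-free observer).
    """

    pse_per_gain: float = 0.3073
    sigma: float = 20.0 / 0.6744897501960817  # JND of about 20 N/m
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")

    @classmethod
    def group1(cls, **kw) -> "ObserverParams":
        """Single-probe group: 30.73 N/m shift at gain 100 mm/m."""
        return cls(pse_per_gain=0.3073, **kw)

    @classmethod
    def group2(cls, **kw) -> "ObserverParams":
        """Free-exploration group: 39.10 N/m shift at gain 100 mm/m."""
        return cls(pse_per_gain=0.3910, **kw)


def probe_kinematics(
    depth: float,
    duration: float,
    fs: float,
    approach_clearance: float = 0.005,
) -> np.ndarray:
    """Vertical position of one probing movement, metres above the boundary.

    A raised-cosine in/out profile: starts and ends at ``+approach_clearance``,
    reaches ``-depth`` at mid-movement, with zero velocity at both ends
    (C1-continuous when concatenated with rest epochs).  Returns
    ``round(duration*fs) + 1`` samples.
    """
    if depth <= 0 or duration <= 0 or fs <= 0 or approach_clearance <= 0:
        raise ValueError("depth, duration, fs and approach_clearance must be positive")
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    amplitude = approach_clearance + depth
    return approach_clearance - amplitude * 0.5 * (1 - np.cos(2 * np.pi * t / duration))


def apply_force_field(y: np.ndarray, k: float) -> np.ndarray:
    """Elastic load force, N: ``-k*y`` inside the field (y <= 0), else 0."""
    if k <= 0:
        raise ValueError("stiffness k must be positive")
    y = np.asarray(y, dtype=float)
    return np.where(y <= 0, -k * y, 0.0)


def apply_tactor(
    y: np.ndarray, g: float, limit: float = 5.0, catch: bool = False
) -> np.ndarray:
    """Tactor displacement, mm: ``-g*y`` inside the field, clipped at ``limit``.

    On a stretch-catch probe the stretch is omitted entirely (all zeros)
    while the load force is untouched.
    """
    if g < 0:
        raise ValueError("gain g must be nonnegative")
    if limit <= 0:
        raise ValueError("tactor limit must be positive")
    y = np.asarray(y, dtype=float)
    if catch:
        return np.zeros_like(y)
    return np.where(y <= 0, np.minimum(-g * y, limit), 0.0)


def _eq3_precontact_value(
    load: np.ndarray,
    i0: int,
    baseline: float,
    slope: float,
    eq3: tuple[float, float, float],
    fs: float,
) -> float:
    """Grip value one sample before contact that makes the intended-peak map exact.

    With affine tracking the realized peak is ``B + S*max(LF)``; solving
    ``peak = a*GF_contact + b*rate + c`` for the backward-difference rate at
    the contact sample fixes the grip value at sample ``i0 - 1``.
    """
    a, b, c = eq3
    gf_contact = baseline + slope * load[i0]
    peak = baseline + slope * float(np.max(load))
    rate = (peak - a * gf_contact - c) / b
    return gf_contact - rate / fs


def simulate_grip(
    load: np.ndarray,
    gain: float,
    probe_number: int,
    params: ControllerParams,
    rng: np.random.Generator | None = None,
    fs: float = 1000.0,
) -> np.ndarray:
    """Grip force for one probing movement's load series, N.

    In contact the noiseless grip is exactly ``B + S*load``.  Before contact
    the grip ramps from the baseline to the value that makes the contact
    (grip, grip-rate) pair consistent with the controller's intended-peak
    coefficients.  Gaussian noise of ``params.noise_sd`` is added when an
    ``rng`` is supplied.
    """
    if probe_number < 1:
        raise ValueError("probe_number must be >= 1")
    load = np.asarray(load, dtype=float)
    B = params.baseline(gain, probe_number)
    S = params.slope(gain, probe_number)
    grip = B + S * load

    contact = np.flatnonzero(load > 0)
    if contact.size and contact[0] >= 1:
        i0 = int(contact[0])
        g0 = _eq3_precontact_value(load, i0, B, S, params.eq3_coeffs, fs)
        grip[:i0] = np.linspace(B, g0, i0)
    if rng is not None and params.noise_sd > 0:
        grip = grip + rng.normal(0.0, params.noise_sd, grip.shape)
    if np.min(grip) <= 0:
        raise ValueError("controller parameters yield non-positive grip force")
    return grip


def response_probability(
    delta_k: float, gain: float, params: ObserverParams
) -> float:
    """P(observer judges the comparison field stiffer)."""
    z = (delta_k - params.pse_per_gain * gain) / params.sigma
    return params.lapse / 2 + (1 - params.lapse) * norm.cdf(z)


def simulate_response(
    delta_k: float,
    gain: float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> bool:
    """Draw one 2AFC response ("comparison stiffer?") from the observer."""
    return bool(rng.random() < response_probability(delta_k, gain, params))


def simulate_responses(
    schedule: list[TrialSpec],
    observer: ObserverParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One response per trial; columns trial, phase, gain, comparison_k,
    delta_k, chose_comparison."""
    if not schedule:
        raise ValueError("schedule is empty")
    rows = []
    for i, trial in enumerate(schedule):
        rows.append(
            dict(
                trial=i,
                session=trial.session,
                phase=trial.phase,
                gain=trial.gain,
                comparison_k=trial.comparison_stiffness,
                delta_k=trial.delta_k,
                chose_comparison=simulate_response(
                    trial.delta_k, trial.gain, observer, rng
                ),
            )
        )
    return pd.DataFrame(rows)


def _field_probe_count(
    trial: TrialSpec,
    field: str,
    probes_per_field: int | tuple[int, int] | None,
    rng: np.random.Generator,
) -> int:
    if trial.experiment == "exp1":
        return EXP1_PROBES_PER_FIELD
    if trial.group == "g1":
        return 1
    if probes_per_field is None:
        probes_per_field = (1, 8)  # free exploration
    if isinstance(probes_per_field, int):
        return probes_per_field
    lo, hi = probes_per_field
    return int(rng.integers(lo, hi + 1))


def generate_trial_trajectory(
    trial: TrialSpec,
    controller: ControllerParams,
    rng: np.random.Generator,
    fs: float = 1000.0,
    depth: float = 0.025,
    duration: float = 0.25,
    approach_clearance: float = 0.005,
    rest_duration: float = 0.5,
    tactor_limit: float = 5.0,
    probes_per_field: int | tuple[int, int] | None = None,
    trial_label: int = 0,
    fields: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Simulate the full time series of one trial (both force fields).

    Each probe contributes a rest epoch (hand above the field, grip held at
    the upcoming probe's baseline) followed by the probing movement.  The
    stretch gain applies only to the standard field; a stretch-catch probe
    zeroes the tactor of the flagged standard probe while leaving load and
    grip untouched.
    """
    if fields is None:
        fields = ("standard", "comparison")
        if trial.field_order == "comparison_first":
            fields = fields[::-1]

    n_rest = int(round(rest_duration * fs))
    y_move = probe_kinematics(depth, duration, fs, approach_clearance)
    cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("y_m", "load_N", "grip_N", "tactor_mm")
    }
    meta: list[tuple[str, int, bool, int]] = []  # field, probe, catch, n
    for field in fields:
        if field == "standard":
            k, gain = trial.standard_stiffness, trial.gain
        else:
            k, gain = trial.comparison_stiffness, 0.0
        n_probes = _field_probe_count(trial, field, probes_per_field, rng)
        catch_at = trial.catch_probe.probe_number if field == "standard" else None
        for p in range(1, n_probes + 1):
            is_catch = catch_at == p
            y = np.concatenate([np.full(n_rest, approach_clearance), y_move])
            load = apply_force_field(y, k)
            tactor = apply_tactor(y, gain, tactor_limit, catch=is_catch)
            grip = np.empty_like(load)
            B = controller.baseline(gain, p)
            grip[:n_rest] = B
            grip[n_rest:] = simulate_grip(
                load[n_rest:], gain, p, controller, rng=None, fs=fs
            )
            # After contact ends, the controller settles onto the *next*
            # probe's baseline so the between-probe quiescent epoch reflects
            # the upcoming safety margin (the immediate baseline effect).
            contact = np.flatnonzero(load > 0)
            if p < n_probes and contact.size:
                grip[contact[-1] + 1 :] = controller.baseline(gain, p + 1)
            if controller.noise_sd > 0:
                grip = grip + rng.normal(0.0, controller.noise_sd, grip.shape)
            cols["y_m"].append(y)
            cols["load_N"].append(load)
            cols["grip_N"].append(grip)
            cols["tactor_mm"].append(tactor)
            meta.append((field, p, is_catch, len(y)))
    n_total = sum(n for *_, n in meta)
    out = pd.DataFrame(
        dict(
            trial=np.full(n_total, trial_label),
            t_s=np.arange(n_total) / fs,
            field=np.repeat([m[0] for m in meta], [m[3] for m in meta]),
            probe=np.repeat([m[1] for m in meta], [m[3] for m in meta]),
            y_m=np.concatenate(cols["y_m"]),
            load_N=np.concatenate(cols["load_N"]),
            grip_N=np.concatenate(cols["grip_N"]),
            tactor_mm=np.concatenate(cols["tactor_mm"]),
            is_catch=np.repeat([m[2] for m in meta], [m[3] for m in meta]),
        )
    )
    return out


def generate_dataset(
    schedule: list[TrialSpec],
    controller: ControllerParams = ControllerParams(),
    observer: ObserverParams = ObserverParams(),
    fs: float = 1000.0,
    seed: int = 0,
    **trajectory_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate trajectories and 2AFC responses for a whole schedule.

    Returns a long-format trajectory table (one row per sample) and a
    responses table (one row per trial).  Fully reproducible from ``seed``.
    """
    if not schedule:
        raise ValueError("schedule is empty")
    traj_rng = substream(seed, "trajectories")
    resp_rng = substream(seed, "responses")
    frames = []
    for i, trial in enumerate(schedule):
        frames.append(
            generate_trial_trajectory(
                trial, controller, traj_rng, fs=fs, trial_label=i, **trajectory_kwargs
            )
        )
    trajectories = pd.concat(frames, ignore_index=True)
    responses = simulate_responses(schedule, observer, resp_rng)
    return trajectories, responses


def eq3_catch_features(
    n: int,
    coeffs: tuple[float, float, float] = DEFAULT_EQ3_COEFFS,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    contact_range: tuple[float, float] = (0.8, 1.8),
    rate_range: tuple[float, float] = (0.5, 6.0),
) -> pd.DataFrame:
    """Stretch-catch probe features drawn exactly from the intended-peak model.

    Returns ``n`` rows of (gf_contact [N], gf_rate_contact [N/s],
    peak_grip [N]) with ``peak = a*contact + b*rate + c`` plus optional
    Gaussian noise on the peak.  The design spans ``contact_range`` and
    ``rate_range`` on a jittered grid, so it is never collinear for n >= 3.
    """
    if n < 3:
        raise ValueError("need at least 3 probes to identify the model")
    rng = np.random.default_rng(0) if rng is None else rng
    a, b, c = coeffs
    contact = rng.uniform(*contact_range, n)
    rate = rng.uniform(*rate_range, n)
    peak = a * contact + b * rate + c
    if noise_sd > 0:
        peak = peak + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(
        dict(gf_contact=contact, gf_rate_contact=rate, peak_grip=peak)
    )


def sample_participants(
    n: int,
    seed: int,
    controller: ControllerParams = ControllerParams(),
    observer: ObserverParams = ObserverParams(),
    baseline0_sd: float = 0.1,
    modulation0_sd: float = 0.02,
    modulation_gain_slope_sd: float = 0.0002,
    pse_per_gain_sd: float = 0.0,
    sigma_sd: float = 3.0,
) -> list[tuple[ControllerParams, ObserverParams]]:
    """Draw a cohort of participants around the given base parameters.

    Between-participant variability is Gaussian on the controller baseline
    and modulation, and optionally on the observer's PSE rate and spread.
    The PSE-rate spread defaults to zero: with the default observer
    (JND about 20 N/m) the sampling noise of a single psychometric fit at
    gain 100 is already as large as the between-participant spread of the
    reported group-level PSE effects, so the observed dispersion is
    attributed to fit noise rather than to true rate heterogeneity.
    """
    rng = substream(seed, "participants")
    cohort = []
    for _ in range(n):
        ctrl = replace(
            controller,
            baseline0=max(rng.normal(controller.baseline0, baseline0_sd), 0.3),
            modulation0=max(rng.normal(controller.modulation0, modulation0_sd), 0.05),
            modulation_gain_slope=max(
                rng.normal(
                    controller.modulation_gain_slope, modulation_gain_slope_sd
                ),
                0.0,
            ),
        )
        obs = replace(
            observer,
            pse_per_gain=rng.normal(observer.pse_per_gain, pse_per_gain_sd),
            sigma=max(rng.normal(observer.sigma, sigma_sd), 5.0),
        )
        cohort.append((ctrl, obs))
    return cohort


def device_inertia_force(
    mass_kg: float = 0.2, peak_accel_ms2: float = 0.2392
) -> float:
    """Inertial force of the handheld stimulation device, N.

    Defaults: 200 g device mass and the average maximum hand acceleration
    measured during probing (0.2392 m/s^2); the product (~0.05 N) is two
    orders of magnitude below the 2-4 N load forces, confirming the device's
    inertia is a negligible contamination of the load-force channel.
    """
    if mass_kg <= 0 or peak_accel_ms2 < 0:
        raise ValueError("mass must be positive and acceleration nonnegative")
    return mass_kg * peak_accel_ms2
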