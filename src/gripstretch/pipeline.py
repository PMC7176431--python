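"""End-to-end pipeline: simulate -> preprocess -> analyze -> report.

Ties the modules together into a reproducible run driven by one root seed:
structured-probing grip-force data (the stretch-catch protocol) feed the
grip-force decomposition and repeated-measures GLMs; 2AFC response data for
the two perception groups feed the psychometric PSE/JND analysis and
repeated-measures regressions.  Every run writes tidy CSV tables, an
ANOVA-style summary and a resolved copy of its configuration, and the same
configuration plus seed always reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from . import gripforce, preprocess, psychometrics
from .inference import rm_glm, rm_regression
from .schedule import (
    GAINS,
    CatchProbe,
    TrialSpec,
    generate_exp1_schedule,
    generate_exp2_schedule,
    schedule_to_frame,
)
from .synth import (
    ControllerParams,
    ObserverParams,
    generate_trial_trajectory,
    sample_participants,
    simulate_responses,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "make_exp1_conditions",
    "analyze_gripforce_dataset",
    "simulate_exp1_participant",
    "psychometric_table",
    "run_perception_group",
    "run_pipeline",
    "make_fixture",
]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    The defaults are a reduced problem size suitable for smoke runs; the
    :meth:`paper` constructor restores the printed protocol sizes (10
    participants per group, 3 stiffness x 4 gain x 9 repetitions, 1 kHz).
    """

    seed: int = 0
    fs: float = 500.0
    exp1_participants: int = 2
    exp1_stiffnesses: tuple[float, ...] = (85.0,)
    exp1_reps_per_gain: int = 3
    exp2_participants: int = 2
    depth: float = 0.025
    duration: float = 0.25
    approach_clearance: float = 0.005
    rest_duration: float = 0.5
    filter_cutoff: float = 12.0
    link: str = "probit"
    controller: dict = field(default_factory=dict)
    observer_g1: dict = field(default_factory=dict)
    observer_g2: dict = field(default_factory=dict)

    @classmethod
    def tiny(cls, seed: int = 0) -> "PipelineConfig":
        return cls(seed=seed)

    @classmethod
    def paper(cls, seed: int = 0) -> "PipelineConfig":
        return cls(
            seed=seed,
            fs=1000.0,
            exp1_participants=10,
            exp1_stiffnesses=(40.0, 85.0, 130.0),
            exp1_reps_per_gain=9,
            exp2_participants=10,
        )

    def base_controller(self) -> ControllerParams:
        return ControllerParams(**self.controller)

    def base_observer(self, group: str) -> ObserverParams:
        overrides = self.observer_g1 if group == "g1" else self.observer_g2
        base = ObserverParams.group1() if group == "g1" else ObserverParams.group2()
        return dataclasses.replace(base, **overrides)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["exp1_stiffnesses"] = list(self.exp1_stiffnesses)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "exp1_stiffnesses" in d:
            d["exp1_stiffnesses"] = tuple(d["exp1_stiffnesses"])
        return cls(**d)


def make_exp1_conditions(
    stiffnesses: tuple[float, ...] = (40.0, 85.0, 130.0),
    reps_per_gain: int = 9,
    gains: tuple[float, ...] = GAINS,
) -> list[TrialSpec]:
    """Structured-probing test conditions with the stretch-catch pattern.

    For every (stiffness, nonzero gain) pair the repetitions cycle through
    catch placements probe2, probe7, none — at the printed nine repetitions
    this yields exactly the 3/3/3 pattern of the full protocol.
    """
    pattern = [CatchProbe.PROBE2, CatchProbe.PROBE7, CatchProbe.NONE]
    trials = []
    i = 0
    for k in stiffnesses:
        for g in gains:
            for rep in range(reps_per_gain):
                catch = pattern[rep % 3] if g > 0 else CatchProbe.NONE
                trials.append(
                    TrialSpec(
                        experiment="exp1",
                        group="none",
                        session=1,
                        phase="test",
                        trial_index=i,
                        comparison_stiffness=k,
                        gain=g,
                        catch_probe=catch,
                    )
                )
                i += 1
    return trials


def simulate_exp1_participant(
    participant: int,
    conditions: list[TrialSpec],
    controller: ControllerParams,
    config: PipelineConfig,
    standard_only: bool = True,
) -> pd.DataFrame:
    """Trajectories of one participant over the structured-probing trials."""
    rng = substream(config.seed, "exp1-trajectories", participant)
    frames = []
    for i, trial in enumerate(conditions):
        frames.append(
            generate_trial_trajectory(
                trial,
                controller,
                rng,
                fs=config.fs,
                depth=config.depth,
                duration=config.duration,
                approach_clearance=config.approach_clearance,
                rest_duration=config.rest_duration,
                trial_label=i,
                fields=("standard",) if standard_only else None,
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "participant", participant)
    return out


def analyze_gripforce_dataset(
    trajectories: pd.DataFrame,
    conditions: list[TrialSpec],
    fs: float,
    filter_cutoff: float = 12.0,
    model: gripforce.IntendedPeakRegressor | None = None,
    max_probe_number: int = 7,
    average_catch_replicates: bool = True,
) -> tuple[pd.DataFrame, gripforce.IntendedPeakRegressor]:
    """Per-probe grip-force features and decomposition for one dataset.

    Filters the grip channel, segments the standard-field series of every
    trial, extracts baselines, contact features and grip-load regressions,
    fits the intended-peak model on the pooled stretch-catch probes (unless
    a pre-fitted ``model`` is supplied), and returns one row per analyzed
    probe (the last probe of each trial is omitted from evolution analyses).

    ``average_catch_replicates`` averages the catch-probe features over the
    repetitions of each (participant, gain, stiffness, probe-number)
    condition before the regression; replicate catch probes share the same
    intended grip-force state, so averaging reduces the attenuation that
    measurement noise on the rate regressor would otherwise induce.
    """
    field_vals = trajectories["field"]
    if (field_vals == "standard").all():
        std = trajectories
    else:
        std = trajectories[field_vals == "standard"]
    per_probe_rows: list[dict] = []
    for (participant, trial), g in std.groupby(["participant", "trial"]):
        spec = conditions[int(trial)]
        grip = preprocess.lowpass_grip(
            g["grip_N"].to_numpy(), fs, cutoff=filter_cutoff
        )
        load = g["load_N"].to_numpy()
        probes = preprocess.segment_field(
            load,
            grip=grip,
            y=g["y_m"].to_numpy(),
            fs=fs,
            trial=int(trial),
            field="standard",
            is_catch=g["is_catch"].to_numpy(),
        )
        for probe in probes:
            if not probe.valid:
                continue
            gf_contact, rate = gripforce.contact_features(probe, grip, fs)
            reg = gripforce.gf_lf_regression(probe, load, grip)
            per_probe_rows.append(
                dict(
                    participant=participant,
                    trial=int(trial),
                    gain=spec.gain,
                    comparison_k=spec.comparison_stiffness,
                    probe_number=probe.probe_number,
                    is_catch=probe.is_catch,
                    baseline=gripforce.baseline_before_probe(grip, fs, probe),
                    gf_contact=gf_contact,
                    gf_rate_contact=rate,
                    peak_load=probe.peak_load,
                    peak_grip=probe.peak_grip,
                    peak_ratio=gripforce.peak_ratio(probe),
                    slope=reg.slope,
                    intercept=reg.intercept,
                    r2=reg.r2,
                    excluded=reg.excluded,
                )
            )
    features = pd.DataFrame(per_probe_rows)
    if features.empty:
        raise ValueError("no valid standard-field probes found")

    if model is None:
        catch = features[features["is_catch"]]
        if len(catch) < 3:
            raise ValueError("too few stretch-catch probes to fit the model")
        if average_catch_replicates:
            catch = catch.groupby(
                ["participant", "gain", "comparison_k", "probe_number"],
                as_index=False,
            )[["gf_contact", "gf_rate_contact", "peak_grip"]].mean()
        model = gripforce.fit_intended_peak_model(
            catch[["gf_contact", "gf_rate_contact", "peak_grip"]]
        )
    features["intended_peak"] = model.predict(
        features[["gf_contact", "gf_rate_contact"]].to_numpy()
    )
    features["modulation"] = features["intended_peak"] - features["gf_contact"]
    features = features[features["probe_number"] <= max_probe_number]
    return features.reset_index(drop=True), model


def psychometric_table(
    responses: pd.DataFrame,
    participant: int,
    link: str = "probit",
    lapse: float = 0.0,
) -> pd.DataFrame:
    """Per-gain psychometric fits for one participant's test responses."""
    rows = []
    test = responses[responses["phase"] == "test"]
    for gain, g in test.groupby("gain"):
        fit = psychometrics.fit_psychometric(
            g[["delta_k", "chose_comparison"]], link=link, lapse=lapse
        )
        rows.append(
            dict(
                participant=participant,
                gain=gain,
                mu=fit.mu_,
                sigma=fit.sigma_,
                pse=fit.pse_,
                jnd=fit.jnd_,
                n_trials=fit.n_trials_,
                converged=fit.converged_,
            )
        )
    return pd.DataFrame(rows)


def run_perception_group(
    group: str,
    n_participants: int,
    config: PipelineConfig,
    replicate: int = 0,
) -> pd.DataFrame:
    """Simulate one perception group and fit all psychometric curves.

    Each participant gets an independently sampled observer, a freshly
    shuffled schedule and an independent response stream; returns the tidy
    fits table (participant, gain, mu, sigma, pse, jnd, converged).
    """
    cohort = sample_participants(
        n_participants,
        seed=substream(config.seed, "cohort", group, replicate).integers(2**31),
        observer=config.base_observer(group),
        controller=config.base_controller(),
    )
    tables = []
    for pid, (_, observer) in enumerate(cohort):
        sched_seed = int(
            substream(config.seed, "exp2-sched", group, replicate, pid).integers(
                2**31
            )
        )
        schedule = generate_exp2_schedule(group, seed=sched_seed)
        rng = substream(config.seed, "exp2-responses", group, replicate, pid)
        responses = simulate_responses(schedule, observer, rng)
        tables.append(
            psychometric_table(responses, pid, link=config.link)
        )
    return pd.concat(tables, ignore_index=True)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage on synthetic data and write the report bundle.

    Writes, under ``out_dir``: the trial schedules, the per-probe grip-force
    feature table, per-(participant, gain, probe) decomposition means and
    their differences versus zero gain, psychometric fits and PSE/JND
    regression lines per perception group, ANOVA-style statistics, a JSON
    summary, and the resolved configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"stages": {}}

    # --- schedules -------------------------------------------------------
    stage = time.time()
    schedule_to_frame(generate_exp1_schedule(config.seed)).to_csv(
        out / "schedule_exp1.csv", index=False
    )
    for group in ("g1", "g2"):
        schedule_to_frame(generate_exp2_schedule(group, config.seed)).to_csv(
            out / f"schedule_exp2_{group}.csv", index=False
        )
    summary["stages"]["schedule"] = round(time.time() - stage, 3)

    # --- structured probing: grip-force decomposition --------------------
    stage = time.time()
    conditions = make_exp1_conditions(
        config.exp1_stiffnesses, config.exp1_reps_per_gain
    )
    cohort = sample_participants(
        config.exp1_participants,
        seed=int(substream(config.seed, "exp1-cohort").integers(2**31)),
        controller=config.base_controller(),
    )
    frames = [
        simulate_exp1_participant(pid, conditions, ctrl, config)
        for pid, (ctrl, _) in enumerate(cohort)
    ]
    trajectories = pd.concat(frames, ignore_index=True)
    features, model = analyze_gripforce_dataset(
        trajectories, conditions, config.fs, config.filter_cutoff
    )
    features.to_csv(out / "gripforce_probes.csv", index=False)

    means = (
        features.groupby(["participant", "gain", "probe_number"], as_index=False)[
            ["baseline", "gf_contact", "intended_peak", "modulation", "peak_ratio"]
        ]
        .mean()
    )
    means.to_csv(out / "gripforce_means.csv", index=False)
    deltas = []
    for metric in ("baseline", "gf_contact", "intended_peak", "modulation"):
        d = gripforce.delta_vs_zero_gain(
            means.rename(columns={metric: "value"})[
                ["participant", "gain", "probe_number", "value"]
            ]
        )
        d["metric"] = metric
        deltas.append(d)
    pd.concat(deltas, ignore_index=True).to_csv(
        out / "gripforce_delta_vs_zero_gain.csv", index=False
    )

    glm_rows = []
    for metric in ("baseline", "gf_contact", "intended_peak", "modulation"):
        table = means.rename(columns={metric: "value"})
        if config.exp1_participants >= 2:
            for res in rm_glm(table):
                glm_rows.append(
                    dict(
                        analysis=metric,
                        effect=res.effect,
                        F=res.F,
                        df1=res.df_num,
                        df2=res.df_den,
                        p=res.p,
                    )
                )
    stats = pd.DataFrame(glm_rows)
    summary["stages"]["gripforce"] = round(time.time() - stage, 3)
    summary["intended_peak_model"] = dict(
        a=model.a_, b=model.b_, c=model.c_, r2=model.r2_
    )

    # --- perception: psychometrics per group -----------------------------
    stage = time.time()
    for group in ("g1", "g2"):
        fits = run_perception_group(group, config.exp2_participants, config)
        fits.to_csv(out / f"psychometrics_{group}.csv", index=False)
        lines, group_summary = psychometrics.pse_vs_gain(fits)
        lines.to_csv(out / f"pse_vs_gain_{group}.csv", index=False)
        if config.exp2_participants >= 2:
            for metric in ("pse", "jnd"):
                res = rm_regression(fits.rename(columns={metric: "value"}))
                glm_rows.append(
                    dict(
                        analysis=f"{group}:{metric}",
                        effect="gain",
                        F=res.F,
                        df1=res.df_num,
                        df2=res.df_den,
                        p=res.p,
                    )
                )
        summary[f"{group}_mean_pse_slope"] = float(lines["pse_slope"].mean())
        summary[f"{group}_mean_pse_at_gain_100"] = float(
            lines["pse_slope"].mean() * 100 + lines["pse_intercept"].mean()
        )
        summary[f"{group}_mean_jnd"] = float(fits["jnd"].mean())
    stats = pd.DataFrame(glm_rows)
    stats.to_csv(out / "statistics.csv", index=False)
    summary["stages"]["psychometrics"] = round(time.time() - stage, 3)

    summary["n_probes_analyzed"] = int(len(features))
    summary["elapsed_s"] = round(time.time() - t0, 3)
    config.to_yaml(out / "config_resolved.yaml")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1f s", summary["elapsed_s"])
    return summary


def make_fixture(
    scale: str, out_dir: str | Path, seed: int = 0
) -> PipelineConfig:
    """Write a ready-to-analyze synthetic dataset to disk.

    ``tiny`` is a two-participant, reduced-repetition, 500 Hz dataset meant
    for smoke tests; ``paper`` restores the printed protocol sizes.
    """
    if scale not in ("tiny", "paper"):
        raise ValueError("scale must be 'tiny' or 'paper'")
    config = (
        PipelineConfig.tiny(seed) if scale == "tiny" else PipelineConfig.paper(seed)
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conditions = make_exp1_conditions(
        config.exp1_stiffnesses, config.exp1_reps_per_gain
    )
    schedule_to_frame(conditions).to_csv(out / "exp1_conditions.csv", index=False)
    cohort = sample_participants(
        config.exp1_participants,
        seed=int(substream(config.seed, "exp1-cohort").integers(2**31)),
        controller=config.base_controller(),
    )
    frames = [
        simulate_exp1_participant(pid, conditions, ctrl, config)
        for pid, (ctrl, _) in enumerate(cohort)
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        out / "exp1_trajectories.csv", index=False
    )
    for group in ("g1", "g2"):
        cohort2 = sample_participants(
            config.exp2_participants,
            seed=int(substream(config.seed, "cohort", group, 0).integers(2**31)),
            observer=config.base_observer(group),
        )
        resp = []
        for pid, (_, observer) in enumerate(cohort2):
            schedule = generate_exp2_schedule(group, seed=config.seed + pid)
            r = simulate_responses(
                schedule,
                observer,
                substream(config.seed, "exp2-responses", group, 0, pid),
            )
            r.insert(0, "participant", pid)
            resp.append(r)
        pd.concat(resp, ignore_index=True).to_csv(
            out / f"exp2_responses_{group}.csv", index=False
        )
    config.to_yaml(out / "config.yaml")
    return config
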