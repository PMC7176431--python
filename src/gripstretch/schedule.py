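"""Trial schedules for the two stiffness-discrimination experiments.

Experiment 1 (structured probing, stretch-catch probes): 24 training trials
plus 108 test trials covering 3 comparison stiffness levels x 4 tactor
displacement gains, nine repetitions each, split into two 66-trial sessions.
In six of the nine repetitions of every nonzero-gain condition one probing
movement into the standard field is a stretch-catch probe (load kept,
skin-stretch omitted): three times the second probe, three times the seventh.
With 8 standard + 8 comparison probes per test trial this makes exactly
54/1728 = 3.125% of the probes stretch-catch probes.

Experiment 2 (perception): 10 comparison stiffness levels x 4 gains.
Group 1 probes each field once (20 training + 320 test trials in one
session); Group 2 explores freely over two sessions of 20 training + 180
test trials each (nine repetitions per condition cell in total).

Condition counts are exact and seed-independent; the seed only permutes the
presentation order within each session.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "STANDARD_STIFFNESS",
    "GAINS",
    "EXP1_COMPARISON_STIFFNESS",
    "EXP2_COMPARISON_STIFFNESS",
    "CatchProbe",
    "TrialSpec",
    "generate_exp1_schedule",
    "generate_exp2_schedule",
    "schedule_to_frame",
    "frame_to_schedule",
]

#: Stiffness of the standard (stretch-augmented) force field, N/m.
STANDARD_STIFFNESS = 85.0

#: Tactor displacement gains, mm of tactor travel per m of penetration.
GAINS = (0.0, 33.0, 66.0, 100.0)

#: Comparison stiffness grid for experiment 1, N/m.
EXP1_COMPARISON_STIFFNESS = (40.0, 85.0, 130.0)

#: Comparison stiffness grid for experiment 2, N/m (40-130 in steps of 10).
EXP2_COMPARISON_STIFFNESS = tuple(float(k) for k in range(40, 131, 10))

#: Probes per field in the structured-probing protocol of experiment 1.
EXP1_PROBES_PER_FIELD = 8


class CatchProbe(str, enum.Enum):
    """Placement of the stretch-catch probe within the standard field."""

    NONE = "none"
    PROBE2 = "probe2"
    PROBE7 = "probe7"

    @property
    def probe_number(self) -> int | None:
        return {"none": None, "probe2": 2, "probe7": 7}[self.value]


@dataclass(frozen=True)
class TrialSpec:
    """Condition of a single 2AFC stiffness-discrimination trial."""

    experiment: str  # "exp1" | "exp2"
    group: str  # "none" | "g1" | "g2"
    session: int
    phase: str  # "training" | "test"
    trial_index: int
    comparison_stiffness: float  # N/m
    gain: float  # mm/m
    catch_probe: CatchProbe = CatchProbe.NONE
    field_order: str = "standard_first"  # | "comparison_first"
    standard_stiffness: float = STANDARD_STIFFNESS  # N/m

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.phase not in ("training", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase == "training" and self.gain != 0:
            raise ValueError("training trials never apply skin-stretch")
        if self.catch_probe is not CatchProbe.NONE:
            if self.experiment != "exp1" or self.phase != "test" or self.gain <= 0:
                raise ValueError(
                    "stretch-catch probes occur only in nonzero-gain exp1 test trials"
                )

    @property
    def delta_k(self) -> float:
        """Comparison minus standard stiffness, N/m."""
        return self.comparison_stiffness - self.standard_stiffness


def _finalize(
    trials: list[dict], session: int, rng: np.random.Generator, offset: int = 0
) -> list[TrialSpec]:
    """Shuffle one session's trial dicts and assign indices/field order."""
    order = rng.permutation(len(trials))
    out = []
    for idx, j in enumerate(order):
        d = dict(trials[j])
        d["session"] = session
        d["trial_index"] = offset + idx
        d["field_order"] = (
            "standard_first" if rng.random() < 0.5 else "comparison_first"
        )
        out.append(TrialSpec(**d))
    return out


def generate_exp1_schedule(seed: int) -> list[TrialSpec]:
    """Generate the 132-trial schedule of experiment 1.

    Two sessions of 66 trials, each opening with 12 training trials
    (4 repetitions x 3 comparison stiffness, gain 0) followed by 54 test
    trials.  Across the two sessions the test trials cover 9 repetitions of
    each of the 12 (stiffness, gain) condition pairs; each nonzero-gain pair
    carries stretch-catch probes in a fixed {probe2 x3, probe7 x3, none x3}
    pattern over its repetitions.  The seed only permutes order (training
    kept first within each session).
    """
    test: list[dict] = []
    for k in EXP1_COMPARISON_STIFFNESS:
        for g in GAINS:
            if g == 0:
                catches = [CatchProbe.NONE] * 9
            else:
                catches = (
                    [CatchProbe.PROBE2] * 3
                    + [CatchProbe.PROBE7] * 3
                    + [CatchProbe.NONE] * 3
                )
            for catch in catches:
                test.append(
                    dict(
                        experiment="exp1",
                        group="none",
                        phase="test",
                        comparison_stiffness=k,
                        gain=g,
                        catch_probe=catch,
                    )
                )
    training = [
        dict(
            experiment="exp1",
            group="none",
            phase="training",
            comparison_stiffness=k,
            gain=0.0,
            catch_probe=CatchProbe.NONE,
        )
        for k in EXP1_COMPARISON_STIFFNESS
        for _ in range(4)
    ]

    rng = substream(seed, "schedule", "exp1")
    # Split the 108 test trials into two 54-trial sessions at random but
    # deterministically given the seed.
    split = rng.permutation(len(test))
    schedule: list[TrialSpec] = []
    for session, half in ((1, split[:54]), (2, split[54:])):
        sess_training = _finalize(training, session, rng)
        sess_test = _finalize(
            [test[i] for i in half], session, rng, offset=len(sess_training)
        )
        schedule.extend(sess_training)
        schedule.extend(sess_test)
    return schedule


def generate_exp2_schedule(
    group: str, seed: int, g2_total_test: int = 360
) -> list[TrialSpec]:
    """Generate the experiment-2 schedule for one participant group.

    Group 1: one session of 20 training trials (2 reps x 10 stiffness,
    gain 0) followed by 320 test trials (8 reps per (stiffness, gain) cell).
    Group 2: two sessions, each 20 training + ``g2_total_test``/2 test
    trials; the default 360 test trials give 9 repetitions per cell, drawn
    evenly (4 or 5 per session, totals exact).  No stretch-catch probes.
    """
    if group not in ("g1", "g2"):
        raise ValueError(f"group must be 'g1' or 'g2', got {group!r}")

    cells = [(k, g) for k in EXP2_COMPARISON_STIFFNESS for g in GAINS]
    n_cells = len(cells)  # 40

    def make(phase: str, k: float, g: float) -> dict:
        return dict(
            experiment="exp2",
            group=group,
            phase=phase,
            comparison_stiffness=k,
            gain=g,
            catch_probe=CatchProbe.NONE,
        )

    training = [make("training", k, 0.0) for k in EXP2_COMPARISON_STIFFNESS] * 2

    rng = substream(seed, "schedule", "exp2", group)
    schedule: list[TrialSpec] = []
    if group == "g1":
        test = [make("test", k, g) for (k, g) in cells for _ in range(8)]
        sess_training = _finalize(training, 1, rng)
        sess_test = _finalize(test, 1, rng, offset=len(sess_training))
        schedule = sess_training + sess_test
    else:
        reps, extra = divmod(g2_total_test, n_cells)
        if extra:
            raise ValueError(
                f"g2_total_test must be a multiple of {n_cells} (got {g2_total_test})"
            )
        lo, hi = reps // 2, reps - reps // 2
        # Alternate which session gets the extra repetition cell-by-cell so
        # each session has exactly g2_total_test/2 trials.
        per_session: dict[int, list[dict]] = {1: [], 2: []}
        for i, (k, g) in enumerate(cells):
            first = 1 if i % 2 == 0 else 2
            second = 2 if first == 1 else 1
            per_session[first] += [make("test", k, g)] * hi
            per_session[second] += [make("test", k, g)] * lo
        for session in (1, 2):
            sess_training = _finalize(training, session, rng)
            sess_test = _finalize(
                per_session[session], session, rng, offset=len(sess_training)
            )
            schedule.extend(sess_training)
            schedule.extend(sess_test)
    return schedule


def schedule_to_frame(schedule: list[TrialSpec]) -> pd.DataFrame:
    """Flatten a schedule to a tidy table, one row per trial."""
    rows = []
    for t in schedule:
        d = {f.name: getattr(t, f.name) for f in fields(t)}
        d["catch_probe"] = t.catch_probe.value
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_schedule(frame: pd.DataFrame) -> list[TrialSpec]:
    """Inverse of :func:`schedule_to_frame`."""
    out = []
    for row in frame.to_dict("records"):
        row["catch_probe"] = CatchProbe(row["catch_probe"])
        out.append(TrialSpec(**row))
    return out
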