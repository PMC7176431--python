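"""Signal conditioning, probe segmentation and validity screening.

Grip-force channels are low-pass filtered with a zero-phase (forward plus
backward) 2nd-order Butterworth designed at 12 Hz.  Applying the filter in
both directions squares its magnitude response, so the effective filter is
4th order with a -3 dB point at ``12*(sqrt(2)-1)**0.25 ~ 9.62 Hz``.

Probing movements are delimited by the load-force channel: the load is zero
whenever the hand is above the field boundary, so each maximal run of
positive load is one probe.  A probe is valid when it penetrated at least
20 mm, finished within 300 ms, and both started and ended out of contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "Probe",
    "lowpass_grip",
    "effective_cutoff",
    "segment_probes",
    "segment_field",
    "validate_probe",
    "find_grip_peaks",
    "released_grip",
    "MIN_DEPTH_M",
    "MAX_DURATION_S",
]

#: Minimum penetration for a successful probing movement, m.
MIN_DEPTH_M = 0.020
#: Maximum duration of a successful probing movement, s.
MAX_DURATION_S = 0.300


@dataclass
class Probe:
    """One contiguous in-contact interval of a trajectory.

    ``start_idx``/``end_idx`` bound the probe's half-open context interval
    (from the end of the previous contact to the start of the next);
    ``contact_idx``/``contact_end`` bound the in-contact run itself.
    Indices are 0-based sample positions local to the (trial, field) series.
    """

    trial: int
    field: str
    probe_number: int
    start_idx: int
    end_idx: int
    contact_idx: int
    contact_end: int
    depth: float  # m
    duration: float  # s (time in contact)
    is_catch: bool = False
    valid: bool = False
    peak_load: float = np.nan  # N
    peak_grip: float = np.nan  # N


def lowpass_grip(
    grip: np.ndarray, fs: float, cutoff: float = 12.0
) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass of the grip channel.

    Forward-backward application doubles the effective order and moves the
    -3 dB point down to ``cutoff*(sqrt(2)-1)**0.25``.  DC gain is exactly 1.
    Edges use reflect padding of three filter lengths.
    """
    if fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {cutoff} Hz design cutoff"
        )
    grip = np.asarray(grip, dtype=float)
    b, a = butter(2, cutoff / (fs / 2))
    padlen = min(3 * max(len(a), len(b)), max(len(grip) - 1, 0))
    return filtfilt(b, a, grip, padtype="even", padlen=padlen)


def effective_cutoff(design_cutoff: float = 12.0) -> float:
    """-3 dB frequency of the forward-backward 2nd-order Butterworth, Hz.

    The two passes square ``|H|^2 = 1/(1+(f/fc)^4)``; solving
    ``|H|^4 = 1/2`` gives ``fc*(sqrt(2)-1)**(1/4)`` (about 9.62 Hz for a
    12 Hz design).
    """
    return design_cutoff * (np.sqrt(2.0) - 1.0) ** 0.25


def segment_field(
    load: np.ndarray,
    grip: np.ndarray | None = None,
    y: np.ndarray | None = None,
    t: np.ndarray | None = None,
    fs: float | None = None,
    trial: int = 0,
    field: str = "standard",
    is_catch: np.ndarray | None = None,
    contact_eps: float = 0.0,
) -> list[Probe]:
    """Segment one (trial, field) series into probes using the load channel.

    ``contact_eps`` is a noise threshold on the load (0 for synthetic data,
    where out-of-contact load is exactly zero).
    """
    load = np.asarray(load, dtype=float)
    if t is not None:
        dt = np.diff(np.asarray(t, dtype=float))
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform time base")
        if fs is None and dt.size:
            fs = 1.0 / dt[0]
    if fs is None:
        raise ValueError("sampling rate unknown: pass fs or a time vector")

    contact = load > contact_eps
    padded = np.concatenate([[False], contact, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])

    probes: list[Probe] = []
    for number, (c0, c1) in enumerate(zip(starts, ends), start=1):
        start_idx = int(ends[number - 2]) if number >= 2 else 0
        end_idx = int(starts[number]) if number < len(starts) else len(load)
        depth = float(-np.min(y[c0:c1])) if y is not None else np.nan
        catch = bool(np.any(is_catch[c0:c1])) if is_catch is not None else False
        probe = Probe(
            trial=trial,
            field=field,
            probe_number=number,
            start_idx=start_idx,
            end_idx=end_idx,
            contact_idx=int(c0),
            contact_end=int(c1),
            depth=depth,
            duration=float(c1 - c0) / fs,
            is_catch=catch,
            peak_load=float(np.max(load[c0:c1])),
            peak_grip=float(np.max(grip[c0:c1])) if grip is not None else np.nan,
        )
        probes.append(validate_probe(probe, n_samples=len(load)))
    return probes


def segment_probes(
    trajectory: pd.DataFrame,
    fs: float | None = None,
    contact_eps: float = 0.0,
) -> list[Probe]:
    """Segment a long-format trajectory table into probes per (trial, field).

    Expects the columns written by the generator: trial, field, t_s, y_m,
    load_N, grip_N, is_catch (the last two optional).
    """
    probes: list[Probe] = []
    for (trial, field), g in trajectory.groupby(["trial", "field"], sort=True):
        probes.extend(
            segment_field(
                g["load_N"].to_numpy(),
                grip=g["grip_N"].to_numpy() if "grip_N" in g else None,
                y=g["y_m"].to_numpy() if "y_m" in g else None,
                t=g["t_s"].to_numpy() if "t_s" in g else None,
                fs=fs,
                trial=trial,
                field=field,
                is_catch=g["is_catch"].to_numpy() if "is_catch" in g else None,
                contact_eps=contact_eps,
            )
        )
    return probes


def validate_probe(
    probe: Probe,
    min_depth: float = MIN_DEPTH_M,
    max_duration: float = MAX_DURATION_S,
    n_samples: int | None = None,
) -> Probe:
    """Flag a probe as a successful movement.

    Valid iff it penetrated at least ``min_depth``, stayed in contact no
    longer than ``max_duration``, and both started and ended out of contact
    (its contact run does not touch the series boundary).
    """
    in_bounds = probe.contact_idx > 0
    if n_samples is not None:
        in_bounds = in_bounds and probe.contact_end < n_samples
    depth_ok = not np.isnan(probe.depth) and probe.depth >= min_depth
    return replace(
        probe, valid=bool(depth_ok and probe.duration <= max_duration and in_bounds)
    )


def find_grip_peaks(grip: np.ndarray, prominence: float = 0.05) -> np.ndarray:
    """Indices of local grip-force maxima with at least the given prominence.

    Deterministic replacement for manually corrected peak picking; the
    default 0.05 N prominence suppresses noise-scale ripples.
    """
    if prominence < 0:
        raise ValueError("prominence must be nonnegative")
    grip = np.asarray(grip, dtype=float)
    peaks, _ = find_peaks(grip, prominence=prominence if prominence > 0 else None)
    return peaks


def released_grip(
    grip: np.ndarray, fs: float, eps: float = 0.05, min_duration: float = 0.05
) -> bool:
    """True if the grip dropped below ``eps`` N for longer than ``min_duration``.

    Trials where the participant released the device cannot be analyzed and
    are dropped.
    """
    low = np.asarray(grip, dtype=float) < eps
    if not low.any():
        return False
    padded = np.concatenate([[False], low, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    return bool(np.max(ends - starts) / fs > min_duration)
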