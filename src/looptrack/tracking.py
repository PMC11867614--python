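"""Rotary-encoder tick integration: calibrated 1D position with lap wrap.

The position controller on a real rig reports signed tick deltas (quadrature
counts, pre-decoded) whenever the animal moves; this module turns those
deltas into linear position in millimetres on a track of length L, counting
laps on wrap.  A physical lap-reset sensor marks each full belt revolution;
applying it cancels integration drift (belt slip, missed ticks) that would
otherwise accumulate without bound.

Positions live in [0, L); on circular tracks distances are circular:
d(a, b) = min(|a-b|, L-|a-b|).  Backward motion floors at 0 within a lap —
laps never go negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class TrackConfig:
    track_length_mm: float
    scale_mm_per_tick: float
    circular: bool = True

    def __post_init__(self):
        if not (self.track_length_mm > 0 and math.isfinite(self.track_length_mm)):
            raise ValueError("track_length_mm must be positive and finite")
        if not (self.scale_mm_per_tick > 0 and math.isfinite(self.scale_mm_per_tick)):
            raise ValueError("scale_mm_per_tick must be positive and finite")


@dataclass(frozen=True)
class TrackState:
    position_mm: float = 0.0
    lap: int = 0
    cumulative_ticks: int = 0
    last_update_ms: int = 0


def circular_distance(a: float, b: float, length: float) -> float:
    """Shortest arc distance between two positions on a ring of given length."""
    d = abs(a - b) % length
    return min(d, length - d)


def signed_offset_from_zero(pos: float, length: float) -> float:
    """Signed shorter-arc offset of ``pos`` from 0: positive just past 0,
    negative just short of a full lap."""
    return pos if pos <= length / 2 else pos - length


def integrate_ticks(s: TrackState, cfg: TrackConfig, delta_ticks: int,
                    now_ms: int) -> TrackState:
    """Advance the track state by a signed tick delta.

    Forward motion past L increments the lap and wraps by subtraction,
    preserving the residual distance.  Backward motion floors at 0 within
    the current lap (no negative laps).
    """
    if now_ms < s.last_update_ms:
        raise ValueError("now_ms precedes last update")
    L = cfg.track_length_mm
    pos = s.position_mm + delta_ticks * cfg.scale_mm_per_tick
    lap = s.lap
    if cfg.circular:
        while pos >= L:
            pos -= L
            lap += 1
    else:
        pos = min(pos, L - math.ulp(L))
    if pos < 0:
        pos = 0.0
    return TrackState(position_mm=pos, lap=lap,
                      cumulative_ticks=s.cumulative_ticks + delta_ticks,
                      last_update_ms=now_ms)


def apply_lap_reset(s: TrackState, cfg: TrackConfig,
                    guard_fraction: float = 0.25) -> tuple[TrackState, float]:
    """Zero the position on a lap-reset sensor event; return the drift.

    drift_mm is the signed shorter-arc distance between the integrated
    position and 0: negative when integration lags the belt (reset arrives
    before the software wrap), positive when it leads.  The lap count is
    incremented only when the software wrap has not already counted this
    revolution — within a guard window of ``guard_fraction * L`` after a
    wrap no double increment occurs.
    """
    L = cfg.track_length_mm
    drift = signed_offset_from_zero(s.position_mm, L)
    lap = s.lap
    if not (0 <= s.position_mm < L * guard_fraction):
        # wrap not yet counted for this revolution
        lap += 1
    return replace(s, position_mm=0.0, lap=lap), drift


def calibrate_scale(tick_counts_per_lap: Sequence[int],
                    belt_length_mm: float) -> float:
    """Estimate mm-per-tick from full-lap tick counts: L / mean(counts)."""
    if not tick_counts_per_lap:
        raise CalibrationError("no complete laps recorded")
    mean_ticks = sum(tick_counts_per_lap) / len(tick_counts_per_lap)
    if mean_ticks == 0:
        raise CalibrationError("zero mean tick count")
    return belt_length_mm / mean_ticks


def tracking_error_report(
    logged: Sequence[tuple[float, float, int]],
    truth: Sequence[tuple[float, float, int]],
    track_length_mm: float,
) -> dict:
    """Per-lap tracking error of a logged stream against ground truth.

    Both streams are (t_ms, position_mm, lap) samples.  For each lap k the
    completion time is the first sample whose lap count reaches k; the time
    error is logged minus truth completion time (s), and the position error
    is the circular distance of the logged position (sampled at the truth
    completion time) from 0, in mm.

    If the streams disagree on lap count the report covers the common laps
    and carries a warning record.
    """
    def completions(stream):
        out = {}
        prev = stream[0][2]
        for t, _pos, lap in stream:
            if lap > prev:
                for k in range(prev + 1, lap + 1):
                    out.setdefault(k, t)
                prev = lap
        return out

    def position_at(stream, t_query):
        best = stream[0][1]
        for t, pos, _lap in stream:
            if t <= t_query:
                best = pos
            else:
                break
        return best

    logged_done = completions(logged)
    truth_done = completions(truth)
    common = sorted(set(logged_done) & set(truth_done))
    warnings = []
    if set(logged_done) != set(truth_done):
        warnings.append(
            f"lap-count mismatch: logged {sorted(logged_done)} vs "
            f"truth {sorted(truth_done)}; report truncated to common laps")
    time_err = [(logged_done[k] - truth_done[k]) / 1000.0 for k in common]
    pos_err = [circular_distance(position_at(logged, truth_done[k]), 0.0,
                                 track_length_mm) for k in common]
    return {"lap_time_error_s": time_err,
            "lap_position_error_mm": pos_err,
            "laps": common,
            "warnings": warnings}
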