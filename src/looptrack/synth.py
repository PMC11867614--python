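"""Seeded synthetic place-cell populations tied to simulated behavior.

Cells are Gaussian-tuned on the circular track: the event rate at position
x is

    rate(x) = baseline + (peak - baseline) * exp(-d(x, center)^2 / (2 w^2))

with d the circular distance.  Untuned distractors have peak = baseline.
Events are Bernoulli per imaging frame with p = rate(x) * dt (valid only
while p <= 1; violating specs raise), and event amplitudes are lognormal.
Ground-truth labels (tuned flag, center, width) ride along so every
analysis stage can be scored against what was actually generated.

The generated trains share the position trace of the behavioral ground
truth, so generated occupancy equals rig occupancy exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from looptrack.analysis import EventTrain
from looptrack.rig import GroundTruth
from looptrack.tracking import circular_distance


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth tuning of one synthetic cell."""

    tuned: bool
    center_mm: float
    width_mm: float               # Gaussian SD of the tuning profile
    peak_rate_hz: float
    baseline_rate_hz: float
    amp_mu: float = 0.0           # lognormal amplitude parameters
    amp_sigma: float = 0.5

    def __post_init__(self):
        if not np.isfinite(self.peak_rate_hz) or self.peak_rate_hz < 0:
            raise ValueError("peak_rate_hz must be finite and >= 0")
        if not np.isfinite(self.baseline_rate_hz) or self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be finite and >= 0")
        if self.width_mm <= 0:
            raise ValueError("width_mm must be > 0")
        if not self.tuned and self.peak_rate_hz != self.baseline_rate_hz:
            raise ValueError("untuned cells must have peak == baseline")

    def rate_at(self, position_mm: np.ndarray, track_length_mm: float
                ) -> np.ndarray:
        d = np.abs(np.asarray(position_mm) - self.center_mm)
        d = np.minimum(d % track_length_mm, track_length_mm - d % track_length_mm)
        return (self.baseline_rate_hz +
                (self.peak_rate_hz - self.baseline_rate_hz) *
                np.exp(-d ** 2 / (2 * self.width_mm ** 2)))


@dataclass
class PopulationSpec:
    """Recipe for a synthetic population.

    Defaults: 600 cells, 40% tuned, 30 Hz imaging — a mid-sized 1-plane
    CA1 recording with a plausible place-cell fraction.
    """

    n_cells: int = 600
    fraction_tuned: float = 0.4
    frame_rate_hz: float = 30.0
    track_length_mm: float = 2000.0
    peak_rate_hz: tuple[float, float] = (1.0, 4.0)     # uniform draw range
    baseline_rate_hz: float = 0.1
    width_mm: tuple[float, float] = (60.0, 150.0)      # SD draw range
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.fraction_tuned <= 1):
            raise ValueError("fraction_tuned must be in [0, 1]")

    def draw_cells(self, rng: np.random.Generator) -> list[CellSpec]:
        n_tuned = int(round(self.n_cells * self.fraction_tuned))
        cells = []
        for i in range(self.n_cells):
            tuned = i < n_tuned
            center = float(rng.uniform(0, self.track_length_mm))
            width = float(rng.uniform(*self.width_mm))
            if tuned:
                peak = float(rng.uniform(*self.peak_rate_hz))
                base = self.baseline_rate_hz
            else:
                peak = base = self.baseline_rate_hz
            cells.append(CellSpec(tuned=tuned, center_mm=center,
                                  width_mm=width, peak_rate_hz=peak,
                                  baseline_rate_hz=base))
        return cells


@dataclass
class Population:
    """Generated event trains plus their ground-truth labels."""

    amplitudes: np.ndarray        # (n_frames, n_cells)
    position_mm: np.ndarray
    lap: np.ndarray
    t_ms: np.ndarray
    frame_period_s: float
    track_length_mm: float
    labels: pd.DataFrame          # tuned, center_mm, width_mm, peak/baseline

    @property
    def n_cells(self) -> int:
        return self.amplitudes.shape[1]

    def train(self, cell: int) -> EventTrain:
        return EventTrain(amplitudes=self.amplitudes[:, cell],
                          frame_period_s=self.frame_period_s,
                          position_mm=self.position_mm, lap=self.lap)

    # -- session-bundle IO (shared with the CLI and analysis loader) -----
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"t_ms": self.t_ms, "position_mm": self.position_mm,
                      "lap": self.lap}).to_csv(out / "frames.csv", index=False)
        frame, cell = np.nonzero(self.amplitudes)
        pd.DataFrame({"frame": frame, "cell": cell,
                      "amplitude": self.amplitudes[frame, cell]}
                     ).to_csv(out / "events.csv", index=False)
        self.labels.to_csv(out / "labels.csv", index=False)
        with open(out / "session.json", "w") as fh:
            json.dump({"frame_period_s": self.frame_period_s,
                       "track_length_mm": self.track_length_mm,
                       "n_cells": self.n_cells}, fh, indent=2)
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "Population":
        d = Path(in_dir)
        with open(d / "session.json") as fh:
            meta = json.load(fh)
        frames = pd.read_csv(d / "frames.csv")
        events = pd.read_csv(d / "events.csv")
        labels = pd.read_csv(d / "labels.csv")
        amps = np.zeros((len(frames), meta["n_cells"]))
        amps[events["frame"].to_numpy(), events["cell"].to_numpy()] = \
            events["amplitude"].to_numpy()
        return cls(amplitudes=amps,
                   position_mm=frames["position_mm"].to_numpy(),
                   lap=frames["lap"].to_numpy(int),
                   t_ms=frames["t_ms"].to_numpy(),
                   frame_period_s=meta["frame_period_s"],
                   track_length_mm=meta["track_length_mm"],
                   labels=labels)


def _frames_from_truth(truth: GroundTruth, frame_rate_hz: float
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample the behavioral ground truth onto the imaging frame clock."""
    frame_ms = 1000.0 / frame_rate_hz
    t = np.arange(frame_ms, truth.t_ms[-1] + 1e-9, frame_ms)
    idx = np.searchsorted(truth.t_ms, t, side="left")
    idx = np.clip(idx, 0, len(truth.t_ms) - 1)
    return t, truth.position_mm[idx], truth.lap[idx]


def generate_population(spec: PopulationSpec, truth: GroundTruth,
                        cells: list[CellSpec] | None = None) -> Population:
    """Generate per-cell event-amplitude trains on a behavioral trace.

    Bernoulli-per-frame events with p = rate(pos) * dt; raises when any
    cell's peak rate violates p <= 1 at the imaging frame rate.
    """
    if truth.lap[-1] < 2:
        raise ValueError("ground truth must cover at least 2 laps")
    rng = np.random.default_rng(spec.seed)
    if cells is None:
        cells = spec.draw_cells(rng)
    dt = 1.0 / spec.frame_rate_hz
    max_rate = max(c.peak_rate_hz for c in cells)
    if max_rate * dt > 1.0:
        raise ValueError(
            f"frame period x max rate = {max_rate * dt:.2f} > 1; "
            "Bernoulli event model invalid")
    t_ms, pos, lap = _frames_from_truth(truth, spec.frame_rate_hz)
    n = len(pos)
    amps = np.zeros((n, len(cells)))
    for j, c in enumerate(cells):
        p = c.rate_at(pos, spec.track_length_mm) * dt
        events = rng.random(n) < p
        k = int(events.sum())
        if k:
            amps[events, j] = rng.lognormal(c.amp_mu, c.amp_sigma, size=k)
    labels = pd.DataFrame({
        "cell": np.arange(len(cells)),
        "tuned": [c.tuned for c in cells],
        "center_mm": [c.center_mm for c in cells],
        "width_mm": [c.width_mm for c in cells],
        "peak_rate_hz": [c.peak_rate_hz for c in cells],
        "baseline_rate_hz": [c.baseline_rate_hz for c in cells],
    })
    return Population(amplitudes=amps, position_mm=pos, lap=lap, t_ms=t_ms,
                      frame_period_s=dt,
                      track_length_mm=spec.track_length_mm, labels=labels)


def constant_speed_truth(track_length_mm: float = 2000.0,
                         speed_mm_s: float = 200.0, n_laps: int = 30,
                         dt_ms: int = 10) -> GroundTruth:
    """Deterministic lap-structured running at constant speed (uniform
    occupancy), the baseline behavior for analysis fixtures."""
    duration_ms = int(n_laps * track_length_mm / speed_mm_s * 1000)
    n = duration_ms // dt_ms
    t = np.arange(1, n + 1) * dt_ms
    dist = speed_mm_s * t / 1000.0
    # a sample landing exactly on the final wrap belongs to the last lap
    lap = np.minimum((dist // track_length_mm).astype(int), n_laps - 1)
    return GroundTruth(t_ms=t.astype(float),
                       position_mm=dist % track_length_mm,
                       lap=lap,
                       lick_times_ms=[], zone_entry_times_ms=[], dt_ms=dt_ms)


def make_benchmark_suite(seed: int = 0, n_laps: int = 30,
                         n_cells: int = 100,
                         track_length_mm: float = 2000.0) -> dict:
    """Standard fixture families for validating the analysis pipeline.

    tuned_rich    - high-SNR tuned cells (peak >= 5x baseline) + distractors
    null          - fully untuned population (shuffle-null calibration)
    remap_pair    - same cells, centers redrawn in the second context
    rotated_pair  - second context = first rotated by a known bin shift
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]
    truth = constant_speed_truth(track_length_mm=track_length_mm,
                                 n_laps=n_laps)
    base = dict(n_cells=n_cells, frame_rate_hz=30.0,
                track_length_mm=track_length_mm,
                peak_rate_hz=(2.0, 5.0), baseline_rate_hz=0.1,
                width_mm=(60.0, 120.0))

    tuned_rich = generate_population(
        PopulationSpec(fraction_tuned=0.8, seed=seeds[0], **base), truth)
    null = generate_population(
        PopulationSpec(fraction_tuned=0.0, seed=seeds[1], **base), truth)

    spec_a = PopulationSpec(fraction_tuned=1.0, seed=seeds[2], **base)
    rng = np.random.default_rng(seeds[2])
    cells_a = spec_a.draw_cells(rng)
    pop_a = generate_population(spec_a, truth, cells=cells_a)
    # remapping: identical rates/widths, centers redrawn independently
    remap_rng = np.random.default_rng(seeds[3])
    cells_b = [CellSpec(tuned=c.tuned,
                        center_mm=float(remap_rng.uniform(0, track_length_mm)),
                        width_mm=c.width_mm, peak_rate_hz=c.peak_rate_hz,
                        baseline_rate_hz=c.baseline_rate_hz)
               for c in cells_a]
    pop_b = generate_population(
        PopulationSpec(fraction_tuned=1.0, seed=seeds[4], **base), truth,
        cells=cells_b)

    shift_bins = 7
    bin_mm = 40.0
    cells_rot = [CellSpec(tuned=c.tuned,
                          center_mm=(c.center_mm + shift_bins * bin_mm)
                          % track_length_mm,
                          width_mm=c.width_mm, peak_rate_hz=c.peak_rate_hz,
                          baseline_rate_hz=c.baseline_rate_hz)
                 for c in cells_a]
    pop_rot = generate_population(
        PopulationSpec(fraction_tuned=1.0, seed=seeds[5], **base), truth,
        cells=cells_rot)

    return {"truth": truth, "tuned_rich": tuned_rich, "null": null,
            "remap_pair": (pop_a, pop_b),
            "rotated_pair": (pop_a, pop_rot), "rotation_bins": shift_bins}
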