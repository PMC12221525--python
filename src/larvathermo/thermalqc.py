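"""Thermal-camera preprocessing: spike smoothing, gradient QC, burn-in removal.

The thermal camera's internal shutter occasionally injects single-frame,
single-pixel temperature spikes.  These are repaired by temporal
interpolation before any quality control.  A run's gradient is then checked
against three rules: both temperature extremes must stay represented (at
least 5% of pixels below 17.5 degC, and at least 5% above 24.5 degC, each in
more than 90% of frames), and no pixel may fluctuate more than 3 degC over
the whole run.  Finally, the first two minutes of every assay are discarded
as a burn-in while larvae acclimatise.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

BURNIN_S_DEFAULT = 120.0
SPIKE_JUMP_C = 3.0


@dataclass
class ThermalFrameSeries:
    """Time-stamped stack of 2D temperature grids covering the arena."""
    frames: np.ndarray      # (n, rows, cols) degC
    timestamps: np.ndarray  # (n,) seconds from assay start
    smoothed: bool = False
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.timestamps.size:
            raise ValueError("frames must be (n, rows, cols) matching timestamps")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("temperatures must be finite")

    @property
    def shape(self):
        return self.frames.shape[1:]


@dataclass
class QCReport:
    """Outcome of the gradient quality-control rules."""
    passed: bool
    frac_frames_cold_ok: float
    frac_frames_warm_ok: float
    max_pixel_range_C: float
    failing_rules: list

    def to_json(self) -> str:
        return json.dumps({
            "passed": bool(self.passed),
            "frac_frames_cold_ok": float(self.frac_frames_cold_ok),
            "frac_frames_warm_ok": float(self.frac_frames_warm_ok),
            "max_pixel_range_C": float(self.max_pixel_range_C),
            "failing_rules": list(self.failing_rules),
        }, indent=2)


# ---------------------------------------------------------------------------
# File I/O: one delimited matrix per frame + a JSON manifest
# ---------------------------------------------------------------------------

def write_thermal_frames(series: ThermalFrameSeries, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    for i, (frame, t) in enumerate(zip(series.frames, series.timestamps)):
        name = f"frame_{i:05d}.txt"
        np.savetxt(os.path.join(out_dir, name), frame, delimiter="\t")
        manifest.append({"file": name, "t_seconds": float(t)})
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_thermal_frames(in_dir) -> ThermalFrameSeries:
    with open(os.path.join(in_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    manifest = sorted(manifest, key=lambda e: e["t_seconds"])
    frames = np.stack([np.loadtxt(os.path.join(in_dir, e["file"]), delimiter="\t")
                       for e in manifest])
    return ThermalFrameSeries(frames=frames,
                              timestamps=[e["t_seconds"] for e in manifest])


# ---------------------------------------------------------------------------
# Spike smoothing
# ---------------------------------------------------------------------------

def smooth_spikes(series: ThermalFrameSeries, jump_C: float = SPIKE_JUMP_C,
                  max_iter: int = 10) -> ThermalFrameSeries:
    """Repair single-frame temperature spikes by temporal interpolation.

    A pixel sample differing from *both* temporal neighbours by more than
    ``jump_C`` is replaced by the mean of those neighbours; first/last frames
    are compared to (and substituted by) their single neighbour after the
    interior has been repaired.  The pass repeats until the series is stable
    so that the operation is idempotent even for adjacent spikes; isolated
    spikes converge in one pass.
    """
    frames = series.frames.copy()
    if frames.shape[0] < 2:
        return replace(series, frames=frames, smoothed=True,
                       warnings=series.warnings + ["single frame: spike smoothing skipped"])
    notes = list(series.warnings)
    for _ in range(max_iter):
        prev = frames
        frames = frames.copy()
        interior = frames[1:-1]
        lo = prev[:-2]
        hi = prev[2:]
        spike = (np.abs(prev[1:-1] - lo) > jump_C) & (np.abs(prev[1:-1] - hi) > jump_C)
        interior[spike] = 0.5 * (lo + hi)[spike]
        first_bad = np.abs(frames[0] - frames[1]) > jump_C
        frames[0][first_bad] = frames[1][first_bad]
        last_bad = np.abs(frames[-1] - frames[-2]) > jump_C
        frames[-1][last_bad] = frames[-2][last_bad]
        if np.array_equal(frames, prev):
            break
    else:
        notes.append("spike smoothing did not converge within max_iter passes")
    return replace(series, frames=frames, smoothed=True, warnings=notes)


# ---------------------------------------------------------------------------
# Gradient quality control
# ---------------------------------------------------------------------------

def qc_gradient(series: ThermalFrameSeries, cold_C: float = 17.5,
                warm_C: float = 24.5, tail_frac: float = 0.05,
                frame_frac: float = 0.90, max_range_C: float = 3.0) -> QCReport:
    """Check that the gradient held its shape for the whole run.

    Rules: (a) at least ``tail_frac`` of pixels below ``cold_C`` in more than
    ``frame_frac`` of frames, (b) the same above ``warm_C``, and (c) every
    pixel's max-min over the run within ``max_range_C``.  Run after
    :func:`smooth_spikes`, so camera artefacts do not trip rule (c).
    """
    if series.frames.shape[0] == 0:
        raise ValueError("empty thermal series")
    n_px = series.frames.shape[1] * series.frames.shape[2]
    cold_ok = np.mean(series.frames < cold_C, axis=(1, 2)) >= tail_frac
    warm_ok = np.mean(series.frames > warm_C, axis=(1, 2)) >= tail_frac
    frac_cold = float(np.mean(cold_ok))
    frac_warm = float(np.mean(warm_ok))
    pixel_range = series.frames.max(axis=0) - series.frames.min(axis=0)
    max_range = float(pixel_range.max())

    failing = []
    if not frac_cold > frame_frac:
        failing.append(f"cold tail (<{cold_C} degC on >={tail_frac:.0%} of pixels) "
                       f"held in only {frac_cold:.0%} of frames")
    if not frac_warm > frame_frac:
        failing.append(f"warm tail (>{warm_C} degC on >={tail_frac:.0%} of pixels) "
                       f"held in only {frac_warm:.0%} of frames")
    if max_range > max_range_C:
        failing.append(f"a pixel fluctuated {max_range:.2f} degC "
                       f"(limit {max_range_C} degC)")
    return QCReport(passed=not failing, frac_frames_cold_ok=frac_cold,
                    frac_frames_warm_ok=frac_warm, max_pixel_range_C=max_range,
                    failing_rules=failing)


# ---------------------------------------------------------------------------
# Burn-in removal
# ---------------------------------------------------------------------------

def remove_burnin(obj, burnin_s: float = BURNIN_S_DEFAULT):
    """Drop all samples with t < burnin_s from a track or a thermal series."""
    if isinstance(obj, ThermalFrameSeries):
        keep = obj.timestamps >= burnin_s
        return replace(obj, frames=obj.frames[keep], timestamps=obj.timestamps[keep])
    keep = obj.t >= burnin_s
    out = replace(obj, t=obj.t[keep], centroid=obj.centroid[keep],
                  head=obj.head[keep], bend_deg=obj.bend_deg[keep])
    if obj.temp_C is not None:
        out.temp_C = obj.temp_C[keep]
    if obj.temp_flags is not None:
        out.temp_flags = obj.temp_flags[keep]
    return out
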