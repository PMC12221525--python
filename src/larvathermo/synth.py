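"""Synthetic assay generator: thermal frames and tracker-style larva tracks.

Emulates one 20-minute thermal-arena assay end to end with known ground
truth, so the whole downstream pipeline is testable without raw video: a
17 x 17 cm arena holding a patchy 17-25 degC gradient imaged at 3 thermal
frames/min, and larvae tracked at 10 Hz.  Locomotion comes from the
agent-based thermotaxis model (or its temperature-blind variant); the
generator then degrades the ground truth the way a real tracker does —
identity loss at larva-larva clashes, tracking drop-outs that fragment
tracks, in-place "non-movers", and single-pixel thermal-camera spikes — at
configurable rates.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abm, thermalqc
from .abm import AgentModel, ThermoscapeConfig
from .thermalqc import ThermalFrameSeries, write_thermal_frames  # noqa: F401 (re-export)
from .tracks import Track, write_fimtrack_csv  # noqa: F401 (re-export)

THERMAL_FRAMES_PER_MIN = 3.0
SPIKE_AMPLITUDE_C = (8.0, 15.0)   # additive single-pixel, single-frame excursions
CLASH_RADIUS_MM = 2.0             # larvae this close can swap identities


@dataclass
class SynthConfig:
    """Study conditions for one synthetic assay.

    Rates are per-track expectations (Poisson); ``spike_rate`` is a
    per-pixel-per-frame probability.  ``agent_model`` is an
    :class:`~larvathermo.abm.AgentModel` or the string ``"blind"`` for
    temperature-blind locomotion.
    """
    arena_mm: float = 170.0
    px_per_mm: float = 4.0
    frame_rate_hz: float = 10.0
    duration_s: float = 1200.0
    n_larvae: int = 30
    agent_model: AgentModel | str = "blind"
    clash_rate: float = 0.0
    fragment_rate: float = 0.0
    spike_rate: float = 0.0
    nonmover_fraction: float = 0.0
    thermal_shape: tuple = (120, 160)   # (rows, cols); camera resolution
    thermal_noise_C: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.clash_rate, self.fragment_rate, self.spike_rate,
               self.nonmover_fraction) < 0:
            raise ValueError("rates must be non-negative")
        if self.px_per_mm <= 0 or self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("scale, duration and frame rate must be positive")
        if self.n_larvae < 0:
            raise ValueError("n_larvae must be >= 0")

    def model(self) -> AgentModel:
        if self.agent_model == "blind":
            return AgentModel(slope=0.0)
        return self.agent_model


@dataclass
class GroundTruth:
    """What the tracker *should* have seen."""
    tracks: list                      # one uncorrupted Track per larva
    larvae: pd.DataFrame              # true_id, kind, t_hsp_C, slope
    segments: pd.DataFrame            # raw_id -> true_id with cut provenance


# ---------------------------------------------------------------------------
# Thermal frames
# ---------------------------------------------------------------------------

def make_thermal_frames(config: SynthConfig,
                        gradient: ThermoscapeConfig) -> ThermalFrameSeries:
    """Render the thermoscape as a timed thermal-camera frame sequence.

    One frame per 20 s of simulated time (3 frames/min); pixel values are
    the analytic field at pixel centres plus optional Gaussian sensor noise
    and injected spikes (additive 8-15 degC, single pixel, single frame) at
    ``spike_rate`` per pixel-frame.
    """
    interval = 60.0 / THERMAL_FRAMES_PER_MIN
    n_frames = int(config.duration_s // interval)
    if n_frames <= 0:
        raise ValueError("duration too short for a single thermal frame")
    rng = np.random.default_rng(config.seed + 1)
    rows, cols = config.thermal_shape
    y = (np.arange(rows) + 0.5) * config.arena_mm / rows
    x = (np.arange(cols) + 0.5) * config.arena_mm / cols
    xx, yy = np.meshgrid(x, y)
    base = abm.thermoscape_at(xx, yy, gradient)
    frames = np.repeat(base[None], n_frames, axis=0)
    if config.thermal_noise_C > 0:
        frames = frames + rng.normal(0.0, config.thermal_noise_C, frames.shape)
    if config.spike_rate > 0:
        mask = rng.random(frames.shape) < config.spike_rate
        amp = rng.uniform(*SPIKE_AMPLITUDE_C, size=int(mask.sum()))
        frames[mask] += amp
    return ThermalFrameSeries(frames=frames,
                              timestamps=np.arange(n_frames) * interval)


# ---------------------------------------------------------------------------
# Larva tracks
# ---------------------------------------------------------------------------

def _nonmover_track(tid: int, nt: int, rate: float, arena_mm: float, rng) -> Track:
    """A larva that jitters in place: slow oscillation, cumulative path
    ~0.4 mm and net displacement ~0.05 mm — both below the mover thresholds."""
    t = np.arange(nt) / rate
    p0 = arena_mm * (0.35 + 0.3 * rng.random(2))
    u = rng.normal(size=2)
    u /= np.linalg.norm(u)
    amp = 0.05  # mm
    periods = 2.0
    disp = amp * np.sin(2 * np.pi * periods * t / t[-1] if nt > 1 else t)
    centroid = p0 + disp[:, None] * u
    phi = rng.uniform(0, 2 * np.pi)
    head = centroid + 2.0 * np.array([np.cos(phi), np.sin(phi)])
    bend = np.abs(rng.normal(0.0, 3.0, nt))
    return Track(id=tid, t=t, centroid=centroid, head=head, bend_deg=bend)


def _synthesize_bend(track: Track, rng, noise_deg: float = 3.0,
                     frame_rate_hz: float = 10.0) -> None:
    """Overlay bend excursions at heading changes onto baseline noise.

    Each reorientation event becomes a triangular |bend| bump lasting ~1 s
    and peaking at the heading-change magnitude, which is what a tracker's
    body-bend channel reports during a head sweep."""
    head_vec = track.head - track.centroid
    theta = np.unwrap(np.arctan2(head_vec[:, 1], head_vec[:, 0]))
    dtheta = np.abs(np.diff(theta, prepend=theta[0]))
    bend = np.abs(rng.normal(0.0, noise_deg, track.t.size))
    half = int(frame_rate_hz / 2)
    bump = np.concatenate([np.linspace(0, 1, half + 1)[1:],
                           np.linspace(1, 0, half + 1)[1:]])
    events = np.flatnonzero(dtheta > np.deg2rad(15.0))
    for e in events:
        lo = max(0, e - half)
        hi = min(track.t.size, e + half)
        seg = bump[(lo - e + half):(hi - e + half)]
        peak = np.rad2deg(dtheta[e])
        bend[lo:hi] = np.maximum(bend[lo:hi], peak * seg)
    track.bend_deg = bend


def make_tracks(config: SynthConfig, gradient: ThermoscapeConfig):
    """Generate raw tracker output plus its ground truth.

    Returns ``(raw_tracks, ground_truth)``.  Movers follow the configured
    agent model for the full assay (no burn-in removed: raw tracker output
    starts at t = 0); a ``nonmover_fraction`` of larvae jitter in place.
    Identity corruption is then layered on: each clash event terminates two
    tracks on the same frame and restarts both under new ids one frame
    later; each fragmentation event deletes a 2-15 s run of samples and
    splits the track.  ``n_larvae = 0`` returns an empty table, not an
    error.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_larvae
    n_non = int(round(config.nonmover_fraction * n))
    n_mov = n - n_non
    nt = int(round(config.duration_s * config.frame_rate_hz))

    true_tracks: list[Track] = []
    if n_mov > 0:
        model = config.model()
        cohort_seed = int(rng.integers(2 ** 31 - 1))
        true_tracks += abm.simulate_cohort(model, gradient, n_mov,
                                           duration_s=config.duration_s,
                                           burnin_s=0.0, seed=cohort_seed)
        for tr in true_tracks:
            _synthesize_bend(tr, rng, frame_rate_hz=config.frame_rate_hz)
    for i in range(n_non):
        true_tracks.append(_nonmover_track(n_mov + i, nt, config.frame_rate_hz,
                                           config.arena_mm, rng))

    model = config.model()
    larvae = pd.DataFrame({
        "true_id": [tr.id for tr in true_tracks],
        "kind": ["mover"] * n_mov + ["nonmover"] * n_non,
        "t_hsp_C": [model.t_hsp_C] * n_mov + [np.nan] * n_non,
        "slope": [model.slope] * n_mov + [np.nan] * n_non,
    })

    # --- plan cuts per larva ------------------------------------------------
    # each cut is (frame_index, kind); a clash cut splits two larvae on the
    # same frame, a fragment cut removes a gap of samples
    cuts = {tr.id: [] for tr in true_tracks}
    mover_ids = [tr.id for tr in true_tracks[:n_mov]]
    if config.clash_rate > 0 and len(mover_ids) >= 2:
        n_events = rng.poisson(config.clash_rate * len(mover_ids) / 2.0)
        for _ in range(n_events):
            a, b = rng.choice(mover_ids, size=2, replace=False)
            f = int(rng.integers(int(5 * config.frame_rate_hz),
                                 nt - int(5 * config.frame_rate_hz)))
            cuts[a].append((f, "clash", 0))
            cuts[b].append((f, "clash", 0))
    if config.fragment_rate > 0:
        for tid in mover_ids:
            for _ in range(rng.poisson(config.fragment_rate)):
                gap_s = rng.uniform(2.0, 15.0)
                gap = int(round(gap_s * config.frame_rate_hz))
                f = int(rng.integers(int(5 * config.frame_rate_hz),
                                     nt - gap - int(5 * config.frame_rate_hz)))
                cuts[tid].append((f, "fragment", gap))

    # --- apply cuts, renumbering segments ----------------------------------
    raw_tracks: list[Track] = []
    seg_rows = []
    next_id = 0
    for tr in true_tracks:
        tr_cuts = sorted(cuts[tr.id])
        bounds = []
        start = 0
        for f, kind, gap in tr_cuts:
            if f <= start or f + gap >= nt:
                continue
            bounds.append((start, f + 1, kind))
            start = f + 1 + gap
        bounds.append((start, nt, "end"))
        for (lo, hi, kind) in bounds:
            if hi <= lo:
                continue
            seg = Track(id=next_id, t=tr.t[lo:hi], centroid=tr.centroid[lo:hi],
                        head=tr.head[lo:hi], bend_deg=tr.bend_deg[lo:hi])
            raw_tracks.append(seg)
            seg_rows.append({"raw_id": next_id, "true_id": tr.id,
                             "start_s": float(tr.t[lo]), "end_s": float(tr.t[hi - 1]),
                             "cut_kind": kind})
            next_id += 1

    segments = pd.DataFrame(seg_rows,
                            columns=["raw_id", "true_id", "start_s", "end_s",
                                     "cut_kind"])
    return raw_tracks, GroundTruth(tracks=true_tracks, larvae=larvae,
                                   segments=segments)
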