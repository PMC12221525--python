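"""Track container, FIMtrack-style CSV I/O, and track cleaning.

Raw tracker output is noisy in three specific ways this module repairs:
tracks shorter than a duration floor, "non-movers" (objects that jitter in
place without crawling), identity loss when two larvae collide (both tracks
end on the same frame), and tracking drop-outs that fragment one larva into
several tracks separated by a spatio-temporal gap.  Cleaning order matters:
short-track and non-mover filters run on raw tracks, clash resolution runs
before gap joining, and temperature assignment runs last on full tracks.

Coordinates are millimetres internally (arena origin at the top-left corner,
x rightward, y downward); CSV files store pixels at ``px_per_mm`` (default
4 px/mm).  Time is seconds from assay start; sample times are derived from
integer frame numbers at the nominal frame rate so that file round-trips are
exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_PX_PER_MM = 4.0
DEFAULT_FRAME_RATE_HZ = 10.0

FIMTRACK_COLUMNS = ["frame", "id", "mom_x", "mom_y", "head_x", "head_y", "bending"]

#: (max spatial gap px, max temporal gap s, max implied speed px/s) per round;
#: the final round is unrestricted.
FRAGMENT_ROUNDS = (
    (150.0, 22.5, 15.0),
    (500.0, 75.0, 30.0),
    (np.inf, np.inf, np.inf),
)


@dataclass
class Track:
    """One larva's per-frame time series.

    Attributes
    ----------
    id : int
        Track identifier (stable across cleaning; joins keep the earlier id).
    t : ndarray
        Sample times in seconds, strictly increasing at nominal 0.1 s spacing;
        gaps are allowed only between joined segments.
    centroid : ndarray, shape (n, 2)
        Body-centre position in mm.
    head : ndarray, shape (n, 2)
        Head-tip position in mm (thermosensors sit at the head tip, so this
        is the default body part for temperature lookup).
    bend_deg : ndarray
        Body-bend magnitude in degrees, 0 = straight posture.
    temp_C : ndarray or None
        Assigned temperature per sample; None until assignment.
    source_ids : list of int
        Raw track ids merged into this track (join audit trail).
    join_rounds : list
        One entry per join event: ("clash", joined_id) or (round_no, joined_id).
    temp_flags : ndarray or None
        True where the position fell outside the thermal frame and the lookup
        was clamped to the nearest edge pixel.
    """

    id: int
    t: np.ndarray
    centroid: np.ndarray
    head: np.ndarray
    bend_deg: np.ndarray
    temp_C: np.ndarray | None = None
    source_ids: list = field(default_factory=list)
    join_rounds: list = field(default_factory=list)
    temp_flags: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.head = np.asarray(self.head, dtype=float)
        self.bend_deg = np.asarray(self.bend_deg, dtype=float)
        if not self.source_ids:
            self.source_ids = [self.id]
        if self.t.ndim != 1 or self.centroid.shape != (self.t.size, 2):
            raise ValueError("inconsistent track array shapes")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def path_length_mm(self) -> float:
        if self.t.size < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.centroid, axis=0), axis=1)))

    def max_displacement_mm(self) -> float:
        """Largest distance from the first sample reached anywhere on the track."""
        if self.t.size < 2:
            return 0.0
        return float(np.max(np.linalg.norm(self.centroid - self.centroid[0], axis=1)))


def tracks_equal(a: Track, b: Track) -> bool:
    """Field-wise equality on the retained (file round-trip) fields."""
    return (
        a.id == b.id
        and np.array_equal(a.t, b.t)
        and np.array_equal(a.centroid, b.centroid)
        and np.array_equal(a.head, b.head)
        and np.array_equal(a.bend_deg, b.bend_deg)
    )


# ---------------------------------------------------------------------------
# FIMtrack-style CSV I/O
# ---------------------------------------------------------------------------

def write_fimtrack_csv(tracks, path, px_per_mm: float = DEFAULT_PX_PER_MM,
                       frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> None:
    """Write tracks as one row per larva-frame with pixel coordinates.

    Columns: ``frame, id, mom_x, mom_y, head_x, head_y, bending``.
    An empty track list produces a header-only file.
    """
    parts = []
    for tr in tracks:
        frames = np.rint(tr.t * frame_rate_hz).astype(np.int64)
        parts.append(pd.DataFrame({
            "frame": frames,
            "id": tr.id,
            "mom_x": tr.centroid[:, 0] * px_per_mm,
            "mom_y": tr.centroid[:, 1] * px_per_mm,
            "head_x": tr.head[:, 0] * px_per_mm,
            "head_y": tr.head[:, 1] * px_per_mm,
            "bending": tr.bend_deg,
        }))
    if parts:
        df = pd.concat(parts, ignore_index=True)
    else:
        df = pd.DataFrame(columns=FIMTRACK_COLUMNS)
    df.to_csv(path, index=False)


def read_fimtrack_csv(path, px_per_mm: float = DEFAULT_PX_PER_MM,
                      frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> list:
    """Read a FIMtrack-style CSV back into Track objects (mm / seconds).

    Raises ``ValueError`` naming the 1-based file line of the first malformed
    row.
    """
    rows = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != FIMTRACK_COLUMNS:
            raise ValueError(f"{path}: line 1: expected header {FIMTRACK_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                frame = int(row[0])
                tid = int(row[1])
                vals = [float(v) for v in row[2:7]]
                if len(row) != 7:
                    raise ValueError("wrong field count")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from None
            rows.setdefault(tid, []).append((frame, *vals))
    tracks = []
    for tid in sorted(rows):
        arr = np.array(sorted(rows[tid]), dtype=float)
        tracks.append(Track(
            id=tid,
            t=arr[:, 0] / frame_rate_hz,
            centroid=arr[:, 1:3] / px_per_mm,
            head=arr[:, 3:5] / px_per_mm,
            bend_deg=arr[:, 5],
        ))
    return tracks


# ---------------------------------------------------------------------------
# Filters (applied to raw tracks, before joining)
# ---------------------------------------------------------------------------

def filter_short(tracks, min_duration_s: float = 10.0) -> list:
    """Drop tracks whose duration is strictly below the floor.

    A track of exactly ``min_duration_s`` is kept (the rule is "shorter
    than", read strictly).
    """
    return [tr for tr in tracks if tr.duration_s >= min_duration_s]


def filter_nonmoving(tracks, min_cum_mm: float = 0.5, min_net_mm: float = 0.3) -> list:
    """Drop tracks that neither travelled ``min_cum_mm`` cumulatively nor
    reached ``min_net_mm`` from their origin.

    Both criteria must fail for removal: a track is kept as soon as it either
    accumulates enough path or strays far enough from its start.
    """
    kept = []
    for tr in tracks:
        if tr.path_length_mm() <= min_cum_mm and tr.max_displacement_mm() <= min_net_mm:
            continue
        kept.append(tr)
    return kept


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------

def _concat(a: Track, b: Track, round_label) -> Track:
    joined = Track(
        id=min(a.id, b.id),
        t=np.concatenate([a.t, b.t]),
        centroid=np.vstack([a.centroid, b.centroid]),
        head=np.vstack([a.head, b.head]),
        bend_deg=np.concatenate([a.bend_deg, b.bend_deg]),
        source_ids=a.source_ids + b.source_ids,
        join_rounds=a.join_rounds + b.join_rounds + [(round_label, b.id)],
    )
    return joined


def _gap(a: Track, b: Track):
    """(temporal gap s, spatial gap mm) from the end of ``a`` to the start of ``b``."""
    dt = b.t[0] - a.t[-1]
    dd = float(np.linalg.norm(b.centroid[0] - a.centroid[-1]))
    return dt, dd


def join_clashes(tracks, frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> list:
    """Resolve larva-larva collisions.

    A clash leaves a signature: two (or more) tracks end abruptly on the same
    frame and new tracks start just after.  Each ended track is paired with
    the candidate starting soonest afterwards whose start point is
    reciprocally closest — ranking is lexicographic with the temporal gap
    first, then the spatial gap; ties break toward the smaller track id.
    Matched pairs are concatenated under the earlier id; unmatched tracks
    pass through unchanged.
    """
    tracks = list(tracks)
    tol = 0.5 / frame_rate_hz  # same-frame tolerance on end times
    while True:
        ends = np.array([tr.t[-1] for tr in tracks])
        # earliest end time shared by >= 2 tracks that has viable successors
        joined_any = False
        for te in sorted(set(np.round(ends * frame_rate_hz).astype(np.int64))):
            te_s = te / frame_rate_hz
            enders = [tr for tr in tracks if abs(tr.t[-1] - te_s) < tol]
            if len(enders) < 2:
                continue
            starters = [tr for tr in tracks if tr.t[0] > te_s + tol]
            if not starters:
                continue
            pairs = _mutual_nearest(enders, starters)
            if not pairs:
                continue
            for x, y in pairs:
                tracks.remove(x)
                tracks.remove(y)
                tracks.append(_concat(x, y, "clash"))
            joined_any = True
            break  # track set changed; rescan end times
        if not joined_any:
            return sorted(tracks, key=lambda tr: (tr.t[0], tr.id))


def _mutual_nearest(enders, starters, max_d=np.inf, max_t=np.inf, max_speed=np.inf):
    """Reciprocally-closest (end, start) pairs under lexicographic (dt, dd) ranking."""
    best_succ = {}
    for x in enders:
        cands = []
        for y in starters:
            if y is x:
                continue
            dt, dd = _gap(x, y)
            if dt <= 0 or dt > max_t or dd > max_d:
                continue
            if np.isfinite(max_speed) and dd / dt >= max_speed:
                continue
            cands.append((dt, dd, y.id, y))
        if cands:
            best_succ[x.id] = min(cands)[3]
    best_pred = {}
    for y in starters:
        cands = []
        for x in enders:
            if x is y:
                continue
            dt, dd = _gap(x, y)
            if dt <= 0 or dt > max_t or dd > max_d:
                continue
            if np.isfinite(max_speed) and dd / dt >= max_speed:
                continue
            cands.append((dt, dd, x.id, x))
        if cands:
            best_pred[y.id] = min(cands)[3]
    pairs = []
    for x in enders:
        y = best_succ.get(x.id)
        if y is not None and best_pred.get(y.id) is x:
            pairs.append((x, y))
    return pairs


def join_fragments(tracks, px_per_mm: float = DEFAULT_PX_PER_MM,
                   rounds=FRAGMENT_ROUNDS) -> list:
    """Rejoin tracks fragmented by tracking drop-outs, in staged rounds.

    Round r admits a candidate pair (end of X, start of Y, Y starting after X
    ends) iff the spatial gap <= D_r, the temporal gap <= T_r, and the implied
    crawl speed across the gap (distance/time) < S_r, with per-round limits
    (150 px, 22.5 s, 15 px/s), (500 px, 75 s, 30 px/s) and finally no limits.
    Joins happen only between reciprocally closest pairs (temporal gap first,
    then spatial); each round iterates until no further joins occur.  Run
    after :func:`join_clashes`.
    """
    tracks = list(tracks)
    for rnd, (max_d_px, max_t, max_speed_px) in enumerate(rounds, start=1):
        max_d = max_d_px / px_per_mm
        max_speed = max_speed_px / px_per_mm
        while True:
            pairs = _mutual_nearest(tracks, tracks, max_d=max_d, max_t=max_t,
                                    max_speed=max_speed)
            if not pairs:
                break
            # apply non-conflicting joins; a track may appear in at most one pair
            used = set()
            merged = []
            for x, y in pairs:
                if x.id in used or y.id in used:
                    continue
                used.update((x.id, y.id))
                merged.append((x, y))
            for x, y in merged:
                tracks.remove(x)
                tracks.remove(y)
                tracks.append(_concat(x, y, rnd))
    return sorted(tracks, key=lambda tr: (tr.t[0], tr.id))


def join_audit(tracks) -> list:
    """Summarize which raw ids merged into each cleaned track and in which round."""
    return [
        {"id": tr.id, "source_ids": list(tr.source_ids),
         "joins": [{"round": r, "joined_id": j} for r, j in tr.join_rounds]}
        for tr in tracks
    ]


# ---------------------------------------------------------------------------
# Temperature assignment
# ---------------------------------------------------------------------------

def assign_temperature(track: Track, series, arena_mm: float = 170.0,
                       use_head: bool = True) -> Track:
    """Attach a temperature to every sample of a track.

    Each sample gets the value of the thermal frame nearest in time (ties
    toward the earlier frame) at the pixel nearest the head position (or the
    centroid with ``use_head=False``).  Positions outside the frame grid are
    clamped to the nearest edge pixel and flagged in ``temp_flags``.
    """
    pos = track.head if use_head else track.centroid
    ts = np.asarray(series.timestamps, dtype=float)
    frames = np.asarray(series.frames)
    n_rows, n_cols = frames.shape[1], frames.shape[2]

    # nearest frame in time, earlier on ties
    idx = np.searchsorted(ts, track.t)
    idx = np.clip(idx, 1, ts.size - 1) if ts.size > 1 else np.zeros_like(idx)
    if ts.size > 1:
        left = ts[idx - 1]
        right = ts[idx]
        choose_left = (track.t - left) <= (right - track.t)  # tie -> earlier
        fidx = np.where(choose_left, idx - 1, idx)
        # samples before the first frame
        fidx[track.t <= ts[0]] = 0
    else:
        fidx = np.zeros(track.t.size, dtype=int)

    col = np.floor(pos[:, 0] / arena_mm * n_cols).astype(int)
    row = np.floor(pos[:, 1] / arena_mm * n_rows).astype(int)
    flags = (col < 0) | (col >= n_cols) | (row < 0) | (row >= n_rows)
    col = np.clip(col, 0, n_cols - 1)
    row = np.clip(row, 0, n_rows - 1)

    out = replace(track)
    out.temp_C = frames[fidx, row, col].astype(float)
    out.temp_flags = flags
    return out
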