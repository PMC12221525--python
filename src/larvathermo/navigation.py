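"""Fine-scale navigation metrics and their temperature-zone statistics.

Three per-frame metrics describe how a larva navigates: crawl velocity over
a sliding 3 s window (in mm/s and body lengths/s), path tortuosity (one
minus straightness, averaged over 2/5/10/20/30 s windows), and head sweeps —
lateral body-bend excursions used to sample the gradient before reorienting.
Zone-level comparisons split the 17-25 degC span into equal thirds (cool /
mid / warm) and contrast metric distributions by bootstrap-style resampled
pairwise differences, linear temperature trends, and rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

FRAME_RATE_HZ = 10.0

#: Temperature zones: equal thirds of the 17-25 degC span.
ZONES = {
    "cool": (17.0, 19.67),
    "mid": (19.67, 22.33),
    "warm": (22.33, 25.0),
}

TORTUOSITY_WINDOWS_S = (2.0, 5.0, 10.0, 20.0, 30.0)


def zone_of(temp_C) -> np.ndarray:
    """Zone label per temperature sample ('' outside the 17-25 degC span).

    The warm zone is closed above so 25.0 degC itself is classified.
    """
    t = np.asarray(temp_C, dtype=float)
    out = np.full(t.shape, "", dtype=object)
    for name, (lo, hi) in ZONES.items():
        mask = (t >= lo) & ((t < hi) if hi < 25.0 else (t <= hi))
        out[mask] = name
    return out


@dataclass
class HeadSweep:
    """One detected lateral head excursion."""
    t_peak: float
    peak_deg: float
    accepted: bool   # peak exceeded the retention threshold (45 deg)


# ---------------------------------------------------------------------------
# Windowed metrics
# ---------------------------------------------------------------------------

def _window_bounds(n: int, half: int):
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return lo, hi


def windowed_velocity(track, window_s: float = 3.0,
                      frame_rate_hz: float = FRAME_RATE_HZ):
    """Per-frame crawl velocity over a centred sliding window.

    Velocity at frame i is the path length of the centroid across the window
    divided by the window's actual time span (so edge frames, where the
    window is truncated, are still well defined but flagged as partial).
    Returns ``(v_mm_s, v_bl_s, partial)``; body-length normalization uses the
    per-larva median body length, estimated as twice the median head-centroid
    distance.  Tracks shorter than the window yield empty arrays.
    """
    n = track.t.size
    if track.duration_s < window_s or n < 2:
        return np.array([]), np.array([]), np.array([], dtype=bool)
    half = int(round(window_s * frame_rate_hz / 2))
    seg = np.linalg.norm(np.diff(track.centroid, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    lo, hi = _window_bounds(n, half)
    span = track.t[hi] - track.t[lo]
    v = (cum[hi] - cum[lo]) / span
    partial = (hi - lo) < 2 * half
    body_len = 2.0 * float(np.median(np.linalg.norm(track.head - track.centroid,
                                                    axis=1)))
    v_bl = v / body_len if body_len > 0 else np.full_like(v, np.nan)
    return v, v_bl, partial


def windowed_tortuosity(track, windows_s=TORTUOSITY_WINDOWS_S,
                        frame_rate_hz: float = FRAME_RATE_HZ) -> np.ndarray:
    """Per-frame tortuosity in [0, 1], averaged over multiple window sizes.

    For each window size, tortuosity = 1 - (net displacement / accumulated
    path) over the centred window; a straight path scores 0 and a path that
    returns to its start scores 1.  Windows with zero accumulated path are
    undefined and excluded from the mean; window sizes longer than the track
    are skipped.
    """
    n = track.t.size
    if n < 2:
        return np.full(n, np.nan)
    seg = np.linalg.norm(np.diff(track.centroid, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    acc_stack = []
    for w in windows_s:
        if track.duration_s < w:
            continue
        half = int(round(w * frame_rate_hz / 2))
        lo, hi = _window_bounds(n, half)
        path = cum[hi] - cum[lo]
        net = np.linalg.norm(track.centroid[hi] - track.centroid[lo], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tort = np.where(path > 0, 1.0 - net / np.where(path > 0, path, 1.0),
                            np.nan)
        acc_stack.append(tort)
    if not acc_stack:
        return np.full(n, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(np.vstack(acc_stack), axis=0)


# ---------------------------------------------------------------------------
# Head sweeps
# ---------------------------------------------------------------------------

def detect_head_sweeps(bend_deg, t=None, init_deg: float = 30.0,
                       straight_deg: float = 10.0, buffer_s: float = 2.0,
                       keep_deg: float = 45.0,
                       frame_rate_hz: float = FRAME_RATE_HZ) -> list:
    """Detect head sweeps in a body-bend magnitude series.

    Local maxima of |bend| above ``init_deg`` qualify as sweeps if the bend
    subsequently returns to within ``straight_deg`` of a straight posture
    (before the next sweep, or by the end of the series).  Peaks closer than
    ``buffer_s`` merge, keeping the larger.  A sweep is *accepted* — i.e.
    kept for analysis — only if its peak exceeds ``keep_deg``.
    """
    bend = np.abs(np.asarray(bend_deg, dtype=float))
    if t is None:
        t = np.arange(bend.size) / frame_rate_hz
    t = np.asarray(t, dtype=float)
    peaks, props = signal.find_peaks(bend, height=init_deg)
    if peaks.size == 0:
        return []
    # merge peaks within the buffer, keeping the larger
    order = list(peaks)
    merged = True
    while merged and len(order) > 1:
        merged = False
        for i in range(len(order) - 1):
            if t[order[i + 1]] - t[order[i]] < buffer_s:
                drop = i if bend[order[i]] < bend[order[i + 1]] else i + 1
                order.pop(drop)
                merged = True
                break
    sweeps = []
    for j, p in enumerate(order):
        nxt = order[j + 1] if j + 1 < len(order) else bend.size
        if not np.any(bend[p:nxt] <= straight_deg):
            continue
        sweeps.append(HeadSweep(t_peak=float(t[p]), peak_deg=float(bend[p]),
                                accepted=bool(bend[p] > keep_deg)))
    return sweeps


def head_sweep_rate(track, accepted_only: bool = True, **kwargs) -> float:
    """Accepted head sweeps per second — the cohort 'turn rate' fed to the
    random-movement null."""
    sweeps = detect_head_sweeps(track.bend_deg, t=track.t, **kwargs)
    if accepted_only:
        sweeps = [s for s in sweeps if s.accepted]
    dur = track.duration_s
    return len(sweeps) / dur if dur > 0 else np.nan


# ---------------------------------------------------------------------------
# Zone statistics
# ---------------------------------------------------------------------------

_CONTRASTS = (("warm", "cool"), ("mid", "cool"), ("warm", "mid"))


def zone_differences(values_by_zone: dict, n_draws: int = 1000, seed=None) -> dict:
    """Resampled pairwise zone differences with Welch t-tests.

    For each contrast (warm-cool, mid-cool, warm-mid), draws ``n_draws``
    independent pairs (one value sampled uniformly from each zone) and
    records their differences; contrasts with an empty zone are skipped with
    a warning.  Returns per-contrast difference samples, their mean/quartile
    summaries, and Welch t-tests of each difference distribution against
    zero mean.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for za, zb in _CONTRASTS:
        a = np.asarray(values_by_zone.get(za, []), dtype=float)
        b = np.asarray(values_by_zone.get(zb, []), dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        name = f"{za}-{zb}"
        if a.size == 0 or b.size == 0:
            warnings.warn(f"zone contrast {name} skipped: empty zone", stacklevel=2)
            continue
        diffs = rng.choice(a, n_draws) - rng.choice(b, n_draws)
        out[name] = {
            "diffs": diffs,
            "mean": float(diffs.mean()),
            "q25": float(np.percentile(diffs, 25)),
            "median": float(np.median(diffs)),
            "q75": float(np.percentile(diffs, 75)),
        }
    return out


def compare_zone_differences(diffs_a, diffs_b):
    """Welch t-test between two resampled difference distributions (e.g. the
    same contrast in two species, or two contrasts within one)."""
    res = stats.ttest_ind(np.asarray(diffs_a, dtype=float),
                          np.asarray(diffs_b, dtype=float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def fit_temperature_trend(temp_C, values, groups=None, conf: float = 0.95) -> dict:
    """Ordinary least-squares metric-vs-temperature trend per group.

    Returns per-group slope, intercept, R^2 and a t-based confidence
    interval on the slope.  Raises on degenerate (constant-temperature) or
    undersized (< 3 samples) groups.
    """
    temp_C = np.asarray(temp_C, dtype=float)
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(temp_C.size, dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        m = (groups == g) & np.isfinite(temp_C) & np.isfinite(values)
        x, y = temp_C[m], values[m]
        if x.size < 3:
            raise ValueError(f"group {g!r}: need at least 3 samples")
        if np.ptp(x) == 0:
            raise ValueError(f"group {g!r}: constant temperature, trend undefined")
        res = stats.linregress(x, y)
        tcrit = stats.t.ppf(0.5 + conf / 2, x.size - 2)
        out[g] = {
            "slope": res.slope, "intercept": res.intercept,
            "r_squared": res.rvalue ** 2,
            "slope_ci": (res.slope - tcrit * res.stderr,
                         res.slope + tcrit * res.stderr),
            "n": int(x.size),
        }
    return out


def correlate(velocity, tortuosity):
    """Pearson correlation between velocity and tortuosity samples."""
    v = np.asarray(velocity, dtype=float)
    u = np.asarray(tortuosity, dtype=float)
    m = np.isfinite(v) & np.isfinite(u)
    res = stats.pearsonr(v[m], u[m])
    return float(res.statistic), float(res.pvalue)


def clade_compare(values_a_by_zone: dict, values_b_by_zone: dict) -> dict:
    """Wilcoxon rank-sum comparison of two clades' metric values per zone,
    Benjamini-Hochberg corrected across zones."""
    names, pvals, zstats = [], [], []
    for zone in ZONES:
        a = np.asarray(values_a_by_zone.get(zone, []), dtype=float)
        b = np.asarray(values_b_by_zone.get(zone, []), dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            continue
        res = stats.ranksums(a, b)
        names.append(zone)
        zstats.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    padj = stats.false_discovery_control(np.asarray(pvals)) if pvals else np.array([])
    return {"zones": names, "statistic": zstats, "p_raw": pvals,
            "p_adjusted": list(padj)}
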