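"""Temperature-preference index against a random-movement null.

On a patchy gradient the available area per temperature is unequal, so raw
residence times are not comparable across temperatures.  Preference is
therefore scored as an electivity index per 1 degC temperature window,

    Tp = (time_larva - time_random) / (time_larva + time_random),

where ``time_random`` is the expected residence time per window of randomly
moving agents simulated on the same gradient with the cohort's own speed and
turn rate.  Tp ranges from -1 (window avoided entirely relative to chance)
through 0 (at-chance occupancy) to +1 (time spent in a window the null never
reaches).  Windows are 1 degC wide and slide in 0.1 degC steps across the
17-25 degC span of the arena (71 windows).

A cohort's profile is summarized by Tp_opt, the window with the highest mean
Tp across larvae, and Tp_breadth, the contiguous range of windows whose
median Tp is not significantly negative (exact sign test per window,
Benjamini-Hochberg corrected): significantly positive windows are strong
preferences, significantly negative ones are aversive and bound the breadth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import abm
from .abm import AgentModel, ThermoscapeConfig

#: Window starts in degC: 17.0, 17.1, ..., 24.0 (71 windows of width 1 degC).
WINDOW_START_C = 17.0
WINDOW_STOP_C = 24.0
WINDOW_STEP_C = 0.1
WINDOW_WIDTH_C = 1.0
N_WINDOWS = 71
WINDOW_STARTS = np.round(WINDOW_START_C + WINDOW_STEP_C * np.arange(N_WINDOWS), 1)

_FINE_PER_WINDOW = int(round(WINDOW_WIDTH_C / abm.BIN_WIDTH_C))
_FINE_OFFSET = int(round((WINDOW_START_C - abm.BIN_LO_C) / abm.BIN_WIDTH_C))


@dataclass
class TpProfile:
    """Per-larva preference profile over the standard window grid."""
    window_starts: np.ndarray
    tp: np.ndarray
    n_samples_obs: np.ndarray    # seconds observed per window
    n_samples_null: np.ndarray   # expected seconds per window under the null


@dataclass
class TpSummary:
    """Cohort-level preference summary."""
    tp_opt_C: float
    tp_opt_mean: float
    breadth_low_C: float | None = None
    breadth_high_C: float | None = None
    strong_windows: list = field(default_factory=list)
    aversive_windows: list = field(default_factory=list)
    p_adjusted: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Occupancy histograms
# ---------------------------------------------------------------------------

def fine_to_window_occupancy(fine: np.ndarray) -> np.ndarray:
    """Roll a fine 0.1 degC histogram up to overlapping 1 degC windows.

    Window w = [start, start + 1) covers exactly ten consecutive fine bins,
    so the rollup is a sliding sum; works on (..., N_BINS) arrays.
    """
    fine = np.asarray(fine, dtype=float)
    c = np.cumsum(fine, axis=-1)
    lo = _FINE_OFFSET
    idx_hi = lo + _FINE_PER_WINDOW + np.arange(N_WINDOWS) - 1
    idx_lo = lo + np.arange(N_WINDOWS) - 1
    hi = c[..., idx_hi]
    low = np.where(idx_lo >= 0, c[..., np.maximum(idx_lo, 0)], 0.0)
    return hi - low


def track_window_occupancy(track) -> np.ndarray:
    """Seconds per 1 degC window from a track's assigned temperatures.

    Each sample contributes its nominal frame interval (median of the time
    diffs) — join gaps are not interpolated.
    """
    if track.temp_C is None:
        raise ValueError("track has no assigned temperatures; run assign_temperature")
    dt = float(np.median(np.diff(track.t))) if track.t.size > 1 else 0.1
    fine = np.zeros(abm.N_BINS)
    bins = np.clip(((track.temp_C - abm.BIN_LO_C) / abm.BIN_WIDTH_C).astype(np.int64),
                   0, abm.N_BINS - 1)
    np.add.at(fine, bins, dt)
    return fine_to_window_occupancy(fine)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

def simulate_null_agents(run_speed_mm_s: float, run_turn_rate_hz: float,
                         thermoscape: ThermoscapeConfig, n: int = 1000,
                         duration_s: float = 1200.0, burnin_s: float = 120.0,
                         seed=None, turn_sigma_deg: float = 60.0) -> np.ndarray:
    """Expected per-agent seconds per window under random movement.

    Temperature-blind agents (slope 0, hence zero gain everywhere) start
    uniformly inside the centred square one third the arena side, move at the
    cohort's average speed, and turn as a Poisson process at the cohort's
    average turn rate with wrapped-normal heading changes.  Walls reflect.
    The first ``burnin_s`` are discarded, as for real larvae.  Returns the
    mean window occupancy across agents (seconds per 1 degC window).
    """
    if n < 1:
        raise ValueError("need at least one null agent")
    if run_speed_mm_s <= 0 or run_turn_rate_hz <= 0:
        raise ValueError("speed and turn rate must be positive")
    occ = abm.simulate_batch(
        n, 21.0, 0.0, thermoscape, speed_mm_s=run_speed_mm_s,
        base_turn_rate_hz=run_turn_rate_hz, turn_sigma_deg=turn_sigma_deg,
        duration_s=duration_s, burnin_s=burnin_s, start_frac=0.33,
        rng=seed).occupancy
    return fine_to_window_occupancy(occ.mean(axis=0))


# ---------------------------------------------------------------------------
# The index and its summaries
# ---------------------------------------------------------------------------

def tp_profile(observed_window_s, null_window_s) -> TpProfile:
    """Electivity index per window: (obs - exp) / (obs + exp).

    Windows with zero observed and zero expected time carry no evidence
    either way and are set to 0 rather than -1.
    """
    obs = np.asarray(observed_window_s, dtype=float)
    exp = np.asarray(null_window_s, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and null histograms must share the window grid")
    total = obs + exp
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = np.where(total > 0, (obs - exp) / np.where(total > 0, total, 1.0), 0.0)
    return TpProfile(window_starts=WINDOW_STARTS.copy(), tp=tp,
                     n_samples_obs=obs, n_samples_null=exp)


def _tp_matrix(profiles) -> np.ndarray:
    rows = [p.tp if isinstance(p, TpProfile) else np.asarray(p, dtype=float)
            for p in profiles]
    mat = np.vstack(rows)
    if mat.shape[1] != N_WINDOWS:
        raise ValueError("profiles not on the standard window grid")
    return mat


def tp_opt(profiles) -> tuple[float, float]:
    """Window with the highest across-larvae mean Tp (ties -> coolest window)."""
    mat = _tp_matrix(profiles)
    means = mat.mean(axis=0)
    idx = int(np.argmax(means))  # argmax returns the first (coolest) maximum
    return float(WINDOW_STARTS[idx]), float(means[idx])


def tp_breadth(profiles, alpha: float = 0.05) -> TpSummary:
    """Classify windows by an exact sign test and derive the breadth.

    Per window, the null hypothesis is that the median Tp is zero: an exact
    two-sided sign test on the nonzero values, Benjamini-Hochberg corrected
    across the 71 windows.  Significant-positive windows are strong
    preferences, significant-negative ones are aversive; the breadth is the
    contiguous run of non-aversive windows containing Tp_opt, reported as
    [coolest window start, warmest window start + 1 degC).
    """
    mat = _tp_matrix(profiles)
    if mat.shape[0] < 6:
        warnings.warn("fewer than 6 larvae: sign test has little power",
                      stacklevel=2)
    pvals = np.ones(N_WINDOWS)
    direction = np.zeros(N_WINDOWS)
    for w in range(N_WINDOWS):
        vals = mat[:, w]
        nz = vals[vals != 0]
        if nz.size == 0:
            continue
        k = int(np.sum(nz > 0))
        res = stats.binomtest(k, nz.size, 0.5, alternative="two-sided")
        pvals[w] = res.pvalue
        direction[w] = np.sign(k - (nz.size - k))
    padj = stats.false_discovery_control(pvals)
    sig = padj <= alpha
    strong = sig & (direction > 0)
    aversive = sig & (direction < 0)

    opt_C, opt_mean = tp_opt(mat)
    opt_idx = int(np.round((opt_C - WINDOW_START_C) / WINDOW_STEP_C))
    summary = TpSummary(tp_opt_C=opt_C, tp_opt_mean=opt_mean,
                        strong_windows=list(WINDOW_STARTS[strong]),
                        aversive_windows=list(WINDOW_STARTS[aversive]),
                        p_adjusted=padj)
    ok = ~aversive
    if ok[opt_idx]:
        lo = opt_idx
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        hi = opt_idx
        while hi < N_WINDOWS - 1 and ok[hi + 1]:
            hi += 1
        summary.breadth_low_C = float(WINDOW_STARTS[lo])
        summary.breadth_high_C = float(WINDOW_STARTS[hi] + WINDOW_WIDTH_C)
    return summary


def compare_profiles_mwu(profiles_a, profiles_b,
                         alternative: str = "two-sided") -> dict:
    """Per-window Mann-Whitney U comparison of two cohorts' Tp values.

    Returns raw and Benjamini-Hochberg-adjusted p-values per window; Tp
    distributions are bounded and typically non-normal, hence the rank test.
    """
    a = _tp_matrix(profiles_a)
    b = _tp_matrix(profiles_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    pvals = np.ones(N_WINDOWS)
    for w in range(N_WINDOWS):
        if np.all(a[:, w] == a[0, w]) and np.all(b[:, w] == a[0, w]):
            continue  # identical constant samples: no evidence
        pvals[w] = stats.mannwhitneyu(a[:, w], b[:, w],
                                      alternative=alternative).pvalue
    return {"window_starts": WINDOW_STARTS.copy(), "p_raw": pvals,
            "p_adjusted": stats.false_discovery_control(pvals)}


def cohort_profiles(model: AgentModel, thermoscape: ThermoscapeConfig, n: int,
                    null_window_s: np.ndarray, duration_s: float = 1200.0,
                    burnin_s: float = 120.0, seed=None) -> np.ndarray:
    """Simulate a cohort and score each agent's Tp profile against a null.

    Returns an (n, 71) matrix of per-agent Tp values; the workhorse behind
    the ABC fit, so it stays trajectory-free.
    """
    occ = abm.cohort_occupancy(model, thermoscape, n, duration_s=duration_s,
                               burnin_s=burnin_s, seed=seed)
    win = fine_to_window_occupancy(occ)
    exp = np.asarray(null_window_s, dtype=float)
    total = win + exp
    return np.where(total > 0, (win - exp) / np.where(total > 0, total, 1.0), 0.0)
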