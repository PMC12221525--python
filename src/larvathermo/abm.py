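"""Cross-inhibition thermotaxis agent-based model.

A larva senses temperature through two antagonistic avoidance circuits,
cool-avoidance and warm-avoidance, whose influence on behaviour is linearly
weighted with temperature around a homeostatic set point ``T_hsp``:

    w_cool = 0.5 + s * (T - T_hsp)
    w_warm = 0.5 + s * (T_hsp - T)

with slope ``s >= 0`` (sensitivity) and both weights clamped to [0, 1].  The
two weights always cross at 0.5 at ``T = T_hsp``, where the circuits balance
and movement is unbiased — the origin of the set-point preference.  The net
gain is their difference,

    G(T) = w_warm - w_cool = 2 s (T_hsp - T),

and the behaviour-modulating perception signal ``A_O`` integrates gain-scaled
relative temperature change (a Weber-Fechner form) with first-order decay:

    dA_O/dt = -c_O * A_O + G(T) * (dT/dt) / T.

Locomotion is a run-and-turn walk: agents crawl at constant speed and turn
stochastically, with the turn probability per step modulated by the
perception signal,

    p_turn = clip(dt * r0 * (1 - k * A_O), 0, 1),

so that negative ``A_O`` (moving into an aversive context: away from the set
point) raises turning, and positive ``A_O`` (approaching the set point)
lengthens runs.  ``k`` is a dimensionless coupling that converts the small
Weber-fraction signal into turn-rate modulation; see ``TURN_GAIN_DEFAULT``.
With ``s = 0`` the gain vanishes at every temperature and the agent is
temperature-blind — the null model used throughout the preference analysis.

The arena carries a parametric "thermoscape": a uniform plate temperature
plus peak-normalized Gaussian bumps at the four Peltier positions (two cold
at 14 °C, two warm at 28 °C on a 21 °C plate, Gaussian spread 0.1 in
normalized arena units), reproducing the patchy 17-25 °C gradient of the
physical assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks import Track

# --- occupancy binning -----------------------------------------------------
# Fine occupancy histogram: 0.1 degC bins spanning every temperature the
# thermoscape can produce, so total occupancy is conserved exactly.
BIN_LO_C = 5.0
BIN_WIDTH_C = 0.1
N_BINS = 300  # covers [5, 35) degC

#: Default coupling from the perception signal A_O to turn-rate modulation.
#: A_O is a Weber fraction: |A_O| ~ |G| * |dT/dt| / T ~ 1e-4 on this arena at
#: the slopes of interest (s ~ 1e-3), so an order-1e4 coupling is needed for
#: the modulation k*A_O to reach order one.  The value is calibrated once so
#: that slopes spanning 0.0005-0.007 produce weak-to-strong thermotaxis.
TURN_GAIN_DEFAULT = 2.0e4


@dataclass(frozen=True)
class ThermoscapeConfig:
    """Parametric arena temperature field.

    ``sources`` are (x, y, source_C) triples in normalized arena coordinates
    (arena side = 1); each source adds a peak-normalized Gaussian bump so the
    field equals ``source_C`` exactly at the source centre and relaxes to
    ``plate_C`` far away.
    """
    arena_mm: float = 170.0
    plate_C: float = 21.0
    sources: tuple = (
        (0.25, 0.25, 14.0),
        (0.75, 0.75, 14.0),
        (0.75, 0.25, 28.0),
        (0.25, 0.75, 28.0),
    )
    spread: float = 0.1


def thermoscape_at(x_mm, y_mm, config: ThermoscapeConfig = ThermoscapeConfig()):
    """Temperature (degC) of the thermoscape at arena position (x, y) in mm.

    Vectorized over array inputs.  Positions outside the arena raise.
    """
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    L = config.arena_mm
    if np.any(x < 0) or np.any(x > L) or np.any(y < 0) or np.any(y > L):
        raise ValueError("position outside the arena")
    return _thermoscape_norm(x / L, y / L, config)


def _thermoscape_norm(u, v, config: ThermoscapeConfig):
    """Field at normalized coordinates (no bounds check; simulation hot path)."""
    T = np.full(np.broadcast(u, v).shape, config.plate_C, dtype=float)
    inv2s2 = 1.0 / (2.0 * config.spread ** 2)
    for (sx, sy, sc) in config.sources:
        d2 = (u - sx) ** 2 + (v - sy) ** 2
        T += (sc - config.plate_C) * np.exp(-d2 * inv2s2)
    return T


@dataclass(frozen=True)
class AgentModel:
    """Thermotaxis model parameters for one agent cohort.

    ``t_hsp_C`` and ``slope`` are the two fitted quantities; the remaining
    locomotor parameters are shared across species.  ``slope = 0`` gives a
    temperature-blind agent.
    """
    t_hsp_C: float = 21.0
    slope: float = 0.0        # 1/degC; 0 => temperature-blind
    c_o: float = 1.0          # perception decay rate, 1/s
    dt: float = 0.1           # integration step, s (matches 10 Hz tracking)
    speed_mm_s: float = 1.0
    base_turn_rate_hz: float = 0.3
    turn_gain: float = TURN_GAIN_DEFAULT
    turn_sigma_deg: float = 60.0
    body_length_mm: float = 4.0

    def __post_init__(self):
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class AgentState:
    """Instantaneous state of a single agent (scalar step API)."""
    position: np.ndarray            # (x, y) mm
    heading_rad: float
    a_o: float = 0.0
    t_prev_C: float | None = None


# ---------------------------------------------------------------------------
# Model primitives
# ---------------------------------------------------------------------------

def sensor_weights(T, s, t_hsp):
    """Cool- and warm-circuit weights at temperature T, clamped to [0, 1].

    Unclamped the two weights sum to 1 and cross at 0.5 at ``T = t_hsp``.
    """
    w_cool = np.clip(0.5 + s * (np.asarray(T, dtype=float) - t_hsp), 0.0, 1.0)
    w_warm = np.clip(0.5 + s * (t_hsp - np.asarray(T, dtype=float)), 0.0, 1.0)
    return w_cool, w_warm


def gain(T, s, t_hsp):
    """Net avoidance gain G(T) = w_warm - w_cool = 2 s (t_hsp - T) (unclamped form)."""
    return 2.0 * s * (t_hsp - np.asarray(T, dtype=float))


def update_perception(a_o, t_prev_C, t_curr_C, dt, c_o, s, t_hsp):
    """One forward-Euler step of the perception dynamics.

    A_O' = A_O + dt * (-c_O A_O + G(T) * (T - T_prev) / (dt * T)), with the
    relative temperature change evaluated against the current temperature in
    degC as printed in the model definition.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = gain(t_curr_C, s, t_hsp)
    tdot_over_t = (np.asarray(t_curr_C, dtype=float) - t_prev_C) / (dt * np.asarray(t_curr_C, dtype=float))
    return a_o + dt * (-c_o * np.asarray(a_o, dtype=float) + g * tdot_over_t)


# ---------------------------------------------------------------------------
# Vectorized simulation core
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Output of a batch simulation.

    ``occupancy`` is seconds per 0.1 degC fine bin per agent, accumulated
    after the burn-in; trajectories are recorded only when requested.
    """
    occupancy: np.ndarray                 # (n, N_BINS) seconds
    times: np.ndarray | None = None       # (nt,) s, burn-in removed
    positions: np.ndarray | None = None   # (n, nt, 2) mm
    headings: np.ndarray | None = None    # (n, nt) rad
    temps: np.ndarray | None = None       # (n, nt) degC


def _reflect(pos, L):
    """Reflective arena walls; also returns a mask of agents that bounced."""
    bounced_x = (pos[:, 0] < 0) | (pos[:, 0] > L)
    bounced_y = (pos[:, 1] < 0) | (pos[:, 1] > L)
    pos[:, 0] = np.abs(pos[:, 0])
    pos[:, 0] = L - np.abs(L - pos[:, 0])
    pos[:, 1] = np.abs(pos[:, 1])
    pos[:, 1] = L - np.abs(L - pos[:, 1])
    return bounced_x, bounced_y


def simulate_batch(n: int, thsp, slope, thermoscape: ThermoscapeConfig,
                   *, speed_mm_s=1.0, base_turn_rate_hz=0.3,
                   turn_gain=TURN_GAIN_DEFAULT, turn_sigma_deg=60.0,
                   c_o=1.0, dt=0.1, duration_s=1200.0, burnin_s=120.0,
                   start_frac=0.33, rng=None, record=False) -> SimResult:
    """Simulate ``n`` agents with (possibly per-agent) parameters.

    ``thsp`` and ``slope`` may be scalars or length-``n`` arrays, which lets a
    whole parameter grid run as one batch.  Agents start uniformly inside the
    centred square of side ``start_frac`` x arena side with uniform random
    heading and ``A_O = 0``.  Occupancy is accumulated for every step with
    ``t >= burnin_s``.
    """
    if n < 1:
        raise ValueError("need at least one agent")
    rng = np.random.default_rng(rng)
    L = thermoscape.arena_mm
    thsp = np.broadcast_to(np.asarray(thsp, dtype=float), (n,))
    slope = np.broadcast_to(np.asarray(slope, dtype=float), (n,))
    sigma = np.deg2rad(turn_sigma_deg)

    # frames 0 .. nt-1 at times i*dt, mirroring 10 Hz tracking of a
    # duration_s assay; frames with t >= burnin_s count toward occupancy,
    # so total retained time is exactly duration_s - burnin_s per agent.
    nt = int(round(duration_s / dt))
    if nt < 1:
        raise ValueError("duration shorter than one step")
    burnin_steps = int(round(burnin_s / dt))
    if burnin_steps >= nt:
        raise ValueError("burn-in consumes the whole simulation")

    lo = 0.5 * L * (1.0 - start_frac)
    pos = lo + rng.random((n, 2)) * (L * start_frac)
    theta = rng.uniform(-np.pi, np.pi, size=n)
    a_o = np.zeros(n)
    T = _thermoscape_norm(pos[:, 0] / L, pos[:, 1] / L, thermoscape)

    occupancy = np.zeros((n, N_BINS))
    n_rec = nt - burnin_steps
    if record:
        rec_pos = np.empty((n, n_rec, 2), dtype=np.float32)
        rec_th = np.empty((n, n_rec), dtype=np.float32)
        rec_T = np.empty((n, n_rec), dtype=np.float32)
        rate = 1.0 / dt
        rec_times = (burnin_steps + np.arange(n_rec)) / rate
    step_mm = speed_mm_s * dt
    agent_idx = np.arange(n)
    two_k = 2.0 * slope

    def _tally(i):
        bins = np.clip(((T - BIN_LO_C) / BIN_WIDTH_C).astype(np.int64), 0, N_BINS - 1)
        np.add.at(occupancy, (agent_idx, bins), dt)
        if record:
            j = i - burnin_steps
            rec_pos[:, j] = pos
            rec_th[:, j] = theta
            rec_T[:, j] = T

    if burnin_steps == 0:
        _tally(0)

    for i in range(1, nt):
        pos[:, 0] += step_mm * np.cos(theta)
        pos[:, 1] += step_mm * np.sin(theta)
        bx, by = _reflect(pos, L)
        theta = np.where(bx, np.pi - theta, theta)
        theta = np.where(by, -theta, theta)

        T_prev = T
        T = _thermoscape_norm(pos[:, 0] / L, pos[:, 1] / L, thermoscape)
        g = two_k * (thsp - T)
        # forward Euler of dA/dt = -c_o A + G * (dT/dt)/T; the dt in the
        # Weber term cancels against the Euler step
        a_o += dt * (-c_o * a_o) + g * (T - T_prev) / T

        p_turn = np.clip(dt * base_turn_rate_hz * (1.0 - turn_gain * a_o), 0.0, 1.0)
        turning = rng.random(n) < p_turn
        dtheta = rng.normal(0.0, sigma, size=n)
        theta = np.where(turning, theta + dtheta, theta)
        theta = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi

        if i >= burnin_steps:
            _tally(i)

    if record:
        return SimResult(occupancy=occupancy, times=rec_times, positions=rec_pos,
                         headings=rec_th, temps=rec_T)
    return SimResult(occupancy=occupancy)


def step_agent(state: AgentState, model: AgentModel,
               thermoscape: ThermoscapeConfig, rng) -> AgentState:
    """Advance a single agent by one time step (scalar convenience API).

    Order of operations matches the batch simulator: move along the current
    heading, reflect at walls, sense the new temperature, update the
    perception signal, then decide stochastically whether to turn.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    L = thermoscape.arena_mm
    dt = model.dt
    pos = np.array(state.position, dtype=float).reshape(1, 2)
    theta = float(state.heading_rad)
    pos[0, 0] += model.speed_mm_s * dt * np.cos(theta)
    pos[0, 1] += model.speed_mm_s * dt * np.sin(theta)
    bx, by = _reflect(pos, L)
    if bx[0]:
        theta = np.pi - theta
    if by[0]:
        theta = -theta
    T = float(_thermoscape_norm(pos[0, 0] / L, pos[0, 1] / L, thermoscape))
    t_prev = state.t_prev_C if state.t_prev_C is not None else T
    a_o = float(update_perception(state.a_o, t_prev, T, dt, model.c_o,
                                  model.slope, model.t_hsp_C))
    p_turn = float(np.clip(dt * model.base_turn_rate_hz * (1.0 - model.turn_gain * a_o),
                           0.0, 1.0))
    if rng.random() < p_turn:
        theta += rng.normal(0.0, np.deg2rad(model.turn_sigma_deg))
    theta = float(np.mod(theta + np.pi, 2.0 * np.pi) - np.pi)
    return AgentState(position=pos[0], heading_rad=theta, a_o=a_o, t_prev_C=T)


def simulate_cohort(model: AgentModel, thermoscape: ThermoscapeConfig, n: int,
                    duration_s: float = 1200.0, burnin_s: float = 120.0,
                    seed=None, id_offset: int = 0) -> list:
    """Simulate ``n`` independent agents and return them as Track objects.

    Burn-in frames are dropped; head positions are placed half a body length
    ahead of the centroid along the heading; the body-bend channel is zero
    (agents are point-like; the synthetic-data generator overlays bend
    excursions at turn events when emulating tracker output).  Each track
    carries the temperature it sensed, taken analytically from the
    thermoscape.
    """
    res = simulate_batch(
        n, model.t_hsp_C, model.slope, thermoscape,
        speed_mm_s=model.speed_mm_s, base_turn_rate_hz=model.base_turn_rate_hz,
        turn_gain=model.turn_gain, turn_sigma_deg=model.turn_sigma_deg,
        c_o=model.c_o, dt=model.dt, duration_s=duration_s, burnin_s=burnin_s,
        rng=seed, record=True)
    half = 0.5 * model.body_length_mm
    out = []
    for a in range(n):
        pos = res.positions[a].astype(float)
        th = res.headings[a].astype(float)
        head = pos + half * np.column_stack([np.cos(th), np.sin(th)])
        # clamp heads protruding past a wall the centroid reflected off
        np.clip(head, 0.0, thermoscape.arena_mm, out=head)
        tr = Track(id=id_offset + a, t=res.times.copy(), centroid=pos, head=head,
                   bend_deg=np.zeros(res.times.size))
        tr.temp_C = res.temps[a].astype(float)
        out.append(tr)
    return out


def cohort_occupancy(model: AgentModel, thermoscape: ThermoscapeConfig, n: int,
                     duration_s: float = 1200.0, burnin_s: float = 120.0,
                     seed=None) -> np.ndarray:
    """Per-agent fine-bin occupancy (n, N_BINS) in seconds, trajectory-free."""
    res = simulate_batch(
        n, model.t_hsp_C, model.slope, thermoscape,
        speed_mm_s=model.speed_mm_s, base_turn_rate_hz=model.base_turn_rate_hz,
        turn_gain=model.turn_gain, turn_sigma_deg=model.turn_sigma_deg,
        c_o=model.c_o, dt=model.dt, duration_s=duration_s, burnin_s=burnin_s,
        rng=seed, record=False)
    return res.occupancy
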