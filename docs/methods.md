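# Methods

This note records the models, parameter choices and numerical conventions
behind `larvathermo`, and what the synthetic-data tests do and do not
establish about real assays.

## Assay geometry and conventions

The arena is a 170 × 170 mm square; coordinates have the origin at the
top-left corner, x rightward, y downward. Internally everything is in mm
and seconds; tracker files store pixels at a default scale of 4 px/mm (the
scale is configurable — physical thresholds such as the non-mover limits
are held in mm and converted once at file I/O). Time is derived from
integer frame numbers at 10 Hz, so file round-trips are bit-exact. Thermal
frames arrive at 3 frames/min; the default synthetic camera resolution is
160 × 120 (rows × cols swapped to 120 × 160 to keep rows = y), a
conventional long-wave-infrared sensor format — the analysis only requires
that the grid covers the arena. The first 120 s of every assay or
simulation is discarded as acclimatisation burn-in.

## Thermal preprocessing and quality control

Single-frame camera spikes are repaired by temporal interpolation: a pixel
sample differing from both temporal neighbours by more than 3 °C is
replaced by their mean; first/last frames substitute their single
neighbour. The pass iterates to a fixed point (capped at 10 passes, with a
warning if unconverged) so the operation is idempotent; isolated spikes —
the realistic case — converge in one pass. The 3 °C jump threshold reuses
the QC fluctuation bound since no separate value is motivated.

Gradient QC enforces three rules on the smoothed series: ≥ 5 % of pixels
below 17.5 °C in more than 90 % of frames, the same above 24.5 °C, and no
pixel spanning more than 3 °C over the run. The two 5 % rules are applied
separately to the cold and warm tails; the fluctuation rule is checked
after smoothing, so it measures gradient drift rather than camera
artefacts.

## Track cleaning

Filters run on raw tracks before joining: tracks shorter than 10 s are
dropped (strict "shorter than": a 10.0 s track is kept), and a track is a
non-mover only if it fails *both* movement criteria (cumulative path
≤ 0.5 mm *and* never straying more than 0.3 mm from its origin). The short
filter is not re-applied after joining.

Clash resolution keys on the tracker's collision signature — two tracks
ending abruptly on the same frame — and joins each ended track to the
reciprocally closest track starting afterwards, ranked lexicographically by
temporal gap then spatial gap, ties broken toward the smaller id.
Fragment joining runs three staged rounds with (distance, time, implied
speed) limits of (150 px, 22.5 s, 15 px/s), then (500 px, 75 s, 30 px/s),
then unrestricted; each round applies mutual-nearest joins iteratively
until exhaustion. Because time takes strict priority over distance, a
fragment of one larva starting inside another larva's tracking gap *can*
steal a join; the synthetic-fixture tests therefore quantify recovery as
sample-level identity purity (≥ 99 % under round-1-scale fragmentation)
rather than demanding perfection.

Temperature is assigned per sample from the thermal frame nearest in time
(ties to the earlier frame) at the pixel under the *head* position, since
larval thermosensors sit at the head tip; centroid lookup is available by
option. Out-of-grid positions clamp to the nearest edge pixel and are
flagged.

## Preference index and summaries

Preference uses 1 °C windows sliding in 0.1 °C steps with starts anchored
at 17.0, 17.1, …, 24.0 °C (71 windows spanning the 17–25 °C design range).
Internally all occupancy is first accumulated into 0.1 °C fine bins over
5–35 °C — wide enough to hold every temperature the thermoscape can
produce, so total time is conserved exactly — and rolled up into windows by
sliding sums.

The null model simulates randomly moving agents (uniform start in the
centred square one-third the arena side, uniform heading, constant speed,
Poisson turning at the cohort's mean rate, wrapped-normal heading changes
with σ = 60°, reflective walls) and takes the per-agent mean window
occupancy as the expectation. The cohort "turn rate" is defined as accepted
head sweeps per second. σ is not identified by a mean speed and turn rate
alone; 60° is a typical larval reorientation spread and is exposed in
configuration.

`Tp = (obs − exp)/(obs + exp)` per window; windows with `obs = exp = 0`
are set to 0 (no evidence) rather than −1, since unexplored windows would
otherwise bias whole profiles downward. The index retains a known
*negative* skew for individual larvae: a constantly moving larva leaves
most windows under-occupied relative to a 1000-agent average, so per-larva
profiles reach −1 often and +1 rarely. Consequently "a blind cohort scores
zero against a blind null" holds for the Tp of the cohort's *mean
occupancy* (tested to |Tp| < 0.05 per window at n = 2000), not for the mean
of per-agent Tp values, which sits visibly below zero in rarely visited
windows.

`Tp_opt` is the window start with the highest across-larvae mean Tp (ties
to the coolest window). `Tp_breadth` classifies windows with an exact
two-sided sign test on nonzero per-larva Tp values (H0: median 0) with
Benjamini–Hochberg correction across the 71 windows — BH being the standard
least-conservative choice where the correction method is otherwise
unspecified; significantly positive windows are strong preferences,
significantly negative ones aversive, and the breadth is the contiguous run
of non-aversive windows containing `Tp_opt`. Cross-cohort comparisons use
per-window Mann–Whitney U tests (Tp is bounded and non-normal), again
BH-corrected. Strains are pooled within species; labels can be retained on
profile tables for hierarchical re-analysis.

## Navigation metrics

Velocity is the centroid path length over a centred 3 s window divided by
the window's time span, stepped one frame at a time; edge windows are
truncated and flagged partial. Body-length normalisation uses twice the
median head–centroid distance. Tortuosity is `1 − net/accumulated`
per centred window, averaged over 2/5/10/20/30 s windows; windows with zero
accumulated path are excluded from the mean. Head sweeps are local maxima
of |body bend| above 30° that subsequently return below 10°, merged within
a 2 s buffer keeping the larger peak, and *accepted* only above 45°. The
signed tracker bend channel is reduced to magnitude (no left/right
asymmetry is analysed). Temperature zones are equal thirds of 17–25 °C
(boundaries 19.67 / 22.33 °C); a windowed metric belongs to the zone of its
central frame's assigned temperature. Zone contrasts draw 1000 independent
uniformly resampled pairs per contrast and compare difference distributions
with Welch t-tests; trends are per-group OLS with t-based slope CIs.

## Agent-based model

The thermoscape is the plate temperature (21 °C) plus peak-normalised
Gaussian bumps (spread 0.1 in arena-normalised units) at the four Peltier
positions — cold 14 °C on one diagonal, warm 28 °C on the other. Peak
normalisation (field equals the source temperature at its centre) is forced
by pinning both the plate and source temperatures; an unnormalised density
could not reach 14 °C at a cold source.

Sensor weights, gain and perception follow the linear symmetric
cross-inhibition form given above, integrated by forward Euler at
dt = 0.1 s (matching the 10 Hz tracking). The Weber term divides the
temperature change by the current temperature in °C as the model is
printed; using Kelvin would only rescale the slope grid by ~270/21 and is
absorbed by the turn-gain calibration below. The locomotor is a minimal
run-and-turn walk: constant crawl speed (default 1 mm/s, a typical
third-instar speed), turning events with per-step probability

    p = clip(dt · r₀ · (1 − k·A_O), 0, 1),   r₀ = 0.3 Hz default,

heading changes from a wrapped normal (σ = 60°), reflective walls. Negative
`A_O` (moving into aversive context) raises turning; positive suppresses
it. `k` converts the perception signal into turn-rate modulation. Because
`A_O` is a Weber fraction of order `|G|·|dT/dt|/T ≈ 1e−4` on this arena at
slopes of order 1e−3, an order-1e4 coupling is required for the modulation
to reach order one; the default `k = 2e4` was calibrated once so that the
fitting grid's slope range 0.0005–0.007 spans weak to strong thermotaxis
(occupancy concentration around the set point strictly increasing in
slope, and a cohort's self-acceptance under the ABC distance threshold
around 0.8). With slope 0 the gain vanishes identically and the agent is
temperature-blind — the shared null cohort. Agents are simulated as one
vectorised batch with per-agent parameters, so an entire parameter grid
runs in a single pass and results are independent of cell order.

## ABC fitting

Each simulated agent's Tp profile (against a common 2000-agent blind null)
is compared to the species' mean profile by Euclidean distance over the
full 71-window vector, accepting at ≤ 1.75; this vector length is recorded
in the output so the threshold can be rescaled as √(m/71)·1.75 for other
grids. The published grids are set points 17–25 °C (step 0.5) with slopes
0.0025–0.05 (step 0.0025, 500 agents/cell) in round 1 and 0.0005–0.007
(step 0.0005, 1000 agents/cell) in round 2. The best fit is the
highest-acceptance cell (ties to smaller slope, then cooler set point); the
95 % credible region is the smallest set of highest-acceptance cells
holding 95 % of total acceptance mass (an HPD-style reading of "the 95th
percentile of the 2D distribution"), which always contains the best fit.
Posterior predictive checks simulate 1000 agents from the best fit, take
each agent's own `Tp_opt`, and test `D = |obs − mean(sim)|` by pooling and
permuting 10 000 times with the first pooled element re-designated as the
observation; p is reported with the add-one Monte Carlo estimator so it is
never exactly zero. Note the permutation floor is ≈ 1/(n_sim + 1), not
1/n_perm: only permutations placing an extreme observation first can reach
the original statistic.

Acceptance-script problem sizes — 300-agent target cohorts, 100 agents per
grid cell over three slopes — are scaled-down versions of the published
design chosen to keep a full recovery experiment under a minute; recovery
of the generating set point is exact at this scale across seeds.

## Phylogenetics

Under Brownian motion with a flat root prior, node states are jointly
Gaussian with precision proportional to the tree's graph Laplacian weighted
by inverse branch lengths. ML ancestral states solve the internal-block
linear system conditioning on tips — algebraically identical to the
classic re-rooting GLS construction (verified against it to 1e−8 in tests)
— with conditional variances scaled by the ML rate. Zero-length branches
are regularised to 1e−12 Myr, effectively fusing their endpoints. Lineage
shifts are reported as tip value minus the parent-node estimate — the
quantity species-level results quote — rather than a formal
shift-regression coefficient; the two agree in sign and approximate
magnitude but not exactly. The phylogenetically corrected ANOVA takes the
observed one-way F and a null from traits simulated under BM on the tree
(rate by REML by default; ML by flag), with the add-one Monte Carlo
p-value; its type-I rate is verified at ~5 % on an 8-tip balanced tree.

## Synthetic data: what it does and does not show

The generator reproduces the *structure* of real assays — geometry, frame
rates, gradient shape, burn-in, tracker failure modes (fragmentation gaps
of 2–15 s, same-frame clash terminations with id reassignment, sub-threshold
non-movers jittering ~0.4 mm, single-pixel thermal spikes of +8–15 °C) —
with locomotion from the agent model itself. Clash events are injected by
sampling random track pairs and times at the configured per-track rate
(physical proximity triggers are too rare among a few dozen independent
agents to exercise the joiner). Passing tests therefore demonstrate that
the pipeline recovers known ground truth under these degradations; they do
not validate the agent model against real larval kinematics (no crawl-bend
coupling, peristalsis, speed modulation, or larva–larva interaction), nor
the preference statistics against biological variability between larvae,
which synthetic cohorts lack. Ground-truth parameter recovery by ABC shows
identifiability of the set point under the model's own data-generating
process — slope remains weakly identified, mirroring the overlapping slope
posteriors of the original analysis.

## Numerical conventions

- Occupancy fine bins: 0.1 °C over [5, 35) °C; bin index by floor division;
  window rollup by sliding sums (exact, since window edges align with bin
  edges).
- Nearest-in-time frame ties resolve to the earlier frame; nearest-pixel
  lookup clamps out-of-grid positions and flags them.
- Mutual-nearest joining ranks by (Δt, Δd, id); speed limits are strict
  (`<`), distance/time limits inclusive (`≤`).
- All randomness flows through `numpy.random.default_rng` seeds; derived
  seeds stay below 2³¹. Identical seed + configuration reproduces outputs
  bit-for-bit.
- `argmax` ties (Tp_opt, best fit) resolve toward cooler temperature /
  smaller slope deterministically.
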