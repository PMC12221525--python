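# larvathermo

Analysis and modelling toolkit for larval thermotaxis assays on patchy
thermal-gradient arenas. It is written for behavioural neuroethologists who
track *Drosophila* (or other) larvae exploring a 17 × 17 cm arena holding a
17–25 °C gradient, and who want to go from raw tracker output to
species-level temperature-preference parameters:

- **Thermal-camera QC** — single-frame spike repair, gradient-shape quality
  control, burn-in removal.
- **Track cleaning** — duration and non-mover filters, clash (identity-loss)
  resolution, staged rejoining of fragmented tracks, per-frame temperature
  assignment.
- **Temperature preference** — an electivity index per 1 °C window against a
  simulated random-movement null, with `Tp_opt` / `Tp_breadth` summaries and
  sign-test / rank-test statistics.
- **Navigation metrics** — windowed velocity, multi-scale tortuosity,
  head-sweep detection, temperature-zone contrasts and linear trends.
- **Agent-based model** — a cross-inhibition thermotaxis simulator whose
  turning is biased by a Weber–Fechner perception signal.
- **ABC fitting** — rejection-sampling estimation of each species'
  homeostatic set point and sensitivity slope, with credible regions and
  posterior predictive checks.
- **Phylogenetics** — Brownian-motion ancestral states, lineage shifts, and
  a simulation-based phylogenetically corrected ANOVA on a dated tree.

A synthetic-data generator (`larvathermo.synth`) emulates complete assays —
thermal frames with camera spikes, 10 Hz tracks with fragmentation, clashes
and non-movers — with known ground truth, so the entire pipeline is testable
without any raw video.

## The model in brief

Temperature preference is scored per 1 °C window *w* as an electivity index

    Tp(w) = (t_obs(w) − t_null(w)) / (t_obs(w) + t_null(w)) ∈ [−1, 1],

where `t_null` is the expected residence time of randomly moving agents on
the same gradient. `Tp_opt` is the window with the highest mean Tp across
larvae.

The simulator assigns each larva two antagonistic avoidance circuits with
temperature-dependent weights

    w_cool = 0.5 + s (T − T_hsp),   w_warm = 0.5 + s (T_hsp − T),

which balance at the homeostatic set point `T_hsp`. Their difference is the
gain `G(T) = 2 s (T_hsp − T)`, and the behaviour-modulating signal `A_O`
integrates

    dA_O/dt = −c_O A_O + G(T) · (dT/dt) / T,

raising the turn rate when the larva moves away from the set point and
suppressing it when approaching — a biased run-and-turn walk that
concentrates agents around `T_hsp`. Fitting simulates cohorts over a
(`T_hsp`, `s`) grid and accepts agents whose Tp profile lies within
Euclidean distance 1.75 of the species' mean profile; the acceptance-rate
surface maps the posterior.

## Worked example

Recover a known set point from a synthetic cohort:

```python
import numpy as np
from larvathermo import abcfit, preference
from larvathermo.abm import AgentModel, ThermoscapeConfig

scape = ThermoscapeConfig()                      # 21 °C plate, 14/28 °C sources
null = abcfit.blind_null_occupancy(scape, n=2000, seed=11)

target = AgentModel(t_hsp_C=19.0, slope=0.003)   # "species" to recover
tp = preference.cohort_profiles(target, scape, 300, null, seed=42)
emp = tp.mean(axis=0)

grid = abcfit.fit_grid(emp, null, n_agents=100,
                       slope_values=np.array([0.001, 0.003, 0.005]), seed=7)
print("best fit:", grid.best_fit)
print("Tp_opt of cohort:", preference.tp_opt(tp))
```

Output:

```
best fit: (19.0, 0.003)
Tp_opt of cohort: (18.6, 0.4829194118799586)
```

The fit recovers the generating set point exactly (grid step 0.5 °C), and
the cohort's `Tp_opt` window of 18.6 °C (mean index 0.48) sits just below
it — `Tp_opt` names the *start* of the best 1 °C window, and a slight
cool-side skew is expected because the index saturates at −1 in rarely
visited warm windows.

The same stages are scriptable from the shell:

```bash
larvathermo synth --config cfg.yaml --out assay/ --seed 5
larvathermo qc --frames assay/thermal --report qc.json
larvathermo tracks --in assay/raw_tracks.csv --frames assay/thermal \
    --out clean.csv --audit joins.json
larvathermo fit --profile species_mean.csv --grid round2 --out fit --seed 1
```

## Layout

```
src/larvathermo/   synth, thermalqc, tracks, preference, navigation,
                   abm, abcfit, phylo, cli
tests/             unit + property + end-to-end acceptance tests
docs/methods.md    modelling and statistical choices in detail
```
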