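# biofilm-flowcell

Quantification of bacterial biofilm formation and dispersal kinetics from
3-D confocal time-lapse imaging in a hyperbolic flow cell.

Microfluidic flow cells let biofilms (here, GFP-tagged *Pseudomonas
putida*) develop under defined flow while a confocal microscope revisits
dozens of positions every few minutes. A channel whose width expands
hyperbolically produces a *linearly decreasing* centerline velocity, so a
single device exposes attached bacteria to a threefold range of flow
speeds. This package provides, for users of such devices:

- **Channel design and flow verification** (`flow_model`): the width
  profile `w(x) = Q / (h v(x))` that yields a linear centerline velocity
  `v(x)` at constant flux, verified by an independent depth-averaged
  (Hele-Shaw) 2-D finite-volume solve with cut-cell walls.
- **Synthetic experiment generator** (`synthetic`): ground-truthed
  confocal time-lapse stacks — clusters attach, grow exponentially
  (`V(t) = V0 e^{gt}`), shed single cells, and disperse downstream-first
  with a fixed upstream propagation delay; rendered with PSF blur,
  Poisson photon noise and Gaussian read noise on an 8-bit scale.
- **Segmentation** (`segmentation`): absolute intensity threshold
  (default 10) + 3-D connected components (26-neighbourhood) + minimum
  object size (3 voxels of 0.42 × 0.42 × 0.78 µm).
- **Quantification** (`quantification`): per-window totals
  `V_pn = Σ_i V_pni`, normalisation `Vnorm_pn = V_pn / V_pn_a` at the 2-h
  reference, initial cluster counts `N_ap`, ascending size distributions,
  and equivalent sphere diameters `D = (6V/π)^{1/3}`.
- **Kinetics** (`kinetics`): OLS fit of `ln V_pn` vs `t` up to the
  biovolume peak (growth rate `g_p`, doubling time `t_d = ln2/g_p`),
  dispersal-onset detection (first decrease after the highest peak of
  `Vnorm`), per-x-location aggregation (mean ± sample SD over replicate
  areas a–c), upstream–downstream propagation delay, and between-run
  reproducibility tables.
- **Pipeline** (`pipeline`, `experiments`, CLI `biofilm-flowcell`):
  simulate → segment → quantify → kinetics with plain CSV/JSON
  intermediates, resumable stages, and deterministic outputs per seed.

## Worked example

```python
import numpy as np
from biofilm_flowcell import (
    design_width_profile, solve_depth_averaged, centerline_linearity,
    SyntheticParams, analyze_synthetic, propagation_stat,
)
from biofilm_flowcell.synthetic import ImagingLayout

# 1. verify the channel design
geom = design_width_profile(q_per_inlet=0.1, velocity_ratio=3.0)
field = solve_depth_averaged(geom, grid_resolution=0.05)
ratio = field.centerline_speed_at(geom.x_start) / field.centerline_speed_at(geom.x_end)
print(f"centerline ratio {ratio:.3f}, R^2 {centerline_linearity(field)[2]:.5f}")
# -> centerline ratio 2.861, R^2 0.99991

# 2. run the analysis chain on a synthetic low-flow experiment
layout = ImagingLayout.reduced(flow_rate=0.1, n_cycles=45)
params = SyntheticParams.reduced_window_defaults(rng_seed=0)
series, result, truth = analyze_synthetic(params, layout)
print(f"position 12 onset {result.onsets['12a'].t_disp:.0f} min, "
      f"propagation delay {propagation_stat(result):.0f} min, "
      f"median doubling time {np.median([f.doubling_time for f in result.fits.values()]):.1f} min")
# -> position 12 onset 380 min, propagation delay 60 min, median doubling time 67.0 min
```

The solver confirms the designed threefold, highly linear velocity drop
across the expansion; the pipeline detects dispersal first at the
downstream position 12 (true onset 370 min, detected at the next imaging
cycle), finds it propagating upstream over about an hour, and recovers
the generator's 65-min doubling time to a few percent.

The numbered scripts under `analysis/` run these studies end to end and
write their tables under `results/`:

```sh
python analysis/01_flow_field.py
python analysis/02_simulate_and_quantify.py
python analysis/03_parameter_recovery.py
python analysis/04_reproducibility.py
```

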