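# Methods

## The measurement problem

A hyperbolic flow cell exposes a developing biofilm to a linear gradient
of flow speed while a confocal microscope acquires z-stacks at 36
positions (12 axial locations × 3 replicate areas) every 10 minutes.
The analysis task is to turn those stacks into per-position time series
of biovolume, fit growth kinetics, detect when dispersal begins at each
position, and quantify how dispersal propagates and how reproducible its
timing is. This package implements that chain plus the two supporting
models it is validated against: a depth-averaged solver for the channel
flow and a ground-truthed generator of synthetic experiments.

## Channel flow model

**Design.** At constant volumetric flux `Q` through a channel of depth
`h`, mass conservation gives a depth-averaged speed `v(x) = Q / (h w(x))`.
Prescribing a linear `v(x)` that falls threefold between the expansion
ends (`x = −1.49` to `−8.99` mm) yields a width profile that is the
reciprocal of a linear function — a hyperbola — with
`w(x_end) = 3 w(x_start)`. Absolute widths of the physical device are
proprietary, so the start width is a configuration parameter (default
1.0 mm); only ratios and linearity are asserted. The channel depth is
0.98 mm and flow rates are 0.1–4.0 ml/h per inlet (two inlets).

**Verification.** The shallow, low-Reynolds channel admits a
depth-averaged (Hele-Shaw) description: the in-plane velocity is a
potential flow, `u = −∇φ`, `∇·u = 0`, with no flux through the walls.
The solver discretises this by finite volumes on a regular Cartesian
grid (default 50 µm) with *cut-cell* walls: each face carries the open
fraction of its length, so the discrete geometry varies smoothly with
the wall position. Influx is prescribed on the upstream boundary,
constant potential on the outlet. Discrete flux conservation is exact
(≈1e-13 relative), and halving the grid spacing changes centerline
speeds by <1%, so a 1% flux tolerance and a 5% agreement band against
the 1-D formula are asserted, not assumed. The two-inlet junction is
modelled as a single merged inflow; the segments outside the expansion
are straight.

**Exit-zone shape.** The physical transition from the expansion to the
outlet zone is not published. A slope discontinuity exactly at the
downstream measurement station would be a modelling artifact — a
machined channel has no sharp corner there, and a corner locally inflates
the depth-averaged centerline speed by ~9%. The design therefore blends
the hyperbola's end slope quadratically to zero over 2.5 mm downstream of
the expansion (the result saturates for blend lengths of 2–3 mm). With
this geometry the solved centerline profile is linear to R² ≈ 0.9999 and
the station speed ratio is ≈ 2.86, within 5% of the designed 3.

**Limits of the model.** A depth-averaged potential flow has no in-plane
viscous boundary layers; near the wide, more steeply diverging end the
centerline speed genuinely exceeds `Q/(h w)` by a few percent (radial
flow concentrates speed on the chord's nearest point). The paper-grade
3-D laminar simulation resolves the full duct profile; agreement is
asserted only at the 5% level and only for the centerline.

## Synthetic experiment generator

The generator reproduces the statistical structure of the experiments,
not their optics in detail. Per imaging window:

- **Attachment.** `N ~ Poisson(mean_initial_clusters)` clusters appear at
  t = 0 with volumes uniform in [2, 25] µm³ (single cells of ~2 µm³ up to
  small clusters below 25 µm³), placed uniformly with a soft minimum
  spacing (12 µm) inside an 8 µm edge margin.
- **Growth.** Each cluster grows clonally, `V(t) = V0 e^{gt}`, with a
  default doubling time of 65 min (within the observed 47–71 min band;
  configurable per x-location).
- **Shedding.** Each cycle before dispersal, every cluster sheds a
  single cell with probability 0.05; the new cell attaches a few µm
  downstream (the +x direction, toward position 12) and grows like its
  parent.
- **Dispersal.** Position 12 starts dispersing at 370 min; the onset
  propagates upstream at 63/11 min per x-location step, so position 1
  follows 63 min later and onset times are non-increasing from position
  1 to 12. After onset a cluster's volume decays exponentially with a
  20-min half-life (the true decay shape is not quantified anywhere; the
  half-life is configurable).
- **Rendering.** Clusters are spheres resting on the substratum (the
  equivalent-diameter metric itself assumes sphericity; merging arises
  implicitly from overlap). Voxels inside a sphere take the cell
  intensity over a uniform background, the stack is blurred with an
  anisotropic Gaussian PSF (σ = 0.2 µm in-plane, 0.4 µm axial),
  Poisson-sampled, read noise (σ = 2) is added, and the result is
  clipped to 8 bits.

**Intensity scale.** The canonical absolute segmentation threshold of 10
is meaningful only on a fixed 8-bit scale. The default cell intensity is
20 with background 2, so the threshold sits at the half-maximum contour
of a blurred edge: thresholding a symmetrically blurred step at half its
height recovers the unblurred boundary, which keeps segmented radii —
and therefore fitted growth rates — unbiased by the PSF. The invariant
`cell_intensity > threshold + 3·read-noise σ` keeps cells detectable.

**Geometry margins.** The ground truth asserts exact exponential volumes,
so the rendered scene must not lose volume to artifacts that the truth
does not model: the edge margin keeps spheres inside the window, the
minimum spacing defers overlap, and at the default sizes only the very
largest clusters graze the top of the 12-slice stack (a ≤ few-% clipped
cap at the final cycles). Real windows are wider (506 × 506 px vs the
128-px study windows) and their boundary clipping is part of the
measurement, not an error.

**Reduced study geometry.** Simulation studies use 128 × 128 × 12
windows at the experimental voxel size (0.42/0.78 µm), 12 x-locations
with one area each, and 45 ten-minute cycles starting at t = 40 min —
enough to observe the upstream end of the dispersal wave (433 min) with
margin — seeded with a mean of 8 clusters per window so windows are
essentially never empty while overlap stays rare. Full-size layouts
(36 positions, per-flow-rate z-slice and cycle counts: 12/47, 14/62,
14/60, 16/73) are available for file-based runs.

**What the generator does not emulate** (so what passing tests do not
show): rod-shaped cell morphology, EPS matrix fluorescence, the surge of
fragment clusters during dispersal break-up, sloughing at the highest
flow rate, photobleaching, drift or stage error. Recovery results
therefore validate the *analysis chain*, not the microscope.

## Segmentation

Foreground is `intensity ≥ threshold` (inclusive reading of an absolute
threshold of 10); clusters are maximal connected components under a
configurable 6/18/26 neighbourhood (default 26 — surface-based
segmentation merges diagonal contacts); components under 3 voxels are
discarded. Biovolume is voxel count × 0.137592 µm³ (0.42·0.42·0.78).
Border-touching clusters are kept. The labelling is validated against a
brute-force BFS flood fill on random grids for both 6- and
26-connectivity, and monotonicity (in threshold and minimum size) and
translation equivariance are property-tested.

## Quantification and kinetics

- `V_pn = Σ_i V_pni` (exact, additive); normalisation uses the cycle
  nearest t = 2 h (ties → earlier cycle; the reference is defined by
  time, not index). A zero reference biovolume raises a flagged error
  rather than silently dropping the position.
- Growth: OLS on `ln V_pn` vs `t` from the first cycle to the earliest
  global biovolume maximum, excluding zero-biovolume cycles (an offset
  would bias the slope; exclusion is exact for exponential input).
  Fewer than three positive cycles is an error; a non-positive slope is
  flagged non-growing, not raised. `t_d = ln 2 / g`.
- Dispersal onset: the earliest cycle attaining the global maximum of
  `Vnorm` is the peak; the onset is the first later cycle strictly below
  the maximum. A never-decreasing series yields a no-onset result. The
  global (not local) maximum ensures a transient dip before the true
  peak is not an onset. Detection is therefore quantised to the cycle
  after the true onset: its error is below one cycle interval except
  when the onset falls within ~2 min after an imaging cycle (the
  straddling cycle then still shows net growth), which at the default
  kinetics affects about 1 position in 12.
- Aggregation: mean ± sample SD (n−1) over areas a–c; a singleton yields
  an undefined (NaN) SD. Propagation: `Δt = t̄_disp(pos 1) − t̄_disp(pos 12)`,
  positive under downstream-first dispersal. Reproducibility rows report
  each run's mean ± SD, SD as % of the mean, and the absolute
  between-run difference `Δ₁₂` with its % of run 1 — times rounded to
  whole minutes and percentages to one decimal at the reporting layer
  only; full precision is kept internally.

## Numerical and design choices

- Connectivity, threshold inclusivity, the 2-h reference tie-break, the
  sample-SD convention and the absolute `Δ₁₂` are all open choices in the
  underlying protocol; the defaults above are fixed and configurable.
- The in-plane pixel count is `round(212.55/0.42) = 506`; the 0.03 µm
  window mismatch is accepted.
- The cycle→time map defaults to `t(n) = 40 + 10(n−1)` min, consistent
  with 47 cycles spanning 8 h 20 min at the lowest flow rate; inter-
  position distances default to even spacing. Both are configurable.
- All randomness flows from a single integer seed; per-position and
  per-cycle RNG streams make every stack byte-reproducible.

## Known limitations

- The flow solver is 2-D; it cannot report depth profiles, transients or
  solute transport, and its centerline agreement with a full 3-D duct
  simulation is only asserted at the 5% level.
- Segmented biovolume underestimates clusters thicker than the imaged
  z-range (as does the real acquisition).
- The dispersal model prescribes onset times rather than emerging from a
  mechanism; the propagation statistic validates detection, not biology.
- Published headline biology (e.g. the 2,388 µm³ largest cluster) is not
  reproducible without the original image data; such values are used
  only as inputs to closed-form metrics and reporting-layer statistics.
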