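"""Ground-truthed synthetic confocal time-lapse generator.

Emulates the statistical structure of biofilm time-lapse experiments in the
hyperbolic flow cell: bacteria attach in an imaging window as single cells
and small clusters, grow clonally and exponentially, occasionally shed
single cells that re-attach slightly downstream, and finally disperse —
starting at the downstream end of the channel (position 12) and propagating
upstream with a fixed per-position delay.

Clusters are rendered as spheres resting on the substratum (the equivalent-
diameter statistic used downstream itself assumes sphericity); acquisition
is emulated by an anisotropic Gaussian PSF blur, Poisson photon noise and
Gaussian read noise on an 8-bit intensity scale.

Every stack is deterministic for a fixed ``rng_seed``; the generator also
returns the exact ground truth (per-cycle true biovolumes, growth rate and
dispersal-onset time per position) so the analysis pipeline can be scored
against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter

# z-slice and cycle counts per flow rate (ml/h per inlet)
FLOW_RATE_TABLE: dict[float, tuple[int, int]] = {
    0.1: (12, 47),
    0.5: (14, 62),
    1.5: (14, 60),
    4.0: (16, 73),
}

AREAS = ("a", "b", "c")

#: canonical 8-bit absolute segmentation threshold the scale is designed for
INTENSITY_SCALE_THRESHOLD = 10.0


@dataclass(frozen=True)
class ImagingLayout:
    """Geometry and timing of the imaging experiment.

    36 positions = 12 x-locations (1 upstream ... 12 downstream, near the
    outlet) x 3 laterally offset areas (a/b/c).  Each window is a square of
    ``window_um`` on a side imaged as a z-stack of ``z_slices`` planes;
    complete imaging cycles repeat every ``cycle_interval_min``.
    """

    flow_rate: float = 0.1  # ml/h per inlet (label)
    window_um: float = 212.55
    voxel_xy: float = 0.42  # um
    voxel_z: float = 0.78  # um
    z_slices: int = 12
    n_cycles: int = 47
    cycle_interval_min: float = 10.0
    t_first_cycle_min: float = 40.0
    x_locations: tuple[int, ...] = tuple(range(1, 13))
    areas: tuple[str, ...] = AREAS

    @property
    def window_px(self) -> int:
        return int(round(self.window_um / self.voxel_xy))

    @property
    def cycle_times(self) -> np.ndarray:
        """Cycle times in minutes, t(n) = t_first + (n-1) * interval."""
        return self.t_first_cycle_min + np.arange(self.n_cycles) * self.cycle_interval_min

    @classmethod
    def for_flow_rate(cls, flow_rate: float, **overrides) -> "ImagingLayout":
        if flow_rate not in FLOW_RATE_TABLE:
            raise ValueError(
                f"unknown flow rate {flow_rate}; expected one of {sorted(FLOW_RATE_TABLE)}"
            )
        z, n = FLOW_RATE_TABLE[flow_rate]
        return cls(flow_rate=flow_rate, z_slices=z, n_cycles=n, **overrides)

    @classmethod
    def reduced(
        cls,
        flow_rate: float = 0.1,
        window_px: int = 128,
        z_slices: int = 12,
        n_cycles: int = 45,
        areas: tuple[str, ...] = ("a",),
    ) -> "ImagingLayout":
        """Smaller windows for fast simulation studies (same voxel grid)."""
        return cls(
            flow_rate=flow_rate,
            window_um=window_px * 0.42,
            z_slices=z_slices,
            n_cycles=n_cycles,
            areas=areas,
        )

    def __post_init__(self) -> None:
        if self.z_slices < 1 or self.n_cycles < 1:
            raise ValueError("z_slices and n_cycles must be >= 1")
        if self.cycle_interval_min <= 0:
            raise ValueError("cycle interval must be positive")


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the synthetic experiment (study conditions).

    Volumes in um^3, times in minutes, intensities in 8-bit counts.
    ``growth_rate`` may be a scalar (same at every x-location) or a
    12-vector of per-location rates.  Dispersal starts at position 12 at
    ``dispersal_onset_t12`` and is delayed upstream by
    ``propagation_min_per_position`` per x-location step.
    """

    mean_initial_clusters: float = 30.0
    single_cell_volume: float = 2.0
    initial_cluster_volume_max: float = 25.0
    growth_rate: float | tuple[float, ...] = math.log(2.0) / 65.0  # min^-1
    detachment_rate: float = 0.05  # events per cluster per cycle
    dispersal_onset_t12: float = 370.0
    propagation_min_per_position: float = 63.0 / 11.0
    dispersal_decay_halflife: float = 20.0
    background_intensity: float = 2.0
    cell_intensity: float = 20.0
    psf_sigma_xy: float = 0.2  # um
    psf_sigma_z: float = 0.4  # um
    read_noise_sigma: float = 2.0
    apply_noise: bool = True
    min_cluster_spacing_um: float = 12.0
    edge_margin_um: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.growth_rate, dtype=float))
        if np.any(g <= 0):
            raise ValueError("growth rate must be positive")
        if self.dispersal_decay_halflife <= 0:
            raise ValueError("decay half-life must be positive")
        if self.cell_intensity <= INTENSITY_SCALE_THRESHOLD + 3.0 * self.read_noise_sigma * self.apply_noise:
            raise ValueError(
                "cell_intensity must exceed the segmentation threshold by at "
                "least 3 read-noise sigmas for detectable cells"
            )
        if self.single_cell_volume <= 0 or self.initial_cluster_volume_max < self.single_cell_volume:
            raise ValueError("initial volume range is invalid")

    @classmethod
    def reduced_window_defaults(cls, **overrides) -> "SyntheticParams":
        """Defaults rescaled for the reduced (128 px) simulation windows.

        Cluster seeding density is kept compatible with the smaller field
        of view (fewer clusters, same kinetics) so that ground-truth
        exponential volumes are not distorted by window-edge clipping.
        """
        kw = dict(mean_initial_clusters=8.0)
        kw.update(overrides)
        return cls(**kw)

    def noise_free(self) -> "SyntheticParams":
        """Copy with PSF blur and photon/read noise disabled."""
        return replace(self, psf_sigma_xy=0.0, psf_sigma_z=0.0, apply_noise=False)

    def growth_rate_at(self, x_index: int) -> float:
        g = np.atleast_1d(np.asarray(self.growth_rate, dtype=float))
        if g.size == 1:
            return float(g[0])
        if g.size != 12:
            raise ValueError("per-location growth_rate must have 12 entries")
        return float(g[x_index - 1])

    def onset_time(self, x_index: int) -> float:
        """True dispersal-onset time (min) at x-location ``x_index`` (1-12)."""
        return self.dispersal_onset_t12 + self.propagation_min_per_position * (12 - x_index)


@dataclass
class SphereCluster:
    """One clonal cluster: a sphere resting on the substratum."""

    cx: float  # um, window coords (x increases downstream)
    cy: float  # um
    v0: float  # volume at birth, um^3
    birth_time: float  # min
    growth_rate: float  # min^-1
    onset_time: float  # min (position onset; decay starts here)
    decay_rate: float  # min^-1

    def volume_at(self, t: float) -> float:
        if t < self.birth_time:
            return 0.0
        t_grow_end = max(self.onset_time, self.birth_time)
        if t <= t_grow_end:
            return self.v0 * math.exp(self.growth_rate * (t - self.birth_time))
        v_peak = self.v0 * math.exp(self.growth_rate * (t_grow_end - self.birth_time))
        return v_peak * math.exp(-self.decay_rate * (t - t_grow_end))

    def radius_at(self, t: float) -> float:
        return (3.0 * self.volume_at(t) / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class PositionTruth:
    """Exact ground truth for one imaging position."""

    position: str
    growth_rate: float  # min^-1
    onset_time: float  # min
    birth_times: list[float]
    cycle_times: np.ndarray
    true_volumes: np.ndarray  # total biovolume per cycle, um^3

    def to_jsonable(self) -> dict:
        return {
            "position": self.position,
            "growth_rate_per_min": self.growth_rate,
            "onset_time_min": self.onset_time,
            "birth_times_min": list(map(float, self.birth_times)),
            "cycle_times_min": [float(t) for t in self.cycle_times],
            "true_volumes_um3": [float(v) for v in self.true_volumes],
        }


def position_label(x_index: int, area: str) -> str:
    return f"{x_index}{area}"


def _sample_centers(
    n: int, layout: ImagingLayout, params: SyntheticParams, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Uniform centers with a soft minimum-spacing constraint."""
    lo = params.edge_margin_um
    hi = layout.window_um - params.edge_margin_um
    if hi <= lo:  # degenerate tiny window: fall back to the full window
        lo, hi = 0.0, layout.window_um
    spacing = params.min_cluster_spacing_um
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        placed = False
        d_min = spacing
        for attempt in range(400):
            cx = rng.uniform(lo, hi)
            cy = rng.uniform(lo, hi)
            if all((cx - x) ** 2 + (cy - y) ** 2 >= d_min**2 for x, y in centers):
                centers.append((cx, cy))
                placed = True
                break
            if attempt % 100 == 99:  # relax if the window is crowded
                d_min *= 0.7
        if not placed:
            centers.append((rng.uniform(lo, hi), rng.uniform(lo, hi)))
    return centers


def evolve_clusters(
    params: SyntheticParams, layout: ImagingLayout, x_index: int, area: str = "a"
) -> tuple[list[list[SphereCluster]], PositionTruth]:
    """Simulate cluster attachment, growth, shedding and dispersal.

    Returns the list of live clusters at each imaging cycle plus the exact
    ground truth for the position.  Deterministic for fixed
    ``params.rng_seed``; each (x-location, area) gets its own RNG stream.
    """
    area_idx = AREAS.index(area) if area in AREAS else 0
    rng = np.random.default_rng([params.rng_seed % (2**31), 101, x_index, area_idx])
    g = params.growth_rate_at(x_index)
    t_on = params.onset_time(x_index)
    decay = math.log(2.0) / params.dispersal_decay_halflife

    n0 = int(rng.poisson(params.mean_initial_clusters))
    centers = _sample_centers(n0, layout, params, rng)
    clusters = [
        SphereCluster(
            cx=cx,
            cy=cy,
            v0=float(rng.uniform(params.single_cell_volume, params.initial_cluster_volume_max)),
            birth_time=0.0,
            growth_rate=g,
            onset_time=t_on,
            decay_rate=decay,
        )
        for cx, cy in centers
    ]

    times = layout.cycle_times
    per_cycle: list[list[SphereCluster]] = []
    for t in times:
        # single-cell shedding: new cells attach slightly downstream (+x)
        if t < t_on and params.detachment_rate > 0:
            n_parents = len(clusters)
            for ci in range(n_parents):
                if rng.random() < params.detachment_rate:
                    parent = clusters[ci]
                    cx = parent.cx + rng.uniform(3.0, 12.0)
                    cy = parent.cy + rng.uniform(-4.0, 4.0)
                    cx = float(np.clip(cx, 0.5, layout.window_um - 0.5))
                    cy = float(np.clip(cy, 0.5, layout.window_um - 0.5))
                    clusters.append(
                        SphereCluster(
                            cx=cx,
                            cy=cy,
                            v0=params.single_cell_volume,
                            birth_time=float(t),
                            growth_rate=g,
                            onset_time=t_on,
                            decay_rate=decay,
                        )
                    )
        per_cycle.append([c for c in clusters if c.volume_at(float(t)) > 0.0])

    truth = PositionTruth(
        position=position_label(x_index, area),
        growth_rate=g,
        onset_time=t_on,
        birth_times=[c.birth_time for c in clusters],
        cycle_times=times,
        true_volumes=np.array(
            [sum(c.volume_at(float(t)) for c in clusters) for t in times]
        ),
    )
    return per_cycle, truth


def render_stack(
    clusters: list[SphereCluster],
    layout: ImagingLayout,
    params: SyntheticParams,
    t: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one z-stack (z, y, x) as an 8-bit intensity grid.

    Voxels inside any sphere are set to ``cell_intensity`` over a uniform
    ``background_intensity``, blurred with the anisotropic PSF, then
    Poisson-sampled with additive Gaussian read noise (when noise is on)
    and clipped to [0, 255].
    """
    npx = layout.window_px
    nz = layout.z_slices
    grid = np.full((nz, npx, npx), params.background_intensity, dtype=np.float32)

    vx, vz = layout.voxel_xy, layout.voxel_z
    # voxel-centre coordinate helpers (um)
    for c in clusters:
        r = c.radius_at(t)
        if r <= 0:
            continue
        cz = r  # sphere rests on the substratum (z = 0)
        ix0 = max(int((c.cx - r) / vx - 0.5), 0)
        ix1 = min(int((c.cx + r) / vx + 0.5) + 1, npx)
        iy0 = max(int((c.cy - r) / vx - 0.5), 0)
        iy1 = min(int((c.cy + r) / vx + 0.5) + 1, npx)
        iz0 = max(int((cz - r) / vz - 0.5), 0)
        iz1 = min(int((cz + r) / vz + 0.5) + 1, nz)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        xs = (np.arange(ix0, ix1) + 0.5) * vx - c.cx
        ys = (np.arange(iy0, iy1) + 0.5) * vx - c.cy
        zs = (np.arange(iz0, iz1) + 0.5) * vz - cz
        d2 = (
            zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
        )
        sub = grid[iz0:iz1, iy0:iy1, ix0:ix1]
        np.maximum(sub, np.where(d2 <= r * r, params.cell_intensity, 0.0), out=sub)

    if params.psf_sigma_xy > 0 or params.psf_sigma_z > 0:
        grid = gaussian_filter(
            grid,
            sigma=(params.psf_sigma_z / vz, params.psf_sigma_xy / vx, params.psf_sigma_xy / vx),
            mode="nearest",
        )

    if params.apply_noise:
        if rng is None:
            rng = np.random.default_rng(params.rng_seed % (2**31))
        grid = rng.poisson(np.maximum(grid, 0.0)).astype(np.float32)
        grid += rng.normal(0.0, params.read_noise_sigma, size=grid.shape).astype(np.float32)

    return np.clip(np.rint(grid), 0, 255).astype(np.uint8)


def iter_position_stacks(
    params: SyntheticParams, layout: ImagingLayout, x_index: int, area: str = "a"
) -> Iterator[tuple[int, float, np.ndarray]]:
    """Yield (cycle_number, time_min, stack) for one position, in order."""
    per_cycle, _ = evolve_clusters(params, layout, x_index, area)
    area_idx = AREAS.index(area) if area in AREAS else 0
    for n, (t, clusters) in enumerate(zip(layout.cycle_times, per_cycle), start=1):
        rng = np.random.default_rng([params.rng_seed % (2**31), 202, x_index, area_idx, n])
        yield n, float(t), render_stack(clusters, layout, params, float(t), rng)


def simulate_experiment(
    params: SyntheticParams, layout: ImagingLayout, out_dir: str | Path
) -> dict:
    """Run the full synthetic experiment and write stacks + ground truth.

    Writes one multi-page TIFF per (position, cycle), named
    ``pos{XX}{a|b|c}_cycle{NNN}.tif``, plus ``truth.json`` and
    ``layout.json``.  Returns a manifest dict.  Deterministic for a fixed
    seed: rerunning produces byte-identical files.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_all: dict[str, dict] = {}
    files: list[str] = []
    for x_index in layout.x_locations:
        for area in layout.areas:
            _, truth = evolve_clusters(params, layout, x_index, area)
            truth_all[truth.position] = truth.to_jsonable()
            for n, _t, stack in iter_position_stacks(params, layout, x_index, area):
                name = f"pos{x_index:02d}{area}_cycle{n:03d}.tif"
                path = out / name
                if path.exists():
                    raise FileExistsError(f"output collision: {path}")
                tifffile.imwrite(path, stack)
                files.append(name)

    (out / "truth.json").write_text(json.dumps(truth_all, indent=1, sort_keys=True))
    (out / "layout.json").write_text(
        json.dumps(
            {
                "flow_rate": layout.flow_rate,
                "window_um": layout.window_um,
                "voxel_xy_um": layout.voxel_xy,
                "voxel_z_um": layout.voxel_z,
                "z_slices": layout.z_slices,
                "n_cycles": layout.n_cycles,
                "cycle_interval_min": layout.cycle_interval_min,
                "t_first_cycle_min": layout.t_first_cycle_min,
            },
            indent=1,
        )
    )
    return {"n_stacks": len(files), "files": files, "out_dir": str(out)}
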