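"""Pipeline orchestration: simulate -> segment -> quantify -> kinetics.

Stages communicate through plain CSV/JSON files (TIFF only at the imaging
boundary) so each stage can be validated or resumed independently.  The
in-memory path (:func:`analyze_synthetic`) runs the same computations
without touching disk and is what the simulation studies use.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .kinetics import (
    DispersalResult,
    GrowthFit,
    InsufficientDataError,
    OnsetResult,
    detect_dispersal_onset,
    fit_growth,
)
from .quantification import NormalizationError, QuantSeries, normalize_series
from .segmentation import SegmentationParams, read_stack, segment_stack
from .synthetic import ImagingLayout, SyntheticParams

log = logging.getLogger("biofilm_flowcell")

_STACK_RE = re.compile(r"pos(\d{2})([a-c])_cycle(\d{3})\.tif$")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    flow_rate: float = 0.1
    out_dir: str = "results/run"
    rng_seed: int = 0
    t_ref_min: float = 120.0  # normalisation reference time (2 h)
    t_first_cycle_min: float = 40.0
    cycle_interval_min: float = 10.0
    intensity_threshold: float = 10.0
    min_voxels: int = 3
    connectivity: int = 26
    reduced: bool = False  # use the small simulation windows
    layout_overrides: dict = field(default_factory=dict)
    synthetic_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    def layout(self) -> ImagingLayout:
        kw = dict(
            t_first_cycle_min=self.t_first_cycle_min,
            cycle_interval_min=self.cycle_interval_min,
        )
        kw.update(self.layout_overrides)
        if self.reduced:
            kw.pop("t_first_cycle_min", None)
            kw.pop("cycle_interval_min", None)
            return ImagingLayout.reduced(flow_rate=self.flow_rate, **self.layout_overrides)
        return ImagingLayout.for_flow_rate(self.flow_rate, **kw)

    def synthetic_params(self) -> SyntheticParams:
        base = (
            SyntheticParams.reduced_window_defaults
            if self.reduced
            else SyntheticParams
        )
        return base(rng_seed=self.rng_seed, **self.synthetic_overrides)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            intensity_threshold=self.intensity_threshold,
            min_voxels=self.min_voxels,
            connectivity=self.connectivity,
        )


def cycle_to_time(n: int, t_first: float = 40.0, interval: float = 10.0) -> float:
    """Imaging-cycle index (1-based) to experiment time in minutes."""
    if n < 1:
        raise ValueError(f"cycle index must be >= 1, got {n}")
    return t_first + (n - 1) * interval

def time_to_cycle(t: float, t_first: float = 40.0, interval: float = 10.0) -> int:
    """Experiment time (min) to the nearest imaging-cycle index."""
    if t < t_first - interval / 2.0:
        raise ValueError(f"time {t} min precedes the first imaging cycle at {t_first} min")
    return int(round((t - t_first) / interval)) + 1


def analyze_position(
    stacks,
    times,
    position: str,
    seg_params: SegmentationParams,
    t_ref: float = 120.0,
) -> tuple[QuantSeries, GrowthFit | None, OnsetResult | None]:
    """Segment and quantify one position's stack sequence, then fit kinetics."""
    clusters_per_cycle = [segment_stack(s, seg_params) for s in stacks]
    series = QuantSeries.from_clusters(position, times, clusters_per_cycle)
    try:
        normalize_series(series, t_ref)
    except NormalizationError:
        log.warning("position %s has zero reference biovolume; left unnormalised", position)
    try:
        fit = fit_growth(series)
    except InsufficientDataError:
        fit = None
    onset = detect_dispersal_onset(series) if series.volumes.max() > 0 else None
    return series, fit, onset


def analyze_synthetic(
    params: SyntheticParams,
    layout: ImagingLayout,
    seg_params: SegmentationParams | None = None,
    t_ref: float = 120.0,
) -> tuple[dict[str, QuantSeries], DispersalResult, dict[str, synthetic.PositionTruth]]:
    """Full in-memory run: simulate, segment, quantify, fit, detect onsets."""
    seg_params = seg_params or SegmentationParams()
    all_series: dict[str, QuantSeries] = {}
    fits: dict[str, GrowthFit] = {}
    onsets: dict[str, OnsetResult] = {}
    truths: dict[str, synthetic.PositionTruth] = {}
    for xi in layout.x_locations:
        for area in layout.areas:
            label = synthetic.position_label(xi, area)
            _, truth = synthetic.evolve_clusters(params, layout, xi, area)
            truths[label] = truth
            stacks = [
                stack for _n, _t, stack in synthetic.iter_position_stacks(params, layout, xi, area)
            ]
            series, fit, onset = analyze_position(
                stacks, layout.cycle_times, label, seg_params, t_ref
            )
            all_series[label] = series
            if fit is not None:
                fits[label] = fit
            if onset is not None:
                onsets[label] = onset
    result = DispersalResult(flow_rate=layout.flow_rate, onsets=onsets, fits=fits)
    return all_series, result, truths


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """File-based pipeline: each stage writes CSV/JSON and is resumable.

    Stages: simulate (TIFF stacks), segment (clusters.csv), quantify
    (quant.csv), kinetics (kinetics.csv, onsets.csv, per_location.csv).
    Existing stage outputs are reused unless ``force`` is set.  Returns a
    manifest of produced files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = config.layout()
    seg_params = config.segmentation_params()
    config.to_yaml(out / "config.yaml")
    log.info("pipeline run: flow_rate=%s seed=%s out=%s", config.flow_rate, config.rng_seed, out)

    stacks_dir = out / "stacks"
    if force or not (stacks_dir / "truth.json").exists():
        synthetic.simulate_experiment(config.synthetic_params(), layout, stacks_dir)

    clusters_csv = out / "clusters.csv"
    if force or not clusters_csv.exists():
        rows = []
        for path in sorted(stacks_dir.glob("pos*.tif")):
            m = _STACK_RE.search(path.name)
            if not m:
                continue
            xi, area, n = int(m.group(1)), m.group(2), int(m.group(3))
            stack, _ = read_stack(path)
            for c in segment_stack(stack, seg_params):
                rows.append(
                    {
                        "position": f"{xi}{area}",
                        "cycle": n,
                        "t_min": cycle_to_time(n, layout.t_first_cycle_min, layout.cycle_interval_min),
                        "cluster_id": c.id,
                        "voxels": c.voxel_count,
                        "V_pni_um3": c.biovolume,
                        "centroid_x_um": c.centroid[0],
                        "centroid_y_um": c.centroid[1],
                        "centroid_z_um": c.centroid[2],
                    }
                )
        pd.DataFrame(
            rows,
            columns=[
                "position", "cycle", "t_min", "cluster_id", "voxels",
                "V_pni_um3", "centroid_x_um", "centroid_y_um", "centroid_z_um",
            ],
        ).to_csv(clusters_csv, index=False)

    quant_csv = out / "quant.csv"
    bubbles_csv = out / "bubbles.csv"
    kinetics_csv = out / "kinetics.csv"
    onsets_csv = out / "onsets.csv"
    per_loc_csv = out / "per_location.csv"
    if force or not per_loc_csv.exists():
        clusters = pd.read_csv(clusters_csv)
        # bubble-plot data: centroid plus equivalent sphere diameter per cluster
        bubbles = clusters[["position", "cycle", "cluster_id", "centroid_x_um", "centroid_y_um"]].copy()
        bubbles["D_pni_um"] = np.cbrt(6.0 * clusters["V_pni_um3"] / np.pi)
        bubbles.to_csv(bubbles_csv, index=False)
        times = layout.cycle_times
        quant_frames = []
        fits: dict[str, GrowthFit] = {}
        onsets: dict[str, OnsetResult] = {}
        for xi in layout.x_locations:
            for area in layout.areas:
                label = f"{xi}{area}"
                sub = clusters[clusters["position"] == label]
                vols_by_cycle = sub.groupby("cycle")["V_pni_um3"].sum()
                counts_by_cycle = sub.groupby("cycle")["cluster_id"].count()
                n_cycles = len(times)
                volumes = np.zeros(n_cycles)
                counts = np.zeros(n_cycles, dtype=int)
                volumes[vols_by_cycle.index.to_numpy() - 1] = vols_by_cycle.to_numpy()
                counts[counts_by_cycle.index.to_numpy() - 1] = counts_by_cycle.to_numpy()
                series = QuantSeries(position=label, times=times, counts=counts, volumes=volumes)
                try:
                    normalize_series(series, config.t_ref_min)
                except NormalizationError:
                    log.warning("position %s: zero reference biovolume", label)
                quant_frames.append(series.to_dataframe())
                try:
                    fits[label] = fit_growth(series)
                except InsufficientDataError:
                    pass
                if series.volumes.max() > 0:
                    onsets[label] = detect_dispersal_onset(series)
        pd.concat(quant_frames, ignore_index=True).to_csv(quant_csv, index=False)
        pd.DataFrame([f.__dict__ for f in fits.values()]).to_csv(kinetics_csv, index=False)
        pd.DataFrame([o.__dict__ for o in onsets.values()]).to_csv(onsets_csv, index=False)
        result = DispersalResult(flow_rate=config.flow_rate, onsets=onsets, fits=fits)
        result.per_location().to_csv(per_loc_csv, index=False)

    manifest = {
        "config": str(out / "config.yaml"),
        "stacks": str(stacks_dir),
        "clusters": str(clusters_csv),
        "bubbles": str(bubbles_csv),
        "quant": str(quant_csv),
        "kinetics": str(kinetics_csv),
        "onsets": str(onsets_csv),
        "per_location": str(per_loc_csv),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
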