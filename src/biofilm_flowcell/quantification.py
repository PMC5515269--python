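"""Per-window biofilm metrics: totals, normalisation and size statistics.

For position ``p`` and imaging cycle ``n`` the total biovolume is the sum
over its clusters, V_pn = sum_i V_pni.  To compare positions, V_pn is
normalised by the value at a reference time (default 2 h, by which cells
are permanently attached): Vnorm_pn = V_pn / V_pn_a.  The cluster count at
the reference cycle is the number of initially attached clusters N_ap.
Cluster size distributions are ascending-sorted V_pni; for bubble plots a
cluster's equivalent sphere diameter is D = (6 V / pi)^(1/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import Cluster


class NormalizationError(ValueError):
    """Reference biovolume is zero: the position cannot be normalised."""


@dataclass
class QuantSeries:
    """Per-position time series of cluster counts and biovolumes."""

    position: str
    times: np.ndarray  # min, one entry per cycle, strictly increasing
    counts: np.ndarray  # N_pn
    volumes: np.ndarray  # V_pn, um^3
    reference_cycle: int | None = None  # 1-based index n_a
    reference_volume: float | None = None  # V_pn_a
    vnorm: np.ndarray | None = None
    clusters_per_cycle: list[list[Cluster]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if not (len(self.times) == len(self.counts) == len(self.volumes)):
            raise ValueError("times, counts and volumes must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("cycle times must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("biovolumes must be non-negative")

    @classmethod
    def from_clusters(
        cls, position: str, times, clusters_per_cycle: list[list[Cluster]]
    ) -> "QuantSeries":
        return cls(
            position=position,
            times=np.asarray(times, dtype=float),
            counts=np.array([len(cs) for cs in clusters_per_cycle]),
            volumes=np.array([total_biovolume(cs) for cs in clusters_per_cycle]),
            clusters_per_cycle=clusters_per_cycle,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": self.position,
                "cycle": np.arange(1, len(self.times) + 1),
                "t_min": self.times,
                "N_pn": self.counts,
                "V_pn_um3": self.volumes,
            }
        )
        if self.vnorm is not None:
            df["Vnorm"] = self.vnorm
        return df


@dataclass(frozen=True)
class BubbleRecord:
    """One bubble: a cluster's centroid and equivalent sphere diameter."""

    cluster_id: int
    x_um: float
    y_um: float
    diameter_um: float
    cycle: int


def total_biovolume(clusters: list[Cluster] | list[float]) -> float:
    """Total biovolume V_pn: arithmetic sum over clusters (0 if empty)."""
    vols = [c.biovolume if isinstance(c, Cluster) else float(c) for c in clusters]
    if any(v < 0 for v in vols):
        raise ValueError("negative cluster biovolume in input")
    return float(sum(vols))


def reference_cycle_index(times: np.ndarray, t_ref: float = 120.0) -> int:
    """1-based cycle index whose time is nearest t_ref (ties -> earlier)."""
    times = np.asarray(times, dtype=float)
    return int(np.argmin(np.abs(times - t_ref))) + 1


def normalize_series(series: QuantSeries, t_ref: float = 120.0) -> QuantSeries:
    """Attach Vnorm_pn = V_pn / V_pn_a using the cycle nearest ``t_ref``.

    Raises :class:`NormalizationError` if the reference biovolume is zero,
    naming the position (the caller may flag rather than drop it).
    """
    n_a = reference_cycle_index(series.times, t_ref)
    v_ref = float(series.volumes[n_a - 1])
    if v_ref <= 0:
        raise NormalizationError(
            f"position {series.position}: zero biovolume at reference cycle {n_a}"
        )
    series.reference_cycle = n_a
    series.reference_volume = v_ref
    series.vnorm = series.volumes / v_ref
    return series


def initial_cluster_count(series: QuantSeries, t_ref: float = 120.0) -> int:
    """N_ap: number of clusters at the reference cycle (nearest ``t_ref``)."""
    n_a = reference_cycle_index(series.times, t_ref)
    return int(series.counts[n_a - 1])


def size_distribution(clusters: list[Cluster] | list[float]) -> np.ndarray:
    """Per-cluster biovolumes sorted ascending (rank plot ordinates)."""
    vols = np.array(
        [c.biovolume if isinstance(c, Cluster) else float(c) for c in clusters]
    )
    return np.sort(vols, kind="stable")


def equivalent_diameter(volume: float | np.ndarray) -> float | np.ndarray:
    """Equivalent sphere diameter D = (6 V / pi)^(1/3), um for V in um^3."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    d = np.cbrt(6.0 * v / math.pi)
    return float(d) if np.isscalar(volume) or v.ndim == 0 else d


def volume_from_diameter(diameter: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`equivalent_diameter`: V = (pi / 6) D^3."""
    d = np.asarray(diameter, dtype=float)
    v = math.pi / 6.0 * d**3
    return float(v) if np.isscalar(diameter) or d.ndim == 0 else v


def bubble_records(clusters: list[Cluster], cycle: int) -> list[BubbleRecord]:
    """Bubble-plot data for one cycle: centroid (x, y) and diameter."""
    return [
        BubbleRecord(
            cluster_id=c.id,
            x_um=c.centroid[0],
            y_um=c.centroid[1],
            diameter_um=float(equivalent_diameter(c.biovolume)),
            cycle=cycle,
        )
        for c in clusters
    ]
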