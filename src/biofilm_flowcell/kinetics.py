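"""Growth and dispersal kinetics of per-position biovolume series.

Growth is modelled as exponential, V_pn(t) = V_pn0 * exp(g_p t); the
apparent growth rate g_p is fitted by ordinary least squares on
ln V_pn vs t over the cycles from the start of the experiment up to the
cycle of maximal biovolume, and the doubling time is t_d = ln 2 / g_p.

Dispersal onset is the first cycle after the global maximum of the
normalised biovolume at which the series decreases (and never again
exceeds that maximum — which is automatic for the global maximum, with
ties broken toward the earliest peak).  Spatial statistics aggregate the
three replicate areas (a/b/c) per x-location as mean +/- sample standard
deviation, and the propagation statistic is the onset-time difference
between the upstream (1) and downstream (12) ends of the channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantification import QuantSeries


class InsufficientDataError(ValueError):
    """Fewer than three positive biovolume cycles before the peak."""


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth fit for one position."""

    position: str
    growth_rate: float  # g_p, min^-1
    doubling_time: float  # t_d = ln2 / g_p, min (nan when non-growing)
    peak_cycle: int  # n_pmax, 1-based
    peak_volume: float  # V_pn at n_pmax, um^3
    v0: float  # fitted V at t = 0
    r_squared: float  # in log space
    n_cycles_used: int
    growing: bool


@dataclass(frozen=True)
class OnsetResult:
    """Dispersal onset for one position (``onset_cycle`` None if absent)."""

    position: str
    onset_cycle: int | None  # 1-based
    t_disp: float | None  # min
    peak_cycle: int | None
    peak_vnorm: float | None


def doubling_time(g: float) -> float:
    """Doubling time ln 2 / g (min) for growth rate g (min^-1)."""
    if g <= 0:
        raise ValueError(f"growth rate must be positive, got {g}")
    return math.log(2.0) / g


def fit_growth(series: QuantSeries) -> GrowthFit:
    """Fit ln V_pn vs t by OLS from cycle 1 to the biovolume peak.

    Cycles with zero biovolume are excluded from the fit.  Requires at
    least three positive cycles up to and including the peak; a fitted
    g <= 0 is returned flagged as non-growing rather than raised.
    """
    v = series.volumes
    t = series.times
    n_pmax = int(np.argmax(v)) + 1  # earliest global maximum
    sel = slice(0, n_pmax)
    vv, tt = v[sel], t[sel]
    pos = vv > 0
    if int(pos.sum()) < 3:
        raise InsufficientDataError(
            f"position {series.position}: only {int(pos.sum())} positive cycles "
            f"before the peak (need >= 3)"
        )
    x, y = tt[pos], np.log(vv[pos])
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    growing = slope > 0
    return GrowthFit(
        position=series.position,
        growth_rate=float(slope),
        doubling_time=math.log(2.0) / slope if growing else float("nan"),
        peak_cycle=n_pmax,
        peak_volume=float(v[n_pmax - 1]),
        v0=float(np.exp(intercept)),
        r_squared=r2,
        n_cycles_used=int(pos.sum()),
        growing=bool(growing),
    )


def detect_dispersal_onset(series: QuantSeries) -> OnsetResult:
    """Find the dispersal onset: first decrease after the highest peak.

    Uses the normalised series when available, else raw V_pn (equivalent
    under positive normalisation).  The peak is the earliest cycle
    attaining the global maximum; the onset is the first later cycle whose
    value falls below the maximum.  A series that never decreases after
    its peak has no onset (``onset_cycle`` is None) — distinct from an
    error.
    """
    v = series.vnorm if series.vnorm is not None else series.volumes
    v = np.asarray(v, dtype=float)
    peak = int(np.argmax(v))  # earliest among ties
    vmax = v[peak]
    after = np.nonzero(v[peak + 1 :] < vmax)[0]
    if after.size == 0:
        return OnsetResult(series.position, None, None, peak + 1, float(vmax))
    onset = peak + 1 + int(after[0])
    return OnsetResult(
        position=series.position,
        onset_cycle=onset + 1,
        t_disp=float(series.times[onset]),
        peak_cycle=peak + 1,
        peak_vnorm=float(vmax),
    )


def aggregate_over_areas(values) -> tuple[float, float]:
    """Mean and sample SD (n-1) over the replicate areas of one x-location.

    Designed for the three a/b/c areas; fewer values are accepted (reduced
    n), a singleton yields (value, nan), empty input is an error.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot aggregate an empty set of areas")
    if vals.size == 1:
        return float(vals[0]), float("nan")
    return float(vals.mean()), float(vals.std(ddof=1))


@dataclass
class DispersalResult:
    """Per-position onsets plus per-x-location aggregates for one run."""

    flow_rate: float
    onsets: dict[str, OnsetResult]  # keyed by position label, e.g. "12a"
    fits: dict[str, GrowthFit]

    def per_location(self) -> pd.DataFrame:
        """Aggregate areas a-c per x-location (Figs. 5/6-style table)."""
        rows = []
        x_indices = sorted({int(p[:-1]) for p in self.onsets})
        for xi in x_indices:
            t_vals = [
                o.t_disp
                for p, o in self.onsets.items()
                if int(p[:-1]) == xi and o.t_disp is not None
            ]
            td_vals = [
                f.doubling_time
                for p, f in self.fits.items()
                if int(p[:-1]) == xi and f.growing
            ]
            vmax_vals = [f.peak_volume for p, f in self.fits.items() if int(p[:-1]) == xi]
            t_mean, t_sd = aggregate_over_areas(t_vals) if t_vals else (np.nan, np.nan)
            td_mean, td_sd = aggregate_over_areas(td_vals) if td_vals else (np.nan, np.nan)
            vm_mean, vm_sd = (
                aggregate_over_areas(vmax_vals) if vmax_vals else (np.nan, np.nan)
            )
            rows.append(
                {
                    "x_location": xi,
                    "t_disp_mean_min": t_mean,
                    "t_disp_sd_min": t_sd,
                    "t_d_mean_min": td_mean,
                    "t_d_sd_min": td_sd,
                    "V_pnmax_mean_um3": vm_mean,
                    "V_pnmax_sd_um3": vm_sd,
                    "n_areas": len(t_vals),
                }
            )
        return pd.DataFrame(rows)

    def mean_onset_at(self, x_index: int) -> float:
        vals = [
            o.t_disp
            for p, o in self.onsets.items()
            if int(p[:-1]) == x_index and o.t_disp is not None
        ]
        if not vals:
            raise ValueError(f"no detected onsets at x-location {x_index}")
        return aggregate_over_areas(vals)[0]


def propagation_stat(result: DispersalResult) -> float:
    """Upstream-downstream onset delay: mean t_disp(pos 1) - t_disp(pos 12).

    Positive under downstream-first dispersal (position 12 disperses
    before position 1).
    """
    return result.mean_onset_at(1) - result.mean_onset_at(12)


@dataclass(frozen=True)
class ReproRow:
    """One reproducibility row: position-12 onset stats of two runs."""

    flow_rate: float
    run1_mean_min: float  # rounded to whole minutes
    run1_sd_min: float
    run1_cv_pct: float  # sigma1 / mean1, percent, 1 decimal
    run2_mean_min: float | None
    run2_sd_min: float | None
    run2_cv_pct: float | None
    delta12_min: float | None  # |mean2 - mean1|, whole minutes
    delta12_pct: float | None  # delta12 / mean1, percent, 1 decimal


def _run_summary(values_or_stats) -> tuple[float, float]:
    """Accept raw a-c onset times or a (mean, sd) pair."""
    arr = np.asarray(list(values_or_stats), dtype=float)
    if arr.size == 2:
        return float(arr[0]), float(arr[1])
    mean, sd = aggregate_over_areas(arr)
    return mean, sd


def reproducibility_row(
    flow_rate: float, run1, run2=None
) -> ReproRow:
    """Between-run reproducibility of the position-12 dispersal time.

    ``run1`` / ``run2`` are either the three a-c onset times (min) or a
    precomputed ``(mean, sd)`` pair.  Times are reported rounded to whole
    minutes and percentages to one decimal, as in the reporting layer;
    full precision is used internally.  A single-run input leaves the
    between-run fields empty.
    """
    m1, s1 = _run_summary(run1)
    row = {
        "flow_rate": flow_rate,
        "run1_mean_min": round(m1),
        "run1_sd_min": round(s1),
        "run1_cv_pct": round(100.0 * s1 / m1, 1),
        "run2_mean_min": None,
        "run2_sd_min": None,
        "run2_cv_pct": None,
        "delta12_min": None,
        "delta12_pct": None,
    }
    if run2 is not None:
        m2, s2 = _run_summary(run2)
        row.update(
            run2_mean_min=round(m2),
            run2_sd_min=round(s2),
            run2_cv_pct=round(100.0 * s2 / m2, 1),
            delta12_min=round(abs(m2 - m1)),
            delta12_pct=round(100.0 * abs(m2 - m1) / m1, 1),
        )
    return ReproRow(**row)


def reproducibility_table(rows: list[ReproRow]) -> pd.DataFrame:
    """Assemble reproducibility rows into a report table."""
    return pd.DataFrame([r.__dict__ for r in rows])
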