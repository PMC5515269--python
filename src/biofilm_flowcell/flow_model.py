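"""Hyperbolic flow-cell channel design and depth-averaged flow solver.

The flow cell is a shallow channel (depth ``h`` ~ 1 mm) whose width expands
hyperbolically between two axial stations so that, at constant volumetric
flux, the depth-averaged centerline velocity decreases *linearly* along the
channel.  Mass conservation in a shallow channel gives

    v(x) = Q_total / (h * w(x)),

so a linear velocity profile ``v(x)`` implies a width profile
``w(x) = Q_total / (h * v(x))`` that is the reciprocal of a linear function
of ``x`` — a hyperbola.

Coordinates follow the device convention: the inlet junction is the origin,
flow runs toward negative ``x``; the expansion spans ``x_start = -1.49`` mm
(narrow, fast) to ``x_end = -8.99`` mm (wide, slow).

Two routes to the velocity field are provided:

* :func:`centerline_velocity_1d` — the exact 1-D mass-conservation formula;
* :func:`solve_depth_averaged` — an independent 2-D depth-averaged
  (Hele-Shaw) potential solve on a masked Cartesian grid.  In the shallow,
  low-Reynolds regime the in-plane depth-averaged velocity is a potential
  flow, ``u = -grad(phi)`` with ``div u = 0``; the solver discretises this
  by finite volumes and verifies that the designed channel indeed produces
  the linear centerline profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

ML_PER_H_TO_MM3_PER_S = 1000.0 / 3600.0


class FlowSolverError(RuntimeError):
    """Raised when the depth-averaged linear solve does not converge."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Geometry and operating point of the hyperbolic flow channel.

    ``width_x`` / ``width_w`` sample the width profile w(x) (mm) on an
    ascending x grid spanning the straight inlet and outlet segments as
    well as the expansion.  ``inlet_flow_Q`` is the rate *per inlet* in
    ml/h; the channel carries twice that.
    """

    depth_h: float = 0.98  # mm
    x_start: float = -1.49  # mm, upstream end of expansion (narrow)
    x_end: float = -8.99  # mm, downstream end of expansion (wide)
    width_x: np.ndarray = field(default_factory=lambda: np.array([-10.0, 0.0]))
    width_w: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    inlet_flow_Q: float = 0.1  # ml/h per inlet
    fluid_density: float = 1016.0  # kg/m^3
    fluid_viscosity: float = 1.09  # mPa s

    def __post_init__(self) -> None:
        if self.depth_h <= 0:
            raise ValueError(f"channel depth must be positive, got {self.depth_h}")
        if self.inlet_flow_Q <= 0:
            raise ValueError(f"inlet flow must be positive, got {self.inlet_flow_Q}")
        w = np.asarray(self.width_w, dtype=float)
        x = np.asarray(self.width_x, dtype=float)
        if x.ndim != 1 or x.shape != w.shape or x.size < 2:
            raise ValueError("width profile needs matching 1-D x and w arrays")
        if np.any(np.diff(x) <= 0):
            raise ValueError("width profile x must be strictly ascending")
        if np.any(w <= 0):
            raise ValueError("channel width must be positive everywhere")

    @property
    def Q_total_mm3_s(self) -> float:
        """Total volumetric flux through the channel in mm^3/s (two inlets)."""
        return 2.0 * self.inlet_flow_Q * ML_PER_H_TO_MM3_PER_S

    def width_at(self, x: float | np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation of w(x) (mm); clamped outside range."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.width_x[0] - 1e-9) or np.any(x > self.width_x[-1] + 1e-9):
            raise ValueError(
                f"x out of profile range [{self.width_x[0]}, {self.width_x[-1]}]"
            )
        return np.interp(x, self.width_x, self.width_w)


@dataclass
class VelocityField:
    """Depth-averaged velocity field on a Cartesian grid.

    ``speed`` is the depth-averaged speed (mm/s) at cell centres, NaN
    outside the channel mask.  ``centerline_x`` / ``centerline_v`` sample
    the speed along y = 0.
    """

    x: np.ndarray  # cell-centre x coords, ascending (nx,)
    y: np.ndarray  # cell-centre y coords (ny,)
    speed: np.ndarray  # (ny, nx), NaN outside channel
    centerline_x: np.ndarray
    centerline_v: np.ndarray
    flux_profile: np.ndarray  # cross-sectional flux (mm^3/s) per interior column face
    geometry: ChannelGeometry

    def centerline_speed_at(self, x: float | np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.centerline_x, self.centerline_v)

    def max_flux_deviation(self) -> float:
        """Largest relative deviation of cross-sectional flux from Q_total."""
        q = self.geometry.Q_total_mm3_s
        return float(np.max(np.abs(self.flux_profile - q)) / q)


def design_width_profile(
    q_per_inlet: float = 0.1,
    depth_h: float = 0.98,
    x_start: float = -1.49,
    x_end: float = -8.99,
    velocity_ratio: float = 3.0,
    w_at_start: float = 1.0,
    inlet_length: float = 1.0,
    outlet_length: float = 3.0,
    exit_transition_length: float = 2.5,
    n_samples: int = 301,
) -> ChannelGeometry:
    """Design the hyperbolic width profile for a linear centerline velocity.

    The centerline velocity interpolates linearly from ``v0`` at ``x_start``
    down to ``v0 / velocity_ratio`` at ``x_end``; the width follows from
    mass conservation, ``w(x) = Q / (h v(x))``, so
    ``w(x_end) = velocity_ratio * w(x_start)``.  A straight segment of the
    start width extends ``inlet_length`` upstream of the expansion.
    Downstream of ``x_end`` the wall slope is blended quadratically to
    zero over ``exit_transition_length`` (a machined channel has no slope
    discontinuity; a sharp corner at the expansion exit would distort the
    local depth-averaged centerline speed), then the width is constant for
    the remaining outlet segment.

    Parameters are in mm and ml/h per inlet; ``velocity_ratio >= 1``.
    """
    if velocity_ratio < 1:
        raise ValueError(f"velocity_ratio must be >= 1, got {velocity_ratio}")
    if w_at_start <= 0 or depth_h <= 0 or q_per_inlet <= 0:
        raise ValueError("geometry parameters must be positive")
    if not x_end < x_start:
        raise ValueError("x_end must lie downstream (more negative) than x_start")

    q_total = 2.0 * q_per_inlet * ML_PER_H_TO_MM3_PER_S
    v0 = q_total / (depth_h * w_at_start)
    # fractional distance through the expansion (0 at x_start, 1 at x_end)
    xs = np.linspace(x_end, x_start, n_samples)  # ascending
    s = (xs - x_start) / (x_end - x_start)
    v = v0 * (1.0 + s * (1.0 / velocity_ratio - 1.0))
    w = q_total / (depth_h * v)

    # exit transition: quadratic blend carrying the hyperbola's end slope
    # (dw/dx at x_end) smoothly to zero over exit_transition_length
    lt = min(exit_transition_length, max(outlet_length - 0.1, 0.0))
    if lt > 0:
        dv_dx = v0 * (1.0 / velocity_ratio - 1.0) / (x_end - x_start)
        m_end = -w[0] * dv_dx / (v0 / velocity_ratio)  # dw/dx at x_end (< 0)
        xt = np.linspace(x_end - lt, x_end, max(int(lt / 0.02), 8), endpoint=False)
        d = xt - x_end  # negative
        wt = w[0] + m_end * d + m_end / (2.0 * lt) * d**2
        w_out = float(wt[0])
        x_full = np.concatenate(([x_end - outlet_length], xt, xs, [x_start + inlet_length]))
        w_full = np.concatenate(([w_out], wt, w, [w[-1]]))
    else:
        x_full = np.concatenate(([x_end - outlet_length], xs, [x_start + inlet_length]))
        w_full = np.concatenate(([w[0]], w, [w[-1]]))
    return ChannelGeometry(
        depth_h=depth_h,
        x_start=x_start,
        x_end=x_end,
        width_x=x_full,
        width_w=w_full,
        inlet_flow_Q=q_per_inlet,
    )


def centerline_velocity_1d(geom: ChannelGeometry, x: float | np.ndarray) -> np.ndarray:
    """Depth-averaged centerline speed (mm/s) from 1-D mass conservation."""
    w = geom.width_at(x)
    return geom.Q_total_mm3_s / (w * geom.depth_h)


def _build_grid(geom: ChannelGeometry, dx: float):
    """Cut-cell grid: cell mask plus fractional face apertures.

    Cells are squares of side ``dx`` on a staggered grid symmetric about
    y = 0.  A cell belongs to the domain when its y-interval overlaps the
    local open channel [-w/2, w/2]; each face carries the open fraction of
    its length, so the discrete geometry varies smoothly with the wall
    position instead of in whole-cell steps.
    """
    x0, x1 = float(geom.width_x[0]), float(geom.width_x[-1])
    nx = max(int(round((x1 - x0) / dx)), 4)
    xc = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    hw = geom.width_at(xc) / 2.0  # half-width per column
    ny = 2 * (int(np.ceil(hw.max() / dx)) + 1)
    yc = (np.arange(ny) - ny / 2.0 + 0.5) * dx
    y_lo, y_hi = yc - dx / 2.0, yc + dx / 2.0

    def overlap(lo, hi, m):
        return np.clip(np.minimum(hi, m) - np.maximum(lo, -m), 0.0, None)

    cell_open = overlap(y_lo[:, None], y_hi[:, None], hw[None, :])  # (ny, nx)
    mask = cell_open > 0.1 * dx

    # x-faces between columns i-1 and i: open fraction of the face length
    ax = np.zeros((ny, nx + 1))
    m_int = np.minimum(hw[:-1], hw[1:])
    ax[:, 1:nx] = overlap(y_lo[:, None], y_hi[:, None], m_int[None, :]) / dx
    ax[:, 0] = overlap(y_lo, y_hi, hw[0]) / dx  # outlet boundary faces
    ax[:, nx] = overlap(y_lo, y_hi, hw[-1]) / dx  # inlet boundary faces
    ax[:, 1:nx] *= mask[:, :-1] & mask[:, 1:]
    ax[:, 0] *= mask[:, 0]
    ax[:, nx] *= mask[:, -1]

    # y-faces between rows j-1 and j: open iff the face lies inside the wall
    y_face = (np.arange(ny + 1) - ny / 2.0) * dx
    ay = (np.abs(y_face)[:, None] < hw[None, :] - 1e-12).astype(float)
    ay[1:ny, :] *= mask[1:, :] & mask[:-1, :]
    ay[0, :] = 0.0
    ay[ny, :] = 0.0
    return xc, yc, mask, ax, ay


def solve_depth_averaged(geom: ChannelGeometry, grid_resolution: float = 0.05) -> VelocityField:
    """Solve the 2-D depth-averaged potential flow through the channel.

    Finite-volume discretisation of ``div u = 0`` with ``u = -grad(phi)``
    on a regular grid masked to the channel footprint.  Walls are no-flux;
    a uniform influx carrying the total flux ``Q_total`` enters at the
    upstream (high-x) boundary and the downstream boundary is held at
    constant potential (outflow).  Narrowest section must be resolved by
    at least 10 cells.
    """
    dx = float(grid_resolution)
    if dx <= 0:
        raise ValueError("grid_resolution must be positive")
    w_min = float(np.min(geom.width_w))
    if w_min / dx < 10:
        raise ValueError(
            f"grid too coarse: narrowest width {w_min} mm needs >=10 cells, "
            f"got {w_min / dx:.1f} at resolution {dx} mm"
        )

    xc, yc, mask, ax, ay = _build_grid(geom, dx)
    ny, nx = mask.shape
    idx = -np.ones((ny, nx), dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))
    n = int(mask.sum())

    # inflow speed at the upstream boundary (depth-averaged, mm/s), spread
    # over the open fraction of the inlet faces
    q = geom.Q_total_mm3_s
    w_in = float(ax[:, nx].sum() * dx)
    u_in = q / (geom.depth_h * w_in)

    rows, cols, vals = [], [], []
    b = np.zeros(n)
    jj, ii = np.nonzero(mask)
    for j, i in zip(jj, ii):
        k = idx[j, i]
        diag = 0.0
        for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            j2, i2 = j + dj, i + di
            if di != 0:
                a = ax[j, i + (di > 0)]
            else:
                a = ay[j + (dj > 0), i]
            if a <= 0.0:
                continue  # wall face: no flux
            inside = 0 <= j2 < ny and 0 <= i2 < nx and mask[j2, i2]
            if inside:
                diag += a
                rows.append(k)
                cols.append(int(idx[j2, i2]))
                vals.append(-a)
            elif di == 1 and i == nx - 1:
                # upstream boundary: prescribed influx through the open face
                b[k] += u_in * a * dx
            elif di == -1 and i == 0:
                # downstream boundary: Dirichlet phi = 0 at the face (ghost)
                diag += 2.0 * a
        rows.append(k)
        cols.append(k)
        vals.append(diag)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    phi_flat = spsolve(A, b)
    if not np.all(np.isfinite(phi_flat)):
        raise FlowSolverError("linear solve produced non-finite potential")
    resid = float(np.linalg.norm(A @ phi_flat - b) / max(np.linalg.norm(b), 1e-300))
    if resid > 1e-8:
        raise FlowSolverError(f"linear solve residual too large: {resid:.3e}")

    phi = np.full((ny, nx), np.nan)
    phi[mask] = phi_flat

    # face-centred x velocities, then cell-centred speed
    ux_face = np.zeros((ny, nx + 1))  # face between i-1 and i
    both = np.zeros((ny, nx + 1), dtype=bool)
    both[:, 1:nx] = (mask[:, 1:] & mask[:, :-1]) & (ax[:, 1:nx] > 0)
    ux_face[both] = (phi[:, :-1] - phi[:, 1:])[both[:, 1:nx]] / dx
    inflow = mask[:, -1] & (ax[:, nx] > 0)
    ux_face[inflow, nx] = -u_in  # inflow faces (flow toward -x)
    # outlet face velocity from half-cell gradient to the phi=0 ghost face
    outflow = mask[:, 0] & (ax[:, 0] > 0)
    ux_face[outflow, 0] = -phi[:, 0][outflow] / (dx / 2.0)

    uy_face = np.zeros((ny + 1, nx))
    vboth = np.zeros((ny + 1, nx), dtype=bool)
    vboth[1:ny, :] = (mask[1:, :] & mask[:-1, :]) & (ay[1:ny, :] > 0)
    uy_face[vboth] = (phi[:-1, :] - phi[1:, :])[vboth[1:ny, :]] / dx

    ux = 0.5 * (ux_face[:, :-1] + ux_face[:, 1:])
    uy = 0.5 * (uy_face[:-1, :] + uy_face[1:, :])
    speed = np.sqrt(ux**2 + uy**2)
    speed[~mask] = np.nan

    # centerline: average the two rows straddling y = 0 (ny even) or take y=0 row
    j0 = np.argmin(np.abs(yc))
    if abs(yc[j0]) < dx / 4:
        center_v = speed[j0, :]
    else:
        j1 = j0 + 1 if yc[j0] < 0 else j0 - 1
        center_v = 0.5 * (speed[j0, :] + speed[j1, :])

    # cross-sectional flux through each interior column of x faces
    flux = (np.abs(ux_face[:, 1:nx]) * ax[:, 1:nx]).sum(axis=0) * dx * geom.depth_h

    return VelocityField(
        x=xc,
        y=yc,
        speed=speed,
        centerline_x=xc,
        centerline_v=center_v,
        flux_profile=flux,
        geometry=geom,
    )


def centerline_linearity(field: VelocityField) -> tuple[float, float, float]:
    """Linear fit of the solved centerline speed over the expansion.

    Returns ``(slope, intercept, r_squared)`` of v(x) for x within
    [x_end, x_start] of the field's geometry.
    """
    g = field.geometry
    sel = (field.centerline_x >= g.x_end) & (field.centerline_x <= g.x_start)
    x = field.centerline_x[sel]
    v = field.centerline_v[sel]
    ok = np.isfinite(v)
    x, v = x[ok], v[ok]
    slope, intercept = np.polyfit(x, v, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2
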