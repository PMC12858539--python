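"""Reduced-order hemodynamics: waveforms, Murray flow splits, pressure fields.

The full 3D finite-volume solve of the clinical workflow is replaced by a
transparent quasi-steady closure on the centerline:

* wall shear magnitude   |tau(s,t)| = 4 mu Q(t) / (pi r(s)^3)   (Poiseuille)
* axial pressure drop    dP/ds = -8 mu Q(t) / (pi r(s)^4)
* a lumped expansion loss at the minimal lumen area,
      dP_exp = K (rho/2) (Q/A_ref)^2 (A_ref/A_min - 1)^2

applied distal to the stenosis.  Every downstream index therefore has an
exact closed-form oracle.  Transient runs follow the three-cycle convention
(simulate ``cycles`` cardiac cycles, analyze the last), and hyperemia is a
direct 2-4x scaling of the baseline waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import GeometryError, ValidationError
from .geometry import VesselGeometry

__all__ = [
    "FlowWaveform",
    "HemoConfig",
    "WallFieldSeries",
    "VolumeFieldSeries",
    "murray_split",
    "apply_hyperemia",
    "solve_reduced_order",
    "write_field_series",
    "read_field_series",
]

MMHG_TO_PA = 133.322387415


@dataclass
class FlowWaveform:
    """Periodic volumetric flow on a uniform time grid spanning one period.

    ``times`` includes both endpoints 0 and T, so ``flow[0] == flow[-1]``.
    """

    times: np.ndarray
    flow: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flow, dtype=float)
        if t.ndim != 1 or t.shape != q.shape or len(t) < 2:
            raise ValidationError("times and flow must be matching 1-D arrays")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > 1e-9 * dt[0]):
            raise ValidationError("waveform time grid must be uniform")
        if abs(q[0] - q[-1]) > 1e-12 * max(1.0, abs(q[0])):
            raise ValidationError("waveform must be periodic: Q(0) == Q(T)")
        self.times = t
        self.flow = q

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def mean_flow(self) -> float:
        """Time-mean flow via the trapezoidal rule (exact for sinusoids)."""
        return float(np.trapezoid(self.flow, self.times) / self.period)

    def scaled(self, factor: float) -> "FlowWaveform":
        return FlowWaveform(self.times.copy(), self.flow * factor)


@dataclass
class HemoConfig:
    """Physical constants and conventions of the reduced-order model.

    viscosity : Pa s — dynamic viscosity of blood (Newtonian).
    density : kg/m^3 — 1056 by convention.
    hyperemia_factor : hyperemic over baseline flow, within [2, 4].
    cycles : cardiac cycles simulated; indices use the last one.
    distal_offset : m — CT-FFR measurement point distance distal to the
        lesion, within [0.02, 0.03].
    expansion_k : lumped expansion-loss coefficient at the MLA.
    inlet_pressure_mmhg : constant aortic inlet pressure when no waveform
        of Pa(t) is supplied.
    """

    viscosity: float = 3.5e-3
    density: float = 1056.0
    hyperemia_factor: float = 3.0
    cycles: int = 3
    samples_per_cycle: int = 48
    distal_offset: float = 0.025
    expansion_k: float = 1.0
    sub_segment_length_mm: float = 3.0
    inlet_pressure_mmhg: float = 93.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValidationError("viscosity and density must be positive")
        if not 2.0 <= self.hyperemia_factor <= 4.0:
            raise ValidationError("hyperemia factor must lie in [2, 4]")
        if not 0.02 - 1e-12 <= self.distal_offset <= 0.03 + 1e-12:
            raise ValidationError("distal FFR offset must lie in [0.02, 0.03] m")

    @property
    def inlet_pressure_pa(self) -> float:
        return self.inlet_pressure_mmhg * MMHG_TO_PA


@dataclass
class WallFieldSeries:
    """Time-resolved wall shear vectors and pressure on the tube surface.

    Arrays cover the one retained cardiac cycle on a uniform grid that
    includes both endpoints.
    """

    times: np.ndarray
    wss: np.ndarray  # (nt, Nv, 3), Pa, tangent to the surface
    pressure: np.ndarray  # (nt, Nv), Pa
    vertex_s: np.ndarray  # (Nv,)
    inlet_pressure: np.ndarray  # (nt,), Pa
    geom: VesselGeometry | None = None

    def __post_init__(self) -> None:
        nt = len(self.times)
        if self.wss.shape[0] != nt or self.pressure.shape[0] != nt:
            raise ValidationError("field arrays must share the time grid")
        dt = np.diff(self.times)
        if np.any(np.abs(dt - dt[0]) > 1e-9 * dt[0]):
            raise ValidationError("wall series time grid must be uniform")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def check_tangency(self) -> float:
        """Max |tau . n| / |tau| over all vertices and times."""
        if self.geom is None:
            raise ValidationError("no geometry attached")
        dots = np.abs(np.einsum("tvk,vk->tv", self.wss, self.geom.normals))
        mags = np.linalg.norm(self.wss, axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(mags > 0, dots / mags, 0.0)
        return float(rel.max())


@dataclass
class VolumeFieldSeries:
    """Time-resolved lumen velocity samples on a structured (s, r, theta) lattice."""

    times: np.ndarray
    points: np.ndarray  # (Np, 3)
    param_s: np.ndarray  # (Np,)
    param_r: np.ndarray  # (Np,) physical radial coordinate
    param_theta: np.ndarray  # (Np,)
    lattice_shape: tuple[int, int, int]  # (ns, nr, ntheta)
    velocity: np.ndarray  # (nt, Np, 3), m/s
    vorticity_analytic: np.ndarray | None = None  # (nt, Np, 3), 1/s
    geom: VesselGeometry | None = None

    def __post_init__(self) -> None:
        ns, nr, ntheta = self.lattice_shape
        if ns * nr * ntheta != len(self.points):
            raise ValidationError("lattice shape inconsistent with point count")
        r_max = (
            self.geom.radius_at(self.param_s) if self.geom is not None else np.inf
        )
        if np.any(self.param_r > r_max + 1e-12):
            raise GeometryError("volume sample point outside the lumen")

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])


def murray_split(child_diameters) -> np.ndarray:
    """Flow fractions to daughter branches by Murray's cube law.

    fraction_i = d_i^3 / sum_j d_j^3, order preserved.
    """
    d = np.asarray(child_diameters, dtype=float)
    if d.size < 2:
        raise ValidationError("Murray split needs at least two children")
    if np.any(d <= 0):
        raise ValidationError("child diameters must be positive")
    cubes = d**3
    return cubes / cubes.sum()


def apply_hyperemia(waveform: FlowWaveform, factor: float) -> FlowWaveform:
    """Scale the baseline waveform to the hyperemic state (2-4x baseline).

    ``factor == 1`` is the resting pass-through.
    """
    if factor != 1.0 and not 2.0 <= factor <= 4.0:
        raise ValidationError("hyperemia factor must be 1 (rest) or within [2, 4]")
    return waveform.scaled(factor)


def _tile_cycles(waveform: FlowWaveform, cycles: int) -> tuple[np.ndarray, np.ndarray]:
    """Time grid and flow over ``cycles`` periods (shared cycle endpoints)."""
    t1, q1 = waveform.times, waveform.flow
    T = waveform.period
    t = t1.copy()
    q = q1.copy()
    for c in range(1, cycles):
        t = np.concatenate([t, t1[1:] + c * T])
        q = np.concatenate([q, q1[1:]])
    return t, q


def solve_reduced_order(
    geom: VesselGeometry,
    waveform: FlowWaveform,
    cfg: HemoConfig,
    inlet_pressure=None,
    radial_samples: int = 12,
):
    """Quasi-steady pressure/shear solve; returns (WallFieldSeries, VolumeFieldSeries).

    Simulates ``cfg.cycles`` cycles and retains the last.  ``inlet_pressure``
    may be a scalar (Pa), an array matching the waveform grid, or None for
    the configured constant aortic pressure.
    """
    s = geom.arclength
    r = geom.radius
    if np.any(r < 1e-9):
        raise GeometryError("lumen radius collapsed to zero: singular geometry")

    t_all, q_all = _tile_cycles(waveform, cfg.cycles)
    nt1 = len(waveform.times)
    keep = slice(len(t_all) - nt1, len(t_all))
    times = t_all[keep] - t_all[keep][0]
    q = q_all[keep]

    if inlet_pressure is None:
        pa_t = np.full(len(times), cfg.inlet_pressure_pa)
    else:
        pa_t = np.broadcast_to(np.asarray(inlet_pressure, dtype=float), (len(times),)).copy()

    # viscous drop: cumulative integral of 8 mu Q / (pi r^4) along s
    resist = 8.0 * cfg.viscosity / (np.pi * r**4)  # per unit Q, per unit s
    cum = cumulative_trapezoid(resist, s, initial=0.0)  # (Ns,)
    visc = q[:, None] * cum[None, :]  # (nt, Ns)

    # lumped expansion loss distal to the MLA
    i_min = int(np.argmin(r))
    a_min = np.pi * r[i_min] ** 2
    a_ref = np.pi * r[0] ** 2
    if a_min < a_ref * (1.0 - 1e-12):
        dp_exp = (
            cfg.expansion_k
            * 0.5
            * cfg.density
            * (q / a_ref) ** 2
            * (a_ref / a_min - 1.0) ** 2
        )
    else:
        dp_exp = np.zeros(len(times))
    step = (s[None, :] >= s[i_min]).astype(float)
    p_center = pa_t[:, None] - visc - dp_exp[:, None] * step  # (nt, Ns)

    # wall shear: Poiseuille magnitude along the axial surface tangent
    tangents = geom.axial_tangents()  # (Nv, 3)
    tau_ring = 4.0 * cfg.viscosity * q[:, None] / (np.pi * r[None, :] ** 3)  # (nt, Ns)
    tau_vertex = np.empty((len(times), len(geom.vertices)))
    p_vertex = np.empty_like(tau_vertex)
    for it in range(len(times)):
        tau_vertex[it] = np.interp(geom.vertex_s, s, tau_ring[it])
        p_vertex[it] = np.interp(geom.vertex_s, s, p_center[it])
    wss = tau_vertex[:, :, None] * tangents[None, :, :]

    wall = WallFieldSeries(
        times=times,
        wss=wss,
        pressure=p_vertex,
        vertex_s=geom.vertex_s.copy(),
        inlet_pressure=pa_t,
        geom=geom,
    )
    vol = poiseuille_volume_series(
        geom, times, q, radial_samples=radial_samples, swirl_rate=0.0
    )
    return wall, vol


def poiseuille_volume_series(
    geom: VesselGeometry,
    times: np.ndarray,
    q: np.ndarray,
    radial_samples: int = 12,
    swirl_rate: float = 0.0,
    axial_samples: int | None = None,
) -> VolumeFieldSeries:
    """Analytic lumen velocity lattice: parabolic axial profile + rigid swirl.

    u_axial(rho; s, t) = 2 Q(t) / (pi r(s)^2) (1 - (rho/r(s))^2),
    u_theta(rho) = swirl_rate * rho.  The corresponding analytic vorticity
    (azimuthal omega_theta = 4 Q rho / (pi r^4), axial omega_z = 2*swirl_rate)
    is stored alongside for oracle use.  The lattice keeps points strictly
    inside the lumen.
    """
    if radial_samples < 4:
        raise ValidationError("radial_samples must be >= 4")
    s_grid = geom.arclength
    if axial_samples is not None:
        if axial_samples < 4:
            raise ValidationError("axial_samples must be >= 4")
        s_grid = np.linspace(s_grid[0], s_grid[-1], axial_samples)
    r_of_s = np.asarray(geom.radius_at(s_grid), dtype=float)
    ns = len(s_grid)
    nr = radial_samples
    ntheta = max(4, geom.n_circ // 4)
    # radial fractions strictly inside (0, 1): wall point would have u=0 anyway
    frac = (np.arange(nr) + 0.5) / nr
    theta = 2.0 * np.pi * np.arange(ntheta) / ntheta

    S, F, TH = np.meshgrid(s_grid, frac, theta, indexing="ij")
    R_local = np.interp(S, s_grid, r_of_s)
    RHO = F * R_local
    # embed on the straight reference axis used by synthetic tubes; for
    # generic centerlines the (s, rho, theta) parameters are authoritative
    axis_pts = np.stack(
        [RHO * np.cos(TH), RHO * np.sin(TH), S], axis=-1
    ).reshape(-1, 3)
    param_s = S.ravel()
    param_r = RHO.ravel()
    param_theta = TH.ravel()

    nt = len(times)
    npts = ns * nr * ntheta
    vel = np.empty((nt, npts, 3))
    vort = np.empty((nt, npts, 3))
    r_pt = np.interp(param_s, s_grid, r_of_s)
    e_r = np.stack([np.cos(param_theta), np.sin(param_theta), np.zeros(npts)], axis=1)
    e_t = np.stack([-np.sin(param_theta), np.cos(param_theta), np.zeros(npts)], axis=1)
    e_z = np.array([0.0, 0.0, 1.0])
    u_theta = swirl_rate * param_r
    for it in range(nt):
        u_z = 2.0 * q[it] / (np.pi * r_pt**2) * (1.0 - (param_r / r_pt) ** 2)
        vel[it] = u_z[:, None] * e_z[None, :] + u_theta[:, None] * e_t
        w_theta = 4.0 * q[it] * param_r / (np.pi * r_pt**4)
        # omega = -du_z/drho e_theta + 2*Omega e_z;  -du_z/drho = +4Q rho/(pi r^4)
        vort[it] = w_theta[:, None] * e_t + (2.0 * swirl_rate) * e_z[None, :]
    return VolumeFieldSeries(
        times=np.asarray(times, dtype=float),
        points=axis_pts,
        param_s=param_s,
        param_r=param_r,
        param_theta=param_theta,
        lattice_shape=(ns, nr, ntheta),
        velocity=vel,
        vorticity_analytic=vort,
        geom=geom,
    )


def write_field_series(
    wall: WallFieldSeries,
    vol: VolumeFieldSeries | None,
    outdir,
) -> Path:
    """Write a field series as per-timestep VTK files plus a JSON manifest."""
    from . import vtkio

    return vtkio.write_field_series(wall, vol, outdir)


def read_field_series(manifest_path) -> tuple[WallFieldSeries, VolumeFieldSeries | None]:
    """Read a field series written by :func:`write_field_series`."""
    from . import vtkio

    return vtkio.read_field_series(manifest_path)
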