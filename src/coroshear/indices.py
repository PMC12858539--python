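"""Hemodynamic indices from wall and volume field series.

Definitions (T is the retained cardiac cycle, tau_w the wall shear vector):

* TAWSS  = (1/T) int_0^T |tau_w| dt                                  [Pa]
* OSI    = 0.5 (1 - |int tau_w dt| / int |tau_w| dt)                 [0, 0.5]
* RRT    = [(1 - 2 OSI) TAWSS]^-1  (== T / |int tau_w dt|)           [1/Pa]
* WSSG   = sqrt((d tau_p / dp)^2 + (d tau_q / dq)^2) of the
  time-averaged shear in a per-vertex tangent frame (p along the mean
  shear direction, q orthogonal)                                     [Pa/m]
* GON    = 1 - |int G dt| / int |G| dt with the instantaneous gradient
  vector G(t) = (d tau_p/dp, d tau_q/dq)                             [0, 1]
* vorticity, helicity: omega = curl v and h = v . omega, magnitudes /
  signed values time-averaged over the cycle
* CT-FFR = mean distal pressure / mean aortic pressure under hyperemia

Time integration is trapezoidal on the uniform retained-cycle grid.
Surface gradients are tangent-plane least squares over structured-grid
1-ring neighbors.  Undefined values (zero shear, zero gradient, OSI = 0.5
singular RRT) are flagged as non-finite and excluded from aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import VesselGeometry
from .hemofields import HemoConfig, VolumeFieldSeries, WallFieldSeries

__all__ = [
    "IndexMaps",
    "compute_tawss",
    "compute_osi",
    "compute_rrt",
    "compute_wssg",
    "compute_gon",
    "compute_vorticity",
    "compute_helicity",
    "compute_ctffr",
    "compute_index_maps",
]


@dataclass
class IndexMaps:
    """Per-vertex / per-point index fields; non-finite entries are flagged."""

    surface: dict = field(default_factory=dict)  # name -> (Nv,) array
    volume: dict = field(default_factory=dict)  # name -> (Np,) array
    ctffr: float | None = None
    flagged_counts: dict = field(default_factory=dict)

    def flag_counts(self) -> dict:
        out = {}
        for name, arr in {**self.surface, **self.volume}.items():
            out[name] = int(np.size(arr) - np.isfinite(arr).sum())
        return out


def _check_uniform(times: np.ndarray) -> None:
    dt = np.diff(times)
    if len(dt) < 1 or np.any(np.abs(dt - dt[0]) > 1e-9 * dt[0]):
        raise ValidationError("index computation requires a uniform time grid")


def _tint(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Trapezoidal time integral along axis 0."""
    return np.trapezoid(values, times, axis=0)


def compute_tawss(wall: WallFieldSeries) -> np.ndarray:
    """Time-averaged wall shear magnitude, Pa."""
    _check_uniform(wall.times)
    mag = np.linalg.norm(wall.wss, axis=2)
    return _tint(mag, wall.times) / wall.period


def compute_osi(wall: WallFieldSeries) -> np.ndarray:
    """Oscillatory shear index in [0, 0.5]; NaN where shear vanishes."""
    _check_uniform(wall.times)
    num = np.linalg.norm(_tint(wall.wss, wall.times), axis=1)
    den = _tint(np.linalg.norm(wall.wss, axis=2), wall.times)
    osi = np.full(num.shape, np.nan)
    ok = den > 0
    osi[ok] = 0.5 * (1.0 - num[ok] / den[ok])
    return np.clip(osi, 0.0, 0.5, out=osi, where=ok)


def compute_rrt(
    tawss: np.ndarray, osi: np.ndarray, singular_tol: float = 1e-9
) -> np.ndarray:
    """Relative residence time 1/((1 - 2 OSI) TAWSS).

    Vertices where the directional factor (1 - 2 OSI) falls below
    ``singular_tol`` (fully oscillatory shear, OSI -> 0.5 up to round-off)
    are flagged as infinite; zero-shear vertices inherit NaN from OSI.
    """
    factor = 1.0 - 2.0 * osi
    denom = factor * tawss
    rrt = np.full(np.shape(denom), np.nan)
    finite = np.isfinite(denom)
    singular = finite & ((factor < singular_tol) | (denom <= 0))
    regular = finite & ~singular
    rrt[regular] = 1.0 / denom[regular]
    rrt[singular] = np.inf
    return rrt


class _SurfaceGradient:
    """Tangent-plane least-squares gradients on the structured tube grid.

    For vertex i with 1-ring neighbors j (axial and circumferential grid
    neighbors), solves  d tau ~ g . (dx . p, dx . q)  in the tangent frame
    (p, q).  The pseudo-inverse rows are precomputed once per frame so the
    same stencil applies to every timestep.
    """

    def __init__(self, geom: VesselGeometry, p: np.ndarray, q: np.ndarray):
        grid = geom.vertex_grid
        ns, nc = grid.shape
        nv = len(geom.vertices)
        nbr = np.full((nv, 4), -1, dtype=int)
        g = grid
        # axial neighbors
        nbr[g[1:, :].ravel(), 0] = g[:-1, :].ravel()
        nbr[g[:-1, :].ravel(), 1] = g[1:, :].ravel()
        # circumferential neighbors (wrap)
        nbr[g.ravel(), 2] = np.roll(g, 1, axis=1).ravel()
        nbr[g.ravel(), 3] = np.roll(g, -1, axis=1).ravel()
        self.nbr = nbr
        self.mask = nbr >= 0
        safe = np.where(self.mask, nbr, 0)
        dx = geom.vertices[safe] - geom.vertices[:, None, :]  # (Nv, 4, 3)
        A = np.stack(
            [np.einsum("vjk,vk->vj", dx, p), np.einsum("vjk,vk->vj", dx, q)], axis=2
        )  # (Nv, 4, 2)
        A = np.where(self.mask[:, :, None], A, 0.0)
        AtA = np.einsum("vja,vjb->vab", A, A)
        # regularize rank-deficient stencils (isolated vertices) -> error
        det = AtA[:, 0, 0] * AtA[:, 1, 1] - AtA[:, 0, 1] ** 2
        if np.any(det <= 0):
            raise ValidationError("degenerate 1-ring: cannot form tangent gradient")
        inv = np.empty_like(AtA)
        inv[:, 0, 0] = AtA[:, 1, 1] / det
        inv[:, 1, 1] = AtA[:, 0, 0] / det
        inv[:, 0, 1] = inv[:, 1, 0] = -AtA[:, 0, 1] / det
        self.W = np.einsum("vab,vjb->vaj", inv, A)  # (Nv, 2, 4)
        self.safe = safe
        self.p = p
        self.q = q

    def gradients(self, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(d tau_p/dp, d tau_q/dq) for shear field(s) tau of shape (..., Nv, 3)."""
        tp = np.einsum("...vk,vk->...v", tau, self.p)
        tq = np.einsum("...vk,vk->...v", tau, self.q)
        dtp = np.where(self.mask, tp[..., self.safe] - tp[..., None], 0.0)
        dtq = np.where(self.mask, tq[..., self.safe] - tq[..., None], 0.0)
        g_pp = np.einsum("vj,...vj->...v", self.W[:, 0, :], dtp)
        g_qq = np.einsum("vj,...vj->...v", self.W[:, 1, :], dtq)
        return g_pp, g_qq


def _tangent_frame(wall: WallFieldSeries, geom: VesselGeometry):
    """Per-vertex (p, q): p along the time-averaged shear, q = n x p."""
    mean_tau = _tint(wall.wss, wall.times) / wall.period  # (Nv, 3)
    axial = geom.axial_tangents()
    mag = np.linalg.norm(mean_tau, axis=1, keepdims=True)
    p = np.where(mag > 1e-14, mean_tau / np.maximum(mag, 1e-300), axial)
    # re-project onto the tangent plane for safety
    p = p - np.einsum("vk,vk->v", p, geom.normals)[:, None] * geom.normals
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    q = np.cross(geom.normals, p)
    return p, q


def compute_wssg(wall: WallFieldSeries, geom: VesselGeometry | None = None) -> np.ndarray:
    """Wall shear stress gradient magnitude of the time-averaged field, Pa/m."""
    geom = geom or wall.geom
    if geom is None:
        raise ValidationError("compute_wssg needs the vessel geometry")
    _check_uniform(wall.times)
    p, q = _tangent_frame(wall, geom)
    grad = _SurfaceGradient(geom, p, q)
    mean_tau = _tint(wall.wss, wall.times) / wall.period
    g_pp, g_qq = grad.gradients(mean_tau)
    return np.sqrt(g_pp**2 + g_qq**2)


def compute_gon(wall: WallFieldSeries, geom: VesselGeometry | None = None) -> np.ndarray:
    """Gradient oscillatory number in [0, 1]; NaN where the gradient vanishes."""
    geom = geom or wall.geom
    if geom is None:
        raise ValidationError("compute_gon needs the vessel geometry")
    _check_uniform(wall.times)
    p, q = _tangent_frame(wall, geom)
    grad = _SurfaceGradient(geom, p, q)
    g_pp, g_qq = grad.gradients(wall.wss)  # (nt, Nv) each
    G = np.stack([g_pp, g_qq], axis=-1)  # (nt, Nv, 2)
    num = np.linalg.norm(_tint(G, wall.times), axis=-1)
    den = _tint(np.linalg.norm(G, axis=-1), wall.times)
    gon = np.full(num.shape, np.nan)
    ok = den > 1e-300
    gon[ok] = 1.0 - num[ok] / den[ok]
    return np.clip(gon, 0.0, 1.0, out=gon, where=ok)


def _fd_vorticity(vol: VolumeFieldSeries) -> np.ndarray:
    """Finite-difference curl on the cylindrical (s, r, theta) lattice, (nt, Np, 3)."""
    ns, nr, ntheta = vol.lattice_shape
    nt = len(vol.times)
    s = vol.param_s.reshape(ns, nr, ntheta)[:, 0, 0]
    theta = vol.param_theta.reshape(ns, nr, ntheta)[0, 0, :]
    rr = vol.param_r.reshape(ns, nr, ntheta)
    e_r = np.stack(
        [np.cos(vol.param_theta), np.sin(vol.param_theta), np.zeros_like(vol.param_s)],
        axis=1,
    )
    e_t = np.stack(
        [-np.sin(vol.param_theta), np.cos(vol.param_theta), np.zeros_like(vol.param_s)],
        axis=1,
    )
    out = np.empty((nt, ns * nr * ntheta, 3))
    dtheta = 2.0 * np.pi / ntheta
    for it in range(nt):
        v = vol.velocity[it]
        u_r = np.einsum("pk,pk->p", v, e_r).reshape(ns, nr, ntheta)
        u_t = np.einsum("pk,pk->p", v, e_t).reshape(ns, nr, ntheta)
        u_z = v[:, 2].reshape(ns, nr, ntheta)
        # wrap-padded theta derivatives (periodic)
        dz = np.gradient(s) if ns > 1 else None

        def d_dr(f):
            g = np.empty_like(f)
            for i in range(ns):
                g[i] = np.gradient(f[i], rr[i, :, 0], axis=0, edge_order=2)
            return g

        def d_dz(f):
            if ns < 2:
                return np.zeros_like(f)
            return np.gradient(f, s, axis=0, edge_order=2)

        def d_dtheta(f):
            fp = np.concatenate([f[:, :, -1:], f, f[:, :, :1]], axis=2)
            return (fp[:, :, 2:] - fp[:, :, :-2]) / (2.0 * dtheta)

        del dz
        r_safe = np.maximum(rr, 1e-300)
        w_r = d_dtheta(u_z) / r_safe - d_dz(u_t)
        w_t = d_dz(u_r) - d_dr(u_z)
        w_z = d_dr(r_safe * u_t) / r_safe - d_dtheta(u_r) / r_safe
        out[it] = (
            w_r.reshape(-1, 1) * e_r
            + w_t.reshape(-1, 1) * e_t
            + np.stack(
                [np.zeros(ns * nr * ntheta), np.zeros(ns * nr * ntheta), w_z.ravel()],
                axis=1,
            )
        )
    return out


def _vorticity_series(vol: VolumeFieldSeries, use_analytic: bool) -> np.ndarray:
    if use_analytic:
        if vol.vorticity_analytic is None:
            raise ValidationError("no analytic vorticity stored on this series")
        return vol.vorticity_analytic
    return _fd_vorticity(vol)


def compute_vorticity(vol: VolumeFieldSeries, use_analytic: bool = False) -> np.ndarray:
    """Per-point time-averaged vorticity magnitude |curl v|, 1/s.

    Finite-difference curl on the structured lattice by default;
    ``use_analytic=True`` switches to the stored closed-form vorticity
    (oracle mode for generated series).
    """
    _check_uniform(vol.times)
    omega = _vorticity_series(vol, use_analytic)
    mag = np.linalg.norm(omega, axis=2)
    return _tint(mag, vol.times) / vol.period


def compute_helicity(vol: VolumeFieldSeries, use_analytic: bool = False) -> np.ndarray:
    """Per-point time-averaged helicity density v . (curl v), m/s^2 (signed)."""
    _check_uniform(vol.times)
    omega = _vorticity_series(vol, use_analytic)
    h = np.einsum("tpk,tpk->tp", vol.velocity, omega)
    return _tint(h, vol.times) / vol.period


def compute_ctffr(
    wall: WallFieldSeries,
    geom: VesselGeometry | None = None,
    lesion_distal_s: float = 0.0,
    cfg: HemoConfig | None = None,
) -> dict:
    """CT-FFR: mean pressure at (lesion end + distal offset) over mean inlet pressure.

    The wall series must have been computed under the hyperemic waveform.
    Returns ``{"ctffr", "s_measure", "clamped"}``; the measurement point is
    clamped to the vessel end when the 2-3 cm offset runs past it.
    """
    geom = geom or wall.geom
    cfg = cfg or HemoConfig()
    _check_uniform(wall.times)
    s_measure = lesion_distal_s + cfg.distal_offset
    s_max = float(np.max(wall.vertex_s))
    clamped = s_measure > s_max
    s_measure = min(s_measure, s_max)

    mean_p = _tint(wall.pressure, wall.times) / wall.period  # (Nv,)
    pa_mean = float(_tint(wall.inlet_pressure, wall.times) / wall.period)
    if pa_mean <= 0:
        raise ValidationError("mean aortic pressure must be positive")
    # ring-average the vertex pressures onto the s axis, then interpolate
    order = np.argsort(wall.vertex_s)
    s_sorted = wall.vertex_s[order]
    p_sorted = mean_p[order]
    uniq, inverse = np.unique(np.round(s_sorted, 12), return_inverse=True)
    p_ring = np.zeros(len(uniq))
    cnt = np.zeros(len(uniq))
    np.add.at(p_ring, inverse, p_sorted)
    np.add.at(cnt, inverse, 1.0)
    p_ring /= cnt
    pd_mean = float(np.interp(s_measure, uniq, p_ring))
    return {"ctffr": pd_mean / pa_mean, "s_measure": s_measure, "clamped": clamped}


def compute_index_maps(
    wall: WallFieldSeries,
    vol: VolumeFieldSeries | None = None,
    geom: VesselGeometry | None = None,
    hyperemic_wall: WallFieldSeries | None = None,
    lesion_distal_s: float | None = None,
    cfg: HemoConfig | None = None,
    use_analytic_vorticity: bool = False,
) -> IndexMaps:
    """Full index panel for one vessel."""
    geom = geom or wall.geom
    tawss = compute_tawss(wall)
    osi = compute_osi(wall)
    maps = IndexMaps()
    maps.surface["tawss"] = tawss
    maps.surface["osi"] = osi
    maps.surface["rrt"] = compute_rrt(tawss, osi)
    maps.surface["wssg"] = compute_wssg(wall, geom)
    maps.surface["gon"] = compute_gon(wall, geom)
    if vol is not None:
        maps.volume["vorticity_ta"] = compute_vorticity(vol, use_analytic_vorticity)
        maps.volume["helicity_ta"] = compute_helicity(vol, use_analytic_vorticity)
    if hyperemic_wall is not None and lesion_distal_s is not None:
        maps.ctffr = compute_ctffr(hyperemic_wall, geom, lesion_distal_s, cfg)["ctffr"]
    maps.flagged_counts = maps.flag_counts()
    return maps
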