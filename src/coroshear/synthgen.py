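"""Synthetic inputs: stenotic tubes, waveforms, analytic fields, cohorts.

Everything downstream of image segmentation and 3D CFD is exercised on
synthetic inputs with known closed forms:

* an axisymmetric tube whose radius narrows as a Gaussian,
  r(s) = R0 (1 - delta exp(-(s - s0)^2 / (2 sigma^2))), so a severity
  ``delta`` produces a diameter stenosis of exactly 100*delta percent;
* an offset-sinusoid flow waveform Q(t) = Qbar (1 + a sin(2 pi t / T));
* quasi-steady Poiseuille wall/volume field series (see ``hemofields``),
  optionally with a zero-mean oscillatory shear component or rigid swirl;
* a lesion-segment cohort whose progression/regression outcomes are drawn
  from logistic models on normalized hemodynamic indices with known
  generating odds ratios.

All randomness flows from a single integer seed through
``numpy.random.default_rng``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ValidationError
from .geometry import VesselGeometry
from .hemofields import (
    FlowWaveform,
    HemoConfig,
    VolumeFieldSeries,
    WallFieldSeries,
    poiseuille_volume_series,
    solve_reduced_order,
)

__all__ = [
    "StenosisSpec",
    "CohortSpec",
    "make_stenotic_vessel",
    "make_flow_waveform",
    "make_wall_field_series",
    "make_volume_field_series",
    "simulate_cohort",
]


@dataclass
class StenosisSpec:
    """Gaussian-narrowed axisymmetric stenosis.

    severity ``delta`` is the fractional radius reduction at the throat, so
    the diameter stenosis degree is 100*delta % and the area stenosis degree
    is 100*(1 - (1 - delta)^2) % by construction.
    """

    base_radius: float = 2.0e-3
    vessel_length: float = 60.0e-3
    stenosis_center: float = 30.0e-3
    stenosis_width: float = 4.0e-3
    severity: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity < 1.0:
            raise ValidationError("severity must lie in [0, 1)")
        if self.stenosis_width <= 0:
            raise ValidationError("stenosis width must be positive")
        if not 0.0 < self.stenosis_center < self.vessel_length:
            raise ValidationError("stenosis center must lie inside the vessel")
        if self.base_radius <= 0 or self.vessel_length <= 0:
            raise ValidationError("base radius and length must be positive")

    def radius_profile(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        bump = np.exp(-((s - self.stenosis_center) ** 2) / (2.0 * self.stenosis_width**2))
        return self.base_radius * (1.0 - self.severity * bump)


def make_stenotic_vessel(
    spec: StenosisSpec,
    axial_resolution: int = 120,
    circumferential_resolution: int = 32,
) -> VesselGeometry:
    """Build a watertight structured tube surface for a stenosis spec.

    The centerline runs along +z; every vertex carries its (s, angle)
    parameters, and the stored minimum radius is exactly R0 (1 - delta)
    because the axial grid is forced to include the stenosis center.
    """
    if axial_resolution < 8 or circumferential_resolution < 8:
        raise ValidationError("resolutions must be >= 8")
    n_s = axial_resolution
    n_c = circumferential_resolution
    s = np.linspace(0.0, spec.vessel_length, n_s)
    # snap the nearest grid point onto the throat so min radius is exact
    i0 = int(np.argmin(np.abs(s - spec.stenosis_center)))
    if 0 < i0 < n_s - 1:
        s[i0] = spec.stenosis_center
    r = spec.radius_profile(s)
    drds = np.gradient(r, s)

    theta = 2.0 * np.pi * np.arange(n_c) / n_c
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    verts = np.empty((n_s * n_c, 3))
    vs = np.empty(n_s * n_c)
    vang = np.empty(n_s * n_c)
    normals = np.empty((n_s * n_c, 3))
    grid = np.arange(n_s * n_c).reshape(n_s, n_c)
    for i in range(n_s):
        idx = grid[i]
        verts[idx, 0] = r[i] * cos_t
        verts[idx, 1] = r[i] * sin_t
        verts[idx, 2] = s[i]
        vs[idx] = s[i]
        vang[idx] = theta
        denom = np.sqrt(1.0 + drds[i] ** 2)
        normals[idx, 0] = cos_t / denom
        normals[idx, 1] = sin_t / denom
        normals[idx, 2] = -drds[i] / denom

    tris = []
    for i in range(n_s - 1):
        for k in range(n_c):
            k1 = (k + 1) % n_c
            a, b = grid[i, k], grid[i, k1]
            c, d = grid[i + 1, k], grid[i + 1, k1]
            tris.append((a, b, d))
            tris.append((a, d, c))
    # end caps as fans over existing rim vertices -> watertight closed surface
    for k in range(1, n_c - 1):
        tris.append((grid[0, 0], grid[0, k + 1], grid[0, k]))
        tris.append((grid[-1, 0], grid[-1, k], grid[-1, k + 1]))

    centerline = np.column_stack([np.zeros(n_s), np.zeros(n_s), s])
    return VesselGeometry(
        centerline=centerline,
        arclength=s,
        radius=r,
        vertices=verts,
        triangles=np.asarray(tris, dtype=int),
        vertex_s=vs,
        vertex_angle=vang,
        normals=normals,
        vertex_grid=grid,
        metadata={
            "base_radius": spec.base_radius,
            "severity": spec.severity,
            "stenosis_center": spec.stenosis_center,
            "stenosis_width": spec.stenosis_width,
            "min_radius": float(r.min()),
        },
    )


def make_flow_waveform(
    period: float = 0.8,
    mean_flow: float = 1.0e-6,
    pulsatility_amplitude: float = 0.5,
    samples_per_cycle: int = 48,
) -> FlowWaveform:
    """Offset-sinusoid inlet flow Q(t) = Qbar (1 + a sin(2 pi t/T)).

    The grid includes both cycle endpoints (``samples_per_cycle`` intervals),
    on which the trapezoidal time-mean is exactly ``mean_flow``.
    """
    if period <= 0 or mean_flow <= 0:
        raise ValidationError("period and mean flow must be positive")
    if not 0.0 <= pulsatility_amplitude <= 1.0:
        raise ValidationError(
            "pulsatility amplitude must lie in [0, 1] so that Q(t) >= 0"
        )
    if samples_per_cycle < 4:
        raise ValidationError("need at least 4 samples per cycle")
    t = np.linspace(0.0, period, samples_per_cycle + 1)
    q = mean_flow * (1.0 + pulsatility_amplitude * np.sin(2.0 * np.pi * t / period))
    q[-1] = q[0]  # kill periodic round-off
    return FlowWaveform(times=t, flow=q)


def make_wall_field_series(
    geom: VesselGeometry,
    waveform: FlowWaveform,
    viscosity: float = 3.5e-3,
    mode: str = "unidirectional",
    cfg: HemoConfig | None = None,
    oscillation_fraction: float = 1.0,
) -> WallFieldSeries:
    """Analytic wall shear + pressure series in one of three regimes.

    mode:
      * ``unidirectional`` — quasi-steady Poiseuille driven by Q(t);
      * ``zero_mean_oscillatory`` — the axial shear follows a zero-mean
        sinusoid of amplitude 4 mu Qbar / (pi r^3) (OSI -> 0.5 limit);
      * ``mixed`` — unidirectional axial shear plus a circumferential
        zero-mean component of relative amplitude ``oscillation_fraction``.

    The pressure series always comes from the reduced-order solve of the
    supplied waveform.
    """
    if cfg is None:
        cfg = HemoConfig(viscosity=viscosity)
    elif cfg.viscosity != viscosity:
        cfg = HemoConfig(**{**cfg.__dict__, "viscosity": viscosity})
    wall, _vol = solve_reduced_order(geom, waveform, cfg)
    if mode == "unidirectional":
        return wall

    t = wall.times
    T = wall.period
    r_v = np.asarray(geom.radius_at(geom.vertex_s), dtype=float)
    amp = 4.0 * viscosity * waveform.mean_flow / (np.pi * r_v**3)  # (Nv,)
    osc = np.sin(2.0 * np.pi * t / T)  # zero-mean over the cycle
    tangents = geom.axial_tangents()
    if mode == "zero_mean_oscillatory":
        tau = amp[None, :] * osc[:, None]
        wss = tau[:, :, None] * tangents[None, :, :]
    elif mode == "mixed":
        circ = np.cross(geom.normals, tangents)  # circumferential unit vectors
        base = np.linalg.norm(wall.wss, axis=2)  # |tau| of the unidirectional part
        extra = oscillation_fraction * amp[None, :] * osc[:, None]
        wss = (
            base[:, :, None] * tangents[None, :, :]
            + extra[:, :, None] * circ[None, :, :]
        )
    else:
        raise ValidationError(f"unknown wall-field mode: {mode!r}")
    return WallFieldSeries(
        times=t,
        wss=wss,
        pressure=wall.pressure,
        vertex_s=wall.vertex_s,
        inlet_pressure=wall.inlet_pressure,
        geom=geom,
    )


def make_volume_field_series(
    geom: VesselGeometry,
    waveform: FlowWaveform,
    swirl_rate: float = 0.0,
    radial_samples: int = 12,
    axial_samples: int | None = None,
    cycles: int = 1,
) -> VolumeFieldSeries:
    """Analytic lumen velocity lattice (parabolic axial profile + rigid swirl)."""
    del cycles  # periodic by construction; retained cycle == any cycle
    return poiseuille_volume_series(
        geom,
        waveform.times,
        waveform.flow,
        radial_samples=radial_samples,
        swirl_rate=swirl_rate,
        axial_samples=axial_samples,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: covariate panel: (column, mean, sd, positive) — moments chosen to emulate
#: reference-normalized index distributions of a lesion-segment cohort
_DEFAULT_COVARIATES = [
    ("N.Min.TAWSS", 1.27, 1.06, True),
    ("N.Max.Helicity", 1.75, 2.89, False),
    ("N.Ave.GON", 1.10, 0.52, True),
    ("N.Ave.Vorticity", 1.10, 0.59, True),
    ("N.Ave.TAWSS", 1.10, 0.66, True),
    ("N.Ave.OSI", 1.81, 2.26, True),
]

_LABELS = ("stable", "progression", "regression")


@dataclass
class CohortSpec:
    """Generating model of the synthetic lesion-segment cohort.

    One row per lesion sub-segment.  Class probabilities default to the
    observed 53/128/28 split of 209 segments (stable, progression,
    regression).  Outcomes are drawn sequentially from two one-vs-rest
    logistic models with log-odds coefficient dicts ``beta_progression``
    and ``beta_regression``; intercepts are calibrated on the drawn
    covariates so the marginal class fractions match ``class_probabilities``.
    """

    n_segments: int = 209
    n_vessels: int = 34
    n_patients: int = 22
    class_probabilities: tuple[float, float, float] = (53 / 209, 128 / 209, 28 / 209)
    covariates: list = field(default_factory=lambda: list(_DEFAULT_COVARIATES))
    correlation: np.ndarray | None = None
    beta_progression: dict = field(
        default_factory=lambda: {
            "N.Min.TAWSS": float(np.log(0.38)),
            "N.Max.Helicity": float(np.log(1.44)),
        }
    )
    beta_regression: dict = field(
        default_factory=lambda: {
            "N.Ave.GON": float(np.log(0.10)),
            "N.Ave.Vorticity": float(np.log(0.13)),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("class probabilities must be 3 values summing to 1")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            k = len(self.covariates)
            if C.shape != (k, k):
                raise ValidationError("correlation matrix shape mismatch")
            eig = np.linalg.eigvalsh((C + C.T) / 2.0)
            if eig.min() < -1e-10:
                raise ValidationError("correlation matrix must be positive semi-definite")

    def beta_vector(self, which: str) -> dict:
        return self.beta_progression if which == "progression" else self.beta_regression


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(sigmoid(alpha + eta)) == target."""

    def f(a):
        return expit(a + eta).mean() - target

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a lesion-segment cohort table with known generating effects.

    Covariates are multivariate normal on a latent scale, exponentiated where
    positivity is required (right-skewed normalized indices).  The
    progression outcome is Bernoulli with logit alpha_p + x.beta_p; rows not
    labeled progression draw regression with logit alpha_r + x.beta_r;
    the rest are stable.  The true coefficient dicts and the seed are stored
    in ``df.attrs["provenance"]``.

    ΔDS% is drawn uniformly inside the band implied by the label
    (progression >= 5, regression <= -5, stable strictly between), and
    plaque-composition volumes are positive right-skewed fillers.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_segments
    k = len(spec.covariates)
    names = [c[0] for c in spec.covariates]

    C = np.eye(k) if spec.correlation is None else np.asarray(spec.correlation, float)
    z = rng.multivariate_normal(np.zeros(k), C, size=n, method="cholesky")
    X = np.empty((n, k))
    for j, (_name, mean, sd, positive) in enumerate(spec.covariates):
        if positive:
            mu, sig = _lognormal_params(mean, sd)
            X[:, j] = np.exp(mu + sig * z[:, j])
        else:
            X[:, j] = mean + sd * z[:, j]

    df = pd.DataFrame(X, columns=names)

    p_stable, p_prog, p_reg = spec.class_probabilities
    eta_p = sum(
        beta * df[name].to_numpy() for name, beta in spec.beta_progression.items()
    )
    eta_p = np.asarray(eta_p) - float(np.mean(eta_p)) if np.ndim(eta_p) else np.zeros(n)
    alpha_p = _calibrate_intercept(eta_p, p_prog)
    is_prog = rng.random(n) < expit(alpha_p + eta_p)

    eta_r = sum(
        beta * df[name].to_numpy() for name, beta in spec.beta_regression.items()
    )
    eta_r = np.asarray(eta_r) - float(np.mean(eta_r)) if np.ndim(eta_r) else np.zeros(n)
    # conditional target so the marginal regression fraction is matched
    cond = p_reg / max(1.0 - p_prog, 1e-9)
    alpha_r = _calibrate_intercept(eta_r, cond)
    is_reg = (~is_prog) & (rng.random(n) < expit(alpha_r + eta_r))

    label = np.where(is_prog, "progression", np.where(is_reg, "regression", "stable"))
    df["label"] = label

    dds = np.empty(n)
    dds[is_prog] = rng.uniform(5.0, 20.0, is_prog.sum())
    dds[is_reg] = rng.uniform(-20.0, -5.0, is_reg.sum())
    rest = ~(is_prog | is_reg)
    dds[rest] = rng.uniform(-4.99, 4.99, rest.sum())
    df["delta_DS_percent"] = dds

    # structural ids: segments nested in vessels nested in patients
    seg_per_vessel = np.full(spec.n_vessels, n // spec.n_vessels)
    seg_per_vessel[: n % spec.n_vessels] += 1
    vessel_id = np.repeat(np.arange(spec.n_vessels), seg_per_vessel)
    ves_per_pat = np.full(spec.n_patients, spec.n_vessels // spec.n_patients)
    ves_per_pat[: spec.n_vessels % spec.n_patients] += 1
    vessel_patient = np.repeat(np.arange(spec.n_patients), ves_per_pat)
    df["vessel_id"] = vessel_id
    df["patient_id"] = vessel_patient[vessel_id]
    df["segment_id"] = np.concatenate([np.arange(c) for c in seg_per_vessel])

    # plaque morphology fillers (right-skewed positive volumes, mm^3)
    lipid = rng.lognormal(np.log(20.0), 0.6, n)
    fibrous = rng.lognormal(np.log(30.0), 0.6, n)
    calcified = rng.lognormal(np.log(10.0), 0.8, n)
    df["lipid_volume_mm3"] = lipid
    df["fibrous_volume_mm3"] = fibrous
    df["calcified_volume_mm3"] = calcified
    df["total_volume_mm3"] = lipid + fibrous + calcified
    df["noncalcified_volume_mm3"] = lipid + fibrous
    df["MLA_mm2"] = rng.lognormal(np.log(5.24), 0.45, n)
    df["lesion_length_mm"] = rng.lognormal(np.log(15.3), 0.5, n)

    df.attrs["provenance"] = {
        "seed": spec.seed,
        "beta_progression": dict(spec.beta_progression),
        "beta_regression": dict(spec.beta_regression),
        "intercept_progression": float(alpha_p),
        "intercept_regression": float(alpha_r),
        "class_probabilities": list(spec.class_probabilities),
        "eta_centering": "generating linear predictors centered at sample mean",
    }
    return df


def write_cohort(df: pd.DataFrame, csv_path, sidecar_path=None) -> None:
    """CSV plus JSON sidecar holding the generating coefficients and seed."""
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(df.attrs.get("provenance", {}), fh, indent=2)
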