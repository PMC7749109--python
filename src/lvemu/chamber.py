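"""Reduced-order left-ventricular chamber model.

A thick-walled, exactly incompressible chamber built on the constitutive
module stands in for full 3D finite-element ventricles.  It produces the
two outputs the surrogate pipeline needs:

* end-diastolic endocardial stress fields on a fixed 576-patch
  truncated-ellipsoid tessellation (passive inflation, radial equilibrium
  integrated across the wall), and
* full-cycle pressure/volume traces on a fixed 401-point time grid
  (four-phase cycle against a minimal valve + resistance-compliance
  afterload).

The wall mechanics are solved for an equivalent sphere (equatorial radius);
local stresses on the ellipsoidal surface are obtained from the spherical
solution via membrane curvature factors, and rotated into the local
fiber-sheet frame, so that stress varies smoothly with position the way an
FE field does.  Anatomical fidelity is explicitly not the goal - only a
deterministic, mechanistically grounded input-to-output map with realistic
structure and magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .constitutive import (
    KPA_PER_MMHG,
    ActiveParams,
    Kinematics,
    PassiveParams,
    active_tension,
    passive_stress,
)

__all__ = [
    "N_CENTROIDS",
    "N_TIMEPOINTS",
    "SolverError",
    "LVGeometry",
    "CirculationParams",
    "CardiacCycleTrace",
    "StressField",
    "DEFAULT_GEOMETRY",
    "DEFAULT_CIRCULATION",
    "mesh_centroids",
    "fiber_field",
    "inflate_diastole",
    "simulate_cycle",
]

#: Fixed cardinalities of the emulated finite-element outputs.
N_CENTROIDS = 576
N_TIMEPOINTS = 401

_N_RINGS = 24
_N_AZIMUTH = 24  # 24 * 24 = 576


class SolverError(RuntimeError):
    """Equilibrium or phase-transition solve failed; message carries
    diagnostics."""


@dataclass(frozen=True)
class LVGeometry:
    """Reduced chamber geometry.

    inner_radius    reference equatorial endocardial radius (mm)
    wall_thickness  reference wall thickness (mm)
    n_shells        transmural Gauss integration points (>= 3)
    helix_endo/epi  fiber helix angle bounds (degrees, endo -> epi)
    elongation      apex-base semi-axis over equatorial radius (1 = sphere)
    base_truncation fraction of the polar semi-axis where the base cuts
    sheet_tilt      sheet inclination from the transmural normal (degrees)
    """

    inner_radius: float = 25.0
    wall_thickness: float = 6.0
    n_shells: int = 8
    helix_endo: float = 60.0
    helix_epi: float = -60.0
    elongation: float = 1.6
    base_truncation: float = 0.5
    sheet_tilt: float = 45.0

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0.0 or self.inner_radius <= 0.0:
            raise ValueError("geometry dimensions must be > 0")
        if self.n_shells < 3:
            raise ValueError("n_shells must be >= 3")
        for ang in (self.helix_endo, self.helix_epi):
            if not math.isfinite(ang):
                raise ValueError("helix bounds must be finite")
        if not (0.0 < self.base_truncation < 1.0):
            raise ValueError("base_truncation must be in (0, 1)")
        if self.elongation <= 0.0:
            raise ValueError("elongation must be > 0")

    def replace(self, **kw) -> "LVGeometry":
        return replace(self, **kw)

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness

    @property
    def cavity_volume_ml(self) -> float:
        """Reference (unloaded) cavity volume of the equivalent sphere."""
        return 4.0 / 3.0 * math.pi * self.inner_radius ** 3 / 1000.0


@dataclass(frozen=True)
class CirculationParams:
    """Minimal preload/afterload description for the reduced cycle.

    Pressures in mmHg, resistances in mmHg·s/ml, compliance in ml/mmHg,
    durations in s.  The rv gains map the normalized right-ventricular
    design triplet (z-scores in [-1, 1] for Tmax, t0, l0) onto preload,
    arterial compliance and peripheral resistance so that all six sampled
    active parameters influence the trace.
    """

    preload: float = 10.0
    aortic_resistance: float = 0.02
    arterial_compliance: float = 1.8
    valve_open_pressure: float = 80.0
    peripheral_resistance: float = 1.0
    mitral_resistance: float = 0.005
    cycle_duration: float = 1.0
    rv_preload_gain: float = 0.20
    rv_compliance_gain: float = 0.20
    rv_resistance_gain: float = 0.20

    def __post_init__(self) -> None:
        for name in ("aortic_resistance", "arterial_compliance",
                     "peripheral_resistance", "mitral_resistance"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.preload < 0.0 or self.valve_open_pressure <= 0.0:
            raise ValueError("pressures must be positive")
        if self.cycle_duration <= 0.0:
            raise ValueError("cycle_duration must be > 0")

    def replace(self, **kw) -> "CirculationParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CardiacCycleTrace:
    """One simulated cardiac cycle: 401 samples of time (s), LV pressure
    (mmHg) and LV cavity volume (ml)."""

    time: np.ndarray
    pressure: np.ndarray
    volume: np.ndarray
    model_id: str = "model"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        v = np.asarray(self.volume, dtype=float)
        if not (t.shape == p.shape == v.shape == (N_TIMEPOINTS,)):
            raise ValueError(f"trace arrays must have {N_TIMEPOINTS} samples")
        if np.any(np.diff(t) <= 0.0):
            raise ValueError("time must be strictly increasing")
        if np.any(v <= 0.0):
            raise ValueError("volume must stay positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pressure", p)
        object.__setattr__(self, "volume", v)


@dataclass(frozen=True)
class StressField:
    """Endocardial stresses at the 576 patch centroids: myofiber (sigma_ff),
    cross-fiber (sigma_cc) and fiber-sheet shear (sigma_fs), in kPa."""

    centroids: np.ndarray
    sigma_ff: np.ndarray
    sigma_cc: np.ndarray
    sigma_fs: np.ndarray
    model_id: str = "model"

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        if c.shape != (N_CENTROIDS, 3):
            raise ValueError(f"centroids must be ({N_CENTROIDS}, 3)")
        for name in ("sigma_ff", "sigma_cc", "sigma_fs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_CENTROIDS,):
                raise ValueError(f"{name} must have {N_CENTROIDS} entries")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "centroids", c)


DEFAULT_GEOMETRY = LVGeometry()
DEFAULT_CIRCULATION = CirculationParams()


# ---------------------------------------------------------------------------
# surface tessellation and fiber architecture
# ---------------------------------------------------------------------------


def _u_bounds(geom: LVGeometry) -> tuple[float, float]:
    # polar parameter u: 0 at apex pole, arccos(-trunc) at the base cut;
    # a small apical cap is excluded to avoid the pole singularity.
    u_base = math.acos(-geom.base_truncation)
    u_min = 0.08 * u_base
    return u_min, u_base


def mesh_centroids(geom: LVGeometry) -> np.ndarray:
    """Deterministic tessellation of the endocardial surface into 576
    patches (24 apex-to-base rings x 24 counterclockwise azimuths);
    returns the (576, 3) patch centroids in mm in that traversal order."""
    a = geom.inner_radius
    c = geom.elongation * geom.inner_radius
    u_min, u_base = _u_bounds(geom)
    du = (u_base - u_min) / _N_RINGS
    dv = 2.0 * math.pi / _N_AZIMUTH
    out = np.empty((N_CENTROIDS, 3), dtype=float)
    k = 0
    for i in range(_N_RINGS):          # apex -> base
        u = u_min + (i + 0.5) * du
        for j in range(_N_AZIMUTH):    # counterclockwise
            v = (j + 0.5) * dv
            out[k, 0] = a * math.sin(u) * math.cos(v)
            out[k, 1] = a * math.sin(u) * math.sin(v)
            out[k, 2] = -c * math.cos(u)
            k += 1
    return out


def _surface_params(centroid: np.ndarray, geom: LVGeometry) -> tuple[float, float]:
    a = geom.inner_radius
    c = geom.elongation * geom.inner_radius
    x, y, z = centroid
    u = math.acos(min(1.0, max(-1.0, -z / c)))
    v = math.atan2(y, x)
    return u, v


def _local_basis(u: float, v: float, geom: LVGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (circumferential, meridional, outward normal) triad on
    the endocardial ellipsoid at parameters (u, v)."""
    a = geom.inner_radius
    c = geom.elongation * geom.inner_radius
    e_c = np.array([-math.sin(v), math.cos(v), 0.0])
    if math.sin(u) < 1.0e-9:
        # apex pole convention: meridian tangent of the v-meridian
        e_m = np.array([math.cos(v), math.sin(v), 0.0])
    else:
        e_m = np.array(
            [a * math.cos(u) * math.cos(v), a * math.cos(u) * math.sin(v),
             c * math.sin(u)]
        )
        e_m /= np.linalg.norm(e_m)
    n = np.cross(e_c, e_m)  # outward for this orientation
    n /= np.linalg.norm(n)
    return e_c, e_m, n


def fiber_field(
    centroid: np.ndarray, geom: LVGeometry, depth: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Reference fiber and sheet unit directions at a surface centroid.

    The fiber lies in the surface plane at the helix angle interpolated
    linearly through the wall (``depth`` 0 = endo, 1 = epi); the sheet is
    transmural, inclined by the sheet-tilt angle toward the in-plane
    normal of the fiber.  f0 and s0 are unit and mutually orthogonal.
    """
    u, v = _surface_params(np.asarray(centroid, dtype=float), geom)
    e_c, e_m, n = _local_basis(u, v, geom)
    alpha = math.radians(
        geom.helix_endo + depth * (geom.helix_epi - geom.helix_endo)
    )
    f0 = math.cos(alpha) * e_c + math.sin(alpha) * e_m
    c_perp = np.cross(n, f0)  # in-plane, perpendicular to the fiber
    beta = math.radians(geom.sheet_tilt)
    s0 = math.cos(beta) * n + math.sin(beta) * c_perp
    return f0, s0


def _curvature_weights(u: float, geom: LVGeometry) -> tuple[float, float]:
    """Membrane stress factors (meridional, circumferential) of the local
    ellipsoid surface relative to the equivalent sphere (=1 on a sphere)."""
    a = geom.inner_radius
    c = geom.elongation * geom.inner_radius
    h = math.sqrt((a * math.cos(u)) ** 2 + (c * math.sin(u)) ** 2)
    r1 = h ** 3 / (a * c)   # meridional curvature radius
    r2 = a * h / c          # second principal radius (normal to axis)
    w_m = r2 / a
    w_c = 2.0 * r2 * (1.0 - r2 / (2.0 * r1)) / a
    return w_m, w_c


# ---------------------------------------------------------------------------
# incompressible thick-wall mechanics (equivalent sphere)
# ---------------------------------------------------------------------------


def _wall_quadrature(geom: LVGeometry) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.legendre.leggauss(geom.n_shells)
    Ri, Ro = geom.inner_radius, geom.outer_radius
    R = 0.5 * (Ro - Ri) * nodes + 0.5 * (Ro + Ri)
    w = 0.5 * (Ro - Ri) * weights
    return R, w


def _shell_state(R: np.ndarray, ri: float, Ri: float) -> tuple[np.ndarray, np.ndarray]:
    """Deformed radius r(R) and in-plane stretch lam(R) for exact
    incompressibility: r^3 = R^3 + ri^3 - Ri^3."""
    r3 = R ** 3 + ri ** 3 - Ri ** 3
    r = np.cbrt(r3)
    lam = r / R
    return r, lam


def _deviatoric_radial_imbalance(p: PassiveParams, lam) -> np.ndarray:
    """g = sigma_mm + sigma_cc - 2 sigma_rr (kPa) of the deviatoric passive
    stress in the incompressible equibiaxial shell state (in-plane fiber,
    radial sheet).  Independent of the in-plane fiber angle.

    Closed form of the tensor evaluation for F = diag(lam^-2, lam, lam):
    the Lagrange/deviatoric isotropic parts cancel in g, leaving
    g = 4 psi1 (lam^2 - lam^-4) + 2 psi4f lam^2 - 4 psi4s lam^-4 with the
    energy derivatives psi_i evaluated at I1, I4f = lam^2, I4s = lam^-4.
    Verified against the full tensor path in the test suite.
    """
    lam = np.asarray(lam, dtype=float)
    lam2 = lam * lam
    lamm4 = lam2 ** -2
    i1 = lamm4 + 2.0 * lam2
    # exponents capped to keep bracketing evaluations finite; the cap is
    # far beyond any physical state (exp(500) kPa-scale stresses)
    cap = 500.0
    psi1 = 0.5 * p.a * np.exp(np.minimum(p.b * (i1 - 3.0), cap))
    e4f = lam2 - 1.0
    psi4f = p.a_f * e4f * np.exp(np.minimum(p.b_f * e4f * e4f, cap))
    e4s = lamm4 - 1.0
    psi4s = p.a_s * e4s * np.exp(np.minimum(p.b_s * e4s * e4s, cap))
    g_mpa = 4.0 * psi1 * (lam2 - lamm4) + 2.0 * psi4f * lam2 - 4.0 * psi4s * lamm4
    return g_mpa * 1000.0  # MPa -> kPa


def _active_tension_profile(
    t: float, eff: np.ndarray, act: ActiveParams
) -> np.ndarray:
    """Vectorized active fiber tension T0(t, Eff) (kPa) across shells."""
    if act.T_max == 0.0 or t < 0.0:
        return np.zeros_like(eff)
    l = act.lR * np.sqrt(np.maximum(2.0 * eff + 1.0, 0.0))
    denom_arg = np.exp(act.B * (l - act.l0)) - 1.0
    active = denom_arg > 0.0
    tr = act.m * l + act.b_relax
    active &= tr > 0.0
    t0 = act.t0
    omega = np.zeros_like(l)
    up = active & (t <= t0)
    omega[up] = math.pi * t / t0
    down = active & (t > t0) & (t <= t0 + tr)
    omega[down] = math.pi * (t - t0 + tr[down]) / tr[down]
    ct = 0.5 * (1.0 - np.cos(omega))
    frac = np.zeros_like(l)
    e50sq = np.empty_like(l)
    e50sq[active] = act.Ca0_max ** 2 / denom_arg[active]
    frac[active] = act.Ca0 ** 2 / (act.Ca0 ** 2 + e50sq[active])
    return act.T_max * frac * ct


def _cavity_pressure_passive(
    p: PassiveParams, geom: LVGeometry, ri: float
) -> float:
    """Passive transmural equilibrium: P = int_ri^ro g(r)/r dr (kPa)."""
    R, w = _wall_quadrature(geom)
    r, lam = _shell_state(R, ri, geom.inner_radius)
    g = _deviatoric_radial_imbalance(p, lam)
    # substitute dr = (R^2/r^2) dR
    return float(np.sum(w * g / r * (R ** 2 / r ** 2)))


def _cavity_pressure_active(
    act: ActiveParams, geom: LVGeometry, ri: float, t: float
) -> float:
    """Active contribution: in-plane fiber tension T0(Eff(r), t) adds
    T0/r to the radial-equilibrium integrand (kPa)."""
    if act.T_max == 0.0:
        return 0.0
    R, w = _wall_quadrature(geom)
    r, lam = _shell_state(R, ri, geom.inner_radius)
    eff = 0.5 * (lam ** 2 - 1.0)
    T0 = _active_tension_profile(t, eff, act)
    return float(np.sum(w * T0 / r * (R ** 2 / r ** 2)))


def _ri_from_volume(v_ml: float) -> float:
    return (3.0 * v_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def _volume_from_ri(ri: float) -> float:
    return 4.0 / 3.0 * math.pi * ri ** 3 / 1000.0


def _solve_inflation(
    p: PassiveParams, geom: LVGeometry, edp_mmhg: float
) -> float:
    """Inner stretch (deformed inner radius, mm) balancing the
    end-diastolic pressure, to 1e-6 mmHg."""
    if edp_mmhg < 0.0:
        raise ValueError("edp must be >= 0")
    Ri = geom.inner_radius
    if edp_mmhg == 0.0:
        return Ri
    edp_kpa = edp_mmhg * KPA_PER_MMHG

    def resid(lam_i: float) -> float:
        return _cavity_pressure_passive(p, geom, lam_i * Ri) - edp_kpa

    lo = 1.0 + 1.0e-9
    flo = resid(lo)
    if flo > 0.0:
        raise SolverError(
            f"no equilibrium root: resid({lo:.3g}) = {flo:.3g} kPa > 0 "
            f"at edp = {edp_mmhg:.3g} mmHg"
        )
    hi, fhi = 1.1, resid(1.1)
    while fhi < 0.0:
        hi *= 1.25
        if hi > 4.0:
            raise SolverError(
                "no equilibrium root in inner-stretch bracket [1, 4] "
                f"at edp = {edp_mmhg:.3g} mmHg (last resid {fhi:.3g} kPa)"
            )
        fhi = resid(hi)
    lam_i = brentq(resid, lo, hi, xtol=1.0e-12, rtol=8.9e-16)
    return lam_i * Ri


def inflate_diastole(
    p: PassiveParams, geom: LVGeometry = DEFAULT_GEOMETRY,
    edp: float = 10.0, model_id: str = "model"
) -> StressField:
    """Passive diastolic inflation to the end-diastolic pressure ``edp``
    (mmHg); returns the endocardial stress field at the 576 centroids.

    Solves radial equilibrium of the incompressible thick-walled chamber
    for the equivalent sphere, then maps endocardial stresses onto the
    truncated-ellipsoid surface with membrane curvature factors and
    rotates them into the local fiber-sheet frame.
    """
    cents = mesh_centroids(geom)
    if edp == 0.0:
        z = np.zeros(N_CENTROIDS)
        return StressField(centroids=cents, sigma_ff=z, sigma_cc=z.copy(),
                           sigma_fs=z.copy(), model_id=model_id)
    ri = _solve_inflation(p, geom, edp)
    lam_i = ri / geom.inner_radius
    edp_kpa = edp * KPA_PER_MMHG

    # full endocardial Cauchy stress in the (radial, meridional,
    # circumferential) frame, Lagrange pressure fixed by sigma_rr = -edp
    alpha = math.radians(geom.helix_endo)
    F = np.diag([lam_i ** -2, lam_i, lam_i])
    f0_loc = np.array([0.0, math.sin(alpha), math.cos(alpha)])
    s0_loc = np.array([1.0, 0.0, 0.0])
    kin = Kinematics(F=F, f0=f0_loc, s0=s0_loc)
    sig_hat = passive_stress(p, kin, volumetric=False).sigma
    sig = sig_hat - (sig_hat[0, 0] + edp_kpa) * np.eye(3)

    beta = math.radians(geom.sheet_tilt)
    # deformed fiber direction stays in-plane under equibiaxial stretch
    f_loc = f0_loc
    c_perp = np.array([0.0, math.cos(alpha), -math.sin(alpha)])
    s_loc = math.cos(beta) * np.array([1.0, 0.0, 0.0]) + math.sin(beta) * c_perp
    x_loc = np.cross(s_loc, f_loc)  # cross-fiber direction

    sff = np.empty(N_CENTROIDS)
    scc = np.empty(N_CENTROIDS)
    sfs = np.empty(N_CENTROIDS)
    for k in range(N_CENTROIDS):
        u, _ = _surface_params(cents[k], geom)
        w_m, w_c = _curvature_weights(u, geom)
        loc = sig.copy()
        loc[1, 1] *= w_m
        loc[2, 2] *= w_c
        s_mc = math.sqrt(max(w_m * w_c, 0.0))
        loc[1, 2] *= s_mc
        loc[2, 1] *= s_mc
        loc[0, 1] *= 1.0  # radial row unweighted
        sff[k] = f_loc @ loc @ f_loc
        scc[k] = x_loc @ loc @ x_loc
        sfs[k] = f_loc @ loc @ s_loc
    return StressField(centroids=cents, sigma_ff=sff, sigma_cc=scc,
                       sigma_fs=sfs, model_id=model_id)


# ---------------------------------------------------------------------------
# full-cycle simulation
# ---------------------------------------------------------------------------


def _effective_circulation(
    circ: CirculationParams, rv_z: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Preload, compliance and peripheral resistance perturbed by the
    normalized RV triplet (z_tmax, z_t0, z_l0), each in [-1, 1]."""
    z_tmax, z_t0, z_l0 = (max(-1.0, min(1.0, z)) for z in rv_z)
    preload = circ.preload * (1.0 + circ.rv_preload_gain * z_tmax)
    compliance = circ.arterial_compliance * (1.0 + circ.rv_compliance_gain * z_t0)
    rp = circ.peripheral_resistance * (1.0 + circ.rv_resistance_gain * z_l0)
    return preload, compliance, rp


class _ChamberPressure:
    """Cached pressure map of one (passive, geometry, active) triplet.

    The passive cavity pressure is tabulated densely over the inner
    stretch once (it is one-dimensional and smooth); the active
    contribution is integrated across the wall at call time because it
    depends on both volume and the activation clock.
    """

    def __init__(self, p: PassiveParams, act: ActiveParams, geom: LVGeometry):
        self.p, self.act, self.geom = p, act, geom
        self.Ri = geom.inner_radius
        self.R, self.w = _wall_quadrature(geom)
        lam_grid = np.linspace(0.70, 2.2, 1600)
        self._lam_grid = lam_grid
        self._p_pas = np.array(
            [_cavity_pressure_passive(p, geom, l * self.Ri) for l in lam_grid]
        )

    def passive_mmhg(self, ri: float) -> float:
        lam = ri / self.Ri
        if lam < self._lam_grid[0] or lam > self._lam_grid[-1]:
            return _cavity_pressure_passive(self.p, self.geom, ri) / KPA_PER_MMHG
        return float(np.interp(lam, self._lam_grid, self._p_pas)) / KPA_PER_MMHG

    def total_mmhg(self, v_ml: float, t: float) -> float:
        ri = _ri_from_volume(v_ml)
        plv = self.passive_mmhg(ri)
        act = self.act
        if act.T_max > 0.0:
            r3 = self.R ** 3 + ri ** 3 - self.Ri ** 3
            r = np.cbrt(r3)
            lam = r / self.R
            eff = 0.5 * (lam * lam - 1.0)
            T0 = _active_tension_profile(t, eff, act)
            pa_kpa = float(np.sum(self.w * T0 / r * (self.R ** 2 / (r * r))))
            plv += pa_kpa / KPA_PER_MMHG
        return plv


def simulate_cycle(
    act_lv: ActiveParams,
    rv_z: tuple[float, float, float] = (0.0, 0.0, 0.0),
    p: PassiveParams | None = None,
    circ: CirculationParams = DEFAULT_CIRCULATION,
    geom: LVGeometry = DEFAULT_GEOMETRY,
    model_id: str = "model",
    n_substeps: int = 6,
) -> CardiacCycleTrace:
    """Simulate one cardiac cycle on the fixed 401-point time grid.

    Four phases emerge from one-way valve flows: passive filling holds the
    chamber at the (RV-perturbed) preload, isovolumic contraction raises
    pressure at fixed volume once active tension develops, ejection drives
    flow through the aortic resistance into the compliant artery when LV
    pressure exceeds arterial pressure, and isovolumic relaxation closes
    the loop before late filling restores the end-diastolic state.
    Deterministic: no internal randomness.
    """
    from .constitutive import DEFAULT_PASSIVE

    if p is None:
        p = DEFAULT_PASSIVE
    # the activation window must fit inside the cycle or the loop cannot
    # close; tr is taken at the stress-free sarcomere length
    tr_nominal = act_lv.m * act_lv.lR + act_lv.b_relax
    if tr_nominal > 0.0 and act_lv.t0 + tr_nominal >= circ.cycle_duration:
        raise ValueError(
            f"cycle duration {circ.cycle_duration} s must exceed "
            f"t0 + tr = {act_lv.t0 + tr_nominal:.3f} s"
        )
    preload, compliance, rp = _effective_circulation(circ, rv_z)

    Ri = geom.inner_radius
    ri_ed = _solve_inflation(p, geom, preload) if preload > 0.0 else Ri
    v_ed = _volume_from_ri(ri_ed)

    p_lv = _ChamberPressure(p, act_lv, geom).total_mmhg

    T = circ.cycle_duration
    tgrid = np.linspace(0.0, T, N_TIMEPOINTS)
    dt = (tgrid[1] - tgrid[0]) / n_substeps

    v = v_ed
    pa = circ.valve_open_pressure
    pressure = np.empty(N_TIMEPOINTS)
    volume = np.empty(N_TIMEPOINTS)
    pressure[0] = p_lv(v, 0.0)
    volume[0] = v

    def rates(v_: float, pa_: float, t_: float) -> tuple[float, float, float]:
        plv = p_lv(v_, t_)
        q_out = max(plv - pa_, 0.0) / circ.aortic_resistance
        q_in = max(preload - plv, 0.0) / circ.mitral_resistance
        dv = q_in - q_out
        dpa = (q_out - pa_ / rp) / compliance
        return dv, dpa, plv

    t = 0.0
    for i in range(1, N_TIMEPOINTS):
        for _ in range(n_substeps):
            # classic RK4 on (V, Pa)
            k1v, k1p, _ = rates(v, pa, t)
            k2v, k2p, _ = rates(v + 0.5 * dt * k1v, pa + 0.5 * dt * k1p, t + 0.5 * dt)
            k3v, k3p, _ = rates(v + 0.5 * dt * k2v, pa + 0.5 * dt * k2p, t + 0.5 * dt)
            k4v, k4p, _ = rates(v + dt * k3v, pa + dt * k3p, t + dt)
            v += dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            pa += dt / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            t += dt
            if not (math.isfinite(v) and math.isfinite(pa)) or v <= 0.0:
                raise SolverError(
                    f"cycle integration diverged at t = {t:.4f} s "
                    f"(V = {v:.4g} ml, Pa = {pa:.4g} mmHg)"
                )
        t = tgrid[i]  # avoid accumulation drift
        pressure[i] = p_lv(v, t)
        volume[i] = v

    return CardiacCycleTrace(time=tgrid, pressure=pressure, volume=volume,
                             model_id=model_id)
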