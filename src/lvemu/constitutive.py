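"""Myocardial constitutive model.

Passive behaviour follows the anisotropic hyperelastic (Holzapfel–Ogden-type)
strain energy with isotropic, fiber, sheet and fiber–sheet coupling terms,

    Psi_dev = a/(2b) exp[b(I1 - 3)]
            + sum_{i=f,s} a_i/(2b_i) {exp[b_i (I4i - 1)^2] - 1}
            + a_fs/(2b_fs) {exp[b_fs I8fs^2] - 1}
    Psi_vol = (1/D) ((J^2 - 1)/2 - ln J),

with the invariants I1 = tr(C), I4i = C:(e0 ⊗ e0), I8fs = C:sym(f0 ⊗ s0)
of the right Cauchy–Green tensor C = F^T F and J = det F.  The deviatoric
part is evaluated on the isochoric invariants (the J^{-2/3}-weighted
invariants of C̄ = J^{-2/3} C), the standard nearly-incompressible
completion; it coincides with the plain form wherever J = 1 and makes the
reference configuration exactly stress free.

Active contraction is a time-varying elastance law on the sarcomere scale:

    T0 = Tmax · Ca0^2 / (Ca0^2 + ECa50^2) · Ct

with the cosine activation waveform Ct(t) rising to 1 at the time to peak
tension t0 and relaxing over the length-dependent duration tr = m·l + b,
and the length-dependent calcium sensitivity

    ECa50 = Ca0_max / sqrt(exp[B (l - l0)] - 1),   l = lR sqrt(2 Eff + 1).

Moduli are supplied in MPa as is conventional for this law; stresses are
returned in kPa, the unit in which ventricular wall stress is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KPA_PER_MPA",
    "KPA_PER_MMHG",
    "InvalidKinematicsError",
    "InvalidParametersError",
    "LengthBelowActivationError",
    "PassiveParams",
    "ActiveParams",
    "Kinematics",
    "InvariantSet",
    "StressTensor",
    "DEFAULT_PASSIVE",
    "DEFAULT_ACTIVE",
    "BASELINE_TMAX_KPA",
    "compute_invariants",
    "passive_energy",
    "passive_stress",
    "sarcomere_length",
    "relaxation_duration",
    "ct_activation",
    "eca50",
    "active_tension",
    "total_stress",
]

KPA_PER_MPA = 1000.0
KPA_PER_MMHG = 0.1333224

#: Baseline isometric tension (kPa) multiplied by the dimensionless Tmax
#: design factor.  Conventional Guccione-model value; not printed in the
#: study this package emulates.
BASELINE_TMAX_KPA = 135.7


class InvalidKinematicsError(ValueError):
    """Deformation state is inadmissible (det F <= 0, bad directions)."""


class InvalidParametersError(ValueError):
    """Material parameters violate their admissibility constraints."""


class LengthBelowActivationError(ValueError):
    """Sarcomere length at or below l0: calcium sensitivity undefined."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PassiveParams:
    """Passive moduli.  Stiffnesses in MPa, exponents dimensionless,
    compressibility D = 2/K in MPa^-1 (K = bulk modulus)."""

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float
    D: float

    def __post_init__(self) -> None:
        for name in ("a", "a_f", "a_s", "a_fs"):
            if getattr(self, name) < 0.0:
                raise InvalidParametersError(f"stiffness {name} must be >= 0")
        for name in ("b", "b_f", "b_s", "b_fs"):
            if getattr(self, name) <= 0.0:
                raise InvalidParametersError(f"exponent {name} must be > 0")
        if self.D <= 0.0:
            raise InvalidParametersError("compressibility D must be > 0")

    def replace(self, **kw) -> "PassiveParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ActiveParams:
    """Active-contraction parameters.

    T_max   isometric tension scale (kPa)
    Ca0     peak intracellular calcium (uM)
    Ca0_max maximum peak calcium (uM)
    B       shape constant of the tension-length relation (1/um)
    l0      sarcomere length producing no active stress (um)
    lR      stress-free sarcomere length (um)
    t0      time to peak tension (s)
    m, b_relax  slope (s/um) and intercept (s) of tr = m l + b
    """

    T_max: float
    Ca0: float
    Ca0_max: float
    B: float
    l0: float
    lR: float
    t0: float
    m: float
    b_relax: float

    def __post_init__(self) -> None:
        if self.T_max < 0.0:
            raise InvalidParametersError("T_max must be >= 0")
        if self.l0 <= 0.0 or self.lR <= 0.0:
            raise InvalidParametersError("sarcomere lengths must be > 0")
        if self.t0 <= 0.0:
            raise InvalidParametersError("t0 must be > 0")
        if self.Ca0 <= 0.0 or self.Ca0_max <= 0.0:
            raise InvalidParametersError("calcium concentrations must be > 0")

    def replace(self, **kw) -> "ActiveParams":
        return replace(self, **kw)

    @classmethod
    def from_design(cls, l0: float, t0: float, tmax: float) -> "ActiveParams":
        """Build from one sampled design triplet.

        ``l0`` is in millimetres (design range 0.0015-0.0028 mm, i.e.
        1.5-2.8 um), ``t0`` in seconds, ``tmax`` a dimensionless
        multiplier on the baseline isometric tension of 135.7 kPa.
        """
        return DEFAULT_ACTIVE.replace(
            l0=l0 * 1.0e3, t0=t0, T_max=tmax * BASELINE_TMAX_KPA
        )


# Default profiles.  Values the emulated study does not print are this
# package's choices: the active constants are conventional Guccione-model
# values; the passive profile is calibrated (in-vivo-literature softness
# class) so the reduced chamber reaches a physiological end-diastolic
# volume near 10 mmHg.  All are overridable everywhere.
DEFAULT_PASSIVE = PassiveParams(
    a=0.64e-3, b=4.0,
    a_f=4.8e-3, b_f=6.0,
    a_s=1.12e-3, b_s=4.0,
    a_fs=0.8e-3, b_fs=4.0,
    D=2.0 / 100.0,  # K = 100 MPa, near incompressible
)

DEFAULT_ACTIVE = ActiveParams(
    T_max=BASELINE_TMAX_KPA,
    Ca0=4.35, Ca0_max=4.35,
    B=4.75, l0=1.58, lR=2.1,
    t0=0.1625,
    m=0.5, b_relax=-0.6,
)


# ---------------------------------------------------------------------------
# kinematics and invariants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Kinematics:
    """Deformation state at a material point: deformation gradient F and
    reference fiber/sheet unit directions f0, s0 (mutually orthogonal)."""

    F: np.ndarray
    f0: np.ndarray
    s0: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        f0 = np.asarray(self.f0, dtype=float)
        s0 = np.asarray(self.s0, dtype=float)
        if F.shape != (3, 3):
            raise InvalidKinematicsError("F must be 3x3")
        if np.linalg.det(F) <= 0.0:
            raise InvalidKinematicsError("det F must be > 0")
        for name, v in (("f0", f0), ("s0", s0)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise InvalidKinematicsError(f"{name} must be a unit vector")
        if abs(float(f0 @ s0)) > 1e-8:
            raise InvalidKinematicsError("f0 and s0 must be orthogonal")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "f0", f0)
        object.__setattr__(self, "s0", s0)


@dataclass(frozen=True)
class InvariantSet:
    I1: float
    I4f: float
    I4s: float
    I8fs: float
    J: float


@dataclass(frozen=True)
class StressTensor:
    """Symmetric Cauchy stress in kPa."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        s = 0.5 * (s + s.T)  # symmetrize exactly
        object.__setattr__(self, "sigma", s)


def compute_invariants(kin: Kinematics) -> InvariantSet:
    """Invariants of C = F^T F: I1 = tr C, I4f, I4s, I8fs and J = det F."""
    F = kin.F
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidKinematicsError("det F must be > 0")
    C = F.T @ F
    f0, s0 = kin.f0, kin.s0
    return InvariantSet(
        I1=float(np.trace(C)),
        I4f=float(f0 @ C @ f0),
        I4s=float(s0 @ C @ s0),
        I8fs=float(f0 @ C @ s0),
        J=J,
    )


# ---------------------------------------------------------------------------
# passive energy and stress
# ---------------------------------------------------------------------------


def passive_energy(
    p: PassiveParams, inv: InvariantSet, isochoric: bool = True
) -> tuple[float, float]:
    """Deviatoric and volumetric strain-energy densities (MPa).

    With ``isochoric=True`` (default) the deviatoric part is evaluated on
    the isochoric invariants J^{-2/3} I; with ``isochoric=False`` it uses
    the invariants as supplied.  The two coincide at J = 1.
    """
    if inv.J <= 0.0:
        raise InvalidKinematicsError("J must be > 0")
    w = inv.J ** (-2.0 / 3.0) if isochoric else 1.0
    i1 = w * inv.I1
    i4f = w * inv.I4f
    i4s = w * inv.I4s
    i8 = w * inv.I8fs
    psi_dev = p.a / (2.0 * p.b) * math.exp(p.b * (i1 - 3.0))
    psi_dev += p.a_f / (2.0 * p.b_f) * (math.exp(p.b_f * (i4f - 1.0) ** 2) - 1.0)
    psi_dev += p.a_s / (2.0 * p.b_s) * (math.exp(p.b_s * (i4s - 1.0) ** 2) - 1.0)
    psi_dev += p.a_fs / (2.0 * p.b_fs) * (math.exp(p.b_fs * i8 * i8) - 1.0)
    psi_vol = (1.0 / p.D) * ((inv.J ** 2 - 1.0) / 2.0 - math.log(inv.J))
    return psi_dev, psi_vol


def _fictitious_pk2(p: PassiveParams, C_bar: np.ndarray, f0: np.ndarray,
                    s0: np.ndarray) -> np.ndarray:
    """S̃ = 2 dPsi_dev/dC̄ evaluated at the isochoric C̄ (MPa)."""
    i1 = float(np.trace(C_bar))
    i4f = float(f0 @ C_bar @ f0)
    i4s = float(s0 @ C_bar @ s0)
    i8 = float(f0 @ C_bar @ s0)
    psi1 = 0.5 * p.a * math.exp(p.b * (i1 - 3.0))
    psi4f = p.a_f * (i4f - 1.0) * math.exp(p.b_f * (i4f - 1.0) ** 2)
    psi4s = p.a_s * (i4s - 1.0) * math.exp(p.b_s * (i4s - 1.0) ** 2)
    psi8 = p.a_fs * i8 * math.exp(p.b_fs * i8 * i8)
    ff = np.outer(f0, f0)
    ss = np.outer(s0, s0)
    fs = 0.5 * (np.outer(f0, s0) + np.outer(s0, f0))
    return 2.0 * (psi1 * np.eye(3) + psi4f * ff + psi4s * ss + psi8 * fs)


def passive_stress(
    p: PassiveParams, kin: Kinematics, volumetric: bool = True
) -> StressTensor:
    """Passive Cauchy stress sigma = (2/J) F (dPsi/dC) F^T in kPa.

    The deviatoric contribution uses the isochoric split, so the reference
    configuration is exactly stress free.  ``volumetric=False`` omits the
    penalty term Psi_vol (used by the incompressible chamber solve, which
    carries its own Lagrange pressure instead).
    """
    F = kin.F
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidKinematicsError("det F must be > 0")
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    w = J ** (-2.0 / 3.0)
    C_bar = w * C
    S_tilde = _fictitious_pk2(p, C_bar, kin.f0, kin.s0)
    # Deviatoric projection in the reference configuration:
    # S_iso = J^{-2/3} [ S̃ - (S̃:C)/3 C^{-1} ]
    S_iso = w * (S_tilde - (float(np.tensordot(S_tilde, C)) / 3.0) * Cinv)
    S = S_iso
    if volumetric:
        dpsi_vol = (1.0 / p.D) * (J - 1.0 / J)
        S = S + dpsi_vol * J * Cinv
    sigma_mpa = (F @ S @ F.T) / J
    return StressTensor(sigma=sigma_mpa * KPA_PER_MPA)


# ---------------------------------------------------------------------------
# active contraction
# ---------------------------------------------------------------------------


def sarcomere_length(Eff: float, act: ActiveParams) -> float:
    """l = lR sqrt(2 Eff + 1) (um) from the Lagrangian fiber strain."""
    arg = 2.0 * Eff + 1.0
    if arg <= 0.0:
        raise InvalidParametersError("2*Eff + 1 must be > 0")
    return act.lR * math.sqrt(arg)


def relaxation_duration(l: float, act: ActiveParams) -> float:
    """tr = m l + b (s); must be positive to be admissible."""
    tr = act.m * l + act.b_relax
    if tr <= 0.0:
        raise InvalidParametersError(
            f"relaxation duration tr = {tr:.4g} s must be > 0 (l = {l:.4g} um)"
        )
    return tr


def ct_activation(t: float, act: ActiveParams, l: float) -> float:
    """Cosine activation waveform Ct(t) in [0, 1].

    omega = pi t/t0 on the upstroke (0 <= t <= t0), pi (t - t0 + tr)/tr on
    the relaxation limb (t0 <= t <= t0 + tr), and 0 afterwards.
    """
    if t < 0.0:
        raise InvalidParametersError("t must be >= 0")
    tr = relaxation_duration(l, act)
    if t <= act.t0:
        omega = math.pi * t / act.t0
    elif t <= act.t0 + tr:
        omega = math.pi * (t - act.t0 + tr) / tr
    else:
        omega = 0.0
    return 0.5 * (1.0 - math.cos(omega))


def eca50(Eff: float, act: ActiveParams) -> float:
    """Length-dependent calcium sensitivity (uM); requires l > l0."""
    l = sarcomere_length(Eff, act)
    denom_arg = math.exp(act.B * (l - act.l0)) - 1.0
    if denom_arg <= 0.0:
        raise LengthBelowActivationError(
            f"sarcomere length {l:.4g} um at or below l0 = {act.l0:.4g} um"
        )
    return act.Ca0_max / math.sqrt(denom_arg)


def active_tension(t: float, Eff: float, act: ActiveParams) -> float:
    """Active fiber tension T0(t, Eff) in kPa.

    T0 = Tmax Ca0^2/(Ca0^2 + ECa50^2) Ct; zero below the activation length
    l0 and outside the activation window.
    """
    if t < 0.0:
        raise InvalidParametersError("t must be >= 0")
    try:
        e50 = eca50(Eff, act)
    except LengthBelowActivationError:
        return 0.0
    l = sarcomere_length(Eff, act)
    ct = ct_activation(t, act, l)
    return act.T_max * act.Ca0 ** 2 / (act.Ca0 ** 2 + e50 * e50) * ct


def total_stress(
    p: PassiveParams, act: ActiveParams, kin: Kinematics, t: float
) -> StressTensor:
    """Total Cauchy stress: passive part plus active tension acting along
    the deformed fiber direction f = F f0."""
    sig_p = passive_stress(p, kin).sigma
    inv = compute_invariants(kin)
    Eff = 0.5 * (inv.I4f - 1.0)
    T0 = active_tension(t, Eff, act)
    f = kin.F @ kin.f0
    sig_a = T0 * np.outer(f, f) / float(f @ f)
    return StressTensor(sigma=sig_p + sig_a)
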