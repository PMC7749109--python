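"""Constitutive law: invariants, passive energy/stress, active kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvemu.constitutive import (
    DEFAULT_ACTIVE,
    DEFAULT_PASSIVE,
    ActiveParams,
    InvalidKinematicsError,
    InvalidParametersError,
    InvariantSet,
    Kinematics,
    LengthBelowActivationError,
    PassiveParams,
    active_tension,
    compute_invariants,
    ct_activation,
    eca50,
    passive_energy,
    passive_stress,
    sarcomere_length,
    total_stress,
)
from conftest import random_kinematics

F0 = np.array([1.0, 0.0, 0.0])
S0 = np.array([0.0, 1.0, 0.0])


class TestInvariants:
    @pytest.mark.parametrize(
        "F, expect",
        [
            (np.eye(3), dict(I1=3.0, I4f=1.0, I4s=1.0, I8fs=0.0, J=1.0)),
            (np.diag([2.0, 1.0, 1.0]), dict(I1=6.0, I4f=4.0, J=2.0)),
        ],
    )
    def test_reference_values(self, F, expect):
        inv = compute_invariants(Kinematics(F=F, f0=F0, s0=S0))
        for k, v in expect.items():
            assert getattr(inv, k) == pytest.approx(v, abs=1e-14)

    def test_off_diagonal_coupling_reads_c12(self):
        # construct F with F^T F having C12 = 0.3
        C = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.0], [0.0, 0.0, 1.0]])
        w, V = np.linalg.eigh(C)
        F = V @ np.diag(np.sqrt(w)) @ V.T
        inv = compute_invariants(Kinematics(F=F, f0=F0, s0=S0))
        assert inv.I8fs == pytest.approx(0.3, abs=1e-12)

    def test_singular_deformation_rejected(self):
        with pytest.raises(InvalidKinematicsError):
            Kinematics(F=np.diag([1.0, 1.0, 0.0]), f0=F0, s0=S0)

    def test_nonunit_fiber_rejected(self):
        with pytest.raises(InvalidKinematicsError):
            Kinematics(F=np.eye(3), f0=2 * F0, s0=S0)


class TestPassiveEnergy:
    def test_reference_state_offset(self, passive):
        inv = compute_invariants(Kinematics(F=np.eye(3), f0=F0, s0=S0))
        psi_dev, psi_vol = passive_energy(passive, inv)
        assert psi_dev == pytest.approx(passive.a / (2 * passive.b))
        assert psi_vol == 0.0

    def test_fiber_terms_vanish_at_unit_stretch(self, passive):
        # isochoric states with I4f = 1, I8fs = 0: fiber/coupling terms zero
        for i1 in (3.0, 3.5, 4.2):
            inv = InvariantSet(I1=i1, I4f=1.0, I4s=1.0, I8fs=0.0, J=1.0)
            psi_dev, _ = passive_energy(passive, inv)
            iso_only = passive.a / (2 * passive.b) * math.exp(
                passive.b * (i1 - 3.0)
            )
            assert psi_dev == pytest.approx(iso_only, rel=1e-14)

    def test_matches_high_precision_reference(self, passive, rng):
        # oracle: direct re-evaluation of the energy expression with
        # mpmath-free extended precision via fractions of float ops is
        # overkill; use independent numpy-free formula at J=1 states
        kin = random_kinematics(rng)
        F = kin.F / np.linalg.det(kin.F) ** (1 / 3)  # force J = 1
        kin = Kinematics(F=F, f0=kin.f0, s0=kin.s0)
        inv = compute_invariants(kin)
        psi_dev, psi_vol = passive_energy(passive, inv)
        p = passive
        expect = (
            p.a / (2 * p.b) * math.exp(p.b * (inv.I1 - 3.0))
            + p.a_f / (2 * p.b_f)
            * (math.exp(p.b_f * (inv.I4f - 1.0) ** 2) - 1.0)
            + p.a_s / (2 * p.b_s)
            * (math.exp(p.b_s * (inv.I4s - 1.0) ** 2) - 1.0)
            + p.a_fs / (2 * p.b_fs)
            * (math.exp(p.b_fs * inv.I8fs ** 2) - 1.0)
        )
        assert psi_dev == pytest.approx(expect, rel=1e-12)
        assert psi_vol == pytest.approx(0.0, abs=1e-12)

    def test_volumetric_term_positive_away_from_unity(self, passive):
        for J in (0.8, 0.95, 1.05, 1.3):
            inv = InvariantSet(I1=3.0, I4f=1.0, I4s=1.0, I8fs=0.0, J=J)
            assert passive_energy(passive, inv)[1] > 0.0
        inv1 = InvariantSet(I1=3.0, I4f=1.0, I4s=1.0, I8fs=0.0, J=1.0)
        assert passive_energy(passive, inv1)[1] == 0.0

    def test_invalid_j_rejected(self, passive):
        inv = InvariantSet(I1=3.0, I4f=1.0, I4s=1.0, I8fs=0.0, J=-1.0)
        with pytest.raises(InvalidKinematicsError):
            passive_energy(passive, inv)


class TestPassiveStress:
    def test_reference_configuration_stress_free(self, passive):
        sig = passive_stress(passive, Kinematics(F=np.eye(3), f0=F0, s0=S0))
        assert np.abs(sig.sigma).max() < 1e-12

    def test_stress_free_for_parameter_draws(self, rng):
        from lvemu.doe import PASSIVE_RANGES

        kin = Kinematics(F=np.eye(3), f0=F0, s0=S0)
        for _ in range(20):
            draws = {k: rng.uniform(*v) for k, v in PASSIVE_RANGES.items()}
            p = DEFAULT_PASSIVE.replace(**draws)
            assert np.abs(passive_stress(p, kin).sigma).max() < 1e-12

    def test_finite_difference_consistency(self, passive, rng):
        """sigma = (1/J) dPsi/dF F^T checked against central differences
        of the energy on random admissible states."""
        h = 1e-6
        for _ in range(100):
            kin = random_kinematics(rng)
            sig = passive_stress(passive, kin).sigma  # kPa
            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    def _psi(dF):
                        Fp = kin.F.copy()
                        Fp[i, j] += dF
                        invp = compute_invariants(
                            Kinematics(F=Fp, f0=kin.f0, s0=kin.s0))
                        return sum(passive_energy(passive, invp))
                    P[i, j] = (_psi(h) - _psi(-h)) / (2 * h)
            sig_fd = P @ kin.F.T / np.linalg.det(kin.F) * 1000.0
            denom = max(np.abs(sig_fd).max(), 1e-8)
            assert np.abs(sig - sig_fd).max() / denom < 1e-5

    def test_symmetry(self, passive, rng):
        kin = random_kinematics(rng)
        sig = passive_stress(passive, kin).sigma
        assert np.abs(sig - sig.T).max() == 0.0

    def test_fiber_stiffness_orders_normal_stresses(self):
        """Equibiaxial stretch with a_f >> a_s loads the fiber direction
        harder than the sheet direction."""
        p = DEFAULT_PASSIVE.replace(a_f=10 * DEFAULT_PASSIVE.a_s,
                                    a_s=DEFAULT_PASSIVE.a_s)
        lam = 1.1
        F = np.diag([lam, lam, 1.0 / lam ** 2])
        kin = Kinematics(F=F, f0=F0, s0=S0)
        sig = passive_stress(p, kin).sigma
        assert sig[0, 0] > sig[1, 1]


class TestActivation:
    def test_waveform_anchors(self, active):
        l = active.lR
        tr = active.m * l + active.b_relax
        t0 = active.t0
        assert ct_activation(0.0, active, l) == 0.0
        assert ct_activation(t0, active, l) == pytest.approx(1.0, abs=1e-14)
        assert ct_activation(t0 / 2, active, l) == pytest.approx(0.5, abs=1e-14)
        assert ct_activation(t0 + tr, active, l) == pytest.approx(0.0, abs=1e-14)
        assert ct_activation(t0 + tr + 0.5, active, l) == 0.0

    def test_branch_continuity(self, active):
        l = active.lR
        tr = active.m * l + active.b_relax
        for tb in (active.t0, active.t0 + tr):
            below = ct_activation(tb - 1e-12, active, l)
            above = ct_activation(tb + 1e-12, active, l)
            assert abs(below - above) < 1e-10

    @given(st.floats(min_value=0.0, max_value=2.0))
    @settings(deadline=None, max_examples=50)
    def test_bounded(self, t):
        act = DEFAULT_ACTIVE
        ct = ct_activation(t, act, act.lR)
        assert 0.0 <= ct <= 1.0

    def test_nonpositive_relaxation_rejected(self, active):
        bad = active.replace(m=0.0, b_relax=-0.1)
        with pytest.raises(InvalidParametersError):
            ct_activation(0.1, bad, bad.lR)


class TestCalciumSensitivity:
    def test_zero_strain_gives_rest_length(self, active):
        assert sarcomere_length(0.0, active) == active.lR

    def test_unit_denominator(self):
        # choose B so that exp(B (lR - l0)) = 2 -> ECa50 = Ca0_max
        act = DEFAULT_ACTIVE.replace(B=math.log(2.0)
                                     / (DEFAULT_ACTIVE.lR - DEFAULT_ACTIVE.l0))
        assert eca50(0.0, act) == pytest.approx(act.Ca0_max, rel=1e-12)

    def test_reference_value(self):
        # frozen from a direct high-precision evaluation of the formula
        act = DEFAULT_ACTIVE.replace(B=4.75, l0=1.58, lR=1.85, Ca0_max=4.35)
        # exp(4.75*0.27) - 1 = exp(1.2825) - 1
        expect = 4.35 / math.sqrt(math.exp(1.2825) - 1.0)
        assert eca50(0.0, act) == pytest.approx(expect, rel=1e-14)
        assert eca50(0.0, act) == pytest.approx(2.694833, rel=1e-5)

    def test_strictly_decreasing_in_strain(self, active):
        effs = np.linspace(0.0, 0.3, 20)
        vals = [eca50(e, active) for e in effs]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_below_activation_length_raises(self, active):
        short = active.replace(l0=active.lR + 0.1)
        with pytest.raises(LengthBelowActivationError):
            eca50(0.0, short)


class TestActiveTension:
    def test_zero_after_relaxation(self, active):
        l = sarcomere_length(0.1, active)
        tr = active.m * l + active.b_relax
        assert active_tension(active.t0 + tr + 0.01, 0.1, active) == 0.0

    def test_half_maximum_at_matched_calcium(self):
        act = DEFAULT_ACTIVE
        # choose Eff so that ECa50 == Ca0
        from scipy.optimize import brentq

        # ECa50 grows without bound as l drops toward l0, so the matched
        # point lies at a (slightly) negative fiber strain
        e_min = 0.5 * ((act.l0 / act.lR) ** 2 - 1.0) + 1e-6
        eff = brentq(lambda e: eca50(e, act) - act.Ca0, e_min, 0.5)
        T0 = active_tension(act.t0, eff, act)
        assert T0 == pytest.approx(act.T_max / 2, rel=1e-7)

    def test_linearity_in_tmax(self, active):
        double = active.replace(T_max=2 * active.T_max)
        for t, eff in [(0.05, 0.1), (0.12, 0.2), (0.3, 0.05)]:
            assert active_tension(t, eff, double) == pytest.approx(
                2 * active_tension(t, eff, active), rel=1e-14)

    def test_zero_below_activation_length(self, active):
        short = active.replace(l0=active.lR + 0.5)
        assert active_tension(active.t0, 0.0, short) == 0.0

    def test_frank_starling_monotonicity(self, active):
        """At fixed time with Ct > 0, tension is non-decreasing in fiber
        strain (decreasing calcium sensitivity raises activation)."""
        effs = np.linspace(0.0, 0.3, 25)
        t = active.t0 * 0.8
        vals = [active_tension(t, e, active) for e in effs]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] > vals[0]


class TestTotalStress:
    def test_reduces_to_passive_without_tension(self, passive, rng):
        act = DEFAULT_ACTIVE.replace(T_max=0.0)
        kin = random_kinematics(rng)
        tot = total_stress(passive, act, kin, t=0.1).sigma
        pas = passive_stress(passive, kin).sigma
        assert np.abs(tot - pas).max() == 0.0

    def test_pure_active_at_reference(self, passive):
        # at the reference configuration the passive stress vanishes and
        # the total stress is T0 along the fiber
        act = DEFAULT_ACTIVE
        kin = Kinematics(F=np.eye(3), f0=F0, s0=S0)
        T0 = active_tension(act.t0, 0.0, act)
        assert T0 > 0.0
        sig = total_stress(passive, act, kin, t=act.t0).sigma
        assert sig[0, 0] == pytest.approx(T0, rel=1e-12)
        assert abs(sig[1, 1]) < 1e-12 and abs(sig[2, 2]) < 1e-12

    def test_fiber_projection_decomposition(self, passive, rng):
        """f.sigma_total.f - f.sigma_passive.f recovers T0 along the
        deformed unit fiber direction."""
        act = DEFAULT_ACTIVE
        kin = random_kinematics(rng, scale=0.08)
        t = act.t0 * 0.9
        inv = compute_invariants(kin)
        T0 = active_tension(t, 0.5 * (inv.I4f - 1.0), act)
        f = kin.F @ kin.f0
        f = f / np.linalg.norm(f)
        tot = total_stress(passive, act, kin, t).sigma
        pas = passive_stress(passive, kin).sigma
        proj = f @ (tot - pas) @ f
        assert proj == pytest.approx(T0, rel=1e-8)


class TestParameterValidation:
    def test_negative_stiffness_rejected(self):
        with pytest.raises(InvalidParametersError):
            PassiveParams(a=-1.0, b=1.0, a_f=0.0, b_f=1.0, a_s=0.0,
                          b_s=1.0, a_fs=0.0, b_fs=1.0, D=0.1)

    def test_nonpositive_compressibility_rejected(self):
        with pytest.raises(InvalidParametersError):
            DEFAULT_PASSIVE.replace(D=0.0)

    def test_design_conversion(self):
        act = ActiveParams.from_design(l0=0.0020, t0=0.1, tmax=1.5)
        assert act.l0 == pytest.approx(2.0)
        assert act.t0 == 0.1
        assert act.T_max == pytest.approx(1.5 * 135.7)
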