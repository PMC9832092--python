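"""Tissue model: kinematics, energy/stress consistency, biaxial response,
and parameter recovery from synthetic biaxial data."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tavrom import hgo
from tavrom.hgo import (
    Deformation,
    HGOBiaxialModel,
    HGOParams,
    biaxial_plane_stress,
    cauchy_and_von_mises,
    fiber_directions,
    fiber_invariant,
    first_pk_stress,
    generate_biaxial_dataset,
    kinematics,
    stenotic_stiffening,
    strain_energy,
)


def random_admissible_F(rng, scale=0.15):
    """Random deformation gradient with positive determinant."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.2:
            return F


class TestKinematics:
    @pytest.mark.parametrize(
        "F, J, I1",
        [
            (np.eye(3), 1.0, 3.0),
            (np.diag([2.0, 1.0, 1.0]), 2.0, 6.0 * 2.0 ** (-2.0 / 3.0)),
            (np.diag([1.2, 1.2 ** -0.5, 1.2 ** -0.5]), 1.0, 1.44 + 2.0 / 1.2),
        ],
    )
    def test_invariants(self, F, J, I1):
        d = kinematics(F)
        assert d.J == pytest.approx(J, rel=1e-12)
        assert d.I1bar == pytest.approx(I1, rel=1e-12)

    def test_isochoric_invariant_under_uniform_scaling(self, rng):
        F = random_admissible_F(rng)
        d1, d2 = kinematics(F), kinematics(2.5 * F)
        assert d2.I1bar == pytest.approx(d1.I1bar, rel=1e-12)

    @pytest.mark.parametrize("F", [np.diag([1.0, 1.0, -1.0]), np.zeros((3, 3))])
    def test_inadmissible_gradient_rejected(self, F):
        with pytest.raises(ValueError, match="determinant"):
            kinematics(F)

    def test_i1_floor_at_identity(self, rng):
        for _ in range(20):
            d = kinematics(random_admissible_F(rng))
            assert d.I1bar >= 3.0 - 1e-12


class TestFiberInvariant:
    def test_identity_gives_one(self):
        assert fiber_invariant(kinematics(np.eye(3)), [1.0, 0.0, 0.0]) == 1.0

    def test_shortened_fiber_clamps_to_one(self):
        lam = 0.8
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        assert fiber_invariant(kinematics(F), [1.0, 0.0, 0.0]) == 1.0

    def test_stretched_fiber_is_lambda_squared(self):
        lam = 1.1
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        i4 = fiber_invariant(kinematics(F), [1.0, 0.0, 0.0])
        assert i4 == pytest.approx(lam**2, rel=1e-12)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            fiber_invariant(kinematics(np.eye(3)), [1.0, 1.0, 0.0])

    @pytest.mark.parametrize(
        "mean, theta, expected",
        [
            (0.0, 0.0, (0.0, 0.0)),
            (45.0, 7.81, (37.19, 52.81)),
            (90.0, 26.21, (63.79, 116.21)),
        ],
    )
    def test_fiber_directions(self, mean, theta, expected):
        f1, f2 = fiber_directions(mean, theta)
        for f, ang in zip((f1, f2), expected):
            assert np.linalg.norm(f) == pytest.approx(1.0, abs=1e-14)
            assert math.degrees(math.atan2(f[1], f[0])) == pytest.approx(ang, abs=1e-10)


class TestEnergyAndStress:
    def test_energy_zero_at_identity(self, porcine, native):
        d = kinematics(np.eye(3))
        assert strain_energy(d, porcine) == 0.0
        assert strain_energy(d, native) == 0.0

    def test_volumetric_energy_closed_form(self, porcine):
        # pure dilation J = 2: W contributes only isotropically, U = beta(2 ln 2 - 1)
        d = kinematics(2.0 ** (1.0 / 3.0) * np.eye(3))
        beta_kPa = porcine.beta_kPa
        expected_U = beta_kPa * (2.0 * math.log(2.0) - 1.0)
        # Fbar = identity for pure dilation, so W = 0 and Psi = U
        assert strain_energy(d, porcine) == pytest.approx(expected_U, rel=1e-12)

    def test_energy_nonnegative(self, porcine, rng):
        for _ in range(50):
            d = kinematics(random_admissible_F(rng))
            assert strain_energy(d, porcine) >= 0.0

    def test_fibers_in_compression_contribute_nothing(self, porcine):
        # equibiaxial in-plane shortening puts both families in compression
        lam = 0.9
        F = np.diag([lam, lam, 1.0 / lam**2])
        p_nofiber = hgo.HGOParams(**{**porcine.to_dict(), "k1_MPa": 0.0})
        d = kinematics(F)
        assert strain_energy(d, porcine) == pytest.approx(
            strain_energy(d, p_nofiber), rel=1e-14
        )
        np.testing.assert_allclose(
            first_pk_stress(d, porcine), first_pk_stress(d, p_nofiber), rtol=1e-14
        )

    def test_stress_free_reference(self, porcine):
        P = first_pk_stress(kinematics(np.eye(3)), porcine)
        np.testing.assert_array_equal(P, np.zeros((3, 3)))

    @pytest.mark.parametrize("tissue", ["porcine", "native"])
    def test_stress_matches_energy_finite_differences(self, tissue, porcine, native, rng):
        """P = dPsi/dF checked against central differences at 100 seeded
        random admissible deformations."""
        p = porcine if tissue == "porcine" else native
        eps = 1e-6
        for _ in range(100):
            F = random_admissible_F(rng, scale=0.08)
            P = first_pk_stress(kinematics(F), p)
            Pfd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += eps
                    Fm[i, j] -= eps
                    Pfd[i, j] = (
                        strain_energy(kinematics(Fp), p)
                        - strain_energy(kinematics(Fm), p)
                    ) / (2 * eps)
            scale = max(np.abs(P).max(), 1.0)
            assert np.abs(P - Pfd).max() / scale < 1e-6

    def test_objectivity_under_rotations(self, porcine, rng):
        """Psi(QF) = Psi(F) for rotations Q."""
        from scipy.stats import special_ortho_group

        F = random_admissible_F(rng)
        psi = strain_energy(kinematics(F), porcine)
        for Q in special_ortho_group.rvs(3, size=20, random_state=12345):
            psi_q = strain_energy(kinematics(Q @ F), porcine)
            assert psi_q == pytest.approx(psi, rel=1e-10)

    def test_overflow_guard_flags_and_stays_finite(self, native):
        F = np.diag([2.5, 2.5, 1.0 / 2.5**2])  # extreme stretch, huge k2 exponent
        psi, capped = strain_energy(kinematics(F), native, return_flag=True)
        assert capped and np.isfinite(psi)


class TestCauchyVonMises:
    def test_zero_stress(self, rng):
        d = kinematics(random_admissible_F(rng))
        s = cauchy_and_von_mises(d, np.zeros((3, 3)))
        assert s.von_mises == 0.0

    def test_hydrostatic_state_has_zero_von_mises(self):
        d = kinematics(np.eye(3))
        s = cauchy_and_von_mises(d, 3.7 * np.eye(3))
        assert s.von_mises == pytest.approx(0.0, abs=1e-14)

    def test_uniaxial_von_mises_equals_stress(self):
        d = kinematics(np.eye(3))
        P = np.zeros((3, 3))
        P[0, 0] = 42.0
        s = cauchy_and_von_mises(d, P)
        assert s.von_mises == pytest.approx(42.0, rel=1e-12)
        np.testing.assert_allclose(s.sigma, s.sigma.T)


class TestBiaxial:
    def test_undeformed_is_stress_free(self, porcine):
        s11, s22 = biaxial_plane_stress(1.0, 1.0, porcine)
        assert s11 == 0.0 and s22 == 0.0

    def test_fiber_direction_stiffer_in_equibiaxial(self, native):
        # mean fiber along axis 1: sigma11 >= sigma22 under equibiaxial stretch
        s11, s22 = biaxial_plane_stress(1.15, 1.15, native)
        assert s11 >= s22

    @pytest.mark.parametrize("tissue", ["porcine", "native"])
    def test_matches_reduced_energy_finite_differences(self, tissue, porcine, native, rng):
        """In-plane stresses equal lambda_a dW/dlambda_a of the
        incompressibility-reduced energy."""
        p = porcine if tissue == "porcine" else native

        def red(l1, l2):
            F = np.diag([l1, l2, 1.0 / (l1 * l2)])
            return strain_energy(kinematics(F), p)

        h = 1e-7
        for l1, l2 in rng.uniform(1.0, 1.2, size=(12, 2)):
            s11, s22 = biaxial_plane_stress(l1, l2, p)
            fd11 = l1 * (red(l1 + h, l2) - red(l1 - h, l2)) / (2 * h)
            fd22 = l2 * (red(l1, l2 + h) - red(l1, l2 - h)) / (2 * h)
            scale = max(abs(s11), abs(s22), 1.0)
            assert abs(s11 - fd11) / scale < 1e-6
            assert abs(s22 - fd22) / scale < 1e-6


class TestDatasetGeneration:
    def test_noise_free_reproduces_model(self, porcine):
        df = generate_biaxial_dataset(porcine)
        s11, s22 = biaxial_plane_stress(
            df["lambda1"].to_numpy(), df["lambda2"].to_numpy(), porcine
        )
        np.testing.assert_array_equal(df["sigma11_kPa"].to_numpy(), s11)
        np.testing.assert_array_equal(df["sigma22_kPa"].to_numpy(), s22)

    def test_same_seed_identical(self, porcine):
        a = generate_biaxial_dataset(porcine, noise_sd=2.0, seed=7)
        b = generate_biaxial_dataset(porcine, noise_sd=2.0, seed=7)
        assert a.equals(b)

    def test_additive_noise_sd_recovered(self, porcine):
        sd = 3.0
        noisy = generate_biaxial_dataset(porcine, noise_sd=sd, seed=3)
        clean = generate_biaxial_dataset(porcine)
        resid = np.concatenate(
            [
                noisy["sigma11_kPa"] - clean["sigma11_kPa"],
                noisy["sigma22_kPa"] - clean["sigma22_kPa"],
            ]
        )
        assert len(resid) >= 400
        assert abs(resid.std() - sd) / sd < 0.15


class TestFitting:
    @pytest.mark.parametrize("tissue", ["porcine", "native"])
    def test_noise_free_parameter_recovery(self, tissue, porcine, native):
        """Noise-free synthetic biaxial data identifies C10 and k2 within 1%."""
        true = porcine if tissue == "porcine" else native
        data = generate_biaxial_dataset(true)
        res = HGOBiaxialModel(
            data, mean_fiber_deg=true.mean_fiber_deg, beta_MPa=true.beta_MPa
        ).fit()
        assert res.converged
        assert res.params.C10_kPa == pytest.approx(true.C10_kPa, rel=0.01)
        assert res.params.k2 == pytest.approx(true.k2, rel=0.01)
        assert res.params.theta_deg == pytest.approx(true.theta_deg, abs=0.5)

    def test_noisy_recovery_within_ten_percent(self, porcine):
        """5% multiplicative noise at n = 400 rows still recovers C10 and k2
        within 10%."""
        data = generate_biaxial_dataset(porcine, noise_rel=0.05, seed=42)
        res = HGOBiaxialModel(
            data, mean_fiber_deg=porcine.mean_fiber_deg, beta_MPa=porcine.beta_MPa
        ).fit()
        assert res.params.C10_kPa == pytest.approx(porcine.C10_kPa, rel=0.10)
        assert res.params.k2 == pytest.approx(porcine.k2, rel=0.10)

    def test_refit_is_idempotent(self, porcine):
        data = generate_biaxial_dataset(porcine)
        first = HGOBiaxialModel(
            data, mean_fiber_deg=porcine.mean_fiber_deg, beta_MPa=porcine.beta_MPa
        ).fit()
        data2 = generate_biaxial_dataset(first.params)
        second = HGOBiaxialModel(
            data2, mean_fiber_deg=porcine.mean_fiber_deg, beta_MPa=porcine.beta_MPa
        ).fit()
        assert second.params.C10_kPa == pytest.approx(first.params.C10_kPa, rel=1e-4)
        assert second.params.k2 == pytest.approx(first.params.k2, rel=1e-4)

    def test_too_few_rows_rejected(self, porcine):
        data = generate_biaxial_dataset(porcine).head(5)
        with pytest.raises(ValueError, match="rows"):
            HGOBiaxialModel(data)


class TestStenoticStiffening:
    def test_scales_only_c10(self, native):
        s = stenotic_stiffening(native)
        assert s.C10_kPa == pytest.approx(146.3, rel=1e-10)
        assert (s.k2, s.C01, s.theta_deg) == (native.k2, native.C01, native.theta_deg)

    def test_identity_and_composition(self, native):
        assert stenotic_stiffening(native, 1.0) == native
        ab = stenotic_stiffening(stenotic_stiffening(native, 5.0), 7.0)
        assert ab.C10_kPa == pytest.approx(
            stenotic_stiffening(native, 35.0).C10_kPa, rel=1e-14
        )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    lam=st.floats(0.85, 1.25),
    angle=st.floats(0.0, 180.0),
)
def test_fiber_invariant_floor_property(lam, angle):
    """I4* >= 1 for any uniaxial incompressible stretch and fiber angle."""
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    f0 = np.array([math.cos(math.radians(angle)), math.sin(math.radians(angle)), 0.0])
    assert fiber_invariant(kinematics(F), f0) >= 1.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(factor=st.floats(1e-2, 1e4))
def test_stiffening_preserves_invariants(factor):
    p = stenotic_stiffening(hgo.NATIVE_LEAFLET, factor)
    assert isinstance(p, HGOParams)  # constructor re-validates invariants
    assert p.C10_kPa == pytest.approx(hgo.NATIVE_LEAFLET.C10_kPa * factor, rel=1e-12)
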