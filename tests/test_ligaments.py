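"""Unit and property tests for the ligament force law and containers."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from kneesim.kinematics import JointPose
from kneesim.ligaments import (
    LigamentBundle,
    LigamentSet,
    fiber_force,
    fiber_strain,
    ligament_wrench,
    read_ligament_table,
    strain_energy,
    write_ligament_table,
    zero_strain_length,
)

stiffness = st.floats(min_value=10.0, max_value=1e4)
transition = st.floats(min_value=1e-3, max_value=0.2)


class TestFiberForce:
    @pytest.mark.parametrize(
        "eps,K,eps1,expected",
        [
            (-0.2, 6468.8, 0.03, 0.0),            # slack branch
            (0.0, 1000.0, 0.03, 0.0),             # exactly unstrained
            (0.06, 1000.0, 0.03, 30.0),           # section boundary, K*eps1
            (0.10, 6468.8, 0.03, 452.816),        # linear branch K*(eps-eps1)
            (0.03, 1200.0, 0.03, 1200.0 / 0.12 * 0.03**2),  # toe region
        ],
    )
    def test_branch_values(self, eps, K, eps1, expected):
        assert fiber_force(eps, K, eps1) == pytest.approx(expected, rel=1e-12)

    def test_vectorised(self):
        eps = np.array([-0.1, 0.02, 0.10])
        F = fiber_force(eps, 2000.0, 0.03)
        assert F.shape == (3,)
        assert F[0] == 0.0 and F[2] == pytest.approx(2000.0 * 0.07)

    @pytest.mark.parametrize("bad", [{"K": -1.0}, {"K": 0.0}, {"eps1": 0.0}, {"eps1": -0.1}])
    def test_parameter_errors(self, bad):
        kwargs = {"K": 1000.0, "eps1": 0.03, **bad}
        with pytest.raises(ValueError):
            fiber_force(0.05, **kwargs)

    @given(K=stiffness, eps1=transition)
    @hyp_settings(max_examples=100, deadline=None)
    def test_c0_c1_continuity_at_section_boundaries(self, K, eps1):
        h = 1e-9
        for b in (0.0, 2.0 * eps1):
            f_lo, f_hi = fiber_force(b - h, K, eps1), fiber_force(b + h, K, eps1)
            assert abs(f_hi - f_lo) < 1e-4 * max(1.0, K * eps1)
            d_lo = (fiber_force(b, K, eps1) - fiber_force(b - h, K, eps1)) / h
            d_hi = (fiber_force(b + h, K, eps1) - fiber_force(b, K, eps1)) / h
            assert abs(d_hi - d_lo) < 1e-4 * K

    @given(K=stiffness, eps1=transition)
    @hyp_settings(max_examples=50, deadline=None)
    def test_monotone_non_decreasing(self, K, eps1):
        eps = np.linspace(-0.5, 6.0 * eps1, 400)
        F = fiber_force(eps, K, eps1)
        assert np.all(np.diff(F) >= -1e-12)


class TestStrainBookkeeping:
    @pytest.mark.parametrize(
        "dist,l0,expected",
        [(50.0, 50.0, 0.0), (52.5, 50.0, 0.05), (25.0, 50.0, -0.5)],
    )
    def test_fiber_strain(self, dist, l0, expected):
        q_fem = np.array([0.0, dist, 0.0])
        assert fiber_strain(q_fem, np.zeros(3), l0) == pytest.approx(expected)

    def test_coincident_points_give_minus_one(self):
        assert fiber_strain(np.ones(3), np.ones(3), 10.0) == pytest.approx(-1.0)

    def test_nonpositive_l0_rejected(self):
        with pytest.raises(ValueError):
            fiber_strain(np.ones(3), np.zeros(3), 0.0)

    @pytest.mark.parametrize(
        "l_ref,eps_ref,expected",
        [(50.0, 0.0, 50.0), (53.0, 0.06, 50.0), (24.5, -0.51, 50.0)],
    )
    def test_zero_strain_length(self, l_ref, eps_ref, expected):
        assert zero_strain_length(l_ref, eps_ref) == pytest.approx(expected)

    def test_zero_strain_length_errors(self):
        with pytest.raises(ValueError):
            zero_strain_length(50.0, -1.0)
        with pytest.raises(ValueError):
            zero_strain_length(-1.0, 0.1)

    @given(
        l0=st.floats(min_value=5.0, max_value=200.0),
        eps_ref=st.floats(min_value=-0.9, max_value=1.0),
    )
    @hyp_settings(max_examples=100, deadline=None)
    def test_round_trip_through_reference_length(self, l0, eps_ref):
        l_ref = l0 * (1.0 + eps_ref)
        back = zero_strain_length(l_ref, eps_ref)
        assert back == pytest.approx(l0, rel=1e-12)
        q = np.array([l_ref, 0.0, 0.0])
        assert fiber_strain(q, np.zeros(3), back) == pytest.approx(eps_ref, abs=1e-12)


class TestStrainEnergy:
    def test_zero_when_slack(self):
        assert strain_energy(-0.3, 1000.0, 0.03, 50.0) == 0.0
        assert strain_energy(0.0, 1000.0, 0.03, 50.0) == 0.0

    @pytest.mark.parametrize("eps", [0.01, 0.05, 0.06, 0.2])
    def test_gradient_reproduces_force(self, eps):
        K, eps1, l0 = 2500.0, 0.03, 60.0
        h = 1e-7
        dE_dl = (
            strain_energy(eps + h, K, eps1, l0) - strain_energy(eps - h, K, eps1, l0)
        ) / (2 * h * l0)
        assert dE_dl == pytest.approx(fiber_force(eps, K, eps1), rel=1e-6)

    def test_non_decreasing_in_strain(self):
        eps = np.linspace(-0.2, 0.4, 500)
        E = strain_energy(eps, 3000.0, 0.03, 40.0)
        assert np.all(np.diff(E) >= 0.0)


def _random_ligset(rng, n=5, with_l0=True):
    bundles = []
    for i in range(n):
        b = LigamentBundle(
            name=f"B{i}",
            p_fem=rng.uniform(-30, 30, 3),
            p_tib=rng.uniform(-30, 30, 3) + np.array([0.0, -40.0, 0.0]),
            K=rng.uniform(500, 5000),
            eps_ref=rng.uniform(-0.3, 0.1),
            l0=rng.uniform(20, 60) if with_l0 else None,
        )
        bundles.append(b)
    return LigamentSet(bundles)


class TestLigamentWrench:
    def test_uninitialised_raises(self, rng):
        ligset = _random_ligset(rng, with_l0=False)
        with pytest.raises(RuntimeError):
            ligament_wrench(JointPose(), ligset)

    def test_all_slack_gives_zero_wrench(self, rng):
        ligset = _random_ligset(rng).with_l0(np.full(5, 500.0))
        f, t = ligament_wrench(JointPose(), ligset)
        assert np.allclose(f, 0.0) and np.allclose(t, 0.0)

    def test_single_vertical_fiber(self):
        b = LigamentBundle("V", (0.0, 30.0, 0.0), (0.0, 0.0, 0.0), 1000.0, 0.0, l0=25.0)
        ligset = LigamentSet([b])
        f, t = ligament_wrench(JointPose(), ligset)
        eps = (30.0 - 25.0) / 25.0
        assert np.allclose(f, [0.0, 1000.0 * (eps - 0.03), 0.0])
        assert np.allclose(t, 0.0)  # chord passes through the origin

    def test_matches_per_fiber_brute_force(self, rng):
        for _ in range(10):
            ligset = _random_ligset(rng)
            pose = JointPose(
                flexion_deg=rng.uniform(0, 80),
                vv_deg=rng.uniform(-3, 3), ie_deg=rng.uniform(-5, 5),
                ap_mm=rng.uniform(-5, 5), si_mm=rng.uniform(20, 30),
                ml_mm=rng.uniform(-3, 3),
            )
            f_sum, t_sum = np.zeros(3), np.zeros(3)
            for b in ligset:
                q = pose.R @ b.p_fem + pose.t
                l = np.linalg.norm(q - b.p_tib)
                from kneesim.ligaments import fiber_force as ff

                F = ff((l - b.l0) / b.l0, b.K, b.eps1)
                if F > 0:
                    u = (q - b.p_tib) / l
                    f_sum += F * u
                    t_sum += np.cross(b.p_tib, F * u)
            f, t = ligament_wrench(pose, ligset)
            assert np.allclose(f, f_sum, atol=1e-9)
            assert np.allclose(t, t_sum, atol=1e-9)

    def test_mirror_symmetric_set_balances(self):
        bundles = [
            LigamentBundle("L", (0.0, 5.0, 20.0), (0.0, -30.0, 18.0), 2000.0, 0.05, l0=30.0),
            LigamentBundle("M", (0.0, 5.0, -20.0), (0.0, -30.0, -18.0), 2000.0, 0.05, l0=30.0),
        ]
        f, t = ligament_wrench(JointPose(si_mm=2.0), LigamentSet(bundles))
        assert abs(f[2]) < 1e-12          # no mediolateral force
        assert abs(t[1]) < 1e-12          # no axial torque


class TestContainersAndIO:
    def test_duplicate_names_rejected(self):
        b = LigamentBundle("X", np.zeros(3), np.ones(3), 100.0, 0.0)
        with pytest.raises(ValueError):
            LigamentSet([b, b])

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            LigamentBundle("bad", np.zeros(3), np.ones(3), -5.0, 0.0)
        with pytest.raises(ValueError):
            LigamentBundle("bad", np.zeros(3), np.ones(3), 5.0, -1.5)

    def test_table_round_trip(self, tmp_path, rng):
        ligset = _random_ligset(rng)
        path = tmp_path / "table.csv"
        write_ligament_table(ligset, path)
        back = read_ligament_table(path)
        assert back.names == ligset.names
        assert np.allclose(back.K, ligset.K)
        assert np.allclose(back.P_fem, ligset.P_fem)
        assert np.allclose(back.eps_ref, ligset.eps_ref)

    def test_json_table_format(self, tmp_path):
        import json

        records = [{
            "name": "X", "K": 1500.0, "eps_ref": 0.04, "eps1": 0.03,
            "p_fem_x": 1.0, "p_fem_y": 2.0, "p_fem_z": 3.0,
            "p_tib_x": 0.0, "p_tib_y": -30.0, "p_tib_z": 3.0,
        }]
        path = tmp_path / "table.json"
        path.write_text(json.dumps(records))
        ligset = read_ligament_table(path)
        assert ligset.names == ["X"] and ligset.K[0] == 1500.0

    def test_reader_reports_row_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "name,K,eps_ref,eps1,p_fem_x,p_fem_y,p_fem_z,p_tib_x,p_tib_y,p_tib_z\n"
            "OK,1000,0.05,0.03,0,1,0,0,0,0\n"
            "BAD,-10,0.05,0.03,0,1,0,0,0,0\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_ligament_table(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("name,K\nX,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_ligament_table(path)
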