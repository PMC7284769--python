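"""Force-field unit tests: pair potentials, whole-chain energies, forces."""

import numpy as np
import pytest

import nanopost as nps
from nanopost.model import (
    ChainState, ForceFieldParams, OverlapError, OverstretchError, WCA_CUTOFF,
    bending_energy, fene_energy, post_monomer_energy, total_energy,
    total_forces, wca_pair_energy,
)
from conftest import make_saw_chain


class TestPairPotentials:
    @pytest.mark.parametrize("r, expected", [
        (WCA_CUTOFF, 0.0),
        (1.0, 1.0),
        (0.9, 4.0 * (0.9**-12 - 0.9**-6) + 1.0),
        (2.0, 0.0),
    ])
    def test_wca_values(self, r, expected):
        assert wca_pair_energy(r) == pytest.approx(expected, abs=1e-12)

    def test_wca_continuous_and_decreasing(self):
        r = np.linspace(0.7, WCA_CUTOFF, 2000)
        u = wca_pair_energy(r)
        assert np.all(np.diff(u) < 0)
        assert wca_pair_energy(WCA_CUTOFF - 1e-9) < 1e-6

    def test_wca_domain_error(self):
        with pytest.raises(ValueError):
            wca_pair_energy(0.0)
        with pytest.raises(ValueError):
            wca_pair_energy(-1.0)

    def test_post_energy_is_shifted_wca(self):
        for r in (0.3, 0.8, 1.0, 1.5):
            assert post_monomer_energy(1.5 + r, D_p=3.0) == pytest.approx(
                wca_pair_energy(r), rel=1e-14)
        assert post_monomer_energy(1.5 + WCA_CUTOFF, D_p=3.0) == 0.0
        assert post_monomer_energy(1.5 + 1.0, D_p=3.0) == pytest.approx(1.0)

    def test_post_overlap_error(self):
        with pytest.raises(OverlapError):
            post_monomer_energy(1.5, D_p=3.0)

    def test_aperture_midpoint_barrier(self):
        # one bead midway between two posts of the S_p = 3.9 array: the
        # translocation barrier is ~1.15e5 per the two flanking posts
        per_post = post_monomer_energy(1.95, D_p=3.0)
        assert per_post == pytest.approx(5.753e4, rel=1e-3)
        assert 2 * per_post == pytest.approx(1.15e5, rel=0.01)

    @pytest.mark.parametrize("l, expected", [
        (0.0, 0.0),
        (1.0, -0.5 * 30.0 * 1.5**2 * np.log(1.0 - (1.0 / 1.5) ** 2)),
    ])
    def test_fene_values(self, l, expected):
        assert fene_energy(l) == pytest.approx(expected, abs=1e-12)

    def test_fene_near_divergence_and_monotone(self):
        # -(30/2)*1.5^2*ln(1-(1.499/1.5)^2) = 223.4: large but finite
        assert fene_energy(1.499) == pytest.approx(223.4387, rel=1e-4)
        assert fene_energy(1.4999999) > fene_energy(1.499) + 100
        l = np.linspace(0.0, 1.49, 500)
        assert np.all(np.diff(fene_energy(l)) > 0)

    def test_fene_overstretch_error(self):
        with pytest.raises(OverstretchError):
            fene_energy(1.5)

    def test_bending(self, stiff_params):
        assert bending_energy(np.pi, stiff_params) == pytest.approx(0.0)
        assert bending_energy(np.pi / 2, stiff_params) == pytest.approx(20.0)
        assert bending_energy(0.0, stiff_params) == pytest.approx(40.0)
        assert bending_energy(1.234, ForceFieldParams(stiffness=0.0)) == 0.0


def brute_force_energy(pos, array, p):
    """Independent O(N^2) double-loop oracle, posts enumerated over a
    patch two lattice shells beyond the chain's bounding cells."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(pos[i] - pos[j])
            if r < WCA_CUTOFF:
                e += 4.0 * (r**-12 - r**-6) + 1.0
    for i in range(n - 1):
        l = np.linalg.norm(pos[i + 1] - pos[i])
        e += -0.5 * p.kappa * p.r_max**2 * np.log(1 - (l / p.r_max) ** 2)
    if p.stiffness > 0:
        for i in range(n - 2):
            b1 = pos[i + 1] - pos[i]
            b2 = pos[i + 2] - pos[i + 1]
            c = np.dot(b1, b2) / np.linalg.norm(b1) / np.linalg.norm(b2)
            e += p.stiffness * (1.0 - c)
    if array is not None:
        sp = array.S_p
        ilo = int(np.floor(pos[:, 1].min() / sp)) - 2
        ihi = int(np.floor(pos[:, 1].max() / sp)) + 2
        jlo = int(np.floor(pos[:, 2].min() / sp)) - 2
        jhi = int(np.floor(pos[:, 2].max() / sp)) + 2
        for i in range(n):
            for ci in range(ilo, ihi + 1):
                for cj in range(jlo, jhi + 1):
                    r = np.hypot(pos[i, 1] - ci * sp, pos[i, 2] - cj * sp)
                    sh = r - array.D_p / 2.0
                    if sh < WCA_CUTOFF:
                        e += 4.0 * (sh**-12 - sh**-6) + 1.0
    return e


class TestTotalEnergy:
    def test_two_beads_at_cutoff_fene_only(self, flexible_params):
        pos = np.array([[0.0, 50.0, 50.0], [WCA_CUTOFF, 50.0, 50.0]])
        arr = nps.derive_parameters(9.0, 3.0)
        e = total_energy(ChainState(pos), arr, flexible_params)
        assert e.wca == 0.0 and e.post == 0.0 and e.bending == 0.0
        assert e.total == pytest.approx(fene_energy(WCA_CUTOFF))

    def test_straight_chain_zero_bending(self, stiff_params):
        pos = np.zeros((3, 3))
        pos[:, 0] = [0.0, 0.97, 1.94]
        pos[:, 1:] = 50.0
        arr = nps.derive_parameters(9.0, 3.0)
        assert total_energy(ChainState(pos), arr, stiff_params).bending == \
            pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("stiffness, seed", [(0.0, 1), (20.0, 2)])
    def test_matches_brute_force_oracle(self, stiffness, seed):
        p = ForceFieldParams(stiffness=stiffness)
        arr = nps.derive_parameters(7.0, 3.0)
        pos = make_saw_chain(40, seed=seed, S_p=7.0, post_clearance=1.7)
        e = total_energy(ChainState(pos), arr, p).total
        oracle = brute_force_energy(pos, arr, p)
        assert e == pytest.approx(oracle, rel=1e-12)


class TestForces:
    @pytest.mark.parametrize("stiffness, use_array", [
        (0.0, False), (20.0, False), (0.0, True), (20.0, True)])
    def test_forces_match_finite_differences(self, stiffness, use_array):
        p = ForceFieldParams(stiffness=stiffness)
        arr = nps.derive_parameters(7.0, 3.0) if use_array else None
        pos = make_saw_chain(15, seed=7, S_p=7.0)
        f = total_forces(ChainState(pos), arr, p)
        h = 1e-6
        for i in range(pos.shape[0]):
            for k in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, k] += h
                pm[i, k] -= h
                fd = -(total_energy(ChainState(pp), arr, p).total
                       - total_energy(ChainState(pm), arr, p).total) / (2 * h)
                assert fd == pytest.approx(
                    f[i, k], rel=1e-6, abs=1e-6 * max(1.0, abs(f[i, k])))

    def test_kernel_agrees_with_reference(self, stiff_params):
        from nanopost import _kernels as K

        arr = nps.derive_parameters(6.0, 3.0)
        pos = make_saw_chain(25, seed=3, S_p=6.0, post_clearance=1.7)
        st = ChainState(pos)
        e_ref = total_energy(st, arr, stiff_params)
        f_ref = total_forces(st, arr, stiff_params)
        f = np.zeros_like(pos)
        status, ew, ef, eb, ep = K.energy_forces(
            pos, stiff_params.kappa, stiff_params.r_max**2,
            stiff_params.stiffness, True, arr.S_p, arr.D_p / 2.0, f)
        assert status == 0
        assert ew == pytest.approx(e_ref.wca, rel=1e-12, abs=1e-12)
        assert ef == pytest.approx(e_ref.fene, rel=1e-12)
        assert eb == pytest.approx(e_ref.bending, rel=1e-12, abs=1e-12)
        assert ep == pytest.approx(e_ref.post, rel=1e-12, abs=1e-12)
        np.testing.assert_allclose(f, f_ref, rtol=1e-9, atol=1e-9)


class TestSymmetries:
    def _energy(self, pos, arr, p):
        return total_energy(ChainState(pos), arr, p).total

    def test_lattice_and_axial_translations(self, stiff_params):
        arr = nps.derive_parameters(6.0, 3.0)
        pos = make_saw_chain(20, seed=11, S_p=6.0, post_clearance=1.8)
        e0 = self._energy(pos, arr, stiff_params)
        assert self._energy(pos + [7.3, 0, 0], arr, stiff_params) == \
            pytest.approx(e0, rel=1e-12)
        assert self._energy(pos + [0, 2 * arr.S_p, -arr.S_p], arr, stiff_params) == \
            pytest.approx(e0, rel=1e-12)

    def test_quarter_turn_about_post_axis(self, stiff_params):
        arr = nps.derive_parameters(6.0, 3.0)
        pos = make_saw_chain(20, seed=13, S_p=6.0, post_clearance=1.8)
        e0 = self._energy(pos, arr, stiff_params)
        rot = pos.copy()
        rot[:, 1], rot[:, 2] = -pos[:, 2], pos[:, 1]  # 90 deg about x post axis
        assert self._energy(rot, arr, stiff_params) == pytest.approx(e0, rel=1e-12)


class TestInvariants:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            ForceFieldParams(kappa=-1.0)
        with pytest.raises(ValueError):
            ForceFieldParams(r_max=0.5)
        with pytest.raises(ValueError):
            ForceFieldParams(stiffness=-1.0)

    def test_chain_state_validation(self):
        with pytest.raises(ValueError):
            ChainState(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            ChainState(np.array([[0.0, 0, 0], [np.inf, 0, 0]]))
        st = ChainState(np.array([[0.0, 0, 0], [1.6, 0, 0]]))
        with pytest.raises(OverstretchError):
            st.validate_bonds(ForceFieldParams())
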