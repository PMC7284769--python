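"""Observable pipeline: span, occupation, gyration, bond correlations,
structure factor and hump detection, checked against closed forms and
brute-force oracles on fixture conformations."""

import numpy as np
import pytest

from nanopost.fixtures import as_trajectory, make_rod, make_synthetic_sq, make_u_turn
from nanopost.geometry import derive_parameters
from nanopost.model import ChainState
from nanopost.observables import (
    axial_span, block_stderr, bond_correlation, default_q_grid, gyration,
    hump_detect, occupation_number, structure_factor,
)
from nanopost.simulate import Trajectory
from conftest import make_saw_chain


def random_trajectory(n_frames=5, n=12, seed=0):
    rng = np.random.default_rng(seed)
    frames = np.stack([make_saw_chain(n, seed=rng.integers(1 << 30))
                       for _ in range(n_frames)])
    return Trajectory(frames, np.arange(n_frames, dtype=float))


class TestAxialSpan:
    def test_rod_along_x(self):
        traj = as_trajectory(make_rod(11, 0.97, "x"))
        mean, _ = axial_span(traj)
        assert mean == pytest.approx(10 * 0.97)

    def test_rod_along_y_has_zero_span(self):
        traj = as_trajectory(make_rod(11, 0.97, "y"))
        assert axial_span(traj)[0] == pytest.approx(0.0)

    def test_matches_per_frame_extremes(self):
        traj = random_trajectory()
        mean, _ = axial_span(traj)
        expected = np.mean([f[:, 0].max() - f[:, 0].min() for f in traj.frames])
        assert mean == pytest.approx(expected, rel=1e-12)

    def test_empty_trajectory_error(self):
        with pytest.raises(ValueError):
            axial_span(Trajectory(np.empty((0, 3, 3)), np.empty(0)))

    def test_span_approaches_end_to_end_under_stretch(self):
        # helices of increasing pitch: the axial rise per bead grows, so
        # the span converges to the end-to-end distance from below
        from nanopost.fixtures import as_trajectory, make_helix

        ratios = []
        for pitch in (0.1, 0.5, 1.0, 1.4):
            h = make_helix(40, pitch_angle=pitch, axis="x")
            span, _ = axial_span(as_trajectory(h))
            e2e = np.linalg.norm(h.positions[-1] - h.positions[0])
            assert span <= e2e + 1e-12
            ratios.append(span / e2e)
        # steeper helices are closer to their end-to-end distance
        # (the lateral phase of the end beads adds a small wiggle, so
        # compare the shallow and steep ends rather than every step)
        assert max(ratios[2:]) > max(ratios[:2])
        assert ratios[2] > 0.995 and ratios[3] > 0.995


class TestOccupation:
    @pytest.fixture
    def array(self):
        return derive_parameters(6.0, 3.0)

    def test_single_cell_rod(self, array):
        rod = make_rod(10, 0.5, "x", origin=(0.0, 3.0, 3.0))
        n_p, _ = occupation_number(as_trajectory(rod), array)
        assert n_p == 1.0

    def test_u_turn_occupies_two_cells(self, array):
        ut = make_u_turn(array, ((0, 0), (1, 0)), N=20)
        n_p, _ = occupation_number(as_trajectory(ut), array)
        assert n_p == 2.0

    def test_matches_brute_force_cell_sets(self, array):
        traj = random_trajectory(n_frames=4, n=15, seed=3)
        n_p, _ = occupation_number(traj, array)
        counts = []
        for f in traj.frames:
            cells = {(int(np.floor(y / 6.0)), int(np.floor(z / 6.0)))
                     for _, y, z in f}
            counts.append(len(cells))
        assert n_p == pytest.approx(np.mean(counts))

    def test_invariant_under_lattice_translation(self, array):
        traj = random_trajectory(n_frames=4, n=15, seed=4)
        n0, _ = occupation_number(traj, array)
        shifted = Trajectory(traj.frames + np.array([0.0, 2 * 6.0, -3 * 6.0]),
                             traj.times)
        assert occupation_number(shifted, array)[0] == pytest.approx(n0)


class TestGyration:
    def test_coincident_beads(self):
        traj = Trajectory(np.zeros((2, 5, 3)), np.arange(2.0))
        g = gyration(traj)
        assert g.r_g == 0.0 and g.axial == 0.0 and g.lateral == 0.0

    def test_discrete_rod_closed_form(self):
        N, l = 21, 0.97
        g = gyration(as_trajectory(make_rod(N, l, "x")))
        # discrete rod: Rg^2 = l^2 (N^2 - 1)/12
        exact = l * np.sqrt((N**2 - 1) / 12.0)
        assert g.axial == pytest.approx(exact, rel=1e-12)
        assert g.lateral == pytest.approx(0.0, abs=1e-12)
        assert g.r_g == pytest.approx(exact, rel=1e-12)
        # continuum limit L/sqrt(12) is approached from above
        # (ratio sqrt((N+1)/(N-1)), ~5% at N = 21)
        continuum = (N - 1) * l / np.sqrt(12.0)
        assert continuum < g.axial < 1.06 * continuum

    def test_components_sum(self):
        traj = random_trajectory(n_frames=3, n=20, seed=5)
        g = gyration(traj)
        assert g.r_g**2 == pytest.approx(g.axial**2 + g.lateral**2, rel=1e-12)


class TestBondCorrelation:
    def test_straight_chain_unit_correlation(self):
        traj = as_trajectory(make_rod(30, 0.97, "x"))
        # correlations are exactly 1 at every separation; the decay fit
        # must refuse to produce a persistence length
        with pytest.raises(ValueError):
            bond_correlation(traj)

    def test_flexible_chain_decorrelates(self, flexible_params):
        from nanopost.simulate import pivot_sample

        traj = pivot_sample(40, flexible_params, n_samples=150, seed=2,
                            stride=20, n_equil_moves=2000)
        s, corr, _ = bond_correlation(traj)
        assert abs(corr[4]) < 0.2  # excluded-volume residual only

    def test_too_few_beads(self):
        with pytest.raises(ValueError):
            bond_correlation(as_trajectory(make_rod(2, 0.97)))


class TestStructureFactor:
    def test_single_bead_is_unity(self):
        traj = Trajectory(np.zeros((2, 1, 3)), np.arange(2.0))
        curve = structure_factor(traj, np.geomspace(0.1, 5.0, 20))
        assert np.allclose(curve.S, 1.0)

    def test_small_q_limit(self):
        traj = as_trajectory(make_rod(10, 0.97))
        curve = structure_factor(traj, np.array([1e-6, 1e-5]))
        assert np.allclose(curve.S, 1.0, atol=1e-6)

    def test_two_bead_closed_form(self):
        r = 1.3
        pos = np.array([[0.0, 0, 0], [r, 0, 0]])
        traj = Trajectory(pos[None], np.zeros(1))
        q = np.array([np.pi / r, 1.0, 2.0])
        curve = structure_factor(traj, np.sort(q))
        for qi, Si in zip(curve.q, curve.S):
            assert Si == pytest.approx(
                0.5 * (1.0 + np.sin(qi * r) / (qi * r)), rel=1e-12)
        # at q*r = pi the sinc vanishes: S = 1/2
        k = np.argmin(abs(curve.q - np.pi / r))
        assert curve.S[k] == pytest.approx(0.5, rel=1e-12)

    def test_matches_naive_double_sum(self):
        traj = random_trajectory(n_frames=3, n=25, seed=8)
        q = np.geomspace(0.2, 6.0, 15)
        curve = structure_factor(traj, q)
        N = traj.n_beads
        naive = np.zeros_like(q)
        for f in traj.frames:
            for iq, qv in enumerate(q):
                s = 0.0
                for i in range(N):
                    for j in range(N):
                        if i == j:
                            s += 1.0
                        else:
                            x = qv * np.linalg.norm(f[i] - f[j])
                            s += np.sin(x) / x
                naive[iq] += s
        naive /= traj.n_frames * N**2
        np.testing.assert_allclose(curve.S, naive, rtol=1e-12, atol=1e-12)

    def test_rod_scattering_slope_minus_one(self):
        N, l = 101, 0.97
        traj = as_trajectory(make_rod(N, l))
        L = (N - 1) * l
        q = np.geomspace(2 * np.pi / L * 1.5, 2 * np.pi / l / 1.5, 40)
        curve = structure_factor(traj, q)
        slope = np.polyfit(np.log(curve.q), np.log(curve.S), 1)[0]
        assert -1.1 < slope < -0.9


class TestHumpDetect:
    @pytest.mark.parametrize("bump_q, two_pi_over_q", [
        (1.02, 6.16), (0.86, 7.31), (0.68, 9.24), (0.56, 11.22)])
    def test_synthetic_bumps(self, bump_q, two_pi_over_q):
        grid = np.geomspace(0.05, 2 * np.pi, 2000)
        curve = make_synthetic_sq(bump_q, grid=grid)
        got = hump_detect(curve)
        assert got is not None
        qstar, omega = got
        assert qstar == pytest.approx(bump_q, abs=5e-3)
        assert omega == pytest.approx(two_pi_over_q, abs=0.05)

    def test_pure_power_law_none(self):
        curve = make_synthetic_sq(1.0, amplitude=0.0)
        assert hump_detect(curve) is None

    def test_edge_bump_rejected(self):
        grid = np.geomspace(0.05, 2 * np.pi, 500)
        curve = make_synthetic_sq(0.4, bump_width=0.02, grid=grid)
        # the bump sits exactly on the window edge: interior maxima only
        assert hump_detect(curve, window=(0.4001, 1.4)) is None

    def test_window_outside_grid(self):
        curve = make_synthetic_sq(1.0)
        with pytest.raises(ValueError):
            hump_detect(curve, window=(1e-4, 1.0))


class TestBlockStderr:
    def test_iid_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        se = block_stderr(x)
        assert se == pytest.approx(1.0 / np.sqrt(4000), rel=0.25)

    def test_correlated_series_larger_error(self):
        rng = np.random.default_rng(1)
        # AR(1) with strong correlation
        x = np.empty(4000)
        x[0] = 0.0
        eta = rng.normal(size=4000)
        for i in range(1, 4000):
            x[i] = 0.95 * x[i - 1] + eta[i]
        assert block_stderr(x) > 3.0 * x.std() / np.sqrt(x.size)
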