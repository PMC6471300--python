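"""Well-tempered metadynamics engine: bias, walls, integrator, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tunnelscape import wtmeta
from tunnelscape.constants import KB
from tunnelscape.fixtures import make_double_well, make_harmonic_well


@pytest.fixture(scope="module")
def short_run():
    """One modest biased run on a shallow double well, shared across tests."""
    pot = make_double_well(barrier=2.0, minima=(-1.0, 1.0))
    return wtmeta.run_wt_metadynamics(
        pot, wtmeta.WTParams(), walls=wtmeta.WallParams(K=40.0, s_lo=-3.0, s_hi=3.0),
        n_steps=2_000_000, dt=0.1, seed=123, x0=-1.0, sample_stride=100,
    )


class TestWallEnergy:
    def test_zero_inside_bounds(self):
        w = wtmeta.WallParams(K=40.0, s_lo=-20.0, s_hi=12.5)
        for s in (-19.9, -5.0, 0.0, 12.49):
            e, g = wtmeta.wall_energy(s, w)
            assert e == 0.0 and g == 0.0

    def test_half_harmonic_above_upper_bound(self):
        w = wtmeta.WallParams(K=40.0, s_lo=-20.0, s_hi=12.5)
        e, g = wtmeta.wall_energy(13.5, w)
        assert e == pytest.approx(20.0)  # (K/2)·1²
        assert g == pytest.approx(40.0)

    def test_half_harmonic_below_lower_bound(self):
        w = wtmeta.WallParams(K=10.0, s_lo=-2.0, s_hi=2.0)
        e, g = wtmeta.wall_energy(-3.5, w)
        assert e == pytest.approx(0.5 * 10.0 * 1.5**2)
        assert g == pytest.approx(-15.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        w = wtmeta.WallParams(K=7.0, s_lo=-1.0, s_hi=2.0)
        h = 1e-6
        for s in rng.uniform(-5, 5, size=50):
            e_plus, _ = wtmeta.wall_energy(s + h, w)
            e_minus, _ = wtmeta.wall_energy(s - h, w)
            _, g = wtmeta.wall_energy(s, w)
            assert g == pytest.approx((e_plus - e_minus) / (2 * h), abs=1e-5)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            wtmeta.WallParams(K=1.0, s_lo=2.0, s_hi=-2.0)


class TestBiasEnergy:
    def test_empty_log_is_zero(self):
        assert wtmeta.bias_energy(wtmeta.HillsLog.empty(), 1.23) == 0.0

    def test_single_hill_peak_value(self):
        log = wtmeta.HillsLog([10.0], [0.5], [0.05], [0.08])
        assert wtmeta.bias_energy(log, 0.5) == pytest.approx(0.08)

    def test_matches_loop_summation_oracle(self):
        rng = np.random.default_rng(17)
        n = 100
        log = wtmeta.HillsLog(
            times=np.arange(n, dtype=float),
            centers=rng.uniform(-3, 3, n),
            widths=rng.uniform(0.02, 0.5, n),
            heights=rng.uniform(0.01, 0.1, n),
        )
        for s in rng.uniform(-4, 4, size=10):
            expected = 0.0
            for i in range(n):
                expected += log.heights[i] * np.exp(
                    -((s - log.centers[i]) ** 2) / (2 * log.widths[i] ** 2)
                )
            assert wtmeta.bias_energy(log, s) == pytest.approx(expected, abs=1e-10)

    def test_vectorized_matches_scalar(self):
        log = wtmeta.HillsLog([1.0, 2.0], [0.0, 1.0], [0.1, 0.2], [0.05, 0.04])
        grid = np.linspace(-1, 2, 7)
        vec = wtmeta.bias_energy(log, grid)
        assert np.allclose(vec, [wtmeta.bias_energy(log, s) for s in grid])


class TestNextHillHeight:
    def test_zero_bias_gives_full_height(self):
        assert wtmeta.next_hill_height(wtmeta.WTParams(H=0.1), 0.0) == pytest.approx(0.1)

    def test_closed_form_half_height(self):
        p = wtmeta.WTParams()
        v = KB * p.deltaT * np.log(2.0)
        assert wtmeta.next_hill_height(p, v) == pytest.approx(p.H / 2)

    def test_bias_factor_value(self):
        p = wtmeta.WTParams(T=298.0, deltaT=4500.0)
        assert wtmeta.bias_factor(p) == pytest.approx((298 + 4500) / 298)
        assert wtmeta.bias_factor(p) == pytest.approx(16.10, abs=0.01)

    def test_negative_bias_rejected(self):
        with pytest.raises(ValueError):
            wtmeta.next_hill_height(wtmeta.WTParams(), -0.1)

    def test_tempering_decays_on_pinned_cv(self):
        # hills repeatedly deposited at one CV value: heights must decay
        # monotonically toward zero (geometric-like tempering)
        p = wtmeta.WTParams(H=0.1, delta=0.05, deltaT=4500.0)
        heights, centers = [], []
        for i in range(200):
            log = wtmeta.HillsLog(
                times=np.arange(len(heights), dtype=float) + 1,
                centers=np.array(centers), widths=np.full(len(heights), p.delta),
                heights=np.array(heights), params=p,
            ) if heights else wtmeta.HillsLog.empty(p)
            h = wtmeta.next_hill_height(p, wtmeta.bias_energy(log, 0.0))
            heights.append(h)
            centers.append(0.0)
        assert all(b < a for a, b in zip(heights, heights[1:]))
        assert heights[-1] < heights[0]


class TestRunDeterminism:
    def test_identical_seed_bit_identical_hills(self):
        pot = make_double_well(2.0, (-1.0, 1.0))
        kw = dict(params=wtmeta.WTParams(), n_steps=50_000, dt=0.1, seed=9, x0=-1.0)
        a = wtmeta.run_wt_metadynamics(pot, **kw)
        b = wtmeta.run_wt_metadynamics(pot, **kw)
        assert a.hills == b.hills
        assert np.array_equal(a.cv_traj, b.cv_traj)

    def test_different_seeds_differ(self):
        pot = make_double_well(2.0, (-1.0, 1.0))
        a = wtmeta.run_wt_metadynamics(pot, n_steps=10_000, dt=0.1, seed=1, x0=-1.0)
        b = wtmeta.run_wt_metadynamics(pot, n_steps=10_000, dt=0.1, seed=2, x0=-1.0)
        assert not np.array_equal(a.cv_traj, b.cv_traj)

    def test_divergence_guard_raises_with_diagnostic(self):
        # inverted harmonic: the walker escapes immediately
        pot = make_harmonic_well(k=5.0)
        pot.axial_gradient = lambda x: -5.0 * np.asarray(x, float)
        with pytest.raises(RuntimeError, match="sanity bound"):
            wtmeta.run_wt_metadynamics(pot, n_steps=5_000_000, dt=0.1, seed=3,
                                       x0=1.0, bias=False, sanity_bound=30.0)


class TestUnbiasedLimit:
    def test_harmonic_variance_matches_boltzmann(self):
        # H -> 0 (bias off): stationary variance of a harmonic well is kBT/k
        k = 5.0
        pot = make_harmonic_well(k=k)
        run = wtmeta.run_wt_metadynamics(pot, wtmeta.WTParams(T=298.0),
                                         n_steps=1_000_000, dt=0.05, seed=11,
                                         bias=False)
        var = run.cv_traj[:, 0].var()
        assert var == pytest.approx(KB * 298.0 / k, rel=0.05)

    def test_biased_run_crosses_barrier_more(self):
        pot = make_double_well(barrier=4.0, minima=(-1.5, 1.5))
        kw = dict(n_steps=2_000_000, dt=0.1, seed=21, x0=-1.5, sample_stride=10)

        def crossings(run):
            side = np.sign(run.cv_traj[:, 0])
            side = side[side != 0]
            return int(np.sum(side[1:] != side[:-1]))

        unbiased = wtmeta.run_wt_metadynamics(pot, bias=False, **kw)
        biased = wtmeta.run_wt_metadynamics(pot, wtmeta.WTParams(), bias=True, **kw)
        assert crossings(biased) > crossings(unbiased)


class TestGriddedBiasCache:
    def test_cache_agrees_with_exact_summation(self, short_run):
        # the engine's internal gridded bias must match the exact Gaussian
        # sum; verified indirectly: hill heights must equal the tempered
        # height computed from the exact bias at each hill's deposition point
        hills = short_run.hills
        p = hills.params
        for i in range(1, len(hills), 37):
            partial = wtmeta.HillsLog(
                times=hills.times[:i], centers=hills.centers[:i],
                widths=hills.widths[:i], heights=hills.heights[:i], params=p,
            )
            v_exact = wtmeta.bias_energy(partial, hills.centers[i])
            expected = wtmeta.next_hill_height(p, v_exact)
            assert hills.heights[i] == pytest.approx(expected, abs=1e-6)


class TestWallContainment:
    def test_fraction_beyond_bounds_is_tiny(self, short_run):
        s = short_run.cv_traj[:, 0]
        beyond = np.mean((s > 3.0 + 2.0) | (s < -3.0 - 2.0))
        assert beyond < 1e-3


class TestReconstructFES:
    def test_empty_hills_zero_curve(self):
        grid = np.linspace(-2, 2, 21)
        fes = wtmeta.reconstruct_fes(wtmeta.HillsLog.empty(), grid)
        assert np.allclose(fes.free_energy, 0.0)

    def test_single_hill_peak_at_center(self):
        p = wtmeta.WTParams(H=0.1, delta=0.5, deltaT=4500.0, T=298.0)
        log = wtmeta.HillsLog([1000.0], [0.3], [0.5], [0.08], params=p)
        grid = np.linspace(-5, 5, 201)
        fes = wtmeta.reconstruct_fes(log, grid)
        scale = (p.T + p.deltaT) / p.deltaT
        # the hill carves the minimum at its center; far tails sit at the
        # rescaled hill height above it
        i = np.argmin(fes.free_energy)
        assert grid[i] == pytest.approx(0.3, abs=0.06)
        assert fes.free_energy[i] == 0.0
        assert fes.free_energy.max() == pytest.approx(scale * 0.08, abs=1e-3)

    def test_reconstruction_consistency_identity(self, short_run):
        # F(s)·ΔT/(T+ΔT) = −V(s) + const on the grid, to machine precision
        hills = short_run.hills
        p = hills.params
        grid = np.linspace(-2.5, 2.5, 101)
        fes = wtmeta.reconstruct_fes(hills, grid)
        v = wtmeta.bias_energy(hills, grid)
        lhs = fes.free_energy * p.deltaT / (p.T + p.deltaT)
        assert np.ptp(lhs + v) == pytest.approx(0.0, abs=1e-9)

    def test_min_is_zero_and_grid_validated(self):
        log = wtmeta.HillsLog([1.0], [0.0], [0.1], [0.05])
        fes = wtmeta.reconstruct_fes(log, np.linspace(-1, 1, 11))
        assert fes.free_energy.min() == 0.0
        with pytest.raises(ValueError):
            wtmeta.reconstruct_fes(log, np.array([]))


class TestDepositionProfile:
    def test_constant_hills_flat_profile(self):
        n = 100
        log = wtmeta.HillsLog(
            times=np.arange(n) + 0.5, centers=np.zeros(n),
            widths=np.full(n, 0.05), heights=np.full(n, 0.1),
        )
        ws, dep = wtmeta.deposition_profile(log, window=10.0)
        assert np.allclose(dep, 1.0)  # 10 hills of 0.1 per window

    def test_empty_log_empty_profile(self):
        ws, dep = wtmeta.deposition_profile(wtmeta.HillsLog.empty(), 10.0)
        assert ws.size == 0 and dep.size == 0

    def test_windows_partition_total(self, short_run):
        ws, dep = wtmeta.deposition_profile(short_run.hills, window=1e4)
        assert dep.sum() == pytest.approx(short_run.hills.heights.sum())


class TestHillsIO:
    def test_round_trip(self, tmp_path, short_run):
        p = tmp_path / "hills.tsv"
        wtmeta.write_hills(short_run.hills, p)
        back = wtmeta.read_hills(p)
        assert back == short_run.hills
        assert back.params == short_run.hills.params
        assert back.seed == short_run.hills.seed

    def test_hand_written_file(self, tmp_path):
        p = tmp_path / "hand.tsv"
        p.write_text(
            "# wtmeta H=0.1 delta=0.05 deltaT=4500 tauG=1000 T=298 seed=5\n"
            "time_fs\tcenter_A\twidth_A\theight_kcal\n"
            "1000\t-1.5\t0.05\t0.1\n"
            "2000\t-1.2\t0.05\t0.09\n"
            "3000\t-0.8\t0.05\t0.085\n"
        )
        log = wtmeta.read_hills(p)
        assert len(log) == 3
        assert log.centers[1] == -1.2
        assert log.heights[2] == 0.085
        assert log.seed == 5

    def test_non_monotone_times_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("1000\t0\t0.05\t0.1\n500\t0\t0.05\t0.1\n")
        with pytest.raises(ValueError, match="increasing"):
            wtmeta.read_hills(p)

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("1000\t0\t0.05\n")
        with pytest.raises(ValueError):
            wtmeta.read_hills(p)


class TestToyPotentials:
    def test_double_well_barrier_exact_by_construction(self):
        pot = make_double_well(barrier=5.0, minima=(-2.0, 2.0))
        assert pot.axial_energy(0.0) - pot.axial_energy(-2.0) == pytest.approx(5.0, abs=1e-10)

    def test_double_well_symmetry(self):
        pot = make_double_well(barrier=3.0, minima=(-1.5, 1.5))
        xs = np.linspace(0, 3, 50)
        assert np.allclose(pot.axial_energy(xs), pot.axial_energy(-xs))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_gradients_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        pot = make_double_well(barrier=rng.uniform(1, 8),
                               minima=tuple(sorted(rng.uniform(-3, 3, 2))))
        h = 1e-5
        xs = rng.uniform(-4, 4, size=20)
        fd = (pot.axial_energy(xs + h) - pot.axial_energy(xs - h)) / (2 * h)
        assert np.allclose(pot.axial_gradient(xs), fd, atol=1e-5)

    def test_tunnel_potential_structure(self):
        from tunnelscape.fixtures import make_tunnel_potential
        axial = make_double_well(4.0, (-2.0, 2.0))
        pot = make_tunnel_potential(axial, radial_k=2.0)
        # on-axis energies equal the 1-D profile
        for x in (-2.0, 0.0, 1.3):
            assert pot.energy([x, 0, 0]) == pytest.approx(float(axial.axial_energy(x)))
        # radial section is harmonic with the requested curvature
        assert (pot.energy([0.0, 1.0, 0.0]) - pot.energy([0.0, 0.0, 0.0])
                == pytest.approx(1.0))
        g = pot.gradient([0.5, 0.7, -0.3])
        assert g[1] == pytest.approx(2.0 * 0.7)
        assert g[2] == pytest.approx(2.0 * -0.3)
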