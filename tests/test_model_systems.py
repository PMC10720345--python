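import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.integrate import quad

import hremkit as hk

GRID = np.linspace(-math.pi, math.pi, 72001)


def local_minima(potential):
    u = potential.energy(GRID)
    du = np.diff(u)
    idx = np.where((np.hstack([du, [1.0]]) > 0) & (np.hstack([[-1.0], du]) < 0))[0]
    return GRID[idx], u[idx]


class TestThermoState:
    def test_beta_and_rt(self, thermo):
        assert thermo.rt == pytest.approx(1.987204e-3 * 300.0)
        assert thermo.beta == pytest.approx(1.0 / thermo.rt)

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            hk.ThermoState(temperature=-10.0)


class TestPotentials:
    def test_phenyl_well_energies(self):
        pot = hk.make_phenyl_analog()
        assert pot.energy(0.0) == 0.0
        assert pot.energy(math.pi) == pytest.approx(0.2)

    def test_phenyl_barrier_about_1_kcal(self):
        # two minima split by 0.2 kcal/mol under a ~1 kcal/mol barrier
        pot = hk.make_phenyl_analog()
        locs, umin = local_minima(pot)
        near0 = umin[np.argmin(np.abs(locs))]
        barrier = pot.energy(GRID).max() - near0
        assert abs(barrier - 1.0) < 0.1
        assert umin.max() - umin.min() == pytest.approx(0.2, abs=1e-6)

    def test_naphthyl_t1_barrier_and_split(self):
        pot = hk.make_naphthyl_analog("T1")
        locs, umin = local_minima(pot)
        barrier = pot.energy(GRID).max() - umin.min()
        assert barrier == pytest.approx(5.0, abs=0.1)
        assert umin.max() - umin.min() == pytest.approx(0.5, abs=1e-6)

    def test_naphthyl_t2_structure(self):
        # global well near -60 deg, secondary displaced by +120 deg and ~1
        # kcal/mol shallower, all under a barrier exceeding 4 kcal/mol
        pot = hk.make_naphthyl_analog("T2")
        locs, umin = local_minima(pot)
        order = np.argsort(umin)
        g, s = locs[order[0]], locs[order[1]]
        assert math.degrees(g) == pytest.approx(-60.0, abs=5.0)
        assert math.degrees(s) == pytest.approx(60.0, abs=5.0)
        assert umin[order[1]] - umin[order[0]] == pytest.approx(1.0, abs=0.1)
        seg = GRID[(GRID >= g) & (GRID <= s)]
        barrier = pot.energy(seg).max() - umin[order[0]]
        assert barrier > 4.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="T1"):
            hk.make_naphthyl_analog("T3")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.0, 10.0), st.integers(1, 6),
                              st.floats(-math.pi, math.pi)),
                    min_size=1, max_size=4),
           st.floats(-math.pi, math.pi))
    def test_torsional_energy_periodic_and_finite(self, terms, theta):
        pot = hk.TorsionalPotential(terms=tuple(terms))
        u = pot.energy(theta)
        assert np.isfinite(u)
        assert pot.energy(theta + 2 * math.pi) == pytest.approx(u, abs=1e-9)


class TestTwoPoseAnalog:
    def test_minor_population_solved_to_1e4(self, thermo):
        pot = hk.make_two_pose_analog(0.07, thermo)
        beta = thermo.beta
        zl, _ = quad(lambda r: math.exp(-beta * pot.energy(r)), 9.0, 13.0)
        zr, _ = quad(lambda r: math.exp(-beta * pot.energy(r)), 13.0, 18.0)
        assert zl / (zl + zr) == pytest.approx(0.07, abs=1e-4)

    def test_minor_well_location(self, thermo):
        pot = hk.make_two_pose_analog(0.07, thermo)
        r = np.linspace(9.0, 13.0, 4001)
        assert 10.0 <= r[np.argmin(pot.energy(r))] <= 12.5

    def test_symmetric_at_half(self, thermo):
        # 50/50 target with symmetric wells needs essentially no offset:
        # the linear term of the solved polynomial vanishes
        pot = hk.make_two_pose_analog(0.4999999, thermo)
        base = hk.model_systems.TWO_POSE_K * (
            -4.0 * hk.model_systems.TWO_POSE_CENTER
            * (hk.model_systems.TWO_POSE_CENTER ** 2 - hk.model_systems.TWO_POSE_HALFW ** 2))
        assert pot.coeffs[1] == pytest.approx(base, abs=1e-3)

    def test_confining_at_bounds(self, thermo):
        pot = hk.make_two_pose_analog(0.07, thermo)
        interior = pot.energy(np.linspace(9.5, 17.5, 1001)).min()
        assert pot.energy(9.0) > interior + 10
        assert pot.energy(18.0) > interior + 10

    def test_unreachable_population_reports_range(self, thermo):
        with pytest.raises(ValueError, match="achievable"):
            hk.make_two_pose_analog(1e-12, thermo)

    def test_invalid_population(self, thermo):
        with pytest.raises(ValueError):
            hk.make_two_pose_analog(0.7, thermo)


class TestBoltzmannPopulations:
    def test_full_partition_sums_to_one(self, thermo):
        pot = hk.make_phenyl_analog()
        basins = hk.BasinPartition(intervals=(
            ("a", -math.pi, 0.0), ("b", 0.0, math.pi)))
        pops = hk.boltzmann_populations(pot, thermo, basins)
        assert sum(pops) == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_double_well(self, thermo):
        pot = hk.TorsionalPotential(terms=((2.0, 2, 0.0),))
        basins = hk.BasinPartition(intervals=(
            ("left", math.radians(90), math.radians(-90)),
            ("right", math.radians(-90), math.radians(90))))
        pops = hk.boltzmann_populations(pot, thermo, basins)
        assert pops[0] == pytest.approx(pops[1], abs=1e-8)

    def test_flat_potential_equal_measure(self, thermo):
        pot = hk.TorsionalPotential(terms=((0.0, 1, 0.0),))
        basins = hk.BasinPartition(intervals=(
            ("a", -1.0, 0.0), ("b", 0.5, 1.5)))
        pops = hk.boltzmann_populations(pot, thermo, basins)
        assert pops[0] == pytest.approx(pops[1], abs=1e-8)

    def test_phenyl_basin_free_energy_gap(self, thermo, phenyl):
        # the basin gap tracks the constructed 0.2 kcal/mol well offset up to
        # the well-width (entropic) term, which quadrature puts at ~0.03
        pops = hk.boltzmann_populations(phenyl.potential, thermo, phenyl.basins)
        gap = -thermo.rt * math.log(pops[1] / pops[0])
        assert gap == pytest.approx(0.2, abs=0.1)
        assert gap == pytest.approx(0.16614, abs=1e-4)  # frozen quadrature value


class TestBasinPartition:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            hk.BasinPartition(intervals=(("a", -1.0, 1.0), ("b", 0.5, 2.0)))

    def test_wrapping_interval_classification(self):
        basins = hk.BasinPartition(intervals=(
            ("seam", math.radians(150), math.radians(-150)),))
        lab = basins.classify(np.array([math.radians(170), math.radians(-170), 0.0]))
        assert lab.tolist() == [0, 0, -1]


class TestSampleChain:
    def test_reproducible_bit_identical(self, thermo):
        pot = hk.make_phenyl_analog()
        a = hk.sample_chain(pot, thermo, s=0.5, n_steps=5000, seed=123)
        b = hk.sample_chain(pot, thermo, s=0.5, n_steps=5000, seed=123)
        assert np.array_equal(a, b)
        c = hk.sample_chain(pot, thermo, s=0.5, n_steps=5000, seed=124)
        assert not np.array_equal(a, c)

    def test_flat_target_uniform(self, thermo):
        # thinned far beyond the walk's mixing time so multinomial bands apply
        pot = hk.TorsionalPotential(terms=((0.0, 1, 0.0),))
        traj = hk.sample_chain(pot, thermo, s=1.0, n_steps=2_000_000, seed=2)
        thin = traj[::1000]
        counts, _ = np.histogram(thin, bins=12, range=(-math.pi, math.pi))
        n, p = len(thin), 1.0 / 12.0
        sd = math.sqrt(n * p * (1 - p))
        assert np.abs(counts - n * p).max() < 3.0 * sd

    @pytest.mark.parametrize("s", [1.0, 0.5, 0.1])
    def test_chain_matches_quadrature_density(self, thermo, s):
        # chi-square goodness of fit at the 0.1% level on a thinned chain
        pot = hk.make_phenyl_analog()
        traj = hk.sample_chain(pot, thermo, s=s, n_steps=2_000_000, seed=9)
        thin = traj[::500]
        edges = np.linspace(-math.pi, math.pi, 25)
        beta_s = thermo.beta * s
        probs = np.array([quad(lambda x: math.exp(-beta_s * pot.energy(x)), a, b)[0]
                          for a, b in zip(edges[:-1], edges[1:])])
        probs /= probs.sum()
        counts, _ = np.histogram(thin, bins=edges)
        chi2 = ((counts - len(thin) * probs) ** 2 / (len(thin) * probs)).sum()
        assert sps.chi2.sf(chi2, df=len(probs) - 1) > 1e-3

    def test_distance_chain_stays_in_domain(self, thermo, two_pose):
        traj = hk.sample_chain(two_pose.potential, thermo, s=1.0, n_steps=50_000,
                               seed=4, x0=14.5)
        assert traj.min() >= 9.0 and traj.max() <= 18.0

    def test_invalid_arguments(self, thermo):
        pot = hk.make_phenyl_analog()
        with pytest.raises(ValueError):
            hk.sample_chain(pot, thermo, s=0.0, n_steps=10)
        with pytest.raises(ValueError):
            hk.sample_chain(pot, thermo, n_steps=10, step_size=-1.0)
        with pytest.raises(ValueError):
            hk.sample_chain(pot, thermo, n_steps=0)


class TestGaussianEnergyModel:
    def test_extensivity(self):
        m1 = hk.GaussianEnergyModel(n_dof=10, mean_per_dof=0.5, var_per_dof=0.3)
        m2 = hk.GaussianEnergyModel(n_dof=20, mean_per_dof=0.5, var_per_dof=0.3)
        assert m2.total_mean == pytest.approx(2 * m1.total_mean)
        assert m2.total_var == pytest.approx(2 * m1.total_var)

    def test_acceptance_probability_closed_form(self, thermo):
        # erfc form against direct Monte Carlo over the two Gaussian energies
        model = hk.GaussianEnergyModel(n_dof=50, var_per_dof=0.32)
        beta, sk, sk1 = thermo.beta, 1.0, 0.72
        rng = np.random.default_rng(0)
        var = model.total_var
        ua = rng.normal(-beta * sk * var, math.sqrt(var), 200_000)
        ub = rng.normal(-beta * sk1 * var, math.sqrt(var), 200_000)
        delta = beta * (sk - sk1) * (ub - ua)
        mc = np.minimum(1.0, np.exp(-delta)).mean()
        assert model.acceptance_probability(beta, sk, sk1) == pytest.approx(mc, abs=3e-3)

    def test_degenerate_pair_accepts_always(self, thermo):
        model = hk.GaussianEnergyModel(n_dof=50, var_per_dof=0.32)
        assert model.acceptance_probability(thermo.beta, 0.5, 0.5) == pytest.approx(1.0)
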