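import math

import numpy as np
import pytest

import hremkit as hk


@pytest.fixture(scope="session")
def thermo():
    return hk.ThermoState(temperature=300.0)


@pytest.fixture(scope="session")
def phenyl(thermo):
    return hk.get_system("phenyl", thermo)


@pytest.fixture(scope="session")
def naphthyl_t2(thermo):
    return hk.get_system("naphthyl_t2", thermo)


@pytest.fixture(scope="session")
def two_pose(thermo):
    return hk.get_system("two_pose", thermo)


@pytest.fixture(scope="session")
def phenyl_runs(phenyl, thermo):
    """Matched-budget phenyl HREM runs: geometric ladder vs adaptive equalization.

    Shared by the equalization, replica-diffusion, and Boltzmann-recovery
    checks; 5x10^4 exchange sweeps of 8 replicas, one fixed seed.
    """
    ladder = hk.geometric_ladder(8, 0.1)
    schedule = hk.ExchangeSchedule(total_steps=500_000, attempt_interval=10)
    geometric = hk.run_hrem(phenyl, ladder, schedule, thermo, adaptive=None, seed=7)
    adaptive = hk.run_hrem(phenyl, ladder, schedule, thermo,
                           adaptive=hk.AdaptiveConfig(c=2.0, n_iterations=10), seed=7)
    return {"geometric": geometric, "adaptive": adaptive}


def quadrature_label_fractions(system, thermo):
    """Basin fractions renormalized over the labelled region (the oracle the
    empirical basin_populations estimator is consistent for)."""
    pops = hk.boltzmann_populations(system.potential, thermo, system.basins)
    total = sum(pops)
    return np.array(pops) / total
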