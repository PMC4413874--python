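"""Shared fixtures.

The expensive session fixtures are simulation runs reused across many
tests: an equilibrated default-parameter chain (local observables), the
alternative soft-spring parameter pair, and the scaled condensation
ensemble (Type I / Type II / no-condensin control over matched seeds).
"""

import numpy as np
import pytest
from hypothesis import settings

from chromodyn.params import SimulationParams

settings.register_profile("chromodyn", derandomize=True, deadline=None)
settings.load_profile("chromodyn")
from chromodyn.protocols import local_equilibrium_run, scaled_condensation_run


@pytest.fixture(scope="session")
def local_eq_traj():
    """Equilibrated 300-bead chain, default parameters, no condensin."""
    return local_equilibrium_run(seed=3)


@pytest.fixture(scope="session")
def alt_pair_traj():
    """Equilibrated chain with the soft parameter pair Ks=10, c1=11."""
    return local_equilibrium_run(
        params=SimulationParams(Ks=10.0, c1=11.0),
        total_steps=400_000,
        seed=11,
    )


CONDENSATION_SEEDS = (1, 2)


@pytest.fixture(scope="session")
def condensation_runs():
    """Scaled condensation ensemble: {(mode, seed): Trajectory}.

    mode 'none' is the matched control without condensin sites.
    """
    runs = {}
    for mode in (None, "type1", "type2"):
        for seed in CONDENSATION_SEEDS:
            r = scaled_condensation_run(mode, seed)
            runs[(mode or "none", seed)] = r.trajectory
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_state():
    """A 30-bead random-geometry chain with 5 condensin sites."""
    from chromodyn.calibrate import equilibrated_chain_positions
    from chromodyn.chain import build_chain

    return build_chain(
        30,
        positions=equilibrated_chain_positions(30, seed=7),
        condensin_sites=[2, 8, 14, 20, 26],
    )


@pytest.fixture(scope="session")
def two_chain_runs():
    """Two overlapping 100-bead chains condensing under each model."""
    from chromodyn.calibrate import equilibrated_chain_positions
    from chromodyn.chain import build_chain, concatenate_chains
    from chromodyn.integrate import Phase, SimulationConfig, run

    runs = {}
    for mode in ("type1", "type2"):
        chains = []
        for k in range(2):
            pos = equilibrated_chain_positions(100, seed=10 + k)
            pos += np.array([20.0 * k, 0.0, 0.0])
            chains.append(build_chain(100, positions=pos, site_interval_bp=2250.0))
        merged = concatenate_chains(*chains)
        cfg = SimulationConfig(
            n_beads=merged.n_beads,
            site_interval_bp=None,
            params=SimulationParams(mode=mode, p=1e-3),
            phases=[Phase(steps=200_000), Phase(steps=400_000, p=1e-4)],
            stride=4000,
            seed=5,
        )
        runs[mode] = run(cfg, state=merged)
    return runs
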