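"""Force-field terms: magnitudes, ranges, symmetries, gradient oracles."""

import numpy as np
import pytest
from scipy import stats

from chromodyn.bonds import BondSet
from chromodyn.chain import ChainState, build_chain
from chromodyn.forces import (
    attraction_force,
    condensin_force,
    entropic_force,
    random_unit_vectors,
    repulsion_force,
    repulsion_magnitude,
    tension_force,
    total_force,
)
from chromodyn.params import SimulationParams

PARAMS = SimulationParams()


def random_chain(n, rng, spacing=15.0, sites=()):
    steps = rng.standard_normal((n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1)[:, None]
    pos = np.vstack([np.zeros(3), np.cumsum(steps * spacing, axis=0)])
    return build_chain(n, positions=pos, condensin_sites=list(sites))


def numeric_gradient(energy, pos, eps=1e-6):
    """Central finite differences of a scalar energy over positions."""
    g = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for k in range(3):
            up = pos.copy()
            up[i, k] += eps
            dn = pos.copy()
            dn[i, k] -= eps
            g[i, k] = (energy(up) - energy(dn)) / (2 * eps)
    return g


class TestEntropicForce:
    def test_magnitude_is_exactly_c1(self, rng):
        state = build_chain(50)
        F = entropic_force(state, PARAMS, rng)
        assert np.allclose(np.linalg.norm(F, axis=1), 24.5)

    def test_isotropy_mean_vanishes(self, rng):
        v = random_unit_vectors(100_000, rng)
        assert np.all(np.abs(v.mean(axis=0)) < 0.02)

    def test_octant_uniformity_chi2(self, rng):
        v = random_unit_vectors(80_000, rng)
        octant = (v[:, 0] > 0) * 4 + (v[:, 1] > 0) * 2 + (v[:, 2] > 0)
        counts = np.bincount(octant, minlength=8)
        _, pval = stats.chisquare(counts)
        assert pval > 1e-3

    def test_redrawn_each_call(self, rng):
        state = build_chain(10)
        assert not np.allclose(
            entropic_force(state, PARAMS, rng), entropic_force(state, PARAMS, rng)
        )


class TestTensionForce:
    def test_zero_at_rest_length(self):
        state = build_chain(10, spacing=15.0)
        assert np.allclose(tension_force(state, PARAMS), 0.0)

    def test_one_stretched_linker_gives_50pN(self):
        state = build_chain(3, spacing=15.0)
        state.positions[2, 2] += 1.0  # linker 1-2 now 16 nm
        F = tension_force(state, PARAMS)
        # Ks=50 pN/nm * 1 nm, pulling the pair together
        assert F[1, 2] == pytest.approx(50.0)
        assert F[2, 2] == pytest.approx(-50.0)
        assert np.allclose(F[0], 0.0)

    def test_matches_finite_difference_gradient(self, rng):
        state = random_chain(5, rng)
        Ks, c2 = PARAMS.Ks, PARAMS.c2

        def energy(pos):
            d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            return 0.5 * Ks * ((d - c2) ** 2).sum()

        F = tension_force(state, PARAMS)
        assert np.allclose(F, -numeric_gradient(energy, state.positions), atol=1e-5)

    def test_end_beads_have_single_term(self, rng):
        state = random_chain(4, rng, spacing=18.0)
        F = tension_force(state, PARAMS)
        v = state.positions[1] - state.positions[0]
        d = np.linalg.norm(v)
        expected = PARAMS.Ks * (d - PARAMS.c2) * v / d
        assert np.allclose(F[0], expected)


class TestRepulsionForce:
    def test_overlapping_pair_feels_c3_each(self):
        state = ChainState(np.array([[0.0, 0, 0], [8.0, 0, 0], [100.0, 0, 0]]))
        F = repulsion_force(state, PARAMS)
        assert F[0, 0] == pytest.approx(-10.0)
        assert F[1, 0] == pytest.approx(10.0)
        assert np.allclose(F[2], 0.0)

    def test_out_of_range_pair_feels_nothing(self):
        state = ChainState(np.array([[0.0, 0, 0], [20.0, 0, 0], [40.0, 0, 0]]))
        assert np.allclose(repulsion_force(state, PARAMS), 0.0)

    def test_magnitude_profile_monotone_and_continuous(self):
        d = np.linspace(0.5, 15.0, 400)
        mag = repulsion_magnitude(d, PARAMS)
        assert np.all(np.diff(mag) <= 1e-12)  # non-increasing
        # continuous at the 10 nm bead diameter
        assert repulsion_magnitude(np.array([10.0 - 1e-9]), PARAMS)[0] == pytest.approx(
            repulsion_magnitude(np.array([10.0 + 1e-9]), PARAMS)[0], rel=1e-6
        )
        # soft-core value at the 15 nm edge: c3 / 1.5^12
        assert repulsion_magnitude(np.array([15.0]), PARAMS)[0] == pytest.approx(
            10.0 / 1.5**12
        )
        assert repulsion_magnitude(np.array([15.01]), PARAMS)[0] == 0.0

    def test_support_is_exactly_repulsion_radius(self, rng):
        state = random_chain(20, rng, spacing=15.5)
        F = repulsion_force(state, PARAMS)
        d = np.linalg.norm(
            state.positions[None] - state.positions[:, None], axis=2
        )
        np.fill_diagonal(d, np.inf)
        isolated = (d > 15.0).all(axis=1)
        assert np.allclose(F[isolated], 0.0)


class TestAttractionForce:
    def test_switch_off(self, rng):
        state = random_chain(10, rng)
        F = attraction_force(state, PARAMS.with_(c4=0.0))
        assert np.allclose(F, 0.0)

    def test_boundary_bead_has_single_term(self, rng):
        state = random_chain(6, rng)
        F = attraction_force(state, PARAMS)
        v = state.positions[2] - state.positions[0]
        assert np.allclose(F[0], PARAMS.c4 * v)

    def test_magnitude_proportional_to_distance(self):
        pos = np.zeros((3, 3))
        pos[1] = [15.0, 0, 0]
        pos[2] = [15.0, 25.0, 0]
        state = ChainState(pos)
        F = attraction_force(state, PARAMS)
        d02 = np.linalg.norm(pos[2] - pos[0])
        assert np.linalg.norm(F[0]) == pytest.approx(PARAMS.c4 * d02)

    def test_matches_finite_difference_gradient(self, rng):
        state = random_chain(6, rng)
        c4 = PARAMS.c4

        def energy(pos):
            d2 = ((pos[2:] - pos[:-2]) ** 2).sum(axis=1)
            return 0.5 * c4 * d2.sum()

        F = attraction_force(state, PARAMS)
        assert np.allclose(F, -numeric_gradient(energy, state.positions), atol=1e-6)


class TestCondensinForce:
    @pytest.fixture
    def sited_state(self):
        pos = np.zeros((10, 3))
        pos[:, 2] = np.arange(10) * 100.0  # far apart along z
        return pos

    def make(self, pos, d):
        pos = pos.copy()
        pos[5] = pos[0] + [d, 0.0, 0.0]
        return ChainState(pos, condensin_sites=[0, 5])

    def test_zero_at_rest_length(self, sited_state):
        state = self.make(sited_state, 30.0)
        F = condensin_force(state, BondSet({(0, 5)}), PARAMS)
        assert np.allclose(F, 0.0)

    def test_zero_beyond_interaction_radius(self, sited_state):
        state = self.make(sited_state, 45.0)
        F = condensin_force(state, BondSet({(0, 5)}), PARAMS)
        assert np.allclose(F, 0.0)

    def test_hooke_arithmetic_at_35nm(self, sited_state):
        state = self.make(sited_state, 35.0)
        F = condensin_force(state, BondSet({(0, 5)}), PARAMS)
        # 50 pN/nm * 5 nm = 250 pN pulling together
        assert F[0, 0] == pytest.approx(250.0)
        assert F[5, 0] == pytest.approx(-250.0)

    def test_bond_between_non_sites_rejected(self, sited_state):
        state = self.make(sited_state, 35.0)
        with pytest.raises(ValueError):
            condensin_force(state, BondSet({(0, 3)}), PARAMS)

    def test_type2_site_sums_two_bond_terms(self):
        pos = np.zeros((9, 3))
        pos[:, 2] = np.arange(9) * 200.0
        pos[4] = [0.0, 0.0, 0.0]
        pos[0] = [35.0, 0.0, 0.0]
        pos[8] = [0.0, 32.0, 0.0]
        state = ChainState(pos, condensin_sites=[0, 4, 8])
        F = condensin_force(state, BondSet({(4, 0), (4, 8)}), PARAMS)
        expected = np.array([50.0 * 5.0, 50.0 * 2.0, 0.0])
        assert np.allclose(F[4], expected)


class TestTotalForce:
    def test_rest_chain_without_noise_is_force_free(self, rng):
        state = build_chain(10, spacing=15.0)
        params = PARAMS.with_(c1=0.0, c4=0.0)
        F = total_force(state, BondSet(), params, rng)
        # linkers sit exactly at the repulsion cutoff (support is (0, 15]),
        # leaving a c3/1.5^12 ~ 0.08 pN residual on the two end beads only;
        # interior beads are exactly force-free
        assert np.allclose(F[1:-1], 0.0)
        assert np.all(np.linalg.norm(F, axis=1) <= PARAMS.c3 / 1.5**12 + 1e-12)

    def test_additivity_of_terms(self, rng):
        state = random_chain(12, rng, sites=[1, 6, 11])
        bonds = BondSet({(1, 6)})
        F, terms = total_force(state, bonds, PARAMS, rng, decompose=True)
        assert np.allclose(F, sum(terms.values()))

    def test_deterministic_given_seed(self):
        state = build_chain(8)
        F1 = total_force(state, BondSet(), PARAMS, np.random.default_rng(5))
        F2 = total_force(state, BondSet(), PARAMS, np.random.default_rng(5))
        assert np.array_equal(F1, F2)


class TestNewtonsThirdLaw:
    """Deterministic pairwise terms must sum to zero over the chain."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_net_deterministic_force_vanishes(self, seed):
        rng = np.random.default_rng(seed)
        state = random_chain(25, rng, spacing=12.0, sites=[0, 6, 12, 18, 24])
        bonds = BondSet({(0, 6), (12, 18)})
        for term in (tension_force, repulsion_force, attraction_force):
            assert np.allclose(term(state, PARAMS).sum(axis=0), 0.0, atol=1e-9)
        assert np.allclose(
            condensin_force(state, bonds, PARAMS).sum(axis=0), 0.0, atol=1e-9
        )

    def test_repulsion_pairwise_antisymmetric(self):
        state = ChainState(np.array([[0.0, 0, 0], [9.0, 0, 0]]))
        F = repulsion_force(state, PARAMS)
        assert np.allclose(F[0], -F[1])
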