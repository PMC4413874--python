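"""Distance maps, rosettes, 4C profiles, volume, contacts, persistence."""

import numpy as np
import pytest

from chromodyn.chain import ChainState, build_chain, concatenate_chains
from chromodyn.structure import (
    interchain_contacts,
    long_range_fraction,
    occupied_volume,
    persistence_length,
    project_genome_volume,
    rosette_clusters,
    rosette_stats,
    site_distance_map,
    viewpoint_profile,
)
from chromodyn.trajectory import Trajectory


def traj_from_frames(frames, sites=(), seconds_per_step=1.0, bp_per_bead=150.0):
    frames = np.asarray(frames, dtype=np.float32)
    return Trajectory(
        frames=frames,
        step_index=np.arange(frames.shape[0]),
        seconds_per_step=seconds_per_step,
        sites=np.array(sorted(sites), np.int64),
        chain_id=np.zeros(frames.shape[1], np.int64),
        bp_per_bead=bp_per_bead,
    )


class TestSiteDistanceMap:
    def test_two_sites(self):
        pos = np.zeros((4, 3))
        pos[3] = [100.0, 0, 0]
        state = ChainState(pos, condensin_sites=[0, 3])
        m = site_distance_map(state)
        assert m.shape == (2, 2)
        assert m[0, 1] == pytest.approx(100.0)
        assert np.allclose(np.diag(m), 0.0)

    def test_symmetry_and_triangle_inequality(self, rng):
        pos = rng.uniform(0, 200, size=(12, 3))
        state = ChainState(pos, condensin_sites=list(range(12)))
        m = site_distance_map(state)
        assert np.allclose(m, m.T)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_collinear_sites_give_arithmetic_rows(self):
        pos = np.zeros((5, 3))
        pos[:, 0] = np.arange(5) * 30.0
        state = ChainState(pos, condensin_sites=list(range(5)))
        m = site_distance_map(state)
        assert np.allclose(m[0], [0.0, 30.0, 60.0, 90.0, 120.0])

    def test_needs_two_sites(self):
        state = ChainState(np.zeros((3, 3)), condensin_sites=[1])
        with pytest.raises(ValueError):
            site_distance_map(state)


class TestRosetteClusters:
    def test_triplet_within_radius_is_one_rosette(self):
        pos = np.zeros((6, 3))
        pos[2] = [30.0, 0, 0]
        pos[4] = [0.0, 30.0, 0]
        state = ChainState(pos, condensin_sites=[0, 2, 4])
        rosettes, web = rosette_clusters(state, radius=40.0)
        assert len(rosettes) == 1 and len(web) == 0
        assert set(rosettes[0]) == {0, 2, 4}

    def test_pairs_are_web_not_rosette(self):
        pos = np.zeros((4, 3))
        pos[3] = [30.0, 0, 0]
        state = ChainState(pos, condensin_sites=[0, 3])
        rosettes, web = rosette_clusters(state, radius=40.0)
        assert rosettes == [] and len(web) == 1

    def test_single_linkage_is_transitive(self):
        """A-B and B-C within 40 nm but A-C beyond: one cluster {A,B,C}."""
        pos = np.zeros((3, 3))
        pos[1] = [38.0, 0, 0]
        pos[2] = [76.0, 0, 0]
        state = ChainState(pos, condensin_sites=[0, 1, 2])
        rosettes, _ = rosette_clusters(state, radius=40.0)
        assert len(rosettes) == 1 and set(rosettes[0]) == {0, 1, 2}

    def test_partition_covers_all_sites(self, rng):
        pos = rng.uniform(0, 150, size=(20, 3))
        state = ChainState(pos, condensin_sites=list(range(20)))
        rosettes, web = rosette_clusters(state, radius=40.0)
        members = sorted(int(x) for grp in rosettes + web for x in grp)
        assert members == list(range(20))


class TestRosetteStats:
    def test_no_triples_gives_zero_percent(self, rng):
        frames = np.tile(rng.uniform(0, 1000, (8, 3)), (5, 1, 1))
        traj = traj_from_frames(frames, sites=[0, 3, 6])
        stats = rosette_stats(traj)
        assert stats.percent_sites_in_rosettes == 0.0
        assert stats.records == []

    def test_permanent_triplet_lives_whole_trajectory(self):
        pos = np.zeros((9, 3))
        pos[:, 0] = np.arange(9) * 100.0
        pos[4] = pos[0] + [20.0, 0, 0]
        pos[8] = pos[0] + [0.0, 20.0, 0]
        frames = np.tile(pos, (6, 1, 1))
        traj = traj_from_frames(frames, sites=[0, 4, 8], seconds_per_step=2.0)
        stats = rosette_stats(traj)
        assert len(stats.records) == 1
        assert stats.records[0].lifespan_frames == 6
        assert stats.mean_lifespan_seconds == pytest.approx(6 * 2.0)
        assert stats.percent_sites_in_rosettes == pytest.approx(100.0)
        assert stats.mean_size == pytest.approx(3.0)

    def test_tracking_by_member_overlap(self):
        """A rosette that loses one of four members keeps its identity."""
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10) * 300.0
        sites = [0, 3, 6, 9]
        for s in sites:
            pos[s] = [0.0, s * 3.0, 0.0]  # all four clustered
        f1 = pos.copy()
        f2 = pos.copy()
        f2[9] = [500.0, 0, 0]  # site 9 leaves
        frames = np.stack([f1, f1, f2])
        traj = traj_from_frames(frames, sites=sites)
        stats = rosette_stats(traj)
        assert len(stats.records) == 1
        assert stats.records[0].lifespan_frames == 3


class TestViewpointProfile:
    def test_profile_sums_to_one(self, local_eq_traj):
        prof = viewpoint_profile(local_eq_traj, 150, discard_frames=120)
        assert prof.frequencies.sum() == pytest.approx(1.0)
        assert np.all(prof.frequencies >= 0.0)
        assert prof.frequencies[150] == 0.0  # self excluded

    def test_immediate_neighbours_dominate(self, local_eq_traj):
        prof = viewpoint_profile(local_eq_traj, 150, discard_frames=120)
        local = prof.frequencies[147:154].sum()
        assert local > 10 * prof.frequencies[[50, 250]].sum()

    def test_no_contacts_is_an_error(self):
        frames = np.zeros((3, 2, 3), dtype=np.float32)
        frames[:, 1] = [500.0, 0, 0]
        traj = traj_from_frames(frames)
        with pytest.raises(ValueError):
            viewpoint_profile(traj, 0)


class TestLongRangeFraction:
    def test_local_contacts_only_gives_zero(self):
        frames = np.zeros((2, 100, 3), dtype=np.float32)
        frames[:] = np.arange(100)[None, :, None] * [15.0, 0, 0]
        frames[:, 51] = frames[:, 50] + [20.0, 0, 0]
        traj = traj_from_frames(frames)
        prof = viewpoint_profile(traj, 50)
        assert long_range_fraction(prof, 10_000.0) == 0.0

    def test_uniform_profile_counting_oracle(self):
        """Uniform contact frequencies: the fraction equals the share of
        beads beyond the genomic threshold."""
        from chromodyn.structure import ViewpointProfile

        n, vp, bpb = 200, 100, 150.0
        freqs = np.full(n, 1.0 / (n - 1))
        freqs[vp] = 0.0
        prof = ViewpointProfile(
            viewpoint=vp, frequencies=freqs,
            genomic_bp=np.arange(n) * bpb, contact_radius=40.0, bp_per_bead=bpb,
        )
        thr = 7500.0  # 50 beads
        expected = 100.0 * (np.abs(np.arange(n) - vp) * bpb > thr).sum() / (n - 1)
        assert long_range_fraction(prof, thr) == pytest.approx(expected)

    def test_threshold_beyond_chain_warns_and_returns_zero(self):
        frames = np.zeros((2, 10, 3), dtype=np.float32)
        frames[:] = np.arange(10)[None, :, None] * [15.0, 0, 0]
        traj = traj_from_frames(frames)
        prof = viewpoint_profile(traj, 5)
        with pytest.warns(UserWarning):
            assert long_range_fraction(prof, 1e9) == 0.0


class TestOccupiedVolume:
    def test_single_bead_occupies_one_cell(self):
        state = ChainState(np.array([[10.0, 10.0, 10.0]]))
        assert occupied_volume(state, 50.0) == pytest.approx(1.25e-4)

    def test_two_beads_in_one_cell_count_once(self):
        state = ChainState(np.array([[10.0, 10, 10], [20.0, 20, 20]]))
        assert occupied_volume(state, 50.0) == pytest.approx(1.25e-4)

    def test_separated_beads_occupy_two_cells(self):
        state = ChainState(np.array([[10.0, 10, 10], [90.0, 10, 10]]))
        assert occupied_volume(state, 50.0) == pytest.approx(2.5e-4)

    def test_projection_scales_by_factor(self):
        assert project_genome_volume(5.0e-2, 40.0) == pytest.approx(2.0)
        assert project_genome_volume(0.0, 40.0) == 0.0
        assert project_genome_volume(0.123, 1.0) == pytest.approx(0.123)


class TestInterchainContacts:
    def test_separated_chains_have_no_contacts(self):
        c1 = build_chain(10)
        c2 = build_chain(10)
        c2.positions[:, 0] += 10_000.0
        merged = concatenate_chains(c1, c2)
        assert interchain_contacts(merged, 40.0) == 0.0

    def test_superposed_chains_hit_floor_of_n_contacts(self):
        c1 = build_chain(10)
        c2 = build_chain(10)
        merged = concatenate_chains(c1, c2)
        assert interchain_contacts(merged, 40.0) >= 10

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            interchain_contacts(build_chain(10), 40.0)


class TestPersistenceLength:
    def test_rigid_rod_lp_equals_cutoff(self):
        """K_or = 1 everywhere, so Lp integrates to the cutoff length."""
        state = build_chain(101, spacing=15.0, bp_per_bead=150.0)
        res = persistence_length([state] * 5, cutoff_bp=6000.0)
        assert np.allclose(res.correlation, 1.0)
        # 6000 bp = 40 beads = 600 nm of contour
        assert res.lp_nm == pytest.approx(600.0, rel=1e-6)

    def test_freely_jointed_chain_matches_closed_form(self, rng):
        """FJC with independent segments: K_or decays as <cos>^k and the
        summed correlation matches b/(1 - <cos>) (here <cos> = 0 -> Lp = b)."""
        b = 15.0
        states = []
        for _ in range(100):
            steps = rng.standard_normal((400, 3))
            steps /= np.linalg.norm(steps, axis=1)[:, None]
            pos = np.vstack([np.zeros(3), np.cumsum(steps * b, axis=0)])
            states.append(ChainState(pos, bp_per_bead=150.0))
        res = persistence_length(states, cutoff_bp=15_000.0)
        assert res.correlation[0] == pytest.approx(1.0)
        assert abs(res.correlation[1]) < 0.02
        assert res.lp_nm == pytest.approx(b, abs=2.0)

    def test_loop_ensembles_show_lp_growing_with_distance(self, condensation_runs):
        traj = condensation_runs[("type1", 1)]
        states = [traj.state(k) for k in range(150, traj.n_frames, 10)]
        res = persistence_length(states, cutoff_bp=20_000.0)
        bond = res.contour_nm[1]
        lp_short = res.lp_at(3000.0, 150.0 / bond)
        lp_long = res.lp_at(20_000.0, 150.0 / bond)
        assert lp_long > lp_short
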