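"""Network simulations: connectivity, initialization, spikes, phases."""

import numpy as np
import pytest

import phaselattice as pl
from phaselattice import ClusterSolution, CouplingWeights, TorusLattice, fixtures
from phaselattice.lattice import phase_field


class TestConnectivity:
    def test_eight_nearest_neighbors(self):
        lat = TorusLattice(6, 6)
        conn = pl.build_connectivity(lat, CouplingWeights.symmetric(h1=1, v1=1, d=1))
        counts = (conn.W > 0).sum(axis=1)
        assert np.all(counts == 8)
        assert np.allclose(conn.W.sum(axis=1), 8.0)
        assert np.all(np.diag(conn.W) == 0.0)

    def test_twelve_neighbors_with_second_nearest(self):
        lat = TorusLattice(6, 6)
        conn = pl.build_connectivity(
            lat, CouplingWeights.symmetric(h1=1, v1=1, d=1, h2=1, v2=1))
        assert np.all((conn.W > 0).sum(axis=1) == 12)
        assert np.allclose(conn.W.sum(axis=1), 12.0)

    def test_coinciding_offsets_summed_on_small_lattice(self, caplog):
        """On a 4-wide torus the +2 and -2 horizontal offsets reach the
        same neighbor, so its weight doubles (and likewise vertically
        when the lattice is also 4 tall)."""
        with caplog.at_level("WARNING"):
            conn = pl.build_connectivity(
                TorusLattice(6, 4), CouplingWeights.symmetric(h1=1, v1=1, d=1, h2=1, v2=1))
        assert np.all((conn.W > 0).sum(axis=1) == 11)
        assert np.allclose(conn.W.sum(axis=1), 12.0)
        assert any("coinciding" in r.message for r in caplog.records)
        conn44 = pl.build_connectivity(
            TorusLattice(4, 4), CouplingWeights.symmetric(h1=1, v1=1, d=1, h2=1, v2=1))
        assert np.all((conn44.W > 0).sum(axis=1) == 10)  # both directions fold
        assert np.allclose(conn44.W.sum(axis=1), 12.0)

    def test_symmetry_from_symmetric_shorthand(self):
        lat = TorusLattice(6, 4)
        conn = pl.build_connectivity(lat, CouplingWeights.symmetric(1, 2, 0.5, 0.2, 0.1))
        assert np.allclose(conn.W, conn.W.T)


class TestInitialization:
    def test_synchronous_pattern_identical_states(self, limit_cycle):
        lat = TorusLattice(4, 4)
        states = pl.init_from_pattern(ClusterSolution(1, 0, 1, 0), limit_cycle, lat)
        assert np.allclose(states, states[0])

    def test_antiphase_states_half_period_apart(self, limit_cycle):
        lat = TorusLattice(4, 4)
        states = pl.init_from_pattern(ClusterSolution(2, 1, 2, 1), limit_cycle, lat)
        uniq = np.unique(np.round(states[:, 0], 9))
        assert len(uniq) == 2
        assert np.allclose(states[1], limit_cycle.state_at_phase(np.pi), atol=1e-9)

    def test_alternating_template_cluster_membership(self):
        """1-based row-major cell numbers of the four clusters on 4x4."""
        lat = TorusLattice(4, 4)
        f = pl.alternating_four_cluster(lat)
        groups = pl.cluster_partition(f)
        numbered = [sorted(lat.site_index(i, j) + 1 for i, j in g) for g in groups]
        assert numbered == [
            [1, 3, 9, 11],      # phase 0
            [2, 4, 10, 12],     # phase pi/2
            [6, 8, 14, 16],     # phase pi
            [5, 7, 13, 15],     # phase 3pi/2
        ]

    def test_alternating_template_on_six_by_six(self):
        groups = pl.cluster_partition(pl.alternating_four_cluster(TorusLattice(6, 6)))
        assert [len(g) for g in groups] == [9, 9, 9, 9]

    def test_unknown_template_rejected(self, limit_cycle):
        with pytest.raises(ValueError, match="unknown template"):
            pl.init_from_pattern("spiral", limit_cycle, TorusLattice(4, 4))


class TestBiophysical:
    def test_decoupled_cells_fire_at_intrinsic_period(self, limit_cycle):
        lat = TorusLattice(2, 2)
        conn = pl.build_connectivity(lat, CouplingWeights.symmetric())
        states = pl.init_from_pattern(ClusterSolution(1, 0, 1, 0), limit_cycle, lat)
        spikes, _ = pl.simulate_biophysical(states, conn, limit_cycle.params, 300.0)
        isis = np.diff(spikes.trains[0])
        assert np.allclose(isis, limit_cycle.T, atol=0.2)

    def test_synchronous_state_stays_synchronous(self, limit_cycle):
        """Exact synchrony is preserved by permutation symmetry."""
        lat = TorusLattice(4, 4)
        conn = pl.build_connectivity(lat, CouplingWeights.symmetric(h1=1, v1=1, d=1))
        states = pl.init_from_pattern(ClusterSolution(1, 0, 1, 0), limit_cycle, lat)
        spikes, _ = pl.simulate_biophysical(states, conn, limit_cycle.params, 400.0)
        n0 = len(spikes.trains[0])
        for train in spikes.trains[1:]:
            assert len(train) == n0
            assert np.allclose(train, spikes.trains[0], atol=0.05)

    def test_translation_equivariance(self, limit_cycle):
        """Shifting the initial pattern by a lattice translation shifts
        the spike pattern identically."""
        lat = TorusLattice(4, 4)
        conn = pl.build_connectivity(lat, CouplingWeights.symmetric(h1=1, v1=1))
        base = phase_field(ClusterSolution(2, 1, 1, 0), lat)
        shifted = pl.PhaseField(lat, np.roll(base.phases, 1, axis=1))
        sp_a, _ = pl.simulate_biophysical(
            pl.init_from_pattern(base, limit_cycle), conn, limit_cycle.params, 300.0)
        sp_b, _ = pl.simulate_biophysical(
            pl.init_from_pattern(shifted, limit_cycle), conn, limit_cycle.params, 300.0)
        for j in range(4):
            for i in range(4):
                a = sp_a.trains[lat.site_index(i, j)]
                b = sp_b.trains[lat.site_index(i + 1, j)]
                assert len(a) == len(b)
                assert np.allclose(a, b, atol=0.05)

    def test_perturbation_window_validated(self):
        with pytest.raises(ValueError, match="t_on < t_off"):
            pl.PerturbationProtocol(targets=(0,), delta_I=0.1, t_on=10.0, t_off=5.0)

    def test_cluster_firing_multiplies_population_rate(self, limit_cycle):
        """In a 2-cluster run the population event rate doubles the
        intrinsic cell rate."""
        lat = TorusLattice(4, 4)
        conn = pl.build_connectivity(lat, CouplingWeights.symmetric(h1=1, v1=1))
        states = pl.init_from_pattern(ClusterSolution(2, 1, 2, 1), limit_cycle, lat)
        spikes, _ = pl.simulate_biophysical(states, conn, limit_cycle.params, 500.0)
        all_spikes = np.sort(np.concatenate([t[t > 100] for t in spikes.trains]))
        events = 1 + int(np.sum(np.diff(all_spikes) > 5.0))
        cell_rate = len(spikes.trains[0][spikes.trains[0] > 100])
        assert events == pytest.approx(2 * cell_rate, abs=1)


class TestEmpiricalPhases:
    def test_decoupled_pattern_phases_recovered(self, limit_cycle, phase_tol):
        """With zero coupling each cell keeps its initial phase, fixing
        the sign convention of the spike-time readout."""
        lat = TorusLattice(6, 6)
        conn = pl.build_connectivity(lat, CouplingWeights.symmetric())
        target = phase_field(ClusterSolution(3, 1, 3, 1), lat)
        states = pl.init_from_pattern(target, limit_cycle)
        spikes, _ = pl.simulate_biophysical(states, conn, limit_cycle.params, 400.0)
        obs = pl.empirical_phases(spikes, lat, window=(50.0, 400.0))
        assert pl.matches_pattern(obs, target, phase_tol)
        # orientation really distinguished: the mirrored pattern differs
        mirror = phase_field(ClusterSolution(3, 2, 3, 2), lat)
        assert not pl.matches_pattern(obs, mirror, phase_tol)

    def test_silent_cell_raises(self):
        trains = [np.array([10.0, 60.0, 110.0, 160.0])] * 3 + [np.array([10.0])]
        spikes = pl.SpikeTrains(trains=trains, duration=200.0)
        with pytest.raises(ValueError, match="fewer than 3 spikes"):
            pl.empirical_phases(spikes, TorusLattice(2, 2))


class TestPatternMatching:
    def test_identity_and_global_shift(self):
        lat = TorusLattice(6, 6)
        f = phase_field(ClusterSolution(2, 1, 3, 1), lat)
        shifted = pl.PhaseField(lat, f.phases + 1.234)
        assert pl.matches_pattern(f, f, 0.01)
        assert pl.matches_pattern(shifted, f, 0.01)

    def test_horizontal_vs_vertical_stripes_differ(self):
        lat = TorusLattice(6, 6)
        horiz = phase_field(ClusterSolution(1, 0, 2, 1), lat)
        vert = phase_field(ClusterSolution(2, 1, 1, 0), lat)
        assert not pl.matches_pattern(horiz, vert, 0.5)


class TestPhaseModel:
    def test_locked_solution_drifts_at_corrected_frequency(self):
        """A cluster solution of the reduced model keeps its phase
        differences and drifts at Omega + eps * omega."""
        H = fixtures.two_harmonic_interaction()
        lat = TorusLattice(6, 6)
        w = CouplingWeights.symmetric(h1=1.0, v1=0.8, d=0.3)
        sol = ClusterSolution(2, 1, 3, 1)
        omega = pl.frequency_correction(sol, w, H)
        eps, Om = 0.05, 0.12
        f0 = phase_field(sol, lat)
        t, theta = pl.simulate_phase_model(f0, w, H, lat, eps=eps, Omega=Om,
                                           duration=200.0)
        drift = theta[-1] - theta[0]
        assert np.allclose(drift, (Om + eps * omega) * t[-1], atol=1e-5)
        diffs = theta[-1] - f0.flat
        assert np.ptp(diffs) < 1e-6

    def test_perturbed_stable_solution_returns(self, ):
        """Reduced-model check consistent with the closed-form verdict:
        (pi, pi) under -sin coupling recovers from a small kick."""
        H = fixtures.negative_sine_interaction()
        lat = TorusLattice(4, 4)
        w = CouplingWeights.symmetric(h1=1.0, v1=1.0)
        sol = ClusterSolution(2, 1, 2, 1)
        rng = np.random.default_rng(5)
        theta0 = phase_field(sol, lat).flat + 0.1 * rng.standard_normal(16)
        _, theta = pl.simulate_phase_model(theta0, w, H, lat, eps=1.0, duration=100.0)
        final = pl.PhaseField(lat, theta[-1].reshape(4, 4))
        assert pl.matches_pattern(final, phase_field(sol, lat), 1e-3)

    def test_perturbed_unstable_solution_departs(self):
        H = fixtures.negative_sine_interaction()
        lat = TorusLattice(4, 4)
        w = CouplingWeights.symmetric(h1=1.0, v1=1.0)
        sync = ClusterSolution(1, 0, 1, 0)
        rng = np.random.default_rng(5)
        theta0 = phase_field(sync, lat).flat + 0.1 * rng.standard_normal(16)
        _, theta = pl.simulate_phase_model(theta0, w, H, lat, eps=1.0, duration=100.0)
        final = pl.PhaseField(lat, theta[-1].reshape(4, 4))
        assert not pl.matches_pattern(final, phase_field(sync, lat), 0.5)


class TestSpikeSerialization:
    def test_roundtrip(self, tmp_path):
        trains = [np.array([1.0, 51.2]), np.array([26.5, 77.0]),
                  np.array([]), np.array([40.0])]
        spikes = pl.SpikeTrains(trains=trains, duration=100.0)
        path = tmp_path / "spikes.csv"
        pl.save_spike_trains(spikes, path)
        back = pl.load_spike_trains(path, n_cells=4, duration=100.0)
        for a, b in zip(trains, back.trains):
            assert np.allclose(a, b)
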