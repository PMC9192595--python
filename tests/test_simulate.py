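"""Generator correctness: CTMC paths, camera rendering, dataset assembly."""

import numpy as np
import pytest

import quadfret as qf
from quadfret.errors import ParameterError
from quadfret.statepath import Segment, StatePath


def two_state_model(rate=0.5):
    return qf.KineticModel(
        states=("A", "B"),
        rates=np.array([[0.0, rate], [rate, 0.0]]),
        emission_mean=np.array([0.3, 0.7]),
        emission_sd=0.0,
    )


class TestKineticModel:
    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            qf.KineticModel(
                states=("A", "B"),
                rates=np.array([[0.0, -1.0], [1.0, 0.0]]),
                emission_mean=np.array([0.3, 0.7]),
            )

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ParameterError):
            qf.KineticModel(
                states=("A",),
                rates=np.array([[1.0]]),
                emission_mean=np.array([0.5]),
            )

    def test_mean_dwell_is_inverse_exit_rate(self):
        m = qf.construct_model("TelG5")
        assert m.mean_dwell["NP"] == pytest.approx(7.6)
        assert m.mean_dwell["P"] == pytest.approx(10.3)

    def test_stationary_distribution_solves_balance(self):
        m = qf.construct_model("TelG5TTT")
        pi = m.stationary_distribution()
        np.testing.assert_allclose(pi @ m.generator, 0.0, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)

    def test_frozen_model_stationary_is_uniform(self):
        m = qf.KineticModel(
            states=("A", "B"),
            rates=np.zeros((2, 2)),
            emission_mean=np.array([0.3, 0.7]),
        )
        np.testing.assert_allclose(m.stationary_distribution(), [0.5, 0.5])


class TestSimulateStatePath:
    def test_single_state_covers_duration(self):
        m = qf.KineticModel(
            states=("A",), rates=np.zeros((1, 1)), emission_mean=np.array([0.5])
        )
        p = qf.simulate_state_path(m, 37.5, np.random.default_rng(0))
        assert len(p.segments) == 1
        assert p.segments[0].start == 0.0
        assert p.segments[0].end == 37.5

    def test_segments_tile_duration_exactly(self):
        p = qf.simulate_state_path(two_state_model(), 50.0, np.random.default_rng(1))
        assert p.start == 0.0
        assert p.end == 50.0
        for a, b in zip(p.segments[:-1], p.segments[1:]):
            assert a.end == b.start
            assert a.state != b.state

    def test_symmetric_two_state_mean_dwell(self):
        """k(1->2)=k(2->1)=0.5/s gives mean dwell 2 s, within 3% on a long path."""
        p = qf.simulate_state_path(two_state_model(0.5), 1e5, np.random.default_rng(2))
        for state in ("A", "B"):
            dwells = [s.duration for s in p.segments[1:-1] if s.state == state]
            assert np.mean(dwells) == pytest.approx(2.0, rel=0.03)

    def test_preset_dwell_means_recovered(self):
        """Construct-preset mean dwells (UF/NP/P seconds scale) are reproduced
        by long-path empirical dwell averages within 5%."""
        m = qf.construct_model("TelG5TAA", docked_fraction=0.0)
        p = qf.simulate_state_path(m, 5e4, np.random.default_rng(3))
        for state, expected in qf.CONSTRUCTS["TelG5TAA"]["dwell"].items():
            dwells = [s.duration for s in p.segments[1:-1] if s.state == state]
            assert np.mean(dwells) == pytest.approx(expected, rel=0.05)


class TestRenderIntensities:
    def test_noiseless_single_state_splits_channels_exactly(self):
        m = qf.KineticModel(
            states=("A",),
            rates=np.zeros((1, 1)),
            emission_mean=np.array([0.5]),
            emission_sd=0.0,
        )
        cfg = qf.SimulationConfig(
            model=m, n_molecules=1, duration=5.0, intensity_noise_sd=0.0
        )
        path = qf.simulate_state_path(m, 5.0, np.random.default_rng(0))
        trace = qf.render_intensities(path, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(trace.donor, 500.0)
        np.testing.assert_allclose(trace.acceptor, 500.0)

    def test_noiseless_frame_boundary_switch_is_exact(self):
        m = two_state_model()
        cfg = qf.SimulationConfig(
            model=m, n_molecules=1, duration=2.0, intensity_noise_sd=0.0
        )
        path = StatePath(
            molecule_id="x",
            segments=[Segment("A", 0.0, 1.0), Segment("B", 1.0, 2.0)],
            emission_centers={"A": 0.3, "B": 0.7},
        )
        trace = qf.render_intensities(path, cfg, np.random.default_rng(0))
        eff = trace.acceptor / (trace.acceptor + trace.donor)
        np.testing.assert_allclose(eff[:10], 0.3)
        np.testing.assert_allclose(eff[10:], 0.7)

    def test_default_noise_preserves_mean_fret(self):
        """With default camera noise the per-frame computed FRET of an
        E=0.47 state averages to 0.47 within 0.01 over 1e4 frames."""
        m = qf.KineticModel(
            states=("NP",), rates=np.zeros((1, 1)), emission_mean=np.array([0.47])
        )
        cfg = qf.SimulationConfig(model=m, n_molecules=1, duration=1000.0)
        path = qf.simulate_state_path(m, 1000.0, np.random.default_rng(4))
        trace = qf.render_intensities(path, cfg, np.random.default_rng(4))
        traj = qf.compute_fret(trace)
        assert np.nanmean(traj.efficiency) == pytest.approx(0.47, abs=0.01)

    def test_bleach_zeroes_channels_and_records_frame(self):
        m = two_state_model()
        cfg = qf.SimulationConfig(
            model=m,
            n_molecules=1,
            duration=100.0,
            bleach_lifetime=10.0,
            intensity_noise_sd=0.0,
        )
        path = qf.simulate_state_path(m, 100.0, np.random.default_rng(5))
        trace = qf.render_intensities(path, cfg, np.random.default_rng(5))
        bf = trace.bleach_frame
        assert bf is not None
        assert np.all(trace.donor[bf - 1 :] == 0.0)
        assert np.all(trace.acceptor[bf - 1 :] == 0.0)
        assert np.all(trace.donor[: bf - 1] > 0.0)


class TestSimulateDataset:
    def test_docked_fraction_floor_arithmetic(self, telg5_model):
        cfg = qf.SimulationConfig(model=qf.construct_model("TelG5", docked_fraction=0.52),
                                  n_molecules=50, duration=2.0, seed=0)
        ts = qf.simulate_dataset(cfg)
        n_docked = sum(rec.docked for rec in ts.truth.values())
        assert n_docked == int(np.floor(0.52 * 50)) == 26

    def test_fully_docked_dataset_has_no_transitions(self):
        m = qf.construct_model("TelG5", docked_fraction=1.0)
        cfg = qf.SimulationConfig(model=m, n_molecules=10, duration=5.0, seed=1)
        ts = qf.simulate_dataset(cfg)
        assert all(rec.path.n_transitions == 0 for rec in ts.truth.values())

    def test_fixed_seed_is_bit_identical(self, telg5_model):
        cfg = qf.SimulationConfig(model=telg5_model, n_molecules=5, duration=10.0, seed=99)
        a = qf.simulate_dataset(cfg)
        b = qf.simulate_dataset(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)

    def test_long_run_occupancy_matches_stationary(self, telg5_model):
        """Empirical occupancy of pooled dynamic paths converges to the
        stationary distribution solved from the rate matrix."""
        rng = np.random.default_rng(11)
        occ = {s: 0.0 for s in telg5_model.states}
        for _ in range(5):
            p = qf.simulate_state_path(telg5_model, 4000.0, rng)
            for seg in p.segments:
                occ[seg.state] += seg.duration
        total = sum(occ.values())
        pi = dict(zip(telg5_model.states, telg5_model.stationary_distribution()))
        for s in occ:
            assert occ[s] / total == pytest.approx(pi[s], abs=0.03)


class TestSimulateBindingCurve:
    def test_half_saturation_at_kd(self):
        bc = qf.simulate_binding_curve(100.0, 1.0, [100.0])
        assert bc.bound_fraction[0] == pytest.approx(0.5)

    def test_zero_concentration_gives_zero(self):
        bc = qf.simulate_binding_curve(100.0, 1.0, [0.0])
        assert bc.bound_fraction[0] == 0.0

    def test_titration_evaluates_hyperbola(self):
        grid = [0, 5, 10, 20, 50, 100, 200, 500, 1000]
        bc = qf.simulate_binding_curve(456.0, 1.0, grid)
        assert bc.bound_fraction[-1] == pytest.approx(1000.0 / 1456.0)

    def test_invalid_kd_rejected(self):
        with pytest.raises(ParameterError):
            qf.simulate_binding_curve(0.0, 1.0, [1.0, 2.0])
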