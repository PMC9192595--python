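"""Classification, HMM segmentation, transition and dwell statistics."""

import numpy as np
import pytest

import quadfret as qf
from quadfret.errors import ParameterError
from quadfret.statepath import Segment, StatePath
from tests.conftest import make_trajectory


def square_wave(levels=(0.3, 0.7), block=30, n_blocks=6, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.concatenate(
        [np.full(block, levels[i % 2]) for i in range(n_blocks)]
    )
    if noise:
        vals = vals + rng.normal(0, noise, vals.size)
    return make_trajectory(vals)


def labeled_path(states_and_times, centers=None, molecule_id="p"):
    segs = [Segment(s, a, b) for s, a, b in states_and_times]
    return StatePath(
        molecule_id=molecule_id,
        segments=segs,
        source="inferred",
        emission_centers=centers or dict(qf.FRET_ANCHORS),
    )


class TestClassifyTrajectory:
    def test_constant_trace_is_docked(self):
        rng = np.random.default_rng(0)
        traj = make_trajectory(0.47 + rng.normal(0, 0.06, 1000))
        assert qf.classify_trajectory(traj) == "docked"

    def test_known_jump_is_transitioning(self):
        traj = square_wave(noise=0.06, block=50, n_blocks=4, seed=1)
        assert qf.classify_trajectory(traj) == "transitioning"

    def test_short_trace_warns_but_classifies(self, caplog):
        traj = square_wave(noise=0.06, block=50, n_blocks=2, seed=2)  # 10 s
        with caplog.at_level("WARNING"):
            out = qf.classify_trajectory(traj, window=100.0)
        assert out == "transitioning"

    def test_mixed_population_fraction_recovered(self, telg5_dataset):
        got = {
            t.molecule_id: qf.classify_trajectory(qf.compute_fret(t))
            for t in telg5_dataset
        }
        true_docked = {m: rec.docked for m, rec in telg5_dataset.truth.items()}
        wrong = sum(
            (got[m] == "transitioning") == true_docked[m] for m in got
        )
        assert wrong <= 2  # near-perfect split on 40 molecules


class TestInferStatePath:
    def test_noiseless_square_wave_exact_segmentation(self):
        traj = square_wave(block=30, n_blocks=6)
        path, report = qf.infer_state_path(traj)
        assert report.effective_k == 2
        assert len(path.segments) == 6
        starts = [round(s.start, 6) for s in path.segments]
        assert starts == [0.0, 3.0, 6.0, 9.0, 12.0, 15.0]

    def test_docked_trace_yields_single_segment(self):
        rng = np.random.default_rng(3)
        traj = make_trajectory(0.47 + rng.normal(0, 0.05, 500))
        path, report = qf.infer_state_path(traj)
        assert report.selected_k == 1
        assert len(path.segments) == 1

    def test_three_state_frame_accuracy(self, telg5_model):
        """>= 95% frame-level accuracy against simulator truth at default
        noise (spot check on a few molecules; the ensemble version runs in
        the acceptance suite)."""
        cfg = qf.SimulationConfig(
            model=qf.construct_model("TelG5", docked_fraction=0.0),
            n_molecules=3,
            duration=200.0,
            seed=17,
        )
        ts = qf.simulate_dataset(cfg)
        states = list(telg5_model.states)
        for trace in ts:
            traj = qf.compute_fret(trace)
            path, _ = qf.infer_state_path(traj)
            labeled = qf.assign_state_labels(path, qf.FRET_ANCHORS)
            truth = ts.truth[trace.molecule_id].path
            tl = truth.frame_labels(trace.n_frames, 0.1, states=states)
            il = labeled.frame_labels(trace.n_frames, 0.1, states=states + ["other"])
            assert np.mean(tl == il) >= 0.95

    def test_too_few_frames_rejected(self):
        with pytest.raises(qf.EmptyDataError):
            qf.infer_state_path(make_trajectory(np.full(10, 0.5)))


class TestAssignStateLabels:
    def path_with_centers(self, centers):
        names = [f"s{i}" for i in range(len(centers))]
        segs, t = [], 0.0
        for n in names:
            segs.append(Segment(n, t, t + 1.0))
            t += 1.0
        return StatePath(
            molecule_id="m",
            segments=segs,
            source="inferred",
            emission_centers=dict(zip(names, centers)),
        )

    def test_nearest_anchor_assignment(self):
        path = self.path_with_centers([0.25, 0.48, 0.65])
        labeled = qf.assign_state_labels(path, qf.FRET_ANCHORS)
        assert [s.state for s in labeled.segments] == ["UF", "NP", "P"]

    def test_bound_state_recognized_when_anchored(self):
        path = self.path_with_centers([0.57])
        anchors = dict(qf.FRET_ANCHORS, BD=qf.BD_LEVEL)
        labeled = qf.assign_state_labels(path, anchors)
        assert labeled.segments[0].state == "BD"

    def test_equidistant_ties_break_low(self):
        path = self.path_with_centers([0.40])
        labeled = qf.assign_state_labels(path, {"low": 0.34, "high": 0.46})
        assert labeled.segments[0].state == "low"

    def test_far_centers_become_other(self):
        path = self.path_with_centers([0.95])
        labeled = qf.assign_state_labels(path, qf.FRET_ANCHORS)
        assert labeled.segments[0].state == "other"

    def test_empty_anchors_rejected(self):
        path = self.path_with_centers([0.5])
        with pytest.raises(ParameterError):
            qf.assign_state_labels(path, {})


class TestTransitionStatistics:
    def test_hand_counted_transitions(self):
        p = labeled_path(
            [("UF", 0, 1), ("NP", 1, 2), ("UF", 2, 3), ("P", 3, 4)]
        )
        counts = qf.count_transitions([p])
        assert counts.counts[("UF", "NP")] == 1
        assert counts.counts[("NP", "UF")] == 1
        assert counts.counts[("UF", "P")] == 1
        assert counts.n_transitions_total == 3

    def test_empty_collection_all_zero(self):
        counts = qf.count_transitions([])
        assert counts.n_transitions_total == 0

    def test_bd_transitions_tallied_separately(self):
        p = labeled_path(
            [("NP", 0, 1), ("BD", 1, 2), ("P", 2, 3)],
            centers=dict(qf.FRET_ANCHORS, BD=0.57),
        )
        counts = qf.count_transitions([p])
        assert counts.n_transitions_total == 0
        assert counts.extra_counts[("NP", "BD")] == 1
        assert counts.extra_counts[("BD", "P")] == 1

    def test_ground_truth_recount_equivalence(self, telg5_dataset):
        """Counting through TransitionCounts equals a brute-force recount of
        the simulator's segment sequences."""
        paths = [rec.path for rec in telg5_dataset.truth.values()]
        counts = qf.count_transitions(paths)
        brute = {}
        for rec in telg5_dataset.truth.values():
            seq = [s.state for s in rec.path.segments]
            for a, b in zip(seq[:-1], seq[1:]):
                brute[(a, b)] = brute.get((a, b), 0) + 1
        for pair, n in counts.counts.items():
            assert brute.get(pair, 0) == n

    def test_single_transition_density_in_one_cell(self):
        p = labeled_path([("UF", 0, 1), ("NP", 1, 2)])
        tdp = qf.transition_density_plot([p])
        assert tdp.n_transitions == 1
        assert tdp.matrix.sum() == pytest.approx(1.0)
        assert tdp.mass((0.2, 0.3), (0.45, 0.5)) == pytest.approx(1.0)

    def test_no_transitions_flagged_empty(self):
        p = labeled_path([("UF", 0, 5)])
        tdp = qf.transition_density_plot([p])
        assert tdp.is_empty

    def test_detailed_balance_symmetry(self):
        """A reversible two-state chain produces a transition density that is
        symmetric across the diagonal (equal forward/backward mass)."""
        m = qf.KineticModel(
            states=("A", "B"),
            rates=np.array([[0.0, 0.5], [0.5, 0.0]]),
            emission_mean=np.array([0.3, 0.7]),
        )
        p = qf.simulate_state_path(m, 2e4, np.random.default_rng(6))
        tdp = qf.transition_density_plot([p])
        forward = tdp.mass((0.25, 0.35), (0.65, 0.75))
        backward = tdp.mass((0.65, 0.75), (0.25, 0.35))
        assert forward == pytest.approx(backward, abs=0.02)

    def test_direct_exchange_dominates_for_fast_variants(self):
        """TelG5TTT-preset dynamics concentrate transition mass in the
        NP<->P cells, matching the construct's direct-exchange pattern."""
        m = qf.construct_model("TelG5TTT", docked_fraction=0.0)
        p = qf.simulate_state_path(m, 1e4, np.random.default_rng(7))
        counts = qf.count_transitions([p])
        direct = counts.counts[("NP", "P")] + counts.counts[("P", "NP")]
        assert direct / counts.n_transitions_total > 0.5


class TestDwellAnalysis:
    def test_single_internal_dwell(self):
        p = labeled_path([("UF", 0, 1), ("NP", 1, 8.6), ("P", 8.6, 10)])
        table = qf.dwell_analysis([p])
        assert table.mean_dwell("NP") == pytest.approx(7.6)

    def test_all_censored_means_undefined(self):
        p = labeled_path([("NP", 0, 10)])
        table = qf.dwell_analysis([p])
        assert np.isnan(table.mean_dwell("NP"))

    def test_first_and_last_dwells_flagged_censored(self):
        p = labeled_path([("UF", 0, 1), ("NP", 1, 2), ("UF", 2, 3)])
        table = qf.dwell_analysis([p])
        flags = table.table["censored"].tolist()
        assert flags == [True, False, True]

    def test_corrected_means_reduce_to_raw_at_zero_dead_time(self):
        p = labeled_path(
            [("UF", 0, 1), ("NP", 1, 4), ("UF", 4, 6), ("NP", 6, 7)]
        )
        table = qf.dwell_analysis([p])
        counts = qf.count_transitions([p])
        corrected = qf.corrected_dwell_means(table, counts, dead_time=0.0)
        assert corrected["NP"] == pytest.approx(table.mean_dwell("NP"))
        assert corrected["UF"] == pytest.approx(table.mean_dwell("UF"))


class TestDirectTransitionDensity:
    def test_stated_formula_arithmetic(self):
        counts = qf.TransitionCounts(
            counts={
                ("NP", "P"): 3,
                ("P", "NP"): 2,
                ("UF", "NP"): 5,
                ("NP", "UF"): 0,
                ("UF", "P"): 0,
                ("P", "UF"): 0,
            }
        )
        summary = qf.direct_transition_density(counts, n_total=100, n_transitioning=50)
        assert summary.direct_density == pytest.approx(0.5 * 5 / 10)

    def test_no_direct_transitions_give_zero(self):
        counts = qf.count_transitions(
            [labeled_path([("UF", 0, 1), ("NP", 1, 2), ("UF", 2, 3)])]
        )
        s = qf.direct_transition_density(counts, n_total=10, n_transitioning=1)
        assert s.direct_density == 0.0

    def test_zero_over_zero_defined_as_zero(self):
        counts = qf.count_transitions([])
        s = qf.direct_transition_density(counts, n_total=10, n_transitioning=0)
        assert s.direct_density == 0.0
        assert s.fraction_transitioning == 0.0

    def test_bounded_by_fraction_transitioning(self):
        counts = qf.TransitionCounts(
            counts={pair: 1 for pair in qf.kinetics.CORE_TRANSITIONS}
        )
        s = qf.direct_transition_density(counts, n_total=4, n_transitioning=3)
        assert 0.0 <= s.direct_density <= s.fraction_transitioning

    def test_monotone_in_direct_rate(self):
        """Quadrupling the direct NP<->P rates strictly increases the
        statistic (count oracle on simulated truth paths)."""
        base = qf.construct_model("TelG5", docked_fraction=0.0)
        boosted = qf.KineticModel(
            states=base.states,
            rates=base.rates * np.array(
                [[1, 1, 1], [1, 1, 4], [1, 4, 1]], dtype=float
            ),
            emission_mean=base.emission_mean,
        )
        rng = np.random.default_rng(9)
        out = []
        for model in (base, boosted):
            paths = [
                qf.simulate_state_path(model, 2000.0, rng, molecule_id=f"m{i}")
                for i in range(5)
            ]
            counts = qf.count_transitions(paths)
            out.append(
                qf.direct_transition_density(
                    counts, n_total=5, n_transitioning=5
                ).direct_density
            )
        assert out[1] > out[0]
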