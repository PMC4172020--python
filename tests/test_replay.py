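"""Replay plans and deterministic replay-with-plasticity episodes."""

import numpy as np
import pytest

from replaynet.network import DIG, MOVE, SynapseSet
from replaynet.plasticity import PlasticityParams
from replaynet.replay import (
    ReplaySegment,
    build_replay_plan,
    first_spike_time,
    run_replay,
    _playback_log,
)
from replaynet.task import ActionStep, TrialRecord, Triplet

DT = 0.5e-3


def record_from(labels_actions, rewarded, timed_out=False):
    steps = []
    t = 0.0
    for label, action in labels_actions:
        trip = Triplet(label[0], int(label[1]), label[2])
        steps.append(ActionStep(trip, hippo_winner=2, action=action,
                                t_start=t, t_end=t + 0.6))
        t += 0.6
    return TrialRecord(steps=steps, rewarded=rewarded, timed_out=timed_out,
                       duration=t, spikes={})


def mid_synapses(n_h=8):
    return SynapseSet(
        exc_sensory_to_hippo=np.full((6, n_h), 0.5),
        exc_hippo_to_motor=np.full((n_h, 2), 0.5),
        inh_hippo=np.zeros((n_h, n_h)),
        inh_motor=np.zeros((2, 2)),
    )


class TestBuildReplayPlan:
    def test_rewarded_trial_forward_in_temporal_order(self):
        rec = record_from([("A2Y", MOVE), ("A1X", DIG)], rewarded=True)
        plan = build_replay_plan(rec)
        assert plan.forward
        assert [s.triplet.label for s in plan.segments] == ["A2Y", "A1X"]
        assert [s.motor_cell for s in plan.segments] == [MOVE, DIG]

    def test_unrewarded_trial_backward_segments_reversed(self):
        rec = record_from([("A1X", MOVE), ("A2Y", DIG)], rewarded=False)
        plan = build_replay_plan(rec)
        assert not plan.forward
        assert [s.triplet.label for s in plan.segments] == ["A2Y", "A1X"]
        assert [s.motor_cell for s in plan.segments] == [DIG, MOVE]

    def test_only_last_two_actions_replayed(self):
        rec = record_from(
            [("A1X", MOVE), ("A2Y", MOVE), ("A1X", MOVE), ("A2Y", DIG)],
            rewarded=True,
        )
        plan = build_replay_plan(rec, n_replay=2)
        assert len(plan.segments) == 2
        assert [s.triplet.label for s in plan.segments] == ["A1X", "A2Y"]

    def test_single_action_trial_single_segment(self):
        rec = record_from([("B1Y", DIG)], rewarded=True)
        plan = build_replay_plan(rec)
        assert len(plan.segments) == 1

    def test_timed_out_trial_rejected(self):
        rec = record_from([("A1X", MOVE)], rewarded=False, timed_out=True)
        with pytest.raises(ValueError):
            build_replay_plan(rec)


class TestPlaybackTiming:
    def test_forward_spike_order_and_gaps(self, network_config, neuron_params):
        """Replayed spikes run sensory -> hippocampal -> motor with every
        adjacent pair inside the 10 ms STDP window."""
        seg = ReplaySegment(Triplet("A", 1, "X"), hippo_cell=2, motor_cell=DIG)
        log, t_seg = _playback_log(seg, True, network_config, neuron_params, DT)
        t_s = log["sensory"][0][0]
        t_h = log["hippo"][2][0]
        t_m = log["motor"][DIG][0]
        assert t_s < t_h < t_m
        assert 0 < t_h - t_s <= 10e-3
        assert 0 < t_m - t_h <= 10e-3
        assert t_seg == t_m

    def test_backward_order_inverts(self, network_config, neuron_params):
        seg = ReplaySegment(Triplet("A", 1, "X"), hippo_cell=2, motor_cell=DIG)
        log, _ = _playback_log(seg, False, network_config, neuron_params, DT)
        t_s = log["sensory"][0][0]
        t_h = log["hippo"][2][0]
        t_m = log["motor"][DIG][0]
        assert t_m < t_h < t_s
        assert 0 < t_s - t_h <= 10e-3
        assert 0 < t_h - t_m <= 10e-3

    def test_first_spike_time_matches_isi(self, neuron_params):
        assert first_spike_time(1.0e-9, neuron_params, DT) == pytest.approx(
            0.1235, abs=1e-3
        )


class TestRunReplay:
    def _replay(self, rec, syn, network_config, neuron_params, task_params):
        plan = build_replay_plan(rec, task_params.n_replay)
        return run_replay(
            network_config, syn, plan, PlasticityParams(), neuron_params,
            task_params, DT,
        )

    def test_forward_replay_potentiates_touched_weights(
        self, network_config, neuron_params, task_params
    ):
        syn = mid_synapses()
        rec = record_from([("A2Y", MOVE), ("A1X", DIG)], rewarded=True)
        self._replay(rec, syn, network_config, neuron_params, task_params)
        # segment A2Y -> cell 2 -> move: sensory cells A2 (1) and Y (5)
        assert syn.exc_sensory_to_hippo[1, 2] > 0.5
        assert syn.exc_sensory_to_hippo[5, 2] > 0.5
        assert syn.exc_hippo_to_motor[2, MOVE] > 0.5
        # segment A1X -> cell 2 -> dig: sensory cells A1 (0) and X (4)
        assert syn.exc_sensory_to_hippo[0, 2] > 0.5
        assert syn.exc_sensory_to_hippo[4, 2] > 0.5
        assert syn.exc_hippo_to_motor[2, DIG] > 0.5
        # weights not on the replayed path untouched
        assert np.all(syn.exc_sensory_to_hippo[:, 3] == 0.5)

    def test_backward_replay_depresses_touched_weights(
        self, network_config, neuron_params, task_params
    ):
        syn = mid_synapses()
        rec = record_from([("A1X", MOVE), ("A2Y", DIG)], rewarded=False)
        self._replay(rec, syn, network_config, neuron_params, task_params)
        assert syn.exc_sensory_to_hippo[0, 2] < 0.5
        assert syn.exc_sensory_to_hippo[4, 2] < 0.5
        assert syn.exc_hippo_to_motor[2, MOVE] < 0.5
        assert syn.exc_sensory_to_hippo[1, 2] < 0.5
        assert syn.exc_sensory_to_hippo[5, 2] < 0.5
        assert syn.exc_hippo_to_motor[2, DIG] < 0.5

    def test_replay_is_deterministic(
        self, network_config, neuron_params, task_params
    ):
        rec = record_from([("A2Y", MOVE), ("A1X", DIG)], rewarded=True)
        outs = []
        for _ in range(2):
            syn = mid_synapses()
            self._replay(rec, syn, network_config, neuron_params, task_params)
            outs.append(
                (syn.exc_sensory_to_hippo.copy(), syn.exc_hippo_to_motor.copy())
            )
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_replay_faster_than_behavior(
        self, network_config, neuron_params, task_params
    ):
        """The whole replay episode fits the 400 ms budget, well below the
        >=0.6 s behaviour phase it re-expresses."""
        seg = ReplaySegment(Triplet("A", 1, "X"), 2, DIG)
        _, t_seg = _playback_log(seg, True, network_config, neuron_params, DT)
        n_playbacks = int(task_params.t_replay // t_seg)
        assert n_playbacks * t_seg <= task_params.t_replay
        assert t_seg < 0.15

    def test_repeated_forward_replay_saturates_path(
        self, network_config, neuron_params, task_params
    ):
        """Repeatedly rewarded replay of one mapping drives its weights to
        the upper bound (within the functional-network tolerance)."""
        syn = mid_synapses()
        rec = record_from([("A1X", DIG)], rewarded=True)
        for _ in range(60):
            self._replay(rec, syn, network_config, neuron_params, task_params)
        assert syn.exc_hippo_to_motor[2, DIG] > 1 - 1e-6
        assert syn.exc_sensory_to_hippo[0, 2] > 1 - 1e-6
        assert syn.exc_sensory_to_hippo[4, 2] > 1 - 1e-6
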