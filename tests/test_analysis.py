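"""Selectivity indices, binariness, functional network, grouping labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replaynet.analysis import (
    compute_binariness,
    compute_si,
    event_rates,
    grouping_table,
    identify_functional_cells,
    block_statistics,
    si_context,
    si_item,
    si_place,
)
from replaynet.network import DIG, MOVE, SynapseSet
from replaynet.task import ActionStep, TrialRecord, Triplet


class TestComputeSi:
    def test_uniform_rates_give_zero(self):
        assert compute_si(np.array([3.0, 3.0, 3.0, 3.0])) == pytest.approx(0.0)

    def test_single_event_firing_gives_one(self):
        assert compute_si(np.array([5.0, 0.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_two_event_example(self):
        # n = 2, rates (10, 2): SI = (2 - 1.2) / 1 = 0.8
        assert compute_si(np.array([10.0, 2.0])) == pytest.approx(0.8)

    def test_silent_cell_is_nan(self):
        assert np.isnan(compute_si(np.zeros(4)))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            compute_si(np.array([1.0, -0.1]))

    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_si_bounded_zero_one(self, rates):
        si = compute_si(np.asarray(rates))
        if not np.isnan(si):
            assert 0.0 <= si <= 1.0


class TestGroupedSi:
    # canonical triplet order: A1X A1Y A2X A2Y B1X B1Y B2X B2Y
    def test_context_item_cell_profile(self):
        """A cell firing only for item X in context A (both places) has
        perfect item and context selectivity but partial place
        selectivity."""
        rates = np.array([8.0, 0, 8.0, 0, 0, 0, 0, 0])
        assert si_item(rates) == pytest.approx(1.0)
        assert si_context(rates) == pytest.approx(1.0)
        assert si_place(rates) == pytest.approx((4 - 2.0) / 3)

    def test_unequal_place_rates_raise_place_si(self):
        rates = np.array([8.0, 0, 4.0, 0, 0, 0, 0, 0])
        assert si_place(rates) > (4 - 2.0) / 3

    def test_pure_place_cell(self):
        """Firing for one context-place regardless of item: place SI 1,
        item SI 0."""
        rates = np.array([6.0, 6.0, 0, 0, 0, 0, 0, 0])
        assert si_place(rates) == pytest.approx(1.0)
        assert si_item(rates) == pytest.approx(0.0)


class TestBinariness:
    def test_midpoint_weights_zero(self):
        assert compute_binariness(np.full((6, 8), 0.5), [0, 1]) == 0.0

    def test_extreme_weights_one(self):
        w = np.zeros((6, 8))
        w[:, 1] = 1.0
        assert compute_binariness(w, [0, 1]) == 1.0

    def test_quarter_value(self):
        assert compute_binariness(np.full((6, 8), 0.75), [2]) == pytest.approx(0.25)

    def test_empty_functional_set_nan(self):
        assert np.isnan(compute_binariness(np.full((6, 8), 0.5), []))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounded_zero_one(self, seed):
        w = np.random.default_rng(seed).uniform(0, 1, (6, 8))
        b = compute_binariness(w, [0, 3, 5])
        assert 0.0 <= b <= 1.0


class TestFunctionalCells:
    def _syn(self, w_hm):
        return SynapseSet(
            exc_sensory_to_hippo=np.full((6, 8), 0.5),
            exc_hippo_to_motor=w_hm,
            inh_hippo=np.zeros((8, 8)),
            inh_motor=np.zeros((2, 2)),
        )

    def test_saturated_cell_included(self):
        w = np.full((8, 2), 0.2)
        w[3, DIG] = 1.0
        assert identify_functional_cells(self._syn(w)) == [3]

    def test_near_but_below_threshold_excluded(self):
        w = np.full((8, 2), 0.2)
        w[3, DIG] = 0.99
        assert identify_functional_cells(self._syn(w)) == []

    def test_threshold_is_tight(self):
        w = np.full((8, 2), 0.2)
        w[2, MOVE] = 1.0 - 5e-7  # above 1 - 1e-6
        assert identify_functional_cells(self._syn(w)) == [2]


def _record(label, winner, action, t0, t1, hippo_spikes):
    trip = Triplet(label[0], int(label[1]), label[2])
    return TrialRecord(
        steps=[ActionStep(trip, winner, action, t0, t1)],
        rewarded=trip.rewarded,
        timed_out=False,
        duration=t1,
        spikes={"hippo": hippo_spikes},
    )


class TestEventRates:
    def test_rates_pool_spikes_over_block(self):
        # two A1X trials for cell 0: 4 spikes / 1 s and 2 spikes / 1 s
        recs = [
            _record("A1X", 0, DIG, 0.0, 1.0, [(0, 0.2), (0, 0.4), (0, 0.6), (0, 0.8)]),
            _record("A1X", 0, DIG, 0.0, 1.0, [(0, 0.3), (0, 0.9)]),
        ]
        rates = event_rates(recs, n_hippo=2, blocks=[(0, 2)])
        assert rates[0, 0, 0] == pytest.approx(3.0)  # 6 spikes / 2 s
        assert rates[0, 1, 0] == 0.0  # silent cell
        assert np.all(rates[0, :, 1:] == 0.0)  # unseen triplets

    def test_spikes_outside_interval_ignored(self):
        recs = [_record("A1X", 0, DIG, 0.5, 1.0, [(0, 0.2), (0, 0.7)])]
        rates = event_rates(recs, n_hippo=1, blocks=[(0, 1)])
        assert rates[0, 0, 0] == pytest.approx(2.0)  # 1 spike / 0.5 s


class TestBlockStatistics:
    def test_mean_and_sem_across_runs(self):
        rep = pd.DataFrame(
            {
                "block": [1, 1, 2, 2],
                "cell": [0, 1, 0, 1],
                "si_place": [0.6, 0.8, 0.7, 0.9],
                "si_item": [1.0, 1.0, 1.0, 1.0],
                "si_context": [0.5, 0.5, 1.0, 1.0],
                "binariness": [0.4, 0.4, 0.7, 0.7],
            }
        )
        rep2 = rep.copy()
        rep2[["si_place"]] += 0.1
        stats = block_statistics([rep, rep2])
        row = stats[(stats.block == 1) & (stats.measure == "si_place")].iloc[0]
        assert row["mean"] == pytest.approx(0.75)  # (0.7 + 0.8) / 2
        assert row["n_runs"] == 2
        assert row["sem"] == pytest.approx(np.std([0.7, 0.8], ddof=1) / np.sqrt(2))

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            block_statistics([pd.DataFrame()])


class TestGroupingTable:
    def test_naive_wiring_labelled_per_triplet(self, naive_wiring):
        table = grouping_table(naive_wiring)
        assert list(table.loc["Function"]) == [
            "A1X", "B1Y", "A2X", "B2Y", "A1Y", "B1X", "A2Y", "B2X",
        ]

    def test_context_item_grouping_label(self):
        w_sh = np.full((6, 8), 0.3)
        w_sh[0, 2] = 1.0  # A1
        w_sh[1, 2] = 1.0  # A2
        w_sh[4, 2] = 1.0  # X
        syn = SynapseSet(w_sh, np.full((8, 2), 0.5), np.zeros((8, 8)), np.zeros((2, 2)))
        assert grouping_table(syn).loc["Function"].iloc[2] == "A1/2,X"

    def test_random_midrange_weights_unlabelled(self, rng):
        w_sh = rng.uniform(0.1, 0.85, (6, 8))
        syn = SynapseSet(w_sh, np.full((8, 2), 0.5), np.zeros((8, 8)), np.zeros((2, 2)))
        assert set(grouping_table(syn).loc["Function"]) == {"None"}

    def test_rows_follow_presentation_order(self, naive_wiring):
        table = grouping_table(naive_wiring)
        assert list(table.index) == [
            "A1", "B1", "A2", "B2", "X", "Y", "Dig", "Move", "Function",
        ]
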