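"""Tests of the CLAW discretisation, transition chain, zones and classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbgtclaw import claw
from cbgtclaw.claw import (
    BinarizationScheme,
    StateSequence,
    assign_zones,
    bin_rates,
    classify_trajectory,
    compare_claws,
    compute_thresholds,
    decode_state,
    encode_state,
    extract_claw,
    state_sequence,
    state_statistics,
    transition_matrix,
    zone_transition_table,
)
from cbgtclaw.errors import MissingDataError, ParameterError


class TestBinRates:
    def test_bin_count(self):
        out = bin_rates(np.ones((100, 3)), 10.0, 1.0)
        assert out.shape == (10, 3)

    def test_constant_trace_mean(self):
        out = bin_rates(np.full((100, 2), 20.0), 10.0, 1.0)
        assert np.all(out == 20.0)

    def test_partial_bin_dropped(self):
        out = bin_rates(np.ones((105, 1)), 10.0, 1.0)
        assert out.shape == (10, 1)

    def test_incompatible_step_rejected(self):
        with pytest.raises(ParameterError):
            bin_rates(np.ones((30, 1)), 10.0, 3.0)


class TestStateCoding:
    def test_all_ones_and_last_bit(self):
        assert encode_state(np.ones(10, dtype=int)) == 1023
        bits = np.zeros(10, dtype=int)
        bits[-1] = 1
        assert encode_state(bits) == 1

    def test_roundtrip_over_all_states(self):
        for k in range(1024):
            assert encode_state(decode_state(k)) == k

    def test_wrong_bit_count(self):
        with pytest.raises(ParameterError):
            encode_state([1, 0, 1])


class TestStateSequence:
    def test_constant_pattern_single_state(self):
        b = np.tile([1, 0, 1, 0, 0, 0, 0, 0, 0, 0], (7, 1))
        seq = state_sequence(b)
        assert len(seq.states) == 1
        assert seq.dwells == [7]

    def test_alternating_pattern(self):
        rows = np.array([[0] * 10, [1] * 10] * 4)
        seq = state_sequence(rows)
        assert seq.states == [0, 1023] * 4
        assert seq.dwells == [1] * 8

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=1, max_value=60), st.integers(min_value=0, max_value=2**32 - 1))
    def test_dwell_time_conservation(self, n_bins, seed):
        rng = np.random.default_rng(seed)
        b = rng.integers(0, 2, size=(n_bins, 10))
        seq = state_sequence(b)
        assert seq.n_bins == n_bins
        assert np.array_equal(
            seq.expand(), b @ (1 << np.arange(9, -1, -1))
        )


class TestTransitionMatrix:
    def test_simple_sequence_probabilities(self):
        seq = StateSequence(states=[5, 7], dwells=[2, 1])  # s5,s5,s7
        P, counts = transition_matrix([seq])
        assert P[5, 5] == pytest.approx(0.5)
        assert P[5, 7] == pytest.approx(0.5)
        assert counts[5].sum() == 2

    def test_visited_rows_stochastic(self, claw_model):
        P = claw_model.transition_matrix_
        rowsums = P.sum(axis=1)
        visited = rowsums > 0
        assert np.allclose(rowsums[visited], 1.0, atol=1e-12)

    def test_count_pooling_additive(self):
        rng = np.random.default_rng(0)
        seqs = [
            state_sequence(rng.integers(0, 2, size=(20, 10))) for _ in range(6)
        ]
        _, pooled = transition_matrix(seqs)
        parts = sum(transition_matrix([s])[1] for s in seqs)
        assert np.array_equal(pooled, parts)

    def test_empty_input_rejected(self):
        with pytest.raises(MissingDataError):
            transition_matrix([])


class TestExtractClaw:
    def _chain(self):
        # 3-state chain with one rare edge (p = 0.005)
        counts = np.zeros((1024, 1024))
        counts[1, 2] = 995
        counts[1, 3] = 5
        counts[2, 2] = 1000
        counts[3, 3] = 50
        P = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1)
        visits = np.zeros(1024, dtype=int)
        visits[[1, 2, 3]] = [1000, 995, 50]
        return P, counts, visits

    def test_rare_edge_excluded_at_default(self):
        P, counts, visits = self._chain()
        g = extract_claw(P, counts, visits)
        assert not g.has_edge(1, 3)
        assert g.has_edge(1, 2)

    def test_lowering_threshold_only_adds_edges(self):
        P, counts, visits = self._chain()
        tight = extract_claw(P, counts, visits, min_edge_prob=0.05)
        loose = extract_claw(P, counts, visits, min_edge_prob=0.001)
        assert set(tight.edges) <= set(loose.edges)

    def test_boundary_threshold_keeps_deterministic_edges(self):
        P, counts, visits = self._chain()
        g = extract_claw(P, counts, visits, min_edge_prob=1.0)
        assert g.has_edge(2, 2)
        assert not g.has_edge(1, 2)


class TestThresholds:
    def test_antimode_between_two_modes(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(5, 1, 3000), rng.normal(40, 3, 3000)])
        scheme = compute_thresholds({"s": x})
        assert 5 < scheme.thresholds["s"] < 40

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(5, 1, 3000), rng.normal(40, 3, 3000)])
        t1 = compute_thresholds({"s": x}).thresholds["s"]
        t2 = compute_thresholds({"s": 2 * x}).thresholds["s"]
        assert t2 == pytest.approx(2 * t1, rel=0.1)

    def test_degenerate_constant_stream(self):
        scheme = compute_thresholds({"s": np.full(2000, 7.0)})
        assert scheme.thresholds["s"] == 7.0
        assert "s" in scheme.degenerate

    def test_empty_stream_rejected(self):
        with pytest.raises(MissingDataError):
            compute_thresholds({"s": np.array([])})

    def test_binarization_idempotent(self):
        """Binarising an already-binary trace with thresholds 0.5 is a
        no-op."""
        rng = np.random.default_rng(3)
        b = rng.integers(0, 2, size=(50, 18)).astype(float)
        scheme = BinarizationScheme(
            thresholds={s: 0.5 for s in claw.DEFAULT_STATE_STREAMS}
        )
        out = claw.binarize(b, scheme)
        cols = [claw.stream_index(s) for s in claw.DEFAULT_STATE_STREAMS]
        assert np.array_equal(out, b[:, cols].astype(np.uint8))


class TestZones:
    def test_user_map_passthrough(self):
        import networkx as nx

        g = nx.DiGraph([(0, 1)])
        zm = assign_zones(g, baseline_state=0, user_map={0: "II", 1: "II"})
        assert zm == {0: "II", 1: "II"}

    def test_baseline_is_zone_one(self, claw_model):
        assert claw_model.zones_[claw_model.baseline_state_] == "I"

    def test_committed_pattern_is_zone_three(self):
        """dSPN-L on, GPi-L off, Th-L on, dSPN-R off marks left commitment."""
        bits = {s: 0 for s in claw.DEFAULT_STATE_STREAMS}
        bits.update({"dSPN-L": 1, "Th-L": 1, "GPi-R": 1, "GPeP-L": 1})
        k = encode_state([bits[s] for s in claw.DEFAULT_STATE_STREAMS])
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from([0, k])
        zm = assign_zones(g, baseline_state=0)
        assert zm[k] == "III"

    def test_partition_exhaustive_and_exclusive(self, claw_model):
        zones = claw_model.zones_
        for seq in claw_model.sequences_:
            for s in seq.states:
                assert zones.get(s) in ("I", "II", "III", "IV", "V", "VI", "other")

    def test_unreachable_baseline_rejected(self):
        import networkx as nx

        g = nx.DiGraph([(1, 2)])
        with pytest.raises(Exception):
            assign_zones(g, baseline_state=999)


class TestTrajectoryClasses:
    @pytest.mark.parametrize(
        "path,label",
        [
            (["I", "II"], "A"),
            (["I", "II", "V"], "A"),
            (["I", "II", "V", "II"], "A"),
            (["I", "II", "III"], "B"),
            (["I", "II", "IV"], "B"),
            (["I", "III"], "C"),
            (["I", "IV"], "C"),
            (["I", "III", "VI"], "D"),
            (["I", "IV", "VI"], "D"),
        ],
    )
    def test_canonical_paths(self, path, label):
        assert classify_trajectory(path) == label

    def test_path_not_starting_at_baseline_flagged(self):
        assert classify_trajectory(["II", "III"]) == "unclassified"
        assert classify_trajectory([]) == "unclassified"

    def test_all_four_classes_occur_pre_learning(self, claw_model, pre_trials):
        labels = set(claw_model.classify(pre_trials))
        assert {"A", "B", "C", "D"} <= labels


class TestStatistics:
    def _mini(self):
        from cbgtclaw.synth import TrialRecord

        trials, seqs = [], []
        rng = np.random.default_rng(0)
        for i in range(40):
            choice = "L" if i % 2 == 0 else "R"
            dt = float(rng.normal(120 if choice == "L" else 150, 10))
            trials.append(
                TrialRecord(i, np.empty((0, 18)), choice, dt, 250.0, 0, 0, 1.0)
            )
            seqs.append(StateSequence([7, 9], [3, 2]))
        return trials, seqs

    def test_kl_nonnegative_and_pl(self):
        trials, seqs = self._mini()
        stats = state_statistics(trials, seqs)
        assert (stats["kl_lr_nats"].dropna() >= 0).all()
        assert ((stats["p_left"] >= 0) & (stats["p_left"] <= 1)).all()

    def test_degenerate_all_left(self):
        trials, seqs = self._mini()
        for t in trials:
            object.__setattr__(t, "choice", "L") if False else setattr(t, "choice", "L")
        stats = state_statistics(trials, seqs)
        assert (stats["p_left"] == 1.0).all()

    def test_identical_distributions_zero_kl(self):
        from cbgtclaw.claw import _kl_decision_times

        x = np.random.default_rng(1).normal(100, 5, 500)
        assert _kl_decision_times(x, x.copy()) == pytest.approx(0.0, abs=1e-6)


class TestCompareClaws:
    def _tables(self, p_new):
        labels = list(claw.ZONES) + ["other"]
        t_old = pd.DataFrame(0.0, index=labels, columns=labels)
        t_new = t_old.copy()
        t_old.loc["I", "II"] = 0.20
        t_new.loc["I", "II"] = p_new
        return t_old, t_new

    def test_identical_tables_no_flags(self):
        t, _ = self._tables(0.2)
        assert compare_claws(t, t.copy()).empty

    def test_fifty_percent_increase_flagged(self):
        rep = compare_claws(*self._tables(0.30))
        row = rep[(rep["from"] == "I") & (rep["to"] == "II")]
        assert len(row) == 1
        assert row.iloc[0]["direction"] == "increase"
        assert row.iloc[0]["rel_change"] == pytest.approx(0.5)

    def test_five_percent_change_not_flagged(self):
        rep = compare_claws(*self._tables(0.21))
        assert rep.empty

    def test_new_transition_flagged_without_division(self):
        t_old, t_new = self._tables(0.2)
        t_old.loc["I", "II"] = 0.0
        rep = compare_claws(t_old, t_new)
        row = rep[(rep["from"] == "I") & (rep["to"] == "II")]
        assert row.iloc[0]["direction"] == "new"


class TestLearningShiftsZones:
    def test_pre_symmetric_entry_and_post_bias(self, claw_model, pre_trials, default_cfg):
        """Pre-learning III/IV entries are symmetric; training biases III."""
        import warnings

        from cbgtclaw import synth

        paths = claw_model.transform(pre_trials)
        e3 = sum("III" in p for p in paths)
        e4 = sum("IV" in p for p in paths)
        assert abs(e3 - e4) < 3 * np.sqrt(e3 + e4)

        post = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for net in range(3):
                cfg = synth.sample_network(default_cfg, 0.05, seed=net)
                plan = synth.SessionPlan(n_train=30, n_pre=0, n_post=25, seed=70 + net)
                post += [r for r in synth.run_session(cfg, plan)
                         if r.block == "post" and r.decided]
        pp = claw_model.transform(post)
        assert sum("III" in p for p in pp) > 2 * sum("IV" in p for p in pp)

    def test_zone_table_rows_normalised(self, claw_model):
        tab = claw_model.zone_table()
        sums = tab.sum(axis=1)
        for z, s in sums.items():
            assert s == pytest.approx(1.0, abs=1e-9) or s == 0.0
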