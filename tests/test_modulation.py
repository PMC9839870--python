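import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnis import modulation, synth
from somnis.datamodel import StateSequence, TraceMatrix


def _flat_trace(level_base, level_post, n=600, fr=5.0):
    """Trace with constant level in first and second halves (120 s each)."""
    x = np.empty(n)
    x[: n // 2] = level_base
    x[n // 2 :] = level_post
    return x, fr, (0.0, n / 2 / fr), (n / 2 / fr, n / fr)


class TestComputeNmi:
    def test_equal_rates_give_zero(self):
        x, fr, base, post = _flat_trace(2.0, 2.0)
        nmi, *_ = modulation.compute_nmi(x, fr, base, post)
        assert nmi == pytest.approx(0.0, abs=1e-12)

    def test_total_suppression_gives_minus_one(self):
        x, fr, base, post = _flat_trace(1.0, 0.0)
        nmi, *_ = modulation.compute_nmi(x, fr, base, post)
        assert nmi == pytest.approx(-1.0, abs=0.02)  # trapezoid edge effect only

    def test_one_to_three_rate_gives_half(self):
        x, fr, base, post = _flat_trace(1.0, 3.0)
        nmi, a_base, a_post, _ = modulation.compute_nmi(x, fr, base, post)
        assert a_base == pytest.approx(1.0, rel=0.02)
        assert a_post == pytest.approx(3.0, rel=0.02)
        assert nmi == pytest.approx(0.5, abs=0.01)

    def test_both_windows_silent_flagged_degenerate(self):
        x, fr, base, post = _flat_trace(0.0, 0.0)
        nmi, _, _, degen = modulation.compute_nmi(x, fr, base, post)
        assert nmi == 0.0 and degen

    def test_negative_trace_rejected(self):
        x, fr, base, post = _flat_trace(1.0, 1.0)
        x[0] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            modulation.compute_nmi(x, fr, base, post)

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_antisymmetry_and_scale_invariance(self, scale, seed):
        x = np.random.default_rng(seed).gamma(1.0, 1.0, 600)
        fr, base, post = 5.0, (0.0, 60.0), (60.0, 120.0)
        nmi, *_ = modulation.compute_nmi(x, fr, base, post)
        flipped, *_ = modulation.compute_nmi(x, fr, post, base)
        scaled, *_ = modulation.compute_nmi(scale * x, fr, base, post)
        assert flipped == pytest.approx(-nmi, abs=1e-9)
        assert scaled == pytest.approx(nmi, abs=1e-9)


class TestSleepWake:
    def _states(self, pattern):
        return StateSequence(labels=np.array(pattern, dtype=object), epoch_length_s=5.0)

    def test_sleep_active_neuron_negative_nmi(self):
        cfg = synth.sleep_config(seed=21, n_neurons=1, total_s=2400.0)
        spec = synth.NeuronSpec(
            neuron_id="n0",
            state_gain={"WAKE": 1.0, "NREM": 2.0, "REM": 1.0, "ANESTHESIA": 1.0, "UNKNOWN": 1.0},
        )
        states = synth.gen_state_sequence(cfg)
        traces, _ = synth.gen_traces(states, [spec], cfg)
        nmi = modulation.sleepwake_nmi(traces.values[0], cfg.frame_rate_hz, states)
        assert nmi is not None and nmi < -0.1

    def test_state_invariant_neuron_near_zero(self):
        vals = []
        for seed in range(5):
            cfg = synth.sleep_config(seed=seed, n_neurons=1, total_s=2400.0)
            states = synth.gen_state_sequence(cfg)
            traces, _ = synth.gen_traces(states, [synth.NeuronSpec(neuron_id="n0")], cfg)
            vals.append(modulation.sleepwake_nmi(traces.values[0], cfg.frame_rate_hz, states))
        assert abs(np.mean(vals)) < 0.08

    def test_wake_only_session_undefined(self):
        states = self._states(["WAKE"] * 200)
        nmi = modulation.sleepwake_nmi(np.ones(5000), 5.0, states)
        assert nmi is None


class TestClassify:
    @pytest.mark.parametrize(
        "nmi,expected",
        [
            (-0.5, "INHIBITED"),
            (0.0, "INSENSITIVE"),
            (0.33, "INSENSITIVE"),  # strict inequality at the boundary
            (-0.33, "INSENSITIVE"),
            (0.34, "EXCITED"),
            (-1.0, "INHIBITED"),
            (1.0, "EXCITED"),
        ],
    )
    def test_thresholds(self, nmi, expected):
        assert modulation.classify(nmi) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            modulation.classify(1.5)

    def test_table_class_column_consistent(self, iso_session):
        cfg, session, truth = iso_session
        tbl = modulation.nmi_table(
            session.traces, "ISO", session.events[0].baseline_window, truth.anesthesia_interval
        )
        for _, row in tbl.iterrows():
            assert row["response_class"] == modulation.classify(row["nmi"])
        assert tbl["nmi"].between(-1, 1).all()


class TestClustering:
    def test_two_neurons_merge_at_their_distance(self):
        X = np.array([[0.0, 0.0], [0.3, 0.4]])
        labels, Z = modulation.cluster_responses(X, k=2)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.5)  # Euclidean distance
        assert set(labels) == {0, 1}

    def test_planted_three_groups_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for _ in range(5):
            truth = np.repeat([0, 1, 2], 30)
            centers = np.array([-0.8, 0.0, 0.8])
            X = np.clip(centers[truth][:, None] + rng.normal(0, 0.1, (90, 4)), -1, 1)
            labels, _ = modulation.cluster_responses(X, k=3)
            assert adjusted_rand_score(truth, labels) >= 0.8

    def test_identical_rows_collapse(self):
        X = np.zeros((5, 3))
        labels, _ = modulation.cluster_responses(X, k=3)
        assert len(set(labels)) <= 3  # degenerate tree cut documented tie-break

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            modulation.cluster_responses(np.zeros((2, 3)), k=3)

    def test_undefined_entries_rejected(self):
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            modulation.cluster_responses(X)


def _table(nmi_a, nmi_b):
    rows = []
    for cond, vec in (("PPF", nmi_a), ("ISO", nmi_b)):
        for i, v in enumerate(vec):
            rows.append(
                {
                    "neuron_id": f"n{i}",
                    "condition": cond,
                    "nmi": v,
                    "auc_base_rate": 1.0,
                    "auc_post_rate": 1.0,
                    "response_class": modulation.classify(v),
                    "degenerate": False,
                }
            )
    return pd.DataFrame(rows)


class TestOverlap:
    def test_identical_vectors_full_overlap_r_one(self, rng):
        v = rng.uniform(-1, 1, 50)
        res = modulation.overlap_and_correlation(_table(v, v), "PPF", "ISO")
        assert res.pearson_r == pytest.approx(1.0)
        assert res.n_only_one_inhibited == 0
        if res.pct_inhibited_mean is not None:
            assert res.pct_inhibited_mean == 100.0

    def test_independent_conditions_r_near_zero(self, rng):
        rs = []
        for _ in range(50):
            res = modulation.overlap_and_correlation(
                _table(rng.uniform(-1, 1, 100), rng.uniform(-1, 1, 100)), "PPF", "ISO"
            )
            rs.append(res.pearson_r)
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_vector_flags_undefined_correlation(self):
        res = modulation.overlap_and_correlation(
            _table(np.zeros(10), np.linspace(-1, 1, 10)), "PPF", "ISO"
        )
        assert res.pearson_r is None and res.r_pvalue is None

    def test_too_few_shared_neurons_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            modulation.overlap_and_correlation(_table([0.1], [0.2]), "PPF", "ISO")

    def test_counts_sum_to_shared_total(self, rng):
        res = modulation.overlap_and_correlation(
            _table(rng.uniform(-1, 1, 80), rng.uniform(-1, 1, 80)), "PPF", "ISO"
        )
        assert res.n_shared == 80
        assert res.n_both_inhibited + res.n_only_one_inhibited <= 80
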