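import numpy as np
import pandas as pd
import pytest

from somnis import depth, spectral, synth
from somnis.datamodel import TreatmentEvent


def dbi_bruteforce(points, labels):
    """Independent loop-based evaluation of the 2-cluster Davies-Bouldin index."""
    cents, spreads = {}, {}
    for k in (0, 1):
        pts = [p for p, l in zip(points, labels) if l == k]
        cents[k] = np.mean(pts, axis=0)
        spreads[k] = np.mean([np.sqrt(np.sum((p - cents[k]) ** 2)) for p in pts])
    total = 0.0
    for i in (0, 1):
        ratios = []
        for j in (0, 1):
            if j != i:
                d_ij = np.sqrt(np.sum((cents[i] - cents[j]) ** 2))
                ratios.append((spreads[i] + spreads[j]) / d_ij)
        total += max(ratios)
    return total / 2.0


def timing_bruteforce(times, rms, thr, t_from, run_len, above):
    """First start time of run_len consecutive windows past t_from meeting the rule."""
    ok = (rms > thr) if above else (rms < thr)
    ok = ok & (times >= t_from)
    for i in range(len(times) - run_len + 1):
        if ok[i : i + run_len].all():
            return times[i]
    return None


class TestDaviesBouldin:
    def test_singleton_clusters_have_zero_index(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert depth.davies_bouldin(pts, np.array([0, 1])) == 0.0

    def test_hand_evaluated_configuration(self):
        pts = np.array([[0, 0], [0, 2], [10, 0], [10, 2]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        assert depth.davies_bouldin(pts, labels) == pytest.approx(0.2, abs=1e-12)

    def test_scale_invariance(self, rng):
        pts = rng.standard_normal((40, 2)) + np.array([[3.0, 0.0]] * 20 + [[0.0, 0.0]] * 20)
        labels = np.array([0] * 20 + [1] * 20)
        a = depth.davies_bouldin(pts, labels)
        b = depth.davies_bouldin(2 * pts, labels)
        assert a == pytest.approx(b, rel=1e-12)

    def test_coincident_centroids_rejected(self):
        pts = np.array([[0, 0], [2, 2], [0, 2], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="coincident"):
            depth.davies_bouldin(pts, np.array([0, 0, 1, 1]))

    def test_matches_bruteforce_and_sklearn(self, rng):
        from sklearn.metrics import davies_bouldin_score

        for _ in range(30):
            pts = rng.standard_normal((20, 2))
            pts[10:] += 4.0
            labels = np.array([0] * 10 + [1] * 10)
            ours = depth.davies_bouldin(pts, labels)
            assert ours == pytest.approx(dbi_bruteforce(pts, labels), abs=1e-10)
            assert ours == pytest.approx(davies_bouldin_score(pts, labels), abs=1e-10)


def _periodic_features(n_base=60, n_post=240, period=12):
    """Post-injection features periodic in 60-s blocks: all candidate windows identical."""
    emg = np.concatenate(
        [np.tile([1.0, 1.2], n_base // 2), np.tile([0.05, 0.06] * (period // 2), n_post // period)]
    )
    ratio = np.concatenate(
        [np.tile([1.0, 1.1], n_base // 2), np.tile([6.0, 7.0] * (period // 2), n_post // period)]
    )
    n = n_base + n_post
    return pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "t_start_s": 5.0 * np.arange(n),
            "delta_power": np.ones(n),
            "theta_power": np.ones(n),
            "dt_ratio": ratio,
            "emg_rms": emg,
        }
    )


class TestDepthSearch:
    def test_recovers_programmed_plateau(self):
        # the 40-seed sweep lives in the acceptance suite
        for seed in (0, 1, 2):
            cfg = synth.anesthesia_config("ISO", seed=seed, n_neurons=1)
            states = synth.gen_state_sequence(cfg)
            rec = synth.gen_eeg_emg(states, cfg)
            feats = spectral.epoch_features(rec)
            res = depth.depth_search(feats, cfg.event)
            t0, t1 = synth.anesthesia_interval(cfg)
            assert t0 <= res.selected_window[0] and res.selected_window[1] <= t1

    def test_saline_control_yields_larger_dbi(self):
        dbis = {}
        for drug in ("ISO", "SALINE"):
            cfg = synth.anesthesia_config(drug, seed=3, n_neurons=1)
            states = synth.gen_state_sequence(cfg)
            rec = synth.gen_eeg_emg(states, cfg)
            res = depth.depth_search(spectral.epoch_features(rec), cfg.event)
            dbis[drug] = res.dbi
        assert dbis["SALINE"] > dbis["ISO"]

    def test_equal_dbi_windows_break_tie_to_earliest(self):
        feats = _periodic_features()
        event = TreatmentEvent("ISO", 300.0, (0.0, 300.0), (300.0, 1500.0))
        res = depth.depth_search(feats, event)
        assert res.selected_window[0] == 300.0
        # every candidate scored identically
        assert res.candidates["dbi"].std() == pytest.approx(0.0, abs=1e-12)

    def test_no_candidate_window_rejected(self):
        feats = _periodic_features(n_post=60)
        event = TreatmentEvent("ISO", 300.0, (0.0, 300.0), (300.0, 500.0))
        with pytest.raises(ValueError, match="candidate"):
            depth.depth_search(feats, event)

    def test_cluster_relabeling_invariance_of_dbi(self, rng):
        pts = rng.standard_normal((30, 2))
        pts[15:] += 5.0
        labels = np.array([0] * 15 + [1] * 15)
        assert depth.davies_bouldin(pts, labels) == pytest.approx(
            depth.davies_bouldin(pts, 1 - labels), rel=1e-12
        )


class TestEmgTiming:
    rate = 250.0

    def _session_emg(self, rng, drop_at=300.0, recover_at=900.0, total=1200.0, factor=0.05):
        n = int(total * self.rate)
        t = np.arange(n) / self.rate
        amp = np.where((t >= drop_at) & (t < recover_at), factor, 1.0)
        return amp * rng.standard_normal(n)

    def test_detection_within_run_length_lag(self, rng):
        # reference interval lies inside the anesthetized period, so the
        # mean + 3*SD threshold sits just above the quiescent EMG level
        emg = self._session_emg(rng)
        res = depth.emg_timing(emg, self.rate, (600.0, 880.0), (300.0, 900.0))
        assert 300.0 <= res.fully_anesthetized_start_s <= 450.0
        assert 900.0 <= res.fully_awake_s <= 990.0
        assert res.induction_time_s == res.fully_anesthetized_start_s - 300.0
        assert res.recovery_time_s == res.fully_awake_s - 900.0

    def test_run_length_logic_equals_bruteforce(self, rng):
        for _ in range(5):
            emg = self._session_emg(rng, factor=float(rng.uniform(0.02, 0.4)))
            times, rms = depth.hopped_rms(emg, self.rate)
            res = depth.emg_timing(emg, self.rate, (600.0, 880.0), (300.0, 900.0))
            ref = (times >= 600.0) & (times + 20.0 <= 880.0)
            thr = rms[ref].mean() + 3 * rms[ref].std()
            assert res.emg_threshold == pytest.approx(thr, rel=1e-12)
            assert res.fully_anesthetized_start_s == timing_bruteforce(
                times, rms, thr, 300.0, 15, above=False
            )
            assert res.fully_awake_s == timing_bruteforce(times, rms, thr, 900.0, 9, above=True)

    def test_never_subthreshold_gives_undefined_without_error(self, rng):
        # quiescent reference period, then EMG stays high forever: the
        # 15-window sub-threshold run never occurs and no exception is raised
        n = int(600 * self.rate)
        t = np.arange(n) / self.rate
        emg = np.where(t < 280.0, 0.05, 1.0) * rng.standard_normal(n)
        res = depth.emg_timing(emg, self.rate, (0.0, 280.0), (300.0, 500.0))
        assert res.fully_anesthetized_start_s is None
        assert res.induction_time_s is None
        assert res.fully_awake_s is not None  # high EMG after the stop

    def test_stationary_signal_never_crosses_upward(self, rng):
        # mean + 3*SD of a stationary RMS distribution is above nearly every
        # window, so the 9-window supra-threshold "awake" run cannot occur
        emg = rng.standard_normal(int(600 * self.rate))
        res = depth.emg_timing(emg, self.rate, (0.0, 280.0), (200.0, 400.0))
        assert res.fully_awake_s is None and res.recovery_time_s is None

    def test_short_reference_interval_rejected(self, rng):
        emg = rng.standard_normal(int(100 * self.rate))
        with pytest.raises(ValueError, match="reference interval"):
            depth.emg_timing(emg, self.rate, (0.0, 10.0), (20.0, 80.0))
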