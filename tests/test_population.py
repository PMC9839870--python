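import numpy as np
import pytest

from somnis import population, synth
from somnis.datamodel import TraceMatrix


def _poisson_traces(rng, rates, n_frames, fr=5.0):
    vals = rng.poisson(np.asarray(rates)[:, None] / fr, (len(rates), n_frames)).astype(float)
    return TraceMatrix(values=vals, frame_rate_hz=fr)


class TestWindowEntropy:
    def test_uniform_activity_max_entropy(self):
        v = np.ones((3, 24 * 25))  # 5 Hz * 120 s, uniform across the 24 bins
        assert population.window_entropy(v, 5.0) == pytest.approx(np.log(24), abs=1e-12)

    def test_single_bin_activity_zero_entropy(self):
        v = np.zeros((1, 600))
        v[0, :25] = 2.0
        assert population.window_entropy(v, 5.0) == 0.0

    def test_two_equal_bins_ln2(self):
        v = np.zeros((1, 600))
        v[0, :25] = 1.0
        v[0, 300:325] = 1.0
        assert population.window_entropy(v, 5.0) == pytest.approx(np.log(2), abs=1e-12)

    def test_scale_invariance_and_bounds(self, rng):
        v = rng.gamma(1.0, 1.0, (10, 600))
        h = population.window_entropy(v, 5.0)
        assert h == pytest.approx(population.window_entropy(5.0 * v, 5.0), abs=1e-12)
        assert 0.0 <= h <= np.log(24)

    def test_silent_neurons_excluded_not_zeroed(self):
        v = np.ones((2, 600))
        v[1] = 0.0  # would drag the mean to H/2 if counted as H = 0
        assert population.window_entropy(v, 5.0) == pytest.approx(np.log(24), abs=1e-12)

    def test_window_shorter_than_two_bins_rejected(self):
        with pytest.raises(ValueError, match="2 bins"):
            population.window_entropy(np.ones((1, 30)), 5.0)


class TestEntropyBootstrap:
    def _traces(self, rng):
        # 1200 s; first half "baseline", second half "condition"
        return _poisson_traces(rng, np.full(20, 1.0), 6000)

    def test_null_condition_ci_straddles_zero(self, rng):
        tm = self._traces(rng)
        res = population.entropy_bootstrap(
            tm, [(0.0, 600.0)], [(600.0, 1200.0)], n_resamples=400, seed=3
        )
        assert res.ci95[0] < 0.0 < res.ci95[1]

    def test_same_seed_reproducible(self, rng):
        tm = self._traces(rng)
        a = population.entropy_bootstrap(tm, [(0, 600)], [(600, 1200)], n_resamples=100, seed=9)
        b = population.entropy_bootstrap(tm, [(0, 600)], [(600, 1200)], n_resamples=100, seed=9)
        assert a.delta_entropy_pct == b.delta_entropy_pct
        np.testing.assert_array_equal(a.resamples, b.resamples)

    def test_single_resample_degenerate_ci(self, rng):
        tm = self._traces(rng)
        res = population.entropy_bootstrap(tm, [(0, 600)], [(600, 1200)], n_resamples=1, seed=0)
        assert res.ci95 == (res.delta_entropy_pct, res.delta_entropy_pct)

    def test_burst_concentration_lowers_entropy(self, rng):
        # condition period concentrates the same activity into sparse bursts
        vals = rng.poisson(0.3, (20, 6000)).astype(float)
        mask = np.zeros(6000, dtype=bool)
        for s in range(3000, 6000, 250):  # one active 10-s burst per 50 s
            mask[s : s + 50] = True
        vals[:, 3000:] *= 0.0
        vals[:, mask] = rng.poisson(2.0, (20, int(mask.sum()))).astype(float)
        tm = TraceMatrix(values=vals, frame_rate_hz=5.0)
        res = population.entropy_bootstrap(
            tm, [(0.0, 600.0)], [(600.0, 1200.0)], n_resamples=400, seed=5
        )
        assert res.delta_entropy_pct < 0.0
        assert res.ci95[1] < 0.0

    def test_delta_pct_base_invariant(self, rng):
        # percent change of entropy is independent of the logarithm base:
        # H_b = H_e / ln(b) cancels in the ratio
        tm = self._traces(rng)
        h1 = population.population_entropy(tm, (0.0, 120.0))
        h2 = population.population_entropy(tm, (600.0, 720.0))
        pct_nat = 100 * (h2 - h1) / h1
        pct_log2 = 100 * (h2 / np.log(2) - h1 / np.log(2)) / (h1 / np.log(2))
        assert pct_nat == pytest.approx(pct_log2, abs=1e-12)

    def test_empty_pool_rejected(self, rng):
        tm = self._traces(rng)
        with pytest.raises(ValueError, match="pool"):
            population.entropy_bootstrap(tm, [(0.0, 60.0)], [(600.0, 1200.0)], n_resamples=10)


class TestStateSpace:
    def _planted(self, rng, n_neur=60, fr=5.0):
        segs = {"A": [(0.0, 300.0)], "B": [(300.0, 600.0)], "C": [(600.0, 900.0)]}
        blocks = [
            rng.poisson(rng.uniform(0.1, 1.0, n_neur)[:, None] / fr, (n_neur, 1500)).astype(float)
            for _ in "ABC"
        ]
        return TraceMatrix(values=np.concatenate(blocks, axis=1), frame_rate_hz=fr), segs

    def test_planted_conditions_separate(self, rng):
        tm, segs = self._planted(rng)
        res = population.build_state_space(tm, segs, 15.0)
        sep = res.separation_matrix().to_numpy()
        assert np.nanmin(sep) > 3.0

    def test_neuron_order_permutation_invariance(self, rng):
        tm, segs = self._planted(rng, n_neur=30)
        res = population.build_state_space(tm, segs, 15.0)
        perm = rng.permutation(30)
        tm_p = TraceMatrix(
            values=tm.values[perm],
            frame_rate_hz=tm.frame_rate_hz,
            neuron_ids=tuple(np.asarray(tm.neuron_ids)[perm]),
        )
        res_p = population.build_state_space(tm_p, segs, 15.0)
        a = res.points[["pc1", "pc2"]].to_numpy()
        b = res_p.points[["pc1", "pc2"]].to_numpy()
        for j in range(2):  # PCA component signs are arbitrary
            assert np.allclose(a[:, j], b[:, j], atol=1e-8) or np.allclose(
                a[:, j], -b[:, j], atol=1e-8
            )

    def test_bin_size_robustness_15_vs_30(self, rng):
        tm, segs = self._planted(rng)
        for bin_s in (15.0, 30.0):
            res = population.build_state_space(tm, segs, bin_s)
            assert np.nanmin(res.separation_matrix().to_numpy()) > 3.0

    def test_constant_neuron_excluded_with_warning(self, rng):
        tm, segs = self._planted(rng, n_neur=20)
        vals = tm.values.copy()
        vals[0] = 1.0
        tm2 = TraceMatrix(values=vals, frame_rate_hz=5.0, neuron_ids=tm.neuron_ids)
        with pytest.warns(UserWarning, match="constant"):
            res = population.build_state_space(tm2, segs, 15.0)
        assert tm.neuron_ids[0] in res.excluded_neurons

    def test_explained_variance_fractions_reported(self, rng):
        tm, segs = self._planted(rng, n_neur=25)
        res = population.build_state_space(tm, segs, 15.0)
        assert res.explained_variance_ratio.shape == (2,)
        assert 0 < res.explained_variance_ratio.sum() <= 1.0
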