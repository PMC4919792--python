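import numpy as np
import pytest
from scipy.linalg import toeplitz

from selsort.synthgen import (
    GroundTruth,
    Recording,
    SimConfig,
    make_templates,
    render_channel,
)
from selsort.cluster import ClusterAssignment
from selsort.overlap import (
    SortConfig,
    TemplateSet,
    build_impulse_trains,
    coiflet_filter_from_cov,
    compute_noise_residual,
    estimate_templates,
    match_unclustered,
    noise_autocovariance,
    place_lag_templates,
    sort_channel,
    templates_from_waveforms,
    whiten,
)


def dense_lstsq_templates(v, trains, lags):
    """Brute-force oracle: explicit shifted-train design matrix."""
    T = v.size
    cols = []
    for tr in trains:
        d = np.zeros(T)
        d[tr] = 1.0
        for u in range(-lags, lags + 1):
            col = np.zeros(T)
            if u >= 0:
                col[u:] = d[: T - u]
            else:
                col[:u] = d[-u:]
            cols.append(col)
    A = np.column_stack(cols)
    w, *_ = np.linalg.lstsq(A, v, rcond=None)
    return w.reshape(len(trains), 2 * lags + 1)


@pytest.fixture
def two_templates():
    w1, w2 = make_templates(2, 60, seed=42)
    return np.stack([w1, w2])


class TestBuildImpulseTrains:
    def test_empty_assignment_all_unassigned(self):
        asg = ClusterAssignment(labels=np.zeros(4, dtype=int),
                                sizes=np.empty(0, dtype=int),
                                chosen_temperature=0.0, method="spc")
        trains, unassigned = build_impulse_trains(
            asg, np.array([10, 20, 30, 40]), T=100
        )
        assert trains == []
        np.testing.assert_array_equal(unassigned, [10, 20, 30, 40])

    def test_train_sums_equal_cluster_sizes_and_union(self):
        labels = np.array([1, 2, 1, 0, 2, 1])
        events = np.array([5, 10, 20, 30, 40, 50])
        asg = ClusterAssignment(labels=labels, sizes=np.array([3, 2]),
                                chosen_temperature=0.0, method="spc")
        trains, unassigned = build_impulse_trains(asg, events, T=100)
        assert [t.size for t in trains] == [3, 2]
        union = np.sort(np.concatenate(trains + [unassigned]))
        np.testing.assert_array_equal(union, events)

    def test_out_of_bounds_event_rejected(self):
        asg = ClusterAssignment(labels=np.array([1]), sizes=np.array([1]),
                                chosen_temperature=0.0, method="spc")
        with pytest.raises(ValueError):
            build_impulse_trains(asg, np.array([200]), T=100)


class TestEstimateTemplates:
    def test_single_spike_recovers_trace_segment(self, two_templates):
        w = two_templates[0]
        peak = int(np.argmax(w))
        x = np.zeros(2000)
        x[700 - peak: 700 - peak + 60] = w
        ts = estimate_templates(Recording(x), [np.array([700])], lags=40)
        seg = x[700 - 40: 700 + 41]
        np.testing.assert_allclose(ts.templates[0], seg, atol=1e-8)

    def test_nonoverlapping_spikes_equal_segment_average(self, two_templates):
        w = two_templates[1]
        peak = int(np.argmax(w))
        spikes = np.array([300, 700, 1100, 1500])
        x = np.zeros(2000)
        for t in spikes:
            x[t - peak: t - peak + 60] += w
        ts = estimate_templates(Recording(x), [spikes], lags=30)
        segs = np.stack([x[t - 30: t + 31] for t in spikes])
        assert np.abs(ts.templates[0] - segs.mean(0)).max() < 1e-6

    def test_overlapping_render_matches_dense_lstsq(self, two_templates):
        cfg = SimConfig(duration=2000, firing_rates=(0.0, 0.0),
                        noise_level=0.05, seed=13)
        truth = GroundTruth(
            spike_times=[np.array([400, 900, 1400]),
                         np.array([410, 980, 1420])],
            templates=two_templates, refractory=60,
        )
        rec = render_channel(truth, cfg)
        lags = 20
        ts = estimate_templates(Recording(rec.samples), truth.spike_times,
                                lags=lags)
        expected = dense_lstsq_templates(
            rec.samples - 0.0, truth.spike_times, lags
        )
        np.testing.assert_allclose(ts.templates, expected, atol=1e-6)

    def test_spike_rates_are_train_density(self):
        x = np.random.default_rng(0).normal(size=1000)
        ts = estimate_templates(Recording(x), [np.array([100, 300, 500])],
                                lags=10)
        assert ts.spike_rates[0] == pytest.approx(3 / 1000)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            estimate_templates(Recording(np.ones(100)), [np.array([], int)],
                               lags=5)


class TestNoiseResidual:
    def test_perfect_model_zero_residual(self, two_templates):
        w = two_templates[0]
        peak = int(np.argmax(w))
        spikes = np.array([200, 600, 1000])
        x = np.zeros(1500)
        for t in spikes:
            x[t - peak: t - peak + 60] += w
        ts = estimate_templates(Recording(x), [spikes], lags=40)
        resid = compute_noise_residual(Recording(x), ts, [spikes])
        assert np.abs(resid).max() < 1e-6

    def test_residual_energy_not_above_original(self, small_sim):
        rec, truth, _ = small_sim
        ts = estimate_templates(Recording(rec.samples), truth.spike_times,
                                lags=30)
        resid = compute_noise_residual(Recording(rec.samples), ts,
                                       truth.spike_times)
        assert np.sum(resid**2) <= np.sum(rec.samples**2)

    def test_unclustered_spikes_survive_in_residual(self, two_templates):
        w1, w2 = two_templates
        p1, p2 = int(np.argmax(w1)), int(np.argmax(w2))
        clustered = np.array([300, 800])
        stray = 1500
        x = np.zeros(2000)
        for t in clustered:
            x[t - p1: t - p1 + 60] += w1
        x[stray - p2: stray - p2 + 60] += w2
        ts = estimate_templates(Recording(x), [clustered], lags=40)
        resid = compute_noise_residual(Recording(x), ts, [clustered])
        assert resid[stray] > 0.5  # stray spike still peaks


class TestNoiseAutocovariance:
    def test_white_noise(self, rng):
        x = rng.normal(0, 2.0, size=100000)
        ac = noise_autocovariance(x, 10)
        assert ac[0] == pytest.approx(4.0, rel=0.05)
        assert np.abs(ac[1:]).max() < 3 * 4.0 / np.sqrt(x.size) * 10

    def test_ar1_closed_form(self, rng):
        phi = 0.8
        e = rng.normal(size=100000)
        x = np.zeros_like(e)
        for t in range(1, e.size):
            x[t] = phi * x[t - 1] + e[t]
        ac = noise_autocovariance(x, 6)
        ratios = ac[1:] / ac[0]
        np.testing.assert_allclose(ratios, phi ** np.arange(1, 6), atol=0.05)

    def test_matches_brute_force_double_loop(self, rng):
        x = rng.normal(size=500)
        ac = noise_autocovariance(x, 5)
        xc = x - x.mean()
        expected = np.array(
            [np.sum(xc[: 500 - k] * xc[k:]) / 500 for k in range(5)]
        )
        np.testing.assert_allclose(ac, expected, atol=1e-10)


class TestCoifletFilter:
    def test_white_noise_gives_unit_impulse(self):
        ac = np.zeros(11)
        ac[0] = 2.5
        f = coiflet_filter_from_cov(ac, 11)
        expected = np.zeros(11)
        expected[5] = 1.0
        np.testing.assert_allclose(f, expected)

    def test_symmetry_and_matrix_oracle(self, rng):
        ac = np.exp(-np.arange(15) / 3.0)
        f = coiflet_filter_from_cov(ac, 15)
        np.testing.assert_allclose(f, f[::-1])
        col = toeplitz(ac)[:, 7]
        np.testing.assert_allclose(f, col / np.linalg.norm(col))

    def test_even_length_rejected(self):
        with pytest.raises(ValueError):
            coiflet_filter_from_cov(np.ones(10), 10)


class TestWhiten:
    def test_impulse_filter_is_identity(self, rng):
        x = rng.normal(size=1000)
        f = np.zeros(11)
        f[5] = 1.0
        np.testing.assert_allclose(whiten(x, f), x, atol=1e-10)

    def test_length_preserved(self, rng):
        x = rng.normal(size=777)
        assert whiten(x, np.ones(11) / np.sqrt(11)).size == 777

    def test_snr_gain_when_residual_carries_spike_structure(self, two_templates):
        # the residual after removing clustered spikes still holds the
        # unclustered spike shapes, so the covariance-derived filter is a
        # matched smoother that lifts spike peaks over the white noise
        rng = np.random.default_rng(5)
        w1, w2 = two_templates
        p1, p2 = int(np.argmax(w1)), int(np.argmax(w2))
        T = 60000
        clustered = np.arange(2000, T - 2000, 1500)
        unclustered = rng.integers(100, T - 100, size=120)
        x = rng.normal(0, 0.15, size=T)
        for t in clustered:
            x[t - p1: t - p1 + 60] += w1
        for t in unclustered:
            x[t - p2: t - p2 + 60] += w2
        resid = x.copy()
        for t in clustered:
            resid[t - p1: t - p1 + 60] -= w1
        ac = noise_autocovariance(resid, 31)
        f = coiflet_filter_from_cov(ac, 31)
        xf = whiten(x, f)
        quiet = np.ones(T, bool)
        for t in np.concatenate([clustered, unclustered]):
            quiet[max(0, t - 80): t + 80] = False
        snr_raw = x[clustered].mean() / x[quiet].std()
        snr_f = xf[clustered].mean() / xf[quiet].std()
        assert snr_f > snr_raw


class TestMatchUnclustered:
    def _tset(self, templates, rates, lag=30):
        return templates_from_waveforms(templates, rates, lag=lag)

    def test_pure_window_wins_and_residual_cleared(self, two_templates):
        ts = self._tset(two_templates, [0.001, 0.001])
        L = ts.lag
        v = np.zeros(500)
        t0 = 250
        v[t0 - L: t0 + L + 1] += ts.templates[1]
        res = match_unclustered(v, ts, np.array([t0]), refractory=60)
        assert res.decisions[0] == (1,)
        assert np.argmax(res.likelihoods[0]) == 1

    def test_overlap_pair_resolved_by_elimination(self, two_templates):
        ts = self._tset(two_templates, [0.001, 0.001])
        L = ts.lag
        v = np.zeros(600)
        t0, lagd = 300, 5
        v[t0 - L: t0 + L + 1] += ts.templates[0]
        v[t0 + lagd - L: t0 + lagd + L + 1] += ts.templates[1]
        res = match_unclustered(v, ts, np.array([t0, t0 + lagd]),
                                refractory=60)
        accepted = sorted(n for d in res.decisions for n in d)
        assert accepted == [0, 1]

    def test_equal_match_prior_decides(self, two_templates):
        w = two_templates[0]
        ts = self._tset(np.stack([w, w]), [0.01, 0.00001])
        L = ts.lag
        v = np.zeros(400)
        v[200 - L: 200 + L + 1] += ts.templates[0]
        res = match_unclustered(v, ts, np.array([200]), refractory=60)
        assert res.decisions[0] == (0,)  # higher-rate neuron wins the tie

    def test_refractory_rejects_duplicate(self, two_templates):
        ts = self._tset(two_templates[:1], [0.001])
        L = ts.lag
        v = np.zeros(500)
        for t in (200, 230):
            v[t - L: t + L + 1] += ts.templates[0]
        res = match_unclustered(v, ts, np.array([200, 230]), refractory=60)
        assert len(res.spike_trains[0]) == 1  # second within refractory

    def test_empty_template_set_rejects_all(self):
        ts = TemplateSet(templates=np.empty((0, 61)), spike_rates=np.empty(0),
                         lag=30)
        res = match_unclustered(np.zeros(100), ts, np.array([50]),
                                refractory=60)
        assert res.decisions == [()]

    def test_overlap_recovery_rate_over_trials(self, two_templates):
        # pairwise collisions, lag >= 3 samples, noise 0.1: both spikes
        # recovered in at least 90% of 200 randomised trials
        ts = self._tset(two_templates, [0.001, 0.001])
        L = ts.lag
        rng = np.random.default_rng(77)
        wins = 0
        n_trials = 200
        for _ in range(n_trials):
            lagd = int(rng.integers(3, 31)) * (1 if rng.random() < 0.5 else -1)
            t0 = 300
            v = rng.normal(0, 0.1, size=700)
            v[t0 - L: t0 + L + 1] += ts.templates[0]
            v[t0 + lagd - L: t0 + lagd + L + 1] += ts.templates[1]
            targets = np.sort(np.array([t0, t0 + lagd]))
            res = match_unclustered(v, ts, targets, refractory=60)
            got = sorted(
                (n, t)
                for n, tr in enumerate(res.spike_trains)
                for t in tr
            )
            want = sorted([(0, t0), (1, t0 + lagd)])
            wins += got == want
        assert wins / n_trials >= 0.9


class TestSortChannel:
    def test_end_to_end_recovers_three_neurons(self, small_sim):
        rec, truth, _ = small_sim
        cfg = SortConfig()
        cfg.spc.min_cluster_size = 40
        result = sort_channel(rec, cfg)
        assert result.n_neurons == 3
        # matching only adds spikes on top of the clustered trains
        clustered = sum(
            int(s) for s in result.stages["assignment"].sizes
        )
        assert result.total_spikes() >= clustered
        # per-neuron refractory holds in the final trains
        for tr in result.spike_trains:
            if tr.size > 1:
                assert np.diff(tr).min() >= cfg.refractory

    def test_deterministic_given_seed(self, small_sim):
        rec, _, _ = small_sim
        cfg = SortConfig()
        cfg.spc.min_cluster_size = 40
        r1 = sort_channel(rec, cfg)
        r2 = sort_channel(rec, cfg)
        assert len(r1.spike_trains) == len(r2.spike_trains)
        for a, b in zip(r1.spike_trains, r2.spike_trains):
            np.testing.assert_array_equal(a, b)
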