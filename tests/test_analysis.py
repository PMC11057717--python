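"""Tree-plots, OSR curves, PSTH, QC and prior summaries."""

import numpy as np
import pytest

from rgcsurprise import (
    BeliefPrior,
    CellModel,
    EncoderParams,
    MarkovParams,
    generate_stimulus,
)
from rgcsurprise.analysis import (
    Psth,
    branching_distance,
    compute_psth,
    detect_osr,
    history_conditioned_means,
    osr_curve,
    prior_summary,
    qc_refractory,
    short_vs_long_history_correlation,
    tree_correlation_by_depth,
)
from rgcsurprise.encoder import predict_rates
from rgcsurprise.synthetic import make_osr_spike_times

ENC = EncoderParams(a=2.0, b=-1.0)


def isolated_runs_stimulus(k_max=8, gap=12):
    """Deterministic stimulus of isolated flash runs of every length 1..k_max."""
    bins = []
    for k in range(1, k_max + 1):
        bins += [0] * gap + [1] * k
    bins += [0] * gap
    return np.array(bins)


class TestHistoryConditionedMeans:
    def test_constant_counts_give_constant_tree(self, short_stimulus):
        counts = np.full(len(short_stimulus), 3.0)
        tree = history_conditioned_means(counts, short_stimulus, n=5)
        assert all(n.mean_response == pytest.approx(3.0) for n in tree.nodes.values())

    def test_parent_child_conservation(self, short_stimulus):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=len(short_stimulus))
        tree = history_conditioned_means(counts, short_stimulus, n=6)
        for h, parent in tree.nodes.items():
            if len(h) == tree.depth_max:
                continue
            kids = [tree.at((s,) + h) for s in (0, 1)]
            kids = [k for k in kids if k is not None]
            assert parent.n_obs == sum(k.n_obs for k in kids)
            weighted = sum(k.mean_response * k.n_obs for k in kids) / parent.n_obs
            assert parent.mean_response == pytest.approx(weighted)

    def test_fixed_model_tree_constant_beyond_depth_two(self, fixed_cell, short_stimulus):
        """A fixed-surprise cell's node means depend only on the final 2 symbols."""
        rates = predict_rates(fixed_cell, short_stimulus)
        tree = history_conditioned_means(rates, short_stimulus, n=6)
        for h, node in tree.nodes.items():
            if len(h) < 2:
                continue
            ref = tree.at(h[-2:])
            assert node.mean_response == pytest.approx(ref.mean_response)

    def test_repeats_are_averaged(self, short_stimulus):
        counts = np.ones((4, len(short_stimulus)))
        counts[0] *= 5.0  # mean across repeats = 2
        tree = history_conditioned_means(counts, short_stimulus, n=3)
        assert all(n.mean_response == pytest.approx(2.0) for n in tree.nodes.values())


class TestOsrCurve:
    def test_adaptive_weak_prior_nondecreasing(self, weak_adaptive_cell):
        x = isolated_runs_stimulus()
        tree = history_conditioned_means(predict_rates(weak_adaptive_cell, x), x, n=9)
        curve = osr_curve(tree, 8)
        vals = [curve[k] for k in range(1, 9)]
        assert all(v is not None for v in vals)
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_fixed_model_constant_from_k1(self, fixed_cell):
        x = isolated_runs_stimulus()
        tree = history_conditioned_means(predict_rates(fixed_cell, x), x, n=9)
        curve = osr_curve(tree, 8)
        assert np.ptp([curve[k] for k in range(1, 9)]) == pytest.approx(0.0, abs=1e-12)

    def test_markov2_constant_from_k2(self, markov2_cell):
        x = isolated_runs_stimulus()
        tree = history_conditioned_means(predict_rates(markov2_cell, x), x, n=9)
        curve = osr_curve(tree, 8)
        assert np.ptp([curve[k] for k in range(2, 9)]) == pytest.approx(0.0, abs=1e-12)
        assert curve[1] != pytest.approx(curve[2], abs=1e-9)

    def test_requires_enough_depth(self, fixed_cell):
        x = isolated_runs_stimulus()
        tree = history_conditioned_means(predict_rates(fixed_cell, x), x, n=4)
        with pytest.raises(ValueError):
            osr_curve(tree, 8)


class TestTreeCorrelationByDepth:
    def test_self_correlation_is_one(self, weak_adaptive_cell, short_stimulus):
        rates = predict_rates(weak_adaptive_cell, short_stimulus)
        tree = history_conditioned_means(rates, short_stimulus, n=6)
        corr = tree_correlation_by_depth(tree, tree)
        for d in range(2, 7):
            assert corr[d] == pytest.approx(1.0)

    def test_affine_invariance(self, weak_adaptive_cell, short_stimulus):
        rates = predict_rates(weak_adaptive_cell, short_stimulus)
        t1 = history_conditioned_means(rates, short_stimulus, n=5)
        t2 = history_conditioned_means(3.0 * rates + 1.0, short_stimulus, n=5)
        corr = tree_correlation_by_depth(t1, t2)
        for d in range(2, 6):
            assert corr[d] == pytest.approx(1.0)

    def test_fixed_model_degrades_beyond_depth_two(self):
        """Against weak-prior adaptive data, a fixed model's tree correlation
        collapses for histories longer than its one-step memory."""
        stim = generate_stimulus(4.0, 0.8, seed=5)
        weak = CellModel(
            belief=BeliefPrior(alpha0={0: 1.0, 1: 1.0}, beta0={0: 1.0, 1: 1.0}, eta=0.2),
            encoder=ENC,
        )
        x = stim.bins
        theta = {
            i: ((x[:-1] == i) & (x[1:] == 1)).sum() / (x[:-1] == i).sum() for i in (0, 1)
        }
        fixed = CellModel(belief=MarkovParams(order=1, theta=theta), encoder=ENC)
        t_data = history_conditioned_means(predict_rates(weak, stim), stim, n=8)
        t_model = history_conditioned_means(predict_rates(fixed, stim), stim, n=8)
        corr = tree_correlation_by_depth(t_data, t_model)
        assert corr[2] > 0.95
        assert all(corr[d] < 0.9 for d in range(3, 9))
        assert corr[2] - max(corr[d] for d in range(3, 9)) > 0.1


class TestBranchingDistance:
    def test_constant_tree_is_zero(self, short_stimulus):
        tree = history_conditioned_means(
            np.full(len(short_stimulus), 2.0), short_stimulus, n=6
        )
        bd = branching_distance(tree)
        assert all(v == pytest.approx(0.0) for v in bd.values())

    def test_markov2_zero_beyond_memory(self, markov2_cell, short_stimulus):
        rates = predict_rates(markov2_cell, short_stimulus)
        tree = history_conditioned_means(rates, short_stimulus, n=8)
        bd = branching_distance(tree)
        assert bd[3] > 1e-6  # within the 2-bin memory, branches differ
        for d in range(4, 9):
            assert bd[d] == pytest.approx(0.0, abs=1e-10)

    def test_adaptive_positive_at_depth(self, weak_adaptive_cell, short_stimulus):
        rates = predict_rates(weak_adaptive_cell, short_stimulus)
        tree = history_conditioned_means(rates, short_stimulus, n=8)
        bd = branching_distance(tree)
        for d in range(4, 9):
            assert bd[d] > 0


class TestPsth:
    def test_single_spike_single_bin(self):
        psth = compute_psth([[102.0]], align_ms=100.0, window_ms=(0.0, 20.0), bin_ms=5.0)
        assert psth.values.sum() == pytest.approx(1.0)
        assert psth.values[0] == pytest.approx(1.0)  # spike at +2 ms

    def test_linearity_in_spike_counts(self):
        reps = [[10.0, 30.0, 55.0], [12.0, 60.0]]
        doubled = [r + r for r in reps]
        a = compute_psth(reps, 0.0, (0.0, 100.0))
        b = compute_psth(doubled, 0.0, (0.0, 100.0))
        assert np.allclose(b.values, 2 * a.values)

    def test_requires_nonempty_window_and_repeats(self):
        with pytest.raises(ValueError):
            compute_psth([], 0.0, (0.0, 10.0))
        with pytest.raises(ValueError):
            compute_psth([[1.0]], 0.0, (10.0, 10.0))


class TestDetectOsr:
    def _psth(self, values, bin_ms=5.0, start=-120.0):
        return Psth(
            bin_ms=bin_ms,
            values=np.asarray(values, dtype=float),
            window_ms=(start, start + bin_ms * len(values)),
            n_repeats=1,
        )

    def test_flat_psth_not_detected(self):
        psth = self._psth(np.ones(84))  # -120..300 ms
        assert not detect_osr(psth, omitted_flash_ms=0.0)["detected"]

    def test_peak_in_window_detected(self):
        values = np.ones(84)
        values[np.arange(84) * 5.0 - 120.0 == 120.0] = 5.0  # 5x peak at +120 ms
        res = detect_osr(self._psth(values), omitted_flash_ms=0.0)
        assert res["detected"]
        assert 60.0 <= res["peak_ms"] <= 180.0

    def test_peak_outside_window_not_detected(self):
        values = np.ones(90)
        values[-1] = 6.0  # peak at ~+320 ms
        assert not detect_osr(self._psth(values), omitted_flash_ms=0.0)["detected"]

    def test_synthetic_spike_fixture_produces_osr(self, weak_adaptive_cell):
        x = isolated_runs_stimulus(k_max=6, gap=10)
        rates = predict_rates(weak_adaptive_cell, x)
        rng = np.random.default_rng(8)
        counts = np.stack([rng.poisson(rates) for _ in range(40)])
        spikes = make_osr_spike_times(x, counts, seed=9)
        # omission after the k=6 run: bins gap*6+1+2+..+? simpler: find it
        run_end = len(x) - 10  # last flash bin index + 1 == start of final silence
        omit_ms = run_end * 120.0
        psth = compute_psth(spikes, omit_ms, (-120.0, 300.0))
        res = detect_osr(psth, omitted_flash_ms=0.0)
        assert res["detected"]
        assert 60.0 <= res["peak_ms"] <= 180.0


class TestQcRefractory:
    def test_counts_short_isis(self):
        assert qc_refractory([0.0, 1.0, 10.0]) == pytest.approx(0.5)

    def test_empty_and_singleton(self):
        assert qc_refractory([]) == 0.0
        assert qc_refractory([5.0]) == 0.0

    def test_poisson_train_violation_rate(self):
        # exponential ISIs at 5 Hz: P(ISI < 2 ms) = 1 - exp(-5 * 0.002)
        rng = np.random.default_rng(4)
        isi = rng.exponential(1000.0 / 5.0, size=50_000)
        t = np.cumsum(isi)
        expect = 1.0 - np.exp(-5 * 0.002)
        frac = qc_refractory(t)
        se = np.sqrt(expect * (1 - expect) / isi.size)
        assert abs(frac - expect) < 4 * se


class TestPriorSummary:
    def test_threshold_labels(self):
        weak = BeliefPrior(alpha0={0: 100.0, 1: 100.0}, beta0={0: 100.0, 1: 100.0})
        strong = BeliefPrior(alpha0={0: 1000.0, 1: 1000.0}, beta0={0: 1000.0, 1: 1000.0})
        rows = prior_summary([weak, strong])
        assert rows[0]["ratio_1"] == pytest.approx(1.0)
        assert rows[0]["strength_1"] == pytest.approx(200.0)
        assert rows[0]["log_strength_1"] == pytest.approx(np.log(200.0))
        assert rows[0]["label"] == "weak"
        assert rows[1]["log_strength_1"] == pytest.approx(np.log(2000.0))
        assert rows[1]["label"] == "strong"


class TestShortVsLongHistory:
    def test_fixed_model_correlation_is_one(self, fixed_cell):
        stim = generate_stimulus(8.0, 0.8, seed=6)
        rates = predict_rates(fixed_cell, stim)
        r = short_vs_long_history_correlation(rates, stim)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_weak_prior_below_one(self, weak_adaptive_cell):
        stim = generate_stimulus(8.0, 0.8, seed=6)
        rates = predict_rates(weak_adaptive_cell, stim)
        r = short_vs_long_history_correlation(rates, stim)
        assert r is not None and r < 0.999

    def test_pure_noise_handled(self, short_stimulus):
        rng = np.random.default_rng(11)
        counts = rng.poisson(2.0, size=len(short_stimulus))
        r = short_vs_long_history_correlation(counts, short_stimulus)
        assert r is None or abs(r) < 0.5
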