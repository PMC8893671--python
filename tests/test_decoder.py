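import numpy as np
import pandas as pd
import pytest
from scipy import stats

from affectloop.decoder import (
    BetaSeries,
    DecoderModel,
    LabeledVolumeSet,
    build_class_regressor,
    decode,
    extract_beta_series,
    fit_platt,
    hyperplane_distance,
    label_volumes,
    platt_probability,
    reliable_stimulus_set,
    train_linear_classifier,
    within_subject_accuracy,
)
from affectloop.synthetic import (
    StimulusCatalog,
    VolumeSeries,
    hrf,
    hrf_kernel,
    make_subject,
    simulate_volume_series,
)


class TestClassRegressor:
    def test_middle_score_contributes_nothing(self):
        reg = build_class_regressor([0.0], [5.0], 2.0, 20)
        assert np.all(reg == 0)

    def test_extreme_score_peak(self):
        reg = build_class_regressor([0.0], [9.0], 2.0, 20)
        peak_idx = int(np.argmax(reg))
        assert peak_idx == round(6.0 / 2.0)
        assert reg[peak_idx] == pytest.approx(4.0 * hrf(6.0))

    def test_antisymmetric_cancellation(self):
        reg = build_class_regressor([0.0, 0.0], [9.0, 1.0], 2.0, 20)
        assert np.allclose(reg, 0)

    def test_offgrid_onset_snaps_to_nearest_volume(self):
        snapped = build_class_regressor([1.8], [9.0], 2.0, 20)
        exact = build_class_regressor([2.0], [9.0], 2.0, 20)
        assert np.allclose(snapped, exact)

    def test_onset_outside_scan_rejected(self):
        with pytest.raises(ValueError):
            build_class_regressor([100.0], [9.0], 2.0, 20)


class TestLabelVolumes:
    def test_zero_regressor_all_unlabeled(self):
        assert np.all(label_volumes(np.zeros(10)) == 0)

    def test_triangular_pulse_threshold(self):
        reg = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25, 0.0])
        labels = label_volumes(reg, theta=0.5)
        assert np.array_equal(labels, (reg >= 0.5).astype(int))

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        reg = rng.normal(size=50)
        assert np.array_equal(label_volumes(-reg), -label_volumes(reg))

    def test_theta_bounds(self):
        with pytest.raises(ValueError):
            label_volumes(np.ones(5), theta=1.5)


class TestLinearClassifier:
    def _toy(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        return LabeledVolumeSet(X, y)

    def test_separable_toy(self):
        model = train_linear_classifier(self._toy())
        h = hyperplane_distance(model, np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert np.sign(h[0]) == 1 and np.sign(h[1]) == -1

    def test_support_vector_margin_is_one(self):
        model = train_linear_classifier(self._toy())
        h = hyperplane_distance(model, np.array([1.0, 0.0]))
        assert abs(h) == pytest.approx(1.0, abs=1e-6)

    def test_label_flip_negates_weights(self):
        data = self._toy()
        m1 = train_linear_classifier(data)
        m2 = train_linear_classifier(LabeledVolumeSet(data.features, -data.labels))
        assert np.allclose(m1.weights, -m2.weights, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_classifier(LabeledVolumeSet(np.eye(3), np.array([1, 1, 1])))

    def test_planted_pattern_recovery_noise_free(self, catalog):
        ids = list(catalog.frame.stim_id[:40])
        onsets = 8.0 * np.arange(40)
        sched = pd.DataFrame(
            {"onset": onsets, "duration": 2.0, "trial_type": "Id-PS", "stim_id": ids}
        )
        sub = make_subject("s", n_voxels=120, noise_sd=1e-8, seed=3)
        ser = simulate_volume_series(sched, sub, catalog, seed=4, drift_slope_sd=0.0)
        scores = [catalog.scores(s)[0] for s in ids]
        reg = build_class_regressor(onsets, scores, 2.0, ser.n_volumes)
        model = train_linear_classifier(LabeledVolumeSet(ser.data.T, label_volumes(reg)))
        cosine = model.weights @ sub.pattern_valence / np.linalg.norm(model.weights)
        assert cosine > 0.95


class TestHyperplaneDistance:
    def test_on_hyperplane_zero(self):
        model = DecoderModel(weights=np.array([1.0, 1.0]), offset=-2.0)
        assert hyperplane_distance(model, np.array([1.0, 1.0])) == 0.0

    def test_linearity(self):
        model = DecoderModel(weights=np.array([2.0, -1.0]), offset=0.7)
        x = np.array([0.3, 1.2])
        a = 3.5
        assert hyperplane_distance(model, a * x) - model.offset == pytest.approx(
            a * (hyperplane_distance(model, x) - model.offset)
        )

    def test_dimension_mismatch(self):
        model = DecoderModel(weights=np.zeros(3), offset=0.0)
        with pytest.raises(ValueError, match="mismatch"):
            hyperplane_distance(model, np.zeros(4))


class TestPlatt:
    def _sample(self, rng, sep=2.0, n=400):
        h = np.concatenate([rng.normal(sep, 1, n // 2), rng.normal(-sep, 1, n // 2)])
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        return h, y

    def test_symmetric_balanced_midpoint(self):
        rng = np.random.default_rng(0)
        h, y = self._sample(rng)
        a, b = fit_platt(h, y)
        assert platt_probability(a, b, 0.0) == pytest.approx(0.5, abs=0.05)

    def test_monotone_and_confident(self):
        rng = np.random.default_rng(1)
        h, y = self._sample(rng, sep=3.0)
        a, b = fit_platt(h, y)
        grid = np.linspace(h.min(), h.max(), 50)
        p = platt_probability(a, b, grid)
        assert np.all(np.diff(p) > 0)
        assert p[-1] > 0.9

    def test_scale_invariance_of_probabilities(self):
        rng = np.random.default_rng(2)
        h, y = self._sample(rng)
        a1, b1 = fit_platt(h, y)
        a10, b10 = fit_platt(10 * h, y)
        p1 = platt_probability(a1, b1, h)
        p10 = platt_probability(a10, b10, 10 * h)
        assert np.max(np.abs(p1 - p10)) < 1e-3

    def test_constant_h_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_platt(np.ones(10), np.array([1, -1] * 5))

    def test_calibration_slope_on_heldout(self):
        # reliability-diagram slope near 1 on held-out data at n=2000
        rng = np.random.default_rng(3)
        h_fit, y_fit = self._sample(rng, sep=1.0, n=2000)
        a, b = fit_platt(h_fit, y_fit)
        h_new, y_new = self._sample(rng, sep=1.0, n=2000)
        p = platt_probability(a, b, h_new)
        bins = np.quantile(p, np.linspace(0, 1, 11))
        mids, freqs = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (p >= lo) & (p < hi)
            if sel.sum() > 20:
                mids.append(p[sel].mean())
                freqs.append((y_new[sel] > 0).mean())
        slope = np.polyfit(mids, freqs, 1)[0]
        assert 0.8 <= slope <= 1.2


class TestDecode:
    def test_uncalibrated_rejected(self):
        model = DecoderModel(weights=np.ones(2), offset=0.0)
        with pytest.raises(ValueError, match="calibrated"):
            decode(model, np.ones(2))

    def test_matches_logistic_formula(self):
        model = DecoderModel(
            weights=np.array([1.0, -1.0]), offset=0.2, platt_a=-1.7, platt_b=0.3
        )
        x = np.array([0.5, 0.1])
        h = hyperplane_distance(model, x)
        assert decode(model, x) == pytest.approx(1 / (1 + np.exp(-1.7 * h + 0.3)))

    def test_monotone_in_h(self):
        model = DecoderModel(
            weights=np.array([1.0]), offset=0.0, platt_a=-2.0, platt_b=0.0
        )
        xs = np.linspace(-3, 3, 21)[:, None]
        p = decode(model, xs)
        assert np.all(np.diff(p) > 0)


class TestBetaSeries:
    def test_recovers_planted_amplitudes(self):
        tr, n_vols = 2.0, 80
        onsets = [0.0, 30.0, 60.0, 90.0]
        amps = [1.0, -2.0, 0.5, 3.0]
        kernel = hrf_kernel(tr)
        signal = np.zeros(n_vols)
        for onset, amp in zip(onsets, amps):
            k = int(onset / tr)
            upper = min(n_vols, k + kernel.size)
            signal[k:upper] += amp * kernel[: upper - k]
        data = np.vstack([signal, 2 * signal])
        series = VolumeSeries(data=data, tr=tr)
        events = pd.DataFrame({"onset": onsets, "tag": ["a", "b", "c", "d"]})
        betas = extract_beta_series(series, events)
        assert np.allclose(betas.maps[:, 0], amps, atol=1e-6)
        assert np.allclose(betas.maps[:, 1], np.array(amps) * 2, atol=1e-6)

    def test_zero_series_zero_betas(self):
        series = VolumeSeries(data=np.zeros((3, 40)), tr=2.0)
        events = pd.DataFrame({"onset": [0.0, 20.0], "tag": ["a", "b"]})
        betas = extract_beta_series(series, events)
        assert np.allclose(betas.maps, 0)

    def test_event_order_permutes_betas(self):
        rng = np.random.default_rng(0)
        series = VolumeSeries(data=rng.normal(size=(4, 60)), tr=2.0)
        e1 = pd.DataFrame({"onset": [0.0, 30.0], "tag": ["a", "b"]})
        e2 = pd.DataFrame({"onset": [30.0, 0.0], "tag": ["b", "a"]})
        b1 = extract_beta_series(series, e1)
        b2 = extract_beta_series(series, e2)
        assert np.allclose(b1.maps[0], b2.maps[1])
        assert np.allclose(b1.maps[1], b2.maps[0])

    def test_collinear_events_named(self):
        series = VolumeSeries(data=np.zeros((2, 40)), tr=2.0)
        events = pd.DataFrame({"onset": [10.0, 10.0], "tag": ["dup1", "dup2"]})
        with pytest.raises(ValueError, match="dup1"):
            extract_beta_series(series, events)


class TestAccuracy:
    def _perfect_model(self):
        return DecoderModel(weights=np.array([1.0]), offset=0.0)

    def test_all_correct_closed_form(self):
        model = self._perfect_model()
        X = np.concatenate([np.ones((45, 1)), -np.ones((45, 1))])
        y = np.concatenate([np.ones(45), -np.ones(45)])
        acc, p = within_subject_accuracy(model, X, y)
        assert acc == 1.0
        assert p == pytest.approx(0.5**90, rel=1e-9)

    def test_tail_sum_matches_independent_computation(self):
        model = self._perfect_model()
        X = np.concatenate([np.ones((54, 1)), np.ones((36, 1))])
        y = np.concatenate([np.ones(54), -np.ones(36)])  # 54/90 correct
        acc, p = within_subject_accuracy(model, X, y)
        assert acc == pytest.approx(54 / 90)
        expected = sum(stats.binom.pmf(k, 90, 0.5) for k in range(54, 91))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_chance_not_significant(self):
        model = self._perfect_model()
        X = np.concatenate([np.ones((45, 1)), np.ones((45, 1))])
        y = np.concatenate([np.ones(45), -np.ones(45)])  # 45/90
        _, p = within_subject_accuracy(model, X, y)
        assert p > 0.05

    def test_empty_heldout_rejected(self):
        with pytest.raises(ValueError):
            within_subject_accuracy(self._perfect_model(), np.zeros((2, 1)), np.zeros(2))


class TestReliableSet:
    def test_identical_maps_always_retained(self):
        rng = np.random.default_rng(0)
        shared = rng.normal(size=30)
        betas = {}
        for s in range(3):
            maps = rng.normal(size=(4, 30))
            maps[0] = shared  # stimulus "a" identical across subjects
            betas[f"s{s}"] = BetaSeries(tags=["a", "b", "c", "d"], maps=maps)
        kept = reliable_stimulus_set(betas, fraction=0.25)
        assert kept == ["a"]

    def test_noise_ranked_low(self):
        rng = np.random.default_rng(1)
        shared = {t: rng.normal(size=50) for t in "abc"}
        betas = {}
        for s in range(4):
            maps = np.vstack(
                [shared[t] + 0.1 * rng.normal(size=50) for t in "abc"]
                + [rng.normal(size=50)]  # stimulus "d": pure noise
            )
            betas[f"s{s}"] = BetaSeries(tags=list("abcd"), maps=maps)
        kept = reliable_stimulus_set(betas, fraction=0.75)
        assert "d" not in kept and len(kept) == 3

    def test_output_size(self):
        rng = np.random.default_rng(2)
        betas = {
            f"s{s}": BetaSeries(tags=list("abcdef"), maps=rng.normal(size=(6, 20)))
            for s in range(2)
        }
        assert len(reliable_stimulus_set(betas, fraction=0.5)) == 3

    def test_single_subject_rejected(self):
        betas = {"s0": BetaSeries(tags=["a"], maps=np.ones((1, 5)))}
        with pytest.raises(ValueError):
            reliable_stimulus_set(betas)
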