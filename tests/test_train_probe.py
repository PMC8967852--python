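"""Leave-one-subject-out protocol, metrics, training and the probe."""

import numpy as np
import pytest
from scipy import signal, stats

from ictalfeat.errors import ConfigError, ParameterError
from ictalfeat.networks import ModelSpec, assemble_model
from ictalfeat.preprocess import EpochSet
from ictalfeat.train_probe import (
    compute_metrics, loo_split, make_input, narrowband_probe, pointbiserial,
    probe_filter_sos, summarize_folds, train_fold,
)


def _dummy_epochset(n_subjects=25, epochs_per_subject=4):
    n = n_subjects * epochs_per_subject
    return EpochSet(
        X=np.zeros((n, 8)),
        y=np.tile([0, 1], n // 2),
        subject_ids=np.repeat([f"S{i:03d}" for i in range(n_subjects)],
                              epochs_per_subject),
        channel_ids=np.array(["c0"] * n),
        offsets=np.zeros(n),
    )


class TestLooSplit:
    def test_subject_counts_for_25_subjects(self):
        es = _dummy_epochset(25)
        tr, va, te = loo_split(es, "S000", n_val_subjects=8, seed=0)
        count = lambda m: len(np.unique(es.subject_ids[m]))
        assert (count(tr), count(va), count(te)) == (16, 8, 1)

    def test_partitions_disjoint_by_subject(self):
        es = _dummy_epochset(12)
        tr, va, te = loo_split(es, "S003", n_val_subjects=4, seed=5)
        groups = [set(es.subject_ids[m]) for m in (tr, va, te)]
        assert groups[0] & groups[1] == set()
        assert groups[0] & groups[2] == set()
        assert groups[1] & groups[2] == set()
        assert (tr | va | te).all()

    def test_same_seed_same_split(self):
        es = _dummy_epochset(12)
        a = loo_split(es, "S003", 4, seed=9)
        b = loo_split(es, "S003", 4, seed=9)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma, mb)

    def test_too_few_subjects_rejected(self):
        es = _dummy_epochset(5)
        with pytest.raises(ConfigError):
            loo_split(es, "S000", n_val_subjects=8, seed=0)


class TestMetrics:
    def test_confusion_closed_forms(self):
        #  y: 1 1 1 0 0 0;  pred at 0.5: 1 0 1 1 0 0  -> tp=2 fn=1 fp=1 tn=2
        y = np.array([1, 1, 1, 0, 0, 0])
        p = np.array([0.9, 0.2, 0.8, 0.7, 0.1, 0.3])
        m = compute_metrics(y, p)
        assert m["ppv"] == pytest.approx(2 / 3)
        assert m["npv"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(4 / 6)
        assert m["brier"] == pytest.approx(np.mean((p - y) ** 2))

    def test_pointbiserial_matches_scipy(self, rng):
        x = rng.standard_normal(200)
        y = rng.integers(0, 2, 200)
        ours = pointbiserial(x, y)
        ref = stats.pointbiserialr(y, x).statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_pointbiserial_zero_for_constant_input(self):
        assert pointbiserial(np.ones(50), np.tile([0, 1], 25)) == 0.0


class TestTrainFold:
    def test_contract_and_early_stopping(self, rng):
        # linearly separable engineered-style features
        n = 400
        y = np.tile([0, 1], n // 2).astype(float)
        X = rng.standard_normal((n, 16)) + 3.0 * y[:, None]
        model = assemble_model(ModelSpec("emc", classifier_dropout=0.1), seed=0)
        fr = train_fold(model, (X[: n // 2], y[: n // 2]),
                        (X[n // 2:], y[n // 2:]),
                        (X[n // 2:], y[n // 2:]),
                        max_epochs=30, patience=3, seed=0)
        assert fr.epochs_trained <= 30
        assert fr.metrics["auc"] > 0.95

    def test_summary_shapes(self, fdbb_folds):
        summary = summarize_folds(fdbb_folds)
        assert set(summary) == {"auc", "brier", "ppv", "npv", "recall",
                                "accuracy"}
        mean_auc, sd_auc = summary["auc"]
        assert 0 <= mean_auc <= 1 and sd_auc >= 0

    def test_loo_one_fold_per_subject(self, fdbb_folds, epochs):
        heldouts = [fr.heldout_subject for fr in fdbb_folds]
        assert sorted(heldouts) == sorted(epochs.subjects)


class TestProbe:
    def test_filter_concentrates_power(self, rng):
        x = rng.standard_normal(400 * 100)
        sos = probe_filter_sos(50.0, 5.0, 400.0)
        xf = signal.sosfiltfilt(sos, x)
        f, p = signal.welch(xf, fs=400.0, nperseg=4096)
        inband = p[(f >= 45) & (f <= 55)].sum()
        assert inband / p.sum() >= 0.90

    def test_center_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            probe_filter_sos(250.0, 5.0, 400.0)

    @staticmethod
    def _channel_subset(epochs, n_subjects=None):
        """Whole recordings (channel 0 of each subject) keep the probe's
        per-recording normalization meaningful."""
        mask = np.char.endswith(epochs.channel_ids.astype(str), "ch0")
        if n_subjects is not None:
            keep = epochs.subjects[:n_subjects]
            mask &= np.isin(epochs.subject_ids, keep)
        return epochs.subset(mask)

    def test_grid_is_2_to_154(self, epochs, fdbb_folds):
        sub = self._channel_subset(epochs, n_subjects=2)
        res = narrowband_probe(fdbb_folds[0].model, sub)
        assert res.center_freqs[0] == 2.0
        assert res.center_freqs[-1] == 154.0
        assert len(res.center_freqs) == 77
        assert np.all(np.abs(res.output_corr) <= 1.0)
        assert res.feature_corr.shape == (77, 16)

    def test_trained_model_peak_in_gained_bands(self, epochs, fdbb_folds):
        sub = self._channel_subset(epochs)
        res = narrowband_probe(fdbb_folds[0].model, sub)
        peak = res.center_freqs[np.argmax(res.output_corr)]
        assert peak >= 12.0  # beta or gamma, the gained seizure bands

    def test_emc_features_localize_to_their_bands(self, epochs):
        from ictalfeat.spectral import ENGINEERED_FEATURE_NAMES

        model = assemble_model(ModelSpec("emc"), seed=0)
        sub = self._channel_subset(epochs, n_subjects=3)
        res = narrowband_probe(model, sub)
        expectations = {"rel_theta": (4, 8), "rel_alpha": (8, 12),
                        "rel_beta": (12, 30), "rel_low_gamma": (30, 80)}
        for feat, (lo, hi) in expectations.items():
            j = ENGINEERED_FEATURE_NAMES.index(feat)
            fmax = res.center_freqs[np.argmax(res.feature_mean[:, j])]
            assert lo - 2 <= fmax <= hi + 2, feat

    def test_make_input_arities(self, rng):
        X = rng.standard_normal((3, 400))
        assert make_input("tdbb", X).shape == (3, 400)
        assert make_input("fdbb", X).shape == (3, 200)
        assert make_input("emc", X).shape == (3, 16)
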