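"""Subject-wise leave-one-out pretraining and narrowband probing.

Training follows the pretraining protocol: Adam at learning rate 0.001,
binary cross-entropy, early stopping when the validation loss has not
improved for 10 epochs (200 epoch cap), with train/validation/test
partitions split *by subject* — all epochs of the held-out subject form
the test fold and all epochs of 8 randomly drawn other subjects form the
validation fold, so subject-level leakage is impossible by construction.

The narrowband probe characterizes what a trained model listens to: the
inputs are band-pass filtered with a biquad (2nd-order) filter of 5 Hz
bandwidth whose center steps in 2 Hz increments from 2 Hz up to (but
never reaching) 155 Hz, min-max normalized and rescaled to the amplitude
of the preictal training class, and the point-biserial correlation of the
model outputs (and of every encoded feature) with the seizure label is
recorded per frequency bin.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.metrics import brier_score_loss, roc_auc_score

from .errors import ConfigError, ParameterError, TrainingError
from .networks import ModelSpec, SeizureModel, assemble_model, encoded_feature_names
from .nnet import Adam, binary_cross_entropy
from .preprocess import EpochSet
from .spectral import engineered_feature_table, spectrum_representation

METRIC_NAMES = ("auc", "brier", "ppv", "npv", "recall", "accuracy")


@dataclass
class FoldResult:
    heldout_subject: str
    metrics: dict[str, float]
    epochs_trained: int
    model: SeizureModel


@dataclass
class ProbeResult:
    center_freqs: np.ndarray
    output_corr: np.ndarray          # (n_bins,)
    output_auc: np.ndarray           # (n_bins,)
    feature_corr: np.ndarray         # (n_bins, 16)
    feature_mean: np.ndarray         # (n_bins, 16) mean encoded response
    feature_names: list[str] = field(default_factory=list)


def compute_metrics(y_true: np.ndarray, probs: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    """AUC, Brier, PPV, NPV, recall and accuracy at the given threshold."""
    y = np.asarray(y_true).astype(int)
    p = np.asarray(probs, dtype=np.float64)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    out = {
        "auc": float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else np.nan,
        "brier": float(brier_score_loss(y, p)),
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
        "recall": tp / (tp + fn) if tp + fn else np.nan,
        "accuracy": (tp + tn) / len(y),
    }
    return out


def make_input(kind: str, X_raw: np.ndarray, fs: float = 400.0,
               strict: bool = True) -> np.ndarray:
    """Model-facing representation of raw (n, 400) epochs."""
    if kind == "tdbb":
        return np.asarray(X_raw, dtype=np.float64)
    if kind == "fdbb":
        return spectrum_representation(X_raw)
    if kind == "emc":
        return engineered_feature_table(X_raw, fs, strict=strict).to_numpy()
    raise ConfigError(f"unknown model kind: {kind!r}")


def loo_split(es: EpochSet, heldout_subject: str, n_val_subjects: int = 8,
              seed: int = 0):
    """Boolean (train, val, test) masks, partitioned by subject.

    The same seed yields the same validation draw for a given held-out
    subject, keeping folds consistent across models.
    """
    subjects = es.subjects
    if heldout_subject not in subjects:
        raise ConfigError(f"unknown subject: {heldout_subject!r}")
    others = np.array([s for s in subjects if s != heldout_subject])
    if len(others) < n_val_subjects + 1:
        raise ConfigError(
            f"need at least {n_val_subjects + 2} subjects for "
            f"{n_val_subjects} validation subjects"
        )
    rng = np.random.default_rng([seed, zlib.crc32(heldout_subject.encode())])
    val_subjects = set(rng.choice(others, size=n_val_subjects, replace=False))
    test = es.subject_ids == heldout_subject
    val = np.isin(es.subject_ids, list(val_subjects))
    train = ~test & ~val
    return train, val, test


def train_fold(model: SeizureModel, train, val, test=None, lr: float = 1e-3,
               patience: int = 10, max_epochs: int = 200, batch_size: int = 128,
               seed: int = 0, heldout_subject: str = "") -> FoldResult:
    """Train one model with early stopping on validation loss; evaluate the
    best-validation checkpoint on the held-out test fold."""
    X_tr, y_tr = train
    X_val, y_val = val
    opt = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng([seed, 3])
    best_loss = np.inf
    best_state = model.get_state()
    best_epoch = 0
    since_best = 0
    n = len(y_tr)
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least two samples
            opt.zero_grad()
            p = model.forward(X_tr[idx], training=True).ravel()
            loss, dp = binary_cross_entropy(p, y_tr[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            model.backward(dp.reshape(-1, 1))
            opt.step()
        val_loss, _ = binary_cross_entropy(model.predict(X_val), y_val)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    model.set_state(best_state)
    metrics: dict[str, float] = {"val_loss": best_loss, "best_epoch": best_epoch}
    if test is not None:
        X_te, y_te = test
        metrics.update(compute_metrics(y_te, model.predict(X_te)))
    return FoldResult(
        heldout_subject=heldout_subject, metrics=metrics,
        epochs_trained=epoch, model=model,
    )


def run_loo(es: EpochSet, kind: str, n_val_subjects: int = 8, seed: int = 0,
            representation: np.ndarray | None = None,
            **train_kw) -> list[FoldResult]:
    """Leave-one-subject-out pretraining: one FoldResult per subject.

    ``representation`` lets callers pass a precomputed model-facing input
    matrix (e.g. the engineered feature table) to avoid recomputation.
    """
    X = make_input(kind, es.X, es.sample_rate) if representation is None \
        else np.asarray(representation, dtype=np.float64)
    results = []
    for i, subject in enumerate(es.subjects):
        tr, va, te = loo_split(es, subject, n_val_subjects, seed)
        model = assemble_model(ModelSpec(kind), seed=seed * 1000 + i)
        fr = train_fold(
            model, (X[tr], es.y[tr]), (X[va], es.y[va]), (X[te], es.y[te]),
            seed=seed * 1000 + i, heldout_subject=subject, **train_kw,
        )
        results.append(fr)
    return results


def summarize_folds(results: list[FoldResult]) -> dict[str, tuple[float, float]]:
    """Mean and SD of every recorded metric across folds."""
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([r.metrics[name] for r in results if name in r.metrics])
        out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return out


def pointbiserial(x: np.ndarray, y: np.ndarray) -> float:
    """Point-biserial correlation (Pearson of a continuous variable with a
    binary label); 0 when either input is constant or non-finite."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    sx, sy = x.std(), y.std()
    if not np.isfinite(sx) or sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r if np.isfinite(r) else 0.0


def probe_filter_sos(center: float, bandwidth: float, fs: float):
    """Biquad band-pass of the given bandwidth centered at ``center`` Hz."""
    nyq = fs / 2
    if center >= nyq:
        raise ParameterError(f"probe center {center} Hz >= Nyquist {nyq} Hz")
    lo = max(center - bandwidth / 2, 0.25)
    hi = min(center + bandwidth / 2, 0.999 * nyq)
    return signal.butter(1, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _recording_groups(es: EpochSet) -> list[np.ndarray]:
    """Indices of each contiguous (subject, channel) recording, offset-sorted."""
    groups = []
    for subject in es.subjects:
        s_mask = es.subject_ids == subject
        for channel in np.unique(es.channel_ids[s_mask]):
            idx = np.flatnonzero(s_mask & (es.channel_ids == channel))
            groups.append(idx[np.argsort(es.offsets[idx])])
    return groups


def _filter_rescale(es: EpochSet, groups, sos, target_ptp: float) -> np.ndarray:
    """Band-pass each recording, min-max normalize it as a whole, and scale
    so its preictal epochs match the negative-class target amplitude.

    Normalizing per recording (not per epoch) keeps the relative amplitude
    contrast between a recording's preictal and ictal epochs, which is the
    signal the probe is designed to expose; the rescale pins the negative
    class to the amplitude the model saw in training.
    """
    n_samples = es.X.shape[1]
    out = np.empty_like(es.X)
    for idx in groups:
        sig = es.X[idx].reshape(-1)
        xf = signal.sosfiltfilt(sos, sig)
        span = xf.max() - xf.min()
        xf = (xf - xf.min()) / (span if span else 1.0) - 0.5
        eps = xf.reshape(len(idx), n_samples)
        neg = eps[es.y[idx] == 0]
        neg_ptp = np.mean(neg.max(axis=1) - neg.min(axis=1)) if len(neg) else 0.0
        scale = target_ptp / neg_ptp if neg_ptp > 0 else 1.0
        out[idx] = eps * scale
    return out


def narrowband_probe(model: SeizureModel, es: EpochSet, bandwidth: float = 5.0,
                     f_start: float = 2.0, f_step: float = 2.0,
                     f_stop: float = 155.0) -> ProbeResult:
    """Frequency-response probe of a trained model (see module docstring).

    ``f_stop`` is an inclusive bound on the grid, not a grid point: the
    default grid is 2, 4, ..., 154 Hz (77 bins).
    """
    fs = es.sample_rate
    centers = np.arange(f_start, f_stop + 1e-9, f_step)
    centers = centers[centers < fs / 2]
    neg = es.X[es.y == 0]
    if len(neg) == 0:
        raise ConfigError("probe needs preictal epochs to set the target amplitude")
    target_ptp = float(np.mean(neg.max(axis=1) - neg.min(axis=1)))
    groups = _recording_groups(es)

    names = encoded_feature_names(model.spec.kind)
    n_bins = len(centers)
    output_corr = np.zeros(n_bins)
    output_auc = np.zeros(n_bins)
    feature_corr = np.zeros((n_bins, len(names)))
    feature_mean = np.zeros((n_bins, len(names)))
    y = es.y
    for i, f in enumerate(centers):
        sos = probe_filter_sos(f, bandwidth, fs)
        Xs = _filter_rescale(es, groups, sos, target_ptp)
        rep = make_input(model.spec.kind, Xs, fs, strict=False)
        out = model.predict(rep)
        feats = model.encode(rep)
        output_corr[i] = pointbiserial(out, y)
        output_auc[i] = roc_auc_score(y, out) if len(np.unique(y)) == 2 else np.nan
        feature_mean[i] = feats.mean(axis=0)
        for j in range(feats.shape[1]):
            feature_corr[i, j] = pointbiserial(feats[:, j], y)
    return ProbeResult(
        center_freqs=centers, output_corr=output_corr, output_auc=output_auc,
        feature_corr=feature_corr, feature_mean=feature_mean, feature_names=names,
    )
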