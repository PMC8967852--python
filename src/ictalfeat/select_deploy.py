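"""48-feature ensemble, Gini-importance feature selection, and deployment.

The ensemble per epoch concatenates the 16 engineered metrics with the 16
FDBB encodings (p0..p15) and 16 TDBB encodings (z0..z15). Encoded features
of a subject's epochs may only come from the leave-one-out checkpoint that
held that subject out — a leakage guard enforces this.

Feature importance is estimated with nested cross-validation: for every
external (held-out subject) fold, a random forest (30 trees, entropy
splits, depth 5) is fitted on each internal fold of the remaining
subjects' epochs, and the per-feature Gini importances are pooled into a
distribution across all (external x internal) fits. The top/bottom of the
mean-importance ranking give the most/least significant features
(MSF/LSF).

Deployment aggregates per-channel features (fold-model averaged) for
recordings from unseen subjects and trains a per-subject random forest
with internal cross-validation for either the seizure-identification task
or the latency task (ictal epochs within the first 15 s of onset as the
positive class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import DataError, LeakageError
from .networks import SeizureModel, encoded_feature_names
from .preprocess import EpochSet, build_epochset
from .spectral import ENGINEERED_FEATURE_NAMES, engineered_feature_table
from .synthetic import Recording
from .train_probe import make_input

ENSEMBLE_FEATURE_NAMES = (
    list(ENGINEERED_FEATURE_NAMES)
    + encoded_feature_names("fdbb")
    + encoded_feature_names("tdbb")
)


def extract_ensemble(
    fold_models: dict[str, dict[str, SeizureModel]],
    es: EpochSet,
    engineered: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """48-column ensemble feature table for every epoch in ``es``.

    ``fold_models`` maps each held-out subject to its fold's trained
    models, e.g. ``{"S000": {"fdbb": m1, "tdbb": m2}, ...}``; the encoded
    features of subject s are computed exclusively by the fold that held s
    out. A ``fold`` column records the checkpoint provenance.

    Raises
    ------
    LeakageError
        If a subject in ``es`` has no matching held-out checkpoint.
    """
    if engineered is None:
        engineered = engineered_feature_table(es.X, es.sample_rate)
    engineered = engineered.reset_index(drop=True)
    n = len(es)
    p_cols = np.zeros((n, 16))
    z_cols = np.zeros((n, 16))
    fold_of = np.empty(n, dtype=object)
    for subject in es.subjects:
        if subject not in fold_models:
            raise LeakageError(
                f"no held-out checkpoint for subject {subject!r}; refusing to "
                "encode its epochs with a model that may have trained on them"
            )
        mask = es.subject_ids == subject
        models = fold_models[subject]
        if "fdbb" in models:
            rep = make_input("fdbb", es.X[mask], es.sample_rate)
            p_cols[mask] = models["fdbb"].encode(rep)
        if "tdbb" in models:
            z_cols[mask] = models["tdbb"].encode(es.X[mask])
        fold_of[mask] = subject
    df = pd.concat(
        [
            engineered,
            pd.DataFrame(p_cols, columns=encoded_feature_names("fdbb")),
            pd.DataFrame(z_cols, columns=encoded_feature_names("tdbb")),
        ],
        axis=1,
    )
    df["fold"] = fold_of
    return df


def rfc_fit(features, labels, n_estimators: int = 30, criterion: str = "entropy",
            max_depth: int = 5, seed: int = 0) -> RandomForestClassifier:
    """Fit the interpretable random forest (30 trees, entropy, depth 5)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise DataError("labels contain a single class; cannot fit a forest")
    rfc = RandomForestClassifier(
        n_estimators=n_estimators, criterion=criterion, max_depth=max_depth,
        random_state=seed,
    )
    rfc.fit(np.asarray(features, dtype=np.float64), y)
    return rfc


@dataclass
class ImportanceTable:
    """Distribution of Gini importances across nested-CV fits."""

    draws: pd.DataFrame  # one row per (external x internal) fit, one col per feature

    def summary(self) -> pd.DataFrame:
        s = pd.DataFrame({
            "mean": self.draws.mean(axis=0),
            "sd": self.draws.std(axis=0),
        })
        # deterministic tie-break: mean importance, then feature name
        order = s.sort_values(["mean"], ascending=False, kind="stable")
        order = order.loc[
            sorted(order.index, key=lambda n: (-order.loc[n, "mean"], n))
        ]
        order["rank"] = np.arange(1, len(order) + 1)
        return order

    def msf(self, k: int = 1) -> list[str]:
        """The k most significant features by mean Gini importance."""
        return list(self.summary().index[:k])

    def lsf(self, k: int = 1) -> list[str]:
        """The k least significant features."""
        return list(self.summary().index[-k:][::-1])


def nested_importances(
    features: pd.DataFrame,
    labels: np.ndarray,
    subjects: np.ndarray,
    internal_folds: int = 100,
    seed: int = 0,
    **rfc_kw,
) -> ImportanceTable:
    """Gini-importance distribution from (external LOO x internal CV) fits.

    ``internal_folds`` is capped at the number of available samples within
    each external fold (the documented scaling knob for small datasets).
    """
    feat_cols = [c for c in features.columns if c != "fold"]
    X_all = features[feat_cols].to_numpy(dtype=np.float64)
    y_all = np.asarray(labels).astype(int)
    subjects = np.asarray(subjects)
    rows = []
    for ext_i, heldout in enumerate(np.unique(subjects)):
        keep = subjects != heldout
        X, y = X_all[keep], y_all[keep]
        k = int(min(internal_folds, len(y)))
        if k < 2:
            raise DataError("not enough samples for internal cross validation")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed + ext_i)
        for int_i, (tr, _) in enumerate(splitter.split(X)):
            if len(np.unique(y[tr])) < 2:
                continue
            rfc = rfc_fit(X[tr], y[tr], seed=seed * 10000 + ext_i * 100 + int_i,
                          **rfc_kw)
            rows.append(rfc.feature_importances_)
    return ImportanceTable(draws=pd.DataFrame(rows, columns=feat_cols))


def correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all feature pairs; zero-variance
    features yield missing (NaN) entries rather than zeros."""
    feat_cols = [c for c in features.columns if c != "fold"]
    return features[feat_cols].corr(method="pearson")


def latency_labels(offsets: np.ndarray, window: float = 15.0) -> np.ndarray:
    """Positive class: ictal epochs within the first ``window`` s of onset."""
    off = np.asarray(offsets, dtype=np.float64)
    return ((off >= 0) & (off < window)).astype(int)


def _fold_averaged_features(
    fold_models: list[dict[str, SeizureModel]], es: EpochSet
) -> pd.DataFrame:
    """Ensemble features with encodings averaged over all fold checkpoints
    (the deployment scheme for unseen subjects)."""
    engineered = engineered_feature_table(es.X, es.sample_rate)
    p_stack, z_stack = [], []
    for models in fold_models:
        if "fdbb" in models:
            rep = make_input("fdbb", es.X, es.sample_rate)
            p_stack.append(models["fdbb"].encode(rep))
        if "tdbb" in models:
            z_stack.append(models["tdbb"].encode(es.X))
    parts = [engineered.reset_index(drop=True)]
    if p_stack:
        parts.append(pd.DataFrame(np.mean(p_stack, axis=0),
                                  columns=encoded_feature_names("fdbb")))
    if z_stack:
        parts.append(pd.DataFrame(np.mean(z_stack, axis=0),
                                  columns=encoded_feature_names("tdbb")))
    return pd.concat(parts, axis=1)


def deploy(
    recordings: list[Recording],
    fold_models: list[dict[str, SeizureModel]],
    feature_subset: list[str] | None = None,
    task: str = "identification",
    overlap: float = 0.0,
    channel_mode: str = "concat",
    internal_folds: int = 5,
    seed: int = 0,
    **rfc_kw,
) -> pd.DataFrame:
    """Per-epoch seizure probabilities for unseen-subject recordings.

    Features are extracted per channel, averaged over all fold
    checkpoints, aggregated across channels (``concat`` when the channel
    count is fixed within a subject, ``mean`` otherwise), and classified
    by a per-subject random forest with ``internal_folds``-fold internal
    cross-validation. ``task`` is 'identification' (preictal vs ictal) or
    'latency' (first 15 s of the seizure vs everything else).
    """
    if task not in ("identification", "latency"):
        raise DataError(f"unknown task: {task!r}")
    results = []
    by_subject: dict[str, list[Recording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    for subject, recs in by_subject.items():
        per_channel = []
        meta = None
        for rec in recs:
            es = build_epochset([rec], overlap=overlap)
            feats = _fold_averaged_features(fold_models, es)
            if feature_subset is not None:
                feats = feats[list(feature_subset)]
            per_channel.append(feats)
            if meta is None:
                meta = es
        if channel_mode == "concat":
            X = pd.concat(
                [f.add_suffix(f"@ch{i}") for i, f in enumerate(per_channel)],
                axis=1,
            )
        elif channel_mode == "mean":
            X = sum(per_channel[1:], per_channel[0].copy()) / len(per_channel)
        else:
            raise DataError(f"unknown channel_mode: {channel_mode!r}")
        y = meta.y if task == "identification" else latency_labels(meta.offsets)
        probs = np.zeros(len(y))
        splitter = StratifiedKFold(n_splits=internal_folds, shuffle=True,
                                   random_state=seed)
        Xv = X.to_numpy(dtype=np.float64)
        for tr, te in splitter.split(Xv, y):
            rfc = rfc_fit(Xv[tr], y[tr], seed=seed, **rfc_kw)
            probs[te] = rfc.predict_proba(Xv[te])[:, 1]
        results.append(pd.DataFrame({
            "subject_id": subject,
            "offset": meta.offsets,
            "label": y,
            "probability": probs,
        }))
    return pd.concat(results, ignore_index=True)
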