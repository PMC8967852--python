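"""The three seizure-detection networks with exact shape contracts.

* TDBB (time-domain black box): a 1-D convolutional encoder acting as a
  bank of trainable discrete filters on the raw 400-sample epoch. Twelve
  convolutions (kernels shrinking 27 -> 8, "same"-style padding k = 2p+1),
  interleaved batch-norm rows and five max-pooling stages (kernel 6,
  stride 2 — the unique stride-2 geometry giving the intermediate lengths
  400 -> 198 -> 97 -> 46 -> 21 -> 8 -> 1) ending in 16 features z0..z15.
* FDBB (frequency-domain black box): a dense encoder on the 200-bin
  one-sided FFT magnitude spectrum (DC dropped), 200 -> 100 -> 50 -> 16
  with leaky ReLU and 75% dropout, producing p0..p15.
* EMC (engineered-metrics classifier): the shared classifier alone,
  consuming the 16 engineered features.

All three share the same classifier subnetwork: dense
16 -> 14 -> 12 -> 10 -> 8 -> 6 -> 4 -> 2 -> 1, leaky ReLU through width 4,
sigmoid on the last two layers, batch-norm + dropout on the input row and
after the width-8 layer. Classifier dropout is 0.90 (TDBB), 0.75 (FDBB),
0.40 (EMC).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from . import nnet
from .errors import ShapeError
from .nnet import (
    BatchNorm, Conv1d, Dense, Dropout, Flatten, LeakyReLU, MaxPool1d, ReLU,
    Sequential, Sigmoid,
)

KINDS = ("tdbb", "fdbb", "emc")
DEFAULT_CLASSIFIER_DROPOUT = {"tdbb": 0.90, "fdbb": 0.75, "emc": 0.40}
INPUT_ARITY = {"tdbb": 400, "fdbb": 200, "emc": 16}
N_ENCODED_FEATURES = 16

#: conv rows of the TDBB encoder: (c_in, c_out, kernel, padding)
_TDBB_CONVS = [
    (1, 2, 27, 13), (2, 4, 27, 13),
    (4, 5, 13, 6), (5, 7, 13, 6),
    (7, 9, 7, 3), (9, 10, 7, 3), (10, 11, 7, 3),
    (11, 12, 5, 2), (12, 13, 5, 2), (13, 14, 5, 2),
    (14, 15, 3, 1),
    (15, 16, 8, 0),
]


@dataclass(frozen=True)
class ModelSpec:
    """Which network to build and with what classifier dropout."""

    kind: str
    classifier_dropout: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ShapeError(f"unknown model kind: {self.kind!r}")
        d = self.dropout
        if not 0 <= d < 1:
            raise ShapeError("classifier_dropout must be in [0, 1)")

    @property
    def dropout(self) -> float:
        if self.classifier_dropout is None:
            return DEFAULT_CLASSIFIER_DROPOUT[self.kind]
        return self.classifier_dropout

    @property
    def input_arity(self) -> int:
        return INPUT_ARITY[self.kind]


def build_tdbb_encoder(rng: np.random.Generator) -> Sequential:
    """Convolutional encoder: (N, 1, 400) -> (N, 16) after flattening."""
    layers: list[nnet.Layer] = []
    bn_after = {1: 4, 3: 7, 6: 11, 9: 14, 10: 15}  # conv index -> BN width
    pool_after = {1, 3, 6, 9, 10}
    for i, (ci, co, k, p) in enumerate(_TDBB_CONVS):
        layers.append(Conv1d(ci, co, k, p, rng))
        layers.append(ReLU())
        if i in bn_after:
            layers.append(BatchNorm(bn_after[i], conv=True))
        if i in pool_after:
            layers.append(MaxPool1d(kernel=6, stride=2))
    layers.append(Flatten())
    return Sequential(layers)


def build_fdbb_encoder(rng: np.random.Generator,
                       dropout_rng: np.random.Generator) -> Sequential:
    """Dense spectral encoder: (N, 200) -> (N, 16)."""
    d = 0.75
    return Sequential([
        BatchNorm(200), Dropout(d, dropout_rng),
        Dense(200, 100, rng), LeakyReLU(), Dropout(d, dropout_rng),
        Dense(100, 50, rng), LeakyReLU(), Dropout(d, dropout_rng),
        Dense(50, 16, rng), LeakyReLU(),
    ])


def build_classifier(dropout: float, rng: np.random.Generator,
                     dropout_rng: np.random.Generator) -> Sequential:
    """Shared classifier subnetwork: (N, 16) -> (N, 1) probability."""
    return Sequential([
        BatchNorm(16), Dropout(dropout, dropout_rng),
        Dense(16, 14, rng), LeakyReLU(),
        Dense(14, 12, rng), LeakyReLU(),
        Dense(12, 10, rng), LeakyReLU(),
        Dense(10, 8, rng), LeakyReLU(), BatchNorm(8), Dropout(dropout, dropout_rng),
        Dense(8, 6, rng), LeakyReLU(),
        Dense(6, 4, rng), LeakyReLU(),
        Dense(4, 2, rng), Sigmoid(),
        Dense(2, 1, rng), Sigmoid(),
    ])


class SeizureModel:
    """Encoder + classifier pair (or classifier alone for the EMC)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng([seed, 1])
        drop_rng = np.random.default_rng([seed, 2])
        if spec.kind == "tdbb":
            self.encoder = build_tdbb_encoder(rng)
        elif spec.kind == "fdbb":
            self.encoder = build_fdbb_encoder(rng, drop_rng)
        else:
            self.encoder = None
        self.classifier = build_classifier(spec.dropout, rng, drop_rng)

    # -- plumbing ---------------------------------------------------------

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.spec.input_arity:
            raise ShapeError(
                f"{self.spec.kind} expects {self.spec.input_arity} inputs, "
                f"got {X.shape[1]}"
            )
        if self.spec.kind == "tdbb":
            return X[:, None, :]
        return X

    def parameters(self) -> list[nnet.Param]:
        params = [] if self.encoder is None else self.encoder.params()
        return params + self.classifier.params()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Full forward pass; returns (N, 1) probabilities."""
        z = self._prep(X)
        if self.encoder is not None:
            z = self.encoder.forward(z, training=training)
        return self.classifier.forward(z, training=training)

    def backward(self, grad: np.ndarray) -> None:
        g = self.classifier.backward(grad)
        if self.encoder is not None:
            self.encoder.backward(g)

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Encoder output (N, 16) in evaluation mode; for the EMC the input
        features are the encoding."""
        z = self._prep(X)
        if self.encoder is None:
            return np.asarray(z, dtype=np.float64)
        return self.encoder.forward(z, training=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Seizure probabilities (N,) in evaluation mode (deterministic)."""
        return self.forward(X, training=False).ravel()

    # -- checkpointing ----------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        nets = [n for n in (self.encoder, self.classifier) if n is not None]
        return [p.value.copy() for n in nets for p in n.params()] + [
            a for n in nets for a in n.state_arrays()
        ]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        nets = [n for n in (self.encoder, self.classifier) if n is not None]
        params = [p for n in nets for p in n.params()]
        for p, a in zip(params, arrays[: len(params)]):
            p.value = a.copy()
        rest = arrays[len(params):]
        i = 0
        for n in nets:
            k = len(n.state_arrays())
            n.set_state_arrays(rest[i : i + k])
            i += k

    def save(self, path) -> None:
        """Single-file checkpoint: arrays plus an embedded spec header."""
        state = self.get_state()
        header = json.dumps(
            {"kind": self.spec.kind, "classifier_dropout": self.spec.dropout}
        )
        arrays = {f"arr_{i}": a for i, a in enumerate(state)}
        buf = io.BytesIO()
        np.savez(buf, spec=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path, seed: int = 0) -> "SeizureModel":
        with np.load(path) as data:
            header = json.loads(bytes(data["spec"]).decode())
            n_arr = len([k for k in data.files if k.startswith("arr_")])
            state = [data[f"arr_{i}"] for i in range(n_arr)]
        spec = ModelSpec(header["kind"], header["classifier_dropout"])
        model = cls(spec, seed=seed)
        model.set_state(state)
        return model


def assemble_model(spec: ModelSpec, seed: int = 0) -> SeizureModel:
    return SeizureModel(spec, seed=seed)


def encoded_feature_names(kind: str) -> list[str]:
    """z0..z15 for the TDBB, p0..p15 for the FDBB, engineered names for EMC."""
    if kind == "tdbb":
        return [f"z{i}" for i in range(N_ENCODED_FEATURES)]
    if kind == "fdbb":
        return [f"p{i}" for i in range(N_ENCODED_FEATURES)]
    from .spectral import ENGINEERED_FEATURE_NAMES

    return list(ENGINEERED_FEATURE_NAMES)
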