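"""The convolutional architecture: forward pass, loss and gradients.

One convolutional layer of F motif detectors (width w, d input channels,
ReLU, zero-padded so the response keeps the input length L), two parallel
global pooling layers (average and maximum of each detector's response),
their concatenation into a 2F-vector, one ReLU hidden layer of H units,
and K = 4 independent sigmoid output units, one per compartment. The
predicted compartment is the argmax of the output scores (ties go to the
first class in the fixed order). Training minimises the cumulative
binary cross-entropy: the sum over classes of the per-class binary
cross-entropy, averaged over the batch.

The network is small and fixed, so the implementation is plain numpy
with analytic gradients (validated against central finite differences in
the test suite); no deep-learning framework is required.

Shape conventions: feature matrices are L x d (rows = positions); the
convolution response C is F x L as is conventional for motif scans.
"""
from __future__ import annotations

import io
import json
import os
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from .encoding import FEATURE_SETS, FeatureMatrix
from .records import COMPARTMENTS

#: Clip applied to output scores inside the loss only, to keep logs finite.
LOSS_EPS = 1e-7

SERIAL_FORMAT_VERSION = 1


@dataclass
class Hyperparameters:
    """Architecture and optimisation settings.

    F : number of convolutional motif detectors.
    w : motif width in residues (odd, so zero-padding of w//2 per side
        keeps the response length equal to the sequence length).
    H : hidden-layer width.
    learning_rate, batch_size, max_epochs, patience : plain-SGD settings;
        early stopping restores the weights of the best validation epoch.
    seed : seeds weight initialisation and batch shuffling.
    """

    F: int
    w: int
    H: int
    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.F, self.w, self.H) < 1:
            raise ValueError("F, w and H must all be >= 1")
        if self.w % 2 == 0:
            raise ValueError(f"motif width w must be odd, got {self.w}")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid optimisation settings")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")

    @property
    def parameter_key(self) -> tuple[int, int, int]:
        return (self.F, self.w, self.H)


@dataclass
class CNNModel:
    """All learnable parameters of the architecture.

    motifs : F x w x d detector weights; conv_bias : F.
    hidden_weights : 2F x H with hidden_bias : H.
    output_weights : H x K with output_bias : K.
    """

    motifs: np.ndarray
    conv_bias: np.ndarray
    hidden_weights: np.ndarray
    hidden_bias: np.ndarray
    output_weights: np.ndarray
    output_bias: np.ndarray
    class_order: tuple[str, ...] = COMPARTMENTS
    feature_set: str = "PSSM+PROP"
    hyperparameters: Hyperparameters | None = None

    PARAM_NAMES = (
        "motifs", "conv_bias", "hidden_weights", "hidden_bias",
        "output_weights", "output_bias",
    )

    def __post_init__(self) -> None:
        F, w, d = self.motifs.shape
        K = len(self.class_order)
        expected = {
            "conv_bias": (F,),
            "hidden_weights": (2 * F, self.hidden_weights.shape[1]),
            "hidden_bias": (self.hidden_weights.shape[1],),
            "output_weights": (self.hidden_weights.shape[1], K),
            "output_bias": (K,),
        }
        for name, shape in expected.items():
            if getattr(self, name).shape != shape:
                raise ValueError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )

    # -- introspection -------------------------------------------------
    @property
    def F(self) -> int:
        return self.motifs.shape[0]

    @property
    def w(self) -> int:
        return self.motifs.shape[1]

    @property
    def d(self) -> int:
        return self.motifs.shape[2]

    @property
    def H(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def K(self) -> int:
        return len(self.class_order)

    def num_parameters(self) -> int:
        """Total learnable parameter count over all six arrays."""
        return sum(getattr(self, n).size for n in self.PARAM_NAMES)

    def parameters(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in self.PARAM_NAMES}

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n).copy() for n in self.PARAM_NAMES}

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for n in self.PARAM_NAMES:
            getattr(self, n)[...] = params[n]

    # -- construction --------------------------------------------------
    @classmethod
    def initialize(
        cls,
        hp: Hyperparameters,
        d: int,
        class_order: tuple[str, ...] = COMPARTMENTS,
        feature_set: str = "PSSM+PROP",
    ) -> "CNNModel":
        """Random initialisation: weights uniform in ±sqrt(1/fan_in), biases zero."""
        rng = np.random.default_rng(hp.seed)
        K = len(class_order)

        def uniform(shape, fan_in):
            a = np.sqrt(1.0 / fan_in)
            return rng.uniform(-a, a, size=shape)

        return cls(
            motifs=uniform((hp.F, hp.w, d), hp.w * d),
            conv_bias=np.zeros(hp.F),
            hidden_weights=uniform((2 * hp.F, hp.H), 2 * hp.F),
            hidden_bias=np.zeros(hp.H),
            output_weights=uniform((hp.H, K), hp.H),
            output_bias=np.zeros(K),
            class_order=tuple(class_order),
            feature_set=feature_set,
            hyperparameters=hp,
        )

    # -- serialization -------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Write a single-archive snapshot (weights + JSON header).

        The archive is a zip of raw ``.npy`` members plus ``header.json``
        written with fixed timestamps, so identical models serialize to
        identical bytes.
        """
        header = {
            "format_version": SERIAL_FORMAT_VERSION,
            "class_order": list(self.class_order),
            "feature_set": self.feature_set,
            "hyperparameters": asdict(self.hyperparameters)
            if self.hyperparameters is not None
            else None,
        }
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            info = zipfile.ZipInfo("header.json", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, json.dumps(header, sort_keys=True, indent=1))
            for name in self.PARAM_NAMES:
                buf = io.BytesIO()
                np.save(buf, getattr(self, name))
                info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CNNModel":
        try:
            with zipfile.ZipFile(path) as zf:
                header = json.loads(zf.read("header.json"))
                arrays = {}
                for name in cls.PARAM_NAMES:
                    arrays[name] = np.load(io.BytesIO(zf.read(f"{name}.npy")))
        except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"malformed model archive {path}: {exc}") from exc
        hp = header.get("hyperparameters")
        return cls(
            **arrays,
            class_order=tuple(header["class_order"]),
            feature_set=header["feature_set"],
            hyperparameters=Hyperparameters(**hp) if hp else None,
        )


@dataclass
class PredictionResult:
    """Per-class scores in (0,1) and the argmax compartment."""

    scores: np.ndarray
    predicted: str
    class_order: tuple[str, ...] = COMPARTMENTS

    def score_dict(self) -> dict[str, float]:
        return {c: float(s) for c, s in zip(self.class_order, self.scores)}


def _as_matrix(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def convolve(X: FeatureMatrix | np.ndarray, model: CNNModel) -> np.ndarray:
    """ReLU motif-detector response, F x L (length preserved by zero-padding)."""
    C, _, _ = _convolve_cached(_as_matrix(X), model)
    return C


def _convolve_cached(X: np.ndarray, model: CNNModel):
    """Convolution returning (C, pre-activation Z (L x F), padded input)."""
    L, d = X.shape
    if d != model.d:
        raise ValueError(f"input has {d} channels, model expects {model.d}")
    w = model.w
    half = w // 2
    Xpad = np.zeros((L + 2 * half, d))
    Xpad[half : half + L] = X
    Z = np.tile(model.conv_bias, (L, 1))  # L x F
    for k in range(w):
        Z += Xpad[k : k + L] @ model.motifs[:, k, :].T
    C = np.maximum(Z, 0.0).T  # F x L
    return C, Z, Xpad


def global_avg_pool(C: np.ndarray) -> np.ndarray:
    """Row-wise mean of the F x L response: the average motif signal."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] < 1:
        raise ValueError("pooling requires an F x L matrix with L >= 1")
    return C.mean(axis=1)


def global_max_pool(C: np.ndarray) -> np.ndarray:
    """Row-wise maximum of the F x L response: the peak motif signal."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] < 1:
        raise ValueError("pooling requires an F x L matrix with L >= 1")
    return C.max(axis=1)


def local_pool(C: np.ndarray, p: int, func=np.max) -> np.ndarray:
    """Local pooling utility: aggregate p non-overlapping columns at a time.

    Returns an F x floor(L/p) matrix; a trailing remainder of fewer than
    p columns is dropped. Not used by the classifier (which pools
    globally) but provided as the general primitive.
    """
    C = np.asarray(C, dtype=float)
    F, L = C.shape
    if p < 1 or p > L:
        raise ValueError("pool size must be in [1, L]")
    nblocks = L // p
    blocks = C[:, : nblocks * p].reshape(F, nblocks, p)
    return func(blocks, axis=2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _forward_cache(X: np.ndarray, model: CNNModel) -> dict:
    C, Z, Xpad = _convolve_cached(X, model)
    avg = C.mean(axis=1)
    argmax = C.argmax(axis=1)  # first max per detector: deterministic
    mx = C[np.arange(model.F), argmax]
    v = np.concatenate([avg, mx])
    zh = v @ model.hidden_weights + model.hidden_bias
    h = np.maximum(zh, 0.0)
    o = _sigmoid(h @ model.output_weights + model.output_bias)
    return {
        "Z": Z, "Xpad": Xpad, "C": C, "argmax": argmax,
        "v": v, "zh": zh, "h": h, "o": o, "L": X.shape[0],
    }


def forward(X: FeatureMatrix | np.ndarray, model: CNNModel) -> PredictionResult:
    """Full forward pass; predicted class is the (first) argmax score."""
    cache = _forward_cache(_as_matrix(X), model)
    o = cache["o"]
    return PredictionResult(
        scores=o,
        predicted=model.class_order[int(np.argmax(o))],
        class_order=model.class_order,
    )


def _validate_target(y: np.ndarray, K: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (K,) or not set(np.unique(y)) <= {0.0, 1.0} or y.sum() != 1.0:
        raise ValueError(f"target must be a one-hot {K}-vector, got {y!r}")
    return y


def loss(batch: list[tuple], model: CNNModel) -> float:
    """Cumulative binary cross-entropy of a batch.

    Sum over the K classes of the per-class binary cross-entropy,
    averaged over the N batch items. Scores are clipped to
    [eps, 1 - eps] so the value is always finite.
    """
    value, _ = loss_and_gradients(batch, model, compute_gradients=False)
    return value


def loss_and_gradients(
    batch: list[tuple], model: CNNModel, compute_gradients: bool = True
) -> tuple[float, dict[str, np.ndarray] | None]:
    """Batch loss and, optionally, analytic gradients for every parameter.

    Backpropagation notes: the derivative of the clipped cross-entropy
    through the sigmoid output is (o - y)/N in the unclipped regime; max
    pooling routes its gradient to the first maximal column of each
    detector's response; average pooling spreads 1/L to every column.
    """
    if not batch:
        raise ValueError("empty batch")
    N = len(batch)
    K = model.K
    total = 0.0
    grads = (
        {n: np.zeros_like(getattr(model, n)) for n in model.PARAM_NAMES}
        if compute_gradients
        else None
    )
    for X, y in batch:
        X = _as_matrix(X)
        y = _validate_target(y, K)
        cache = _forward_cache(X, model)
        o = np.clip(cache["o"], LOSS_EPS, 1.0 - LOSS_EPS)
        total += -np.sum(y * np.log(o) + (1.0 - y) * np.log(1.0 - o)) / N
        if not compute_gradients:
            continue
        # Output layer: d(loss)/d(pre-sigmoid) = (o - y)/N.
        delta_o = (cache["o"] - y) / N
        grads["output_weights"] += np.outer(cache["h"], delta_o)
        grads["output_bias"] += delta_o
        dh = model.output_weights @ delta_o
        dzh = dh * (cache["zh"] > 0)
        grads["hidden_weights"] += np.outer(cache["v"], dzh)
        grads["hidden_bias"] += dzh
        dv = model.hidden_weights @ dzh
        F, L = model.F, cache["L"]
        dC = np.tile(dv[:F, None] / L, (1, L))  # avg-pool branch
        dC[np.arange(F), cache["argmax"]] += dv[F:]  # max-pool branch
        dZ = dC.T * (cache["Z"] > 0)  # L x F
        Xpad = cache["Xpad"]
        for k in range(model.w):
            grads["motifs"][:, k, :] += dZ.T @ Xpad[k : k + L]
        grads["conv_bias"] += dZ.sum(axis=0)
    return float(total), grads
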