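"""Deep autoencoder with a feature-weighted binary cross-entropy loss.

The model is a symmetric seven-hidden-layer funnel: three ReLU encoder
layers, a low-dimensional ReLU bottleneck, three ReLU decoder layers, and a
sigmoid output of the same width as the input, so each output dimension is the
reconstruction probability of one binary feature.

Multi-hot claim encodings are extremely sparse, and a plain BCE objective lets
the network collapse to predicting all zeros: with so few ones per vector, the
all-zeros reconstruction already achieves a small loss.  The feature-weighted
BCE (fwBCE) loss counters this by down-weighting the zero-target terms with a
factor ``w`` in (0, 1]:

    fwBCE = -(1/N) * sum_i sum_j [ y_ij * log(p_ij) + w * (1 - y_ij) * log(1 - p_ij) ]

where N is the batch size, y the binary targets and p the sigmoid outputs.
Note the normalization divides by N only, not by N*M — the per-sample loss is
a *sum* over the M feature dimensions, unlike the per-element mean most
frameworks default to.  At ``w = 1`` fwBCE reduces exactly to BCE.  The closer
``w`` is to 0, the less false positives (ones predicted where the target is
zero) influence the loss.

Everything here is plain NumPy: forward pass, analytic backpropagation of the
fwBCE objective, Adam updates, and early stopping on a validation split.  The
analytic gradients are validated against central finite differences in the
test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .feature_encoding import EncodedClaim, EncoderSpec

logger = logging.getLogger(__name__)


class ModelConfigError(ValueError):
    """Architecture or loss configuration violates a structural constraint."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class AutoencoderArchitecture:
    """Symmetric funnel architecture: 3 encoder layers, bottleneck, 3 mirrored
    decoder layers, sigmoid output at input width."""

    input_dim: int
    encoder_widths: tuple[int, int, int] = (2048, 1024, 512)
    bottleneck_dim: int = 128
    decoder_widths: tuple[int, int, int] = (512, 1024, 2048)

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ModelConfigError("input_dim must be positive")
        if any(w < 1 for w in self.encoder_widths) or self.bottleneck_dim < 1:
            raise ModelConfigError("layer widths must be strictly positive")
        if tuple(reversed(self.decoder_widths)) != tuple(self.encoder_widths):
            raise ModelConfigError(
                f"decoder widths {self.decoder_widths} must mirror "
                f"encoder widths {self.encoder_widths}"
            )
        if self.bottleneck_dim >= min(self.encoder_widths):
            raise ModelConfigError("bottleneck must be narrower than every encoder layer")

    @property
    def layer_widths(self) -> tuple[int, ...]:
        """All layer output widths from first encoder layer to output."""
        return (*self.encoder_widths, self.bottleneck_dim, *self.decoder_widths, self.input_dim)

    @classmethod
    def for_input_dim(cls, input_dim: int, bottleneck_dim: int | None = None) -> "AutoencoderArchitecture":
        """Geometric-taper default: the first layer is the largest power of two
        not exceeding half the input, halved twice more; the bottleneck is 128
        capped at half the innermost encoder layer (floor 8).  Reproduces
        (2048, 1024, 512)/128 at input width 4835."""
        w1 = 2 ** int(np.floor(np.log2(max(input_dim, 4) / 2)))
        widths = (w1, w1 // 2, w1 // 4)
        if bottleneck_dim is None:
            bottleneck_dim = max(min(128, widths[2] // 2), 2)
        return cls(
            input_dim=input_dim,
            encoder_widths=widths,
            bottleneck_dim=bottleneck_dim,
            decoder_widths=tuple(reversed(widths)),
        )


@dataclass(frozen=True)
class LossConfig:
    """fwBCE configuration: zero-target weight ``w`` in (0, 1] and the clip
    epsilon keeping probabilities away from {0, 1} inside the logs."""

    w: float = 0.05
    probability_clip: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 < self.w <= 1.0:
            raise ModelConfigError(f"w must lie in (0, 1], got {self.w}")
        if not 0.0 < self.probability_clip < 0.5:
            raise ModelConfigError("probability_clip must lie in (0, 0.5)")


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 256
    epochs: int = 30
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ModelConfigError("batch_size must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ModelConfigError("validation_fraction must lie in [0, 1)")


def _check_shapes(targets: np.ndarray, probabilities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    p = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    if t.shape != p.shape:
        raise ModelConfigError(f"targets shape {t.shape} != probabilities shape {p.shape}")
    return t, p


def fwbce_loss(
    targets: np.ndarray, probabilities: np.ndarray, cfg: LossConfig = LossConfig()
) -> float:
    """Feature-weighted BCE, normalized by batch size only (sum over features)."""
    y, p = _check_shapes(targets, probabilities)
    eps = cfg.probability_clip
    p = np.clip(p, eps, 1.0 - eps)
    per_elem = y * np.log(p) + cfg.w * (1.0 - y) * np.log(1.0 - p)
    return float(-per_elem.sum() / y.shape[0])


def bce_loss(targets: np.ndarray, probabilities: np.ndarray, probability_clip: float = 1e-7) -> float:
    """Standard BCE; identical to fwBCE at w = 1."""
    return fwbce_loss(targets, probabilities, LossConfig(w=1.0, probability_clip=probability_clip))


@dataclass
class Autoencoder:
    """Fully connected autoencoder with ReLU hidden layers and sigmoid output.

    ``weights[k]`` has shape (fan_in, fan_out); layer k computes
    ``a_k = act(a_{k-1} @ W_k + b_k)``.
    """

    architecture: AutoencoderArchitecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, X: np.ndarray, return_cache: bool = False):
        """Forward pass; activations are ReLU except the final sigmoid."""
        A = np.asarray(X, dtype=np.float64)
        if A.ndim == 1:
            A = A[None, :]
        if A.shape[1] != self.architecture.input_dim:
            raise ModelConfigError(
                f"input width {A.shape[1]} != model input_dim {self.architecture.input_dim}"
            )
        cache = [A]
        for k in range(self.n_layers):
            Z = A @ self.weights[k] + self.biases[k]
            if k == self.n_layers - 1:
                A = _sigmoid(Z)
            else:
                A = np.maximum(Z, 0.0)
            cache.append(A)
        return (A, cache) if return_cache else A

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Activations at the bottleneck layer (layer index 3)."""
        A = np.atleast_2d(np.asarray(X, dtype=np.float64))
        for k in range(4):  # 3 encoder layers + bottleneck
            A = np.maximum(A @ self.weights[k] + self.biases[k], 0.0)
        return A

    def copy_parameters(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_autoencoder(arch: AutoencoderArchitecture, seed: int = 0) -> Autoencoder:
    """He-initialized model; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    widths = (arch.input_dim, *arch.layer_widths)
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return Autoencoder(architecture=arch, weights=weights, biases=biases)


def loss_and_gradients(
    model: Autoencoder, X: np.ndarray, cfg: LossConfig
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """fwBCE loss on batch X (targets == inputs) and its analytic gradients.

    Output-layer gradient: with p = sigmoid(z) and the N-normalized fwBCE,
    dL/dz = (w * (1 - y) * p - y * (1 - p)) / N, which backpropagates through
    the ReLU stack in the usual way.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    probs, cache = model.forward(X, return_cache=True)
    loss = fwbce_loss(X, probs, cfg)
    if not np.isfinite(loss):
        raise TrainingError("non-finite loss")

    grad_w = [np.empty_like(w) for w in model.weights]
    grad_b = [np.empty_like(b) for b in model.biases]
    # clip-aware delta: zero gradient where the probability was clipped
    eps = cfg.probability_clip
    p = cache[-1]
    inside = (p > eps) & (p < 1.0 - eps)
    delta = (cfg.w * (1.0 - X) * p - X * (1.0 - p)) * inside / n
    for k in range(model.n_layers - 1, -1, -1):
        grad_w[k] = cache[k].T @ delta
        grad_b[k] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ model.weights[k].T) * (cache[k] > 0.0)
    return loss, grad_w, grad_b


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")


def train_autoencoder(
    model: Autoencoder,
    encoded_train: "np.ndarray | Sequence[EncodedClaim]",
    loss_cfg: LossConfig = LossConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
) -> TrainingHistory:
    """Train in place with Adam and early stopping on validation fwBCE.

    ``encoded_train`` is either an (n, M) binary matrix or a sequence of
    encoded claims.  A validation split is held out before shuffling; the
    parameters of the best validation epoch are restored at the end, so the
    returned model is the checkpoint minimizing validation loss.
    """
    if not isinstance(encoded_train, np.ndarray):
        encoded_train = np.stack([c.vector for c in encoded_train])
    X = np.asarray(encoded_train, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.architecture.input_dim:
        raise ModelConfigError(f"training matrix shape {X.shape} incompatible with model")

    rng = np.random.default_rng(train_cfg.seed)
    n = X.shape[0]
    n_val = int(round(train_cfg.validation_fraction * n))
    perm = rng.permutation(n)
    X_val, X_tr = X[perm[:n_val]], X[perm[n_val:]]
    if len(X_tr) == 0:
        raise ModelConfigError("no training rows left after validation split")

    # Adam state
    lr, b1, b2, adam_eps = train_cfg.learning_rate, 0.9, 0.999, 1e-8
    m_w = [np.zeros_like(w) for w in model.weights]
    v_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    t = 0

    history = TrainingHistory()
    best_params = model.copy_parameters()
    since_best = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(X_tr))
        epoch_losses = []
        for start in range(0, len(X_tr), train_cfg.batch_size):
            batch = X_tr[order[start : start + train_cfg.batch_size]]
            try:
                loss, gw, gb = loss_and_gradients(model, batch, loss_cfg)
            except TrainingError:
                raise TrainingError(
                    f"training diverged at epoch {epoch} (learning_rate={lr})"
                ) from None
            epoch_losses.append(loss)
            t += 1
            corr1, corr2 = 1.0 - b1**t, 1.0 - b2**t
            for k in range(model.n_layers):
                for g, m, v, param in (
                    (gw[k], m_w[k], v_w[k], model.weights[k]),
                    (gb[k], m_b[k], v_b[k], model.biases[k]),
                ):
                    m *= b1
                    m += (1.0 - b1) * g
                    v *= b2
                    v += (1.0 - b2) * g * g
                    param -= lr * (m / corr1) / (np.sqrt(v / corr2) + adam_eps)

        train_loss = float(np.mean(epoch_losses))
        if n_val:
            val_loss = fwbce_loss(X_val, model.forward(X_val), loss_cfg)
        else:
            val_loss = train_loss
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        logger.info("epoch %d: train fwBCE %.5f, val fwBCE %.5f", epoch, train_loss, val_loss)

        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_params = model.copy_parameters()
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_cfg.early_stop_patience:
                logger.info("early stop at epoch %d (best %d)", epoch, history.best_epoch)
                break

    model.weights, model.biases = best_params
    return history


def reconstruct(model: Autoencoder, encoded: "np.ndarray | Sequence[EncodedClaim]") -> np.ndarray:
    """Per-dimension reconstruction probabilities, strictly inside (0, 1)."""
    if not isinstance(encoded, np.ndarray):
        encoded = np.stack([c.vector for c in encoded])
    probs = model.forward(np.atleast_2d(np.asarray(encoded, dtype=np.float64)))
    return np.clip(probs, 1e-12, 1.0 - 1e-12)


def per_cpt_scores(
    probabilities: np.ndarray, encoded: EncodedClaim, spec: EncoderSpec
) -> dict[str, float]:
    """Reconstruction probability of each procedure code active on the claim.

    A value near one means the code fits its context; near zero flags the code
    as a potential outlier.
    """
    if not encoded.cpt_positions:
        raise ModelConfigError(f"claim {encoded.claim_id}: no active CPT positions")
    row = np.asarray(probabilities, dtype=np.float64).ravel()
    return {
        spec.vocabulary.cpt_codes[p]: float(row[p]) for p in encoded.cpt_positions
    }


def save_checkpoint(
    model: Autoencoder,
    path: str | Path,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainingConfig | None = None,
    encoder_spec_hash: str | None = None,
) -> None:
    """Write parameters (.npz) plus a JSON sidecar with the run metadata."""
    path = Path(path)
    arrays = {}
    for k, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{k}"] = w
        arrays[f"b{k}"] = b
    np.savez_compressed(path, **arrays)
    sidecar = {
        "architecture": asdict(model.architecture),
        "loss": asdict(loss_cfg) if loss_cfg else None,
        "training": asdict(train_cfg) if train_cfg else None,
        "encoder_spec_hash": encoder_spec_hash,
        "n_layers": model.n_layers,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> Autoencoder:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    a = sidecar["architecture"]
    arch = AutoencoderArchitecture(
        input_dim=a["input_dim"],
        encoder_widths=tuple(a["encoder_widths"]),
        bottleneck_dim=a["bottleneck_dim"],
        decoder_widths=tuple(a["decoder_widths"]),
    )
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        weights = [data[f"W{k}"] for k in range(sidecar["n_layers"])]
        biases = [data[f"b{k}"] for k in range(sidecar["n_layers"])]
    return Autoencoder(architecture=arch, weights=weights, biases=biases)
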