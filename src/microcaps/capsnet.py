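"""Micro-capsule network core.

The model classifies small 2-D expansions of 1-D EEG segments:

    input (h, w, 1)
      -> Conv-1: 8 filters, 4x4, same padding, ReLU          (h, w, 8)
      -> Conv-2 stage: two 4x4 valid convolutions, ReLU      (h-6, w-6, 8)
      -> primary capsules: reshape into 4-D vectors, squash  (n_primary, 4)
      -> per-pair prediction u_hat[i,j] = u[i] @ W[i,j]      (n_primary, K, 16)
      -> dynamic routing-by-agreement (r iterations)         (K, 16)
      -> class scores = capsule lengths ||v_k||              (K,)

The length of each label capsule encodes the probability that the
corresponding seizure state is present; training minimises a per-class
margin loss on those lengths. There is no reconstruction decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Adam, Tensor, conv2d, einsum, relu, softmax

__all__ = [
    "MarginLossParams",
    "ModelConfig",
    "MicroCapsNet",
    "squash",
    "dynamic_routing",
    "class_probabilities",
    "margin_loss",
]

_EPS = 1e-8


@dataclass
class MarginLossParams:
    """Margins of the per-class hinge loss on capsule lengths.

    The true class is pushed above ``m_plus``, every other class below
    ``m_minus``; ``lam`` down-weights the absent-class term. ``loss_threshold``
    optionally stops training early once the epoch loss falls below it.
    """

    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5
    loss_threshold: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.m_minus < self.m_plus <= 1.0):
            raise ValueError("need 0 <= m_minus < m_plus <= 1")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults reproduce the reference layout
    for a (19, 18) input and binary classification)."""

    input_hw: tuple[int, int] = (19, 18)
    n_classes: int = 2
    conv1_filters: int = 8
    conv1_kernel: tuple[int, int] = (4, 4)
    conv2_filters: int = 8
    conv2_kernel: tuple[int, int] = (4, 4)
    primary_caps_dim: int = 4
    label_caps_dim: int = 16
    routing_iters: int = 3
    loss: MarginLossParams = field(default_factory=MarginLossParams)

    def __post_init__(self):
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        h, w = self.feature_hw
        if h < 1 or w < 1:
            raise ValueError(
                f"input {self.input_hw} too small for two valid "
                f"{self.conv2_kernel} convolutions"
            )
        if (h * w * self.conv2_filters) % self.primary_caps_dim:
            raise ValueError(
                f"feature map {h}x{w}x{self.conv2_filters} not divisible by "
                f"primary capsule dimension {self.primary_caps_dim}"
            )

    @property
    def feature_hw(self) -> tuple[int, int]:
        """Spatial size after the Conv-2 stage (two valid convolutions)."""
        kh, kw = self.conv2_kernel
        h, w = self.input_hw
        return h - 2 * (kh - 1), w - 2 * (kw - 1)

    @property
    def n_primary(self) -> int:
        h, w = self.feature_hw
        return h * w * self.conv2_filters // self.primary_caps_dim


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Squashing nonlinearity v = (|s|^2 / (1 + |s|^2)) * s / |s|.

    Maps any vector to length < 1 preserving direction; the zero vector maps
    to itself (the norm is guarded with a small epsilon).
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("squash requires finite input")
    sq = (s**2).sum(axis=axis, keepdims=True)
    norm = np.sqrt(sq + _EPS**2)
    return (sq / (1.0 + sq)) * s / norm


def _squash_t(s: Tensor, axis: int = -1) -> Tensor:
    sq = (s**2).sum(axis=axis, keepdims=True)
    norm = (sq + _EPS**2) ** 0.5
    return s * (sq / (1.0 + sq) / norm)


def dynamic_routing(
    u_hat: np.ndarray, r: int = 3, return_state: bool = False
):
    """Routing-by-agreement over prediction vectors.

    u_hat has shape (n_primary, K, dim) — the prediction each primary capsule
    makes for each label capsule. Routing logits b start at zero; for r
    rounds, coupling coefficients c_i. = softmax(b_i.), the weighted sums
    s_j = sum_i c_ij u_hat_ij are squashed into v_j, and b_ij grows by the
    agreement dot product u_hat_ij . v_j (no update after the last round).

    Returns v (K, dim), and optionally the final (b, c, s) state.
    """
    if r < 1:
        raise ValueError("routing needs at least one iteration")
    u_hat = np.asarray(u_hat, dtype=float)
    n_primary, k, _ = u_hat.shape
    b = np.zeros((n_primary, k))
    for it in range(r):
        e = np.exp(b - b.max(axis=1, keepdims=True))
        c = e / e.sum(axis=1, keepdims=True)
        s = np.einsum("ij,ijd->jd", c, u_hat)
        v = squash(s)
        if it < r - 1:
            b = b + np.einsum("ijd,jd->ij", u_hat, v)
    if return_state:
        return v, {"b": b, "c": c, "s": s}
    return v


def class_probabilities(v: np.ndarray) -> np.ndarray:
    """Euclidean lengths of the label capsules (presence probabilities)."""
    v = np.asarray(v, dtype=float)
    return np.sqrt((v**2).sum(axis=-1))


def predict_class(lengths: np.ndarray) -> np.ndarray:
    """Argmax over capsule lengths; ties break toward the lowest index."""
    return np.argmax(lengths, axis=-1)


def margin_loss(
    lengths: np.ndarray,
    labels: np.ndarray,
    params: MarginLossParams | None = None,
    class_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-sample and batch-mean margin loss.

    L_k = p_k max(0, m+ - |v_k|)^2 + lam (1 - p_k) max(0, |v_k| - m-)^2 with
    p_k = 1 for the true class; the sample loss sums over classes and the
    batch loss is the mean over samples.
    """
    params = params or MarginLossParams()
    lengths = np.atleast_2d(np.asarray(lengths, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    if lengths.min() < -1e-6 or lengths.max() > 1 + 1e-6:
        raise ValueError("capsule lengths must lie in [0, 1]")
    n, k = lengths.shape
    p = np.zeros((n, k))
    p[np.arange(n), labels] = 1.0
    pos = np.maximum(0.0, params.m_plus - lengths) ** 2
    neg = np.maximum(0.0, lengths - params.m_minus) ** 2
    per_sample = (p * pos + params.lam * (1 - p) * neg).sum(axis=1)
    if class_weights is not None:
        per_sample = per_sample * np.asarray(class_weights, dtype=float)[labels]
    return per_sample, float(per_sample.mean())


class MicroCapsNet:
    """The trainable network: holds weight tensors, runs the differentiable
    forward pass, and exposes save/load.

    Weight initialisation: fan-in scaled normal for the convolution kernels,
    truncated normal (sd 0.05, clipped at 2 sd) for the routing weight array.
    """

    def __init__(self, config: ModelConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config

        def conv_init(kh, kw, cin, cout):
            fan_in = kh * kw * cin
            return Tensor(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), (kh, kw, cin, cout)),
                requires_grad=True,
            )

        k1h, k1w = c.conv1_kernel
        k2h, k2w = c.conv2_kernel
        self.conv1_w = conv_init(k1h, k1w, 1, c.conv1_filters)
        self.conv1_b = Tensor(np.zeros(c.conv1_filters), requires_grad=True)
        self.conv2a_w = conv_init(k2h, k2w, c.conv1_filters, c.conv2_filters)
        self.conv2a_b = Tensor(np.zeros(c.conv2_filters), requires_grad=True)
        self.conv2b_w = conv_init(k2h, k2w, c.conv2_filters, c.conv2_filters)
        self.conv2b_b = Tensor(np.zeros(c.conv2_filters), requires_grad=True)
        w = rng.normal(
            0.0, 0.05, (c.n_primary, c.n_classes, c.primary_caps_dim, c.label_caps_dim)
        )
        self.routing_w = Tensor(np.clip(w, -0.1, 0.1), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [
            self.conv1_w, self.conv1_b,
            self.conv2a_w, self.conv2a_b,
            self.conv2b_w, self.conv2b_b,
            self.routing_w,
        ]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    # -- forward stages (each returns a Tensor on the tape) -------------------

    def feature_extract(self, x: Tensor) -> Tensor:
        """Conv-1 (same, ReLU) then the two-convolution Conv-2 stage."""
        h = relu(conv2d(x, self.conv1_w, self.conv1_b, padding="same"))
        h = relu(conv2d(h, self.conv2a_w, self.conv2a_b, padding="valid"))
        h = relu(conv2d(h, self.conv2b_w, self.conv2b_b, padding="valid"))
        return h

    def to_primary_capsules(self, features: Tensor) -> Tensor:
        """Reshape the feature map (row-major over h, w, channel) into
        capsules of length primary_caps_dim, then squash."""
        bsz = features.shape[0]
        u = features.reshape(bsz, self.config.n_primary, self.config.primary_caps_dim)
        return _squash_t(u)

    def route(self, u: Tensor) -> Tensor:
        """Predictions u_hat followed by differentiable unrolled routing."""
        cfg = self.config
        u_hat = einsum("bip,ijpq->bijq", u, self.routing_w)
        b = Tensor(np.zeros((u.shape[0], cfg.n_primary, cfg.n_classes)))
        for it in range(cfg.routing_iters):
            c = softmax(b, axis=2)
            s = einsum("bij,bijq->bjq", c, u_hat)
            v = _squash_t(s)
            if it < cfg.routing_iters - 1:
                b = b + einsum("bijq,bjq->bij", u_hat, v)
        return v

    def forward(
        self,
        x: np.ndarray,
        labels: np.ndarray | None = None,
        class_weights: np.ndarray | None = None,
    ):
        """Full pass. x: (B, h, w) or (B, h, w, 1). Returns (lengths Tensor
        of shape (B, K), loss Tensor or None)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != tuple(self.config.input_hw):
            raise ValueError(
                f"expected input {self.config.input_hw}, got {x.shape[1:3]}"
            )
        v = self.route(self.to_primary_capsules(self.feature_extract(Tensor(x))))
        lengths = ((v**2).sum(axis=-1) + _EPS**2) ** 0.5
        if labels is None:
            return lengths, None
        loss = self._margin_loss_t(lengths, np.asarray(labels), class_weights)
        return lengths, loss

    def _margin_loss_t(self, lengths: Tensor, labels, class_weights=None) -> Tensor:
        p = np.zeros(lengths.shape)
        p[np.arange(len(labels)), labels] = 1.0
        mp, mm, lam = (
            self.config.loss.m_plus,
            self.config.loss.m_minus,
            self.config.loss.lam,
        )
        pos = relu(mp - lengths) ** 2
        neg = relu(lengths - mm) ** 2
        per_sample = (Tensor(p) * pos + lam * Tensor(1.0 - p) * neg).sum(axis=1)
        if class_weights is not None:
            wvec = np.asarray(class_weights, dtype=float)[np.asarray(labels)]
            per_sample = per_sample * Tensor(wvec)
        return per_sample.mean()

    def predict_lengths(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Capsule lengths for a (possibly large) batch, without the tape."""
        out = []
        for start in range(0, len(x), batch_size):
            lengths, _ = self.forward(x[start : start + batch_size])
            out.append(lengths.data)
        return np.concatenate(out, axis=0)

    # -- persistence ----------------------------------------------------------

    _WEIGHT_NAMES = (
        "conv1_w", "conv1_b", "conv2a_w", "conv2a_b",
        "conv2b_w", "conv2b_b", "routing_w",
    )

    def save(self, path) -> None:
        """Single-file .npz archive: weight arrays + the config as JSON."""
        import json

        cfg = asdict(self.config)
        np.savez(
            path,
            config_json=np.frombuffer(
                json.dumps(cfg).encode("utf-8"), dtype=np.uint8
            ),
            **{name: getattr(self, name).data for name in self._WEIGHT_NAMES},
        )

    @classmethod
    def load(cls, path) -> "MicroCapsNet":
        import json

        with np.load(path) as archive:
            cfg = json.loads(bytes(archive["config_json"].tobytes()).decode("utf-8"))
            cfg["input_hw"] = tuple(cfg["input_hw"])
            cfg["conv1_kernel"] = tuple(cfg["conv1_kernel"])
            cfg["conv2_kernel"] = tuple(cfg["conv2_kernel"])
            cfg["loss"] = MarginLossParams(**cfg["loss"])
            model = cls(ModelConfig(**cfg))
            for name in cls._WEIGHT_NAMES:
                stored = archive[name]
                current = getattr(model, name)
                if stored.shape != current.data.shape:
                    raise ValueError(
                        f"checkpoint weight {name} has shape {stored.shape}, "
                        f"expected {current.data.shape}"
                    )
                current.data = stored.astype(np.float64)
        return model


def make_optimizer(model: MicroCapsNet, learning_rate: float = 5e-4) -> Adam:
    return Adam(model.params, lr=learning_rate)
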