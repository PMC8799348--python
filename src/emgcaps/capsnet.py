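"""Improved capsule network: multilevel convolution, dynamic routing with a
pluggable squash family, margin loss, and the end-to-end classifier.

The 7 x 7 x 256 fused map passes through a multilevel convolution block
(3 x 3 and 5 x 5 padded convolutions concatenated with the input, then a
1 x 1 bottleneck back to 256 channels), is reshaped into 7*7*32 = 1568
primary capsules of dimension 8, and routed by agreement over 3 iterations
to 5 action capsules of dimension 16 — one per gesture.  A capsule's length
in [0, 1) is the probability that its gesture is present; prediction is the
argmax of lengths.  Training minimizes the per-class margin loss.

The squash nonlinearity rescales a vector ``s`` to length ``g(||s||)`` while
preserving direction.  Five length laws are supported; ``e_squash``,
``1 - exp(-||s||^2)``, grows faster than the classic ``x^2/(1+x^2)`` once the
length leaves the origin, sharpening sensitivity to capsule-length changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .fusion import FusedInput, FusionConfig, FusionFrontEnd
from .nn import Tensor, concat, conv2d, einsum2, softmax

__all__ = [
    "SQUASH_KINDS",
    "MultilevelConvConfig",
    "MarginLossConfig",
    "CapsNetConfig",
    "CapsuleSet",
    "RoutingState",
    "apply_squash",
    "squash_length",
    "MultilevelConv",
    "to_primary_caps",
    "dynamic_routing",
    "margin_loss",
    "predict",
    "CapsNet",
]

SQUASH_KINDS = ("squash", "hsquash", "strict_squash", "squash_4", "e_squash")


def squash_length(x: np.ndarray, kind: str = "squash") -> np.ndarray:
    """The scalar length law ``g(x)`` of each squash variant, ``x = ||s||``.

    squash        x^2 / (1 + x^2)
    hsquash       (x/4)^2 / (1 + (x/4)^2)
    strict_squash 0.69 x^2 * 2^(-0.6 x - 1.115)
    squash_4      x^2 / (0.5 + x^2)
    e_squash      1 - exp(-x^2)
    """
    x = np.asarray(x, dtype=float)
    if kind == "squash":
        return x**2 / (1.0 + x**2)
    if kind == "hsquash":
        q = (x / 4.0) ** 2
        return q / (1.0 + q)
    if kind == "strict_squash":
        return 0.69 * x**2 * 2.0 ** (-0.6 * x - 1.115)
    if kind == "squash_4":
        return x**2 / (0.5 + x**2)
    if kind == "e_squash":
        return 1.0 - np.exp(-(x**2))
    raise KeyError(f"unknown squash kind {kind!r}; expected one of {SQUASH_KINDS}")


def _squash_tensor(s: Tensor, kind: str, axis: int = -1) -> Tensor:
    """Differentiable squash: ``v = g(||s||) * s / ||s||`` along ``axis``.

    The zero vector maps exactly to the zero vector (the direction factor
    ``s / max(||s||, eps)`` vanishes with ``s``).
    """
    n = s.norm(axis=axis, keepdims=True)
    if kind == "squash":
        length = n**2 / (1.0 + n**2)
    elif kind == "hsquash":
        q = (n * 0.25) ** 2
        length = q / (1.0 + q)
    elif kind == "strict_squash":
        # 2^y = exp(y ln 2)
        length = 0.69 * n**2 * ((n * (-0.6) - 1.115) * np.log(2.0)).exp()
    elif kind == "squash_4":
        length = n**2 / (0.5 + n**2)
    elif kind == "e_squash":
        length = 1.0 - (-(n**2)).exp()
    else:
        raise KeyError(f"unknown squash kind {kind!r}; expected one of {SQUASH_KINDS}")
    return s * (length / n)


def apply_squash(s: np.ndarray, kind: str = "squash", axis: int = -1) -> np.ndarray:
    """Squash a vector (or batch of vectors) along ``axis``; NumPy in/out."""
    return _squash_tensor(Tensor(np.asarray(s, dtype=float)), kind, axis=axis).data


@dataclass(frozen=True)
class MultilevelConvConfig:
    """Channel width of the multilevel block (256 at full reference widths)."""

    channels: int = 256
    k3: tuple[int, int] = (3, 3)
    k5: tuple[int, int] = (5, 5)

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise ValueError("channels must be >= 1")


@dataclass(frozen=True)
class MarginLossConfig:
    """Margin-loss hyperparameters: m+ = 0.9, m- = 0.1, lambda = 0.5."""

    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5
    n_classes: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.m_minus < self.m_plus < 1:
            raise ValueError("need 0 < m_minus < m_plus < 1")


@dataclass(frozen=True)
class CapsNetConfig:
    """End-to-end architecture widths and routing settings.

    ``width_profile`` "full" uses 256-channel convolutions (1568 primary
    capsules); "test" reduces every convolution to 32 channels (196 primary
    capsules) so the full pipeline trains in seconds per epoch on one CPU.
    """

    n_classes: int = 5
    primary_dim: int = 8
    action_dim: int = 16
    routing_iters: int = 3
    squash_kind: str = "e_squash"
    width_profile: str = "full"
    n_electrodes: int = 16
    w_init_std: float = 0.05

    def __post_init__(self) -> None:
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.squash_kind not in SQUASH_KINDS:
            raise KeyError(f"unknown squash kind {self.squash_kind!r}")
        if self.width_profile not in ("full", "test"):
            raise ValueError("width_profile must be 'full' or 'test'")

    @property
    def channels(self) -> int:
        return 256 if self.width_profile == "full" else 32

    @property
    def n_primary(self) -> int:
        # 7 x 7 spatial grid, channels / primary_dim capsule types per cell
        return 7 * 7 * (self.channels // self.primary_dim)


@dataclass
class CapsuleSet:
    """Equal-dimension capsule vectors; lengths are existence probabilities."""

    vectors: np.ndarray  # (..., count, dim)
    role: str = "primary"

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


@dataclass
class RoutingState:
    """Final routing quantities: logits b, couplings c, sums s, outputs v."""

    b: np.ndarray
    c: np.ndarray
    s: np.ndarray
    v: np.ndarray


class MultilevelConv:
    """Padded 3 x 3 and 5 x 5 convolutions concatenated with the input map,
    then a 1 x 1 bottleneck restoring the channel count; ReLU throughout."""

    def __init__(
        self,
        config: MultilevelConvConfig = MultilevelConvConfig(),
        rng: Optional[np.random.Generator] = None,
    ):
        from .fusion import _variance_scaled

        self.config = config
        rng = rng or np.random.default_rng()
        c = config.channels
        self.w3 = Tensor(_variance_scaled(rng, (c, c, *config.k3)), requires_grad=True)
        self.b3 = Tensor(np.zeros(c), requires_grad=True)
        self.w5 = Tensor(_variance_scaled(rng, (c, c, *config.k5)), requires_grad=True)
        self.b5 = Tensor(np.zeros(c), requires_grad=True)
        self.w1 = Tensor(_variance_scaled(rng, (c, 3 * c, 1, 1)), requires_grad=True)
        self.b1 = Tensor(np.zeros(c), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.w3, self.b3, self.w5, self.b5, self.w1, self.b1]

    def __call__(self, x: Tensor) -> Tensor:
        y3 = conv2d(x, self.w3, self.b3, padding=(1, 1)).relu()
        y5 = conv2d(x, self.w5, self.b5, padding=(2, 2)).relu()
        stacked = concat([y3, y5, x], axis=1)  # (N, 3C, 7, 7)
        return conv2d(stacked, self.w1, self.b1).relu()

    def forward_parts(self, x: Tensor):
        y3 = conv2d(x, self.w3, self.b3, padding=(1, 1)).relu()
        y5 = conv2d(x, self.w5, self.b5, padding=(2, 2)).relu()
        stacked = concat([y3, y5, x], axis=1)
        return conv2d(stacked, self.w1, self.b1).relu(), stacked


def to_primary_caps(map_: Union[Tensor, np.ndarray], kind: str = "squash",
                    primary_dim: int = 8) -> Tensor:
    """Reshape (N, C, 7, 7) into (N, 7*7*C/dim, dim) squashed capsules.

    Each capsule groups ``primary_dim`` consecutive channels at one spatial
    location; the channel axis must divide evenly by the capsule dimension.
    """
    t = map_ if isinstance(map_, Tensor) else Tensor(np.asarray(map_, dtype=float))
    n, c, h, w = t.shape
    if c % primary_dim:
        raise ValueError(f"channel count {c} not divisible by capsule dim {primary_dim}")
    types = c // primary_dim
    # (N, types, dim, H, W) -> (N, H, W, types, dim) -> (N, H*W*types, dim)
    caps = (
        t.reshape(n, types, primary_dim, h, w)
        .transpose(0, 3, 4, 1, 2)
        .reshape(n, h * w * types, primary_dim)
    )
    return _squash_tensor(caps, kind, axis=-1)


def dynamic_routing(
    primary: Tensor,
    W: Tensor,
    iterations: int = 3,
    kind: str = "squash",
) -> tuple[Tensor, RoutingState]:
    """Route primary capsules to action capsules by agreement.

    ``primary``: (N, P, d_in) squashed capsules; ``W``: (P, A, d_in, d_out)
    transformation matrices.  Logits ``b`` start at 0 each forward pass.
    Per iteration: couplings ``c = softmax_j(b)``, weighted sum
    ``s_j = sum_i c_ij u_hat_j|i``, output ``v_j = squash(s_j)``, and the
    agreement update ``b_ij += u_hat_j|i . v_j`` (skipped after the final
    iteration).  Gradients flow through all iterations.
    """
    if iterations < 1:
        raise ValueError("routing iterations must be >= 1")
    if isinstance(primary, CapsuleSet):
        primary = primary.vectors
    if not isinstance(primary, Tensor):
        arr = np.asarray(primary, dtype=float)
        primary = Tensor(arr[None] if arr.ndim == 2 else arr)
    if not isinstance(W, Tensor):
        W = Tensor(np.asarray(W, dtype=float))
    u_hat = einsum2("npi,paij->npaj", primary, W)  # (N, P, A, d_out)
    n, p, a, _ = u_hat.shape
    b = Tensor(np.zeros((n, p, a)))
    v = c = s = None
    for it in range(iterations):
        c = softmax(b, axis=2)
        s = (c.reshape(n, p, a, 1) * u_hat).sum(axis=1)  # (N, A, d_out)
        v = _squash_tensor(s, kind, axis=-1)
        if it < iterations - 1:
            agreement = (u_hat * v.reshape(n, 1, a, -1)).sum(axis=-1)
            b = b + agreement
    state = RoutingState(b=b.data.copy(), c=c.data.copy(), s=s.data.copy(), v=v.data.copy())
    return v, state


def margin_loss(
    lengths: Union[Tensor, np.ndarray],
    true_labels: Union[int, np.ndarray],
    config: MarginLossConfig = MarginLossConfig(),
) -> Union[Tensor, float]:
    """Per-class margin loss, averaged over the batch.

    ``L = sum_k T_k max(0, m+ - ||v_k||)^2
         + lambda (1 - T_k) max(0, ||v_k|| - m-)^2``.

    Accepts a single sample (length-N vector of capsule lengths and an int
    label, returns a float) or a batch as a Tensor (returns a Tensor for
    backprop).
    """
    is_tensor = isinstance(lengths, Tensor)
    t = lengths if is_tensor else Tensor(np.atleast_2d(np.asarray(lengths, dtype=float)))
    if len(t.shape) == 1:
        t = t.reshape(1, -1)
    labels = np.atleast_1d(np.asarray(true_labels, dtype=int))
    onehot = np.zeros(t.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    tk = Tensor(onehot)
    pos = (Tensor(config.m_plus) - t).relu() ** 2
    neg = (t - Tensor(config.m_minus)).relu() ** 2
    per_sample = (tk * pos + config.lambda_down * (1.0 - tk) * neg).sum(axis=1)
    loss = per_sample.mean()
    return loss if is_tensor else loss.item()


def predict(action: Union[CapsuleSet, np.ndarray]) -> np.ndarray:
    """Predicted class = argmax of action-capsule lengths (ties -> lowest)."""
    if isinstance(action, CapsuleSet):
        lengths = action.lengths
    else:
        arr = np.asarray(action, dtype=float)
        lengths = np.linalg.norm(arr, axis=-1) if arr.ndim >= 2 else arr
    return np.argmax(np.atleast_2d(lengths), axis=-1)


class CapsNet:
    """The full feature-fusion capsule classifier.

    fusion front-end -> multilevel convolution -> primary capsules ->
    dynamic routing -> action-capsule lengths.  Differentiable end to end
    under the margin loss.
    """

    def __init__(self, config: CapsNetConfig = CapsNetConfig(), seed: Optional[int] = None):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.channels
        self.frontend = FusionFrontEnd(
            FusionConfig(fusion_channels=c, mix_channels=c, n_electrodes=config.n_electrodes),
            rng,
        )
        self.mlconv = MultilevelConv(MultilevelConvConfig(channels=c), rng)
        self.W = Tensor(
            rng.normal(0.0, config.w_init_std,
                       size=(config.n_primary, config.n_classes,
                             config.primary_dim, config.action_dim)),
            requires_grad=True,
        )

    @property
    def params(self) -> list[Tensor]:
        return self.frontend.params + self.mlconv.params + [self.W]

    def forward(
        self, feature_maps: np.ndarray, segment_matrices: np.ndarray
    ) -> tuple[Tensor, RoutingState]:
        """Batched forward: (N, E, 15, 15) + (N, E, 15, 20) -> lengths (N, 5)."""
        fused = self.frontend(Tensor(feature_maps), Tensor(segment_matrices))
        mapped = self.mlconv(fused)
        primary = to_primary_caps(mapped, self.config.squash_kind, self.config.primary_dim)
        v, state = dynamic_routing(
            primary, self.W, self.config.routing_iters, self.config.squash_kind
        )
        lengths = v.norm(axis=-1)
        return lengths, state

    def forward_input(self, fused: FusedInput) -> tuple[Tensor, RoutingState]:
        return self.forward(fused.feature_maps[None], fused.segment_matrices[None])

    def predict_batch(self, feature_maps: np.ndarray, segment_matrices: np.ndarray) -> np.ndarray:
        lengths, _ = self.forward(feature_maps, segment_matrices)
        return np.argmax(lengths.data, axis=-1)

    # -- checkpointing -------------------------------------------------------

    _PARAM_NAMES = (
        "frontend.w_semg", "frontend.b_semg", "frontend.w_feat", "frontend.b_feat",
        "frontend.w_mix", "frontend.b_mix",
        "mlconv.w3", "mlconv.b3", "mlconv.w5", "mlconv.b5", "mlconv.w1", "mlconv.b1",
        "W",
    )

    def save(self, path: Union[str, Path]) -> None:
        """Save weights (.npz) plus a JSON architecture descriptor."""
        path = Path(path)
        arrays = {name: p.data for name, p in zip(self._PARAM_NAMES, self.params)}
        np.savez(path, **arrays)
        desc = {
            "n_classes": self.config.n_classes,
            "primary_dim": self.config.primary_dim,
            "action_dim": self.config.action_dim,
            "routing_iters": self.config.routing_iters,
            "squash_kind": self.config.squash_kind,
            "width_profile": self.config.width_profile,
            "n_electrodes": self.config.n_electrodes,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(desc, fh, indent=1)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CapsNet":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            desc = json.load(fh)
        model = cls(CapsNetConfig(**desc))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            for name, p in zip(cls._PARAM_NAMES, model.params):
                p.data = z[name].astype(np.float64)
        return model
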