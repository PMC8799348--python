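"""Feature fusion: outer-product feature maps, segment matrices, and the
convolutional front-end.

Per electrode channel, the 15-entry feature vector ``f`` is lifted to a
15 x 15 abstract feature map ``F = sigmoid(alpha * beta * f f^T)`` and the
300-sample window signal is stacked into a 15 x 20 segment matrix.  Both
matrices are independently Min-Max normalized to [0, 1].  The 16 electrode
channels enter the front-end as the depth dimension: 256 stride-2 valid
convolutions with 3 x 3 kernels (feature branch) and 3 x 8 kernels (segment
branch) each give a 7 x 7 x 256 map; channel concatenation (7 x 7 x 512)
followed by a 1 x 1 mixing convolution yields the 7 x 7 x 256 input of the
capsule network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .features import FeatureVector, SpectralConfig, build_feature_vector
from .nn import Tensor, concat, conv2d
from .windowing import SignalWindow, solve_segmentation, stack_segments

__all__ = [
    "FusionConfig",
    "FusedInput",
    "FrontEndOutput",
    "outer_feature_map",
    "minmax_normalize",
    "build_fused_input",
    "FusionFrontEnd",
    "fusion_frontend",
    "save_fused",
    "load_fused",
]


@dataclass(frozen=True)
class FusionConfig:
    """Fusion constants and front-end architecture.

    ``alpha`` and ``beta`` are the conversion parameters of the outer-product
    map (both 0.5).  ``fusion_channels`` is the kernel count of each branch
    (256 at full reference widths; reduce for fast test profiles).
    """

    alpha: float = 0.5
    beta: float = 0.5
    semg_kernel: tuple[int, int] = (3, 8)
    feat_kernel: tuple[int, int] = (3, 3)
    fusion_stride: int = 2
    fusion_channels: int = 256
    mix_kernel: tuple[int, int] = (1, 1)
    mix_channels: int = 256
    n_electrodes: int = 16

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.fusion_channels < 1 or self.mix_channels < 1:
            raise ValueError("channel counts must be >= 1")


@dataclass
class FusedInput:
    """Paired per-electrode feature maps and segment matrices for one window.

    ``feature_maps``: (electrodes, 15, 15); ``segment_matrices``:
    (electrodes, 15, 20); both Min-Max normalized per electrode matrix.
    """

    feature_maps: np.ndarray
    segment_matrices: np.ndarray
    label: Optional[int] = None

    @property
    def channels(self) -> int:
        return self.feature_maps.shape[0]


@dataclass
class FrontEndOutput:
    """The fused 7 x 7 spatial map with ``mix_channels`` channels."""

    map: Tensor  # (N, C, 7, 7)


def outer_feature_map(f: FeatureVector | np.ndarray, config: FusionConfig = FusionConfig()) -> np.ndarray:
    """``F[i][j] = sigmoid(alpha * beta * f[i] * f[j])``: symmetric, in (0,1).

    The leading 1 of ``f`` preserves the original features in row/column 0.
    """
    vec = f.values if isinstance(f, FeatureVector) else np.asarray(f, dtype=float)
    outer = (config.alpha * config.beta) * np.outer(vec, vec)
    # sigmoid; large |x| saturates without overflow warnings
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-outer))


def minmax_normalize(matrix: np.ndarray) -> np.ndarray:
    """Min-Max normalize to [0, 1]; a constant matrix maps to all zeros."""
    x = np.asarray(matrix, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def build_fused_input(
    window: SignalWindow,
    spectral: SpectralConfig = SpectralConfig(),
    fusion: FusionConfig = FusionConfig(),
) -> FusedInput:
    """Compute the fused front-end input for one window.

    Per electrode: feature vector -> outer map (15 x 15) and segment matrix
    (n x l from the balanced factorization of w), each independently Min-Max
    normalized; electrodes stacked as the leading (depth) axis.
    """
    if window.n_channels != fusion.n_electrodes:
        raise ValueError(
            f"expected {fusion.n_electrodes} electrode channels, got {window.n_channels}"
        )
    plan = solve_segmentation(window.w)
    fmaps = []
    smats = []
    for ch in range(window.n_channels):
        sig = window.data[ch]
        fv = build_feature_vector(sig, spectral)
        fmaps.append(minmax_normalize(outer_feature_map(fv, fusion)))
        smats.append(minmax_normalize(stack_segments(sig, plan)))
    return FusedInput(
        feature_maps=np.stack(fmaps),
        segment_matrices=np.stack(smats),
        label=window.label,
    )


def _variance_scaled(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """He/variance-scaling init: std = sqrt(2 / fan_in)."""
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class FusionFrontEnd:
    """The learnable convolutional fusion front-end.

    Two valid stride-2 branches (segment: 3 x 8 kernels; feature: 3 x 3
    kernels, ``fusion_channels`` each) produce 7 x 7 maps that are
    concatenated on the channel axis and mixed by a 1 x 1 convolution down to
    ``mix_channels``.  ReLU follows each convolution.
    """

    def __init__(self, config: FusionConfig = FusionConfig(), rng: Optional[np.random.Generator] = None):
        self.config = config
        rng = rng or np.random.default_rng()
        c, e = config.fusion_channels, config.n_electrodes
        self.w_semg = Tensor(_variance_scaled(rng, (c, e, *config.semg_kernel)), requires_grad=True)
        self.b_semg = Tensor(np.zeros(c), requires_grad=True)
        self.w_feat = Tensor(_variance_scaled(rng, (c, e, *config.feat_kernel)), requires_grad=True)
        self.b_feat = Tensor(np.zeros(c), requires_grad=True)
        self.w_mix = Tensor(
            _variance_scaled(rng, (config.mix_channels, 2 * c, *config.mix_kernel)),
            requires_grad=True,
        )
        self.b_mix = Tensor(np.zeros(config.mix_channels), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.w_semg, self.b_semg, self.w_feat, self.b_feat, self.w_mix, self.b_mix]

    def __call__(self, feature_maps: Tensor, segment_matrices: Tensor) -> Tensor:
        """(N, E, 15, 15) and (N, E, 15, 20) -> (N, mix_channels, 7, 7)."""
        s = self.config.fusion_stride
        branch_s = conv2d(segment_matrices, self.w_semg, self.b_semg, stride=(s, s)).relu()
        branch_f = conv2d(feature_maps, self.w_feat, self.b_feat, stride=(s, s)).relu()
        fused = concat([branch_s, branch_f], axis=1)  # (N, 2C, 7, 7)
        return conv2d(fused, self.w_mix, self.b_mix).relu()

    def forward_parts(self, feature_maps: Tensor, segment_matrices: Tensor):
        """As ``__call__`` but also returning the pre-mix concatenation."""
        s = self.config.fusion_stride
        branch_s = conv2d(segment_matrices, self.w_semg, self.b_semg, stride=(s, s)).relu()
        branch_f = conv2d(feature_maps, self.w_feat, self.b_feat, stride=(s, s)).relu()
        fused = concat([branch_s, branch_f], axis=1)
        return conv2d(fused, self.w_mix, self.b_mix).relu(), fused


def fusion_frontend(
    fused_input: FusedInput, frontend: FusionFrontEnd
) -> FrontEndOutput:
    """Apply the front-end to one fused input (batch of one)."""
    fm = Tensor(fused_input.feature_maps[None])
    sm = Tensor(fused_input.segment_matrices[None])
    return FrontEndOutput(map=frontend(fm, sm))


def save_fused(path, fused: FusedInput) -> None:
    import json

    label = -1 if fused.label is None else int(fused.label)
    np.savez(path, feature_maps=fused.feature_maps,
             segment_matrices=fused.segment_matrices, label=label)
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {"feature_maps": list(fused.feature_maps.shape),
             "segment_matrices": list(fused.segment_matrices.shape)},
            fh,
        )


def load_fused(path) -> FusedInput:
    with np.load(path) as z:
        label = int(z["label"])
        return FusedInput(
            feature_maps=z["feature_maps"],
            segment_matrices=z["segment_matrices"],
            label=None if label < 0 else label,
        )
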