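"""Mask-attention feature fusion.

The generator runs two encoders — one over the (whitened) image, one over
the attention map.  At coarse scales their feature maps are fused by a
dot-product attention: both maps are projected pointwise (1x1 convolution),
the projections are compared by inner products S[i, j] = A_i . B_j over
flattened spatial positions, a column-wise softmax turns each column of S
into a distribution of attention D over source positions, and a
value projection of the image features is aggregated under D.  The result
is handed back to the decoder through a residual connection.

Two faces of the same math live here:

* plain-numpy functions (:func:`project_features`, :func:`similarity`,
  :func:`attention_distribution`, :func:`apply_attention`) that define the
  operations exactly and are easy to check against hand arithmetic;
* :class:`MaskAttentionFusion`, the differentiable module the generator
  trains, built from the same primitives on the autodiff tape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .errors import ShapeMismatch
from .nn import Tensor


# ---------------------------------------------------------------------------
# Functional reference forms (numpy, float64)
# ---------------------------------------------------------------------------

def _as_feature_map(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 3:
        raise ShapeMismatch(f"feature map must be (H, W, C), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature map values must be finite")
    return arr


def project_features(fmap, weights) -> np.ndarray:
    """Pointwise (1x1-convolution) linear projection of the channel vectors.

    ``fmap`` is (H, W, C_in), ``weights`` is (C_in, C_out); the spatial
    shape is preserved.
    """
    fmap = _as_feature_map(fmap)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.ndim != 2 or weights.shape[0] != fmap.shape[2]:
        raise ShapeMismatch(
            f"weights {weights.shape} do not match {fmap.shape[2]} input channels"
        )
    return fmap @ weights


def similarity(a, b) -> np.ndarray:
    """Inner-product similarity S[i, j] = A_i . B_j over flattened positions.

    Positions are flattened row-major; both maps must share spatial shape
    and channel count.  Returns an (N, N) matrix with N = H * W.
    """
    a, b = _as_feature_map(a), _as_feature_map(b)
    if a.shape != b.shape:
        raise ShapeMismatch(f"feature maps differ: {a.shape} vs {b.shape}")
    n = a.shape[0] * a.shape[1]
    return a.reshape(n, -1) @ b.reshape(n, -1).T


@dataclass(frozen=True)
class AttentionDistribution:
    """Column-stochastic attention weights over feature positions.

    ``values[i, j]`` is the attention paid to source position *i* when
    synthesizing position *j*; every column sums to one.
    """

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ShapeMismatch(f"attention matrix must be square, got {arr.shape}")
        object.__setattr__(self, "values", arr)

    @property
    def position_count(self) -> int:
        return self.values.shape[0]


def attention_distribution(s) -> AttentionDistribution:
    """Column-wise softmax of a similarity matrix, max-stabilized."""
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ShapeMismatch(f"similarity matrix must be square, got {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("similarity entries must be finite")
    shifted = s - s.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    return AttentionDistribution(e / e.sum(axis=0, keepdims=True))


def apply_attention(d: AttentionDistribution, v) -> np.ndarray:
    """Aggregate value features under an attention distribution.

    Output position *j* is the D-weighted mixture sum_i D[i, j] * V_i of the
    value map's channel vectors, reshaped back to V's spatial layout.  The
    caller adds the result residually to its decoder stream.
    """
    v = _as_feature_map(v)
    h, w, c = v.shape
    if h * w != d.position_count:
        raise ShapeMismatch(
            f"value map has {h * w} positions, distribution expects {d.position_count}"
        )
    out = d.values.T @ v.reshape(h * w, c)
    return out.reshape(h, w, c)


# ---------------------------------------------------------------------------
# Differentiable fusion module used inside the generator
# ---------------------------------------------------------------------------

class MaskAttentionFusion(nn.Module):
    """Trainable attention fusion of the two encoder streams at one scale.

    Query features A come from the image path, key features B from the
    attention-map path, and a value projection V of the image features is
    aggregated under the column-softmax distribution.  All three
    projections are learned 1x1 convolutions of equal width.
    """

    def __init__(self, channels: int, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.query = nn.Conv2d(channels, channels, kernel=1, rng=rng)
        self.key = nn.Conv2d(channels, channels, kernel=1, rng=rng)
        self.value = nn.Conv2d(channels, channels, kernel=1, rng=rng)

    def __call__(self, feat_image: Tensor, feat_mask: Tensor) -> Tensor:
        if feat_image.shape != feat_mask.shape:
            raise ShapeMismatch(
                f"encoder features differ: {feat_image.shape} vs {feat_mask.shape}"
            )
        n, c, h, w = feat_image.shape
        if n != 1:
            raise ShapeMismatch("attention fusion is defined for batch size 1")
        a = self.query(feat_image).reshape((n, c, h * w))
        b = self.key(feat_mask).reshape((n, c, h * w))
        v = self.value(feat_image).reshape((n, c, h * w))
        # S[i, j] = A_i . B_j over flattened positions (batch is 1 here).
        s = nn.matmul(nn.transpose(a, (0, 2, 1)), b)      # (n, N, N)
        d = nn.softmax_cols(nn.reshape(s, (h * w, h * w)))  # column-stochastic
        out = nn.matmul(nn.reshape(v, (c, h * w)), d)     # out[:, j] = sum_i V_i D[i,j]
        return nn.reshape(out, (n, c, h, w))
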