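"""Image-to-network encoding: contrast, frequency and coupling maps.

Each pixel drives one oscillator.  The pixel's salience is its contrast
``C``, the weighted mean absolute deviation of its features (gray, R, G, B)
from the image-wide feature means:

    C_jk = sum_l w_l |f^l_jk - mean(f^l)| / sum_l w_l

Contrast sets the oscillator's natural frequency through an affine map

    o_jk = 1 - 0.5*delta_o + delta_o * C_jk          (o in [1-delta_o/2, 1+delta_o/2])

and the per-pixel positive (binding) and negative (separation) coupling
strengths through a Gaussian of the distance to full contrast:

    lam+_jk = lam_max_pos * exp(-(1 - C_jk)^2 / (2 sigma^2))
    lam-_jk = lam_max_neg * (1 - exp(-(1 - C_jk)^2 / (2 sigma^2)))

Links run between 8-neighbours only and are split by feature similarity:
similar neighbours (weighted feature distance <= theta) carry the positive
term, dissimilar ones the negative term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian as _gaussian_blur
from skimage.transform import resize as _resize

__all__ = [
    "FeatureStack",
    "CouplingTopology",
    "DEFAULT_WEIGHTS",
    "NEIGHBOR_OFFSETS",
    "preprocess",
    "contrast_map",
    "frequency_map",
    "central_frequency",
    "coupling_maps",
    "build_topology",
]

#: feature weights for (gray, R, G, B)
DEFAULT_WEIGHTS = np.array([0.5, 1.0 / 6.0, 1.0 / 6.0, 1.0 / 6.0])

#: the 8-neighbourhood as (row, col) offsets
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel features in [0, 1], shape (4, M, N): gray, R, G, B."""

    features: np.ndarray
    weights: np.ndarray = field(default_factory=lambda: DEFAULT_WEIGHTS.copy())

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if f.ndim != 3 or f.shape[0] != w.size:
            raise ValueError(f"features must be (n_features, M, N) matching {w.size} weights")
        if w.sum() <= 0:
            raise ValueError("feature weights must sum to a positive value")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "weights", w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.features.shape[1:]


@dataclass(frozen=True)
class CouplingTopology:
    """Similarity-gated 8-neighbour link sets on an M×N grid.

    ``positive[i]`` / ``negative[i]`` are boolean (M, N) masks: True where
    the link from pixel (j, k) to its i-th neighbour offset exists and is
    in that set.  The two sets partition the in-grid neighbour pairs and
    are symmetric (a link and its reverse are in the same set).
    """

    positive: np.ndarray  # (8, M, N) bool
    negative: np.ndarray  # (8, M, N) bool

    def degree(self) -> np.ndarray:
        """Number of links per pixel (3 at corners, 5 on edges, 8 inside)."""
        return (self.positive | self.negative).sum(axis=0)


def _to_rgb01(image: np.ndarray) -> np.ndarray:
    """Coerce an image array to float RGB in [0, 1], shape (M, N, 3)."""
    img = np.asarray(image)
    if img.dtype.kind in "ui":
        img = img.astype(float) / 255.0
    else:
        img = img.astype(float)
        if img.max() > 1.0 + 1e-9:
            img = img / 255.0
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:  # drop alpha
        img = img[..., :3]
    return np.clip(img, 0.0, 1.0)


def preprocess(
    image: np.ndarray,
    blur: bool = False,
    resize: tuple[int, int] | None = None,
    weights: np.ndarray | None = None,
) -> FeatureStack:
    """Build the normalized (gray, R, G, B) feature stack for an image.

    ``image`` is an (M, N[, 3|4]) array, 8-bit or float; grayscale inputs
    replicate gray into the colour channels.  ``resize`` is (rows, cols).
    Blurring (3×3 Gaussian, sd 1 px) is meant for natural images and is
    off by default.
    """
    rgb = _to_rgb01(image)
    if resize is not None:
        rgb = _resize(rgb, resize, order=1, anti_aliasing=True, preserve_range=True)
    if blur:
        rgb = _gaussian_blur(rgb, sigma=1.0, truncate=1.0, channel_axis=-1, preserve_range=True)
    gray = rgb.mean(axis=-1)
    feats = np.stack([gray, rgb[..., 0], rgb[..., 1], rgb[..., 2]])
    w = DEFAULT_WEIGHTS.copy() if weights is None else np.asarray(weights, dtype=float)
    return FeatureStack(features=feats, weights=w)


def contrast_map(features: FeatureStack) -> np.ndarray:
    """Weighted mean absolute deviation from the image-wide feature means."""
    f = features.features
    w = features.weights
    dev = np.abs(f - f.mean(axis=(1, 2), keepdims=True))
    return np.tensordot(w, dev, axes=(0, 0)) / w.sum()


def frequency_map(contrast: np.ndarray, delta_o: float = 0.04) -> np.ndarray:
    """Affine contrast-to-frequency coding, order-preserving in C."""
    if delta_o <= 0:
        raise ValueError(f"delta_o must be positive, got {delta_o}")
    return 1.0 - 0.5 * delta_o + delta_o * np.asarray(contrast, dtype=float)


def central_frequency(freq: np.ndarray) -> float:
    """Natural frequency of the central unit: mean of the grid frequencies."""
    freq = np.asarray(freq, dtype=float)
    if freq.size == 0:
        raise ValueError("frequency map is empty")
    return float(freq.mean())


def coupling_maps(
    contrast: np.ndarray,
    lam_max_pos: float = 0.05,
    lam_max_neg: float = 0.02,
    sigma: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel positive/negative coupling strengths from contrast.

    ``lam_pos`` increases and ``lam_neg`` decreases with contrast; both are
    bounded by their maxima.  Returns (lam_pos, lam_neg).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    g = np.exp(-((1.0 - np.asarray(contrast, dtype=float)) ** 2) / (2.0 * sigma**2))
    return lam_max_pos * g, lam_max_neg * (1.0 - g)


def shifted(plane: np.ndarray, offset: tuple[int, int], fill: float = 0.0) -> np.ndarray:
    """The plane as seen from each pixel's neighbour at ``offset``.

    ``shifted(x, (dr, dc))[j, k] = x[j + dr, k + dc]`` with ``fill`` outside
    the grid.
    """
    dr, dc = offset
    out = np.full_like(plane, fill, dtype=float)
    m, n = plane.shape
    rs, re = max(0, -dr), min(m, m - dr)
    cs, ce = max(0, -dc), min(n, n - dc)
    out[rs:re, cs:ce] = plane[rs + dr : re + dr, cs + dc : ce + dc]
    return out


def build_topology(features: FeatureStack, theta: float = 0.1) -> CouplingTopology:
    """Split the 8-neighbour graph into similar (positive) and dissimilar
    (negative) link sets by weighted feature distance.

    The distance between pixels is ``sum_l w_l |f^l_p - f^l_q| / sum_l w_l``;
    links at distance <= ``theta`` are positive.  Symmetry holds because
    the distance is symmetric.
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    f = features.features
    w = features.weights
    m, n = features.shape
    positive = np.zeros((8, m, n), dtype=bool)
    negative = np.zeros((8, m, n), dtype=bool)
    rows = np.arange(m)[:, None]
    cols = np.arange(n)[None, :]
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        valid = (rows + dr >= 0) & (rows + dr < m) & (cols + dc >= 0) & (cols + dc < n)
        dist = np.zeros((m, n))
        for l in range(f.shape[0]):
            dist += w[l] * np.abs(shifted(f[l], (dr, dc)) - f[l])
        dist /= w.sum()
        positive[i] = valid & (dist <= theta)
        negative[i] = valid & (dist > theta)
    return CouplingTopology(positive=positive, negative=negative)
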