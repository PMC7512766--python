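"""Synthetic test scenes: uniformly coloured objects on a uniform background.

The generator emulates the structure of the artificial desk-scale test
images used throughout the package: K non-overlapping rectangles or
ellipses, each a single RGB colour, on a single-colour background, with
ground-truth labels (0 = background, 1..K = objects in list order).
Colours in the presets are chosen so the encoded contrasts of the objects
are strictly ordered — giving every scene an unambiguous salience order —
with the most salient object the brightest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rossler import ChainConfig

__all__ = ["SceneObject", "SceneSpec", "make_scene", "preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class SceneObject:
    """One uniformly coloured object: axis-aligned rectangle or ellipse.

    ``position`` is the (row, col) of the top-left corner of the bounding
    box; ``size`` is (height, width) in pixels; ``color`` is 8-bit RGB.
    """

    shape: str  # "rectangle" | "ellipse"
    position: tuple[int, int]
    size: tuple[int, int]
    color: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if min(self.size) < 1:
            raise ValueError("object size must be at least 1x1")

    def mask(self, canvas_shape: tuple[int, int]) -> np.ndarray:
        m, n = canvas_shape
        r0, c0 = self.position
        hh, ww = self.size
        if r0 < 0 or c0 < 0 or r0 + hh > m or c0 + ww > n:
            raise ValueError(f"object {self} extends outside the {m}x{n} canvas")
        out = np.zeros((m, n), dtype=bool)
        if self.shape == "rectangle":
            out[r0 : r0 + hh, c0 : c0 + ww] = True
        else:
            rr = np.arange(m)[:, None]
            cc = np.arange(n)[None, :]
            cy, cx = r0 + (hh - 1) / 2.0, c0 + (ww - 1) / 2.0
            out = ((rr - cy) / (hh / 2.0)) ** 2 + ((cc - cx) / (ww / 2.0)) ** 2 <= 1.0
        return out


@dataclass(frozen=True)
class SceneSpec:
    """A full scene: canvas, background colour, objects, optional noise."""

    canvas: tuple[int, int]  # (rows, cols)
    background: tuple[int, int, int] = (70, 70, 70)
    objects: tuple[SceneObject, ...] = ()
    noise_sd: float = 0.0  # additive Gaussian pixel noise, 8-bit units
    seed: int = 0

    @property
    def n_objects(self) -> int:
        return len(self.objects)


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene; returns (uint8 RGB image (M,N,3), label grid (M,N)).

    Labels are 0 for background and 1..K for objects in list order.
    Raises on overlapping or out-of-canvas objects.  Deterministic under
    the spec seed.
    """
    m, n = spec.canvas
    image = np.empty((m, n, 3), dtype=float)
    image[:] = np.asarray(spec.background, dtype=float)
    labels = np.zeros((m, n), dtype=int)
    covered = np.zeros((m, n), dtype=bool)
    for idx, obj in enumerate(spec.objects, start=1):
        mask = obj.mask((m, n))
        if np.any(mask & covered):
            raise ValueError(f"object {idx} overlaps an earlier object")
        covered |= mask
        image[mask] = np.asarray(obj.color, dtype=float)
        labels[mask] = idx
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(image, 0, 255).round().astype(np.uint8), labels


def _scaled(v: float, scale: float) -> int:
    return max(1, int(round(v * scale)))


def _fig8_spec(scale: float, seed: int) -> SceneSpec:
    """Three rectangles (blue, yellow, green) on dark gray, 210x151 at scale 1.

    Colours are calibrated so the encoded contrasts come out strictly
    ordered and roughly evenly spaced (about 0.11 / 0.31 / 0.53 / 0.74 for
    background / blue / green / yellow at desk scale): the salience scan
    attends yellow first and the background last, and adjacent groups are
    separated by comparable frequency gaps.
    """
    m, n = _scaled(151, scale), _scaled(210, scale)
    objects = (
        SceneObject("rectangle", (_scaled(20, scale), _scaled(20, scale)),
                    (_scaled(40, scale), _scaled(45, scale)), (85, 112, 210)),    # blue
        SceneObject("rectangle", (_scaled(90, scale), _scaled(50, scale)),
                    (_scaled(40, scale), _scaled(45, scale)), (255, 255, 230)),   # yellow
        SceneObject("rectangle", (_scaled(30, scale), _scaled(130, scale)),
                    (_scaled(40, scale), _scaled(45, scale)), (160, 255, 160)),   # green
    )
    return SceneSpec(canvas=(m, n), background=(30, 30, 30), objects=objects, seed=seed)


def _fig13_spec(scale: float, seed: int) -> SceneSpec:
    """Five objects (yellow, purple, green, azure, red) on dark gray.

    Contrasts are strictly ordered yellow > green > azure > red > purple >
    background (about 0.75 / 0.66 / 0.51 / 0.32 / 0.21 / 0.10 at desk
    scale); with six groups inside the fixed frequency band the adjacent
    gaps are necessarily tighter than in the three-object scene.
    """
    m, n = _scaled(151, scale), _scaled(210, scale)
    objects = (
        SceneObject("rectangle", (_scaled(10, scale), _scaled(10, scale)),
                    (_scaled(30, scale), _scaled(35, scale)), (255, 255, 230)),   # yellow
        SceneObject("rectangle", (_scaled(95, scale), _scaled(30, scale)),
                    (_scaled(30, scale), _scaled(35, scale)), (120, 30, 150)),    # purple
        SceneObject("rectangle", (_scaled(55, scale), _scaled(90, scale)),
                    (_scaled(30, scale), _scaled(35, scale)), (205, 255, 205)),   # green
        SceneObject("rectangle", (_scaled(10, scale), _scaled(155, scale)),
                    (_scaled(30, scale), _scaled(35, scale)), (115, 210, 230)),   # azure
        SceneObject("rectangle", (_scaled(100, scale), _scaled(150, scale)),
                    (_scaled(30, scale), _scaled(35, scale)), (220, 95, 95)),     # red
    )
    return SceneSpec(canvas=(m, n), background=(30, 30, 30), objects=objects, seed=seed)


def _two_band_chain(n: int = 10, seed: int = 0) -> ChainConfig:
    """Chain split into two frequency bands, [1.01, 1.02] and [0.98, 0.99].

    Group 1 (the faster band) is the first half of the chain.  Used for
    controller-only experiments where the group structure is imposed
    directly instead of being encoded from an image.
    """
    n_fast = n // 2
    fast = np.linspace(1.01, 1.02, n_fast)
    slow = np.linspace(0.98, 0.99, n - n_fast)
    return ChainConfig(n=n, lam=-0.09, frequencies=np.concatenate([fast, slow]))


PRESET_NAMES = ("fig8-like", "fig13-like", "two-band-chain")


def preset(name: str, scale: float = 1.0, seed: int = 0, n: int = 10):
    """Named study setups.

    ``fig8-like`` and ``fig13-like`` return a :class:`SceneSpec` (three and
    five objects on gray; ``scale`` shrinks the 210×151 canvas, e.g. 0.2
    for the 42×30 desk-scale default used in tests).  ``two-band-chain``
    returns a :class:`ChainConfig` with ``n`` oscillators split over the
    two frequency bands.
    """
    if name == "fig8-like":
        return _fig8_spec(scale, seed)
    if name == "fig13-like":
        return _fig13_spec(scale, seed)
    if name == "two-band-chain":
        return _two_band_chain(n=n, seed=seed)
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
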