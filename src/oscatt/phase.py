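"""Phase extraction, synchronization detection, phase-based segmentation,
and entropy readouts.

The instantaneous phase of a Rössler-type oscillator is the quadrant-correct
angle of its (x, y) rotation, unwrapped over time so that it grows without
2π jumps.  All segmentation and synchronization statistics in the package
are read off these unwrapped phase traces: oscillators driving the same
object stay phase-synchronized (bounded pairwise difference) while
different objects drift apart, so a 1-D clustering of the phase profile at
a late readout time recovers the object labels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrapped_phase",
    "unwrap",
    "unwrap_incremental",
    "group_phase_std",
    "sync_detect",
    "segment_by_phase",
    "segmentation_entropy",
]

TWO_PI = 2.0 * np.pi


def wrapped_phase(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Quadrant-correct angle atan2(y, x) in (-pi, pi]; errors at the origin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x == 0.0) & (y == 0.0)):
        raise ValueError("phase undefined at the origin (x, y) = (0, 0)")
    return np.arctan2(y, x)


def unwrap(wrapped: np.ndarray, axis: int = 0) -> np.ndarray:
    """Unwrap a series of wrapped phases along ``axis`` (first sample kept)."""
    return np.unwrap(np.asarray(wrapped, dtype=float), axis=axis)


def unwrap_incremental(psi_prev: np.ndarray, wrapped_prev: np.ndarray, wrapped_now: np.ndarray) -> np.ndarray:
    """One-step unwrap: extend ``psi_prev`` by the principal increment.

    Used by the simulators to accumulate unwrapped phase at full step
    resolution without storing every wrapped sample.
    """
    inc = wrapped_now - wrapped_prev
    inc = (inc + np.pi) % TWO_PI - np.pi
    return psi_prev + inc


def group_phase_std(
    phases: np.ndarray,
    labels: np.ndarray,
    group: int,
    time_index: int | slice = -1,
) -> float | np.ndarray:
    """Population standard deviation of member phases at a time index.

    ``phases`` has shape (T, n_pixels) and ``labels`` (n_pixels,).  A slice
    for ``time_index`` returns one value per retained time.
    """
    labels = np.asarray(labels).ravel()
    mask = labels == group
    if not np.any(mask):
        raise ValueError(f"no members with label {group}")
    sel = np.asarray(phases)[time_index][..., mask]
    return np.std(sel, axis=-1)  # population (divide-by-n) form


def sync_detect(psi_a: np.ndarray, psi_b: np.ndarray, window: slice | None = None, bound: float = np.pi) -> bool:
    """Bounded-phase-difference test for phase synchronization.

    True iff, on the window, the phase difference stays within ``bound`` of
    its median offset (amplitudes are never compared).
    """
    diff = np.asarray(psi_a, dtype=float) - np.asarray(psi_b, dtype=float)
    if window is not None:
        diff = diff[window]
    return bool(np.max(np.abs(diff - np.median(diff))) < bound)


def segment_by_phase(
    psi: np.ndarray,
    gap_threshold: float = 1.0,
    shape: tuple[int, int] | None = None,
    min_cluster_size: int = 1,
    median_size: int = 1,
) -> np.ndarray:
    """Cluster a phase profile into group labels by 1-D gap cutting.

    Pixel phases at the readout time are sorted; a gap larger than
    ``gap_threshold`` (radians) starts a new cluster.  Clusters smaller
    than ``min_cluster_size`` (stray boundary pixels pushed off their group
    by the separation links) are absorbed into the phase-adjacent cluster
    across the smaller gap.  If ``shape`` (rows, cols) is given the result
    is reshaped to the image grid and the cluster holding the most
    border-frame pixels becomes label 0 (background); remaining clusters
    are renumbered 1.. in ascending phase order.  Without a shape, clusters
    are labelled 0.. in ascending phase order.

    ``median_size`` > 1 (grid input only) applies a spatial median filter
    to the phase map first: object-corner oscillators dragged off their
    group's phase by the separation links are isolated in image space, and
    the median pulls them back before the 1-D cut so they cannot bridge the
    gap between adjacent groups.
    """
    psi = np.asarray(psi, dtype=float).ravel()
    if shape is not None and median_size > 1:
        from scipy.ndimage import median_filter

        psi = median_filter(psi.reshape(shape), size=median_size).ravel()
    order = np.argsort(psi, kind="stable")
    sorted_psi = psi[order]
    cuts = np.nonzero(np.diff(sorted_psi) > gap_threshold)[0]

    # clusters as index intervals [start, end) over the sorted profile
    bounds = [0, *(c + 1 for c in cuts), psi.size]
    intervals = [[bounds[i], bounds[i + 1]] for i in range(len(bounds) - 1)]
    while len(intervals) > 1:
        sizes = [e - s for s, e in intervals]
        i = int(np.argmin(sizes))
        if sizes[i] >= min_cluster_size:
            break
        s, e = intervals[i]
        gap_lo = sorted_psi[s] - sorted_psi[s - 1] if i > 0 else np.inf
        gap_hi = sorted_psi[e] - sorted_psi[e - 1] if i < len(intervals) - 1 else np.inf
        j = i - 1 if gap_lo <= gap_hi else i + 1
        lo, hi = (j, i) if j < i else (i, j)
        intervals[lo] = [intervals[lo][0], intervals[hi][1]]
        del intervals[hi]

    cluster_of_sorted = np.empty(psi.size, dtype=int)
    for c, (s, e) in enumerate(intervals):
        cluster_of_sorted[s:e] = c
    labels = np.empty(psi.size, dtype=int)
    labels[order] = cluster_of_sorted

    if shape is None:
        return labels
    grid = labels.reshape(shape)
    border = np.concatenate([grid[0, :], grid[-1, :], grid[1:-1, 0], grid[1:-1, -1]])
    bg = np.bincount(border).argmax()
    n_clusters = labels.max() + 1
    remap = np.empty(n_clusters, dtype=int)
    remap[bg] = 0
    others = [c for c in range(n_clusters) if c != bg]
    for new, old in enumerate(others, start=1):
        remap[old] = new
    return remap[grid]


def segmentation_entropy(
    labels: np.ndarray,
    image: np.ndarray,
    include_background: bool = False,
) -> tuple[dict[int, float], float]:
    """Shannon entropy (bits) of the 256-bin gray histogram per segment.

    ``image`` is a gray-level array in [0, 1] or [0, 255]; lower entropy
    means more homogeneous segments.  Returns (per-label entropy, mean over
    object labels; background label 0 excluded unless requested).
    """
    labels = np.asarray(labels)
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.max() <= 1.0:
        img = img * 255.0
    levels = np.clip(img.round().astype(int), 0, 255)

    per_label: dict[int, float] = {}
    for lab in np.unique(labels):
        counts = np.bincount(levels[labels == lab].ravel(), minlength=256)
        p = counts[counts > 0] / counts.sum()
        per_label[int(lab)] = float(-(p * np.log2(p)).sum())
    object_labels = [l for l in per_label if include_background or l != 0]
    mean_entropy = float(np.mean([per_label[l] for l in object_labels])) if object_labels else 0.0
    return per_label, mean_entropy
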