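"""The first layer: an M×N grid of fractional Rössler oscillators driven by
an encoded image.

Every pixel (j, k) hosts one oscillator with natural frequency ``o_jk``
from the frequency map.  Its x equation carries two coupling terms over the
8-neighbour graph: a binding term through the similar-neighbour links,

    lam_pos_jk * sum_{(p,q) in pos links} (x_pq - x_jk),

and a separation term through the dissimilar-neighbour links,

    - lam_neg_jk * sum_{(p,q) in neg links} (x_pq - x_jk),

so similar neighbours attract each other's phases and dissimilar ones repel.
Oscillators belonging to one uniformly coloured object share a frequency and
positive links, hence phase-synchronize; different objects drift apart, and
a late phase profile segments the scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import NEIGHBOR_OFFSETS, CouplingTopology
from .phase import unwrap_incremental, wrapped_phase
from .rossler import RosslerParams
from .solver import FractionalConfig, integrate

__all__ = ["EncodedScene", "Layer1Result", "layer1_rhs", "simulate_layer1"]


@dataclass(frozen=True)
class EncodedScene:
    """Everything layer 1 needs from the encoder, shapes all (M, N)."""

    freq: np.ndarray
    lam_pos: np.ndarray
    lam_neg: np.ndarray
    topology: CouplingTopology

    def __post_init__(self) -> None:
        shape = self.freq.shape
        for name in ("lam_pos", "lam_neg"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != freq shape {shape}")
        if self.topology.positive.shape[1:] != shape:
            raise ValueError("topology shape does not match the frequency map")

    @property
    def shape(self) -> tuple[int, int]:
        return self.freq.shape


@dataclass
class Layer1Result:
    """Products of a layer-1 run.

    ``times``/``phases`` are subsampled (phases unwrapped at full step
    resolution first); ``states``, when recorded, is the full-resolution
    (n_steps+1, M, N, 3) trajectory needed to drive the control layer.
    """

    times: np.ndarray            # (T,) subsampled
    phases: np.ndarray           # (T, M*N) unwrapped
    shape: tuple[int, int]
    config: FractionalConfig
    states: np.ndarray | None = None  # (n_steps+1, M, N, 3) full resolution
    final_state: np.ndarray | None = None

    def phase_grid(self, time_index: int = -1) -> np.ndarray:
        return self.phases[time_index].reshape(self.shape)


def layer1_rhs(
    state: np.ndarray,
    scene: EncodedScene,
    params: RosslerParams = RosslerParams(),
) -> np.ndarray:
    """Derivatives of the image-coupled grid; ``state`` has shape (M, N, 3)."""
    if state.shape != scene.shape + (3,):
        raise ValueError(f"expected state shape {scene.shape + (3,)}, got {state.shape}")
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    m, n = scene.shape

    pos_sum = np.zeros((m, n))
    neg_sum = np.zeros((m, n))
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        # x as seen at each pixel's neighbour, zero-filled outside; the
        # masks are False there so the fill never contributes
        xs = np.zeros((m, n))
        rs, re = max(0, -dr), min(m, m - dr)
        cs, ce = max(0, -dc), min(n, n - dc)
        xs[rs:re, cs:ce] = x[rs + dr : re + dr, cs + dc : ce + dc]
        diff = xs - x
        p = scene.topology.positive[i]
        q = scene.topology.negative[i]
        pos_sum += np.where(p, diff, 0.0)
        neg_sum += np.where(q, diff, 0.0)

    d = np.empty_like(state)
    d[..., 0] = -scene.freq * y - z + scene.lam_pos * pos_sum - scene.lam_neg * neg_sum
    d[..., 1] = scene.freq * x + params.a * y
    d[..., 2] = params.b + z * (x - params.c)
    return d


def simulate_layer1(
    scene: EncodedScene,
    frac: FractionalConfig,
    params: RosslerParams = RosslerParams(),
    initial: np.ndarray | None = None,
    subsample: int = 10,
    record_states: bool = False,
) -> Layer1Result:
    """Integrate the grid; deterministic given the config seed.

    Initial states default to i.i.d. uniform [0,1]^3 per pixel under the
    seed.  Phases are unwrapped incrementally at every step and stored
    every ``subsample`` steps.  ``record_states=True`` additionally keeps
    the full-resolution trajectory (needed by the control layer; sized for
    desk-scale grids).
    """
    m, n = scene.shape
    if initial is None:
        rng = np.random.default_rng(frac.seed)
        initial = rng.uniform(0.0, 1.0, size=(m, n, 3))
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (m, n, 3):
        raise ValueError(f"initial state must have shape {(m, n, 3)}")

    n_steps = frac.n_steps
    n_out = n_steps // subsample + 1
    phases = np.empty((n_out, m * n))
    psi = np.empty(m * n)
    prev = np.empty(m * n)
    full = np.empty((n_steps + 1, m, n, 3)) if record_states else None

    def observer(k: int, s: np.ndarray) -> None:
        w = wrapped_phase(s[..., 0].ravel(), s[..., 1].ravel())
        if k == 0:
            psi[:] = w
        else:
            psi[:] = unwrap_incremental(psi, prev, w)
        prev[:] = w
        if k % subsample == 0:
            phases[k // subsample] = psi
        if full is not None:
            full[k] = s

    times, states = _integrate_grid(scene, params, initial, frac, observer)
    return Layer1Result(
        times=times[::subsample],
        phases=phases,
        shape=(m, n),
        config=frac,
        states=full,
        final_state=states,
    )


def _integrate_grid(scene, params, initial, frac, observer):
    """Grid integration via the generic GL driver, keeping final state only."""
    return integrate(
        lambda s, t: layer1_rhs(s, scene, params),
        initial,
        frac,
        observer=observer,
        keep_trajectory=False,
    )
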