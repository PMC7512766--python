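"""Explicit Grünwald–Letnikov integration of fractional-order systems.

Solves Caputo-type initial value problems ``D^alpha s = F(s, t)`` with
``alpha`` in (0, 1] for scalar systems or large flat state vectors (an
oscillator grid is integrated as one vector).  The scheme is the explicit
GL discretization with the short-memory principle: writing
``delta_k = s_k - s_0`` (constant pre-history, so the discrete operator is
Caputo-consistent),

    delta_k = h**alpha * F(s_{k-1}, t_{k-1}) - sum_{j=1..min(k,L)} c_j delta_{k-j}

with binomial weights ``c_j = (1 - (1 + alpha)/j) c_{j-1}``, ``c_0 = 1``.
For ``alpha = 1`` the weights collapse to ``c_1 = -1``, ``c_j = 0`` (j >= 2)
and every update is algebraically forward Euler.

An Adams–Bashforth–Moulton predictor–corrector (full-memory, O(n^2)) is
provided as a higher-accuracy cross-check mode for small systems.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma
from typing import Callable

import numpy as np

__all__ = [
    "FractionalConfig",
    "TrajectoryBuffer",
    "DivergenceError",
    "gl_coefficients",
    "gl_step",
    "integrate",
    "integrate_abm",
]

#: abort threshold for chaotic blow-up detection
DIVERGENCE_BOUND = 1e6


class DivergenceError(RuntimeError):
    """State left the finite/bounded region during integration."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(
            f"non-finite or divergent state (|s| > {DIVERGENCE_BOUND:g}) "
            f"at step {step} (t = {time:g})"
        )


@dataclass(frozen=True)
class FractionalConfig:
    """Integration settings for a fractional-order run.

    Parameters
    ----------
    alpha
        Fractional derivative order, in (0, 1].  ``1`` recovers the
        ordinary first derivative (forward Euler updates).
    h
        Time step, > 0.
    t_end
        End time of the integration window starting at 0.
    memory_length
        Short-memory window in steps (``None`` keeps the full history).
    seed
        Seed for any randomized initial conditions drawn by callers.
    """

    alpha: float = 0.9
    h: float = 0.01
    t_end: float = 100.0
    memory_length: int | None = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.h <= 0.0:
            raise ValueError(f"h must be positive, got {self.h}")
        if self.memory_length is not None and self.memory_length < 1:
            raise ValueError("memory_length must be >= 1 or None")

    @property
    def n_steps(self) -> int:
        return int(np.floor(self.t_end / self.h + 1e-12))


def gl_coefficients(order: float, n_terms: int) -> np.ndarray:
    """Grünwald–Letnikov binomial weights ``c_0 .. c_{n_terms-1}``.

    ``c_k = (-1)^k binom(order, k)`` via the stable recurrence
    ``c_k = (1 - (1 + order)/k) c_{k-1}``; ``c_0 = 1`` and ``c_k <= 0``
    for ``k >= 1`` when ``0 < order <= 1``.
    """
    if not 0.0 < order <= 1.0:
        raise ValueError(f"order must be in (0, 1], got {order}")
    if n_terms < 1:
        raise ValueError(f"n_terms must be >= 1, got {n_terms}")
    c = np.empty(n_terms)
    c[0] = 1.0
    for k in range(1, n_terms):
        c[k] = (1.0 - (1.0 + order) / k) * c[k - 1]
    return c


class TrajectoryBuffer:
    """Ring buffer of the offset history ``delta = s - s_0`` for the GL sum.

    Keeps at most ``memory_length`` past offsets plus the running state.
    Times advance with constant spacing ``h`` from 0.
    """

    def __init__(self, s0: np.ndarray, config: FractionalConfig):
        self.s0 = np.asarray(s0, dtype=float).copy()
        self.config = config
        n_keep = config.memory_length or (config.n_steps + 1)
        self._hist = np.zeros((n_keep, self.s0.size))
        self._n_keep = n_keep
        self.step_index = 0
        self.state = self.s0.copy()

    @property
    def time(self) -> float:
        return self.step_index * self.config.h

    def n_memory(self) -> int:
        return min(self.step_index, self._n_keep)

    def push(self, delta: np.ndarray) -> None:
        self._hist[self.step_index % self._n_keep] = delta
        self.step_index += 1
        self.state = self.s0 + delta.reshape(self.s0.shape)

    def memory_sum(self, coeffs: np.ndarray) -> np.ndarray:
        """``sum_{j=1..m} c_j delta_{k-j}`` for the current step k."""
        m = self.n_memory()
        if m == 0:
            return np.zeros(self.s0.size)
        k = self.step_index
        # delta_{k-j} lives at slot (k-j) % n_keep; split the ring at the wrap
        idx_new = (k - 1) % self._n_keep
        take_tail = min(m, idx_new + 1)
        out = coeffs[1 : take_tail + 1][::-1] @ self._hist[idx_new - take_tail + 1 : idx_new + 1]
        if m > take_tail:
            rest = m - take_tail
            out += coeffs[take_tail + 1 : m + 1][::-1] @ self._hist[self._n_keep - rest :]
        return out


def gl_step(
    rhs: Callable[[np.ndarray, float], np.ndarray],
    buffer: TrajectoryBuffer,
    coeffs: np.ndarray,
) -> np.ndarray:
    """Advance the buffer by one GL step; returns the new state.

    Raises :class:`DivergenceError` if the new state is non-finite or its
    magnitude exceeds the blow-up bound.
    """
    cfg = buffer.config
    f = np.asarray(rhs(buffer.state, buffer.time), dtype=float).ravel()
    delta = f * cfg.h**cfg.alpha - buffer.memory_sum(coeffs)
    buffer.push(delta)
    s = buffer.state
    if not np.all(np.isfinite(s)) or np.max(np.abs(s)) > DIVERGENCE_BOUND:
        raise DivergenceError(buffer.step_index, buffer.time)
    return s


def integrate(
    rhs: Callable[[np.ndarray, float], np.ndarray],
    s0: np.ndarray,
    config: FractionalConfig,
    observer: Callable[[int, np.ndarray], None] | None = None,
    keep_trajectory: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``D^alpha s = rhs(s, t)`` from ``s0`` over [0, t_end].

    Returns ``(times, states)`` with ``floor(t_end/h) + 1`` points;
    deterministic given identical inputs.  ``observer(k, state)`` is called
    after every step (and once for the initial state) and may be used to
    record derived quantities without storing the full trajectory; with
    ``keep_trajectory=False`` only the final state is returned in place of
    the full state array (large-grid runs record what they need through the
    observer instead).
    """
    s0 = np.asarray(s0, dtype=float)
    n = config.n_steps
    buf = TrajectoryBuffer(s0, config)
    coeffs = gl_coefficients(config.alpha, (config.memory_length or n) + 1)
    times = np.arange(n + 1) * config.h
    states = np.empty((n + 1,) + s0.shape) if keep_trajectory else None
    if keep_trajectory:
        states[0] = s0
    if observer is not None:
        observer(0, s0)
    state = s0
    for k in range(1, n + 1):
        state = gl_step(rhs, buf, coeffs).reshape(s0.shape)
        if keep_trajectory:
            states[k] = state
        if observer is not None:
            observer(k, state)
    return times, states if keep_trajectory else state


def integrate_abm(
    rhs: Callable[[np.ndarray, float], np.ndarray],
    s0: np.ndarray,
    config: FractionalConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Adams–Bashforth–Moulton predictor–corrector for Caputo systems.

    Full-memory O(n^2) fractional Adams method; higher order than the GL
    scheme and used as a cross-check on scalar systems and small chains.
    """
    s0 = np.asarray(s0, dtype=float)
    a, h, n = config.alpha, config.h, config.n_steps
    times = np.arange(n + 1) * h
    d = s0.size
    states = np.empty((n + 1, d))
    states[0] = s0.ravel()
    f_hist = np.empty((n + 1, d))
    f_hist[0] = np.asarray(rhs(s0, 0.0), dtype=float).ravel()

    j = np.arange(n + 2, dtype=float)
    # corrector weights a_j and predictor weights b_j (Diethelm et al.)
    acoef = (j[:-1] + 2) ** (a + 1) - 2 * (j[:-1] + 1) ** (a + 1) + j[:-1] ** (a + 1)
    bcoef = (j[1:] ) ** a - j[:-1] ** a

    ha = h**a
    c_pred = ha / a / gamma(a)
    c_corr = ha / gamma(a + 2)
    for k in range(1, n + 1):
        fk = f_hist[:k]
        # predictor: sum b_{k-1-j} f_j
        pred = states[0] + c_pred * (bcoef[:k][::-1] @ fk)
        f_pred = np.asarray(rhs(pred.reshape(s0.shape), times[k]), dtype=float).ravel()
        # corrector: ((k-1)^{a+1} - (k-1-a) k^a) f_0 + sum a_{k-1-j} f_j + f_pred
        w0 = (k - 1) ** (a + 1) - (k - 1 - a) * k**a
        corr = w0 * f_hist[0] + (acoef[: k - 1][::-1] @ fk[1:]) + f_pred
        states[k] = states[0] + c_corr * corr
        if not np.all(np.isfinite(states[k])) or np.max(np.abs(states[k])) > DIVERGENCE_BOUND:
            raise DivergenceError(k, times[k])
        f_hist[k] = np.asarray(rhs(states[k].reshape(s0.shape), times[k]), dtype=float).ravel()
    return times, states.reshape((n + 1,) + s0.shape)
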