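"""The second layer: a single central oscillator that attends to one object
group at a time.

Each object group in the network is summarized by a *hybrid system* — the
componentwise mean w = (w_x, w_y, w_z) of its members' states.  Because the
mean is linear, the hybrid inherits its members' dynamics: D^a w equals the
mean of the members' right-hand sides (the drift Omega), and its phase grows
like the group's.

The central (response) unit is a fractional Rössler oscillator at the
scene-mean frequency o_r with an additive control input u.  During an
attention epoch targeting group g, active control cancels the unit's own
dynamics and injects the hybrid's, plus linear error feedback:

    u = Omega - F_r(s_r) - K e,       e = s_r - w,

so the closed-loop error obeys D^a e = -K e and decays like the
Mittag-Leffler function E_a(-K t^a): the unit phase-locks onto the group.
Epochs follow the salience order (fastest phase growth first), each lasting
the attention span F_t, separated by a 0.01 gap with the controller off;
after the last epoch the unit runs free.  The controller never feeds back
into the first layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import EncodedScene, Layer1Result, layer1_rhs
from .phase import unwrap_incremental, wrapped_phase
from .rossler import RosslerParams
from .solver import FractionalConfig, integrate

__all__ = [
    "ControlGains",
    "AttentionEpoch",
    "AttentionSchedule",
    "AttentionResult",
    "hybrid_state",
    "hybrid_drift",
    "active_control",
    "rank_groups_by_salience",
    "build_schedule",
    "run_attention",
    "count_transitions",
]


@dataclass(frozen=True)
class ControlGains:
    """Diagonal feedback gain; positive entries keep the fractional error
    dynamics stable (|arg(-K)| = pi > a*pi/2 for every a in (0, 1])."""

    k: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        k = np.broadcast_to(np.asarray(self.k, dtype=float), (3,)).copy()
        if np.any(k <= 0):
            raise ValueError("control gains must be positive")
        object.__setattr__(self, "k", k)


@dataclass(frozen=True)
class AttentionEpoch:
    group: int
    onset: float
    offset: float

    def active(self, t: float) -> bool:
        return self.onset <= t < self.offset


@dataclass(frozen=True)
class AttentionSchedule:
    """Non-overlapping epochs; onsets form an arithmetic progression with
    step span + gap."""

    epochs: tuple[AttentionEpoch, ...]
    span: float
    gap: float = 0.01

    def __post_init__(self) -> None:
        groups = [e.group for e in self.epochs]
        if len(set(groups)) != len(groups):
            raise ValueError("schedule groups must be distinct")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.onset < a.offset:
                raise ValueError("epochs must not overlap")

    @property
    def end(self) -> float:
        return self.epochs[-1].offset if self.epochs else 0.0

    def active_epoch(self, t: float) -> AttentionEpoch | None:
        for e in self.epochs:
            if e.active(t):
                return e
        return None


def _member_mask(labels: np.ndarray, group: int) -> np.ndarray:
    mask = np.asarray(labels) == group
    if not np.any(mask):
        raise ValueError(f"group {group} has no members")
    return mask


def hybrid_state(states: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Componentwise mean (3,) of member oscillator states.

    ``states`` is (..., 3) and ``members`` a boolean mask over the leading
    axes (or a group-membership mask already).
    """
    members = np.asarray(members, dtype=bool)
    if not members.any():
        raise ValueError("member set is empty")
    return np.asarray(states, dtype=float)[members].mean(axis=0)


def hybrid_drift(
    state: np.ndarray,
    members: np.ndarray,
    scene: EncodedScene,
    params: RosslerParams = RosslerParams(),
) -> np.ndarray:
    """Drift Omega of the hybrid: mean of members' layer-1 right-hand sides.

    Exact, because the mean of derivatives is the derivative of the mean.
    """
    return hybrid_state(layer1_rhs(state, scene, params), members)


def _free_rhs(state: np.ndarray, o_r: float, params: RosslerParams) -> np.ndarray:
    x, y, z = state
    return np.array([-o_r * y - z, o_r * x + params.a * y, params.b + z * (x - params.c)])


def active_control(
    response: np.ndarray,
    hybrid: np.ndarray,
    drift: np.ndarray,
    gains: ControlGains,
    o_r: float = 1.0,
    params: RosslerParams = RosslerParams(),
) -> np.ndarray:
    """Exact-cancellation active control u = Omega - F_r(s_r) - K (s_r - w)."""
    response = np.asarray(response, dtype=float)
    e = response - np.asarray(hybrid, dtype=float)
    return np.asarray(drift, dtype=float) - _free_rhs(response, o_r, params) - gains.k * e


def rank_groups_by_salience(
    phases: np.ndarray,
    times: np.ndarray,
    labels: np.ndarray,
    window: tuple[float, float],
) -> list[int]:
    """Group ids sorted by descending mean phase velocity over the window.

    Velocity is the mean member slope (psi(t_hi) - psi(t_lo)) / (t_hi -
    t_lo); ties break toward the smaller group id.  More salient (higher
    contrast) objects oscillate faster and come first.
    """
    t_lo, t_hi = window
    i_lo = int(np.searchsorted(times, t_lo, side="left"))
    i_hi = min(int(np.searchsorted(times, t_hi, side="right")) - 1, len(times) - 1)
    if i_hi <= i_lo:
        raise ValueError(f"window {window} does not span two retained samples")
    vel = (phases[i_hi] - phases[i_lo]) / (times[i_hi] - times[i_lo])
    labels = np.asarray(labels).ravel()
    groups = np.unique(labels)
    mean_vel = {int(g): float(vel[labels == g].mean()) for g in groups}
    return sorted(mean_vel, key=lambda g: (-mean_vel[g], g))


def build_schedule(
    groups: list[int] | tuple[int, ...],
    t1: float = 20.0,
    span: float = 10.0,
    gap: float = 0.01,
) -> AttentionSchedule:
    """One epoch per group in order: onset_k = t1 + k (span + gap)."""
    if t1 < 0 or span <= 0:
        raise ValueError("need t1 >= 0 and span > 0")
    epochs = tuple(
        AttentionEpoch(group=int(g), onset=t1 + i * (span + gap), offset=t1 + i * (span + gap) + span)
        for i, g in enumerate(groups)
    )
    return AttentionSchedule(epochs=epochs, span=span, gap=gap)


@dataclass
class AttentionResult:
    """Central-unit run products (subsampled to the layer-1 output grid)."""

    times: np.ndarray
    central_states: np.ndarray        # (T, 3)
    central_phase: np.ndarray         # (T,)
    hybrid_phases: dict[int, np.ndarray]
    schedule: AttentionSchedule
    lock_report: list[dict]           # per epoch: group, onset, offset, locked, mean_abs_err

    def locked_epochs(self) -> int:
        return sum(1 for r in self.lock_report if r["locked"])


def run_attention(
    layer1: Layer1Result,
    labels: np.ndarray,
    schedule: AttentionSchedule,
    scene: EncodedScene,
    o_r: float,
    gains: ControlGains = ControlGains(),
    params: RosslerParams = RosslerParams(),
    lock_bound: float = np.pi,
    subsample: int = 10,
    initial: np.ndarray | None = None,
) -> AttentionResult:
    """Drive the central unit over a completed layer-1 run (one-way drive).

    The layer-1 trajectory must have been recorded at full resolution
    (``record_states=True``); it is never modified.  Between epochs and
    after the last one the control input is zero.  The lock criterion per
    epoch: |psi_central - psi_hybrid| stays within ``lock_bound`` over the
    final half of the epoch.
    """
    if layer1.states is None:
        raise ValueError("layer-1 run must be recorded with record_states=True")
    frac = layer1.config
    h, alpha = frac.h, frac.alpha
    n_steps = layer1.states.shape[0] - 1
    if schedule.epochs and schedule.end > n_steps * h + 1e-9:
        raise ValueError(f"schedule ends at t={schedule.end} beyond the run (t_end={n_steps * h:g})")

    labels = np.asarray(labels).reshape(layer1.shape)
    masks = {e.group: _member_mask(labels, e.group) for e in schedule.epochs}

    if initial is None:
        rng = np.random.default_rng(frac.seed + 1)  # distinct stream from layer 1
        initial = rng.uniform(0.0, 1.0, size=3)
    initial = np.asarray(initial, dtype=float)

    err_sums: dict[int, list[float]] = {e.group: [] for e in schedule.epochs}

    def rhs(s: np.ndarray, t: float) -> np.ndarray:
        epoch = schedule.active_epoch(t)
        f = _free_rhs(s, o_r, params)
        if epoch is None:
            return f
        k = int(round(t / h))
        grid = layer1.states[k]
        mask = masks[epoch.group]
        w = hybrid_state(grid, mask)
        omega = hybrid_drift(grid, mask, scene, params)
        if t >= epoch.onset + (epoch.offset - epoch.onset) / 2.0:
            err_sums[epoch.group].append(float(np.linalg.norm(s - w)))
        return f + active_control(s, w, omega, gains, o_r, params)

    n_out = n_steps // subsample + 1
    central = np.empty((n_out, 3))
    cphase = np.empty(n_out)
    tracker = {"psi": 0.0, "prev": 0.0}

    def observer(k: int, s: np.ndarray) -> None:
        wph = float(wrapped_phase(s[0], s[1]))
        if k == 0:
            tracker["psi"] = wph
        else:
            tracker["psi"] = float(unwrap_incremental(tracker["psi"], tracker["prev"], wph))
        tracker["prev"] = wph
        if k % subsample == 0:
            central[k // subsample] = s
            cphase[k // subsample] = tracker["psi"]

    times_full = np.arange(n_steps + 1) * h
    run_cfg = FractionalConfig(
        alpha=alpha, h=h, t_end=n_steps * h, memory_length=frac.memory_length, seed=frac.seed
    )
    integrate(rhs, initial, run_cfg, observer=observer, keep_trajectory=False)
    times = times_full[::subsample]

    # hybrid phase traces per attended group, from the recorded trajectory
    hybrid_phases: dict[int, np.ndarray] = {}
    for g, mask in masks.items():
        w_series = layer1.states[:, mask, :].mean(axis=1)  # (n_steps+1, 3)
        psi_w = np.unwrap(np.arctan2(w_series[:, 1], w_series[:, 0]))
        hybrid_phases[g] = psi_w[::subsample]

    lock_report = []
    for e in schedule.epochs:
        half = e.onset + (e.offset - e.onset) / 2.0
        sel = (times >= half) & (times <= e.offset)
        diff = cphase[sel] - hybrid_phases[e.group][sel]
        locked = bool(diff.size) and float(np.max(np.abs(diff))) < lock_bound
        errs = err_sums[e.group]
        lock_report.append(
            {
                "group": e.group,
                "onset": e.onset,
                "offset": e.offset,
                "locked": locked,
                "mean_abs_err": float(np.mean(errs)) if errs else float("nan"),
            }
        )

    return AttentionResult(
        times=times,
        central_states=central,
        central_phase=cphase,
        hybrid_phases=hybrid_phases,
        schedule=schedule,
        lock_report=lock_report,
    )


def count_transitions(result: AttentionResult) -> int:
    """Number of attention epochs in which the central unit locked onto its
    target hybrid (phase difference within the lock bound over the final
    half of the epoch); equals the number of attended groups on a
    successful scan."""
    return result.locked_epochs()
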