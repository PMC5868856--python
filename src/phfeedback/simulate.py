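"""Time integration: continuous batch growth and serial-transfer protocols.

Batch growth integrates the coupled density–proton system with an adaptive
explicit Runge–Kutta stepper.  The serial-transfer protocol alternates a
fixed-length growth cycle with an instantaneous dilution event that divides
both densities by the dilution factor ``D`` and resets the proton
concentration toward fresh medium::

    p  ->  p / D + (D - 1) / D * p0

i.e. the proton content is mixed ``1:(D-1)`` with fresh medium at ``p0``.
A fixed-step forward-Euler integrator is provided as an independent
cross-check oracle for the adaptive solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import Environment, SpeciesParams, SystemState, rhs_vector

__all__ = [
    "TransferProtocol",
    "Trajectory",
    "SolverError",
    "integrate",
    "euler_endpoint",
    "apply_dilution",
    "run_serial_transfer",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

EVENT_NONE = "none"
EVENT_PRE = "pre_dilution"
EVENT_POST = "post_dilution"

DEFAULT_SOLVER_OPTS = {"method": "RK45", "rtol": 1e-8, "atol": 1e-10}


class SolverError(RuntimeError):
    """Adaptive integration failed; carries the offending initial state."""

    def __init__(self, message: str, state: SystemState):
        super().__init__(f"{message} (from state {state})")
        self.state = state


@dataclass(frozen=True)
class TransferProtocol:
    """Serial-transfer schedule: grow ``cycle_length``, dilute by ``D``, repeat.

    ``p0`` is the fresh-medium proton concentration used in the reset; if
    ``None`` the environment's ``p0`` is used.  The experimental cadence of
    daily 1/10x or 1/100x transfers maps nominally onto ``cycle_length = 5``
    model-time units; the mapping is not calibrated.
    """

    cycle_length: float = 5.0
    dilution_factor: float = 10.0
    n_cycles: int = 10
    p0: float | None = None

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class Trajectory:
    """Time-ordered samples of the system state with dilution-event markers."""

    t: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    p: np.ndarray
    event: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.n_a = np.asarray(self.n_a, dtype=float)
        self.n_b = np.asarray(self.n_b, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.event is None:
            self.event = np.full(self.t.shape, EVENT_NONE, dtype=object)
        else:
            self.event = np.asarray(self.event, dtype=object)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def final_state(self) -> SystemState:
        return SystemState(
            n_a=float(self.n_a[-1]),
            n_b=float(self.n_b[-1]),
            p=float(self.p[-1]),
            t=float(self.t[-1]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "n_a": self.n_a, "n_b": self.n_b, "p": self.p, "event": self.event}
        )

    @classmethod
    def concatenate(cls, parts: Iterable["Trajectory"]) -> "Trajectory":
        parts = list(parts)
        return cls(
            t=np.concatenate([tr.t for tr in parts]),
            n_a=np.concatenate([tr.n_a for tr in parts]),
            n_b=np.concatenate([tr.n_b for tr in parts]),
            p=np.concatenate([tr.p for tr in parts]),
            event=np.concatenate([tr.event for tr in parts]),
        )


def _clean(y: np.ndarray, env: Environment, atol: float, n_max: np.ndarray) -> np.ndarray:
    """Clamp solver output back onto the invariant region.

    Densities with ``|n| < atol`` are set to 0 (absorbing extinction; a sign
    flip is never allowed to seed regrowth) and capped at the invariant
    bound ``max(n0, K)`` (the excess is accumulated solver drift against
    the flat above-K field); ``p`` is clipped to ``[0, 2b]``.
    """
    y = y.copy()
    y[0:2][np.abs(y[0:2]) < atol] = 0.0
    y[0:2] = np.clip(y[0:2], 0.0, n_max)
    y[2] = np.clip(y[2], 0.0, 2.0 * env.b)
    return y


def integrate(
    state0: SystemState,
    sp_a: SpeciesParams,
    sp_b: SpeciesParams,
    env: Environment,
    horizon: float = 200.0,
    solver_opts: dict | None = None,
    n_samples: int = 200,
) -> Trajectory:
    """Integrate the system from ``state0`` for ``horizon`` time units.

    Uses an adaptive explicit Runge–Kutta pair (``rtol=1e-8, atol=1e-10``
    default) sampled on a dense grid of ``n_samples`` points.  Output is
    clamped to the invariant region (nonnegative densities, ``p`` in
    ``[0, 2b]``) within solver tolerance only.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    method = opts.pop("method")
    t0 = state0.t
    t_eval = np.linspace(t0, t0 + horizon, n_samples)

    sol = solve_ivp(
        lambda t, y: rhs_vector(y, sp_a, sp_b, env),
        (t0, t0 + horizon),
        state0.as_vector(),
        method=method,
        t_eval=t_eval,
        **opts,
    )
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}", state0)
    n_max = np.array([max(state0.n_a, sp_a.K), max(state0.n_b, sp_b.K)])
    y = np.vstack(
        [_clean(sol.y[:, k], env, opts.get("atol", 1e-10), n_max) for k in range(sol.y.shape[1])]
    ).T
    return Trajectory(t=sol.t, n_a=y[0], n_b=y[1], p=y[2])


def euler_endpoint(
    state0: SystemState,
    sp_a: SpeciesParams,
    sp_b: SpeciesParams,
    env: Environment,
    horizon: float,
    dt: float = 1e-4,
) -> tuple[float, float, float]:
    """Fixed-step forward-Euler endpoint ``(n_a, n_b, p)``.

    Independent transcription of the governing equations used as a
    cross-check oracle for :func:`integrate`; deliberately does not share
    the adaptive solver's right-hand-side code path.
    """
    na, nb, p = state0.n_a, state0.n_b, state0.p
    two_b = 2.0 * env.b
    b2 = env.b**2
    n_steps = int(round(horizon / dt))
    for _ in range(n_steps):
        ga = math.exp(-((p - sp_a.p_pref) ** 2) / sp_a.sigma**2) - sp_a.delta
        gb = math.exp(-((p - sp_b.p_pref) ** 2) / sp_b.sigma**2) - sp_b.delta
        dna = na * max(1.0 - na / sp_a.K, 0.0) * ga
        dnb = nb * max(1.0 - nb / sp_b.K, 0.0) * gb
        dp = (sp_a.c * sp_a.d * na + sp_b.c * sp_b.d * nb) * p * (two_b - p) / b2
        na = max(na + dt * dna, 0.0)
        nb = max(nb + dt * dnb, 0.0)
        p = min(max(p + dt * dp, 0.0), two_b)
    return na, nb, p


def apply_dilution(
    state: SystemState, D: float, env: Environment, p0: float | None = None
) -> SystemState:
    """Instantaneous transfer into fresh medium: ``n -> n/D``, ``p`` mixed with ``p0``."""
    if D < 1:
        raise ValueError("dilution factor must be >= 1")
    p_fresh = env.p0 if p0 is None else p0
    return SystemState(
        n_a=state.n_a / D,
        n_b=state.n_b / D,
        p=state.p / D + (D - 1.0) / D * p_fresh,
        t=state.t,
    )


def run_serial_transfer(
    state0: SystemState,
    sp_a: SpeciesParams,
    sp_b: SpeciesParams,
    env: Environment,
    protocol: TransferProtocol,
    solver_opts: dict | None = None,
    samples_per_cycle: int = 200,
) -> Trajectory:
    """Alternate growth cycles with dilution events, ``n_cycles`` times.

    The pre-transfer proton concentration enters the reset formula.  Each
    dilution is recorded as a matched ``pre_dilution`` / ``post_dilution``
    sample pair; the post-transfer sample's time is nudged by an
    infinitesimal offset so trajectory time stays strictly increasing.
    """
    eps = 1e-9 * protocol.cycle_length
    parts: list[Trajectory] = []
    state = state0
    for cycle in range(protocol.n_cycles):
        tr = integrate(
            state, sp_a, sp_b, env, protocol.cycle_length, solver_opts, samples_per_cycle
        )
        if cycle > 0:
            # the post-dilution marker already holds this cycle's first state
            tr = Trajectory(
                t=tr.t[1:], n_a=tr.n_a[1:], n_b=tr.n_b[1:], p=tr.p[1:], event=tr.event[1:]
            )
        pre = tr.final_state
        tr.event[-1] = EVENT_PRE
        parts.append(tr)
        if cycle < protocol.n_cycles - 1:
            post = apply_dilution(pre, protocol.dilution_factor, env, protocol.p0)
            parts.append(
                Trajectory(
                    t=[post.t + eps],
                    n_a=[post.n_a],
                    n_b=[post.n_b],
                    p=[post.p],
                    event=[EVENT_POST],
                )
            )
            state = SystemState(post.n_a, post.n_b, post.p, t=post.t + eps)
    return Trajectory.concatenate(parts)


def write_trajectory_csv(traj: Trajectory, path, meta: dict | None = None) -> None:
    """Write a trajectory as CSV with ``#``-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        traj.to_dataframe().to_csv(fh, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path, comment="#")
    return Trajectory(
        t=df["t"].to_numpy(),
        n_a=df["n_a"].to_numpy(),
        n_b=df["n_b"].to_numpy(),
        p=df["p"].to_numpy(),
        event=df["event"].to_numpy(dtype=object),
    )
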