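"""Fixed points and linear stability of the density–proton system.

The system has three kinds of equilibria:

* the **sterile line** ``(0, 0, p)`` for every ``p`` — a continuum, so
  hyperbolic classification does not apply along the line; representative
  points are reported at grid nodes and only transverse stability is
  meaningful there;
* **boundary points** with each density at ``0`` or ``K`` and the proton
  drive shut off either by ``p`` at a scale boundary (``q(p) = 0``) or by a
  cancelling density combination;
* **niche-edge points** where a species' growth factor vanishes,
  ``p = p_pref ± sigma * sqrt(ln(1/delta))``.

Candidates are enumerated analytically, polished by Newton root-finding on
the full right-hand side, deduplicated, and classified from the eigenvalues
of the analytic Jacobian.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import Environment, SpeciesParams, SystemState, rhs_vector

__all__ = [
    "FixedPoint",
    "find_fixed_points",
    "jacobian_at",
    "classify_fixed_point",
    "write_fixed_point_csv",
]

CLASS_STABLE = "stable"
CLASS_UNSTABLE = "unstable"
CLASS_SADDLE = "saddle"
CLASS_NON_HYPERBOLIC = "non_hyperbolic"


@dataclass
class FixedPoint:
    """An equilibrium with its residual, eigenvalues and classification."""

    n_a: float
    n_b: float
    p: float
    residual: float
    eigenvalues: np.ndarray
    classification: str
    on_sterile_line: bool = False

    @property
    def state(self) -> SystemState:
        return SystemState(max(self.n_a, 0.0), max(self.n_b, 0.0), self.p)

    def surviving_species(self, threshold: float) -> tuple[bool, bool]:
        return (self.n_a >= threshold, self.n_b >= threshold)


def jacobian_at(
    state: SystemState | np.ndarray,
    sp_a: SpeciesParams,
    sp_b: SpeciesParams,
    env: Environment,
) -> np.ndarray:
    """Analytic 3x3 Jacobian of the right-hand side at a state."""
    if isinstance(state, SystemState):
        n_a, n_b, p = state.n_a, state.n_b, state.p
    else:
        n_a, n_b, p = float(state[0]), float(state[1]), float(state[2])
    b = env.b
    J = np.zeros((3, 3))
    drive = sp_a.c * sp_a.d * n_a + sp_b.c * sp_b.d * n_b
    q = p * (2.0 * b - p) / b**2
    dq = (2.0 * b - 2.0 * p) / b**2
    for i, (sp, n) in enumerate(((sp_a, n_a), (sp_b, n_b))):
        gauss = np.exp(-((p - sp.p_pref) ** 2) / sp.sigma**2)
        g = gauss - sp.delta
        dg = -2.0 * (p - sp.p_pref) / sp.sigma**2 * gauss
        J[i, i] = (1.0 - 2.0 * n / sp.K) * g
        J[i, 2] = n * (1.0 - n / sp.K) * dg
        J[2, i] = sp.c * sp.d * q
    J[2, 2] = drive * dq
    return J


def classify_fixed_point(eigenvalues: np.ndarray, tol: float = 1e-8) -> str:
    """Classification from eigenvalue real parts with tolerance ``tol``.

    Any eigenvalue with ``|Re| <= tol`` makes the point non-hyperbolic;
    otherwise all negative is stable, all positive unstable, mixed a saddle.
    """
    re = np.real(np.asarray(eigenvalues))
    if np.any(np.abs(re) <= tol):
        return CLASS_NON_HYPERBOLIC
    if np.all(re < 0):
        return CLASS_STABLE
    if np.all(re > 0):
        return CLASS_UNSTABLE
    return CLASS_SADDLE


def _niche_edge_ps(sp: SpeciesParams, env: Environment) -> list[float]:
    """Proton levels where the species' net growth factor crosses zero."""
    width = sp.sigma * np.sqrt(np.log(1.0 / sp.delta))
    return [
        p
        for p in (sp.p_pref - width, sp.p_pref + width)
        if 0.0 <= p <= 2.0 * env.b
    ]


def find_fixed_points(
    sp_a: SpeciesParams,
    sp_b: SpeciesParams,
    env: Environment,
    sterile_p_nodes: np.ndarray | None = None,
    polish_tol: float = 1e-12,
    dedup_radius: float = 1e-6,
    residual_tol: float = 1e-9,
) -> list[FixedPoint]:
    """Enumerate, polish and classify the system's fixed points.

    Returns polished candidates with residual norm below ``residual_tol``,
    deduplicated within ``dedup_radius``.  Sterile-line representatives (at
    ``sterile_p_nodes``, default eleven nodes across the scale) are kept as
    exact equilibria and flagged; they are not Newton-polished since every
    point of the line is an equilibrium.
    """
    two_b = 2.0 * env.b
    candidates: list[np.ndarray] = []

    p_specials = [0.0, two_b] + _niche_edge_ps(sp_a, env) + _niche_edge_ps(sp_b, env)
    for n_a, n_b in itertools.product((0.0, sp_a.K), (0.0, sp_b.K)):
        for p in p_specials:
            candidates.append(np.array([n_a, n_b, p]))
    # cancelling-drive interior candidates: drive = 0 with one density free
    ca, cb = sp_a.c * sp_a.d, sp_b.c * sp_b.d
    if ca != 0 and cb != 0 and np.sign(ca) != np.sign(cb):
        shared = sorted(set(_niche_edge_ps(sp_a, env)) & set(_niche_edge_ps(sp_b, env)))
        for n_b in (sp_b.K, 0.5 * sp_b.K):
            n_a = -cb * n_b / ca
            if 0.0 < n_a <= sp_a.K:
                for p in _niche_edge_ps(sp_b, env) + shared:
                    candidates.append(np.array([n_a, n_b, p]))

    fps: list[FixedPoint] = []

    def add(y: np.ndarray, sterile: bool = False) -> None:
        # restrict to the model's domain: the numerically hardened RHS is
        # flat above K, which would otherwise admit spurious equilibria
        if y[0] > sp_a.K + dedup_radius or y[1] > sp_b.K + dedup_radius:
            return
        res = float(np.linalg.norm(rhs_vector(y, sp_a, sp_b, env)))
        if res > residual_tol:
            return
        sterile = sterile or (y[0] < dedup_radius and y[1] < dedup_radius)
        for fp in fps:
            if (
                np.linalg.norm([fp.n_a - y[0], fp.n_b - y[1], fp.p - y[2]])
                < dedup_radius
            ):
                return
        ev = np.linalg.eigvals(jacobian_at(y, sp_a, sp_b, env))
        fps.append(
            FixedPoint(
                n_a=float(y[0]),
                n_b=float(y[1]),
                p=float(y[2]),
                residual=res,
                eigenvalues=ev,
                classification=classify_fixed_point(ev),
                on_sterile_line=sterile,
            )
        )

    for y0 in candidates:
        sol = optimize.root(
            lambda y: rhs_vector(y, sp_a, sp_b, env), y0, method="hybr", tol=polish_tol
        )
        y = sol.x if sol.success else y0
        # keep polished points inside the closed invariant region
        if y[0] < -dedup_radius or y[1] < -dedup_radius:
            continue
        if not (-dedup_radius <= y[2] <= two_b + dedup_radius):
            continue
        y = np.array([max(y[0], 0.0), max(y[1], 0.0), np.clip(y[2], 0.0, two_b)])
        add(y)

    if sterile_p_nodes is None:
        sterile_p_nodes = np.linspace(0.0, two_b, 11)
    for p in sterile_p_nodes:
        add(np.array([0.0, 0.0, float(p)]), sterile=True)

    return fps


def write_fixed_point_csv(fps: list[FixedPoint], path, meta: dict | None = None) -> None:
    import pandas as pd

    rows = []
    for fp in fps:
        ev = np.asarray(fp.eigenvalues)
        rows.append(
            {
                "n_a": fp.n_a,
                "n_b": fp.n_b,
                "p": fp.p,
                "class": fp.classification,
                "re_ev1": ev[0].real,
                "re_ev2": ev[1].real,
                "re_ev3": ev[2].real,
                "im_ev1": ev[0].imag,
                "im_ev2": ev[1].imag,
                "im_ev3": ev[2].imag,
                "residual": fp.residual,
                "sterile_line": int(fp.on_sterile_line),
            }
        )
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
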