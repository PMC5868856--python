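"""Coupled density–proton dynamics for pH-mediated microbial interactions.

Two bacterial populations grow logistically with a pH-dependent rate and in
turn shift the environmental proton concentration ``p``:

.. math::

    \\dot n_i &= n_i (1 - n_i/K_i)\\,\\bigl(e^{-(p - p_{pref,i})^2/\\sigma_i^2}
                 - \\delta_i\\bigr) \\\\
    \\dot p   &= \\Bigl(\\sum_i c_i d_i n_i\\Bigr)\\, q(p), \\qquad
    q(p) = \\frac{p\\,(2b - p)}{b^2}

Growth is maximal at the preferred proton concentration ``p_pref`` and turns
into death (at most rate ``delta``) far from it.  The quadratic boundary
factor ``q`` confines ``p`` to ``[0, 2b]``; it is normalized so that
``q(b) = 1`` at the mid-scale neutral point, which makes ``c*n`` directly
readable as a mid-scale drive rate.  ``p`` is an abstract proton scale:
high ``p`` displays as low pH and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "SpeciesParams",
    "Environment",
    "SystemState",
    "growth_rate_factor",
    "density_derivative",
    "proton_derivative",
    "system_rhs",
    "rhs_vector",
    "load_archetypes",
    "p_to_ph_display",
    "ph_display_to_p",
    "NULL_SPECIES",
]

#: Display-pH endpoints of the linear map onto the proton scale: the full
#: proton range [0, 2b] displays as pH 11 (p = 0) down to pH 2 (p = 2b).
#: Display convention only — p is an abstract scale, not -log10[H+].
PH_DISPLAY_HIGH = 11.0
PH_DISPLAY_LOW = 2.0


def p_to_ph_display(p, b: float = 5.0):
    """Map proton concentration onto the reversed display-pH axis."""
    return PH_DISPLAY_HIGH - (PH_DISPLAY_HIGH - PH_DISPLAY_LOW) * np.asarray(p, float) / (2.0 * b)


def ph_display_to_p(ph, b: float = 5.0):
    """Inverse of :func:`p_to_ph_display`."""
    return (PH_DISPLAY_HIGH - np.asarray(ph, float)) * 2.0 * b / (PH_DISPLAY_HIGH - PH_DISPLAY_LOW)


@dataclass(frozen=True)
class Environment:
    """Abiotic parameters: proton scale half-range ``b`` and fresh-medium ``p0``.

    The reachable proton scale is ``[0, 2b]``; ``p0`` is the proton
    concentration of fresh (dilution) medium.
    """

    b: float = 5.0
    p0: float = 5.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if not 0.0 <= self.p0 <= 2.0 * self.b:
            raise ValueError(f"p0 must lie in [0, {2 * self.b}], got {self.p0}")


@dataclass(frozen=True)
class SpeciesParams:
    """One species' pH niche and pH-drive parameters.

    Parameters
    ----------
    p_pref : float
        Preferred proton concentration (growth optimum), in ``[0, 2b]``.
    sigma : float
        Niche width of the Gaussian growth response, ``> 0``.
    delta : float
        Maximal death rate far from the optimum, in ``(0, 1)``.
    c : float
        Signed proton-drive coefficient: ``c > 0`` raises ``p``
        (acidifier on the display-pH convention), ``c < 0`` lowers it.
    d : float
        Relative drive strength multiplier (default 1); in a coculture,
        ``d = y`` means this species shifts ``p`` ``y`` times more strongly
        per unit density than a ``d = 1`` partner with equal ``|c|``.
    K : float
        Logistic carrying capacity, ``> 0``.
    """

    p_pref: float
    sigma: float
    delta: float
    c: float
    d: float = 1.0
    K: float = 10.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.d <= 0:
            raise ValueError(f"d must be > 0, got {self.d}")
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must lie in (0, 1), got {self.delta}")

    def with_(self, **kwargs) -> "SpeciesParams":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)

    def validate_against(self, env: Environment) -> None:
        if not 0.0 <= self.p_pref <= 2.0 * env.b:
            raise ValueError(
                f"p_pref={self.p_pref} outside the environment's proton "
                f"scale [0, {2 * env.b}]"
            )


#: Inert placeholder used for single-species runs (zero drive, never grows
#: from zero density).  Its niche parameters are irrelevant because the
#: absent species' density is pinned at 0.
NULL_SPECIES = SpeciesParams(p_pref=5.0, sigma=1.0, delta=0.5, c=0.0, name="none")


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state: two densities, proton concentration, time."""

    n_a: float
    n_b: float
    p: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError(f"densities must be >= 0, got ({self.n_a}, {self.n_b})")

    def as_vector(self) -> np.ndarray:
        return np.array([self.n_a, self.n_b, self.p], dtype=float)


def growth_rate_factor(p, sp: SpeciesParams):
    """Dimensionless growth-rate factor ``exp(-(p - p_pref)^2 / sigma^2) - delta``.

    Ranges over ``(-delta, 1 - delta]``: positive near the optimum, tending to
    the maximal death rate ``-delta`` far from it.  Accepts scalar or array ``p``.
    """
    p = np.asarray(p, dtype=float)
    out = np.exp(-((p - sp.p_pref) ** 2) / sp.sigma**2) - sp.delta
    return out if out.ndim else float(out)


def density_derivative(n, p, sp: SpeciesParams):
    """Logistic growth modulated by the pH niche: ``n (1 - n/K) g(p)``."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("density n must be >= 0")
    out = n_arr * (1.0 - n_arr / sp.K) * growth_rate_factor(p, sp)
    return out if out.ndim else float(out)


def _q(p, b: float):
    """Boundary-confining quadratic, normalized to 1 at the midpoint ``p=b``."""
    return p * (2.0 * b - p) / b**2


def proton_derivative(n_a, n_b, sp_a: SpeciesParams, sp_b: SpeciesParams, p, env: Environment):
    """Net proton drive ``(c_a d_a n_a + c_b d_b n_b) * q(p)``.

    Zero at the scale boundaries ``p = 0`` and ``p = 2b``; linear in each
    density at fixed ``p``.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 2.0 * env.b):
        raise ValueError(f"p must lie in [0, {2 * env.b}]")
    drive = sp_a.c * sp_a.d * np.asarray(n_a, float) + sp_b.c * sp_b.d * np.asarray(n_b, float)
    out = drive * _q(p_arr, env.b)
    return out if np.ndim(out) else float(out)


def system_rhs(
    state: SystemState, sp_a: SpeciesParams, sp_b: SpeciesParams, env: Environment
) -> tuple[float, float, float]:
    """Full right-hand side ``(dn_a/dt, dn_b/dt, dp/dt)`` at a state."""
    return (
        density_derivative(state.n_a, state.p, sp_a),
        density_derivative(state.n_b, state.p, sp_b),
        proton_derivative(state.n_a, state.n_b, sp_a, sp_b, state.p, env),
    )


def rhs_vector(
    y: np.ndarray, sp_a: SpeciesParams, sp_b: SpeciesParams, env: Environment
) -> np.ndarray:
    """Solver-facing RHS on the raw vector ``y = [n_a, n_b, p]``.

    Unlike :func:`system_rhs` this is total and numerically hardened:
    densities are floored at 0, and the logistic factor is clamped at 0
    (densities above ``K`` neither grow nor decay).  Without that clamp,
    ``n = K`` is repelling from above whenever the growth factor is
    negative, so a solver overshoot of order ``atol`` would seed a genuine
    blow-up; on the model's domain ``n <= K`` the clamp changes nothing.
    ``p`` is evaluated clipped to ``[0, 2b]`` for the same reason: outside
    the scale ``q(p) < 0`` reverses the drive's sign, so an overshoot
    followed by a drive-sign change would run away instead of returning.
    """
    n_a = max(y[0], 0.0)
    n_b = max(y[1], 0.0)
    p = min(max(y[2], 0.0), 2.0 * env.b)
    g_a = np.exp(-((p - sp_a.p_pref) ** 2) / sp_a.sigma**2) - sp_a.delta
    g_b = np.exp(-((p - sp_b.p_pref) ** 2) / sp_b.sigma**2) - sp_b.delta
    drive = sp_a.c * sp_a.d * n_a + sp_b.c * sp_b.d * n_b
    return np.array(
        [
            n_a * max(1.0 - n_a / sp_a.K, 0.0) * g_a,
            n_b * max(1.0 - n_b / sp_b.K, 0.0) * g_b,
            drive * _q(p, env.b),
        ]
    )


def load_archetypes(path=None) -> tuple[dict[str, SpeciesParams], Environment]:
    """Load the shipped (or a user) archetype configuration.

    Returns a mapping of archetype name to :class:`SpeciesParams` plus the
    shared :class:`Environment`.  The shipped file declares four species
    archetypes spanning the four single-species characters: two
    self-benefiting environment modifiers (acid-loving acidifier,
    alkali-loving alkalizer) and two self-harming ones.
    """
    if path is None:
        text = resources.files("phfeedback.data").joinpath("archetypes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    env = Environment(**raw["environment"])
    species = {}
    for name, kw in raw["species"].items():
        sp = SpeciesParams(name=name, **kw)
        sp.validate_against(env)
        species[name] = sp
    return species, env
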