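"""Phase diagrams: initial-condition sweeps, survival calls, motif labels.

A sweep integrates the model over a 2-D grid of initial conditions (initial
density or species-A fraction x initial proton concentration), calls
survival of each species from its final density, and a rule-based classifier
maps the mono- and coculture grids to one of the interaction motifs:

``allee``
    survival of a single species requires a minimal initial density;
``ecological_suicide``
    a single species' own environmental drive kills it everywhere;
``bistability``
    two alternative sole-survivor outcomes selected by initial conditions;
``successive_growth``
    one species survives in coculture only because the partner first moved
    the environment into its niche;
``extended_suicide``
    a self-killing species' drive also kills a partner that would survive
    alone;
``stabilization``
    two self-killing species with opposing drives rescue each other;
``oscillatory_coexistence``
    sustained oscillations keep both species above threshold;
``coexistence`` / ``exclusion``
    the remaining outcomes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .model import Environment, SpeciesParams, SystemState, NULL_SPECIES
from .simulate import Trajectory, integrate

__all__ = [
    "MotifLabel",
    "OutcomeGrid",
    "MotifConflictError",
    "classify_survival",
    "count_final_oscillations",
    "sweep_single",
    "sweep_pair",
    "allee_threshold",
    "species_character",
    "label_motif",
    "write_outcome_csv",
    "read_outcome_csv",
]


class MotifLabel(str, enum.Enum):
    ALLEE = "allee"
    ECOLOGICAL_SUICIDE = "ecological_suicide"
    BISTABILITY = "bistability"
    SUCCESSIVE_GROWTH = "successive_growth"
    EXTENDED_SUICIDE = "extended_suicide"
    STABILIZATION = "stabilization"
    COEXISTENCE = "coexistence"
    EXCLUSION = "exclusion"
    OSCILLATORY_COEXISTENCE = "oscillatory_coexistence"


class MotifConflictError(ValueError):
    """More than one motif rule matched under strict evaluation."""


@dataclass
class OutcomeGrid:
    """Survival flags and final states over a 2-D initial-condition grid.

    ``axis1`` is either an initial-density grid (single-species sweeps) or a
    species-A fraction grid (pair sweeps); ``axis2`` is always the initial
    proton concentration.  Arrays are indexed ``[i_axis1, i_axis2]``.  Pair
    sweeps optionally carry matched monoculture reference runs
    (``a_alone_survives`` / ``b_alone_survives``): species A alone started
    from the same density ``f * N`` and initial ``p`` as the coculture cell.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    a_survives: np.ndarray
    b_survives: np.ndarray
    n_a_final: np.ndarray
    n_b_final: np.ndarray
    p_final: np.ndarray
    oscillatory: np.ndarray
    kind: str  # "single" | "pair"
    axis1_name: str = "density"
    a_alone_survives: np.ndarray | None = None
    b_alone_survives: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        i1, i2 = np.meshgrid(
            np.arange(len(self.axis1)), np.arange(len(self.axis2)), indexing="ij"
        )
        cell = np.where(
            self.oscillatory,
            "oscillatory",
            np.where(
                self.a_survives & self.b_survives,
                "coexist",
                np.where(
                    self.a_survives,
                    "only_a",
                    np.where(self.b_survives, "only_b", "none"),
                ),
            ),
        )
        df = pd.DataFrame(
            {
                "axis1": self.axis1[i1.ravel()],
                "axis2": self.axis2[i2.ravel()],
                "a_survives": self.a_survives.ravel().astype(int),
                "b_survives": self.b_survives.ravel().astype(int),
                "n_a_final": self.n_a_final.ravel(),
                "n_b_final": self.n_b_final.ravel(),
                "p_final": self.p_final.ravel(),
                "motif_cell": cell.ravel(),
            }
        )
        return df


def classify_survival(
    traj: Trajectory, extinction_threshold: float
) -> tuple[bool, bool]:
    """A species survives iff its final density is at or above threshold."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return (
        bool(traj.n_a[-1] >= extinction_threshold),
        bool(traj.n_b[-1] >= extinction_threshold),
    )


def count_final_oscillations(
    t: np.ndarray, n: np.ndarray, threshold: float, tail_fraction: float = 0.3
) -> int:
    """Number of prominent local maxima of ``n(t)`` in the trajectory tail.

    Maxima must rise above ``threshold`` with prominence of at least
    ``threshold``, so numerical jitter around a steady level never counts
    as oscillation.
    """
    t = np.asarray(t)
    cut = t[-1] - tail_fraction * (t[-1] - t[0])
    tail = np.asarray(n)[t >= cut]
    if len(tail) < 3:
        return 0
    peaks, _ = find_peaks(tail, height=threshold, prominence=threshold)
    return int(len(peaks))


def _default_threshold(*species: SpeciesParams) -> float:
    return 1e-3 * max(sp.K for sp in species)


def sweep_single(
    sp: SpeciesParams,
    env: Environment,
    density_grid: np.ndarray | None = None,
    p0_grid: np.ndarray | None = None,
    horizon: float = 200.0,
    extinction_threshold: float | None = None,
    solver_opts: dict | None = None,
) -> OutcomeGrid:
    """Monoculture phase diagram over (initial density, initial ``p``)."""
    if density_grid is None:
        density_grid = np.geomspace(1e-4 * sp.K, 0.9 * sp.K, 21)
    if p0_grid is None:
        p0_grid = np.linspace(0.5, 9.5, 21)
    density_grid = np.asarray(density_grid, float)
    p0_grid = np.asarray(p0_grid, float)
    if density_grid.size == 0 or p0_grid.size == 0:
        raise ValueError("grids must be non-empty")
    thr = extinction_threshold if extinction_threshold is not None else _default_threshold(sp)
    shape = (len(density_grid), len(p0_grid))
    surv = np.zeros(shape, bool)
    n_f = np.zeros(shape)
    p_f = np.zeros(shape)
    osc = np.zeros(shape, bool)
    for i, n0 in enumerate(density_grid):
        for j, p0 in enumerate(p0_grid):
            tr = integrate(
                SystemState(n0, 0.0, p0), sp, NULL_SPECIES, env, horizon, solver_opts
            )
            surv[i, j], _ = classify_survival(tr, thr)
            n_f[i, j] = tr.n_a[-1]
            p_f[i, j] = tr.p[-1]
            osc[i, j] = count_final_oscillations(tr.t, tr.n_a, thr) >= 2
    return OutcomeGrid(
        axis1=density_grid,
        axis2=p0_grid,
        a_survives=surv,
        b_survives=np.zeros(shape, bool),
        n_a_final=n_f,
        n_b_final=np.zeros(shape),
        p_final=p_f,
        oscillatory=osc,
        kind="single",
        axis1_name="density",
        meta={"species": sp.name, "threshold": thr, "horizon": horizon},
    )


def sweep_pair(
    sp_a: SpeciesParams,
    sp_b: SpeciesParams,
    env: Environment,
    fraction_grid: np.ndarray | None = None,
    p0_grid: np.ndarray | None = None,
    total_density: float | None = None,
    horizon: float = 200.0,
    extinction_threshold: float | None = None,
    solver_opts: dict | None = None,
    include_alone: bool = True,
) -> OutcomeGrid:
    """Coculture phase diagram over (species-A fraction, initial ``p``).

    Initial densities per cell are ``(f*N, (1-f)*N)`` with total inoculum
    ``N`` (default ``0.1 * max(K)``, a 1:100-scale starting inoculum).  With
    ``include_alone`` each cell also runs both matched monocultures, which
    the motif classifier compares against.
    """
    if fraction_grid is None:
        fraction_grid = np.linspace(0.0, 1.0, 21)
    if p0_grid is None:
        p0_grid = np.linspace(0.5, 9.5, 21)
    fraction_grid = np.asarray(fraction_grid, float)
    p0_grid = np.asarray(p0_grid, float)
    if np.any((fraction_grid < 0) | (fraction_grid > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    N = total_density if total_density is not None else 0.1 * max(sp_a.K, sp_b.K)
    thr = (
        extinction_threshold
        if extinction_threshold is not None
        else _default_threshold(sp_a, sp_b)
    )
    shape = (len(fraction_grid), len(p0_grid))
    surv_a = np.zeros(shape, bool)
    surv_b = np.zeros(shape, bool)
    alone_a = np.zeros(shape, bool)
    alone_b = np.zeros(shape, bool)
    n_a_f = np.zeros(shape)
    n_b_f = np.zeros(shape)
    p_f = np.zeros(shape)
    osc = np.zeros(shape, bool)
    for i, f in enumerate(fraction_grid):
        for j, p0 in enumerate(p0_grid):
            tr = integrate(
                SystemState(f * N, (1.0 - f) * N, p0), sp_a, sp_b, env, horizon, solver_opts
            )
            surv_a[i, j], surv_b[i, j] = classify_survival(tr, thr)
            n_a_f[i, j] = tr.n_a[-1]
            n_b_f[i, j] = tr.n_b[-1]
            p_f[i, j] = tr.p[-1]
            # oscillatory coexistence: both species persist (steadily or by
            # cycling above threshold) and at least one of them cycles
            osc_a = count_final_oscillations(tr.t, tr.n_a, thr) >= 2
            osc_b = count_final_oscillations(tr.t, tr.n_b, thr) >= 2
            persist_a = surv_a[i, j] or osc_a
            persist_b = surv_b[i, j] or osc_b
            osc[i, j] = (osc_a or osc_b) and persist_a and persist_b
            if include_alone:
                tra = integrate(
                    SystemState(f * N, 0.0, p0), sp_a, NULL_SPECIES, env, horizon, solver_opts
                )
                alone_a[i, j] = tra.n_a[-1] >= thr
                trb = integrate(
                    SystemState(0.0, (1.0 - f) * N, p0), NULL_SPECIES, sp_b, env, horizon, solver_opts
                )
                alone_b[i, j] = trb.n_b[-1] >= thr
    return OutcomeGrid(
        axis1=fraction_grid,
        axis2=p0_grid,
        a_survives=surv_a,
        b_survives=surv_b,
        n_a_final=n_a_f,
        n_b_final=n_b_f,
        p_final=p_f,
        oscillatory=osc,
        kind="pair",
        axis1_name="fraction_a",
        a_alone_survives=alone_a if include_alone else None,
        b_alone_survives=alone_b if include_alone else None,
        meta={
            "species_a": sp_a.name,
            "species_b": sp_b.name,
            "total_density": N,
            "threshold": thr,
            "horizon": horizon,
        },
    )


def allee_threshold(
    sp: SpeciesParams,
    env: Environment,
    p0: float,
    horizon: float = 200.0,
    bracket: tuple[float, float] | None = None,
    rel_tol: float = 1e-3,
    extinction_threshold: float | None = None,
    solver_opts: dict | None = None,
) -> float | None:
    """Critical initial density separating extinction from survival at ``p0``.

    Bisects the survival boundary on a log-density scale to relative
    tolerance ``rel_tol``.  Returns ``None`` when no threshold exists in the
    bracket (survival identical at both ends — e.g. a favorable ``p0`` where
    the species survives at any tested density, or a self-killing species
    that dies at every density).
    """
    thr = extinction_threshold if extinction_threshold is not None else _default_threshold(sp)
    lo, hi = bracket if bracket is not None else (1e-4 * sp.K, 0.9 * sp.K)

    def survives(n0: float) -> bool:
        tr = integrate(SystemState(n0, 0.0, p0), sp, NULL_SPECIES, env, horizon, solver_opts)
        return tr.n_a[-1] >= thr

    s_lo, s_hi = survives(lo), survives(hi)
    if s_lo == s_hi:
        return None
    while hi / lo > 1.0 + rel_tol:
        mid = float(np.sqrt(lo * hi))
        if survives(mid) == s_hi:
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))


def species_character(grid: OutcomeGrid) -> str:
    """Single-species character from a monoculture sweep.

    ``"suicide"``     extinct in every cell;
    ``"conditional"`` survival depends on initial density at some initial
                      ``p`` (an Allee wedge);
    ``"robust"``      survival depends at most on initial ``p``.
    """
    if grid.kind != "single":
        raise ValueError("species_character expects a single-species grid")
    s = grid.a_survives
    if not s.any():
        return "suicide"
    density_dependent = np.any(s.any(axis=0) & ~s.all(axis=0))
    return "conditional" if density_dependent else "robust"


def _check_axes(*grids: OutcomeGrid) -> None:
    ref = grids[0].axis2
    for g in grids[1:]:
        if len(g.axis2) != len(ref) or not np.allclose(g.axis2, ref):
            raise ValueError("grids must share the initial-p axis")


def label_motif(
    grid_a: OutcomeGrid,
    grid_b: OutcomeGrid,
    grid_pair: OutcomeGrid,
    min_cells: int = 1,
    strict: bool = False,
) -> MotifLabel:
    """Rule-based interaction-motif label for a species pair.

    ``grid_a`` / ``grid_b`` are the monoculture sweeps (used for each
    species' single-species character); ``grid_pair`` is the coculture sweep
    and must carry matched monoculture reference runs.  Rules are evaluated
    in a declared order; with ``strict=True`` a case matching more than one
    rule raises :class:`MotifConflictError` instead of using the order.
    """
    _check_axes(grid_a, grid_b, grid_pair)
    if grid_pair.a_alone_survives is None or grid_pair.b_alone_survives is None:
        raise ValueError("grid_pair must be swept with include_alone=True")

    char_a = species_character(grid_a)
    char_b = species_character(grid_b)
    sa, sb = grid_pair.a_survives, grid_pair.b_survives
    aa, ab = grid_pair.a_alone_survives, grid_pair.b_alone_survives
    osc = grid_pair.oscillatory
    both = (sa & sb) | osc
    only_a = sa & ~sb & ~osc
    only_b = sb & ~sa & ~osc
    none = ~sa & ~sb & ~osc

    matches: list[MotifLabel] = []

    if char_a == "suicide" and char_b == "suicide":
        if both.sum() >= min_cells:
            matches.append(MotifLabel.STABILIZATION)
    elif char_a == "suicide" or char_b == "suicide":
        # X is the self-killer, Y the partner.
        y_pair, y_alone = (sb, ab) if char_a == "suicide" else (sa, aa)
        rescued = y_pair & ~y_alone  # Y lives only with X conditioning the medium
        murdered = none & y_alone  # X's drive also kills Y where Y lives alone
        if rescued.sum() >= min_cells:
            matches.append(MotifLabel.SUCCESSIVE_GROWTH)
        if murdered.sum() >= min_cells:
            matches.append(MotifLabel.EXTENDED_SUICIDE)
    else:
        # Winner selected by initial conditions: both sole-survivor regions
        # occur, somewhere within the same initial-p column.
        col_has_both = (only_a.any(axis=0) & only_b.any(axis=0)).any()
        if only_a.sum() >= min_cells and only_b.sum() >= min_cells and col_has_both:
            matches.append(MotifLabel.BISTABILITY)

    if strict and len(matches) > 1:
        raise MotifConflictError(
            f"multiple motif rules matched: {[m.value for m in matches]}"
        )
    if matches:
        return matches[0]

    # Fallbacks: no environmental-feedback motif fired.
    if osc.sum() >= min_cells and both.sum() <= osc.sum():
        return MotifLabel.OSCILLATORY_COEXISTENCE
    if both.sum() >= min_cells:
        return MotifLabel.COEXISTENCE
    if only_a.any() or only_b.any():
        return MotifLabel.EXCLUSION
    return MotifLabel.ECOLOGICAL_SUICIDE


def write_outcome_csv(grid: OutcomeGrid, path, meta: dict | None = None) -> None:
    """Long-format CSV with ``#``-prefixed metadata header lines."""
    header = dict(grid.meta)
    header.update(meta or {})
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"# kind: {grid.kind}\n")
        fh.write(f"# axis1_name: {grid.axis1_name}\n")
        grid.to_dataframe().to_csv(fh, index=False)


def read_outcome_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
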