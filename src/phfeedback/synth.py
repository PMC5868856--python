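"""Experiment-like synthetic datasets with known ground truth.

Three table kinds mirror the wet-lab assays the pipeline consumes:

* **fold-growth vs initial pH** — growth in buffered, low-nutrient medium,
  so the proton concentration is held frozen during the assay; fold growth
  over the assay window follows the logistic closed form and is corrupted
  by lognormal noise;
* **endpoint pH** — unbuffered growth from a common starting pH; the final
  pH reports the species' drive direction, corrupted by pH-meter noise;
* **daily serial-transfer records** — the serial-transfer simulator
  provides ground-truth densities; each day's density is observed through a
  simulated dilution-plating series with Poisson colony counts, and the pH
  through Gaussian meter noise.

Ground truth is always emitted next to the noisy values so parameter- and
outcome-recovery can be scored.  All randomness flows through a single
integer-seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    Environment,
    SpeciesParams,
    SystemState,
    NULL_SPECIES,
    growth_rate_factor,
    p_to_ph_display,
    ph_display_to_p,
)
from .simulate import TransferProtocol, run_serial_transfer, EVENT_PRE

__all__ = [
    "DilutionSpec",
    "NoiseModel",
    "expected_fold_growth",
    "gen_growth_vs_ph",
    "gen_ph_endpoint_table",
    "plating_counts",
    "gen_serial_transfer_dataset",
]


@dataclass(frozen=True)
class DilutionSpec:
    """Serial 10-fold dilution row plated as fixed-volume spots.

    ``n_steps`` spots are plated: the undiluted sample plus ``n_steps - 1``
    successive ``fold``-fold dilutions.  A spot is countable when its colony
    count lies in ``[min_count, max_count]``.
    """

    fold: float = 10.0
    n_steps: int = 8
    volume: float = 0.01  # plated volume per spot (mL; 10 uL)
    min_count: int = 1
    max_count: int = 300

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("dilution fold must be > 1")
        if self.n_steps < 1:
            raise ValueError("need at least one dilution step")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise magnitudes (declared defaults, all configurable).

    ``growth_sd`` is the standard deviation of lognormal multiplicative
    noise on fold growth; ``ph_sd`` the Gaussian pH-meter noise in display
    units; ``cfu_per_density`` converts model density units into CFU/mL for
    plating (carrying capacity 10 then corresponds to 1e8 CFU/mL).
    """

    growth_sd: float = 0.1
    ph_sd: float = 0.05
    cfu_per_density: float = 1e7
    dilution: DilutionSpec = field(default_factory=DilutionSpec)

    def __post_init__(self) -> None:
        if self.growth_sd < 0 or self.ph_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def expected_fold_growth(
    sp: SpeciesParams, p: float, tau: float = 5.0, n0_frac: float = 1e-3
) -> float:
    """Noise-free fold growth over an assay window ``tau`` at frozen ``p``.

    With the proton concentration clamped (buffered medium), the density
    follows a logistic with constant rate ``g(p)``; the fold is the closed
    form ``e^{g tau} / (1 + n0_frac (e^{g tau} - 1))`` where ``n0_frac`` is
    the inoculum as a fraction of carrying capacity.  ``n0_frac = 0`` gives
    the pure exponential-phase fold ``e^{g tau}``.
    """
    g = growth_rate_factor(p, sp)
    e = math.exp(g * tau)
    return e / (1.0 + n0_frac * (e - 1.0))


def gen_growth_vs_ph(
    sp: SpeciesParams,
    env: Environment,
    ph_grid: np.ndarray | None = None,
    replicates: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
    tau: float = 5.0,
    n0_frac: float = 1e-3,
) -> pd.DataFrame:
    """Fold-growth vs initial pH table (buffered-assay emulation).

    ``ph_grid`` is in display-pH units (default 10 levels spanning the
    displayable scale); output columns are
    ``species, pH_initial, replicate, fold_growth, true_fold``.
    """
    noise = noise or NoiseModel()
    if ph_grid is None:
        ph_grid = np.linspace(2.5, 10.5, 10)
    rng = np.random.default_rng(seed)
    rows = []
    for ph in np.asarray(ph_grid, float):
        p = float(ph_display_to_p(ph, env.b))
        true_fold = expected_fold_growth(sp, p, tau, n0_frac)
        for rep in range(replicates):
            fold = true_fold * math.exp(rng.normal(0.0, noise.growth_sd)) if noise.growth_sd > 0 else true_fold
            rows.append(
                {
                    "species": sp.name,
                    "pH_initial": ph,
                    "replicate": rep,
                    "fold_growth": fold,
                    "true_fold": true_fold,
                }
            )
    return pd.DataFrame(rows)


def gen_ph_endpoint_table(
    sp: SpeciesParams,
    env: Environment,
    initial_ph: float = 7.0,
    replicates: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
    tau: float = 5.0,
    n0: float | None = None,
) -> pd.DataFrame:
    """Endpoint-pH table: grow unbuffered from ``initial_ph``, report final pH."""
    from .simulate import integrate

    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    p0 = float(ph_display_to_p(initial_ph, env.b))
    n_start = 0.1 * sp.K if n0 is None else n0
    tr = integrate(SystemState(n_start, 0.0, p0), sp, NULL_SPECIES, env, tau)
    ph_final_true = float(p_to_ph_display(tr.p[-1], env.b))
    rows = [
        {
            "species": sp.name,
            "pH_initial": initial_ph,
            "pH_final": ph_final_true + rng.normal(0.0, noise.ph_sd),
            "replicate": rep,
            "true_pH_final": ph_final_true,
        }
        for rep in range(replicates)
    ]
    return pd.DataFrame(rows)


def plating_counts(
    true_density: float,
    dilution: DilutionSpec | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, float, bool]:
    """Simulate a dilution-plating series and the CFU estimate read from it.

    ``true_density`` is in CFU/mL.  Spot ``k`` receives a Poisson count with
    mean ``density * volume * fold^-k``.  The estimate is read from the
    first (least diluted) spot whose count is countable, back-multiplied by
    its dilution; all-zero counts give estimate 0 flagged below detection.

    Returns ``(counts, cfu_estimate, below_detection)``.
    """
    if true_density < 0:
        raise ValueError("density must be >= 0")
    dil = dilution or DilutionSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    means = true_density * dil.volume * dil.fold ** -np.arange(dil.n_steps)
    counts = rng.poisson(means)
    for k in range(dil.n_steps):
        if dil.min_count <= counts[k] <= dil.max_count:
            return counts, counts[k] / dil.volume * dil.fold**k, False
    # nothing countable: saturated everywhere or sterile
    if counts[-1] > dil.max_count:
        return counts, counts[-1] / dil.volume * dil.fold ** (dil.n_steps - 1), False
    return counts, 0.0, True


def gen_serial_transfer_dataset(
    sp_a: SpeciesParams,
    sp_b: SpeciesParams,
    env: Environment,
    protocol: TransferProtocol,
    noise: NoiseModel | None = None,
    seed: int = 0,
    state0: SystemState | None = None,
    well_id: str = "w0",
    solver_opts: dict | None = None,
) -> pd.DataFrame:
    """Daily CFU and pH records from a simulated serial-transfer experiment.

    Runs the serial-transfer simulator for ground truth, then observes each
    cycle-end (pre-dilution) state through plating noise and pH-meter
    noise.  Species with a ``NULL_SPECIES``-like zero drive and zero
    density are skipped.  Columns: ``day, species, cfu_estimate,
    below_detection, counts, measured_pH, well, true_density, true_p``.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    if state0 is None:
        state0 = SystemState(0.05 * sp_a.K, 0.05 * sp_b.K, env.p0)
    traj = run_serial_transfer(state0, sp_a, sp_b, env, protocol, solver_opts)
    pre_idx = np.flatnonzero(traj.event == EVENT_PRE)
    rows = []
    for day, idx in enumerate(pre_idx, start=1):
        ph_meas = float(p_to_ph_display(traj.p[idx], env.b)) + rng.normal(0.0, noise.ph_sd)
        for label, dens, sp in (
            ("a", traj.n_a[idx], sp_a),
            ("b", traj.n_b[idx], sp_b),
        ):
            if sp is NULL_SPECIES:
                continue
            counts, cfu, below = plating_counts(
                dens * noise.cfu_per_density, noise.dilution, rng
            )
            rows.append(
                {
                    "day": day,
                    "species": sp.name or label,
                    "cfu_estimate": cfu,
                    "below_detection": below,
                    "counts": ";".join(map(str, counts)),
                    "measured_pH": ph_meas,
                    "well": well_id,
                    "true_density": dens,
                    "true_p": traj.p[idx],
                }
            )
    return pd.DataFrame(rows)
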