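"""Discrete-time fuzzy-logic counterpart of the density–proton ODE model.

Instead of defined rate functions, growth and environmental drive are
expressed as linguistic rules over fuzzy partitions ("IF pH is low AND
preferred_pH is low THEN cell_density_change is positive"), evaluated by
Mamdani inference: AND is ``min``, rule aggregation is ``max``, and the
crisp output is the centroid of the aggregated clipped output sets.  Each
iteration both species' densities and the shared pH value are updated
synchronously by the gain-scaled crisp outputs and clamped to their
universes.

The pH universe is the display image ``[2, 11]`` of the ODE model's proton
scale (high proton = low pH), so the fuzzy boundaries coincide with the
ODE's saturating scale boundaries.  Densities are normalized to ``[0, 1]``
(1 = carrying capacity).  A species' ``ph_change_ability`` is the *sign* of
its pH drive on the display scale (+1 raises pH, i.e. an alkalizer); the
``relative_strength`` multiplier scales species B's pH contribution, the
fuzzy analog of the ODE's relative drive strength ``d``.

All membership breakpoints, rule lists and the step gain are declared in
the shipped ``data/fuzzy_default.yaml`` so alternatives are drop-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .model import SpeciesParams, Environment, p_to_ph_display
from .outcomes import OutcomeGrid, count_final_oscillations

__all__ = [
    "Trapezoid",
    "Partition",
    "Rule",
    "FuzzyConfig",
    "FuzzySpecies",
    "FuzzyState",
    "FuzzyTrajectory",
    "NoRuleFiredError",
    "load_fuzzy_config",
    "fuzzify",
    "infer_density_change",
    "infer_ph_change",
    "fuzzy_iterate",
    "fuzzy_sweep_single",
    "fuzzy_sweep_pair",
]


class NoRuleFiredError(RuntimeError):
    """No rule produced any activation — universe/rule misconfiguration."""


@dataclass(frozen=True)
class Trapezoid:
    """Piecewise-linear membership function (a <= b <= c <= d); b == c is a triangle."""

    a: float
    b: float
    c: float
    d: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.b > self.a:
            rising = (x > self.a) & (x < self.b)
            out[rising] = (x[rising] - self.a) / (self.b - self.a)
        out[(x >= self.b) & (x <= self.c)] = 1.0
        if self.d > self.c:
            falling = (x > self.c) & (x < self.d)
            out[falling] = (self.d - x[falling]) / (self.d - self.c)
        return out


@dataclass(frozen=True)
class Partition:
    """Named, labeled membership functions over a declared universe."""

    name: str
    universe: tuple[float, float]
    mfs: dict[str, Trapezoid]

    def fuzzify(self, value) -> dict[str, np.ndarray]:
        v = np.asarray(value, dtype=float)
        lo, hi = self.universe
        if np.any((v < lo - 1e-9) | (v > hi + 1e-9)):
            raise ValueError(
                f"value outside universe [{lo}, {hi}] of partition '{self.name}'"
            )
        return {label: mf(v) for label, mf in self.mfs.items()}


def fuzzify(value, partition: Partition) -> dict[str, np.ndarray]:
    """Membership degrees of ``value`` for every label of ``partition``."""
    return partition.fuzzify(value)


@dataclass(frozen=True)
class Rule:
    """IF <antecedents> THEN <consequent label>.

    Antecedents map a variable name to one or more labels; several labels
    for one variable are OR-ed (max), distinct variables are AND-ed (min).
    """

    antecedents: dict[str, tuple[str, ...]]
    consequent: str

    def firing(self, memberships: dict[str, dict[str, np.ndarray]]) -> np.ndarray:
        strength = None
        for var, labels in self.antecedents.items():
            mu = np.maximum.reduce([memberships[var][lab] for lab in labels])
            strength = mu if strength is None else np.minimum(strength, mu)
        return strength


def _mamdani(
    rules: list[Rule],
    memberships: dict[str, dict[str, np.ndarray]],
    out: Partition,
    n_disc: int = 241,
) -> np.ndarray:
    """Min–max Mamdani inference with centroid defuzzification.

    Vectorized over any common broadcast shape of the membership arrays;
    returns the crisp output with that shape.
    """
    y = np.linspace(out.universe[0], out.universe[1], n_disc)
    agg_by_label: dict[str, np.ndarray] = {}
    for rule in rules:
        f = rule.firing(memberships)
        prev = agg_by_label.get(rule.consequent)
        agg_by_label[rule.consequent] = f if prev is None else np.maximum(prev, f)
    agg = None
    for label, f in agg_by_label.items():
        mf_y = out.mfs[label](y)  # (n_disc,)
        clipped = np.minimum(f[..., None], mf_y)
        agg = clipped if agg is None else np.maximum(agg, clipped)
    if agg is None:
        raise NoRuleFiredError("rule base is empty")
    area = agg.sum(axis=-1)
    if np.any(area <= 0):
        raise NoRuleFiredError(
            "no rule fired for some input (centroid undefined); "
            "check universe coverage of the rule base"
        )
    return (agg * y).sum(axis=-1) / area


@dataclass(frozen=True)
class FuzzySpecies:
    """Linguistic species description: preferred display pH and drive sign."""

    preferred_pH: float
    ph_change_ability: int  # +1 raises pH, -1 lowers it
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.ph_change_ability not in (-1, 1):
            raise ValueError("ph_change_ability must be -1 or +1")

    @classmethod
    def from_species_params(cls, sp: SpeciesParams, env: Environment) -> "FuzzySpecies":
        """Translate ODE parameters: p_pref maps to display pH; a positive
        proton drive (c > 0) lowers display pH, so ability = -sign(c)."""
        if sp.c == 0:
            raise ValueError("fuzzy species needs a nonzero drive direction")
        return cls(
            preferred_pH=float(p_to_ph_display(sp.p_pref, env.b)),
            ph_change_ability=-int(np.sign(sp.c)),
            name=sp.name,
        )


@dataclass
class FuzzyConfig:
    """Partitions, rule bases and iteration parameters of the fuzzy model."""

    partitions: dict[str, Partition]
    density_rules: list[Rule]
    ph_rules: list[Rule]
    gain: float = 0.05
    n_iterations: int = 200
    relative_strength: float = 1.0
    n_disc: int = 241

    def __post_init__(self) -> None:
        if self.relative_strength <= 0:
            raise ValueError("relative_strength must be > 0")
        for rule, outvar in [(r, "cell_density_change") for r in self.density_rules] + [
            (r, "pH_change") for r in self.ph_rules
        ]:
            for var, labels in rule.antecedents.items():
                part = self.partitions.get(var)
                if part is None:
                    raise ValueError(f"rule references undeclared partition '{var}'")
                for lab in labels:
                    if lab not in part.mfs:
                        raise ValueError(f"rule references unknown label '{var}.{lab}'")
            if rule.consequent not in self.partitions[outvar].mfs:
                raise ValueError(
                    f"rule consequent '{rule.consequent}' not in partition '{outvar}'"
                )


def _parse_rules(raw: list[dict]) -> list[Rule]:
    rules = []
    for entry in raw:
        ants = {
            var: tuple([labs] if isinstance(labs, str) else labs)
            for var, labs in entry["if"].items()
        }
        rules.append(Rule(antecedents=ants, consequent=entry["then"]))
    return rules


def load_fuzzy_config(path=None, **overrides) -> FuzzyConfig:
    """Load the shipped (or a user) fuzzy model configuration."""
    if path is None:
        text = resources.files("phfeedback.data").joinpath("fuzzy_default.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    partitions = {}
    for name, spec in raw["partitions"].items():
        if isinstance(spec, str):  # alias: reuse another partition's shape
            src = partitions[spec]
            partitions[name] = Partition(name=name, universe=src.universe, mfs=src.mfs)
            continue
        mfs = {lab: Trapezoid(*pts) for lab, pts in spec["mfs"].items()}
        partitions[name] = Partition(
            name=name, universe=tuple(spec["universe"]), mfs=mfs
        )
    kwargs = dict(
        partitions=partitions,
        density_rules=_parse_rules(raw["density_rules"]),
        ph_rules=_parse_rules(raw["ph_rules"]),
        gain=float(raw.get("gain", 0.05)),
        n_iterations=int(raw.get("n_iterations", 200)),
        relative_strength=float(raw.get("relative_strength", 1.0)),
    )
    kwargs.update(overrides)
    return FuzzyConfig(**kwargs)


def infer_density_change(pH, preferred_pH, cell_density, config: FuzzyConfig):
    """Gain-scaled crisp per-iteration density change for one species."""
    memberships = {
        "pH": config.partitions["pH"].fuzzify(pH),
        "preferred_pH": config.partitions["preferred_pH"].fuzzify(preferred_pH),
        "cell_density": config.partitions["cell_density"].fuzzify(cell_density),
    }
    crisp = _mamdani(
        config.density_rules,
        memberships,
        config.partitions["cell_density_change"],
        config.n_disc,
    )
    return config.gain * crisp


def infer_ph_change(
    cell_density,
    pH,
    ph_change_ability,
    relative_strength: float | None = None,
    config: FuzzyConfig | None = None,
):
    """Gain-scaled crisp per-iteration pH change, summed over species.

    ``cell_density`` and ``ph_change_ability`` may be scalars (one species)
    or length-2 sequences (species A and B); species B's contribution is
    multiplied by ``relative_strength`` (default from ``config``).
    """
    if config is None:
        raise TypeError("config is required")
    rs = config.relative_strength if relative_strength is None else relative_strength
    densities = cell_density if isinstance(cell_density, (tuple, list)) else [cell_density]
    abilities = (
        ph_change_ability
        if isinstance(ph_change_ability, (tuple, list))
        else [ph_change_ability]
    )
    if len(densities) != len(abilities):
        raise ValueError("need one ability per density")
    total = 0.0
    for k, (dens, abil) in enumerate(zip(densities, abilities)):
        memberships = {
            "cell_density": config.partitions["cell_density"].fuzzify(dens),
            "pH_change_ability": config.partitions["pH_change_ability"].fuzzify(
                np.broadcast_to(float(abil), np.shape(np.asarray(dens))).copy()
                if np.shape(np.asarray(dens))
                else float(abil)
            ),
        }
        crisp = _mamdani(
            config.ph_rules, memberships, config.partitions["pH_change"], config.n_disc
        )
        total = total + (rs * crisp if k == 1 else crisp)
    return config.gain * total


@dataclass(frozen=True)
class FuzzyState:
    """Densities of both species, shared pH, iteration index."""

    n_a: float
    n_b: float
    pH: float
    iteration: int = 0


@dataclass
class FuzzyTrajectory:
    """Iteration-ordered fuzzy states (arrays indexed by iteration)."""

    n_a: np.ndarray
    n_b: np.ndarray
    pH: np.ndarray

    def __len__(self) -> int:
        return len(self.pH)

    @property
    def final_state(self) -> FuzzyState:
        return FuzzyState(
            float(self.n_a[-1]), float(self.n_b[-1]), float(self.pH[-1]), len(self) - 1
        )


def _step_batch(
    n_a: np.ndarray,
    n_b: np.ndarray,
    pH: np.ndarray,
    species: tuple[FuzzySpecies, ...],
    config: FuzzyConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One synchronous update of a batch of systems."""
    ph_lo, ph_hi = config.partitions["pH"].universe
    d_lo, d_hi = config.partitions["cell_density"].universe
    new_n = []
    for sp, n in zip(species, (n_a, n_b)):
        if sp is None:
            new_n.append(n)
            continue
        dn = infer_density_change(pH, sp.preferred_pH, n, config)
        new_n.append(np.clip(n + dn, d_lo, d_hi))
    densities = [n for sp, n in zip(species, (n_a, n_b)) if sp is not None]
    abilities = [sp.ph_change_ability for sp in species if sp is not None]
    dph = infer_ph_change(densities, pH, abilities, config=config)
    return new_n[0], new_n[1], np.clip(pH + dph, ph_lo, ph_hi)


def fuzzy_iterate(
    state0: FuzzyState,
    species_a: FuzzySpecies,
    species_b: FuzzySpecies | None,
    config: FuzzyConfig,
) -> FuzzyTrajectory:
    """Run ``config.n_iterations`` synchronous updates from ``state0``.

    Densities and pH are clamped to their declared universes after each
    update; a single-species run passes ``species_b=None`` (its density is
    carried through unchanged and contributes no pH drive).
    """
    n_a = np.array(state0.n_a, float)
    n_b = np.array(state0.n_b, float)
    pH = np.array(state0.pH, float)
    traj_na, traj_nb, traj_ph = [n_a.copy()], [n_b.copy()], [pH.copy()]
    for _ in range(config.n_iterations):
        n_a, n_b, pH = _step_batch(n_a, n_b, pH, (species_a, species_b), config)
        traj_na.append(np.asarray(n_a))
        traj_nb.append(np.asarray(n_b))
        traj_ph.append(np.asarray(pH))
    return FuzzyTrajectory(np.array(traj_na), np.array(traj_nb), np.array(traj_ph))


def _batch_run(
    n_a0: np.ndarray,
    n_b0: np.ndarray,
    ph0: np.ndarray,
    species: tuple[FuzzySpecies | None, FuzzySpecies | None],
    config: FuzzyConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterate a flat batch; returns per-iteration stacked arrays."""
    n_a, n_b, pH = n_a0.copy(), n_b0.copy(), ph0.copy()
    hist = [(n_a.copy(), n_b.copy(), pH.copy())]
    for _ in range(config.n_iterations):
        n_a, n_b, pH = _step_batch(n_a, n_b, pH, species, config)
        hist.append((n_a, n_b, pH))
    return (
        np.stack([h[0] for h in hist]),
        np.stack([h[1] for h in hist]),
        np.stack([h[2] for h in hist]),
    )


def _survival_threshold(config: FuzzyConfig) -> float:
    return 1e-3 * config.partitions["cell_density"].universe[1]


def fuzzy_sweep_single(
    species: FuzzySpecies,
    config: FuzzyConfig,
    density_grid: np.ndarray | None = None,
    ph_grid: np.ndarray | None = None,
) -> OutcomeGrid:
    """Monoculture outcome grid over (initial density, initial pH)."""
    if density_grid is None:
        density_grid = np.geomspace(1e-4, 0.9, 21)
    if ph_grid is None:
        lo, hi = config.partitions["pH"].universe
        ph_grid = np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), 21)
    density_grid = np.asarray(density_grid, float)
    ph_grid = np.asarray(ph_grid, float)
    D, P = np.meshgrid(density_grid, ph_grid, indexing="ij")
    na, nb, ph = _batch_run(
        D.ravel(), np.zeros(D.size), P.ravel(), (species, None), config
    )
    thr = _survival_threshold(config)
    iters = np.arange(na.shape[0], dtype=float)
    shape = D.shape
    osc = np.array(
        [count_final_oscillations(iters, na[:, k], thr) >= 2 for k in range(na.shape[1])]
    ).reshape(shape)
    return OutcomeGrid(
        axis1=density_grid,
        axis2=ph_grid,
        a_survives=(na[-1] >= thr).reshape(shape),
        b_survives=np.zeros(shape, bool),
        n_a_final=na[-1].reshape(shape),
        n_b_final=np.zeros(shape),
        p_final=ph[-1].reshape(shape),
        oscillatory=osc,
        kind="single",
        axis1_name="density",
        meta={"species": species.name, "backend": "fuzzy", "threshold": thr},
    )


def fuzzy_sweep_pair(
    species_a: FuzzySpecies,
    species_b: FuzzySpecies,
    config: FuzzyConfig,
    fraction_grid: np.ndarray | None = None,
    ph_grid: np.ndarray | None = None,
    total_density: float = 1.0,
    include_alone: bool = True,
) -> OutcomeGrid:
    """Coculture outcome grid over (species-A fraction, initial pH).

    Same grid and classification contract as the ODE backend's pair sweep;
    with ``include_alone`` each cell also runs the matched monocultures.
    """
    if fraction_grid is None:
        fraction_grid = np.linspace(0.0, 1.0, 21)
    if ph_grid is None:
        lo, hi = config.partitions["pH"].universe
        ph_grid = np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), 21)
    fraction_grid = np.asarray(fraction_grid, float)
    ph_grid = np.asarray(ph_grid, float)
    if np.any((fraction_grid < 0) | (fraction_grid > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    F, P = np.meshgrid(fraction_grid, ph_grid, indexing="ij")
    na0 = (F * total_density).ravel()
    nb0 = ((1.0 - F) * total_density).ravel()
    ph0 = P.ravel()
    na, nb, ph = _batch_run(na0, nb0, ph0, (species_a, species_b), config)
    thr = _survival_threshold(config)
    shape = F.shape
    iters = np.arange(na.shape[0], dtype=float)
    osc = np.empty(na.shape[1], bool)
    for k in range(na.shape[1]):
        osc_a = count_final_oscillations(iters, na[:, k], thr) >= 2
        osc_b = count_final_oscillations(iters, nb[:, k], thr) >= 2
        persist_a = na[-1, k] >= thr or osc_a
        persist_b = nb[-1, k] >= thr or osc_b
        osc[k] = (osc_a or osc_b) and persist_a and persist_b
    osc = osc.reshape(shape)
    alone_a = alone_b = None
    if include_alone:
        na_al, _, _ = _batch_run(na0, np.zeros(na0.size), ph0, (species_a, None), config)
        _, nb_al, _ = _batch_run(np.zeros(nb0.size), nb0, ph0, (None, species_b), config)
        alone_a = (na_al[-1] >= thr).reshape(shape)
        alone_b = (nb_al[-1] >= thr).reshape(shape)
    return OutcomeGrid(
        axis1=fraction_grid,
        axis2=ph_grid,
        a_survives=(na[-1] >= thr).reshape(shape),
        b_survives=(nb[-1] >= thr).reshape(shape),
        n_a_final=na[-1].reshape(shape),
        n_b_final=nb[-1].reshape(shape),
        p_final=ph[-1].reshape(shape),
        oscillatory=osc,
        kind="pair",
        axis1_name="fraction_a",
        a_alone_survives=alone_a,
        b_alone_survives=alone_b,
        meta={
            "species_a": species_a.name,
            "species_b": species_b.name,
            "backend": "fuzzy",
            "total_density": total_density,
            "threshold": thr,
        },
    )
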