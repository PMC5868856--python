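"""Run configuration, validation, and the staged pipeline.

A :class:`RunConfig` declares everything a run needs — backend, species
(inline parameters or shipped archetype names), environment, transfer
protocol, sweep grids, solver options, noise model and seed — and is
schema-validated before any computation starts (unknown keys are
rejected).  :func:`run_pipeline` executes any subset of the stages
``simulate | sweep | stability | fuzzy | synth | characterize | predict``,
writing CSV/JSON artifacts whose headers embed the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .model import Environment, SpeciesParams, SystemState, load_archetypes
from .simulate import TransferProtocol

__all__ = ["RunConfig", "load_config", "save_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "sweep", "stability", "fuzzy", "synth", "characterize", "predict")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesConfig(_Strict):
    p_pref: float
    sigma: float = Field(gt=0)
    delta: float = Field(gt=0, lt=1)
    c: float
    d: float = Field(default=1.0, gt=0)
    K: float = Field(default=10.0, gt=0)


class EnvironmentConfig(_Strict):
    b: float = Field(default=5.0, gt=0)
    p0: float = 5.0


class ProtocolConfig(_Strict):
    cycle_length: float = Field(default=5.0, gt=0)
    dilution_factor: float = Field(default=10.0, ge=1)
    n_cycles: int = Field(default=10, ge=1)


class SweepConfig(_Strict):
    n_density: int = Field(default=21, ge=2)
    n_fraction: int = Field(default=21, ge=2)
    n_p0: int = Field(default=21, ge=2)
    p0_min: float = 0.5
    p0_max: float = 9.5
    total_density: float | None = None
    horizon: float = Field(default=200.0, gt=0)


class SolverConfig(_Strict):
    method: str = "RK45"
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-10, gt=0)


class NoiseConfig(_Strict):
    growth_sd: float = Field(default=0.1, ge=0)
    ph_sd: float = Field(default=0.05, ge=0)
    cfu_per_density: float = Field(default=1e7, gt=0)


class RunConfig(_Strict):
    """Validated, hashable description of a full run."""

    backend: str = "ode"
    species_a: str | SpeciesConfig = "acid_lover_acidifier"
    species_b: str | SpeciesConfig | None = "alkali_lover_alkalizer"
    environment: EnvironmentConfig = EnvironmentConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    sweep: SweepConfig = SweepConfig()
    solver: SolverConfig = SolverConfig()
    noise: NoiseConfig = NoiseConfig()
    seed: int = 0
    initial_state: tuple[float, float, float] | None = None

    @field_validator("backend")
    @classmethod
    def _backend_known(cls, v: str) -> str:
        if v not in ("ode", "fuzzy"):
            raise ValueError("backend must be 'ode' or 'fuzzy'")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def resolve_species(self) -> tuple[SpeciesParams, SpeciesParams | None, Environment]:
        archetypes, _ = load_archetypes()
        env = Environment(**self.environment.model_dump())

        def build(entry, fallback_name):
            if entry is None:
                return None
            if isinstance(entry, str):
                if entry not in archetypes:
                    raise KeyError(
                        f"unknown archetype '{entry}'; known: {sorted(archetypes)}"
                    )
                return archetypes[entry]
            return SpeciesParams(name=fallback_name, **entry.model_dump())

        return build(self.species_a, "a"), build(self.species_b, "b"), env

    def solver_opts(self) -> dict:
        return self.solver.model_dump()

    def transfer_protocol(self) -> TransferProtocol:
        return TransferProtocol(**self.protocol.model_dump())


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def _grids(cfg: RunConfig, K: float):
    sw = cfg.sweep
    density = np.geomspace(1e-4 * K, 0.9 * K, sw.n_density)
    fraction = np.linspace(0.0, 1.0, sw.n_fraction)
    p0 = np.linspace(sw.p0_min, sw.p0_max, sw.n_p0)
    return density, fraction, p0


def run_pipeline(config: RunConfig, stages, out_dir, seed: int | None = None) -> list[Path]:
    """Execute the requested stages, returning the artifact paths written.

    Every artifact embeds the config hash and seed (CSV ``#`` headers or
    JSON keys); a ``run.log`` records stages, versions and timing.  An
    empty stage list is a no-op that still writes the log.
    """
    from . import characterize as chz
    from . import fuzzy as fz
    from . import outcomes as oc
    from . import stability as st
    from . import synth as sy
    from .simulate import integrate, run_serial_transfer, write_trajectory_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
    sp_a, sp_b, env = config.resolve_species()
    meta = {"config_hash": config.config_hash(), "seed": seed, "version": __version__}
    written: list[Path] = []
    log_lines = [f"phfeedback {__version__} seed={seed} hash={meta['config_hash']}"]

    def record(path: Path) -> Path:
        written.append(path)
        log_lines.append(f"wrote {path.name}")
        return path

    from .model import NULL_SPECIES

    sp_b_eff = sp_b if sp_b is not None else NULL_SPECIES
    t_start = time.time()

    if "simulate" in stages:
        if config.initial_state is not None:
            state0 = SystemState(*config.initial_state)
        else:
            state0 = SystemState(0.05 * sp_a.K, 0.05 * sp_b_eff.K if sp_b else 0.0, env.p0)
        traj = run_serial_transfer(
            state0, sp_a, sp_b_eff, env, config.transfer_protocol(), config.solver_opts()
        )
        write_trajectory_csv(traj, out / "trajectory.csv", meta)
        record(out / "trajectory.csv")

    if "sweep" in stages:
        density, fraction, p0 = _grids(config, sp_a.K)
        g_a = oc.sweep_single(sp_a, env, density, p0, config.sweep.horizon,
                              solver_opts=config.solver_opts())
        oc.write_outcome_csv(g_a, out / "sweep_single_a.csv", meta)
        record(out / "sweep_single_a.csv")
        if sp_b is not None:
            g_b = oc.sweep_single(sp_b, env, density, p0, config.sweep.horizon,
                                  solver_opts=config.solver_opts())
            oc.write_outcome_csv(g_b, out / "sweep_single_b.csv", meta)
            record(out / "sweep_single_b.csv")
            g_p = oc.sweep_pair(sp_a, sp_b, env, fraction, p0,
                                config.sweep.total_density, config.sweep.horizon,
                                solver_opts=config.solver_opts())
            oc.write_outcome_csv(g_p, out / "sweep_pair.csv", meta)
            record(out / "sweep_pair.csv")
            motif = oc.label_motif(g_a, g_b, g_p)
            (out / "motif.json").write_text(
                json.dumps({**meta, "backend": "ode", "motif": motif.value}, indent=2)
            )
            record(out / "motif.json")

    if "stability" in stages:
        fps = st.find_fixed_points(sp_a, sp_b_eff, env)
        st.write_fixed_point_csv(fps, out / "fixed_points.csv", meta)
        record(out / "fixed_points.csv")

    if "fuzzy" in stages:
        fcfg = fz.load_fuzzy_config()
        fa = fz.FuzzySpecies.from_species_params(sp_a, env)
        ga = fz.fuzzy_sweep_single(fa, fcfg)
        oc.write_outcome_csv(ga, out / "fuzzy_single_a.csv", meta)
        record(out / "fuzzy_single_a.csv")
        if sp_b is not None:
            fb = fz.FuzzySpecies.from_species_params(sp_b, env)
            gb = fz.fuzzy_sweep_single(fb, fcfg)
            oc.write_outcome_csv(gb, out / "fuzzy_single_b.csv", meta)
            record(out / "fuzzy_single_b.csv")
            gp = fz.fuzzy_sweep_pair(fa, fb, fcfg)
            oc.write_outcome_csv(gp, out / "fuzzy_pair.csv", meta)
            record(out / "fuzzy_pair.csv")
            motif = oc.label_motif(ga, gb, gp)
            (out / "fuzzy_motif.json").write_text(
                json.dumps({**meta, "backend": "fuzzy", "motif": motif.value}, indent=2)
            )
            record(out / "fuzzy_motif.json")

    if "synth" in stages:
        noise = sy.NoiseModel(**config.noise.model_dump())
        frames_g, frames_e = [], []
        truth = {}
        for k, sp in enumerate(s for s in (sp_a, sp_b) if s is not None):
            frames_g.append(sy.gen_growth_vs_ph(sp, env, noise=noise, seed=seed + 101 + k))
            frames_e.append(sy.gen_ph_endpoint_table(sp, env, noise=noise, seed=seed + 201 + k))
            truth[sp.name] = {
                "p_pref": sp.p_pref, "sigma": sp.sigma, "delta": sp.delta,
                "c": sp.c, "d": sp.d, "K": sp.K,
            }
        import pandas as pd

        for fname, frames in (("growth_vs_ph.csv", frames_g), ("ph_endpoints.csv", frames_e)):
            with open(out / fname, "w") as fh:
                for key, val in meta.items():
                    fh.write(f"# {key}: {val}\n")
                pd.concat(frames, ignore_index=True).to_csv(fh, index=False)
            record(out / fname)
        serial = sy.gen_serial_transfer_dataset(
            sp_a, sp_b_eff, env, config.transfer_protocol(), noise, seed + 301
        )
        with open(out / "serial_transfer.csv", "w") as fh:
            for key, val in meta.items():
                fh.write(f"# {key}: {val}\n")
            serial.to_csv(fh, index=False)
        record(out / "serial_transfer.csv")
        (out / "ground_truth.json").write_text(json.dumps({**meta, "species": truth}, indent=2))
        record(out / "ground_truth.json")

    if "characterize" in stages:
        import pandas as pd

        growth = pd.read_csv(out / "growth_vs_ph.csv", comment="#")
        endpoints = pd.read_csv(out / "ph_endpoints.csv", comment="#")
        profiles = {}
        for name in growth["species"].unique():
            prof = chz.characterize_species(growth, endpoints, b=env.b, species=name)
            profiles[name] = json.loads(chz.profile_to_json(prof))
        (out / "profiles.json").write_text(json.dumps({**meta, "profiles": profiles}, indent=2))
        record(out / "profiles.json")

    if "predict" in stages:
        import pandas as pd

        payload = json.loads((out / "profiles.json").read_text())
        profs = {
            name: chz.SpeciesProfile(**vals) for name, vals in payload["profiles"].items()
        }
        names = sorted(profs)
        rows = []
        for i, a in enumerate(names):
            for b_name in names[i + 1:]:
                rows.append(
                    {
                        "species_a": a,
                        "species_b": b_name,
                        "predicted_motif": chz.predict_pair_motif(profs[a], profs[b_name], b=env.b).value,
                    }
                )
        with open(out / "motif_predictions.csv", "w") as fh:
            for key, val in meta.items():
                fh.write(f"# {key}: {val}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)
        record(out / "motif_predictions.csv")

    log_lines.append(f"elapsed {time.time() - t_start:.1f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return written
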