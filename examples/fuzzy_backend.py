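"""The rule-based (fuzzy-logic) counterpart of the ODE model.

The same ecology expressed as linguistic rules — "IF pH is low AND the
preferred pH is low THEN the cell density change is positive" — evaluated
by Mamdani inference over 200 iterations, reproduces the ODE backend's
interaction motifs without any defined rate functions.
"""

import numpy as np

from phfeedback import (
    FuzzySpecies,
    FuzzyState,
    fuzzy_iterate,
    fuzzy_sweep_pair,
    fuzzy_sweep_single,
    label_motif,
    load_archetypes,
    load_fuzzy_config,
)

config = load_fuzzy_config()
species, env = load_archetypes()
sm = FuzzySpecies.from_species_params(species["mid_lover_acidifier"], env)
pv = FuzzySpecies.from_species_params(species["acid_lover_alkalizer"], env)

# single self-killer: rise then collapse, as in the ODE model
traj = fuzzy_iterate(FuzzyState(n_a=0.1, n_b=0.0, pH=8.5), sm, None, config)
print(f"self-killer alone: density peaks at {traj.n_a.max():.2f}, "
      f"ends at {traj.n_a[-1]:.3f} after {len(traj) - 1} iterations")

# the two self-killers with opposing drives rescue each other
grid = np.linspace(0, 1, 9)
ph_grid = np.linspace(2.5, 10.5, 9)
g_a = fuzzy_sweep_single(sm, config, np.geomspace(1e-3, 0.9, 9), ph_grid)
g_b = fuzzy_sweep_single(pv, config, np.geomspace(1e-3, 0.9, 9), ph_grid)
g_pair = fuzzy_sweep_pair(sm, pv, config, grid, ph_grid)
both = (g_pair.a_survives & g_pair.b_survives).sum()
print(f"alone: {g_a.a_survives.sum()} and {g_b.a_survives.sum()} surviving cells")
print(f"together: both survive in {both} / {g_pair.a_survives.size} cells")
print(f"motif: {label_motif(g_a, g_b, g_pair).value}")
print()
print("Each species is extinct everywhere on its own, but their opposing pH")
print("drives cancel in coculture: mutual stabilization.")
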