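"""Coculture phase diagram and interaction-motif label.

Sweeps initial species-A fraction x initial proton concentration for the
acid-loving acidifier vs the alkali-loving alkalizer, and labels the
interaction motif from the mono- and coculture survival patterns.
"""

import numpy as np

from phfeedback import label_motif, load_archetypes, sweep_pair, sweep_single

species, env = load_archetypes()
lp = species["acid_lover_acidifier"]
ca = species["alkali_lover_alkalizer"]

# reduced 9x9 grids keep this demo fast; defaults are 21x21
density = np.geomspace(1e-3, 9.0, 9)
fraction = np.linspace(0, 1, 9)
p0 = np.linspace(0.5, 9.5, 9)

g_a = sweep_single(lp, env, density, p0)
g_b = sweep_single(ca, env, density, p0)
g_pair = sweep_pair(lp, ca, env, fraction, p0)

label = label_motif(g_a, g_b, g_pair)
only_a = (g_pair.a_survives & ~g_pair.b_survives).sum()
only_b = (g_pair.b_survives & ~g_pair.a_survives).sum()
print(f"coculture cells won by the acidifier:  {only_a} / {g_pair.a_survives.size}")
print(f"coculture cells won by the alkalizer:  {only_b} / {g_pair.a_survives.size}")
print(f"interaction motif: {label.value}")
print()
print("Two sole-winner regions within the same initial-p columns mean the")
print("outcome is selected by the starting fraction/pH: bistability.")
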