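"""Fixed points and linear stability of a bistable coculture.

Enumerates the equilibria of the acidifier/alkalizer pair, classifies them
from the eigenvalues of the analytic Jacobian, and reports the stable
states' surviving species.
"""

from phfeedback import find_fixed_points, load_archetypes

species, env = load_archetypes()
lp = species["acid_lover_acidifier"]
ca = species["alkali_lover_alkalizer"]

fps = find_fixed_points(lp, ca, env)
print(f"{len(fps)} equilibria (sterile-line representatives included)")
for fp in fps:
    if fp.on_sterile_line:
        continue
    print(
        f"  (n_a={fp.n_a:5.1f}, n_b={fp.n_b:5.1f}, p={fp.p:5.2f})  {fp.classification:>14s}"
        f"  |rhs| = {fp.residual:.1e}"
    )

stable = [fp for fp in fps if fp.classification == "stable"]
print()
print(f"{len(stable)} locally stable state(s):")
for fp in stable:
    winner = "acidifier" if fp.n_a >= 0.01 else "alkalizer" if fp.n_b >= 0.01 else "none"
    print(f"  sole survivor: {winner} at p = {fp.p:.1f}")
print()
print("Two stable states with different sole survivors are the fixed-point")
print("signature of the bistability seen in the phase diagram.")
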