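"""Ecological suicide in batch culture.

A species that prefers a mildly acidic environment (optimum proton level
3.5) but keeps acidifying (c > 0) first improves its own conditions, booms,
then overshoots its optimum and drives itself extinct.
"""

from phfeedback import SystemState, NULL_SPECIES, integrate, load_archetypes

species, env = load_archetypes()
sm = species["mid_lover_acidifier"]

traj = integrate(SystemState(n_a=0.1, n_b=0.0, p=1.0), sm, NULL_SPECIES, env, horizon=200)

peak = traj.n_a.max()
t_peak = traj.t[traj.n_a.argmax()]
print(f"start:  n = {traj.n_a[0]:.3f} at p = {traj.p[0]:.2f} (optimum {sm.p_pref})")
print(f"boom:   n peaks at {peak:.2f} (x{peak / traj.n_a[0]:.0f}) around t = {t_peak:.0f}")
print(f"crash:  n = {traj.n_a[-1]:.2e} at t = {traj.t[-1]:.0f}, p driven to {traj.p[-1]:.2f}")
print()
print("The population rises while its own acidification moves p toward the")
print("optimum, then keeps pushing p far past it and goes extinct — the")
print("hallmark rise-then-collapse of ecological suicide.")
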