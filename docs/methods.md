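# Methods

## The coupled density–proton model

The state is `(n_a, n_b, p)`: two population densities and one abstract
environmental proton concentration on `[0, 2b]`. Densities follow logistic
growth whose rate is a Gaussian function of `p` minus a death floor:

```
dn_i/dt = n_i (1 − n_i/K_i) ( exp(−(p − p_pref,i)²/σ_i²) − δ_i )
dp/dt   = ( Σ_i c_i d_i n_i ) · q(p),    q(p) = p (2b − p) / b²
```

Assumptions worth stating explicitly:

* `p` is a qualitative environmental axis, not `−log10[H+]`; no acid/base
  chemistry, buffering, or gas exchange is modeled. Any "pH" axis in
  outputs is the linear display map `pH = 11 − 0.9 p` (for `b = 5`), a
  convention only.
* The quadratic boundary factor `q` saturates environmental modification
  at the scale edges. We normalize it to `q(b) = 1` so that `c_i n_i` is
  read directly as a mid-scale drive rate; `c` and the normalization are
  config keys.
* The relative drive strength enters as `drive = Σ c_i d_i n_i` with
  `d = 1` by default; pairwise sweeps vary one species' `d` ("y times
  stronger than the partner").
* The model's density domain is `[0, K]`. For `n > K` with a negative
  growth factor the raw logistic term changes sign and diverges, so the
  numerical right-hand side clamps the logistic factor at zero (densities
  above `K` are neutral) and evaluates `q` with `p` clipped to its scale.
  On the domain this changes nothing; it only prevents solver-tolerance
  overshoots from seeding runaways. With these guards the invariants
  `p ∈ [0, 2b]` and `n ∈ [0, max(n_0, K)]` hold along all trajectories up
  to solver tolerance.

### Parameters and defaults

| parameter | meaning | default | origin |
|---|---|---|---|
| `σ` | niche width | 4 | study conditions |
| `δ` | maximal death rate | 0.5 | study conditions |
| `|c|` | drive coefficient | 0.1 | study conditions |
| `b` | half-range of the `p` scale | 5 | study conditions |
| `K` | carrying capacity | 10 | declared default (scale-free) |
| `d` | relative drive strength | 1 | declared default |
| horizon | batch simulation length | 200 | see below |

The four archetypes (`src/phfeedback/data/archetypes.yaml`) place
`p_pref` at 8 (acid-loving acidifier), 2 (alkali-loving alkalizer), 8.5
with `σ = 2.5` and `d = 2` (acid-loving alkalizer, the "murder–suicide"
species), and 3.5 (mid-loving acidifier). The first, second and fourth
values are declared assumptions consistent with the qualitative species
descriptions; the third is differentiated deliberately: with identical
niches the killer/victim pair's density ratio is frozen whenever both are
below `K`, `p` becomes monotone, and no oscillation is possible, whereas
a narrower niche and doubled drive for the self-killer produce the
sustained oscillatory rescue of rare killers (limit cycle of period ≈ 27
time units) that coculture phase diagrams are expected to show.

### Numerical choices

* Adaptive explicit Runge–Kutta (`RK45`) with `rtol 1e-8`, `atol 1e-10`
  by default; dense output at 200 samples per run. Large sweeps may pass
  `{"method": "LSODA", "rtol": 1e-6}`; labels are insensitive to this at
  the grid resolutions used.
* An independently transcribed fixed-step forward-Euler integrator
  (`dt = 1e-4`) serves as the cross-check oracle; endpoints agree within
  `1e-3` relative.
* Extinction is absorbing: densities below the solver's absolute
  tolerance are clamped to zero on output, never sign-flipped.
* Default horizon is 200 time units. At horizon 100 the ecological-suicide
  transient from the smallest default inoculum (`1e-4 K`) is still in
  progress and misclassifies as survival; 200 completes every archetype
  transient. Sweeps of parameter-jittered species (weaker drives) use 300
  for the same reason.
* The default initial-density grid spans `1e-4 K` to `0.9 K` (21 log
  points). Exactly `n_0 = K` is excluded: it is a degenerate logistic
  fixed point (`dn/dt ≡ 0` regardless of pH) at which even a self-killing
  species formally persists.

## Sweeps, survival, motifs

A cell of a phase diagram is one simulation from `(n_0, p_0)` (single) or
`(f N, (1−f) N, p_0)` (pair, total inoculum `N = 0.1 max(K)`). A species
survives iff its final density is at least `1e-3 K` (sensitivity checks
from `1e-2 K` to `1e-4 K` leave archetype classifications unchanged).
Oscillation is detected as ≥ 2 local maxima above the extinction threshold
with prominence at least that threshold in the final 30% of the horizon
(prominence excludes numerical jitter around steady states); a cell is
oscillatory coexistence when both species persist — steadily or by
cycling — and at least one cycles.

Pair sweeps also run each cell's two matched monocultures, so coculture
survival is compared against "the same inoculum, alone" cell-by-cell.
The motif classifier is rule-based and ordered, keyed on each species'
single-species character (`suicide`: extinct everywhere alone;
`conditional`: density-dependent survival, i.e. an Allee wedge; `robust`):

1. both suicidal and coculture cells where both persist → **stabilization**;
2. exactly one suicidal: partner cells alive-with-killer but dead-alone →
   **successive growth**; both-dead cells where the partner lives alone →
   **extended suicide** (evaluated in this order; `strict=True` raises on
   multiple matches instead);
3. neither suicidal: both sole-winner outcomes occurring within a shared
   initial-p column → **bistability** (winner selected by initial
   conditions, not by pH niche partitioning);
4. otherwise coexistence / exclusion / ecological-suicide fallbacks.

The Allee threshold at fixed `p_0` is located by bisection on log initial
density to `1e-3` relative tolerance and agrees with a 1000-point
brute-force scan to within one scan step. Weakening the drive (`|c|`
smaller — the analog of stronger buffering) raises the threshold
monotonically.

## Stability analysis

Fixed points are enumerated analytically — densities in `{0, K}`, `p` at a
scale boundary or at a niche edge `p_pref ± σ √ln(1/δ)`, plus
cancelling-drive interior candidates — polished by Newton root-finding on
the full right-hand side (tolerance `1e-12`, dedup radius `1e-6`,
residual bound `1e-9`), restricted to the domain, and classified from the
eigenvalues of the analytic Jacobian (cross-checked against central
finite differences; tolerance `1e-8` on real parts). The sterile set
`(0, 0, p)` is a continuum, so hyperbolic classification does not apply
along it; representative grid nodes are reported flagged, and only
transverse stability is meaningful there. Every stable point re-attracts
a `1e-3`-perturbed simulation; the bistable archetype pair has exactly two
stable states with different sole survivors.

## Serial transfer

Growth cycles of length 5 alternate with instantaneous transfers: both
densities are divided by the dilution factor `D` and the pre-transfer
proton concentration is mixed with fresh medium,
`p → p/D + (D−1)/D · p0`. The daily 1:10 / 1:100 laboratory cadence maps
nominally (not calibrated) onto `cycle_length = 5`. For a self-killing
species, survival over 20 cycles is non-monotone in `D`: extinct in batch,
rescued at intermediate `D`, outdiluted at high `D`.

## The fuzzy-logic counterpart

The discrete-time backend replaces the rate functions with linguistic
rules over fuzzy partitions, evaluated by Mamdani inference (min for AND,
max for aggregation, centroid defuzzification — the conventional choices)
and applied synchronously each iteration with a gain of 0.05, 200
iterations by default, all declared in
`src/phfeedback/data/fuzzy_default.yaml`:

* universes: pH on `[2, 11]` (the display image of the `p` scale, so the
  rule base saturates where the ODE's drive does), density on `[0, 1]`
  (1 = carrying capacity), with triangular partitions forming a partition
  of unity and trapezoidal shoulders at the ends;
* growth rules: density change is positive when the current-pH label
  matches the species' preferred-pH label (and a population is present),
  mildly negative one label away, strongly negative two away — a coarse
  Gaussian-minus-δ;
* drive rules: the pH change follows the species' ability sign (±1) with
  magnitude set by the density label; species B's contribution is
  multiplied by the `relative_strength` parameter (the fuzzy analog of
  `d`); opposite abilities at equal density cancel exactly by symmetry.

Membership breakpoints and the gain are declared defaults chosen once so
that 200 iterations traverse the dynamics (growth, environmental
conditioning, collapse) without overshoot. The fuzzy backend reproduces
all four coculture motifs on grids matched to the ODE backend's, with a
stabilization region at least as wide — rule-based smoothing broadens the
mutual-rescue regime.

## Characterization and prediction

`fit_ph_response` fits `log(fold growth) = A·exp(−(p−p_pref)²/σ²) + B` by
nonlinear least squares (display pH mapped linearly onto `p`), giving
`δ = −B/A`; the log transform stabilizes multiplicative noise, and folds
below 1 (net death) are what identify `δ`. `p_pref` and `σ` estimates are
invariant to rescaling all folds (only `B` shifts); `δ` is not, since
fold = 1 anchors it. Zero-noise tables generated in the exponential-phase
limit are recovered exactly; under lognormal noise of sd 0.1 (10 pH
levels, 3 replicates) the median optimum error is ≈ 0.03 display-pH
units. Flat tables and tables with < 5 pH levels are rejected as
degenerate rather than fitted.

The drive is the sign and magnitude of the median endpoint-pH shift from
the assay start (display pH 7), with shifts below 0.1 pH units reported
as sign 0. A species is *self-benefiting* if its drive moves `p` toward
its fitted optimum from the assay start, else *self-harming* — evaluated
at the start point because the direction can reverse across the optimum.
The unordered pair of classes maps to the predicted motif:

| classes | drives | prediction |
|---|---|---|
| benefit + benefit | opposing | bistability |
| benefit + benefit | same | coexistence |
| harm + benefit | toward partner's optimum | successive growth |
| harm + benefit | away from it | extended suicide |
| harm + harm | opposing | stabilization |
| harm + harm | same | ecological suicide |

This explicit mapping is a reconstruction of a narrative rule and is
config-overridable. On 50 seeded near-archetype pairs (optimum jitter
±0.5, niche-width ±10%, drive ±20–25%) the prediction agrees with the
full phase-diagram label in ≈ 90% of cases; the residual disagreements
are slow jittered suicide transients still in progress at the truth
sweep's horizon.

## Synthetic data

The generator emulates three table kinds with known ground truth emitted
alongside: fold-growth vs initial pH (proton level frozen during the
assay, matching a buffered low-nutrient protocol; logistic closed form,
lognormal noise, default sd 0.1), endpoint pH after unbuffered growth
(Gaussian meter noise, sd 0.05), and daily serial-transfer CFU/pH records.
Plating is modeled mechanistically: a 10-fold dilution row of 8 spots of
10 µL, Poisson colony counts per spot, a countable window of 1–300
colonies, and the CFU estimate read from the least-diluted countable spot
(sterile rows report 0, flagged below detection; the implied detection
limit is 100 CFU/mL, where a spot yields ≥ 1 colony with probability
1 − 1/e). Model density converts to CFU/mL at `1e7` per density unit.
All noise magnitudes are declared defaults (none are reported for the
assays emulated) and config keys.

What passing recovery tests shows — and does not: the generator shares
the simulator's growth model, so recovery results certify the inference
machinery under the stated noise processes, not robustness to real-world
effects the generator omits (species-dependent plating efficiency, colony
miscounting between species, pH drift during "buffered" assays, nutrient
depletion distinct from pH feedback).

## Problem sizes used in the shipped checks

Default phase diagrams are 21×21 (densities/fractions × initial `p`),
horizon 200; the end-to-end prediction study uses 9×9 grids at horizon
300 with the LSODA option; bound conservation uses 1000 random starts in
the test suite and 300 in the acceptance script; recovery studies use 100
noisy tables, 50 jittered pairs, and 100 plating runs. These sizes are
the package's declared defaults for its own regression checks; all are
parameters.

## Known limitations

* One environmental axis; no nutrients, oxygen, or explicit chemistry.
* The motif vocabulary is rule-based on grid summaries; exotic dynamics
  outside it (e.g. heteroclinic cycling) would fall into the fallback
  labels and be reported as findings, not errors.
* The fuzzy backend's universes normalize both species to a common
  carrying capacity; unequal `K` pairs are only supported by the ODE
  backend.
* Oscillatory rescue requires niche differentiation between killer and
  victim (see above); it is absent in the fully symmetric parameterization.
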