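# Methods

## The estimation problem

Hansen solubility parameters (HSPs) describe a substance's cohesive energy
density as three components — dispersion δD, dipolar δP and hydrogen-bonding
δH, each in MPa^1/2 — placing it at a point in a 3D "Hansen space".
Compatibility between a solute (1) and a solvent (2) is measured by the
Hansen distance

    R = sqrt(4 (δD1 − δD2)² + (δP1 − δP2)² + (δH1 − δH2)²),

an anisotropic metric whose dispersion axis counts double (doubling δD turns
R into a plain Euclidean norm; `to_scaled_space` exposes that isometry).
Smaller R means better affinity. The Hildebrand total parameter
δT = sqrt(δD² + δP² + δH²) is the 1D collapse of the same information.

For amorphous porous organic polymers (POPs) the molecular structure — hence
any bottom-up group-contribution HSP estimate — is not accessible, and
classical Hansen-sphere fitting needs binary soluble/insoluble calls that
discard most of the signal. The approach implemented here instead treats
the material M as the *centroid of a one-cluster* of test solvents: each
solvent i with known HSPs δS_i is assigned a solubility score w_i, the UV/vis
maximum absorbance of a saturated suspension of M in that solvent (read
consistently from the same absorption band across the panel). The estimate
is the minimizer of the total weighted distance

    f(δM) = Σ_i w_i R_i(δM),

a weighted geometric median (Fermat–Weber point) under the Hansen metric.
f is convex — a non-negative combination of norms of affine maps — so every
local minimum is global. The two modeling assumptions are that a better
solvent sits closer in Hansen space and yields a stronger absorbance for
the same aliquot of material.

Weights are used raw: the argmin of f is invariant under uniform positive
scaling of w, so normalization would add nothing to the estimand (it does
affect the stopping point of the optimizer; see "What the optimizer
actually returns" below). Blank subtraction and band selection are the
experimenter's responsibility.

## Initialization

Instead of a random start, the optimizer starts at the closed-form
minimizer of the squared surrogate Σ_i w_i² R_i²(δM):

    δM_init = Σ_i w_i² δS_i / Σ_i w_i²   (component-wise).

Squaring removes the non-smoothness at the data points and yields a
weighted least-squares centroid — a convex combination of the panel
solvents, hence always inside their bounding box. This both accelerates
convergence and anchors the search in chemically plausible territory.
(The anisotropy factor 4 cancels from the component-wise stationarity
conditions of the squared problem, so the same closed form holds under
the Hansen metric.)

## Optimization

Fixed-step gradient descent, exactly:

    δM ← δM + Δ,   Δ = −α ∇f(δM),
    ∇f = Σ_i w_i (4 (δD − δD_i), (δP − δP_i), (δH − δH_i)) / R_i,

with the term of any solvent closer than `eps_guard` (default 1e−9
MPa^1/2) contributing a zero vector — a valid subgradient at the kink, and
the choice that makes a solvent carrying the majority of the weight an
exact fixed point. After each step the iterate is clamped to the
non-negative orthant (the minimal projection keeping all three components
physically meaningful). Iteration stops when ‖Δ‖₂ < `tol` or at
`max_iter`. There is no line search and no momentum, deliberately: the
update rule above, with its published defaults, is the method this package
implements and validates.

| parameter   | default | units    | meaning |
|-------------|---------|----------|---------|
| `alpha`     | 0.01    | —        | learning rate of the fixed step |
| `tol`       | 0.005   | MPa^1/2  | convergence threshold on ‖Δ‖₂ |
| `max_iter`  | 10,000  | steps    | iteration cap |
| `eps_guard` | 1e−9    | MPa^1/2  | kink guard: distance below which a term's subgradient is taken as zero |

The reported "global error" is `tol` rounded to the report precision
(0.005 → 0.01 at two decimals); it is a statement about the stopping rule,
not a statistical uncertainty.

On the bundled 14-solvent case-study panel the descent converges in 189
iterations to (16.8099, 5.7819, 7.9626), i.e. (16.81, 5.78, 7.96) at report
precision, with tetrahydrofuran (R = 0.09) the best-ranked solvent.

## What the optimizer actually returns

This section records properties that matter when interpreting results;
they are all measurable with the package's own oracles and are exercised
in the test suite.

The stopping rule bounds the *update*, not the distance to the optimum:
iteration ends anywhere in the band where ‖∇f‖ < tol/α (0.5 for the
defaults). Consequences:

- **The estimate is a threshold-stopped iterate, not the exact median.**
  On the case-study panel the exact minimizer of f is tetrahydrofuran's own
  coordinates (the strongest-weighted solvent); the stopped iterate lies
  0.09 MPa^1/2 away from it. The two agree at the ±0.1 level, which is the
  honest resolution of the method.
- **Absolute weight scale matters to the stopping point.** Scaling every
  absorbance by c scales the gradient by c, which is algebraically the same
  walk as scaling α by c. Larger total weight stops closer to the optimum,
  smaller farther away (scaling the case-study panel by 0.1 moves the
  stopped estimate by 1.3 MPa^1/2). The estimand is scale-invariant; the
  stopping point is not. Panels should be supplied in natural absorbance
  units (O(0.01–1) AU), where the defaults are calibrated.
- **Kink oscillation.** When the minimum sits at a solvent whose weight
  dominates but does not overwhelm, the gradient magnitude does not vanish
  near the kink and the iterate orbits it with amplitude up to ~2 α w;
  the run may hit `max_iter` with a perfectly useful final iterate (this is
  why `LocateResult` carries both the flag and the trajectory). With an
  overwhelming weight ratio (others ≲ 1e−7 of the dominant) the analytic
  start lands inside the kink guard and the fixed point is returned
  exactly.
- **Random starts disperse.** `multistart_validate` re-runs the descent
  from seeded uniform starts in the candidate box (default
  [14,20]×[0,19]×[0,43] MPa^1/2, spanning the recommended test-solvent
  ranges). Convexity guarantees all runs descend toward the same minimum,
  but converged stopping points on the case-study panel spread over
  ~0.4 MPa^1/2 and a minority of starts exhaust the cap — use the report's
  dispersion as an empirical resolution estimate, not as a convergence
  failure of the analytic-start pipeline.

`grid_oracle` is the independent check on all of the above: a brute-force
scan of f over a regular grid (ties broken lexicographically, cell count
capped), which finds the global minimizer to grid resolution without any
descent machinery. Because the median lies in the convex hull of the panel,
a grid spanning the panel's component-wise bounding box suffices.

## Synthetic data generator

`synthetic` provides seeded ground-truth experiments. A material is drawn
uniformly from a Hansen-space box; a panel's absorbances follow

    A_i = max(floor, amplitude · exp(−R_i/τ) + ε_i),  ε_i ~ N(0, noise_sd²),

the simplest monotone link consistent with the estimator's two assumptions.
Defaults: amplitude 1.0 AU (order of a strong band maximum in a 1 cm
cell), τ = 5 MPa^1/2 (about an e-fold of signal loss over a typical
good-solvent radius, giving a realistic dynamic range across a panel
spanning R ≈ 0–35), noise_sd 0.02 AU (bench spectrometer repeatability),
floor 0. `recovery_experiment` draws a truth, samples database solvents,
adds one probe solvent at the truth itself (the favourable regime where
the panel brackets the material), simulates and re-estimates.

What passing recovery tests do and do not show: the generator emulates the
*geometry* the estimator assumes — monotone absorbance in R with additive
noise — so recovery demonstrates internal consistency (the pipeline inverts
its own forward model) and quantifies the stopping-band artifacts above.
It does not validate Beer–Lambert linearity, band-shape stability,
scattering in suspensions, or any chemistry-specific deviation of real
panels from exponential decay; τ and noise_sd for real suspensions are not
characterized here. Estimates always lie in (or within one descent step
of) the convex hull of the panel in scaled coordinates — with no solvent
near the truth the estimator is therefore biased toward the panel's
interior, which no noiseless test can repair.

## Numerical and design choices

- Never round internally; 2-decimal rounding is applied only at display
  and report boundaries, matching tabulation practice in the field.
- Subgradient at a data point: zero contribution (see `eps_guard`).
- Clamping to the non-negative orthant after every step.
- Grid-oracle ties: lexicographic (δD, δP, δH), first-node-wins, so
  results are deterministic under ties.
- Gradient terms are accumulated in panel order with float64; shuffling
  the panel reproduces estimates to ~1e−15 per component (asserted at
  1e−9), not bit-for-bit — exact bitwise permutation invariance would
  require canonical term ordering and is not worth the cost.
- Measurement and database CSVs are read with round-trip float precision,
  and written with shortest-repr floats, so export → import preserves every
  number exactly.
- Degenerate inputs: all-zero absorbance panels are rejected
  (`DegenerateWeightsError`); a single-solvent panel is legal and returns
  that solvent's HSPs immediately; duplicate solvents in one panel are
  rejected; negative HSP components warn at construction, are errors in a
  database, and cannot be produced by the optimizer (clamp).
- The bundled database carries only the 14 case-study solvents (the full
  published solvent handbooks are not redistributable); CAS numbers,
  synonyms and SMILES in the fixture come from standard registry data.
  CAS checksums and SMILES parses are validated as warnings only.

## Known limitations

- Accuracy is panel-dependent: with no strongly absorbing solvent near the
  material, the stopped iterate can sit far (≳1 MPa^1/2) from the weighted
  median, and the weighted median itself sits in the panel's convex hull
  regardless of where the material truly is. Panel design (diverse,
  well-spread solvents, at least one good one) is part of the method.
- No uncertainty quantification beyond the rounding-derived global error.
- No Hansen-sphere radius (R0) or relative energy difference scoring, no
  solvent-blend design, no temperature dependence, and no unit systems
  other than MPa^1/2.
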