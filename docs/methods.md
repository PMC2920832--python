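# Methods

## Model and assumptions

The simulator advances a cell one pseudopod at a time.  The state is the
direction α of the last pseudopod and, if it was a split, its side (R/L).
Each step consumes four uniform random numbers, in a fixed order:

1. `R1 < s` — the next pseudopod is a split, otherwise de novo;
2. for a split whose predecessor was also a split: `R2 < a` — alternate to
   the opposite side, otherwise repeat the side;
3. for a split whose predecessor was de novo: `R3 < 0.5` — right, else left
   (the measurement convention provides no side memory across a de novo
   event);
4. for a de novo pseudopod: direction uniform on the circle via `R4`.

The projected mean direction is α ± ϕ for splits (left = counter-clockwise
= positive; the sign convention is fixed package-wide, the data do not
determine it) or uniform for de novo; the emitted direction adds a von
Mises deviate with concentration κ = 1/σ_ϕ² (σ_ϕ in radians).  σ_ϕ = 0 is a
legal degenerate input handled as a point mass.  The first pseudopod of a
trajectory is uniformly random and carries no side; every step has length
exactly λ_p.

Deliberately **not** modelled (they have only minor effects on trajectories
over many steps, or are properties of real cells outside the model): the
within-step growth dynamics of a pseudopod, variation of pseudopod size and
interval (time is step-indexed; a constant synthetic clock of one pseudopod
per 30 s with a 13 s growth phase fills exported event times), temporal
overlap of two pseudopodia, centroid mechanics, and the slight dip of the
de novo direction distribution near 0°.  Simulated de novo steps that
happen to fall near the previous direction are not re-annotated as splits:
the two misclassification fluxes (random de novo landing inside the
splitting cone, noisy splits leaving it) approximately cancel.

Because the centroid of the cell body turns less sharply than the
pseudopod tip (the rear of a cell, like the rear axle of a car, cuts the
corner; temporally overlapping pseudopodia average directions further),
correlation factors measured on centroid tracks run ~15% above the
pseudopod-level predictions produced here.  This geometric correction is
documented but not implemented.

## Parameters

| Parameter | Meaning                              | Units   | Range    | Typical |
|-----------|--------------------------------------|---------|----------|---------|
| λ_p       | pseudopod size                       | µm      | > 0      | ~5      |
| s         | fraction of splitting pseudopodia    | —       | [0, 1]   | 0.4–0.9 |
| a         | right/left alternation bias          | —       | [0, 1]   | ~0.75   |
| ϕ         | splitting angle                      | degrees | [0, 180] | ~55     |
| σ_ϕ       | SD of the extension angle            | degrees | ≥ 0      | 26–47   |

The built-in strain table (`fixtures.strain_table`) carries the measured
values for wild type at 1/3/5/7 h of starvation and four mutants, plus the
observed and predicted correlation factors; these serve as canonical inputs
throughout.

## Dispersal theory

The MSD closed form ⟨d²(n)⟩ = λ²[n(1+γ)/(1−γ) − 2γ(1−γⁿ)/(1−γ)²] is the
standard steps-and-turns result for a two-dimensional CRW; it is pinned in
the tests by two independent oracles (γ = 0 → nλ² Brownian; n = 2 →
2λ²(1+γ) from expanding |r₁+r₂|²) and has a dedicated ballistic branch at
γ = 1.  `fit_crw` fits γ as the single free parameter with λ fixed at
λ_p·cos(ϕ/2), by unweighted least squares over all lags (default 1..30,
the ~15-minute horizon in which a cell extends ~30 pseudopodia), on the
ensemble MSD (displacement from the origin averaged over trajectories;
time-averaged MSD is deliberately not used).  γ is reported unclamped with
an `in_range` flag.

The pair-level closed form is
γ_pair = s²·[a + (1−a)·cos 2ϕ]·E[cos ε], where ε is the accumulated noise
of a pair (variance 2σ_ϕ²), and γ_step = √γ_pair with the per-step noise
attenuation.  Three attenuation conventions are exposed and none is
silently preferred:

* `"cos"` — cos σ_ϕ, the small-noise surrogate; the default for
  `gamma_step` because it reproduces the published per-step predictions;
* `"von_mises"` — I₁(κ)/I₀(κ) with κ = 1/σ² (κ = 1/(2σ²) at pair level);
* `"wrapped_normal"` — e^(−σ²/2) (e^(−σ²) at pair level).

Note a genuine subtlety: under the κ = 1/σ² convention the von Mises mean
resultant deviates from cos σ by more than 2% well below σ = 40°, so the
often-quoted agreement of the pair and per-step forms ("within a few
percent below σ ≈ 30°") holds cleanly only for the wrapped-normal pairing,
where it is exact up to the cos σ ≈ e^(−σ²/2) approximation.  The test
suite checks the 5% agreement with the wrapped-normal expectation for
σ ≤ 30° and the von Mises variant in its own narrower regime (σ ≤ ~25°).
Above σ ≈ 40° (e.g. the star-shaped formin-null morphology at σ = 46.5°)
all surrogates degrade and per-step predictions carry a wider uncertainty.

The pair reduction also discards the correlation contributed by a split
whose predecessor was de novo.  A faithful simulation is therefore slightly
*more* persistent than γ_step, most visibly at intermediate splitting
fractions: fitted ensemble γ exceeds the closed form by up to ~0.07 at
s ≈ 0.5 and by ≤ 0.03 at s ≥ 0.85.  Tests assert this one-sided gap rather
than a symmetric band.

## Shape parameter Ψ

Ψ compares an outline polygon (~150 nodes, simple, positive area; stored
counter-clockwise) with an area-matched ellipse: the largest ellipse inside
the outline and the smallest outside it are constructed, an intermediate
ellipse is interpolated between them until the cell area outside it (O)
equals its area outside the cell (I), and Ψ = (O + I)/T.

Choices where the construction is genuinely open:

* the inner/outer ellipses share the centre, orientation and axis ratio of
  an algebraic least-squares ellipse fit to the vertices, scaled about the
  centre — deterministic, fast, and exact for elliptical outlines; a
  general maximal-inscribed-ellipse optimisation is out of scope.  The
  outer scale is the largest normalised vertex radius (an ellipse is
  convex, so covering the vertices covers the polygon); the inner scale is
  found by 50 bisection steps on polygon containment and verified at 512
  boundary samples;
* interpolation is parameter-wise and linear in a single scalar t ∈ [0, 1]
  (centre, semi-axes; orientation along the shortest 180°-periodic path) —
  an interpolation of radial distance fields would be an equally valid
  reading;
* boolean areas discretise the ellipse at 256 vertices; the O = I residual
  is bisected to |O − I| ≤ 10⁻³·T (≤ 60 iterations), falling back to the
  |O − I| minimiser with a warning flag if the residual never changes sign.

Under these tolerances Ψ of an exact ellipse evaluates to ~10⁻⁴, and Ψ is
similarity-invariant to ~10⁻³.

## Synthetic data

Generators are pure functions of their spec and seed.  Outlines come in
three kinds: exact ellipses; stars with radial modulation
r(u) = r₀(u)(1 + A·sin ku), chosen because it is star-shaped (always a
simple polygon) and gives Ψ monotone in A; and ellipses with smooth random
low-order Fourier boundary noise.  The empirical coupling
σ_ϕ = 37.6·Ψ + 22.8 is used generatively only — it assigns a
shape-consistent noise level to a synthetic strain; reproducing its slope
from synthetic cells is a non-goal, since it is an empirical property of
real mutants.

`make_event_table` emulates a contour-tracker export: it runs the same
decision tree as the simulator but decomposes split-angle noise into two
independent normal components — tangent wobble (σ_t = 24.9° default) and
deviation from the tangent normal (σ_β = 13.3°, about a mean β = 89.1°) —
so the emitted split-angle SD is √(σ_t² + σ_β²) ≈ 28.2° and each event
carries consistent `tangent_deg`/`beta_deg` columns.  What synthetic tables
do *not* contain: misannotated events, pseudopod-size variation, temporal
overlap, or any chemotactic bias; tests passing on them demonstrate the
internal consistency of the model and estimators, not tracker-level realism.

## Numerical choices

* Angles are degrees at all public interfaces, radians internally,
  normalised to (−180°, 180°]; κ = 1/σ² (σ in radians) package-wide.
* von Mises densities and moments use exponentially-scaled Bessel functions
  (`i0e`, `i1e`), stable at large κ.
* The bimodal ±ϕ mixture fit is bounded maximum likelihood (L-BFGS-B over
  ϕ ∈ [0°, 180°], log κ) from 8 grid starts; ties broken by likelihood,
  then smaller ϕ; an all-|angles|-equal input takes the σ = 0 branch.
  Fitting a von Mises mixture to wrapped-normal data recovers ϕ without
  bias but maps σ through the differing κ conventions (≈26.5° recovered
  for 28° generated); recovery tests on von Mises data are exact.
* Ensembles are simulated in vectorised blocks of 25,000 trajectories, each
  block from an independent child stream spawned from the master seed:
  memory stays bounded, and results are reproducible for a fixed
  (seed, chunk size).
* Ensemble sizes in tests are scaled to the precision each assertion needs
  (3 Monte Carlo standard errors where applicable); the reproduction
  pipeline defaults to the full 100,000 × 30 ensemble, which runs in
  seconds.

## Known limitations

* Predictions are pseudopod-level; centroid-track correlation factors run
  ~15% higher (see above) and no correction is applied.
* The cos σ closed form is a small-noise surrogate; for σ_ϕ ≳ 40° prefer
  the Monte Carlo pipeline.
* The inner/outer ellipse family is tied to the least-squares base fit; for
  pathological outlines whose best-fit ellipse centre falls outside the
  polygon the construction raises rather than guessing.
* The γ–s regression helper is plain OLS on (s, γ) pairs and ignores the
  measurement uncertainty of both coordinates.
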