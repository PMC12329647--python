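# Methods

## Model family

`drivewave` integrates a deterministic three-genotype model of a homing
suppression drive in a 1-D continuous habitat. The state is the vector of
genotype densities (drive homozygotes DD, heterozygotes DW, wild-type
homozygotes WW); total density n is their sum. The model's assumptions:

* **Random mating through a gamete pool.** Offspring genotype frequencies are
  the Hardy–Weinberg products of the post-conversion gamete fractions
  g_D = (n_DD + (1+c) n_DW/2)/n and g_W = 1 − g_D. Germline conversion
  succeeds with probability c; failure leaves the wild-type allele intact
  (no resistance-allele class, no non-homologous end-joining).
* **Fecundity selection.** The drive costs fecundity only: the birth flux
  into each offspring class carries the factor 1−s (DD), 1−sh (DW) or 1 (WW).
  Survival is genotype-independent.
* **Four demographies.** Density dependence acts on births (models BN, BA)
  or on deaths (DN, DA), with (BA, DA) or without (BN, DN) an Allee effect of
  threshold a ∈ [−1, 1]; a < 0 is a weak effect (low-density growth rate
  −ar > 0), a > 0 a strong one. Density is scaled to carrying capacity 1,
  time to a baseline death rate of 1; r is the intrinsic growth rate. Birth
  terms are clamped at 0 pointwise: the BA term goes negative at low density
  under a strong Allee effect, and both births-regulated terms go negative
  during transient overshoot beyond n = 1 + 1/r.
* **Unbiased diffusive movement.** All genotypes share a unit diffusion
  coefficient; space is in units of the dispersal scale.

Parameters and defaults: s, c, h ∈ [0, 1] (no package-wide default — every
analysis states its own; the regime figures use c = 0.85, h ∈ {0.3, 0.9}),
r ≥ 0, a ∈ [−1, 1].

## Analytic layer

All closed-form results assume the wake reaches a fixed allele composition
with mean fecundity F, and solve F·B(n) = D(n) for the final density.

* **Cost thresholds.** s₁ = c/(1 − h(1−c)) and s₂,g = c/(h(1+c)) partition
  the cost axis. s₂,g is where the net production rate of drive alleles by
  rare heterozygotes in a saturated wild-type population,
  λ = (1−sh)(1+c) − 1, changes sign. Sentinels: s₂,g = +∞ at h = 0 and
  s₁ = +∞ at c = 1 (the corresponding band is unreachable for s ≤ 1), so
  region logic composes without exceptions.
* **Interior equilibrium.** In the band between the thresholds (h ≠ 1/2) the
  root p* = (1 − (1−sh)(1+c))/(s(2h−1)) solves
  (2h−1)s·p + (1−sh)(1+c) − 1 = 0. For the genotype-density system this
  root is the equilibrium **gamete-pool** drive fraction g_D: the interior
  equilibrium satisfies F(g) = (1−s)g + (1+c)(1−sh)(1−g), which is the same
  equation rearranged. The adult allele frequency at that equilibrium is
  lower (0.528 vs 0.849 at s=0.95, c=0.85, h=0.3) because standing adult
  genotypes are not at Hardy–Weinberg under strong selection; the wake
  density is governed by F evaluated at the gamete-pool root, and the
  simulations confirm this to well under 1%.
* **Wake regimes.** With K = (1−F)/(rF) (births-regulated) or
  K′ = (r+1)(1−F)/r (deaths-regulated), the Allee models persist or go
  extinct according to the roots n± = [1+a ± √((1+a)² − 4(a+K))]/2: no real
  root means eradication; a negative low-density growth rate
  (F·B(0) < D(0)) makes the outcome bistable with basin threshold n_τ = n−.
  The no-Allee models have the single root n⁺ = 1 − K (BN) or 1 − K′ (DN)
  and no density bistability. Boundary ties are assigned to the less
  persistent regime (a measure-zero, conservative choice).
* **Pulled speeds.** When λ > 0 the drive front is pulled by its low-density
  leading edge: v = 2√λ for births regulation and 2√((1+r)λ) for deaths
  regulation — the deaths-regulated front turns over r+1 times faster at
  carrying capacity, and the speed is independent of a because the front
  sits in a population above any Allee threshold. The implementation follows
  these closed forms, giving a speed ratio √(1+r) between the two families,
  and the measured ratio in simulations matches √(1+r) to ~2%.

## Numerical scheme

Diffusion is discretised with second differences in finite-volume form
(zero-flux boundaries; column sums vanish, so pure diffusion conserves mass
to solver precision) and advanced by the Crank–Nicolson trapezoidal rule.
The nonlinear reaction advances inside the same step as the average of its
value at the current state and at an explicit one-step predictor
(Heun-type), so the full step is second-order in time without a nonlinear
solve; the tridiagonal systems are solved directly per genotype. Small
negative undershoots (of the order of the truncation error) are floored at 0
after each step. The empirical convergence order of the measured wave speed
under joint (dx, dt) halving is ≈ 1.87.

Reference discretisation: dt = 1/6, dx = 1, horizon T = 500, initial
condition pure drive at density 1 on the left half of the domain and pure
wild type on the right (midpoint node assigned to the wild-type side).
Choices the reference setting leaves open, fixed here:

* **Boundary conditions** are zero-flux. The default domain length is
  max(300, ⌈2 v_est T⌉ + 100) with v_est the analytic pulled speed when it
  exists (300 otherwise): the interface starts at L/2, so this keeps the
  front inside the window until T with a 100-unit margin clear of the
  boundary.
* **Time step at high growth rate.** Per-capita rates scale with 1+r, so the
  reference dt = 1/6 loses accuracy once (1+r)·dt is of order 1 (at r = 30
  it misclassifies outcomes). Sweeps use dt = min(1/6, 1/(3(1+r)))
  (`solver.suggested_dt`).
* **Grid spacing for speed measurements.** The pulled-front speed on a
  lattice is biased upward by O(dx²); at dx = 1 the bias is ≈ 2% for the
  births-regulated family and ≈ 6% for deaths regulation at r = 3. Speed
  measurements therefore use dx = 1/2 (bias ≲ 2%).
* **Division guard.** The mating brackets are quadratic over n; below
  n = 10⁻¹² birth terms are set to their analytic limit 0 to avoid 0/0.

## Front tracking and outcome classification

The front is the rightmost level-0.5 crossing of the drive allele frequency,
linearly interpolated, with frequency treated as undefined where total
density is below ε_erad = 10⁻³ (so eradicated-wake debris is ignored). An
eradication wave at low r travels as a low-density pulse whose frequency
front lies in that masked vacuum; the tracker then falls back to the
half-maximum crossing of the drive allele *density* profile. Speed is the
least-squares slope of front position over the second half of the run.

Classification order: (1) *gene-drive clearance* when the drive allele mass
decreases over the last quarter of the run and no front survives late;
(2) *coexistence* when the intermediate-frequency zone's two edges have moved
≥ 5 space units in opposite directions; (3) otherwise the signed speed
decides drive vs wild-type invasion, and for drive invasions the wake
density (spatial mean of total density over the leftmost 10% of the domain
at final time) sets the wake state: ≥ 1 − 10⁻² replacement, < 10⁻³
eradication, suppression in between. Runs matching none of the patterns are
reported `unclassified` with diagnostics rather than guessed.

At finite growth rate the qualitative outcome table (derived at r = 0 and
r → ∞) leaves some cells genuinely open, and the validation helper
`experiments.expected_wave_types` encodes the finite-r reading: below both
thresholds the drive always invades; at r = 0 it invades exactly when the
pulled wave exists (s < s₂,g) and otherwise clears; above both thresholds
the wild type wins, but when the drive bulk is in its eradication regime
(r < s/(1−s) for a pure-drive wake) it collapses in place before a wild-type
front can sweep it, which presents as clearance — at c = 0.85, h = 0.9 a
persistent drive bulk above s₁ would require r > 56, so sweeps at moderate r
legitimately see clearance there; in the intermediate band the outcome is
coexistence (h < 1/2) or initial-condition-dependent (h > 1/2), with the
collapse-degenerate analogues admissible when the relevant wake cannot
persist.

## Scope of the validation suite

All inputs are generated programmatically (parameter draws, initial
conditions); there is no observational data anywhere. The simulations are
therefore checked against independent *analytic* oracles — closed-form
equilibria, linearised speeds, and the well-mixed ODE integrated by an
adaptive stiff solver — not against biological measurements: a passing suite
shows the solver and classifier faithfully realise this model family, not
that the family describes any particular organism. Problem sizes used by the
validation runs: 200 random parameter draws for the ODE/regime comparison;
speed runs to T = 500 on domains of up to ~3,500 space units at dx = 1/2;
a 72-cell (r, s, h) outcome sweep at T = 150; a three-level refinement study
at T = 150.

## Known limitations

Deterministic dynamics only: no demographic stochasticity, so wild-type
"chasing" recolonisation behind an eradication wave cannot occur. One
spatial dimension, homogeneous habitat, one-sex model, no age or stage
structure, no resistance alleles, fecundity-only fitness costs. The
half-domain initial condition maximises the chance of drive spread; outcomes
in the threshold-dependent band depend on it. Equal diffusion for all
genotypes. Behaviour of the demographic rate functions for n > 1 follows the
formulas as written (plus the non-negativity clamp); the models are only
interpreted on densities of order the carrying capacity.
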