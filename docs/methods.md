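# Methods

## Model

A protein carries n ligand-binding sites, each exchanging ligand by mass
action with association rate `k⁺ᵢ` and dissociation rate `k⁻ᵢ`
(`Kᵢ = k⁻ᵢ/k⁺ᵢ`). Sites are independent unless stated otherwise, so the
protein's 2ⁿ molecular forms (indexed by the occupancy bit vector, bit i =
site i) have product-form probabilities. All experiments modelled here are
*concentration jumps*: the system is equilibrated at a pre-jump ligand
level for t < 0, the level steps instantaneously at t = 0, and the
conformational distribution relaxes. Negative times are rejected by the
API; the pre-jump state is queried through the steady-state functions.

Two physiological regimes:

1. **Abundant ligand** — free ligand is clamped (ligand ≫ protein, no
   buffering). Each site relaxes independently and mono-exponentially with
   `τ(U₁) = K/(k⁻(U₁+K))`; every form concentration is a product of
   single-site exponentials. This makes all derived metrics closed-form.
2. **Conserved ligand** — total ligand `U_T` is fixed and comparable to the
   protein concentration, so binding depletes free ligand
   (`U + bound = U_T`). The single-site case is a Riccati-type nonlinear
   ODE with an exact tanh-like solution built from
   `F(u_T) = √((u_T−l_T)² + 2(u_T+l_T) + 1)` (computed internally in the
   equivalent stable form `hypot(u_T−l_T+1, 2√l_T)`). n identical sites are
   treated by pooling all n·L_T sites into one single-site system and
   assembling conformations as `N_m/L_T = p₁^m p₀^{n−m}`.

**Exactness of the pooled construction.** For *identical* sites the pooled
model is not an approximation: every site sees the same deterministic free
ligand U(t), so a product (binomial) form distribution propagates exactly,
and the common occupancy p(t) obeys precisely the pooled single-site ODE.
The oracle comparison (`multikin.oracle.validate_all`,
`conserved_mean_field_gap_n4`) measures the residual at solver tolerance
(~1e-10), not at a modelling-error scale. The construction is *not* valid
for heterogeneous affinities under conservation (the pooled quadratic has
no per-site meaning there); the conserved regime therefore accepts
identical sites only.

**Cooperativity** is modelled at the domain level (calmodulin
architecture): two independent domains, each a pair of identical sites
whose dissociation constant tightens from K to K^c when the neighbour is
occupied. The 4-state domain scheme has a closed steady state
(`a₀, a₁, a₂ ∝ K·K^c, U·K^c, U²` over `U² + 2K^cU + K·K^c`); kinetics after
a jump are linear at fixed post-jump ligand and are integrated numerically
(no closed form exists for the 4-state relaxation). The whole molecule's
m-bound conformations combine the two domain distributions
multiplicatively and are class-aggregated by construction.

## Conventions and units

- Non-dimensional variables are canonical: `u = U/K`, `η = t·k⁻`,
  concentrations as fractions of L_T. Dimensional entry points
  (`SiteParams`, `ConservedSystem` with physical K, k⁻) convert at the
  boundary. CaM fixtures are in µM.
- **Per-form vs class-aggregated:** identical-site results default to
  per-form (one specific occupancy pattern, no binomial coefficient) —
  this is the convention under which the printed maxima 0.105/0.063 arise.
  Class-aggregated values (×C(n,m)) are available via
  `independent.class_aggregate` and the CLI `--convention aggregated`.
  The cooperative whole-molecule distribution is inherently
  class-aggregated.
- Form indexing: `j = Σ 2^i·cᵢ`, LSB = first site.

## Parameters that matter

| parameter | meaning | default / fixture |
|---|---|---|
| n | number of sites | 4 (CaM-like); enumeration capped at 16 |
| K, k⁻ | site dissociation constant and off-rate | 1 (non-dimensional) |
| h, h⁻ | per-site association/dissociation ratios vs site 1 | (1, 0.9, 0.8, 0.7) "marginal"; (1, 0.6, 0.2, 0.1) "significant" |
| K, K^c per domain | intrinsic / cooperative dissociation constants | 0.9/0.2 and 0.8/0.1 µM (CaM) |
| kc⁻ | cooperative off-rate | = k⁻ (not fixed by equilibrium data; free parameter) |
| L_T/K | protein level in the conserved regime | 2 (weak buffering), 50 (strong), 3 (time-metric sweeps) |
| jump protocols | (u₀, u₁) or (u_T0, u_T1) | 0.1→10 (abundant), 0.01→200 (buffered), 0.1→U_T1 sweeps |

## Numerical choices

- ODE integration (oracle and cooperative kinetics): `solve_ivp` with
  LSODA, rtol 1e-9, atol 1e-12; initial conditions are computed
  analytically from the pre-jump equilibrium, never by pre-integration.
- Root finding (bell half-widths, EC50 confirmations): Brent's method on
  log-u with brackets `[u_peak·1e−6, u_peak]` and `[u_peak, u_peak·1e6]`
  (the bell is monotone on each side of its peak).
- Time grids for argmax/crossing confirmations: geometric over
  `η ∈ [1e−6, 50/(1+u₁)]`, which resolves the early transient at any jump
  size.
- Degenerate cases: a null jump returns the constant steady state (the
  conserved-regime jump constant C is singular there and is special-cased);
  time-to-maximum expressions whose logarithm degenerates return the
  `MONOTONIC` sentinel (serialised as JSON null) rather than a complex
  value. Downward jumps are supported wherever the algebra remains valid
  (form time courses, half-transition times, the conserved n = 1
  solution); time-to-maximum functions require upward jumps and raise
  otherwise.
- The site-count inversion from the saturated form's EC50 uses ln 2 by
  default; `paper_faithful=True` substitutes the rounded literal 0.693
  (difference < 0.1 %).

## Known discrepancies and open choices

- **Bound ligand at U = K.** Direct summation of `Σⱼ Mⱼ·(bound count)`
  over all 2ⁿ forms at u = 1 gives exactly half of saturation
  (`n·L_T/2`, the binomial mean at p = ½) for every n. A printed claim
  that this ratio is ¼ is inconsistent with the direct sum;
  `bound_ligand_at_K` computes the direct sum and this note records the
  discrepancy. Nothing asserts the ¼ value.
- **Dose–response width A_n.** The linear width `u(0.9) − u(0.1)` of the
  saturated form *grows* with n (the transition shifts right roughly ∝ n)
  while its span in decades shrinks; "steepening with n" is a log-axis
  statement. `saturation_width` exposes both scales.
- **Non-cooperative comparison.** Comparisons against the cooperative CaM
  model use K^c = K with K equal to each domain's intrinsic constant;
  this choice is exposed (`without_cooperativity()`), not hard-coded into
  results.

## What the tests do and do not show

The suite verifies internal mathematical consistency (closed forms vs
independent mass-action integration, limiting-case reductions, conservation
laws) and reproduction of the model's own headline numbers. It does not
test against experimental stopped-flow/pressure-jump data, heterogeneous
sites under ligand conservation, sequential (Adair–Klotz-type) binding
order, stochastic single-molecule effects, or downstream effector
activation — all outside this package's scope. Oracle-equivalence tests
use seeded random parameter draws over log-uniform ranges
(K, k⁻ ∈ [0.1, 10], ligand levels ∈ [0.01, 100]·K, protein levels up to
~30·K in the buffered regime); problem sizes (n ≤ 6 for random draws,
50 draws per model, grids of 25–150 points) keep each check at desk scale
while covering the fast/slow-separation extremes.
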