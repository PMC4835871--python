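# multikin

Closed-form kinetics of multisite ligand–protein binding, with independent
mass-action ODE validation.

Many signalling proteins carry several binding sites for the same ligand —
calmodulin, troponin C and calcineurin each bind four Ca²⁺ ions — and their
biological activity depends not just on *how much* ligand is bound but on
the distribution of conformations with 0, 1, …, n bound ligands, and on how
that distribution evolves after a rapid change in ligand concentration
(concentration-jump, flash-photolysis or stopped-flow experiments).
`multikin` implements exact and closed-form solutions for this problem and
the dose–response/transient metrics derived from them, in two regimes:

- **Abundant ligand** (free ligand clamped): after a step `U₀ → U₁` each
  site relaxes mono-exponentially with `τ(U₁) = K/(k⁻(U₁+K))`, and the
  concentration of any molecular form factorises,
  `M_j(U,t) = L_T ∏ᵢ pᵢ^{cᵢ(j)}(U,t)` with `p¹ᵢ = U/(Kᵢ+U)` at equilibrium.
  For n identical sites the per-form fraction is
  `N_m/L_T = u^m/(1+u)^n` (`u = U/K`), the intermediates peak at
  `u_m^max = m/(n−m)` with magnitude `m^m(n−m)^{n−m}/n^n`, and the times at
  which intermediates peak, or the apo/saturated forms cross their half
  levels, are closed-form in `η = t·k⁻`.
- **Conserved ligand** (buffered): total ligand is fixed,
  `U + bound = U_T`, as when the ligand pool is comparable to the protein
  concentration. The single-site relaxation is solved exactly (a tanh-like
  form built from `F(u_T) = √((u_T−l_T)² + 2(u_T+l_T) + 1)`), and n
  identical sites are handled by pooling all `n·L_T` sites into one such
  system — a construction that turns out to be exact for identical sites.

Cooperativity is modelled for the calmodulin architecture: two independent
EF-hand domains, each a pair of identical cooperative sites whose
dissociation constant tightens from `K` to `K^c` once the neighbour is
occupied (CaM values `K₁ = 0.9, K₁ᶜ = 0.2, K₂ = 0.8, K₂ᶜ = 0.1 µM` ship as
fixtures).

Every closed form is validated against brute-force mass-action integration
(`multikin.oracle`): the 2ⁿ-form system, the occupancy chain, the 4-state
cooperative domain, and the chain coupled to a dynamic free-ligand variable.

## Worked example

```python
>>> import multikin as mk
>>> mk.n_max(4, 1), mk.n_max(4, 2), mk.u_max(4, 3)
(0.10546875, 0.0625, 3.0)
```

A four-site protein's singly-bound conformation never exceeds ≈ 10.5 % of
the total protein (per molecular form), the doubly-bound form 6.3 %, and the
triply-bound form peaks at a ligand level of 3 K. After a ligand step from
`u₀ = 0.1` to `u₁ = 10`:

```python
>>> mk.tau_m_max(4, 1, 0.1, 10.0)
0.019656646224512363
>>> mk.tau_half(4, 0.1, 10.0, "apo"), mk.tau_half(4, 0.1, 10.0, "saturated")
(0.017682324132388186, 0.15754285735849047)
>>> mk.tau_m_max(4, 3, 0.1, 2.9)
'monotonic'
```

i.e. the singly-bound intermediate peaks at `η ≈ 0.0197`, the apo form
crosses its half-fall at `η ≈ 0.0177`, the saturated form half-rises at
`η ≈ 0.158`, and for `u₁ < 3` the triply-bound intermediate has no
transient overshoot at all (it rises monotonically — the `'monotonic'`
sentinel). The same quantities are available from the shell:

```bash
multikin jump --n 4 --u0 0.1 --u1 10 --out jump.csv --summary jump.json
multikin cam --u0 0 --u1 1            # calmodulin Ca²⁺ jump (µM units)
multikin conserved --n 4 --lt 3 --ut0 0.1 --ut1 10
multikin validate                     # oracle-vs-closed-form deviations
multikin figures all                  # regenerate all reference curve sets
```

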