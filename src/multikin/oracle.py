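"""Brute-force mass-action integrators validating every closed form.

Each scheme in the package has an independent ODE representation here,
integrated with a stiff-capable method (LSODA, rtol 1e-9 / atol 1e-12) from
analytically computed pre-jump equilibria.  None of these integrators share
code with the closed-form modules they check:

- ``integrate_chain``: the (n+1)-state occupancy-class master equation for
  n identical sites at clamped ligand (rates (n-m)*k+ *U up, m*k- down).
- ``integrate_full_forms``: all 2**n molecular forms of an independent
  (possibly heterogeneous) protein at clamped ligand.
- ``integrate_cooperative``: the four-state cooperative domain.
- ``integrate_conserved``: the occupancy chain coupled to a dynamic free
  ligand variable under total-ligand conservation.

``validate_all`` runs the whole oracle-vs-closed-form comparison and
reports maximal deviations.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import comb

from . import conserved as cons
from . import identical as ident
from .cooperative import CooperativeDomainParams, domain_steady
from .independent import IndependentProtein, bits_of_form, form_timecourse
from .site_kinetics import JumpProtocol

__all__ = [
    "integrate_chain",
    "integrate_full_forms",
    "integrate_cooperative",
    "integrate_conserved",
    "validate_all",
]

_RTOL = 1e-9
_ATOL = 1e-12


def _solve(rhs, y0, t_grid):
    t_grid = np.asarray(t_grid, dtype=float)
    t_end = float(t_grid[-1]) if t_grid[-1] > 0 else 1.0
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, t_eval=t_grid, method="LSODA",
        rtol=_RTOL, atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    return sol.y


def integrate_chain(
    n: int, K: float, k_minus: float, U0: float, U1: float, t_grid, L_T: float = 1.0
) -> np.ndarray:
    """Occupancy-class concentrations (rows m = 0..n) at clamped post-jump U1.

    Class m gains from class m-1 at rate (n-m+1)*k+*U and from m+1 at rate
    (m+1)*k-.  Initial condition: binomial equilibrium at U0.  Per-form
    values follow by dividing row m by C(n, m).
    """
    if n > 16:
        raise ValueError("chain oracle limited to n <= 16")
    k_plus = k_minus / K
    p1 = U0 / (K + U0)
    m_arr = np.arange(n + 1)
    y0 = L_T * comb(n, m_arr) * p1**m_arr * (1 - p1) ** (n - m_arr)
    up = k_plus * U1  # per free site

    def rhs(_t, y):
        dy = np.empty_like(y)
        flux_up = up * (n - m_arr[:-1]) * y[:-1]  # m -> m+1
        flux_dn = k_minus * m_arr[1:] * y[1:]  # m -> m-1
        dy[:] = 0.0
        dy[:-1] -= flux_up
        dy[1:] += flux_up
        dy[1:] -= flux_dn
        dy[:-1] += flux_dn
        return dy

    return _solve(rhs, y0, t_grid)


def integrate_full_forms(
    protein: IndependentProtein, jump: JumpProtocol, t_grid
) -> np.ndarray:
    """All 2**n molecular-form concentrations at clamped post-jump ligand.

    Transitions flip one bit at a time: site i binds at k_i+*U1 and releases
    at k_i-.  Initial condition: product equilibrium at U0.
    """
    n = protein.n
    if n > 10:
        raise ValueError("full-form oracle limited to n <= 10")
    nforms = 2**n
    # product-form equilibrium at U0 (independent sites)
    y0 = np.empty(nforms)
    p1s = [jump.U0 / (s.K + jump.U0) for s in protein.sites]
    for j in range(nforms):
        bits = bits_of_form(j, n)
        v = protein.L_T
        for i, c in enumerate(bits):
            v *= p1s[i] if c else 1.0 - p1s[i]
        y0[j] = v

    kp = np.array([s.k_plus for s in protein.sites])
    km = np.array([s.k_minus for s in protein.sites])
    U1 = jump.U1

    # precompute sparse transition structure
    transitions = []  # (j_from, j_to, rate)
    for j in range(nforms):
        for i in range(n):
            if (j >> i) & 1:
                transitions.append((j, j ^ (1 << i), km[i]))  # unbind
            else:
                transitions.append((j, j ^ (1 << i), kp[i] * U1))  # bind
    src = np.array([t[0] for t in transitions])
    dst = np.array([t[1] for t in transitions])
    rate = np.array([t[2] for t in transitions])

    def rhs(_t, y):
        flux = rate * y[src]
        dy = np.zeros_like(y)
        np.subtract.at(dy, src, flux)
        np.add.at(dy, dst, flux)
        return dy

    return _solve(rhs, y0, t_grid)


def integrate_cooperative(
    params: CooperativeDomainParams, U0: float, U1: float, t_grid
) -> np.ndarray:
    """Four-state cooperative domain (A00, A10, A01, A11) at clamped U1."""
    a0, a1, a2 = domain_steady(params, U0)
    y0 = params.A_T * np.array([a0, a1, a1, a2])
    kp, km = params.k1_plus, params.k1_minus
    kcp, kcm = params.kc1_plus, params.kc1_minus

    def rhs(_t, y):
        A00, A10, A01, A11 = y
        return [
            -2 * kp * A00 * U1 + km * (A10 + A01),
            kp * A00 * U1 - km * A10 - kcp * A10 * U1 + kcm * A11,
            kp * A00 * U1 - km * A01 - kcp * A01 * U1 + kcm * A11,
            kcp * (A01 + A10) * U1 - 2 * kcm * A11,
        ]

    return _solve(rhs, y0, t_grid)


def integrate_conserved(
    system: cons.ConservedSystem, jump: cons.TotalLigandJump, t_grid
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy chain with dynamic free ligand under total conservation.

    Returns (class concentrations rows m = 0..n, free ligand U(t)).  The
    pre-jump equilibrium is computed from the closed-form conserved steady
    state at U_T0 (exact for any n: free ligand solves the same pooled
    quadratic, and classes are binomial in it); the post-jump free ligand
    evolves as U = U_T1 - sum_m m*N_m.
    """
    n = system.n
    if n > 16:
        raise ValueError("conserved oracle limited to n <= 16")
    K, k_minus, L_T = system.K, system.k_minus, system.L_T
    k_plus = k_minus / K
    m_arr = np.arange(n + 1)

    # equilibrium at U_T0: free ligand from pooled quadratic, then binomial
    lt = system.lt_pool
    ut0 = jump.U_T0 / K
    F0 = float(cons.aux_F(ut0, lt))
    p1_eq = (lt + ut0 + 1.0 - F0) / (2.0 * lt)
    y0 = L_T * comb(n, m_arr) * p1_eq**m_arr * (1 - p1_eq) ** (n - m_arr)

    U_T1 = jump.U_T1

    def rhs(_t, y):
        U = U_T1 - float(m_arr @ y)
        dy = np.zeros_like(y)
        flux_up = k_plus * U * (n - m_arr[:-1]) * y[:-1]
        flux_dn = k_minus * m_arr[1:] * y[1:]
        dy[:-1] -= flux_up
        dy[1:] += flux_up
        dy[1:] -= flux_dn
        dy[:-1] += flux_dn
        return dy

    classes = _solve(rhs, y0, t_grid)
    U_free = U_T1 - m_arr @ classes
    return classes, U_free


def validate_all(n_draws: int = 10, seed: int = 0) -> dict:
    """Run the oracle-vs-closed-form suite; return max deviations per model.

    Random parameter draws are log-uniform over physiologically wide ranges;
    each entry reports the worst absolute deviation observed.
    """
    rng = np.random.default_rng(seed)
    report: dict[str, float] = {}

    # identical-sites chain vs closed form
    worst = 0.0
    for _ in range(n_draws):
        n = int(rng.integers(1, 7))
        u0, u1 = sorted(10.0 ** rng.uniform(-2, 2, size=2))
        eta = np.geomspace(1e-4, 50.0 / (1.0 + u1), 60)
        classes = integrate_chain(n, 1.0, 1.0, u0, u1, eta)
        for m in range(n + 1):
            closed = ident.jump_form_timecourse(n, m, u0, u1, eta)
            per_form = classes[m] / comb(n, m)
            worst = max(worst, float(np.max(np.abs(per_form - closed))))
    report["identical_chain_max_abs_dev"] = worst

    # heterogeneous full forms vs product closed form
    worst = 0.0
    for _ in range(n_draws):
        n = int(rng.integers(1, 5))
        protein = IndependentProtein.from_h_constants(
            h=[1.0] + list(10.0 ** rng.uniform(-1, 1, size=n - 1)),
            h_minus=[1.0] + list(10.0 ** rng.uniform(-0.5, 0.5, size=n - 1)),
        )
        jump = JumpProtocol(*10.0 ** rng.uniform(-2, 2, size=2))
        t = np.geomspace(1e-4, 30.0, 50)
        forms = integrate_full_forms(protein, jump, t)
        for j in range(2**n):
            closed = form_timecourse(protein, jump, j, t)
            worst = max(worst, float(np.max(np.abs(forms[j] - closed))))
    report["independent_forms_max_abs_dev"] = worst

    # conserved n = 1 exact solution vs nonlinear oracle
    worst = 0.0
    for _ in range(n_draws):
        system = cons.ConservedSystem(n=1, L_T=float(10.0 ** rng.uniform(-1, 1.5)))
        jump = cons.TotalLigandJump(*10.0 ** rng.uniform(-2, 2, size=2))
        t = np.geomspace(1e-4, 30.0, 50)
        classes, U_free = integrate_conserved(system, jump, t)
        _, L1, U = cons.jump_single_timecourse(system, jump, t)
        worst = max(
            worst,
            float(np.max(np.abs(classes[1] - L1))),
            float(np.max(np.abs(U_free - U))),
        )
    report["conserved_single_max_abs_dev"] = worst

    # mean-field multisite conserved model vs full chain (approximation gap)
    system = cons.ConservedSystem(n=4, L_T=3.0)
    jump = cons.TotalLigandJump(0.1, 20.0)
    t = np.geomspace(1e-4, 30.0, 80)
    classes, _ = integrate_conserved(system, jump, t)
    worst = 0.0
    for m in range(5):
        mf = cons.form_timecourse_conserved(system, jump, m, t)
        per_form_frac = classes[m] / (comb(4, m) * system.L_T)
        worst = max(worst, float(np.max(np.abs(per_form_frac - mf))))
    report["conserved_mean_field_gap_n4"] = worst

    return report
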