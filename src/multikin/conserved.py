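"""Ligand-conserved (buffered) binding: total ligand U_T is fixed.

When ligand and protein concentrations are comparable, binding depletes the
free ligand: U(t) + S(t) = U_T.  For a single site this nonlinear two-state
system has an exact closed-form relaxation after a total-ligand jump
U_T0 -> U_T1, built from the discriminant-like auxiliary

    F(u_t) = sqrt((u_t - l_t)**2 + 2*(u_t + l_t) + 1)

(u_t = U_T/K, l_t = L_T/K) and the jump constant

    C = (F(u_t0) + F(u_t1) + d) / (F(u_t0) - F(u_t1) + d),  d = u_t1 - u_t0.

For n identical sites the model treats the whole site pool n*L_T as one
single-site system (mean-field construction: all F, C evaluated with
l_t = n*L_T/K) and assembles conformations as N_m/L_T = p1^m p0^(n-m).
This is exact for n = 1 and an approximation for n > 1, quantified against
the full nonlinear chain in :mod:`multikin.oracle`.

The conserved regime here assumes identical sites; heterogeneous affinities
with ligand conservation are not supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .identical import MONOTONIC

__all__ = [
    "ConservedSystem",
    "TotalLigandJump",
    "aux_F",
    "aux_C",
    "steady_single",
    "jump_single_timecourse",
    "mean_field_site_probabilities",
    "form_timecourse_conserved",
    "steady_form_conserved",
    "u_max_conserved",
    "ec50_conserved",
    "tau_m_max_conserved",
    "tau_half_conserved",
]


@dataclass(frozen=True)
class ConservedSystem:
    """n identical sites per protein under total-ligand conservation."""

    n: int
    K: float = 1.0
    k_minus: float = 1.0
    L_T: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError("n must be an integer >= 1")
        for name in ("K", "k_minus", "L_T"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")

    @property
    def lt_pool(self) -> float:
        """Site-pool concentration n*L_T in units of K."""
        return self.n * self.L_T / self.K


@dataclass(frozen=True)
class TotalLigandJump:
    """Step of the total ligand from U_T0 to U_T1 at t = 0."""

    U_T0: float
    U_T1: float

    def __post_init__(self) -> None:
        if self.U_T0 < 0 or self.U_T1 < 0:
            raise ValueError("total ligand must be non-negative")


def aux_F(ut, lt):
    """F = sqrt((ut - lt)**2 + 2*(ut + lt) + 1), in units of K.

    Evaluated in the algebraically equivalent stable form
    hypot(ut - lt + 1, 2*sqrt(lt)).
    """
    ut = np.asarray(ut, dtype=float)
    return np.hypot(ut - lt + 1.0, 2.0 * np.sqrt(lt))


def aux_C(ut0: float, ut1: float, lt: float) -> float:
    """Jump constant C; singular at ut1 == ut0 (handled by callers)."""
    d = ut1 - ut0
    F0 = float(aux_F(ut0, lt))
    F1 = float(aux_F(ut1, lt))
    denom = F0 - F1 + d
    if denom == 0.0:
        raise ZeroDivisionError("C is singular (no jump)")
    return (F0 + F1 + d) / denom


def _x_of_eta(eta, ut0: float, ut1: float, lt: float):
    """x(eta) = F1 * (C e^{eta F1} + 1)/(C e^{eta F1} - 1), overflow-safe.

    x interpolates from F(ut0) + d at eta = 0 to F(ut1) as eta -> inf and
    carries the entire time dependence of the conserved-ligand solution.
    """
    eta = np.asarray(eta, dtype=float)
    F1 = float(aux_F(ut1, lt))
    C = aux_C(ut0, ut1, lt)
    w = np.exp(-eta * F1)  # divide through by e^{eta F1}: safe for eta >= 0
    return F1 * (C + w) / (C - w)


def _probs_from_x(x, ut1: float, lt: float):
    p0 = (lt - ut1 - 1.0 + x) / (2.0 * lt)
    p1 = (lt + ut1 + 1.0 - x) / (2.0 * lt)
    return p0, p1


def steady_single(system: ConservedSystem, U_T):
    """Equilibrium (L0, L1, U_free) of the single-site buffered system.

    The positive root of the conservation quadratic:
    L1 = (K/2) * (l_t + u_t + 1 - F); satisfies both the binding isotherm
    L1 = L_T*U/(K+U) and the conservation U + L1 = U_T.
    """
    if system.n != 1:
        raise ValueError("steady_single requires n = 1 (use steady_form_conserved)")
    K, L_T = system.K, system.L_T
    ut = np.asarray(U_T, dtype=float) / K
    lt = L_T / K
    F = aux_F(ut, lt)
    L1 = 0.5 * K * (lt + ut + 1.0 - F)
    L0 = L_T - L1
    U = np.asarray(U_T, dtype=float) - L1
    return L0, L1, U


def jump_single_timecourse(system: ConservedSystem, jump: TotalLigandJump, t):
    """Exact (L0(t), L1(t), U_free(t)) after a total-ligand step, n = 1.

    Closed tanh-like form; U(t) + L1(t) = U_T1 for t > 0 and the t -> inf
    limit equals :func:`steady_single` at U_T1.  A null jump returns the
    constant steady state (the jump constant C is singular there).
    """
    if system.n != 1:
        raise ValueError("jump_single_timecourse requires n = 1")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    K, L_T = system.K, system.L_T
    lt = L_T / K
    if jump.U_T1 == jump.U_T0:
        L0, L1, U = steady_single(system, jump.U_T1)
        shape = np.broadcast_shapes(t.shape, ())
        ones = np.ones(shape) if t.ndim else 1.0
        return L0 * ones, L1 * ones, U * ones
    eta = t * system.k_minus
    x = _x_of_eta(eta, jump.U_T0 / K, jump.U_T1 / K, lt)
    p0, p1 = _probs_from_x(x, jump.U_T1 / K, lt)
    L1 = L_T * p1
    return L_T * p0, L1, jump.U_T1 - L1


def mean_field_site_probabilities(system: ConservedSystem, jump: TotalLigandJump, t):
    """(p0, p1, u_free) of one site under the pooled mean-field model.

    All auxiliaries are evaluated at the site-pool concentration n*L_T;
    p0 + p1 = 1 identically and U(t) = U_T1 - n*L_T*p1(t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    K = system.K
    lt = system.lt_pool
    ut1 = jump.U_T1 / K
    if jump.U_T1 == jump.U_T0:
        F = float(aux_F(ut1, lt))
        x = np.full_like(t, F) if t.ndim else F
    else:
        x = _x_of_eta(t * system.k_minus, jump.U_T0 / K, ut1, lt)
    p0, p1 = _probs_from_x(x, ut1, lt)
    u_free = ut1 - lt * p1
    return p0, p1, u_free


def form_timecourse_conserved(system: ConservedSystem, jump: TotalLigandJump, m: int, t):
    """Conformation fraction N_m/L_T = p1^m p0^(n-m) under ligand conservation."""
    n = system.n
    if not (0 <= m <= n):
        raise ValueError(f"m = {m} out of range for n = {n}")
    p0, p1, _ = mean_field_site_probabilities(system, jump, t)
    out = p1**m * p0 ** (n - m)
    return float(out) if np.ndim(out) == 0 else out


def _steady_probs(system: ConservedSystem, U_T):
    lt = system.lt_pool
    ut = np.asarray(U_T, dtype=float) / system.K
    F = aux_F(ut, lt)
    p1 = (lt + ut + 1.0 - F) / (2.0 * lt)
    return 1.0 - p1, p1


def steady_form_conserved(system: ConservedSystem, m: int, U_T):
    """Steady conformation fraction N_m/L_T as a function of total ligand."""
    n = system.n
    if not (0 <= m <= n):
        raise ValueError(f"m = {m} out of range for n = {n}")
    p0, p1 = _steady_probs(system, U_T)
    out = p1**m * p0 ** (n - m)
    return float(out) if np.ndim(out) == 0 else out


def u_max_conserved(system: ConservedSystem, m: int) -> float:
    """Total ligand U_T maximising intermediate m: m*(L_T + K/(n-m)).

    Reduces to the abundant-ligand peak m*K/(n-m) as L_T -> 0; the peak
    value itself is unchanged by buffering (same m^m (n-m)^(n-m)/n^n).
    """
    n = system.n
    if not (1 <= m <= n - 1):
        raise ValueError(f"interior m required (1..{n - 1}), got {m}")
    return m * (system.L_T + system.K / (n - m))


def ec50_conserved(system: ConservedSystem) -> tuple[float, float]:
    """Total-ligand levels halving the apo form and half-filling the saturated.

    U_0_half = (1 - r) * (n*L_T + K/r),
    U_n_half = r * (n*L_T + K/(1 - r)),  r = 0.5**(1/n).

    Both exceed their abundant-ligand counterparts by the ligand consumed in
    binding (strictly increasing in L_T); L_T -> 0 recovers the K-unit EC50s.
    """
    n = system.n
    r = 0.5 ** (1.0 / n)
    pool = n * system.L_T
    return (
        (1.0 - r) * (pool + system.K / r),
        r * (pool + system.K / (1.0 - r)),
    )


def _H_eta(x: float, ut0: float, ut1: float, lt: float):
    """Time (eta units) at which the solution reaches auxiliary level x.

    eta = ln( (1 + ut1 + F1 + x) / (C * (1 + ut1 - F1 + x)) ) / F1;
    returns the MONOTONIC sentinel when the log argument degenerates
    (the level is never crossed at positive time).
    """
    F1 = float(aux_F(ut1, lt))
    C = aux_C(ut0, ut1, lt)
    num = 1.0 + ut1 + F1 + x
    den = C * (1.0 + ut1 - F1 + x)
    if den == 0.0 or num / den <= 0.0:
        return MONOTONIC
    eta = np.log(num / den) / F1
    if eta <= 0.0:
        return MONOTONIC
    return float(eta)


def tau_m_max_conserved(system: ConservedSystem, jump: TotalLigandJump, m: int):
    """Non-dimensional time at which intermediate m peaks (conserved regime).

    eta = H(V(m)) with V(m) = (L_T/K)*(n - 2m); the peak exists only when
    the post-jump total ligand exceeds the asymptote
    q_m = m*(L_T/K + 1/(n-m)) (in units of K) — below it the conformation
    rises monotonically and the MONOTONIC sentinel is returned.
    """
    n = system.n
    if not (1 <= m <= n - 1):
        raise ValueError(f"interior m required (1..{n - 1}), got {m}")
    if not (jump.U_T1 > jump.U_T0):
        raise ValueError("requires an upward jump (U_T1 > U_T0)")
    K = system.K
    V = (system.L_T / K) * (n - 2 * m)
    return _H_eta(V, jump.U_T0 / K, jump.U_T1 / K, system.lt_pool)


def tau_half_conserved(system: ConservedSystem, jump: TotalLigandJump, which: str):
    """Half-transition time (eta units) of the apo or saturated form.

    which = "apo": eta = H(W); which = "saturated": eta = H(Y), where W and
    Y locate the midpoint crossing of p0^n and p1^n respectively through
    the n-th-root average of the initial and final levels.
    """
    if jump.U_T1 == jump.U_T0:
        raise ValueError("tau_half undefined without a jump")
    n, K = system.n, system.K
    lt = system.lt_pool
    ut0, ut1 = jump.U_T0 / K, jump.U_T1 / K
    F0 = float(aux_F(ut0, lt))
    F1 = float(aux_F(ut1, lt))
    if which == "apo":
        # 2*lt*p0 at eta=0 and inf, averaged through the n-th power
        g0 = lt - ut0 - 1.0 + F0
        g1 = lt - ut1 - 1.0 + F1
        W = (0.5 * (g0**n + g1**n)) ** (1.0 / n) - lt
        return _H_eta(W, ut0, ut1, lt)
    if which == "saturated":
        g0 = lt + ut0 + 1.0 - F0
        g1 = lt + ut1 + 1.0 - F1
        Y = lt - (0.5 * (g0**n + g1**n)) ** (1.0 / n)
        return _H_eta(Y, ut0, ut1, lt)
    raise ValueError("which must be 'apo' or 'saturated'")
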