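"""Two-domain cooperative binding: the calmodulin (CaM) model.

Calmodulin carries four Ca2+ sites in two independent globular domains, each
an EF-hand pair whose two sites are identical but cooperative: the first
ligand binds with intrinsic dissociation constant K, the second — with the
neighbouring site already occupied — with the cooperative constant K_c
(positive cooperativity when K_c < K).  Per domain the scheme is four-state,

    A00 <-> A10, A01 <-> A11,

with rates k1 (first binding) and kc1 (second binding).  The steady state is
closed-form; the kinetics after a ligand step are obtained by integrating
the linear four-state mass-action system at the post-jump ligand level.

Whole-molecule conformations with m = 0..4 bound ligands combine the two
domain distributions (a0, a1, a2) and (b0, b1, b2) multiplicatively; these
are class-aggregated by construction (the factor 2 on the singly-bound
domain states counts both site patterns).

The paper's CaM affinities ship as :data:`CAM_N_DOMAIN` / :data:`CAM_C_DOMAIN`
(K1 = 0.9, K1c = 0.2, K2 = 0.8, K2c = 0.1 µM).  Off-rates are not fixed by
equilibrium data; ``kc1_minus`` defaults to ``k1_minus`` and is a free
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CooperativeDomainParams",
    "DomainTrajectory",
    "domain_steady",
    "domain_kinetics",
    "molecule_distribution",
    "molecule_distribution_timecourse",
    "half_saturation_u",
    "CAM_N_DOMAIN",
    "CAM_C_DOMAIN",
]


@dataclass(frozen=True)
class CooperativeDomainParams:
    """One two-site cooperative domain.

    K is the intrinsic dissociation constant (first binding), K_c the
    cooperative one (second binding); on-rates derive as k/K.
    """

    K: float
    K_c: float
    k1_minus: float = 1.0
    kc1_minus: float | None = None  # defaults to k1_minus
    A_T: float = 1.0

    def __post_init__(self) -> None:
        if self.kc1_minus is None:
            object.__setattr__(self, "kc1_minus", self.k1_minus)
        for name in ("K", "K_c", "k1_minus", "kc1_minus", "A_T"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")

    @property
    def k1_plus(self) -> float:
        return self.k1_minus / self.K

    @property
    def kc1_plus(self) -> float:
        return self.kc1_minus / self.K_c

    @property
    def cooperative(self) -> bool:
        return self.K_c < self.K

    def without_cooperativity(self) -> "CooperativeDomainParams":
        """Same intrinsic affinity with cooperativity switched off (K_c = K)."""
        return CooperativeDomainParams(
            K=self.K, K_c=self.K, k1_minus=self.k1_minus,
            kc1_minus=self.k1_minus, A_T=self.A_T,
        )


# CaM EF-hand pair affinities (µM)
CAM_N_DOMAIN = CooperativeDomainParams(K=0.9, K_c=0.2)
CAM_C_DOMAIN = CooperativeDomainParams(K=0.8, K_c=0.1)


def domain_steady(params: CooperativeDomainParams, U):
    """Equilibrium domain-state probabilities (a0, a1, a2).

    a0 = K*K_c/D, a1 = U*K_c/D, a2 = U**2/D with
    D = U**2 + 2*K_c*U + K*K_c; a1 is the probability of *each* of the two
    singly-bound patterns, so a0 + 2*a1 + a2 = 1.
    """
    U = np.asarray(U, dtype=float)
    if np.any(U < 0):
        raise ValueError("U must be non-negative")
    K, Kc = params.K, params.K_c
    D = U**2 + 2.0 * Kc * U + K * Kc
    return K * Kc / D, U * Kc / D, U**2 / D


@dataclass(frozen=True)
class DomainTrajectory:
    """Four-state trajectory (A00, A10, A01, A11) on a time grid."""

    t: np.ndarray
    A00: np.ndarray
    A10: np.ndarray
    A01: np.ndarray
    A11: np.ndarray
    A_T: float = 1.0

    @property
    def probabilities(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(a0, a1, a2) with a1 the per-pattern singly-bound probability."""
        return (
            self.A00 / self.A_T,
            0.5 * (self.A10 + self.A01) / self.A_T,
            self.A11 / self.A_T,
        )


def domain_kinetics(
    params: CooperativeDomainParams,
    U0: float,
    U1: float,
    t_grid: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> DomainTrajectory:
    """Integrate the four-state domain ODEs after a ligand jump U0 -> U1.

    Initial condition is the equilibrium distribution at U0; the system is
    linear at fixed U1 and integrated with a stiff-capable method.  Total
    domain concentration A_T is conserved to solver tolerance.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be non-negative")
    a0, a1, a2 = domain_steady(params, U0)
    y0 = params.A_T * np.array([a0, a1, a1, a2])
    kp, km = params.k1_plus, params.k1_minus
    kcp, kcm = params.kc1_plus, params.kc1_minus
    U = float(U1)

    def rhs(_t, y):
        A00, A10, A01, A11 = y
        return [
            -2 * kp * A00 * U + km * A10 + km * A01,
            kp * A00 * U - km * A10 - kcp * A10 * U + kcm * A11,
            kp * A00 * U - km * A01 - kcp * A01 * U + kcm * A11,
            kcp * A01 * U + kcp * A10 * U - 2 * kcm * A11,
        ]

    t_end = float(t_grid[-1]) if t_grid[-1] > 0 else 1.0
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, t_eval=t_grid, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"domain kinetics integration failed: {sol.message}")
    return DomainTrajectory(
        t=sol.t, A00=sol.y[0], A10=sol.y[1], A01=sol.y[2], A11=sol.y[3],
        A_T=params.A_T,
    )


def molecule_distribution(a, b, L_T: float = 1.0):
    """Whole-molecule conformations N_0..N_4 from two domain distributions.

    ``a`` and ``b`` are (x0, x1, x2) probability triples (x1 per pattern):

        N_0/L_T = a0*b0
        N_1/L_T = 2*(a0*b1 + a1*b0)
        N_2/L_T = a0*b2 + 4*a1*b1 + a2*b0
        N_3/L_T = 2*(a1*b2 + a2*b1)
        N_4/L_T = a2*b2

    Class-aggregated by construction; the five values sum to L_T.
    """
    a0, a1, a2 = (np.asarray(x, dtype=float) for x in a)
    b0, b1, b2 = (np.asarray(x, dtype=float) for x in b)
    return (
        L_T * a0 * b0,
        L_T * 2.0 * (a0 * b1 + a1 * b0),
        L_T * (a0 * b2 + 4.0 * a1 * b1 + a2 * b0),
        L_T * 2.0 * (a1 * b2 + a2 * b1),
        L_T * a2 * b2,
    )


def molecule_distribution_timecourse(
    domainA: CooperativeDomainParams,
    domainB: CooperativeDomainParams,
    U0: float,
    U1: float,
    t_grid: np.ndarray,
    L_T: float = 1.0,
):
    """N_0..N_4 trajectories after a ligand jump, via per-domain integration."""
    trajA = domain_kinetics(domainA, U0, U1, t_grid)
    trajB = domain_kinetics(domainB, U0, U1, t_grid)
    return molecule_distribution(trajA.probabilities, trajB.probabilities, L_T)


def half_saturation_u(
    domainA: CooperativeDomainParams,
    domainB: CooperativeDomainParams,
    u_hi: float = 1e6,
) -> float:
    """Ligand level where the fully bound form N_4 reaches half its asymptote.

    Used to compare cooperative vs non-cooperative parameterisations:
    positive cooperativity pulls this level below the independent-pair value.
    """
    from scipy.optimize import brentq

    def n4(U: float) -> float:
        a = domain_steady(domainA, U)
        b = domain_steady(domainB, U)
        return float(a[2] * b[2])

    target = 0.5  # asymptote of N_4/L_T is 1 at saturating ligand
    return float(brentq(lambda U: n4(U) - target, 1e-12, u_hi, rtol=1e-12))
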