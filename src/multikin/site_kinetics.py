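"""Single-site ligand binding: equilibrium occupancy and step-response relaxation.

A binding site exchanges ligand by mass action,

    L0 + U  <-->  L1        (k_plus forward, k_minus back)

with equilibrium dissociation constant ``K = k_minus / k_plus``.  After an
instantaneous jump of the free-ligand concentration from ``U0`` to ``U1`` at
``t = 0`` (the system being equilibrated with ``U0`` beforehand), the
occupancy relaxes mono-exponentially with time constant

    tau(U1) = K / (k_minus * (U1 + K)).

Every multisite model in this package composes these single-site solutions.
Internally everything is expressible in the non-dimensional variables
``u = U / K`` and ``eta = t * k_minus``; the functions here accept
dimensional quantities and convert where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteParams",
    "JumpProtocol",
    "steady_occupancy",
    "relaxation_time",
    "jump_occupancy",
]


@dataclass(frozen=True)
class SiteParams:
    """Rate constants of one binding site.

    Parameters
    ----------
    k_plus : float
        Association rate constant (concentration⁻¹ · time⁻¹).
    k_minus : float
        Dissociation rate constant (time⁻¹).

    Attributes
    ----------
    K : float
        Equilibrium dissociation constant ``k_minus / k_plus`` (concentration).
    """

    k_plus: float
    k_minus: float
    K: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.k_plus > 0):
            raise ValueError(f"k_plus must be positive, got {self.k_plus}")
        if not (self.k_minus > 0):
            raise ValueError(f"k_minus must be positive, got {self.k_minus}")
        object.__setattr__(self, "K", self.k_minus / self.k_plus)

    @classmethod
    def from_K(cls, K: float, k_minus: float = 1.0) -> "SiteParams":
        """Construct from the dissociation constant and off-rate."""
        if not (K > 0):
            raise ValueError(f"K must be positive, got {K}")
        return cls(k_plus=k_minus / K, k_minus=k_minus)


@dataclass(frozen=True)
class JumpProtocol:
    """Step change of free ligand from ``U0`` to ``U1`` at ``t = 0``.

    The system is assumed equilibrated with ``U0`` for ``t < 0``.
    """

    U0: float
    U1: float

    def __post_init__(self) -> None:
        if self.U0 < 0 or self.U1 < 0:
            raise ValueError("ligand concentrations must be non-negative")


def steady_occupancy(site: SiteParams, U):
    """Equilibrium probabilities (p0, p1) of the free and occupied states.

    p0 = K / (K + U),  p1 = U / (K + U);  p0 + p1 = 1.
    """
    U = np.asarray(U, dtype=float)
    if np.any(U < 0):
        raise ValueError("U must be non-negative")
    p1 = U / (site.K + U)
    return 1.0 - p1, p1


def relaxation_time(site: SiteParams, U1) -> float:
    """Exponential relaxation time tau(U1) = K / (k_minus * (U1 + K)).

    Strictly decreasing in ``U1``; equals ``1/k_minus`` at ``U1 = 0``.
    """
    U1 = np.asarray(U1, dtype=float)
    if np.any(U1 < 0):
        raise ValueError("U1 must be non-negative")
    out = site.K / (site.k_minus * (U1 + site.K))
    return float(out) if out.ndim == 0 else out


def jump_occupancy(site: SiteParams, jump: JumpProtocol, t):
    """Occupancy probabilities (p0(t), p1(t)) after the ligand step.

    p_i(t) = p_i(U1) - (p_i(U1) - p_i(U0)) * exp(-t / tau(U1)).

    ``t = 0`` returns the pre-jump equilibrium at ``U0``; ``t -> inf``
    converges to the equilibrium at ``U1``.  Negative ``t`` is rejected:
    the pre-jump state is queried via :func:`steady_occupancy`.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative (pre-jump state via steady_occupancy)")
    _, p1_0 = steady_occupancy(site, jump.U0)
    _, p1_inf = steady_occupancy(site, jump.U1)
    tau = relaxation_time(site, jump.U1)
    p1 = p1_inf - (p1_inf - p1_0) * np.exp(-t / tau)
    return 1.0 - p1, p1
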