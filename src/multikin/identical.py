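"""Proteins with n identical binding sites: closed-form conformational kinetics.

With a shared dissociation constant K and off-rate k_minus, everything is a
function of the non-dimensional ligand level ``u = U/K`` and time
``eta = t * k_minus``.  The per-form steady-state concentration of a
conformation with m of n sites occupied is

    N_m(u) / L_T = u^m / (1 + u)^n

(one specific occupied/free pattern, *not* multiplied by C(n, m); the
class-aggregated quantity lives in :mod:`multikin.independent`).  The
intermediate conformations (0 < m < n) are bell-shaped in u, peaking at
``u_m_max = m/(n-m)`` with magnitude ``m^m (n-m)^(n-m) / n^n``.

After a ligand step u0 -> u1 every site relaxes with the same rate
``(1 + u1)`` (in eta units), so the transient conformation distribution and
the characteristic times below (time-to-maximum of intermediates, half-rise
and half-fall times of the saturated and apo forms) are all closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MONOTONIC",
    "IdenticalProtein",
    "steady_form",
    "u_max",
    "n_max",
    "ec50",
    "n_from_ec50",
    "bound_ligand_at_K",
    "jump_site_probabilities",
    "jump_form_timecourse",
    "tau_m_max",
    "tau_half",
    "saturation_width",
    "bell_half_width",
]

#: Sentinel returned where a time-to-maximum does not exist because the
#: conformation approaches steady state monotonically.
MONOTONIC = "monotonic"


@dataclass(frozen=True)
class IdenticalProtein:
    """n identical sites with shared K and k_minus, total protein L_T."""

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


def _check_m(n: int, m: int, interior: bool = False) -> None:
    lo, hi = (1, n - 1) if interior else (0, n)
    if not (lo <= m <= hi):
        kind = "interior (1..n-1)" if interior else f"0..{n}"
        raise ValueError(f"m = {m} outside {kind} for n = {n}")


def steady_form(n: int, m: int, u):
    """Per-form steady fraction N_m/L_T = u^m / (1+u)^n."""
    _check_m(n, m)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("u must be non-negative")
    with np.errstate(divide="ignore"):
        # log-space evaluation keeps large u and large n finite
        logv = np.where(u > 0, m * np.log(np.maximum(u, 1e-300)), -np.inf)
    out = np.where(
        (u == 0) & (m == 0), 1.0, np.exp(logv - n * np.log1p(u))
    )
    return float(out) if out.ndim == 0 else out


def u_max(n: int, m: int) -> float:
    """Ligand level (units of K) maximising the intermediate N_m: m/(n-m)."""
    _check_m(n, m, interior=True)
    return m / (n - m)


def n_max(n: int, m: int) -> float:
    """Peak fraction of intermediate m: m^m (n-m)^(n-m) / n^n.

    Symmetric under m <-> n-m and strictly decreasing in n for fixed m.
    """
    _check_m(n, m, interior=True)
    k = n - m
    return float(np.exp(m * np.log(m) + k * np.log(k) - n * np.log(n)))


def ec50(n: int) -> tuple[float, float]:
    """Half-maximal ligand levels (u0_half, un_half) of the apo/saturated forms.

    u0_half = (1 - r)/r and un_half = r/(1 - r) with r = 0.5**(1/n); their
    product is exactly 1, and both equal 1 (EC50 = K) for n = 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = 0.5 ** (1.0 / n)
    return (1.0 - r) / r, r / (1.0 - r)


def n_from_ec50(un_half: float, paper_faithful: bool = False) -> float:
    """Site count inferred from the saturated form's half-maximal level.

    n = ln2 / ln((1 + un_half)/un_half); with ``paper_faithful`` the literal
    rounded constant 0.693 replaces ln 2 (difference < 0.1 %).
    """
    if not (un_half > 0):
        raise ValueError("un_half must be positive")
    if not np.isfinite(un_half):
        raise ValueError("un_half must be finite")
    num = 0.693 if paper_faithful else np.log(2.0)
    return float(num / np.log((1.0 + un_half) / un_half))


def bound_ligand_at_K(n: int) -> float:
    """Fraction of saturation bound at u = 1 (U = K), by direct form summation.

    Evaluates S(K) = sum_j M_j * (bound count) over all 2**n forms and
    divides by the saturating value n*L_T.  The direct sum gives exactly 1/2
    for every n (the binomial mean n/2 at p = 1/2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = 0.0
    for j in range(2**n):
        c = int(j).bit_count()
        total += c * 0.5**n
    return total / n


def jump_site_probabilities(u0: float, u1: float, eta):
    """Shared-site occupancy (p0, p1) at non-dimensional time eta after u0 -> u1.

    p1(eta) = u1/(1+u1) - (u1/(1+u1) - u0/(1+u0)) * exp(-eta*(1+u1)).
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("eta must be non-negative")
    if u0 < 0 or u1 < 0:
        raise ValueError("ligand levels must be non-negative")
    p1_inf = u1 / (1.0 + u1)
    p1_0 = u0 / (1.0 + u0)
    p1 = p1_inf - (p1_inf - p1_0) * np.exp(-eta * (1.0 + u1))
    return 1.0 - p1, p1


def jump_form_timecourse(n: int, m: int, u0: float, u1: float, eta):
    """Per-form fraction N_m/L_T = p1^m * p0^(n-m) along the relaxation."""
    _check_m(n, m)
    p0, p1 = jump_site_probabilities(u0, u1, eta)
    out = p1**m * p0 ** (n - m)
    return float(out) if np.ndim(out) == 0 else out


def tau_m_max(n: int, m: int, u0: float, u1: float):
    """Non-dimensional time at which intermediate m peaks after an upward jump.

    eta_m_max = ln( n (u1 - u0) / ((1 + u0) ((n - m) u1 - m)) ) / (1 + u1).

    Returns :data:`MONOTONIC` when ``(n - m) * u1 <= m`` (equivalently
    ``u1 <= m/(n-m)``): the post-jump ligand level is too low for N_m to
    overshoot, and it rises monotonically instead.
    """
    _check_m(n, m, interior=True)
    if not (u1 > u0):
        raise ValueError("tau_m_max requires an upward jump (u1 > u0)")
    denom = (n - m) * u1 - m
    if denom <= 0:
        return MONOTONIC
    arg = n * (u1 - u0) / ((1.0 + u0) * denom)
    if arg <= 1.0:
        # peak would sit at eta <= 0: already past the maximum at the jump
        return MONOTONIC
    return float(np.log(arg) / (1.0 + u1))


def tau_half(n: int, u0: float, u1: float, which: str):
    """Half-transition time of the apo (m=0) or saturated (m=n) form.

    ``which`` is "apo" or "saturated".  The value is the exact eta at which
    the form crosses the midpoint (N(0) + N(inf))/2 of its transition:

        eta = ln(argument) / (1 + u1)

    with the argument given by inverting the mono-exponential site
    relaxation through the n-th power.  Valid for jumps in either
    direction (u0 != u1).
    """
    if u0 == u1:
        raise ValueError("tau_half undefined for u0 == u1")
    if u0 < 0 or u1 < 0:
        raise ValueError("ligand levels must be non-negative")
    if which == "apo":
        mid = 0.5 * ((1.0 + u0) ** -n + (1.0 + u1) ** -n)
        arg = (u1 - u0) / ((1.0 + u0) * ((1.0 + u1) * mid ** (1.0 / n) - 1.0))
    elif which == "saturated":
        mid = 0.5 * ((u0 / (1.0 + u0)) ** n + (u1 / (1.0 + u1)) ** n)
        arg = (u1 - u0) / ((1.0 + u0) * (u1 - (1.0 + u1) * mid ** (1.0 / n)))
    else:
        raise ValueError("which must be 'apo' or 'saturated'")
    return float(np.log(arg) / (1.0 + u1))


def saturation_width(
    n: int, q_hi: float = 0.9, q_lo: float = 0.1, scale: str = "linear"
) -> float:
    """Dose-response width A_n of the saturated form.

    The saturated form crosses fraction q of L_T at
    ``u(q) = q**(1/n) / (1 - q**(1/n))``.  With ``scale="linear"`` (default)
    the width is ``u(q_hi) - u(q_lo)`` in units of K; with ``scale="log10"``
    it is ``log10(u(q_hi)/u(q_lo))``, the span in decades.  The response
    steepens with n: the log-scale width shrinks monotonically, while the
    linear width grows because the whole transition shifts to higher u
    (roughly proportionally to n).
    """
    if not (0 < q_lo <= q_hi < 1):
        raise ValueError("need 0 < q_lo <= q_hi < 1")

    def u_at(q: float) -> float:
        r = q ** (1.0 / n)
        return r / (1.0 - r)

    if scale == "linear":
        return u_at(q_hi) - u_at(q_lo)
    if scale == "log10":
        return float(np.log10(u_at(q_hi) / u_at(q_lo)))
    raise ValueError("scale must be 'linear' or 'log10'")


def bell_half_width(n: int, m: int) -> tuple[float, float, float]:
    """Half-maximum crossing points of the intermediate bell N_m(u).

    Returns ``(u_left, u_right, log10_width)`` where the two u values solve
    ``steady_form(n, m, u) = n_max(n, m)/2`` on either side of the peak and
    ``log10_width = log10(u_right/u_left)``.
    """
    _check_m(n, m, interior=True)
    peak_u = u_max(n, m)
    half = 0.5 * n_max(n, m)

    def f(log_u: float) -> float:
        return steady_form(n, m, float(np.exp(log_u))) - half

    lo = float(np.log(peak_u))
    left = brentq(f, lo + np.log(1e-6), lo, xtol=1e-14, rtol=1e-12)
    right = brentq(f, lo, lo + np.log(1e6), xtol=1e-14, rtol=1e-12)
    u_left, u_right = float(np.exp(left)), float(np.exp(right))
    return u_left, u_right, float(np.log10(u_right / u_left))
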