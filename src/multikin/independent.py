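"""Proteins with n independent (possibly non-identical) binding sites.

Because the sites do not interact, the probability of any of the 2**n
molecular forms factorises into single-site probabilities: form ``j`` with
bit pattern ``c_i(j)`` (bit i set when site i is occupied) has concentration

    M_j(U, t) = L_T * prod_i p_i^{c_i(j)}(U, t),

both at steady state and along the relaxation after a ligand step.  The
bound-ligand total S = sum_j M_j * sum_i c_i(j) collapses, by independence,
to the per-site sum ``L_T * sum_i p_i^1``.

Form indexing convention: bit i of ``j`` is site i (LSB = first site), i.e.
``j = sum_i 2**i * c_i(j)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .site_kinetics import JumpProtocol, SiteParams, jump_occupancy, steady_occupancy

__all__ = [
    "IndependentProtein",
    "bits_of_form",
    "bound_count",
    "form_steady",
    "form_timecourse",
    "class_aggregate",
    "bound_ligand",
]

MAX_SITES = 16  # exhaustive 2**n form enumeration stays desk-scale


@dataclass(frozen=True)
class IndependentProtein:
    """Ordered collection of independent binding sites plus total protein L_T."""

    sites: tuple[SiteParams, ...]
    L_T: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= len(self.sites) <= MAX_SITES):
            raise ValueError(f"need 1..{MAX_SITES} sites, got {len(self.sites)}")
        if not (self.L_T > 0):
            raise ValueError("L_T must be positive")
        object.__setattr__(self, "sites", tuple(self.sites))

    @property
    def n(self) -> int:
        return len(self.sites)

    @classmethod
    def from_h_constants(
        cls,
        h: Sequence[float],
        h_minus: Sequence[float] | None = None,
        K1: float = 1.0,
        k1_minus: float = 1.0,
        L_T: float = 1.0,
    ) -> "IndependentProtein":
        """Build from non-dimensional heterogeneity ratios.

        ``h_i = k_i_plus / k_1_plus`` and ``h_i_minus = k_i_minus / k_1_minus``
        (both 1 for the first site).  ``K1`` and ``k1_minus`` set the scale of
        the first site; with the defaults the site constants are expressed in
        units of K1 and 1/k1_minus.
        """
        h = list(h)
        if h_minus is None:
            h_minus = [1.0] * len(h)
        h_minus = list(h_minus)
        if len(h) != len(h_minus):
            raise ValueError("h and h_minus must have equal length")
        if abs(h[0] - 1.0) > 1e-12 or abs(h_minus[0] - 1.0) > 1e-12:
            raise ValueError("first-site ratios must be 1 (h_1 = h_1_minus = 1)")
        if any(x <= 0 for x in h) or any(x <= 0 for x in h_minus):
            raise ValueError("heterogeneity ratios must be positive")
        k1_plus = k1_minus / K1
        sites = tuple(
            SiteParams(k_plus=hi * k1_plus, k_minus=hmi * k1_minus)
            for hi, hmi in zip(h, h_minus)
        )
        return cls(sites=sites, L_T=L_T)


def bits_of_form(j: int, n: int) -> tuple[int, ...]:
    """Occupancy bit vector c_i(j) of form ``j`` for an n-site protein."""
    if not (0 <= j < 2**n):
        raise ValueError(f"form index {j} out of range for {n} sites")
    return tuple((j >> i) & 1 for i in range(n))


def bound_count(j: int, n: int) -> int:
    """Number of occupied sites in form ``j``."""
    if not (0 <= j < 2**n):
        raise ValueError(f"form index {j} out of range for {n} sites")
    return int(j).bit_count()


def _site_probs_steady(protein: IndependentProtein, U):
    return [steady_occupancy(s, U) for s in protein.sites]


def _site_probs_jump(protein: IndependentProtein, jump: JumpProtocol, t):
    return [jump_occupancy(s, jump, t) for s in protein.sites]


def _form_product(probs, j: int, n: int, L_T: float):
    bits = bits_of_form(j, n)
    out = np.asarray(L_T, dtype=float)
    for (p0, p1), c in zip(probs, bits):
        out = out * (p1 if c else p0)
    return out


def form_steady(protein: IndependentProtein, j: int, U):
    """Steady-state concentration M_j(U) of molecular form ``j``."""
    probs = _site_probs_steady(protein, U)
    return _form_product(probs, j, protein.n, protein.L_T)


def form_timecourse(protein: IndependentProtein, jump: JumpProtocol, j: int, t):
    """Concentration M_j(t) of form ``j`` after the ligand step."""
    probs = _site_probs_jump(protein, jump, t)
    return _form_product(probs, j, protein.n, protein.L_T)


def class_aggregate(protein: IndependentProtein, jump: JumpProtocol, m: int, t):
    """Total concentration N_m(t) of all forms with exactly ``m`` bound sites.

    Sums the C(n, m) form products directly; for identical sites this equals
    C(n, m) times the per-form value.
    """
    n = protein.n
    if not (0 <= m <= n):
        raise ValueError(f"bound count {m} out of range for {n} sites")
    probs = _site_probs_jump(protein, jump, t)
    total = None
    for occupied in combinations(range(n), m):
        j = sum(1 << i for i in occupied)
        term = _form_product(probs, j, n, protein.L_T)
        total = term if total is None else total + term
    return total


def class_aggregate_steady(protein: IndependentProtein, m: int, U):
    """Steady-state N_m(U): sum over all forms with ``m`` occupied sites."""
    n = protein.n
    if not (0 <= m <= n):
        raise ValueError(f"bound count {m} out of range for {n} sites")
    probs = _site_probs_steady(protein, U)
    total = None
    for occupied in combinations(range(n), m):
        j = sum(1 << i for i in occupied)
        term = _form_product(probs, j, n, protein.L_T)
        total = term if total is None else total + term
    return total


def bound_ligand(protein: IndependentProtein, jump: JumpProtocol, t):
    """Total bound ligand S(t) = sum_j M_j * (bound count of j).

    Computed via the independence identity S = L_T * sum_i p_i^1; the
    brute-force double sum is checked against this in the test suite.
    """
    probs = _site_probs_jump(protein, jump, t)
    total = None
    for _, p1 in probs:
        total = np.asarray(p1, dtype=float) if total is None else total + p1
    return protein.L_T * total


def bound_ligand_brute(protein: IndependentProtein, jump: JumpProtocol, t):
    """S(t) by exhaustive enumeration of all 2**n forms (oracle path)."""
    n = protein.n
    probs = _site_probs_jump(protein, jump, t)
    total = None
    for j in range(2**n):
        c = bound_count(j, n)
        if c == 0:
            continue
        term = c * _form_product(probs, j, n, protein.L_T)
        total = term if total is None else total + term
    return total
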