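"""Named parameter sets used throughout the package and its figure scripts.

All abundant-ligand fixtures are non-dimensional (K = 1, k_minus = 1);
the CaM cooperative affinities are in µM.
"""

from __future__ import annotations

from .cooperative import CAM_C_DOMAIN, CAM_N_DOMAIN
from .independent import IndependentProtein

__all__ = [
    "fig5_marginal",
    "fig6_significant",
    "FIG5_JUMPS",
    "FIG6_JUMPS",
    "FIG8_WEAK_LT",
    "FIG8_STRONG_LT",
    "FIG8_JUMP",
    "FIG9_LT",
    "FIG9_UT0",
    "CAM_N_DOMAIN",
    "CAM_C_DOMAIN",
]


def fig5_marginal(L_T: float = 1.0) -> IndependentProtein:
    """Four sites with marginally different association rates.

    h = (1, 0.9, 0.8, 0.7), shared off-rate (h_minus all 1).
    """
    return IndependentProtein.from_h_constants(h=[1.0, 0.9, 0.8, 0.7], L_T=L_T)


def fig6_significant(L_T: float = 1.0) -> IndependentProtein:
    """Four sites with significantly different association rates.

    h = (1, 0.6, 0.2, 0.1), shared off-rate.
    """
    return IndependentProtein.from_h_constants(h=[1.0, 0.6, 0.2, 0.1], L_T=L_T)


#: Ligand steps (u0, u1) used with the heterogeneous four-site proteins.
FIG5_JUMPS = ((0.001, 1.43), (0.001, 100.0))
FIG6_JUMPS = ((0.001, 8.0), (0.001, 400.0))

#: Conserved-ligand protein levels L_T/K: weak vs strong buffering.
FIG8_WEAK_LT = 2.0
FIG8_STRONG_LT = 50.0
#: Total-ligand step (U_T0/K, U_T1/K) for the buffering comparison.
FIG8_JUMP = (0.01, 200.0)

#: Conserved-regime characteristic-time sweep: L_T/K and pre-jump U_T0/K.
FIG9_LT = 3.0
FIG9_UT0 = 0.1
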