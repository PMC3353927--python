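"""Calcium control of the pectin hardening rate.

Freshly extruded pectin is methyl-esterified; demethylation exposes
carboxyl groups that external Ca2+ cross-links, stiffening the film.
Treating the rate-limiting step as diffusion of calcium into the new
wall with binding (a diffusion-fixation process) gives a hardening
rate that is linear in the external calcium concentration and scales
with the square root of the gel's calcium binding constant K_c and of
the diffusivity D:

    alpha = k_scale * C_Ca * sqrt(K_c * D)

The absolute prefactor is not separately measurable here, so
``k_scale`` is calibrated once so that the baseline medium
(0.1 mM Ca2+) reproduces the baseline hardening rate of the standard
parameter set.  Any wall-thickness dependence of alpha is neglected:
at baseline the film thickness is regulated to a narrow band, so alpha
is taken as thickness-independent (an extension point, not a law).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParameters

__all__ = ["HardeningLaw", "alpha_from_calcium", "law_for_baseline"]


@dataclass(frozen=True)
class HardeningLaw:
    """Diffusion-fixation parameters of the tip pectin gel.

    ``K_c`` is the calcium binding constant (per mM), ``D`` the
    calcium diffusivity in the wall (um^2/s) and ``k_scale`` a
    proportionality constant absorbing all unknown prefactors
    (MPa per (mM.um/s^0.5) so that alpha comes out in MPa.s/s).
    """

    K_c: float = 1.0
    D: float = 100.0
    k_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.K_c, self.D, self.k_scale) <= 0:
            raise ValueError("K_c, D and k_scale must be strictly positive")


def alpha_from_calcium(law: HardeningLaw, C_Ca: float) -> float:
    """Hardening rate alpha for external calcium ``C_Ca`` (mM).

    Linear in calcium, square-root in binding constant and diffusivity.
    Zero calcium means no cross-linking: the film keeps its native
    viscosity and the tip is headed for bursting.
    """
    if C_Ca < 0:
        raise ValueError("calcium concentration must be non-negative")
    return law.k_scale * C_Ca * math.sqrt(law.K_c * law.D)


def law_for_baseline(params: ModelParameters, K_c: float = 1.0,
                     D: float = 100.0) -> HardeningLaw:
    """Hardening law whose prediction at the parameter set's baseline
    calcium equals the parameter set's baseline alpha."""
    k_scale = params.alpha / (params.C_Ca * math.sqrt(K_c * D))
    return HardeningLaw(K_c=K_c, D=D, k_scale=k_scale)
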