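"""Steady-state diffusion-theory reflectance — the analytic transport oracle.

Implements the classic extrapolated-boundary dipole solution for a pencil
beam on a semi-infinite homogeneous medium: an isotropic source at depth
``z0 = 1/(mua + mus')`` and its negative image mirrored about the
extrapolated boundary at ``-2*zb`` produce the spatially resolved diffuse
reflectance

    R(rho) = (1/4pi) * [ z0 (mueff + 1/r1) exp(-mueff r1) / r1^2
                       + (z0 + 2 zb)(mueff + 1/r2) exp(-mueff r2) / r2^2 ]

with ``mueff = sqrt(3 mua (mua + mus'))``.  This closed form is independent
of the Monte-Carlo kernel and serves as its verification oracle; it is also
the fast forward model behind the synthetic cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .optics import LayeredSkinModel


def effective_attenuation(mua: float, musp: float) -> float:
    """mueff = sqrt(3 * mua * (mua + mus')), 1/mm."""
    if mua < 0 or musp <= 0:
        raise InvalidParameterError("need mua >= 0 and mus' > 0")
    return float(np.sqrt(3.0 * mua * (mua + musp)))


def internal_reflection_parameter(n_rel: float) -> float:
    """Groenhuis polynomial for the internal-reflection parameter A.

    ``n_rel`` is tissue index over ambient index.  A = (1 + r_i)/(1 - r_i)
    with r_i approximated by the standard cubic fit in 1/n.
    """
    ri = -1.440 * n_rel**-2 + 0.710 * n_rel**-1 + 0.668 + 0.0636 * n_rel
    return (1.0 + ri) / (1.0 - ri)


@dataclass(frozen=True)
class OracleResult:
    """Reflectance per unit area (1/mm^2) with a near-field validity flag."""

    reflectance: np.ndarray
    near_field: np.ndarray  # True where rho is inside the validity bound


def dipole_reflectance(
    mua: float, musp: float, rho, n_rel: float = 1.4
) -> np.ndarray:
    """Spatially resolved diffuse reflectance R(rho), 1/mm^2 per unit incident power."""
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    mueff = effective_attenuation(mua, musp)
    z0 = 1.0 / (mua + musp)
    d = 1.0 / (3.0 * (mua + musp))
    zb = 2.0 * internal_reflection_parameter(n_rel) * d
    r1 = np.hypot(rho, z0)
    r2 = np.hypot(rho, z0 + 2.0 * zb)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return (term1 + term2) / (4.0 * np.pi)


def diffusion_reflectance_oracle(
    model: LayeredSkinModel, rho, wavelength: float
) -> OracleResult:
    """Diffusion-approximation reflectance of a homogeneous semi-infinite model.

    Requires a single-layer semi-infinite model.  Distances closer than one
    transport mean free path (``rho <= 1/(mua + mus')``) are flagged
    ``near_field`` — the diffusion approximation is unreliable there.
    """
    if len(model.layers) != 1 or not model.layers[0].semi_infinite:
        raise InvalidParameterError(
            "the diffusion oracle requires a single semi-infinite layer"
        )
    layer = model.layers[0]
    props = model.optical_properties([wavelength])
    mua = float(props["mua"][0, 0])
    musp = float(props["mus"][0, 0]) * (1.0 - layer.g)
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    refl = dipole_reflectance(mua, musp, rho_arr, n_rel=layer.n / model.n_ambient)
    near = rho_arr <= 1.0 / (mua + musp)
    return OracleResult(reflectance=refl, near_field=near)
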