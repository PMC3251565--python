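"""Spectral density functions and the forward relaxation model.

The extended Lipari-Szabo spectral density for isotropic tumbling is

    J(ω) = (2/5) [ S² τm / (1 + (ω τm)²)
                 + (S²f − S²) τ' / (1 + (ω τ')²) ],   1/τ' = 1/τm + 1/τe

with S² = S²f S²s.  The simple (single-timescale) form is the S²f = 1
special case.  For an axially symmetric diffusion tensor the single τm
Lorentzian pair is replaced by a three-component sum whose correlation
times depend on D∥/D⊥ and whose weights depend on the angle between the
N-H vector and the unique axis.

Observable rates follow the standard dipolar + CSA expressions:

    R1  = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c² J(ωN)
    R2  = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
        + (c²/6)[4J(0) + 3J(ωN)] + Rex
    NOE = 1 + (d²/4)(γH/γN)(1/R1)[6J(ωH+ωN) − J(ωH−ωN)]
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from .context import DiffusionModel, DynamicsParams, SpectrometerContext


class Rates(NamedTuple):
    """Back-calculated observables at one field."""

    r1: float
    r2: float
    noe: float


def axial_weights(angle_deg: float) -> tuple[float, float, float]:
    """Orientation weights (A1, A2, A3) for an axially symmetric tensor.

    ``angle_deg`` is the angle between the N-H vector and the unique
    diffusion axis.  The weights sum to one for any angle.
    """
    c2 = math.cos(math.radians(angle_deg)) ** 2
    s2 = 1.0 - c2
    a1 = (1.5 * c2 - 0.5) ** 2
    a2 = 3.0 * s2 * c2
    a3 = 0.75 * s2 * s2
    return a1, a2, a3


def axial_correlation_times(tm_s: float, anisotropy_ratio: float) -> tuple[float, float, float]:
    """The three global correlation times of axially symmetric tumbling.

    ``tm_s`` is interpreted as the isotropic-equivalent correlation time
    1/(6 D_iso) with D_iso = (2 D⊥ + D∥)/3; the ratio is D∥/D⊥.
    """
    d_iso = 1.0 / (6.0 * tm_s)
    d_perp = 3.0 * d_iso / (2.0 + anisotropy_ratio)
    d_par = anisotropy_ratio * d_perp
    return (
        1.0 / (6.0 * d_perp),
        1.0 / (5.0 * d_perp + d_par),
        1.0 / (2.0 * d_perp + 4.0 * d_par),
    )


def _lorentzian_pair(omega: float, tau: float, params: DynamicsParams) -> float:
    """S²-weighted global Lorentzian plus the internal-motion term."""
    s2, s2f, te = params.s2, params.s2f, params.te_s
    out = s2 * tau / (1.0 + (omega * tau) ** 2)
    if te > 0.0 and s2f > s2:
        tau_p = tau * te / (tau + te)
        out += (s2f - s2) * tau_p / (1.0 + (omega * tau_p) ** 2)
    return out


def spectral_density(omega: float, diffusion: DiffusionModel, params: DynamicsParams) -> float:
    """Evaluate J(ω) in s/rad for one N-H vector.

    Dispatches on ``diffusion.kind``; the axially symmetric branch
    requires ``diffusion.nh_axis_angle_deg``.
    """
    if not np.isfinite(omega) or omega < 0:
        raise ValueError("omega must be finite and >= 0")
    if diffusion.kind == "axially_symmetric":
        return spectral_density_axial(omega, diffusion, params)
    return 0.4 * _lorentzian_pair(omega, diffusion.tm_s, params)


def spectral_density_axial(
    omega: float, diffusion: DiffusionModel, params: DynamicsParams
) -> float:
    """J(ω) under axially symmetric overall tumbling.

    Reduces exactly to the isotropic form when D∥/D⊥ = 1.
    """
    if not np.isfinite(omega) or omega < 0:
        raise ValueError("omega must be finite and >= 0")
    if diffusion.nh_axis_angle_deg is None:
        raise ValueError(
            "axially symmetric diffusion requires per-residue N-H axis "
            "orientations (nh_axis_angle_deg)"
        )
    weights = axial_weights(diffusion.nh_axis_angle_deg)
    taus = axial_correlation_times(diffusion.tm_s, diffusion.anisotropy_ratio)
    return 0.4 * sum(
        a * _lorentzian_pair(omega, tau, params) for a, tau in zip(weights, taus)
    )


def predict_rates(
    params: DynamicsParams,
    diffusion: DiffusionModel,
    context: SpectrometerContext,
) -> Rates:
    """Back-calculate (R1, R2, NOE) from model-free parameters.

    ``params.rex`` enters R2 additively and is understood to be the
    exchange contribution at this context's field.
    """
    wh, wn = context.omega_h, context.omega_n
    d2, c2 = context.d2, context.c2

    def j(w: float) -> float:
        return spectral_density(w, diffusion, params)

    j0 = j(0.0)
    jn = j(wn)
    jh = j(wh)
    jdiff = j(wh - wn)
    jsum = j(wh + wn)

    r1 = d2 / 4.0 * (jdiff + 3.0 * jn + 6.0 * jsum) + c2 * jn
    r2 = (
        d2 / 8.0 * (4.0 * j0 + jdiff + 3.0 * jn + 6.0 * jh + 6.0 * jsum)
        + c2 / 6.0 * (4.0 * j0 + 3.0 * jn)
        + params.rex
    )
    # degenerate parameter sets (S2 = 0, te = 0) have no relaxation at all;
    # the NOE enhancement is then zero by construction
    noe = 1.0 if r1 == 0.0 else 1.0 + d2 / 4.0 * context.gamma_ratio * (6.0 * jsum - jdiff) / r1
    return Rates(r1=r1, r2=r2, noe=noe)
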