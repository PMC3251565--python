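"""Experimental context and dynamics parameter types.

A :class:`SpectrometerContext` fixes the static magnetic field and the
physical constants of the two backbone-amide relaxation mechanisms
(¹H-¹⁵N dipolar coupling and ¹⁵N chemical-shift anisotropy).
A :class:`DiffusionModel` describes the overall rotational tumbling of
the molecule, and :class:`DynamicsParams` the local motion of one N-H
bond vector in the Lipari-Szabo model-free picture.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator

MU0 = 4.0e-7 * math.pi  # vacuum permeability, T^2 m^3 / J
HBAR = 1.054571817e-34  # reduced Planck constant, J s
GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad / s / T

#: Model-free model ids and the parameters each leaves free.
MODEL_FREE_PARAMS: dict[int, tuple[str, ...]] = {
    1: ("s2",),
    2: ("s2", "te"),
    3: ("s2", "rex"),
    4: ("s2", "te", "rex"),
    5: ("s2f", "s2s", "te"),
}


class SpectrometerContext(BaseModel):
    """Field strength and interaction constants for ¹⁵N relaxation.

    Parameters
    ----------
    proton_frequency_mhz:
        ¹H Larmor frequency in MHz. "600 MHz" spectrometers operate at
        600.13 MHz, the default here.
    r_nh_angstrom:
        Effective N-H bond length in Å (default 1.02, the value in
        long-standing use for backbone amide model-free analysis).
    csa_ppm:
        ¹⁵N chemical-shift anisotropy Δσ in ppm (default -160).
    gamma_ratio:
        Signed gyromagnetic-ratio ratio γH/γN (default -9.8656); the
        sign only enters the steady-state NOE.
    """

    model_config = ConfigDict(frozen=True)

    proton_frequency_mhz: float = 600.13
    r_nh_angstrom: float = 1.02
    csa_ppm: float = -160.0
    gamma_ratio: float = -9.8656

    @model_validator(mode="after")
    def _check(self) -> "SpectrometerContext":
        if not (self.proton_frequency_mhz > 0):
            raise ValueError("proton_frequency_mhz must be > 0")
        if not (self.r_nh_angstrom > 0):
            raise ValueError("nh bond length must be > 0")
        if not (abs(self.gamma_ratio) > 1):
            raise ValueError("|gamma_ratio| must exceed 1 (gamma_H > gamma_N)")
        return self

    # ---- derived angular frequencies (rad/s, magnitudes) ----

    @property
    def omega_h(self) -> float:
        """¹H angular Larmor frequency, rad/s."""
        return 2.0 * math.pi * self.proton_frequency_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """¹⁵N angular Larmor frequency magnitude, rad/s."""
        return self.omega_h / abs(self.gamma_ratio)

    @property
    def omega_sum(self) -> float:
        return self.omega_h + self.omega_n

    @property
    def omega_diff(self) -> float:
        return self.omega_h - self.omega_n

    # ---- interaction constants ----

    @property
    def d2(self) -> float:
        """Squared dipolar coupling constant d², s⁻²."""
        r = self.r_nh_angstrom * 1e-10
        gamma_n = GAMMA_H / abs(self.gamma_ratio)
        d = MU0 * HBAR * GAMMA_H * gamma_n / (4.0 * math.pi * r**3)
        return d * d

    @property
    def c2(self) -> float:
        """Squared CSA interaction constant c² = (ωN Δσ/√3)², s⁻²."""
        c = self.omega_n * abs(self.csa_ppm) * 1e-6 / math.sqrt(3.0)
        return c * c

    @classmethod
    def from_config(cls, config: dict) -> "SpectrometerContext":
        """Build from a plain config mapping (JSON/YAML block)."""
        return cls(**config)

    def to_config(self) -> dict:
        return self.model_dump()


class DiffusionModel(BaseModel):
    """Overall rotational diffusion of the molecule.

    ``isotropic`` tumbling is characterised by the single correlation
    time ``tm_s``.  ``axially_symmetric`` tumbling additionally needs
    the tensor anisotropy D∥/D⊥ and, per residue, the angle between the
    N-H bond vector and the unique diffusion axis.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["isotropic", "axially_symmetric"] = "isotropic"
    tm_s: float
    anisotropy_ratio: float = 1.0
    nh_axis_angle_deg: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DiffusionModel":
        if not (self.tm_s > 0):
            raise ValueError("tm_s must be > 0")
        if not (self.anisotropy_ratio > 0):
            raise ValueError("anisotropy_ratio must be > 0")
        return self


class DynamicsParams(BaseModel):
    """Model-free parameters of one N-H bond vector.

    Models 1-4 use the generalized order parameter ``s2`` with optional
    internal correlation time ``te_s`` and exchange broadening ``rex``;
    model 5 resolves the order parameter into fast and slow components
    with ``s2 = s2f * s2s``.
    """

    model_config = ConfigDict(frozen=True)

    model_id: int = 2
    s2: Optional[float] = None
    te_s: float = 0.0
    rex: float = 0.0
    s2f: float = 1.0
    s2s: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DynamicsParams":
        if self.model_id not in MODEL_FREE_PARAMS:
            raise ValueError(f"model_id must be in {sorted(MODEL_FREE_PARAMS)}")
        if self.model_id == 5:
            if self.s2s is None:
                raise ValueError("model 5 requires s2f and s2s")
            if not (0.0 <= self.s2f <= 1.0 and 0.0 <= self.s2s <= 1.0):
                raise ValueError("s2f and s2s must lie in [0, 1]")
            derived = self.s2f * self.s2s
            if self.s2 is None:
                object.__setattr__(self, "s2", derived)
            elif abs(self.s2 - derived) > 1e-9:
                raise ValueError("model 5 requires s2 = s2f * s2s")
        else:
            if self.s2 is None:
                raise ValueError("s2 is required")
            if self.s2f != 1.0:
                raise ValueError("s2f is free only in model 5")
        if not (0.0 <= self.s2 <= 1.0):
            raise ValueError("s2 must lie in [0, 1]")
        if self.te_s < 0:
            raise ValueError("te_s must be >= 0")
        if self.rex < 0:
            raise ValueError("rex must be >= 0")
        if self.model_id in (1, 3) and self.te_s != 0.0:
            raise ValueError(f"model {self.model_id} fixes te = 0")
        if self.model_id in (1, 2, 5) and self.rex != 0.0:
            raise ValueError(f"model {self.model_id} fixes rex = 0")
        return self
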