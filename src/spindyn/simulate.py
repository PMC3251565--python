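"""Synthetic relaxation datasets for a small disulfide-rich protein.

Emulates a 68-residue disintegrin tumbling isotropically at
τm = 6.38 ns, with a rigid disulfide-bonded core, flexible termini and
an exposed, mobile RGD loop (residues 49-51).  The ``rho_like`` and
``p48a_like`` presets anchor the loop residues to the published
wild-type and P48A-mutant dynamics parameters, so recovery tests have
a realistic and fully known ground truth.  Prolines carry no backbone
amide and are generated but withheld from every observable output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .context import DiffusionModel, DynamicsParams, SpectrometerContext
from .decay import R1_DELAYS_S, R2_DELAYS_S
from .modelfree import ResidueRelaxationRecord
from .spectral import predict_rates

#: Published loop-residue dynamics used as generator truth:
#: residue -> (model_id, S2, te_ns, rex) per preset.
_LOOP_TRUTH = {
    "rho_like": {
        49: ("R", 4, 0.75, 0.11, 0.91),
        50: ("G", 2, 0.50, 0.84, 0.0),
        51: ("D", 4, 0.85, 0.19, 1.42),
    },
    "p48a_like": {
        48: ("A", 2, 0.74, 1.04, 0.0),
        49: ("R", 2, 0.53, 1.04, 0.0),
        50: ("G", 2, 0.43, 0.93, 0.0),
        51: ("D", 2, 0.61, 0.98, 0.0),
    },
}

_PROLINES = {"rho_like": (48, 53), "p48a_like": (53,), "rigid": (), "custom": ()}


@dataclass(frozen=True)
class ResidueTruth:
    residue_id: int
    residue_name: str
    params: DynamicsParams
    region: str  # "core" | "loop" | "terminus"


@dataclass(frozen=True)
class GroundTruthProfile:
    """Per-residue true dynamics of one synthetic protein."""

    preset: str
    seed: int
    residues: tuple[ResidueTruth, ...]
    proline_positions: tuple[int, ...]
    diffusion: DiffusionModel

    def observable(self) -> tuple[ResidueTruth, ...]:
        """Residues with a backbone amide (prolines withheld)."""
        return tuple(r for r in self.residues if r.residue_id not in self.proline_positions)

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue": r.residue_id,
                "name": r.residue_name,
                "region": r.region,
                "model": r.params.model_id,
                "S2": r.params.s2,
                "te_ns": r.params.te_s * 1e9,
                "rex": r.params.rex,
            }
            for r in self.observable()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise and replication structure of the experiments."""

    height_cv: float = 0.02
    n_rate_replicates: int = 2
    n_noe_pairs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_cv < 0:
            raise ValueError("height_cv must be >= 0")
        if self.n_rate_replicates < 1 or self.n_noe_pairs < 1:
            raise ValueError("replicate counts must be >= 1")


def _core_params(rng: np.random.Generator) -> DynamicsParams:
    s2 = float(np.clip(rng.normal(0.82, 0.05), 0.70, 0.95))
    if rng.random() < 0.5:
        return DynamicsParams(model_id=1, s2=s2)
    return DynamicsParams(model_id=2, s2=s2, te_s=float(rng.uniform(5e-12, 50e-12)))


def _terminus_params(rng: np.random.Generator) -> DynamicsParams:
    return DynamicsParams(
        model_id=2,
        s2=float(rng.uniform(0.45, 0.65)),
        te_s=float(rng.uniform(1e-10, 5e-10)),
    )


def _loop_filler_params(rng: np.random.Generator) -> DynamicsParams:
    return DynamicsParams(
        model_id=2,
        s2=float(rng.uniform(0.60, 0.75)),
        te_s=float(rng.uniform(1e-10, 5e-10)),
    )


def make_profile(
    preset: str,
    n_residues: int = 68,
    tm_ns: float = 6.38,
    seed: int = 0,
    overrides: Optional[dict[int, DynamicsParams]] = None,
) -> GroundTruthProfile:
    """Build a ground-truth dynamics profile.

    Presets: ``rho_like`` (wild-type loop values, prolines at 48 and
    53), ``p48a_like`` (mutant loop values, proline at 53), ``rigid``
    (all residues S² = 0.85, no internal motion) and ``custom`` (core
    statistics everywhere; use ``overrides`` to place features).
    Deterministic for a given seed.
    """
    if preset not in _PROLINES:
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng([seed, zlib.crc32(preset.encode())])
    loop_truth = _LOOP_TRUTH.get(preset, {})
    loop_span = range(47, 54) if preset in _LOOP_TRUTH else range(0)
    residues = []
    for rid in range(1, n_residues + 1):
        name = "X"
        if preset == "rigid":
            params, region = DynamicsParams(model_id=1, s2=0.85), "core"
        elif rid in loop_truth:
            name, model_id, s2, te_ns, rex = loop_truth[rid]
            params = DynamicsParams(model_id=model_id, s2=s2, te_s=te_ns * 1e-9, rex=rex)
            region = "loop"
        elif rid in loop_span:
            params, region = _loop_filler_params(rng), "loop"
            name = {48: "P", 52: "M", 53: "P"}.get(rid, "X")
        elif rid <= 3 or rid > n_residues - 3:
            params, region = _terminus_params(rng), "terminus"
        else:
            params, region = _core_params(rng), "core"
        if overrides and rid in overrides:
            params = overrides[rid]
        residues.append(ResidueTruth(rid, name, params, region))
    return GroundTruthProfile(
        preset=preset,
        seed=seed,
        residues=tuple(residues),
        proline_positions=tuple(p for p in _PROLINES[preset] if p <= n_residues),
        diffusion=DiffusionModel(kind="isotropic", tm_s=tm_ns * 1e-9),
    )


def simulate_rates(
    profile: GroundTruthProfile,
    context: SpectrometerContext,
    sigma_frac: float = 0.005,
) -> list[ResidueRelaxationRecord]:
    """Noiseless records: exact forward rates with floor uncertainties."""
    records = []
    for res in profile.observable():
        r1, r2, noe = predict_rates(res.params, profile.diffusion, context)
        records.append(
            ResidueRelaxationRecord(
                residue_id=res.residue_id,
                residue_name=res.residue_name,
                r1=r1, r1_err=sigma_frac * r1,
                r2=r2, r2_err=sigma_frac * r2,
                noe=noe, noe_err=sigma_frac * max(abs(noe), 1.0),
                context=context,
            )
        )
    return records


def simulate_decays(
    profile: GroundTruthProfile,
    context: SpectrometerContext,
    noise: NoiseModel = NoiseModel(),
    amplitude: float = 1.0e5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Noisy long-format peak-height dataset plus truth table.

    For every observable residue, replicate and delay, the height is
    I0 exp(-R t)(1 + ε) with ε ~ N(0, height_cv) — multiplicative
    noise, since peak-height scatter scales with intensity.  NOE
    saturated/reference pairs are generated analogously.  Returns
    (decays, truth, manifest); regeneration from the manifest
    reproduces the dataset exactly.
    """
    rng = np.random.default_rng([noise.seed, profile.seed, len(profile.residues)])
    rows = []
    for res in profile.observable():
        r1, r2, noe = predict_rates(res.params, profile.diffusion, context)
        for experiment, rate, delays in (("R1", r1, R1_DELAYS_S), ("R2", r2, R2_DELAYS_S)):
            for rep in range(1, noise.n_rate_replicates + 1):
                eps = rng.normal(0.0, noise.height_cv, size=len(delays)) if noise.height_cv else np.zeros(len(delays))
                for delay, e in zip(delays, eps):
                    rows.append(
                        {
                            "residue": res.residue_id,
                            "experiment": experiment,
                            "replicate": rep,
                            "delay_s": delay,
                            "height": amplitude * np.exp(-rate * delay) * (1.0 + e),
                        }
                    )
        for pair in range(1, noise.n_noe_pairs + 1):
            eps_ref, eps_sat = (
                rng.normal(0.0, noise.height_cv, size=2) if noise.height_cv else (0.0, 0.0)
            )
            rows.append(
                {
                    "residue": res.residue_id, "experiment": "NOE_REF",
                    "replicate": pair, "delay_s": np.nan,
                    "height": amplitude * (1.0 + eps_ref),
                }
            )
            rows.append(
                {
                    "residue": res.residue_id, "experiment": "NOE_SAT",
                    "replicate": pair, "delay_s": np.nan,
                    "height": amplitude * noe * (1.0 + eps_sat),
                }
            )
    decays = pd.DataFrame(rows, columns=["residue", "experiment", "replicate", "delay_s", "height"])
    manifest = {
        "preset": profile.preset,
        "profile_seed": profile.seed,
        "n_residues": len(profile.residues),
        "tm_ns": profile.diffusion.tm_s * 1e9,
        "noise": {
            "height_cv": noise.height_cv,
            "n_rate_replicates": noise.n_rate_replicates,
            "n_noe_pairs": noise.n_noe_pairs,
            "seed": noise.seed,
        },
        "context": context.to_config(),
    }
    return decays, profile.truth_frame(), manifest
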