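"""Relaxation-rate estimation from peak-height decay series.

R1 and R2 come from nonlinear least-squares fits of I(t) = I0 exp(-R t)
to peak heights measured at a series of relaxation delays; replicate
series are fitted independently and averaged.  The steady-state NOE is
the ratio of peak heights with and without proton saturation, averaged
over experiment pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model

#: Relaxation-delay schedules (s) of the R1 and R2 experiment series.
R1_DELAYS_S: tuple[float, ...] = (
    0.030, 0.100, 0.150, 0.300, 0.450, 0.600, 0.800, 1.000, 1.500, 3.000,
)
R2_DELAYS_S: tuple[float, ...] = (
    0.018, 0.036, 0.048, 0.072, 0.090, 0.100, 0.120, 0.150, 0.300, 0.500,
)

#: Plausible range of backbone 15N rates in s^-1; values outside suggest
#: delays supplied in the wrong unit (e.g. ms instead of s).
PLAUSIBLE_RATE_RANGE = (0.01, 100.0)


@dataclass(frozen=True)
class DecaySeries:
    """Peak heights of one residue vs relaxation delay, one replicate."""

    residue_id: int
    experiment: str  # "R1" | "R2"
    delays_s: tuple[float, ...]
    heights: tuple[float, ...]
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if self.experiment not in ("R1", "R2"):
            raise ValueError("experiment must be 'R1' or 'R2'")
        delays = np.asarray(self.delays_s, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if delays.shape != heights.shape or delays.ndim != 1:
            raise ValueError("delays and heights must be equal-length 1-D")
        if len(np.unique(delays)) < 2:
            raise ValueError("need >= 2 distinct relaxation delays")
        if np.any(delays < 0) or not np.all(np.isfinite(delays)):
            raise ValueError("delays must be finite and non-negative")
        if not np.all(np.isfinite(heights)):
            raise ValueError("heights must be finite")

    def sorted(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(self.delays_s)
        return (
            np.asarray(self.delays_s, dtype=float)[order],
            np.asarray(self.heights, dtype=float)[order],
        )


@dataclass(frozen=True)
class RateEstimate:
    """Fitted relaxation rate with uncertainty."""

    residue_id: int
    rate: float
    sigma: float
    amplitude: float
    n_replicates: int = 1
    status: str = "ok"  # "ok" | "warning"
    messages: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class NOEEstimate:
    """Steady-state heteronuclear NOE with pair-scatter uncertainty."""

    residue_id: int
    noe: float
    sigma: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.noe > 1.05:
            raise ValueError("NOE above 1.05 indicates corrupt input")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _log_linear_start(delays: np.ndarray, heights: np.ndarray) -> tuple[float, float]:
    """Initial (I0, R) from a log-linear regression on positive heights."""
    pos = heights > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(delays[pos], np.log(heights[pos]), 1)
        return float(np.exp(intercept)), float(-slope)
    return float(np.max(np.abs(heights)) or 1.0), 1.0


def fit_monoexponential(series: DecaySeries) -> RateEstimate:
    """Fit I(t) = I0 exp(-R t) to one decay series.

    Nonlinear least squares on the untransformed heights (two free
    parameters), initialised from a log-linear fit.  Two distinct
    delays are the minimum: they determine the exponential exactly.
    Non-decaying data (best-fit R <= 0) and rates outside the
    plausible 0.01-100 s^-1 window are returned flagged, not raised.
    """
    delays, heights = series.sorted()
    i0_start, r_start = _log_linear_start(delays, heights)

    model = Model(lambda t, i0, r: i0 * np.exp(-r * t))
    params = model.make_params(i0=i0_start, r=r_start)
    result = model.fit(heights, params, t=delays)

    rate = float(result.params["r"].value)
    amplitude = float(result.params["i0"].value)
    sigma = float(result.params["r"].stderr or 0.0)

    status, messages = "ok", []
    if rate <= 0:
        status = "warning"
        messages.append("non-decaying data: best-fit rate <= 0")
    elif not (PLAUSIBLE_RATE_RANGE[0] <= rate <= PLAUSIBLE_RATE_RANGE[1]):
        status = "warning"
        messages.append(
            f"fitted rate {rate:.3g} s^-1 outside the plausible "
            f"{PLAUSIBLE_RATE_RANGE[0]}-{PLAUSIBLE_RATE_RANGE[1]} s^-1 window; "
            "check that delays are in seconds"
        )
        warnings.warn(messages[-1], stacklevel=2)
    return RateEstimate(
        residue_id=series.residue_id,
        rate=rate,
        sigma=sigma,
        amplitude=amplitude,
        n_replicates=1,
        status=status,
        messages=tuple(messages),
    )


def aggregate_replicates(estimates: Sequence[RateEstimate]) -> RateEstimate:
    """Combine replicate fits of one residue into the reported rate.

    The rate is the mean over replicates.  The uncertainty is the
    larger of the propagated fit sigma of the mean and the half-range
    of the replicate rates — a conservative rule covering both the
    per-fit precision and the replicate scatter.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    ids = {e.residue_id for e in estimates}
    if len(ids) > 1:
        raise ValueError(f"mixed residues in replicate aggregation: {sorted(ids)}")
    if len(estimates) == 1:
        return estimates[0]
    rates = np.array([e.rate for e in estimates])
    sigmas = np.array([e.sigma for e in estimates])
    propagated = float(np.sqrt(np.sum(sigmas**2)) / len(estimates))
    half_range = float((rates.max() - rates.min()) / 2.0)
    status = "ok" if all(e.status == "ok" for e in estimates) else "warning"
    return RateEstimate(
        residue_id=estimates[0].residue_id,
        rate=float(rates.mean()),
        sigma=max(propagated, half_range),
        amplitude=float(np.mean([e.amplitude for e in estimates])),
        n_replicates=len(estimates),
        status=status,
        messages=tuple(m for e in estimates for m in e.messages),
    )


def compute_noe(
    sat_heights: Sequence[float], ref_heights: Sequence[float], residue_id: int
) -> NOEEstimate:
    """NOE = mean over pairs of (saturated / reference) peak height.

    The uncertainty is the sample standard deviation over pairs
    (zero when only one pair is available).
    """
    sat = np.asarray(sat_heights, dtype=float)
    ref = np.asarray(ref_heights, dtype=float)
    if sat.size == 0 or sat.shape != ref.shape:
        raise ValueError("sat and ref heights must be equal-length and non-empty")
    if np.any(ref <= 0):
        raise ValueError("reference peak heights must be positive")
    ratios = sat / ref
    sigma = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return NOEEstimate(
        residue_id=residue_id,
        noe=float(ratios.mean()),
        sigma=sigma,
        n_pairs=int(ratios.size),
    )


def rates_from_decays(decays: pd.DataFrame) -> pd.DataFrame:
    """Full rate table from a long-format peak-height table.

    Input columns: residue, experiment (R1|R2|NOE_SAT|NOE_REF),
    replicate, delay_s (empty for NOE rows), height.  Output: one row
    per residue with columns residue, R1, R1_err, R2, R2_err, NOE,
    NOE_err (missing experiments yield NaN).
    """
    rows = []
    for residue, group in decays.groupby("residue"):
        row: dict = {"residue": int(residue)}
        for experiment in ("R1", "R2"):
            sub = group[group["experiment"] == experiment]
            fits = [
                fit_monoexponential(
                    DecaySeries(
                        residue_id=int(residue),
                        experiment=experiment,
                        delays_s=tuple(rep["delay_s"].astype(float)),
                        heights=tuple(rep["height"].astype(float)),
                        replicate_id=int(rep_id),
                    )
                )
                for rep_id, rep in sub.groupby("replicate")
            ]
            if fits:
                agg = aggregate_replicates(fits)
                row[experiment] = agg.rate
                row[f"{experiment}_err"] = agg.sigma
            else:
                row[experiment] = np.nan
                row[f"{experiment}_err"] = np.nan
        sat = group[group["experiment"] == "NOE_SAT"].sort_values("replicate")
        ref = group[group["experiment"] == "NOE_REF"].sort_values("replicate")
        if len(sat) and len(sat) == len(ref):
            noe = compute_noe(
                sat["height"].to_numpy(float), ref["height"].to_numpy(float), int(residue)
            )
            row["NOE"] = noe.noe
            row["NOE_err"] = noe.sigma
        else:
            row["NOE"] = np.nan
            row["NOE_err"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["residue", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"])
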