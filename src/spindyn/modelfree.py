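"""Model-free inference from per-residue relaxation rates.

Per residue, the five standard model-free parameterisations are fitted
by chi-square minimisation of the three observables (R1, R2, NOE):

    m1 {S²}   m2 {S², τe}   m3 {S², Rex}   m4 {S², τe, Rex}
    m5 {S²f, S²s, τe}

Model selection follows the stepwise procedure of the classic
model-free literature: accept the simplest model passing a Monte-Carlo
chi-square goodness-of-fit test, escalating through F-tests for added
parameters.  The overall correlation time τm is optimised on a rigid
"core" residue subset and then fixed for the final per-residue fits.
Parameter uncertainties come from Monte-Carlo resampling of the rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .context import MODEL_FREE_PARAMS, DiffusionModel, DynamicsParams, SpectrometerContext
from .spectral import axial_correlation_times, axial_weights, predict_rates

#: Parameter bounds used by every fit; te upper bound is replaced by tm.
BOUNDS = {"s2": (0.0, 1.0), "te": (0.0, None), "rex": (0.0, 20.0), "s2f": (0.0, 1.0), "s2s": (0.0, 1.0)}

#: Multi-start grids (te in seconds).
STARTS = {"s2": (0.3, 0.6, 0.9), "te": (1e-11, 1e-10, 1e-9), "rex": (0.0, 2.0), "s2f": (0.9,), "s2s": (0.3, 0.6, 0.9)}


@dataclass(frozen=True)
class ResidueRelaxationRecord:
    """One residue's (R1, R2, NOE) triplet with uncertainties at one field."""

    residue_id: int
    r1: float
    r1_err: float
    r2: float
    r2_err: float
    noe: float
    noe_err: float
    context: SpectrometerContext
    residue_name: str = ""

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("rates must be positive")

    def sigmas(self, floor_frac: float = 0.005) -> np.ndarray:
        """Uncertainties with a relative floor keeping chi-square finite.

        Sigmas below ``floor_frac`` of the observable's magnitude are
        raised to that floor (NOE floor uses magnitude 1 reference
        scaled by the observed value or 0.01, whichever is larger).
        """
        obs = np.array([self.r1, self.r2, self.noe])
        raw = np.array([self.r1_err, self.r2_err, self.noe_err])
        floor = floor_frac * np.maximum(np.abs(obs), [0.0, 0.0, 1.0])
        return np.maximum(raw, floor)


@dataclass(frozen=True)
class ModelFit:
    """Result of fitting one model-free model to one record."""

    residue_id: int
    params: DynamicsParams
    chi2: float
    dof: int
    status: str = "converged"  # "converged" | "boundary" | "failed"
    mc_sigmas: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SelectionConfig:
    """Settings of the stepwise model-selection procedure."""

    gof_level: float = 0.90
    ftest_level: float = 0.80
    n_sims: int = 500
    seed: int = 0
    sigma_floor: float = 0.005


def _params_from_vector(model_id: int, x: np.ndarray) -> DynamicsParams:
    names = MODEL_FREE_PARAMS[model_id]
    kw = dict(zip(names, (float(v) for v in x)))
    if model_id == 5:
        return DynamicsParams(model_id=5, s2f=kw["s2f"], s2s=kw["s2s"], te_s=kw["te"])
    return DynamicsParams(
        model_id=model_id,
        s2=kw["s2"],
        te_s=kw.get("te", 0.0),
        rex=kw.get("rex", 0.0),
    )


def chi_square(
    record: ResidueRelaxationRecord,
    params: DynamicsParams,
    diffusion: DiffusionModel,
    sigma_floor: float = 0.005,
) -> float:
    """chi2 = sum over {R1, R2, NOE} of ((observed - predicted)/sigma)^2."""
    sig = record.sigmas(sigma_floor)
    if np.any(sig <= 0):
        raise ValueError("sigmas must be positive")
    pred = predict_rates(params, diffusion, record.context)
    obs = np.array([record.r1, record.r2, record.noe])
    return float(np.sum(((obs - np.array(pred)) / sig) ** 2))


def _residual_fn(record, model_id, diffusion, sigma_floor):
    """Weighted-residual closure over raw floats.

    Avoids per-evaluation construction of validated parameter objects;
    agrees with the public ``predict_rates`` to machine precision (the
    formulas are identical, only the plumbing differs).
    """
    sig = record.sigmas(sigma_floor)
    obs = np.array([record.r1, record.r2, record.noe])
    ctx = record.context
    wh, wn, d2, c2, gr = ctx.omega_h, ctx.omega_n, ctx.d2, ctx.c2, ctx.gamma_ratio
    if diffusion.kind == "axially_symmetric":
        if diffusion.nh_axis_angle_deg is None:
            raise ValueError("axial fitting requires nh_axis_angle_deg")
        weights = axial_weights(diffusion.nh_axis_angle_deg)
        taus = axial_correlation_times(diffusion.tm_s, diffusion.anisotropy_ratio)
    else:
        weights, taus = (1.0,), (diffusion.tm_s,)
    freqs = (0.0, wn, wh, wh - wn, wh + wn)

    def residuals(x: np.ndarray) -> np.ndarray:
        if model_id == 5:
            s2f, s2s, te = x
            s2, rex = s2f * s2s, 0.0
        else:
            s2 = x[0]
            te = x[1] if model_id in (2, 4) else 0.0
            rex = x[-1] if model_id in (3, 4) else 0.0
            s2f = 1.0
        j = []
        for w in freqs:
            val = 0.0
            for a, tau in zip(weights, taus):
                val += a * s2 * tau / (1.0 + (w * tau) ** 2)
                if te > 0.0 and s2f > s2:
                    tp = tau * te / (tau + te)
                    val += a * (s2f - s2) * tp / (1.0 + (w * tp) ** 2)
            j.append(0.4 * val)
        j0, jn, jh, jdiff, jsum = j
        r1 = d2 / 4.0 * (jdiff + 3.0 * jn + 6.0 * jsum) + c2 * jn
        r2 = (
            d2 / 8.0 * (4.0 * j0 + jdiff + 3.0 * jn + 6.0 * jh + 6.0 * jsum)
            + c2 / 6.0 * (4.0 * j0 + 3.0 * jn)
            + rex
        )
        noe = 1.0 + d2 / 4.0 * gr * (6.0 * jsum - jdiff) / r1
        return (np.array([r1, r2, noe]) - obs) / sig

    return residuals


def _x_scale(model_id: int) -> np.ndarray:
    """Per-parameter optimizer scales; te lives on the ns scale."""
    return np.array([1e-9 if n == "te" else 1.0 for n in MODEL_FREE_PARAMS[model_id]])


def _bounds_for(model_id: int, tm_s: float) -> tuple[np.ndarray, np.ndarray]:
    names = MODEL_FREE_PARAMS[model_id]
    lo, hi = [], []
    for name in names:
        lb, ub = BOUNDS[name]
        lo.append(lb)
        hi.append(tm_s if name == "te" else ub)
    return np.array(lo), np.array(hi)


def _start_vectors(model_id: int) -> list[np.ndarray]:
    names = MODEL_FREE_PARAMS[model_id]
    grids = [STARTS[n] for n in names]
    mesh = np.meshgrid(*grids, indexing="ij")
    return [np.array(v) for v in zip(*(m.ravel() for m in mesh))]


def _warm_starts(record, model_id, diffusion, sigma_floor) -> list[np.ndarray]:
    """Extra starting points from the solutions of nested simpler models.

    Guarantees nested chi-square dominance in practice: the optimum of
    a simpler model is always reachable from one of the starts of the
    model that contains it.
    """
    extra: list[np.ndarray] = []
    if model_id in (2, 3):
        f1 = fit_model(record, 1, diffusion, sigma_floor=sigma_floor)
        extra.append(np.array([f1.params.s2, 0.0]))
    elif model_id == 4:
        f2 = fit_model(record, 2, diffusion, sigma_floor=sigma_floor)
        f3 = fit_model(record, 3, diffusion, sigma_floor=sigma_floor)
        extra.append(np.array([f2.params.s2, f2.params.te_s, 0.0]))
        extra.append(np.array([f2.params.s2, f2.params.te_s, 0.5]))
        extra.append(np.array([f3.params.s2, 0.0, f3.params.rex]))
    elif model_id == 5:
        f2 = fit_model(record, 2, diffusion, sigma_floor=sigma_floor)
        extra.append(np.array([1.0, f2.params.s2, f2.params.te_s]))
    return extra


def fit_model(
    record: ResidueRelaxationRecord,
    model_id: int,
    diffusion: DiffusionModel,
    context: Optional[SpectrometerContext] = None,
    sigma_floor: float = 0.005,
    starts: Optional[Sequence[np.ndarray]] = None,
) -> ModelFit:
    """Fit one model by multi-start bounded least squares.

    Starting points span the physically relevant ranges and include
    the solutions of nested simpler models, so the result is
    independent of initialisation despite the multimodal chi-square
    surface in τe.  ``context`` defaults to the record's own.
    """
    if context is not None and context != record.context:
        record = replace(record, context=context)
    residuals = _residual_fn(record, model_id, diffusion, sigma_floor)
    lo, hi = _bounds_for(model_id, diffusion.tm_s)
    if starts is None:
        starts = _start_vectors(model_id) + _warm_starts(
            record, model_id, diffusion, sigma_floor
        )
    scale = _x_scale(model_id)
    best_x, best_cost = None, np.inf
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        # a start that is itself the embedding of a nested model's
        # optimum is already a valid candidate solution
        cost0 = 0.5 * float(np.sum(residuals(x0) ** 2))
        if cost0 < best_cost - 1e-12:
            best_x, best_cost = x0, cost0
        # keep the optimizer start strictly inside the bounds on the
        # parameter's own scale (scipy otherwise nudges an on-bound
        # start by a step that is huge on the te axis)
        x0_run = np.clip(x0, lo + 1e-6 * scale, hi - 1e-6 * scale)
        try:
            res = optimize.least_squares(
                residuals, x0_run, bounds=(lo, hi), x_scale=scale,
                xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if res.cost < best_cost - 1e-12:
            best_x, best_cost = res.x, res.cost
    if best_x is None:
        return ModelFit(
            residue_id=record.residue_id,
            params=DynamicsParams(model_id=model_id, s2=0.0),
            chi2=np.inf,
            dof=3 - len(lo),
            status="failed",
        )
    tol = 1e-4 * (hi - lo)
    at_bound = np.any((np.abs(best_x - lo) < tol) | (np.abs(best_x - hi) < tol))
    return ModelFit(
        residue_id=record.residue_id,
        params=_params_from_vector(model_id, best_x),
        chi2=float(2.0 * best_cost),
        dof=3 - len(lo),
        status="boundary" if at_bound else "converged",
    )


def _refit_from(record, model_id, diffusion, sigma_floor, x0):
    """Single-start refit used inside Monte-Carlo loops."""
    residuals = _residual_fn(record, model_id, diffusion, sigma_floor)
    lo, hi = _bounds_for(model_id, diffusion.tm_s)
    scale = _x_scale(model_id)
    res = optimize.least_squares(
        residuals, np.clip(x0, lo + 1e-6 * scale, hi - 1e-6 * scale),
        bounds=(lo, hi), x_scale=scale, xtol=1e-10, ftol=1e-10,
    )
    return res


def _vector_of(params: DynamicsParams, model_id: int) -> np.ndarray:
    names = MODEL_FREE_PARAMS[model_id]
    lookup = {"s2": params.s2, "te": params.te_s, "rex": params.rex, "s2f": params.s2f, "s2s": params.s2s}
    return np.array([lookup[n] for n in names], dtype=float)


def _mc_records(record: ResidueRelaxationRecord, fit: ModelFit, diffusion, sigma_floor, n, rng):
    """Synthetic records resampled around the back-calculated rates."""
    pred = np.array(predict_rates(fit.params, diffusion, record.context))
    sig = record.sigmas(sigma_floor)
    draws = pred[None, :] + rng.standard_normal((n, 3)) * sig[None, :]
    out = []
    for d in draws:
        r1, r2, noe = d
        out.append(
            replace(record, r1=max(r1, 1e-6), r1_err=record.r1_err,
                    r2=max(r2, 1e-6), r2_err=record.r2_err, noe=noe, noe_err=record.noe_err)
        )
    return out


def _mc_gof_critical(record, fit, diffusion, config) -> float:
    """Goodness-of-fit critical chi2 from Monte-Carlo simulation.

    Simulates records from the fitted model with the record's sigmas,
    refits the same model, and returns the ``gof_level`` quantile of
    the resulting chi-square distribution.
    """
    rng = np.random.default_rng([config.seed, record.residue_id, fit.params.model_id])
    x_fit = _vector_of(fit.params, fit.params.model_id)
    chi2s = []
    for rec in _mc_records(record, fit, diffusion, config.sigma_floor, config.n_sims, rng):
        res = _refit_from(rec, fit.params.model_id, diffusion, config.sigma_floor, x_fit)
        chi2s.append(2.0 * res.cost)
    return float(np.quantile(chi2s, config.gof_level))


def _passes_gof(record, fit, diffusion, config) -> bool:
    """Monte-Carlo goodness-of-fit decision with analytic brackets.

    The simulated null distribution tracks chi-square with ``fit.dof``
    degrees of freedom, distorted somewhat by the parameter bounds.
    When the observed chi-square falls below the 5th percentile of the
    analytic distribution the Monte-Carlo critical value cannot reject
    it, and when it exceeds three times the 1-1e-6 quantile no
    plausible critical value can accept it; simulation is only needed
    between those extremes.
    """
    if fit.dof <= 0:
        return False
    if fit.chi2 <= stats.chi2.ppf(0.05, fit.dof):
        return True
    if fit.chi2 >= 3.0 * stats.chi2.ppf(1.0 - 1e-6, fit.dof):
        return False
    return fit.chi2 <= _mc_gof_critical(record, fit, diffusion, config)


def _f_test_passes(chi2_simple, chi2_complex, n_extra, dof_complex, level) -> bool:
    if dof_complex <= 0:
        return False
    if chi2_complex <= 0:
        return True
    f = (chi2_simple - chi2_complex) / n_extra / (chi2_complex / dof_complex)
    return f > stats.f.ppf(level, n_extra, dof_complex)


def select_model(
    record: ResidueRelaxationRecord,
    diffusion: DiffusionModel,
    context: Optional[SpectrometerContext] = None,
    config: SelectionConfig = SelectionConfig(),
) -> ModelFit:
    """Stepwise model selection for one residue.

    Stage 1 accepts m1 if it passes the Monte-Carlo goodness-of-fit
    test.  Stage 2 fits m2 and m3 and accepts a model passing both its
    own goodness-of-fit test and an F-test against m1.  Stage 3 falls
    back to the three-parameter models (m4, m5), which fit three
    observables exactly; the one with lower chi-square wins, ties
    breaking toward the lower model id.  Deterministic given
    ``config`` (the Monte-Carlo seed derives from config.seed and the
    residue id).
    """
    if context is not None and context != record.context:
        record = replace(record, context=context)
    floor = config.sigma_floor

    fit1 = fit_model(record, 1, diffusion, sigma_floor=floor, starts=_start_vectors(1))
    if fit1.status != "failed" and _passes_gof(record, fit1, diffusion, config):
        return fit1

    # warm starts from the accepted-or-not simpler fits avoid redundant refits
    s1 = fit1.params.s2
    fits2 = {
        2: fit_model(record, 2, diffusion, sigma_floor=floor,
                     starts=_start_vectors(2) + [np.array([s1, 0.0])]),
        3: fit_model(record, 3, diffusion, sigma_floor=floor,
                     starts=_start_vectors(3) + [np.array([s1, 0.0])]),
    }
    candidates = []
    for m, fit in fits2.items():
        if fit.status == "failed":
            continue
        if not _f_test_passes(fit1.chi2, fit.chi2, 1, fit.dof, config.ftest_level):
            continue
        if _passes_gof(record, fit, diffusion, config):
            candidates.append(fit)
    if candidates:
        return min(candidates, key=lambda f: (round(f.chi2, 9), f.params.model_id))

    p2, p3 = fits2[2].params, fits2[3].params
    starts4 = _start_vectors(4) + [
        np.array([p2.s2, p2.te_s, 0.0]),
        np.array([p2.s2, p2.te_s, 0.5]),
        np.array([p3.s2, 0.0, p3.rex]),
    ]
    starts5 = _start_vectors(5) + [np.array([1.0, p2.s2, p2.te_s])]
    fits3 = [
        fit_model(record, 4, diffusion, sigma_floor=floor, starts=starts4),
        fit_model(record, 5, diffusion, sigma_floor=floor, starts=starts5),
    ]
    fits3 = [f for f in fits3 if f.status != "failed"]
    pool = fits3 + [f for f in fits2.values() if f.status != "failed"] + (
        [fit1] if fit1.status != "failed" else []
    )
    if not pool:
        return fit1
    return min(pool, key=lambda f: (round(f.chi2, 6), f.params.model_id))


def monte_carlo_errors(
    fit: ModelFit,
    record: ResidueRelaxationRecord,
    diffusion: DiffusionModel,
    context: Optional[SpectrometerContext] = None,
    n_draws: int = 500,
    seed: int = 0,
    sigma_floor: float = 0.005,
) -> ModelFit:
    """Parameter uncertainties by Monte-Carlo resampling.

    Draws ``n_draws`` synthetic records Gaussian-distributed around the
    back-calculated rates with the record's sigmas, refits the same
    model, and reports the standard deviation of each parameter.
    Bitwise reproducible for a fixed seed.
    """
    if fit.status == "failed":
        raise ValueError("cannot propagate errors through a failed fit")
    if context is not None and context != record.context:
        record = replace(record, context=context)
    model_id = fit.params.model_id
    rng = np.random.default_rng([seed, record.residue_id, model_id, n_draws])
    x_fit = _vector_of(fit.params, model_id)
    samples = []
    for rec in _mc_records(record, fit, diffusion, sigma_floor, n_draws, rng):
        res = _refit_from(rec, model_id, diffusion, sigma_floor, x_fit)
        samples.append(res.x)
    sds = np.std(np.array(samples), axis=0, ddof=1)
    names = MODEL_FREE_PARAMS[model_id]
    return replace(fit, mc_sigmas={n: float(s) for n, s in zip(names, sds)})


# ---------------------------------------------------------------------------
# Overall correlation time
# ---------------------------------------------------------------------------


def _rigid_r2_over_r1(tm_s: float, context: SpectrometerContext) -> float:
    diffusion = DiffusionModel(kind="isotropic", tm_s=tm_s)
    params = DynamicsParams(model_id=1, s2=1.0)
    rates = predict_rates(params, diffusion, context)
    return rates.r2 / rates.r1


def _invert_r2r1(ratio: float, context: SpectrometerContext) -> float:
    """Numerically invert the rigid-body R2/R1 ratio for tm."""
    f = lambda tm: _rigid_r2_over_r1(tm, context) - ratio
    lo, hi = 0.2e-9, 50e-9
    if f(lo) > 0 and f(hi) > 0:
        return lo
    if f(lo) < 0 and f(hi) < 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-14))


def estimate_tm_r2r1(
    records: Sequence[ResidueRelaxationRecord],
    noe_min: float = 0.65,
    trim: float = 0.10,
) -> float:
    """Initial τm from the trimmed-mean R2/R1 ratio of rigid residues.

    Residues with NOE below ``noe_min`` (fast internal motion) are
    excluded; if none qualify the untrimmed full set is used with a
    warning.  Returns τm in seconds.
    """
    if not records:
        raise ValueError("need at least one record")
    qualifying = [r for r in records if r.noe > noe_min]
    if not qualifying:
        warnings.warn(
            f"no records with NOE > {noe_min}; falling back to the full set",
            stacklevel=2,
        )
        qualifying = list(records)
        trim = 0.0
    ratios = np.array([r.r2 / r.r1 for r in qualifying])
    ratio = float(stats.trim_mean(ratios, trim)) if len(ratios) > 1 else float(ratios[0])
    # all qualifying records must share a field for the inversion; use the first
    return _invert_r2r1(ratio, qualifying[0].context)


def _core_subset(records: Sequence[ResidueRelaxationRecord], noe_min: float = 0.65):
    """Rigid residues for τm optimisation: high NOE, no exchange flag.

    The exchange flag excludes residues whose R2/R1 sits more than 1.5
    standard deviations above the mean of the high-NOE subset.
    """
    high = [r for r in records if r.noe > noe_min]
    if len(high) < 5:
        return list(records)
    ratios = np.array([r.r2 / r.r1 for r in high])
    cut = ratios.mean() + 1.5 * ratios.std()
    return [r for r, ratio in zip(high, ratios) if ratio <= cut]


def _tm_objective(tm_s, core, sigma_floor, ftest_level=0.80):
    """Total chi2 at a trial τm with per-residue model re-selection.

    Core residues carry no exchange, so re-selection is between m1 and
    m2 by an F-test; the Monte-Carlo test is not needed inside the τm
    scan because only relative chi-square matters.
    """
    total = 0.0
    for rec in core:
        diffusion = DiffusionModel(kind="isotropic", tm_s=tm_s)
        f1 = fit_model(rec, 1, diffusion, sigma_floor=sigma_floor, starts=[np.array([0.85])])
        f2 = fit_model(
            rec, 2, diffusion, sigma_floor=sigma_floor,
            starts=[np.array([0.85, 2e-11]), np.array([0.85, 5e-10])],
        )
        use2 = _f_test_passes(f1.chi2, f2.chi2, 1, f2.dof, ftest_level)
        total += f2.chi2 if use2 else f1.chi2
    return total


def optimize_tm(
    records: Sequence[ResidueRelaxationRecord],
    diffusion_kind: str = "isotropic",
    context: Optional[SpectrometerContext] = None,
    sigma_floor: float = 0.005,
    grid_ns: tuple[float, float, float] = (1.0, 15.0, 0.1),
) -> DiffusionModel:
    """Overall rotational correlation time by total-chi2 minimisation.

    A coarse grid over τm (default 1-15 ns, 0.1 ns steps) restricted to
    the rigid core subset is followed by bounded scalar refinement
    around the best grid point.  Records from several fields are fitted
    jointly — τm is a property of the molecule, not of the field.
    """
    if len(records) < 5:
        raise ValueError("tau_m optimisation needs >= 5 records (underdetermined)")
    if diffusion_kind != "isotropic":
        raise NotImplementedError(
            "tau_m optimisation currently supports isotropic tumbling only"
        )
    core = _core_subset(records)
    start, stop, step = grid_ns
    t0 = estimate_tm_r2r1(records)
    # scan a window of the full grid around the R2/R1 seed; the rigid-body
    # seed is accurate to a few percent so +-1.5 ns covers the minimum
    lo = max(start, t0 * 1e9 - 1.5)
    hi = min(stop, t0 * 1e9 + 1.5)
    grid = np.arange(lo, hi + step / 2, step)
    objective = [_tm_objective(t * 1e-9, core, sigma_floor) for t in grid]
    best = grid[int(np.argmin(objective))]
    res = optimize.minimize_scalar(
        lambda t: _tm_objective(t * 1e-9, core, sigma_floor),
        bounds=(max(start, best - step), min(stop, best + step)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return DiffusionModel(kind="isotropic", tm_s=float(res.x) * 1e-9)
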