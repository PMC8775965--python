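"""MRI-to-PBPK covariate modelling.

The DCE-MRI parameters Ktrans and Vp are linked to the tumor PBPK parameters
through two covariate equations:

    Q_TU      = theta_Q * x                    (tumor plasma flow)
    sigma_V   = 1 / (1 + theta_sigma * x)      (vascular reflection coeff.)

where x is the subject's MRI parameter (Ktrans, Vp, or the additive linear
predictor theta_1*Ktrans + theta_2*Vp for the two-covariate structure).  The
reciprocal form keeps sigma_V in (0, 1] for any non-negative predictor.

Slopes are estimated on a non-binding-antibody cohort by maximum likelihood
under a proportional residual-error model (each subject contributes a single
terminal tumor concentration), and the fitted relationship is then used to
predict — a priori, with no refitting — the tumor kinetics of a
target-binding antibody in new subjects from their own MRI parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .pbpk import (
    PlasmaPKParams,
    SimResult,
    TumorPBPKParams,
    simulate,
    simulate_terminal_batch,
)

if TYPE_CHECKING:  # circular at runtime: synthetic imports covariate_arrays
    from .synthetic import MouseRecord

__all__ = [
    "STRUCTURES",
    "CovariateError",
    "CovariateModel",
    "FitSettings",
    "FitResult",
    "PredictionTable",
    "apply_covariates",
    "covariate_arrays",
    "fit_population",
    "predict_individual",
    "predict_cohort",
]

#: Candidate covariate structures, with the number of slopes per equation.
STRUCTURES = {"base": 0, "population": 0, "ktrans": 1, "vp": 1, "ktrans+vp": 2}


class CovariateError(ValueError):
    """Inadmissible covariate inputs (negative predictor, zero Q_TU, ...)."""


@dataclass(frozen=True)
class CovariateModel:
    """A covariate structure plus its slope values.

    ``theta_q`` (units L: flow per unit Ktrans in min^-1) and ``theta_sigma``
    (units min) hold one slope per covariate; for ``structure="population"``
    the fitted shared values live in ``population_q``/``population_sigma``
    instead, and for ``structure="base"`` the tabulated base parameters are
    used unchanged.
    """

    structure: str = "base"
    theta_q: tuple[float, ...] = ()
    theta_sigma: tuple[float, ...] = ()
    error_cv: float = 0.2
    population_q: float | None = None
    population_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        k = STRUCTURES[self.structure]
        if len(self.theta_q) != k or len(self.theta_sigma) != k:
            raise ValueError(
                f"structure {self.structure!r} needs {k} slope(s) per equation"
            )
        if any(t < 0 for t in self.theta_q + self.theta_sigma):
            raise ValueError("slopes must be non-negative")
        if self.error_cv < 0:
            raise ValueError("error_cv must be non-negative")

    @property
    def n_fitted(self) -> int:
        """Fitted fixed effects (excluding the residual-error parameter)."""
        if self.structure == "base":
            return 0
        if self.structure == "population":
            return 2
        return 2 * STRUCTURES[self.structure]


def _predictor(model: CovariateModel, theta: Sequence[float],
               ktrans: np.ndarray, vp: np.ndarray) -> np.ndarray:
    if model.structure == "ktrans":
        return theta[0] * ktrans
    if model.structure == "vp":
        return theta[0] * vp
    return theta[0] * ktrans + theta[1] * vp


def covariate_arrays(
    model: CovariateModel,
    ktrans: np.ndarray,
    vp: np.ndarray,
    base: TumorPBPKParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (Q_TU, sigma_v) for a cohort of MRI parameter values."""
    ktrans = np.atleast_1d(np.asarray(ktrans, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    if np.any(ktrans < 0) or np.any(vp < 0):
        raise CovariateError("MRI parameters must be non-negative")
    n = ktrans.size
    if model.structure == "base":
        return np.full(n, base.q_tu), np.full(n, base.sigma_v)
    if model.structure == "population":
        if model.population_q is None or model.population_sigma is None:
            raise CovariateError("population structure lacks fitted values")
        return np.full(n, model.population_q), np.full(n, model.population_sigma)
    lin_q = _predictor(model, model.theta_q, ktrans, vp)
    lin_s = _predictor(model, model.theta_sigma, ktrans, vp)
    if np.any(lin_q < 0) or np.any(lin_s < 0):
        raise CovariateError("negative linear predictor")
    if np.any(lin_q == 0):
        raise CovariateError(
            "zero Q_TU from a zero MRI predictor: subject unpredictable"
        )
    return lin_q, 1.0 / (1.0 + lin_s)


def apply_covariates(
    model: CovariateModel,
    ktrans: float,
    vp: float,
    base: TumorPBPKParams,
) -> TumorPBPKParams:
    """Individualise the tumor parameters for one subject's MRI values."""
    q, s = covariate_arrays(model, ktrans, vp, base)
    return replace(base, q_tu=float(q[0]), sigma_v=float(s[0]))


@dataclass(frozen=True)
class FitSettings:
    """Numerical controls of the population maximum-likelihood fit."""

    sim_rtol: float = 1e-6       # ODE tolerance inside the likelihood
    xatol: float = 1e-5          # simplex tolerance on transformed params
    fatol: float = 1e-9
    maxfev: int = 400
    n_grid: int = 5              # coarse-grid points per parameter for starts
    n_starts: int = 2            # simplex restarts from the best grid points
    grid_span: float = 30.0      # multiplicative span of the start grid
    seed: int = 0


@dataclass
class FitResult:
    """A fitted covariate model with its likelihood bookkeeping."""

    model: CovariateModel
    loglik: float
    n_params: int
    aic: float
    predictions: pd.DataFrame    # subject_id, group, terminal_time_h, observed, predicted
    converged: bool
    n_fev: int = 0

    def __post_init__(self) -> None:
        expected = -2.0 * self.loglik + 2.0 * self.n_params
        if np.isfinite(self.aic) and abs(self.aic - expected) > 1e-8:
            raise ValueError("aic inconsistent with loglik and n_params")


@dataclass
class PredictionTable:
    """Per-subject observed vs predicted concentrations plus summary MPE."""

    rows: pd.DataFrame
    mpe_percent: float
    signed_mpe_percent: float
    label: str = ""


def _neg2ll(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """Profiled -2 log-likelihood of the proportional (lognormal) error model.

    obs_i ~ LogNormal(log pred_i, s^2), matching the multiplicative error the
    observations carry; the residual scale is profiled out analytically,
    s_hat^2 = mean(log(obs/pred)^2).  Returned scale is s_hat (the geometric
    CV, ~ the proportional CV for small noise).
    """
    n = obs.size
    r = np.log(obs / pred)
    s2 = max(float(np.mean(r * r)), 1e-24)  # zero-noise cohorts: keep finite
    n2ll = (n * np.log(2.0 * np.pi) + n * np.log(s2)
            + 2.0 * float(np.sum(np.log(obs))) + n)
    return n2ll, float(np.sqrt(s2))


def _cohort_vectors(cohort: Sequence["MouseRecord"]):
    kt = np.array([r.ktrans for r in cohort])
    vp = np.array([r.vp for r in cohort])
    tt = np.array([r.terminal_time_h for r in cohort]) * 60.0
    obs = np.array([r.observed_tumor_conc for r in cohort])
    return kt, vp, tt, obs


def _predict_terminal(model, kt, vp, tt_min, base, plasma, rtol, c_egfr=None):
    q, s = covariate_arrays(model, kt, vp, base)
    if np.any(q <= 1.05 * base.l_tu):
        # plasma flow below lymph flow makes the vascular balance unstable
        raise CovariateError("Q_TU not safely above lymph flow")
    ce = np.zeros_like(q) if c_egfr is None else np.asarray(c_egfr, dtype=float)
    return simulate_terminal_batch(q, s, ce, tt_min, base, plasma, rtol=rtol)


def fit_population(
    cohort: Sequence["MouseRecord"],
    structure: str,
    base: TumorPBPKParams,
    plasma: PlasmaPKParams,
    settings: FitSettings | None = None,
) -> FitResult:
    """Maximum-likelihood fit of a covariate structure on a non-binding cohort.

    Every subject must carry Patlak parameters (for covariate structures) and
    one terminal tumor observation; target binding must be off (the antibody
    does not recognise any antigen in these tumors).  For
    ``structure="population"`` the shared (Q_TU, sigma_v) pair is estimated
    directly; ``structure="base"`` evaluates the likelihood of the tabulated
    parameters once, with only the residual CV estimated.

    Optimisation is Nelder-Mead on log (and logit, for sigma_v) transformed
    parameters, started from the best points of a deterministic coarse grid;
    AIC = -2 loglik + 2 (fitted fixed effects + 1 error parameter).
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    if not cohort:
        raise ValueError("empty cohort")
    if any(r.antibody != "non-binding" for r in cohort):
        raise ValueError("population fit requires the non-binding-antibody arm")
    settings = settings or FitSettings()
    kt, vp, tt, obs = _cohort_vectors(cohort)
    if np.any(obs <= 0):
        raise ValueError("non-positive observed tumor concentration")
    if structure == "vp" and np.all(vp == 0):
        raise ValueError("vp structure with all-zero Vp values")

    def result_for(model: CovariateModel, converged: bool, nfev: int) -> FitResult:
        pred = _predict_terminal(model, kt, vp, tt, base, plasma, settings.sim_rtol)
        n2ll, cv = _neg2ll(obs, pred)
        model = replace(model, error_cv=cv)
        n_params = model.n_fitted + 1
        rows = pd.DataFrame({
            "subject_id": [r.subject_id for r in cohort],
            "group": [r.group for r in cohort],
            "terminal_time_h": tt / 60.0,
            "observed": obs,
            "predicted": pred,
        })
        return FitResult(
            model=model, loglik=-0.5 * n2ll, n_params=n_params,
            aic=n2ll + 2.0 * n_params, predictions=rows,
            converged=converged, n_fev=nfev,
        )

    if structure == "base":
        return result_for(CovariateModel(structure="base"), True, 0)

    # --- transformed-parameter objective -------------------------------
    k = STRUCTURES[structure]

    def unpack(z: np.ndarray) -> CovariateModel:
        if structure == "population":
            q = float(np.exp(z[0]))
            s = float(1.0 / (1.0 + np.exp(-z[1])))   # logit^-1
            return CovariateModel(structure="population",
                                  population_q=q, population_sigma=s)
        return CovariateModel(
            structure=structure,
            theta_q=tuple(np.exp(z[:k])),
            theta_sigma=tuple(np.exp(z[k:])),
        )

    def objective(z: np.ndarray) -> float:
        if np.any(np.abs(z) > 50):
            return 1e12
        try:
            pred = _predict_terminal(unpack(z), kt, vp, tt, base, plasma,
                                     settings.sim_rtol)
        except (CovariateError, RuntimeError):
            return 1e12
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            return 1e12
        return _neg2ll(obs, pred)[0]

    # deterministic start grid centred on scale-matching heuristics
    if structure == "population":
        centre = np.array([np.log(base.q_tu),
                           np.log(base.sigma_v / (1.0 - base.sigma_v))])
    else:
        x = kt if structure == "ktrans" else vp if structure == "vp" else None
        if structure == "ktrans+vp":
            xbar = np.array([np.mean(kt), np.mean(np.maximum(vp, 1e-4))])
            centre = np.log(np.concatenate([base.q_tu / (2.0 * xbar),
                                            (1.0 / base.sigma_v - 1.0) / (2.0 * xbar)]))
        else:
            xbar = float(np.mean(x))
            centre = np.log(np.array([base.q_tu / xbar,
                                      (1.0 / base.sigma_v - 1.0) / xbar]))
    span = np.log(settings.grid_span)
    offsets = np.linspace(-span, span, settings.n_grid)
    grid = [centre + np.array(off)
            for off in np.stack(np.meshgrid(*[offsets] * centre.size),
                                axis=-1).reshape(-1, centre.size)]
    scores = [objective(z) for z in grid]
    order = np.argsort(scores)

    best = None
    nfev = len(grid)
    for idx in order[: settings.n_starts]:
        res = minimize(
            objective, grid[idx], method="Nelder-Mead",
            options={"xatol": settings.xatol, "fatol": settings.fatol,
                     "maxfev": settings.maxfev, "adaptive": True},
        )
        nfev += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"population fit failed to converge for {structure!r}")
    return result_for(unpack(best.x), bool(best.fun < 1e12), nfev)


def predict_individual(
    fit: FitResult | CovariateModel,
    subject: "MouseRecord",
    base: TumorPBPKParams,
    plasma: PlasmaPKParams,
    t_grid: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
) -> SimResult:
    """A priori tumor concentration-time prediction for one subject.

    The covariate relationship fitted on the non-binding antibody supplies
    (Q_TU, sigma_v) from the subject's own MRI parameters; target binding is
    controlled by ``base.c_egfr`` (set it to the group's receptor
    concentration for a binding antibody).  No refitting to the subject's
    observation takes place.
    """
    model = fit.model if isinstance(fit, FitResult) else fit
    params = apply_covariates(model, subject.ktrans, subject.vp, base)
    if t_grid is None:
        t_grid = np.linspace(0.0, subject.terminal_time_h * 60.0, 200)
    return simulate(params, plasma, t_grid, rtol=rtol)


def predict_cohort(
    fit: FitResult | CovariateModel,
    cohort: Sequence["MouseRecord"],
    base: TumorPBPKParams,
    plasma: PlasmaPKParams,
    *,
    egfr_by_group: dict[str, float] | None = None,
    rtol: float = 1e-8,
    label: str = "",
) -> PredictionTable:
    """Terminal-time predictions for a cohort, with MPE summaries.

    ``egfr_by_group`` switches on target binding per tumor group (omit or use
    zeros for a non-binding antibody).
    """
    from .evaluation import mean_prediction_error, signed_mean_prediction_error

    model = fit.model if isinstance(fit, FitResult) else fit
    kt, vp, tt, obs = _cohort_vectors(cohort)
    ce = np.array([(egfr_by_group or {}).get(r.group, 0.0) for r in cohort])
    pred = _predict_terminal(model, kt, vp, tt, base, plasma, rtol, c_egfr=ce)
    rows = pd.DataFrame({
        "subject_id": [r.subject_id for r in cohort],
        "group": [r.group for r in cohort],
        "terminal_time_h": tt / 60.0,
        "observed": obs,
        "predicted": pred,
    })
    return PredictionTable(
        rows=rows,
        mpe_percent=mean_prediction_error(rows),
        signed_mpe_percent=signed_mean_prediction_error(rows),
        label=label or model.structure,
    )
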