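"""Tumor PBPK model for monoclonal antibodies.

The tumor is represented by three sub-compartments — vascular, endothelial
(endosomal) and interstitial — exchanging with systemic plasma, plus a cellular
layer carrying the target antigen (EGFR).  Transport processes:

* plasma flow ``q_tu`` perfuses the vascular space; lymph flow ``l_tu`` leaves
  through the interstitium, so vascular outflow back to plasma is
  ``(q_tu - l_tu)``;
* convective extravasation ``(1 - sigma_v) * l_tu`` carries antibody from the
  vascular to the interstitial space; lymphatic drainage
  ``(1 - sigma_l) * l_tu`` removes free interstitial antibody;
* fluid-phase endosomal uptake ``clup_tu`` samples both the vascular and the
  free interstitial concentration; inside the endosome the antibody binds FcRn
  at quasi-equilibrium (``kd_fcrn``, ``c_fcrn``); FcRn-bound antibody is
  recycled at ``clup_tu * fr`` to the vascular space and ``clup_tu * (1 - fr)``
  to the interstitium, while unbound endosomal antibody is catabolised with
  clearance ``cl_tu``;
* free interstitial antibody binds the target at quasi-equilibrium
  (``kd_egfr``, ``c_egfr``); the complex is internalised and degraded with
  ``cl_tmd = kint * vi_tu`` (equivalently: first-order loss of the bound
  amount at rate ``kint``);
* all sub-compartment volumes grow exponentially at ``kgrowth``, which dilutes
  concentrations.

State variables are amounts (mol); concentrations are amount / current volume,
so growth dilution needs no explicit term.  Plasma is an external forcing
function by default; a closed two-region configuration (used for mass-balance
checks) promotes plasma to a state and returns lymph drainage to it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "TumorPBPKParams",
    "PlasmaPKParams",
    "ClosedSystem",
    "SimResult",
    "EGFR_CONC",
    "bound_quasi_equilibrium",
    "egfr_bound",
    "plasma_forcing",
    "simulate",
    "simulate_terminal_batch",
    "tumor_to_plasma_ratio",
    "ode_equations_text",
]

#: Literature EGFR tumor concentrations (M) per xenograft cell line.
EGFR_CONC = {
    "LS174T": 3.53e-8,
    "LS174T+sorafenib": 3.53e-8,
    "NCI-N87": 1.14e-7,
    "Panc-1": 9.24e-8,
}


@dataclass(frozen=True)
class TumorPBPKParams:
    """Tumor-compartment parameters (base values for a ~0.16 mL xenograft).

    Flows and clearances are in L/min, volumes in L, concentrations molar,
    rate constants min^-1; ``sigma_v``, ``sigma_l`` and ``fr`` are
    dimensionless fractions in [0, 1].
    """

    q_tu: float = 1e-4          # tumor plasma flow
    l_tu: float = 4e-6          # tumor lymph flow
    clup_tu: float = 8.18e-9    # endosomal (pinocytotic) uptake clearance
    sigma_v: float = 0.734      # vascular reflection coefficient
    sigma_l: float = 0.2        # lymph reflection coefficient
    cl_tu: float = 8.96e-9      # catabolic clearance of unbound endosomal mAb
    kd_fcrn: float = 7.5e-7     # FcRn-mAb dissociation constant (M)
    c_fcrn: float = 1.64e-5     # endosomal FcRn concentration (M)
    fr: float = 0.715           # fraction of FcRn-bound mAb recycled to plasma
    kgrowth: float = 8.08e-5    # exponential tumor growth rate
    vi_tu: float = 1.38e-4      # initial interstitial volume
    ve_tu: float = 1.25e-6      # initial endothelial (endosomal) volume
    vv_tu: float = 1.75e-5      # initial vascular volume
    kd_egfr: float = 1.5e-10    # mAb-EGFR dissociation constant (M)
    kint: float = 1.38e-3       # EGFR internalisation rate
    c_egfr: float = 0.0         # total EGFR concentration (0 = non-binder)

    @property
    def cl_tmd(self) -> float:
        """Target-mediated clearance, ``kint * vi_tu`` (L/min)."""
        return self.kint * self.vi_tu

    def with_egfr(self, group: str) -> "TumorPBPKParams":
        """Return a copy with the cell-line EGFR concentration switched on."""
        return replace(self, c_egfr=EGFR_CONC[group])

    def __post_init__(self) -> None:
        for name in ("sigma_v", "sigma_l", "fr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "q_tu", "l_tu", "clup_tu", "cl_tu", "kd_fcrn", "c_fcrn",
            "kgrowth", "vi_tu", "ve_tu", "vv_tu", "kd_egfr", "kint", "c_egfr",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PlasmaPKParams:
    """Systemic disposition driving the tumor.

    The plasma concentration is a dose-normalised biexponential

        Cp(t) = D_mol * (A exp(-alpha t) + B exp(-beta t)),

    with ``A``, ``B`` in L^-1 (so the implied central volume is
    ``1 / (A + B)``), or an arbitrary tabulated curve (``curve_times_min``,
    ``curve_conc_m``) which overrides the biexponential.
    """

    dose_mg_per_kg: float = 1.0
    bodyweight_kg: float = 0.025
    molecular_weight: float = 1.5e5      # g/mol, IgG
    coef_a: float = 333.3                # L^-1
    rate_alpha: float = np.log(2) / 600.0    # min^-1, ~10 h distribution
    coef_b: float = 500.0                # L^-1
    rate_beta: float = np.log(2) / 8640.0    # min^-1, ~6 d terminal
    curve_times_min: tuple[float, ...] | None = None
    curve_conc_m: tuple[float, ...] | None = None

    @property
    def dose_mol(self) -> float:
        return self.dose_mg_per_kg * self.bodyweight_kg * 1e-3 / self.molecular_weight

    @property
    def central_volume_l(self) -> float:
        ab = self.coef_a + self.coef_b
        if ab <= 0:
            raise ValueError("A + B must be positive to imply a central volume")
        return 1.0 / ab

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg < 0:
            raise ValueError("dose must be non-negative")
        if self.rate_alpha <= 0 or self.rate_beta <= 0:
            raise ValueError("disposition rates must be positive")
        if (self.curve_times_min is None) != (self.curve_conc_m is None):
            raise ValueError("tabulated curve needs both times and concentrations")
        if self.curve_conc_m is not None and np.any(np.asarray(self.curve_conc_m) < 0):
            raise ValueError("tabulated plasma curve must be non-negative")


@dataclass(frozen=True)
class ClosedSystem:
    """Closed two-region configuration: plasma becomes a state variable.

    Lymph drainage and vascular outflow return to plasma, so with catabolism
    and target binding switched off total antibody amount is conserved.
    """

    plasma_volume_l: float = 1.2e-3


@dataclass
class SimResult:
    """Trajectories from :func:`simulate` (times min, concentrations M, amounts mol)."""

    times: np.ndarray
    plasma_conc: np.ndarray
    tumor_total_conc: np.ndarray
    vascular_amount: np.ndarray
    endothelial_free_amount: np.ndarray
    endothelial_bound_amount: np.ndarray
    interstitial_free_amount: np.ndarray
    egfr_bound_amount: np.ndarray
    tumor_volume: np.ndarray
    plasma_amount: np.ndarray | None = None

    def total_tumor_amount(self) -> np.ndarray:
        return (
            self.vascular_amount
            + self.endothelial_free_amount
            + self.endothelial_bound_amount
            + self.interstitial_free_amount
            + self.egfr_bound_amount
        )


def bound_quasi_equilibrium(c_total, r_total, kd):
    """Quasi-equilibrium bound concentration from the binding mass balance.

    For ligand total ``c_total``, receptor total ``r_total`` and dissociation
    constant ``kd`` the bound concentration is the smaller root of

        B^2 - B (C_T + R_T + K_D) + C_T R_T = 0,

    evaluated in the numerically stable form ``2 C_T R_T / (b + sqrt(b^2 - 4
    C_T R_T))``.  ``kd = 0`` yields the stoichiometric limit
    ``min(C_T, R_T)``.  Broadcasts over array inputs.
    """
    c_total = np.asarray(c_total, dtype=float)
    r_total = np.asarray(r_total, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(c_total < 0) or np.any(r_total < 0) or np.any(kd < 0):
        raise ValueError("binding inputs must be non-negative")
    b = c_total + r_total + kd
    disc = b * b - 4.0 * c_total * r_total
    disc = np.maximum(disc, 0.0)
    denom = b + np.sqrt(disc)
    with np.errstate(invalid="ignore"):
        bound = np.where(denom > 0.0, 2.0 * c_total * r_total / np.where(denom > 0, denom, 1.0), 0.0)
    return bound if bound.ndim else float(bound)


def egfr_bound(c_total_interstitial, r_total, kd):
    """EGFR-bound antibody concentration at quasi-equilibrium (alias of the
    generic binding quadratic; see :func:`bound_quasi_equilibrium`)."""
    return bound_quasi_equilibrium(c_total_interstitial, r_total, kd)


def plasma_forcing(params: PlasmaPKParams, t):
    """Molar plasma concentration at time ``t`` (min; scalar or array)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if params.curve_times_min is not None:
        cp = np.interp(t, params.curve_times_min, params.curve_conc_m)
    else:
        cp = params.dose_mol * (
            params.coef_a * np.exp(-params.rate_alpha * t)
            + params.coef_b * np.exp(-params.rate_beta * t)
        )
    return cp if cp.ndim else float(cp)


@njit(cache=True)
def _qe_bound(ct: float, rt: float, kd: float) -> float:
    """Scalar quasi-equilibrium bound concentration (stable quadratic root)."""
    b = ct + rt + kd
    if b <= 0.0:
        return 0.0
    disc = b * b - 4.0 * ct * rt
    if disc < 0.0:
        disc = 0.0
    return 2.0 * ct * rt / (b + np.sqrt(disc))


@njit(cache=True)
def _rhs_batch(t, y, q, sv, ce_tot, l, clup, sl, cl, kd_f, r_f, fr,
               kd_e, kint, g, vv0, ve0, vi0,
               cp_amp_a, rate_a, cp_amp_b, rate_b,
               curve_t, curve_c, closed_vp):
    """Batch RHS: m tumors with 3 amount states each; shared parameters
    except (q, sv, ce_tot).  Plasma is the biexponential ``cp_amp_a *
    exp(-rate_a t) + cp_amp_b exp(-rate_b t)``, a tabulated curve when
    ``curve_t`` is non-empty, or — when ``closed_vp > 0`` (m must be 1) — an
    extra state appended at index 3 with volume ``closed_vp``."""
    m = q.size
    growth = np.exp(g * t)
    closed = closed_vp > 0.0
    if closed:
        cp = y[3 * m] / closed_vp
    elif curve_t.size > 0:
        cp = np.interp(t, curve_t, curve_c)
    else:
        cp = cp_amp_a * np.exp(-rate_a * t) + cp_amp_b * np.exp(-rate_b * t)
    out = np.empty(y.size)
    lymph_to_plasma = 0.0
    for i in range(m):
        cv = y[3 * i] / (vv0 * growth)
        ce = y[3 * i + 1] / (ve0 * growth)
        ci = y[3 * i + 2] / (vi0 * growth)
        if ce < 0.0:
            ce = 0.0
        if ci < 0.0:
            ci = 0.0
        # quasi-equilibrium partitioning in endosome and interstitium
        cb_f = _qe_bound(ce, r_f, kd_f)
        cf_f = ce - cb_f
        cb_e = _qe_bound(ci, ce_tot[i], kd_e)
        cf_i = ci - cb_e
        qi = q[i]
        svi = sv[i]
        out[3 * i] = (qi * cp - (qi - l) * cv - (1.0 - svi) * l * cv
                      - clup * cv + clup * fr * cb_f)
        out[3 * i + 1] = clup * (cv + cf_i) - clup * cb_f - cl * cf_f
        out[3 * i + 2] = ((1.0 - svi) * l * cv + clup * (1.0 - fr) * cb_f
                          - (1.0 - sl) * l * cf_i - clup * cf_i
                          - kint * (vi0 * growth) * cb_e)
        lymph_to_plasma += -qi * cp + (qi - l) * cv + (1.0 - sl) * l * cf_i
    if closed:
        out[3 * m] = lymph_to_plasma
    return out


_EMPTY = np.empty(0)


def _rhs_args(
    q: np.ndarray,
    sv: np.ndarray,
    c_egfr: np.ndarray,
    p: TumorPBPKParams,
    plasma: "PlasmaPKParams | None",
    closed_vp: float,
) -> tuple:
    """Assemble the argument tuple for :func:`_rhs_batch`."""
    if plasma is not None and plasma.curve_times_min is not None:
        curve_t = np.asarray(plasma.curve_times_min, dtype=float)
        curve_c = np.asarray(plasma.curve_conc_m, dtype=float)
        amp_a = rate_a = amp_b = rate_b = 0.0
        rate_a = rate_b = 1.0
    elif plasma is not None:
        curve_t = curve_c = _EMPTY
        amp_a = plasma.dose_mol * plasma.coef_a
        amp_b = plasma.dose_mol * plasma.coef_b
        rate_a, rate_b = plasma.rate_alpha, plasma.rate_beta
    else:
        curve_t = curve_c = _EMPTY
        amp_a = amp_b = 0.0
        rate_a = rate_b = 1.0
    return (
        q, sv, c_egfr, p.l_tu, p.clup_tu, p.sigma_l, p.cl_tu, p.kd_fcrn,
        p.c_fcrn, p.fr, p.kd_egfr, p.kint, p.kgrowth, p.vv_tu, p.ve_tu,
        p.vi_tu, amp_a, rate_a, amp_b, rate_b, curve_t, curve_c, closed_vp,
    )


def _integrate(args, y0, t_grid, rtol, atol, band):
    """LSODA with a banded Jacobian matching the block-diagonal structure."""
    sol = solve_ivp(
        _rhs_batch,
        (float(t_grid[0]), float(t_grid[-1])),
        y0,
        method="LSODA",
        t_eval=np.asarray(t_grid, dtype=float),
        rtol=rtol,
        atol=atol,
        lband=band,
        uband=band,
        args=args,
    )
    if not sol.success:
        raise RuntimeError(f"tumor ODE integration failed: {sol.message}")
    return sol


def _check_negative(y: np.ndarray, scale: float) -> np.ndarray:
    floor = -1e-3 * scale
    if np.any(y < floor):
        raise RuntimeError(
            f"integration produced negative amounts below tolerance (min {y.min():.3e})"
        )
    return np.maximum(y, 0.0)


def simulate(
    tumor: TumorPBPKParams,
    plasma: PlasmaPKParams,
    t_grid: Sequence[float],
    *,
    closed: ClosedSystem | None = None,
    rtol: float = 1e-8,
    atol_scale: float = 1e-12,
) -> SimResult:
    """Simulate antibody tumor disposition on ``t_grid`` (minutes from dosing).

    By default plasma is the forcing function :func:`plasma_forcing`; with
    ``closed`` a finite plasma pool is integrated alongside the tumor (used
    for mass-balance verification).  ``atol_scale`` multiplies the dose to
    set the absolute tolerance.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing with at least 2 points")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at dose time 0")

    dose = plasma.dose_mol
    q = np.array([tumor.q_tu])
    sv = np.array([tumor.sigma_v])
    ce = np.array([tumor.c_egfr])
    if closed is None:
        y0 = np.zeros(3)
        args = _rhs_args(q, sv, ce, tumor, plasma, 0.0)
        band = 2
    else:
        y0 = np.array([0.0, 0.0, 0.0, dose])
        args = _rhs_args(q, sv, ce, tumor, None, closed.plasma_volume_l)
        band = 3

    atol = atol_scale * max(dose, 1e-30)
    if dose == 0.0:
        sol_y = np.zeros((y0.size, t_grid.size))
    else:
        sol_y = _integrate(args, y0, t_grid, rtol, atol, band).y
    y = _check_negative(sol_y, max(dose, 1e-30))

    growth = np.exp(tumor.kgrowth * t_grid)
    av, ae, ai = y[0], y[1], y[2]
    ve_t = tumor.ve_tu * growth
    vi_t = tumor.vi_tu * growth
    ce_tot = ae / ve_t
    ci_tot = ai / vi_t
    cb_f = bound_quasi_equilibrium(ce_tot, tumor.c_fcrn, tumor.kd_fcrn)
    cb_e = bound_quasi_equilibrium(ci_tot, tumor.c_egfr, tumor.kd_egfr)
    v_tot = (tumor.vv_tu + tumor.ve_tu + tumor.vi_tu) * growth
    if closed is None:
        cp = plasma_forcing(plasma, t_grid)
        ap = None
    else:
        ap = y[3]
        cp = ap / closed.plasma_volume_l
    return SimResult(
        times=t_grid,
        plasma_conc=np.asarray(cp, dtype=float),
        tumor_total_conc=(av + ae + ai) / v_tot,
        vascular_amount=av,
        endothelial_free_amount=(ce_tot - cb_f) * ve_t,
        endothelial_bound_amount=cb_f * ve_t,
        interstitial_free_amount=(ci_tot - cb_e) * vi_t,
        egfr_bound_amount=cb_e * vi_t,
        tumor_volume=v_tot,
        plasma_amount=ap,
    )


def simulate_terminal_batch(
    q_tu: np.ndarray,
    sigma_v: np.ndarray,
    c_egfr: np.ndarray,
    terminal_times_min: np.ndarray,
    base: TumorPBPKParams,
    plasma: PlasmaPKParams,
    *,
    rtol: float = 1e-8,
    atol_scale: float = 1e-12,
) -> np.ndarray:
    """Total tumor concentration at each subject's terminal time.

    Integrates a batch of m subjects (sharing all parameters except ``q_tu``,
    ``sigma_v`` and ``c_egfr``) as one block-diagonal ODE system — the
    workhorse of the population likelihood, where the model must be evaluated
    for every subject at every candidate slope vector.
    """
    q_tu = np.atleast_1d(np.asarray(q_tu, dtype=float))
    sigma_v = np.atleast_1d(np.asarray(sigma_v, dtype=float))
    c_egfr = np.broadcast_to(np.asarray(c_egfr, dtype=float), q_tu.shape).copy()
    tt = np.atleast_1d(np.asarray(terminal_times_min, dtype=float))
    m = q_tu.size
    if not (sigma_v.size == m == tt.size):
        raise ValueError("q_tu, sigma_v and terminal_times_min must have equal length")

    uniq = np.unique(tt)
    t_grid = np.concatenate([[0.0], uniq])
    dose = plasma.dose_mol
    if dose == 0.0:
        return np.zeros(m)
    args = _rhs_args(q_tu, sigma_v, c_egfr, base, plasma, 0.0)
    sol = _integrate(args, np.zeros(3 * m), t_grid, rtol, atol_scale * dose, 2)
    y = _check_negative(sol.y, dose)

    idx = np.searchsorted(uniq, tt) + 1  # column in t_grid
    growth = np.exp(base.kgrowth * tt)
    v_tot = (base.vv_tu + base.ve_tu + base.vi_tu) * growth
    rows = np.arange(m)
    total = (y[0::3][rows, idx] + y[1::3][rows, idx] + y[2::3][rows, idx])
    return total / v_tot


def tumor_to_plasma_ratio(sim: SimResult, t: float) -> float:
    """Tumor/plasma concentration ratio at time ``t`` (linear interpolation)."""
    if not (sim.times[0] <= t <= sim.times[-1]):
        raise ValueError("t outside simulated range")
    cp = float(np.interp(t, sim.times, sim.plasma_conc))
    if cp <= 0:
        raise ZeroDivisionError("plasma concentration is zero at t")
    ct = float(np.interp(t, sim.times, sim.tumor_total_conc))
    return ct / cp


def ode_equations_text(params: TumorPBPKParams | None = None) -> str:
    """Symbolic text of the integrated ODE system, for audit."""
    return (
        "Tumor PBPK sub-compartment system (amounts A in mol; V_x(t) = V_x0*exp(kgrowth*t);\n"
        "concentrations C_x = A_x / V_x(t)).\n"
        "\n"
        "FcRn quasi-equilibrium (endothelial):  Cb_FcRn = pos. root of\n"
        "  B^2 - B*(C_E + C_FcRn + KD_FcRn) + C_E*C_FcRn = 0;  Cf_FcRn = C_E - Cb_FcRn\n"
        "EGFR quasi-equilibrium (interstitial): Cb_EGFR = pos. root of\n"
        "  B^2 - B*(C_I + C_EGFR + KD_EGFR) + C_I*C_EGFR = 0;  Cf_I = C_I - Cb_EGFR\n"
        "\n"
        "dA_V/dt = Q_TU*Cp(t) - (Q_TU - L_TU)*C_V - (1 - sigma_V)*L_TU*C_V\n"
        "          - Clup_TU*C_V + Clup_TU*FR*Cb_FcRn\n"
        "dA_E/dt = Clup_TU*(C_V + Cf_I) - Clup_TU*Cb_FcRn - Cl_TU*Cf_FcRn\n"
        "dA_I/dt = (1 - sigma_V)*L_TU*C_V + Clup_TU*(1 - FR)*Cb_FcRn\n"
        "          - (1 - sigma_L)*L_TU*Cf_I - Clup_TU*Cf_I - Kint*V_I(t)*Cb_EGFR\n"
        "\n"
        "closed configuration adds:\n"
        "dA_P/dt = -Q_TU*Cp + (Q_TU - L_TU)*C_V + (1 - sigma_L)*L_TU*Cf_I,  Cp = A_P/V_P\n"
        "\n"
        "Total tumor concentration = (A_V + A_E + A_I) / (V_V + V_E + V_I)(t).\n"
    )
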