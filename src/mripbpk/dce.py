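"""DCE-MRI kinetic analysis: T1 mapping, signal-to-concentration conversion
and Patlak model fitting with per-subject arterial input functions.

The Patlak model assumes no reflux of contrast agent from the interstitium
back to plasma over the acquisition window, so the tissue concentration is

    Ct(t) = Ktrans * integral_0^t Cp(tau) dtau + Vp * Cp(t),

linear in (Ktrans, Vp).  The fit is therefore a constrained linear
least-squares problem solved exactly — no iterative initialisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit, lsq_linear

__all__ = [
    "AcquisitionProtocol",
    "AIFCurve",
    "TumorConcCurve",
    "PrecontrastT1",
    "PatlakFit",
    "fit_t10",
    "spgr_signal",
    "signal_to_concentration",
    "patlak_integral",
    "patlak_forward",
    "patlak_fit",
]

DEFAULT_SR_TIMES_MS = (200.0, 400.0, 800.0, 1500.0, 3000.0, 5000.0)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """DCE acquisition settings.

    Frame timestamps are end-of-frame: frame k (1-based) is stamped at
    ``k * frame_interval_s``, so the default 70-frame protocol spans
    ~19.8 min with contrast injection 2 min after scan start.
    ``r1_relaxivity`` is the contrast agent longitudinal relaxivity in
    L mmol^-1 s^-1 (gadobutrol at high field ~= 3.3; an assumed default,
    to be configured per agent and field strength).
    """

    frame_interval_s: float = 17.0
    n_frames: int = 70
    injection_time_min: float = 2.0
    tr_ms: float = 10.0
    flip_angle_deg: float = 20.0
    r1_relaxivity: float = 3.3
    sr_recovery_times_ms: tuple[float, ...] = DEFAULT_SR_TIMES_MS

    def __post_init__(self) -> None:
        if min(self.frame_interval_s, self.injection_time_min, self.tr_ms,
               self.flip_angle_deg, self.r1_relaxivity) <= 0:
            raise ValueError("protocol fields must be positive")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")
        if self.injection_time_min >= self.total_duration_min:
            raise ValueError("injection must occur within the scan")
        if not 0.0 < self.flip_angle_deg < 90.0:
            raise ValueError("flip angle must be in (0, 90) degrees")

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(1, self.n_frames + 1) * self.frame_interval_s / 60.0

    @property
    def total_duration_min(self) -> float:
        return self.n_frames * self.frame_interval_s / 60.0

    @property
    def n_baseline_frames(self) -> int:
        """Frames acquired entirely before contrast injection."""
        return int(np.sum(self.frame_times_min < self.injection_time_min))


@dataclass
class AIFCurve:
    """Arterial plasma contrast concentration (mM) vs time (min)."""

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.size < 3:
            raise ValueError("AIF needs at least 3 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("AIF times must be strictly increasing")
        if np.any(self.cp < 0):
            raise ValueError("AIF concentrations must be non-negative")


@dataclass
class TumorConcCurve:
    """Tumor contrast concentration (mM) vs time (min).

    ``valid`` marks frames whose signal could be inverted; invalid frames are
    excluded from kinetic fitting.
    """

    times: np.ndarray
    ct: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class PrecontrastT1:
    """Saturation-recovery T1 fit: ``S(TR) = M0 * (1 - exp(-TR / T1))``."""

    t10_ms: float
    m0: float
    rss: float
    converged: bool = True


@dataclass
class PatlakFit:
    ktrans: float          # min^-1
    vp: float              # dimensionless, in [0, 1]
    rss: float
    n_points: int
    converged: bool = True


def fit_t10(recovery_times_ms, signals) -> PrecontrastT1:
    """Fit the saturation-recovery relaxation curve for pre-contrast T1.

    Least-squares fit of ``S = M0 * (1 - exp(-TR/T1))`` over the variable
    repetition times.  Degenerate data (already-saturated signals, or
    non-monotone data pushing T1 beyond any sampled recovery time) are
    flagged ``converged=False`` rather than silently clipped.
    """
    tr = np.asarray(recovery_times_ms, dtype=float)
    s = np.asarray(signals, dtype=float)
    if np.unique(tr).size < 3:
        raise ValueError("need at least 3 distinct recovery times")
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")

    def model(t, m0, t1):
        return m0 * (1.0 - np.exp(-t / t1))

    p0 = (float(s.max()) if s.max() > 0 else 1.0, float(np.median(tr)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model, tr, s, p0=p0,
                bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=10000,
            )
    except RuntimeError:
        return PrecontrastT1(t10_ms=float("nan"), m0=float("nan"),
                             rss=float("inf"), converged=False)
    m0, t1 = popt
    rss = float(np.sum((s - model(tr, *popt)) ** 2))
    ok = np.all(np.isfinite(pcov)) and t1 < 50.0 * tr.max()
    if not ok:
        warnings.warn("T1 fit poorly determined (unbounded or degenerate data)",
                      stacklevel=2)
    if t1 <= 2.0 * tr.min() and np.ptp(s) < 1e-3 * max(s.max(), 1e-30):
        # constant (already saturated) signals: T1 hits the small-T1 limit
        warnings.warn("signals saturated at all recovery times; T1 has large "
                      "uncertainty", stacklevel=2)
    return PrecontrastT1(t10_ms=float(t1), m0=float(m0), rss=rss,
                         converged=bool(ok))


def spgr_signal(c_mM, t10_ms, m0, protocol: AcquisitionProtocol):
    """Spoiled gradient-echo steady-state signal for contrast conc ``c_mM``.

    ``S = M0 sin(a) (1 - E1) / (1 - E1 cos(a))`` with
    ``E1 = exp(-TR * R1)`` and ``R1 = 1/T10 + r1 * C`` (linear relaxivity;
    r1 converted from s^-1 mM^-1 to ms^-1 mM^-1).
    """
    c = np.asarray(c_mM, dtype=float)
    alpha = np.deg2rad(protocol.flip_angle_deg)
    r1_ms = protocol.r1_relaxivity / 1000.0
    r1 = 1.0 / t10_ms + r1_ms * c
    e1 = np.exp(-protocol.tr_ms * r1)
    return m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def signal_to_concentration(
    times_min,
    signal,
    t10: PrecontrastT1,
    protocol: AcquisitionProtocol,
    baseline_frames: int | None = None,
) -> TumorConcCurve:
    """Invert the SPGR signal equation frame-by-frame for contrast conc.

    ``M0`` is calibrated from the mean pre-injection baseline signal together
    with ``R10 = 1/T10``; each frame's signal is then inverted for ``E1`` and
    ``C(t) = (R1(t) - R10) / r1``.  Frames whose signal implies ``E1``
    outside (0, 1) (non-invertible, e.g. beyond the signal ceiling) are
    flagged invalid and excluded from fitting.
    """
    times = np.asarray(times_min, dtype=float)
    s = np.asarray(signal, dtype=float)
    if baseline_frames is None:
        baseline_frames = int(np.sum(times < protocol.injection_time_min))
    if baseline_frames < 1:
        raise ValueError("need at least one pre-injection baseline frame")
    s_base = float(np.mean(s[:baseline_frames]))
    if s_base <= 0:
        raise ValueError("zero baseline signal; cannot calibrate M0")

    alpha = np.deg2rad(protocol.flip_angle_deg)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    r10 = 1.0 / t10.t10_ms
    e10 = np.exp(-protocol.tr_ms * r10)
    m0 = s_base * (1.0 - e10 * cos_a) / (sin_a * (1.0 - e10))

    denom = m0 * sin_a - s * cos_a
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(denom != 0.0, (m0 * sin_a - s) / denom, np.nan)
    valid = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0)
    r1 = np.full_like(s, np.nan)
    r1[valid] = -np.log(e1[valid]) / protocol.tr_ms
    ct = (r1 - r10) / (protocol.r1_relaxivity / 1000.0)
    ct[~valid] = np.nan
    return TumorConcCurve(times=times, ct=ct, valid=valid)


def patlak_integral(aif: AIFCurve) -> np.ndarray:
    """Running trapezoid integral of the AIF on its own grid (mM * min)."""
    return cumulative_trapezoid(aif.cp, aif.times, initial=0.0)


def patlak_forward(ktrans: float, vp: float, aif: AIFCurve) -> TumorConcCurve:
    """Noise-free tissue curve implied by the Patlak model."""
    if ktrans < 0 or vp < 0:
        raise ValueError("ktrans and vp must be non-negative")
    ct = ktrans * patlak_integral(aif) + vp * aif.cp
    return TumorConcCurve(times=aif.times.copy(), ct=ct)


def patlak_fit(
    ct: TumorConcCurve,
    aif: AIFCurve,
    fit_window: tuple[float, float] | None = None,
) -> PatlakFit:
    """Constrained linear least-squares Patlak fit.

    Minimises ``sum_i [Ct(t_i) - (Ktrans * int_0^{t_i} Cp + Vp * Cp(t_i))]^2``
    subject to ``Ktrans >= 0`` and ``0 <= Vp <= 1``.  The tissue curve and
    AIF must share a time grid; ``fit_window = (t_lo, t_hi)`` in minutes
    restricts the frames used.
    """
    if ct.times.shape != aif.times.shape or not np.allclose(ct.times, aif.times):
        raise ValueError("tumor curve and AIF must share a time grid")
    if not np.any(aif.cp > 0):
        raise ValueError("all-zero AIF: Patlak parameters unidentifiable")

    x1 = patlak_integral(aif)
    mask = ct.valid & np.isfinite(ct.ct)
    if fit_window is not None:
        lo, hi = fit_window
        mask = mask & (ct.times >= lo) & (ct.times <= hi)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} usable frames; need at least 3")

    X = np.column_stack([x1[mask], aif.cp[mask]])
    y = ct.ct[mask]
    res = lsq_linear(X, y, bounds=([0.0, 0.0], [np.inf, 1.0]), tol=1e-14)
    ktrans, vp = res.x
    rss = float(np.sum((X @ res.x - y) ** 2))
    return PatlakFit(ktrans=float(ktrans), vp=float(min(max(vp, 0.0), 1.0)),
                     rss=rss, n_points=n, converged=bool(res.success))
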