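"""Michaelis-Menten fitting, catalytic constants and melt-curve analysis.

Units follow enzymology convention for this system: substrate in mM, rates
in U/mg (umol min^-1 mg^-1), k_cat in min^-1 and catalytic efficiency
k_cat/K_M in mM^-1 min^-1.  Converting a specific activity to a turnover
number requires the catalytic-unit mass: k_cat [min^-1] = V_max [U/mg]
x subunit mass [Da] x 1e-3.  The subunit mass is always an explicit,
visible parameter (default 33,200 Da for the ~66 kDa homodimer studied
here).

Melting temperatures from dye-based thermal-shift (thermofluor) data are the
inflection point of a fitted Boltzmann sigmoid, with a smoothed-derivative
argmax fallback when the sigmoid fit fails; the method used is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

DEFAULT_SUBUNIT_MASS_DA = 33200.0


class FitError(RuntimeError):
    """Raised when a curve fit cannot produce a physically meaningful result."""


@dataclass
class MMFit:
    km: float  # mM
    vmax: float  # U/mg
    km_se: float
    vmax_se: float
    kcat: float | None  # min^-1
    efficiency: float | None  # mM^-1 min^-1
    n: int
    converged: bool
    subunit_mass: float | None = None

    def to_dict(self) -> dict:
        return {
            "K_M_mM": self.km,
            "V_max_U_per_mg": self.vmax,
            "K_M_se": self.km_se,
            "V_max_se": self.vmax_se,
            "k_cat_per_min": self.kcat,
            "efficiency_per_mM_per_min": self.efficiency,
            "n_points": self.n,
            "converged": self.converged,
            "subunit_mass_Da": self.subunit_mass,
        }


@dataclass
class TmResult:
    tm: float  # degrees C
    method: str  # "boltzmann" or "derivative"
    slope: float | None
    residual_norm: float | None

    def to_dict(self) -> dict:
        return {
            "T_m_C": self.tm,
            "method": self.method,
            "slope": self.slope,
            "residual_norm": self.residual_norm,
        }


def _mm_model(S, vmax, km):
    return vmax * S / (km + S)


def _linearized_init(S: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Hanes-Woolf initialisation: S/v = S/Vmax + Km/Vmax is linear in S."""
    mask = v > 0
    if mask.sum() >= 2:
        y = S[mask] / v[mask]
        slope, intercept = np.polyfit(S[mask], y, 1)
        if slope > 0 and intercept > 0:
            return intercept / slope, 1.0 / slope  # km, vmax
    return float(np.median(S)), float(v.max()) if v.max() > 0 else 1.0


def fit_mm(S, v, subunit_mass: float | None = None) -> MMFit:
    """Nonlinear least-squares fit of v = V_max S / (K_M + S).

    ``S`` in mM (>=4 distinct positive values), ``v`` in U/mg.  Standard
    errors come from the fit covariance.  If ``subunit_mass`` (Da) is given,
    k_cat and k_cat/K_M are filled in.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape:
        raise ValueError("S and v must have equal length")
    if len(np.unique(S[S > 0])) < 4:
        raise ValueError("need at least 4 distinct positive substrate concentrations")
    if np.any(v < 0):
        raise ValueError("rates must be non-negative")

    # fit on rate scale v/max(v) so the result is exactly equivariant under
    # rescaling of the rate axis
    vscale = float(v.max())
    if vscale <= 0:
        raise ValueError("all rates are zero")
    vn = v / vscale
    km0, vmax0 = _linearized_init(S, vn)
    try:
        popt, pcov = curve_fit(
            _mm_model,
            S,
            vn,
            p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    popt = [popt[0] * vscale, popt[1]]
    pcov = np.diag([pcov[0, 0] * vscale**2, pcov[1, 1]])
    vmax, km = (float(x) for x in popt)
    if vmax <= 0 or km <= 0:
        raise FitError("fit converged to a non-positive parameter")
    # no-curvature guard: v proportional to S means km blew past the data
    if km > 100 * S.max():
        raise FitError("no curvature in data (v proportional to S); K_M unidentifiable")
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    kcat = eff = None
    if subunit_mass is not None:
        kcat, eff = catalytic_constants(vmax, subunit_mass, km)
    return MMFit(
        km=km,
        vmax=vmax,
        km_se=float(se[1]),
        vmax_se=float(se[0]),
        kcat=kcat,
        efficiency=eff,
        n=len(S),
        converged=True,
        subunit_mass=subunit_mass,
    )


def catalytic_constants(vmax: float, subunit_mass: float, km: float) -> tuple[float, float]:
    """Turnover number and catalytic efficiency from a specific activity.

    k_cat [min^-1] = V_max [U/mg] x subunit mass [Da] x 1e-3;
    efficiency = k_cat / K_M [mM^-1 min^-1].
    """
    if vmax <= 0 or subunit_mass <= 0 or km <= 0:
        raise ValueError("vmax, subunit_mass and km must be positive")
    kcat = vmax * subunit_mass * 1e-3
    return kcat, kcat / km


def efficiency_from_printed(kcat: float, km: float) -> int:
    """Catalytic efficiency, nearest-integer, from already-rounded k_cat and
    K_M values (the form tabulated in kinetics reports)."""
    if kcat <= 0 or km <= 0:
        raise ValueError("kcat and km must be positive")
    return int(round(kcat / km))


def _boltzmann(T, f_lo, f_hi, tm, slope):
    return f_lo + (f_hi - f_lo) / (1.0 + np.exp((tm - T) / slope))


def fit_tm(T, F) -> TmResult:
    """Melting temperature from a thermal-shift fluorescence curve.

    Fits a Boltzmann sigmoid and reports its midpoint; if that fails, falls
    back to the argmax of the 5-point moving-average smoothed dF/dT.  A curve
    with no transition (flat or strictly linear) raises :class:`FitError`.
    """
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    if T.shape != F.shape or len(T) < 10:
        raise ValueError("need >=10 paired (T, F) points")
    order = np.argsort(T)
    T, F = T[order], F[order]

    # no-transition guard: residual of a straight-line fit vs data range
    coef = np.polyfit(T, F, 1)
    resid = F - np.polyval(coef, T)
    spread = F.max() - F.min()
    if spread == 0 or np.abs(resid).max() < 1e-9 * max(1.0, spread) or np.allclose(resid, 0, atol=1e-12):
        raise FitError("no melting transition detectable (flat or linear curve)")

    tm0 = float(T[np.argmax(np.gradient(F, T))])
    try:
        popt, pcov = curve_fit(
            _boltzmann,
            T,
            F,
            p0=[float(F.min()), float(F.max()), tm0, 2.0],
            maxfev=20000,
        )
        f_lo, f_hi, tm, slope = (float(x) for x in popt)
        if T.min() <= tm <= T.max() and slope > 0 and f_hi > f_lo:
            resid_norm = float(np.linalg.norm(F - _boltzmann(T, *popt)))
            return TmResult(tm=tm, method="boltzmann", slope=slope, residual_norm=resid_norm)
    except RuntimeError:
        pass

    # fallback: smoothed derivative maximum
    kernel = np.ones(5) / 5.0
    Fs = np.convolve(F, kernel, mode="same")
    dF = np.gradient(Fs, T)
    tm = float(T[np.argmax(dF)])
    if not (T.min() < tm < T.max()):
        raise FitError("no melting transition detectable")
    return TmResult(tm=tm, method="derivative", slope=None, residual_norm=None)
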