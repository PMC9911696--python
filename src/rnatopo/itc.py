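"""Isothermal titration calorimetry: SVD deconvolution and binding fits.

A titration is stored as an m x n matrix M of heat-compensation traces
(m time samples per injection, n injection points).  Singular components
whose left singular vectors have a normalized lag-1 autocorrelation below
a threshold (default 0.75) are treated as systematic noise and excluded
from reconstruction.  Reconstructed per-component isotherms are fitted
with the classical one-site (1:1) binding model — the closed-form
finite-injection treatment, numerically equivalent to integrating the
Wiseman isotherm ODE — or a two-site independent model; the model is
chosen by an extra-sum-of-squares F-test.

Concentrations are molar, volumes in liters, heats in kcal (isotherms in
kcal per mole of injectant).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ITCConfig, DEFAULTS


@dataclass
class InjectionSchedule:
    """Titration setup: syringe into cell, constant injection volumes."""

    cell_conc: float                 # M (macromolecule in the cell)
    syringe_conc: float              # M (ligand in the syringe)
    cell_volume: float = 1.4e-3      # L
    injection_volume: float = 10e-6  # L
    n_injections: int = 25

    @property
    def volumes(self) -> np.ndarray:
        return np.full(self.n_injections, self.injection_volume)

    def concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Total (macromolecule, ligand) cell concentrations after each
        injection, with the standard perfusion displacement correction."""
        dv = np.cumsum(self.volumes)
        v0 = self.cell_volume
        mt = self.cell_conc * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        lt = self.syringe_conc * (dv / v0) * (1 - dv / (2 * v0))
        return mt, lt

    def molar_ratios(self) -> np.ndarray:
        mt, lt = self.concentrations()
        return lt / mt


@dataclass
class Thermogram:
    """m x n matrix of per-injection power traces plus the schedule."""

    M: np.ndarray                    # (m, n), power (kcal/s per trace sample)
    dt: float                        # s between time samples
    schedule: InjectionSchedule

    def __post_init__(self):
        self.M = np.asarray(self.M, float)
        if self.M.ndim != 2 or self.M.shape[0] < 2 or self.M.shape[1] < 2:
            raise ValueError("M must be m x n with m, n >= 2")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("non-finite entries in thermogram")


@dataclass
class Isotherm:
    molar_ratio: np.ndarray
    heat: np.ndarray                 # kcal per mole of injectant
    label: str = ""

    def __post_init__(self):
        self.molar_ratio = np.asarray(self.molar_ratio, float)
        self.heat = np.asarray(self.heat, float)
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar ratio must be strictly increasing")
        if not np.all(np.isfinite(self.heat)):
            raise ValueError("non-finite heats")


@dataclass
class SVDSelection:
    singular_values: np.ndarray
    fractions: np.ndarray            # share of each singular value
    autocorr: np.ndarray             # lag-1 autocorrelation of left vectors
    kept: np.ndarray                 # component indices retained
    threshold: float
    U: np.ndarray
    Vt: np.ndarray


@dataclass
class BindingFit:
    model: str                       # "one_site" | "two_site_independent"
    params: dict                     # per-site N, Kd (M), dH (kcal/mol)
    rss: float
    n_points: int
    n_params: int
    dG: float | dict                 # kcal/mol
    dS: float | dict                 # kcal/mol/K
    n_apparent: float
    flags: list = field(default_factory=list)


# --------------------------------------------------------------------------
# binding models
# --------------------------------------------------------------------------

def one_site_heats(schedule: InjectionSchedule, N: float, kd: float,
                   dH: float) -> np.ndarray:
    """Per-injection heats (kcal/mol of injectant) of the 1:1 model.

    The bound concentration after each injection solves the quadratic mass
    balance; the injection heat is the difference of cell heat content with
    the displaced-volume correction.  This finite-difference treatment is
    the integral of the Wiseman isotherm ODE over each injection.
    """
    mt, lt = schedule.concentrations()
    sites = N * mt
    b = sites + lt + kd
    bound = 0.5 * (b - np.sqrt(np.maximum(b * b - 4.0 * sites * lt, 0.0)))
    v0 = schedule.cell_volume
    Q = dH * v0 * bound
    dv = schedule.volumes
    qprev = np.concatenate([[0.0], Q[:-1]])
    dq = Q - qprev + (dv / v0) * 0.5 * (Q + qprev)
    moles = schedule.syringe_conc * dv
    return dq / moles


def one_site_heats_ode(schedule: InjectionSchedule, N: float, kd: float,
                       dH: float, n_sub: int = 50) -> np.ndarray:
    """Same isotherm by explicit integration of dQ/dL_t in small steps.

    Provided as a fidelity cross-check of :func:`one_site_heats`; the two
    agree to the sub-step discretization error.
    """
    q_out = []
    v0 = schedule.cell_volume
    for i in range(schedule.n_injections):
        dv = schedule.volumes[i] / n_sub
        total = 0.0
        dv_done = np.sum(schedule.volumes[:i])
        for k in range(n_sub):
            dvc = dv_done + k * dv
            def content(dvx):
                mt = schedule.cell_conc * (1 - dvx / (2 * v0)) / (1 + dvx / (2 * v0))
                lt = schedule.syringe_conc * (dvx / v0) * (1 - dvx / (2 * v0))
                sites = N * mt
                b = sites + lt + kd
                bound = 0.5 * (b - np.sqrt(max(b * b - 4.0 * sites * lt, 0.0)))
                return dH * v0 * bound
            q0 = content(dvc)
            q1 = content(dvc + dv)
            total += q1 - q0 + (dv / v0) * 0.5 * (q0 + q1)
        q_out.append(total / (schedule.syringe_conc * schedule.volumes[i]))
    return np.asarray(q_out)


def two_site_heats(schedule: InjectionSchedule, N1: float, kd1: float, dH1: float,
                   N2: float, kd2: float, dH2: float) -> np.ndarray:
    """Per-injection heats of the independent two-site model.

    Free ligand is solved per titration point from the scalar mass balance
    L_t = L + M (N1 L/(kd1+L) + N2 L/(kd2+L)) by bisection.
    """
    from scipy.optimize import brentq

    mt, lt = schedule.concentrations()
    v0 = schedule.cell_volume
    Q = np.empty(len(mt))
    for i, (m, l) in enumerate(zip(mt, lt)):
        if l <= 0:
            Q[i] = 0.0
            continue

        def balance(Lf):
            return Lf + m * (N1 * Lf / (kd1 + Lf) + N2 * Lf / (kd2 + Lf)) - l

        Lf = brentq(balance, 0.0, l, xtol=1e-18, rtol=1e-14)
        Q[i] = v0 * m * (N1 * dH1 * Lf / (kd1 + Lf) + N2 * dH2 * Lf / (kd2 + Lf))
    dv = schedule.volumes
    qprev = np.concatenate([[0.0], Q[:-1]])
    dq = Q - qprev + (dv / v0) * 0.5 * (Q + qprev)
    return dq / (schedule.syringe_conc * dv)


# --------------------------------------------------------------------------
# thermogram processing
# --------------------------------------------------------------------------

def integrate_peaks(thermo: Thermogram, baseline_window: int = 5) -> Isotherm:
    """Integrate per-injection power traces into an isotherm.

    A local linear baseline is fitted to the first and last
    ``baseline_window`` samples of each trace (assumed quiescent) and
    subtracted; the remaining area (trapezoid) is normalized per mole of
    injectant.
    """
    m, n = thermo.M.shape
    if m < 2 * baseline_window + 2:
        raise ValueError("traces too short for the requested baseline window")
    t = np.arange(m) * thermo.dt
    heats = np.empty(n)
    for j in range(n):
        y = thermo.M[:, j]
        idx = np.concatenate([np.arange(baseline_window), np.arange(m - baseline_window, m)])
        coef = np.polyfit(t[idx], y[idx], 1)
        corrected = y - np.polyval(coef, t)
        heats[j] = np.trapezoid(corrected, t)
    moles = thermo.schedule.syringe_conc * thermo.schedule.volumes
    return Isotherm(thermo.schedule.molar_ratios(), heats / moles)


def _lag1_autocorr(u: np.ndarray) -> float:
    x = u - u.mean()
    denom = np.sum(x * x)
    if denom == 0:
        return 0.0
    return float(np.sum(x[:-1] * x[1:]) / denom)


def svd_select(thermo: Thermogram, threshold: float | None = None,
               cfg: ITCConfig | None = None) -> SVDSelection:
    """Economy SVD of the thermogram with the autocorrelation filter.

    Components whose left singular vector (time course) has a normalized
    lag-1 autocorrelation below the threshold are considered systematic
    noise and excluded.  Eigenvalue fractions are sigma_i / sum(sigma) by
    default (configurable power).
    """
    cfg = cfg or DEFAULTS.itc
    threshold = cfg.autocorr_threshold if threshold is None else threshold
    M = thermo.M
    if not M.any():
        raise ValueError("all-zero thermogram: SVD selection undefined")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    power = cfg.eigenfraction_power
    sp = s ** power
    fractions = sp / sp.sum() if sp.sum() > 0 else sp
    autocorr = np.array([_lag1_autocorr(U[:, k]) for k in range(len(s))])
    kept = np.nonzero(autocorr >= threshold)[0]
    return SVDSelection(s, fractions, autocorr, kept, threshold, U, Vt)


def reconstruct_isotherms(thermo: Thermogram, sel: SVDSelection,
                          mode: str = "sigma_v") -> list[Isotherm]:
    """Per-kept-component isotherms.

    ``"sigma_v"`` (default) integrates each rank-1 reconstruction
    U_k s_k V_k^T over time, i.e. heat_j = s_k V_kj int U_k dt; the sum of
    kept reconstructions equals the truncated-SVD denoised matrix.
    ``"projected"`` re-projects the data matrix onto each left vector
    before integrating (equivalent for exact rank-1 data).
    """
    if len(sel.kept) == 0:
        raise ValueError("no kept components to reconstruct")
    ratios = thermo.schedule.molar_ratios()
    moles = thermo.schedule.syringe_conc * thermo.schedule.volumes
    out = []
    for k in sel.kept:
        if mode == "sigma_v":
            Mk = sel.singular_values[k] * np.outer(sel.U[:, k], sel.Vt[k])
        elif mode == "projected":
            Mk = np.outer(sel.U[:, k], sel.U[:, k] @ thermo.M)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        heats = np.trapezoid(Mk, dx=thermo.dt, axis=0)
        # orient so the dominant heat keeps the data's sign
        out.append(Isotherm(ratios, heats / moles, label=f"component_{k}"))
    return out


def reconstruct_matrix(sel: SVDSelection) -> np.ndarray:
    """Truncated-SVD reconstruction from the kept components."""
    if len(sel.kept) == 0:
        raise ValueError("no kept components")
    U = sel.U[:, sel.kept]
    s = sel.singular_values[sel.kept]
    Vt = sel.Vt[sel.kept]
    return (U * s) @ Vt


# --------------------------------------------------------------------------
# isotherm fitting
# --------------------------------------------------------------------------

def _thermo_state(kd: float, dH: float, cfg: ITCConfig):
    dG = cfg.R_kcal * cfg.temperature_K * np.log(kd)
    dS = (dH - dG) / cfg.temperature_K
    return float(dG), float(dS)


def fit_one_site(iso: Isotherm, schedule: InjectionSchedule,
                 cfg: ITCConfig | None = None,
                 x0: tuple[float, float, float] | None = None) -> BindingFit:
    """Nonlinear least squares of the exact 1:1 isotherm for (N, Kd, dH)."""
    from scipy.optimize import least_squares

    cfg = cfg or DEFAULTS.itc
    if len(iso.heat) < 5:
        raise ValueError("need at least 5 injections to fit")
    heats = iso.heat
    flags: list[str] = []
    if np.allclose(heats, 0.0, atol=1e-12):
        fitp = {"N": 1.0, "Kd": 1e-6, "dH": 0.0}
        dG, dS = _thermo_state(fitp["Kd"], fitp["dH"], cfg)
        return BindingFit("one_site", fitp, 0.0, len(heats), 3, dG, dS,
                          n_apparent=fitp["N"], flags=["flat"])

    dH0 = heats[0]
    ratios = iso.molar_ratio
    half = np.interp(0.5, np.linspace(0, 1, len(ratios)),
                     np.sort(ratios)) if len(ratios) else 1.0
    n0 = float(np.clip(ratios[np.argmin(np.abs(heats - 0.5 * dH0))], 0.3, 3.0))
    x0 = x0 or (n0, 1e-6, dH0)

    def resid(x):
        lnN, lnkd, dH = x
        model = one_site_heats(schedule, np.exp(lnN), np.exp(lnkd), dH)
        return model - heats

    sol = least_squares(resid, (np.log(x0[0]), np.log(x0[1]), x0[2]),
                        method="lm", xtol=1e-15, ftol=1e-15, max_nfev=20000)
    N, kd, dH = float(np.exp(sol.x[0])), float(np.exp(sol.x[1])), float(sol.x[2])
    rss = float(np.sum(sol.fun ** 2))
    c_value = N * schedule.cell_conc / kd
    if c_value < 0.1:
        flags.append("low_c_value")
        warnings.warn(f"c value {c_value:.3g} < 0.1: isotherm carries little "
                      "information on Kd")
    dG, dS = _thermo_state(kd, dH, cfg)
    return BindingFit("one_site", {"N": N, "Kd": kd, "dH": dH}, rss,
                      len(heats), 3, dG, dS, n_apparent=N, flags=flags)


def fit_two_site(iso: Isotherm, schedule: InjectionSchedule,
                 cfg: ITCConfig | None = None,
                 x0: dict | None = None) -> BindingFit:
    """Independent two-site fit (N1, Kd1, dH1, N2, Kd2, dH2).

    Opposite-sign enthalpies (an endothermic event followed by an
    exothermic one, or vice versa) are supported.  Near-collinear site
    parameters trigger a degeneracy warning.
    """
    from scipy.optimize import least_squares

    cfg = cfg or DEFAULTS.itc
    heats = iso.heat
    if len(heats) < 7:
        raise ValueError("need at least 7 injections for a two-site fit")
    flags: list[str] = []
    if x0 is None:
        x0 = {"N1": 0.5, "Kd1": 3e-7, "dH1": heats[0],
              "N2": 0.5, "Kd2": 3e-6, "dH2": heats[0] * 0.5}

    def resid(x):
        ln_n1, ln_k1, dh1, ln_n2, ln_k2, dh2 = x
        model = two_site_heats(schedule, np.exp(ln_n1), np.exp(ln_k1), dh1,
                               np.exp(ln_n2), np.exp(ln_k2), dh2)
        return model - heats

    start = (np.log(x0["N1"]), np.log(x0["Kd1"]), x0["dH1"],
             np.log(x0["N2"]), np.log(x0["Kd2"]), x0["dH2"])
    sol = least_squares(resid, start, method="lm", xtol=1e-15, ftol=1e-15,
                        max_nfev=40000)
    n1, k1, dh1 = float(np.exp(sol.x[0])), float(np.exp(sol.x[1])), float(sol.x[2])
    n2, k2, dh2 = float(np.exp(sol.x[3])), float(np.exp(sol.x[4])), float(sol.x[5])
    # report sites ordered by affinity (smallest Kd first)
    if k2 < k1:
        (n1, k1, dh1), (n2, k2, dh2) = (n2, k2, dh2), (n1, k1, dh1)
    rss = float(np.sum(sol.fun ** 2))
    if abs(np.log(k1 / k2)) < 0.2 and abs(dh1 - dh2) < 0.2 * max(abs(dh1), abs(dh2), 1e-12):
        flags.append("degenerate_sites")
        warnings.warn("two-site parameters nearly collinear (K1~K2, dH1~dH2)")
    dG1, dS1 = _thermo_state(k1, dh1, cfg)
    dG2, dS2 = _thermo_state(k2, dh2, cfg)
    params = {"N1": n1, "Kd1": k1, "dH1": dh1, "N2": n2, "Kd2": k2, "dH2": dh2}
    return BindingFit("two_site_independent", params, rss, len(heats), 6,
                      {"site1": dG1, "site2": dG2}, {"site1": dS1, "site2": dS2},
                      n_apparent=n1 + n2, flags=flags)


def select_model_ftest(fit1: BindingFit, fit2: BindingFit,
                       cfg: ITCConfig | None = None) -> tuple[str, float, float]:
    """Extra-sum-of-squares F-test between nested binding fits.

    Returns (chosen model, F, p).  The two-site model is chosen iff
    p < alpha; if the larger model fits worse (optimizer failure) the
    one-site model wins outright.
    """
    from scipy.stats import f as f_dist

    cfg = cfg or DEFAULTS.itc
    if fit1.n_params >= fit2.n_params:
        raise ValueError("fit1 must be the smaller (nested) model")
    if fit1.n_points != fit2.n_points:
        raise ValueError("fits must be on the same data")
    n = fit1.n_points
    df1 = fit2.n_params - fit1.n_params
    df2 = n - fit2.n_params
    if df2 <= 0:
        raise ValueError("too few points for the larger model")
    if fit2.rss >= fit1.rss:
        return fit1.model, 0.0, 1.0
    if fit2.rss == 0:
        return fit2.model, np.inf, 0.0
    F = ((fit1.rss - fit2.rss) / df1) / (fit2.rss / df2)
    p = float(f_dist.sf(F, df1, df2))
    chosen = fit2.model if p < cfg.alpha else fit1.model
    return chosen, float(F), p
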