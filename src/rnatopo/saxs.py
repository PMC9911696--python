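"""Small-angle X-ray scattering analysis for coarse-grained ensembles.

Per-conformer profiles come from a uniform-bead Debye sum; ensemble curves
are volume-fraction-weighted sums I_syn(q) = sum_k nu_k * I_k(q).  The
goodness of fit is

    chi^2 = 1/(N_q - 1) * sum_i [(I_saxs(q_i) - a*I_syn(q_i) - b) / sigma(q_i)]^2

with the scale a from its closed form and b a background offset.  Standard
structural parameters (Guinier Rg and I(0), P(r) and Dmax by regularized
indirect Fourier transform, correlation-volume molecular weight) are
derived from 1-D profiles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SAXSConfig, DEFAULTS
from .errors import FormatError
from .rna_cg import CGStructure


@dataclass
class SAXSProfile:
    """1-D scattering profile: q (1/A), intensity, optional per-point error."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.I = np.asarray(self.I, float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
        if self.q.ndim != 1 or len(self.q) != len(self.I):
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(np.diff(self.q) <= 0) or np.any(self.q < 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if self.sigma is not None:
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    @property
    def n_q(self) -> int:
        return len(self.q)

    def same_grid(self, other: "SAXSProfile") -> bool:
        return self.n_q == other.n_q and np.allclose(self.q, other.q)


@dataclass
class EnsembleFit:
    fractions: np.ndarray
    chi2: float
    scale: float
    offset: float
    curves: list[SAXSProfile]
    degenerate: bool = False


# --------------------------------------------------------------------------
# profile computation
# --------------------------------------------------------------------------

def default_q_grid(cfg: SAXSConfig | None = None) -> np.ndarray:
    cfg = cfg or DEFAULTS.saxs
    # open interval (0, q_max]: q = 0 is kept out to match measured ranges
    return np.linspace(cfg.q_max / cfg.n_q, cfg.q_max, cfg.n_q)


def debye_profile(cg: CGStructure, q_grid=None,
                  cfg: SAXSConfig | None = None,
                  bin_width: float = 0.25) -> SAXSProfile:
    """Debye scattering of uniform beads: I(q) = sum_uv f^2 sinc(q d_uv).

    Pair distances are histogrammed (``bin_width`` A) so the double sum
    costs O(N^2 + n_bins * n_q); I(0) = (N f)^2 exactly.
    """
    cfg = cfg or DEFAULTS.saxs
    if cg.n_beads == 0:
        raise ValueError("empty structure")
    q = np.asarray(q_grid, float) if q_grid is not None else default_q_grid(cfg)
    f = cfg.bead_form_factor
    xyz = cg.coords
    n = len(xyz)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    iu = np.triu_indices(n, k=1)
    dists = d[iu]
    nbin = max(int(np.ceil(dists.max() / bin_width)), 1) if len(dists) else 1
    hist, edges = np.histogram(dists, bins=nbin, range=(0.0, nbin * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    qr = np.outer(q, centers)
    sinc = np.where(qr > 1e-12, np.sin(qr) / np.maximum(qr, 1e-12), 1.0)
    I = f * f * (n + 2.0 * sinc @ hist)
    return SAXSProfile(q, I)


def synthesize_ensemble(curves: list[SAXSProfile], fractions) -> SAXSProfile:
    """Pointwise volume-fraction-weighted sum of per-conformer curves."""
    fractions = np.asarray(fractions, float)
    if len(curves) != len(fractions):
        raise ValueError("one fraction per curve required")
    if np.any(fractions < -1e-12):
        raise ValueError("fractions must be non-negative")
    base = curves[0]
    for c in curves[1:]:
        if not base.same_grid(c):
            raise ValueError("curves are not on a common q grid; resample explicitly")
    I = np.zeros(base.n_q)
    for nu, c in zip(fractions, curves):
        I += nu * c.I
    return SAXSProfile(base.q.copy(), I)


def resample_profile(p: SAXSProfile, q_grid) -> SAXSProfile:
    """Explicit linear interpolation onto a new q grid (no extrapolation)."""
    q_grid = np.asarray(q_grid, float)
    if q_grid.min() < p.q.min() - 1e-12 or q_grid.max() > p.q.max() + 1e-12:
        raise ValueError("requested grid extends beyond the measured range")
    I = np.interp(q_grid, p.q, p.I)
    sig = np.interp(q_grid, p.q, p.sigma) if p.sigma is not None else None
    return SAXSProfile(q_grid, I, sig)


# --------------------------------------------------------------------------
# ensemble fitting
# --------------------------------------------------------------------------

def chi_square(expt: SAXSProfile, syn: SAXSProfile,
               cfg: SAXSConfig | None = None) -> tuple[float, float, float]:
    """Reduced chi-square between an experimental and a synthesized profile.

    Returns (chi2, a, b).  The scale ``a`` follows the configured closed
    form — ``"expnorm"``: a = sum(I_saxs*I_syn)/sum(I_saxs^2), normalized
    by the experimental intensities; ``"lsq"``:
    ordinary weighted least squares.  With ``offset_mode="sequential"`` the
    background b minimizes chi^2 given a; ``"joint"`` solves (a, b)
    together by weighted least squares.
    """
    cfg = cfg or DEFAULTS.saxs
    if expt.sigma is None:
        raise ValueError("experimental profile must carry sigma")
    if not expt.same_grid(syn):
        raise ValueError("profiles are not on a common q grid; resample explicitly")
    Ie = expt.I
    Is = syn.I
    w = 1.0 / expt.sigma ** 2

    if cfg.offset_mode == "joint":
        A = np.stack([Is, np.ones_like(Is)], axis=1)
        Aw = A * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(Aw, Ie * np.sqrt(w), rcond=None)
        a, b = float(coef[0]), float(coef[1])
    else:
        if cfg.a_convention == "expnorm":
            a = float(np.sum(Ie * Is) / np.sum(Ie * Ie))
        elif cfg.a_convention == "lsq":
            a = float(np.sum(w * Ie * Is) / np.sum(w * Is * Is))
        else:
            raise ValueError(f"unknown a_convention {cfg.a_convention!r}")
        b = float(np.sum(w * (Ie - a * Is)) / np.sum(w))
    resid = (Ie - a * Is - b) / expt.sigma
    chi2 = float(np.sum(resid ** 2) / (expt.n_q - 1))
    return chi2, a, b


def optimize_fractions(expt: SAXSProfile, curves: list[SAXSProfile],
                       init_fractions=None,
                       cfg: SAXSConfig | None = None) -> EnsembleFit:
    """Simplex-constrained chi-square minimization of volume fractions.

    Starts from ``init_fractions`` (e.g. particle tallies from AFM images;
    uniform if omitted) and runs sequential least squares with nu_k >= 0,
    sum nu_k = 1.  Numerically collinear basis curves are flagged, not
    fatal.
    """
    from scipy.optimize import minimize

    cfg = cfg or DEFAULTS.saxs
    k = len(curves)
    if k < 1:
        raise ValueError("at least one conformer curve required")
    init = np.full(k, 1.0 / k) if init_fractions is None else np.asarray(init_fractions, float)
    if init.min() < -1e-12 or abs(init.sum() - 1.0) > 1e-6:
        raise ValueError("initial fractions must lie on the simplex")

    M = np.stack([c.I for c in curves], axis=1)
    degenerate = False
    if k > 1:
        Mn = M / np.linalg.norm(M, axis=0, keepdims=True)
        cond = np.linalg.cond(Mn)
        if cond > 1e8:
            degenerate = True
            warnings.warn(f"conformer curves nearly collinear (cond {cond:.2g}); "
                          "fractions are weakly determined")

    def objective(nu):
        syn = SAXSProfile(expt.q, M @ nu)
        return chi_square(expt, syn, cfg)[0]

    # normalize so the line search is well-scaled even for tiny sigmas
    f0 = objective(init)
    scale = f0 if f0 > 0 else 1.0
    res = minimize(lambda nu: objective(nu) / scale, init, method="SLSQP",
                   bounds=[(0.0, 1.0)] * k,
                   constraints=[{"type": "eq", "fun": lambda nu: nu.sum() - 1.0}],
                   options={"maxiter": 500, "ftol": 1e-14})
    nu = np.clip(res.x, 0.0, None)
    nu = nu / nu.sum()
    syn = SAXSProfile(expt.q, M @ nu)
    chi2, a, b = chi_square(expt, syn, cfg)
    return EnsembleFit(nu, chi2, a, b, list(curves), degenerate)


# --------------------------------------------------------------------------
# structural parameters
# --------------------------------------------------------------------------

def guinier_fit(expt: SAXSProfile, qrg_max: float | None = None,
                min_points: int = 5) -> tuple[float, float, tuple[float, float]]:
    """Iterative Guinier fit: ln I = ln I0 - q^2 Rg^2 / 3 for q*Rg < 1.3.

    Returns (Rg, I0, (q_min, q_max_used)).  The admissible window is
    re-derived from the current Rg estimate until it stabilizes.
    """
    qrg_max = qrg_max if qrg_max is not None else DEFAULTS.saxs.guinier_qrg_max
    q = expt.q
    I = expt.I
    pos = I > 0
    if pos.sum() < min_points:
        raise ValueError("too few positive intensities for a Guinier fit")
    mask = pos & (np.arange(len(q)) < max(min_points, len(q) // 4))
    rg = None
    for _ in range(50):
        qq = q[mask]
        if mask.sum() < 3:
            raise ValueError("no q range satisfies the Guinier condition")
        slope, intercept = np.polyfit(qq ** 2, np.log(I[mask]), 1)
        if slope >= 0:
            raise ValueError("non-decaying profile: Guinier slope >= 0")
        rg_new = float(np.sqrt(-3.0 * slope))
        new_mask = pos & (q * rg_new < qrg_max)
        if rg is not None and abs(rg_new - rg) < 1e-9 * max(rg, 1.0):
            rg = rg_new
            mask = new_mask
            break
        rg = rg_new
        if new_mask.sum() < 3:
            break
        mask = new_mask
    i0 = float(np.exp(intercept))
    used = q[mask]
    return rg, i0, (float(used.min()), float(used.max()))


def _ift_solve(q, I, sig, dmax, n_r, lam_rel):
    """One regularized non-negative IFT solve on [0, dmax]."""
    from scipy.optimize import nnls

    r = np.linspace(0.0, dmax, n_r)
    dr = r[1] - r[0]
    qr = np.outer(q, r[1:-1])
    A = np.where(qr > 1e-12, np.sin(qr) / np.maximum(qr, 1e-12), 1.0) * dr
    Aw = A / sig[:, None]
    yw = I / sig
    L = np.zeros((n_r - 4, n_r - 2))
    for i in range(n_r - 4):
        L[i, i: i + 3] = (1.0, -2.0, 1.0)
    lam = lam_rel * np.linalg.norm(Aw) / max(np.linalg.norm(L), 1e-12)
    p, _ = nnls(np.vstack([Aw, lam * L]),
                np.concatenate([yw, np.zeros(L.shape[0])]),
                maxiter=30 * (n_r + len(q)))
    P = np.zeros(n_r)
    P[1:-1] = p
    resid = float(np.linalg.norm(Aw @ p - yw))
    return r, P, resid


def pr_distribution(expt: SAXSProfile, dmax_search=None, n_r: int = 100,
                    lam_rel: float = 1e-2,
                    support_threshold: float = 0.02) -> tuple[np.ndarray, np.ndarray, float]:
    """Regularized indirect Fourier transform: returns (r, P(r), Dmax).

    P(r) is solved by non-negative least squares with a second-difference
    smoothness penalty; P(0) = P(Dmax) = 0 by construction, so P is
    near-non-negative and smooth.  Without an explicit ``dmax_search`` the
    maximum dimension is read off a generous first pass (4 Rg): Dmax is
    where the recovered P(r) support ends (last r with P above 2% of its
    peak), and P is then re-solved on [0, Dmax].  With ``dmax_search`` the
    smallest candidate whose reduced residual is within tolerance of the
    best is kept.
    """
    if expt.sigma is not None:
        sig = expt.sigma
    else:
        sig = np.maximum(0.01 * np.abs(expt.I), 1e-12 * np.abs(expt.I).max())
    q = expt.q
    I = expt.I

    if dmax_search is None:
        rg0, _, _ = guinier_fit(expt)
        r, P, _ = _ift_solve(q, I, sig, 4.0 * rg0, max(n_r, 120), lam_rel)
        supp = np.nonzero(P >= support_threshold * P.max())[0]
        if len(supp) == 0:
            raise RuntimeError("indirect Fourier transform recovered an empty P(r)")
        dmax = float(r[supp.max()])
        r, P, _ = _ift_solve(q, I, sig, dmax, n_r, lam_rel)
        return r, P, dmax

    dmax_search = np.asarray(dmax_search, float)
    results = [_ift_solve(q, I, sig, dm, n_r, lam_rel) for dm in dmax_search]
    red = np.array([res[2] ** 2 / len(q) for res in results])
    if not np.all(np.isfinite(red)):
        raise RuntimeError("indirect Fourier transform failed to converge")
    best = red.min()
    for (r, P, _), dm, rr in zip(results, dmax_search, red):
        if rr <= best + max(0.25, 0.05 * best):
            return r, P, float(dm)
    k = int(np.argmin(red))
    r, P, _ = results[k]
    return r, P, float(dmax_search[k])


def rg_from_pr(r: np.ndarray, P: np.ndarray) -> float:
    """Real-space radius of gyration: Rg^2 = int r^2 P dr / (2 int P dr)."""
    num = np.trapezoid(r ** 2 * P, r)
    den = np.trapezoid(P, r)
    if den <= 0:
        raise ValueError("P(r) has non-positive integral")
    return float(np.sqrt(num / (2.0 * den)))


def vc_molecular_weight(expt: SAXSProfile, rg: float | None = None,
                        i0: float | None = None,
                        cfg: SAXSConfig | None = None) -> tuple[float, float]:
    """Correlation-volume mass estimate: returns (Vc in A^2, MW in Da).

    Vc = I(0) / int q I(q) dq over the measured range; the molecular weight
    uses the RNA power-law calibration MW = (Vc^2/Rg / c)^k with the
    constants recorded in config.  A warning is attached when the integrand
    has not decayed at the end of the range (truncated integral).
    """
    cfg = cfg or DEFAULTS.saxs
    if rg is None or i0 is None:
        rg_fit, i0_fit, _ = guinier_fit(expt)
        rg = rg if rg is not None else rg_fit
        i0 = i0 if i0 is not None else i0_fit
    integrand = expt.q * expt.I
    total = np.trapezoid(integrand, expt.q)
    if total <= 0:
        raise ValueError("non-positive q*I integral")
    if integrand[-1] > 0.05 * integrand.max():
        warnings.warn("q*I(q) not fully decayed at q_max: Vc integral is "
                      "truncated; consider extrapolating the profile")
    vc = float(i0 / total)
    qr = vc ** 2 / rg
    mw = float((qr / cfg.vc_mw_coefficient) ** cfg.vc_mw_exponent)
    return vc, mw


# --------------------------------------------------------------------------
# 3-column text I/O (q, I, sigma)
# --------------------------------------------------------------------------

def read_dat(path: str | Path) -> SAXSProfile:
    """Read a whitespace-delimited (q, I[, sigma]) file; '#' comments."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        s = line.strip()
        if not s or s.startswith(("#", ";")):
            continue
        parts = s.split()
        try:
            vals = [float(x) for x in parts[:3]]
        except ValueError:
            continue        # SASBDB files may carry text headers without '#'
        if len(vals) >= 2:
            rows.append(vals + [np.nan] * (3 - len(vals)))
    if not rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.array(rows)
    sigma = arr[:, 2]
    has_sigma = np.isfinite(sigma).all() and (sigma > 0).all()
    return SAXSProfile(arr[:, 0], arr[:, 1], sigma if has_sigma else None)


def write_dat(p: SAXSProfile, path: str | Path) -> None:
    cols = [p.q, p.I] + ([p.sigma] if p.sigma is not None else [])
    header = "q(1/A) I(a.u.)" + (" sigma" if p.sigma is not None else "")
    np.savetxt(str(path), np.column_stack(cols), header=header, fmt="%.8g")
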