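"""Simulated AFM molecular surfaces.

A molecule resting on the mica plane (z = 0) is scanned by a spherical tip:
the height at a pixel is the lowest tip position at which the tip sphere
touches any bead sphere — grey-scale dilation of the bead cloud by the tip.
Heights are stored in nm, pixel size in Angstrom per pixel, matching the
plain-text "pseudoAFM" grid convention (5 A/pixel).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AFMConfig, BeadModel, DEFAULTS
from .errors import FormatError
from .rna_cg import CGStructure

A_PER_NM = 10.0


@dataclass
class TipModel:
    """Spherical scanning tip of nominal radius (nm)."""

    radius_nm: float = 1.0

    def __post_init__(self):
        if self.radius_nm < 0:
            raise ValueError("tip radius must be >= 0")

    @property
    def radius_A(self) -> float:
        return self.radius_nm * A_PER_NM


@dataclass
class AFMImage:
    """Height grid in nm; ``heights[iy, ix]``, x along columns."""

    heights: np.ndarray
    pixel_size: float = 5.0          # A / pixel
    origin: tuple[float, float] = (0.0, 0.0)   # lab coordinates (A) of pixel (0, 0)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def max_height(self) -> float:
        return float(self.heights.max())

    def same_grid(self, other: "AFMImage") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.pixel_size, other.pixel_size))

    def copy(self) -> "AFMImage":
        return AFMImage(self.heights.copy(), self.pixel_size, tuple(self.origin))


def drop_to_plane(cg: CGStructure, beads: BeadModel | None = None) -> CGStructure:
    """Translate so the lowest bead surface rests on the mica plane z = 0."""
    radii = cg.bead_radii(beads)
    zmin = float((cg.coords[:, 2] - radii).min())
    return cg.translate((0.0, 0.0, -zmin))


def render_surface(cg: CGStructure, tip: TipModel | None = None,
                   pixel_size: float | None = None,
                   grid: AFMImage | None = None,
                   beads: BeadModel | None = None,
                   afm: AFMConfig | None = None,
                   drop: bool = True) -> AFMImage:
    """Render the AFM molecular surface of a bead model.

    For every pixel the height is the lowest tip-sphere center (minus the
    tip radius) at which a tip of radius R touches a bead of radius r at
    lateral distance d <= R + r:  h = z_bead + sqrt((R+r)^2 - d^2) - R.
    With R = 0 this reduces to the z-projection of the bead tops.

    Passing ``grid`` renders onto an existing image geometry (used during
    fitting so experiment and simulation share a frame).
    """
    afm = afm or DEFAULTS.afm
    tip = tip if tip is not None else TipModel(afm.tip_radius_nm)
    px = pixel_size if pixel_size is not None else (grid.pixel_size if grid else afm.pixel_size)
    if px <= 0:
        raise ValueError("pixel_size must be > 0")
    if cg.n_beads == 0:
        warnings.warn("empty structure: returning an all-zero image")
        return AFMImage(np.zeros((8, 8)), px)

    if drop:
        cg = drop_to_plane(cg, beads)
    xyz = cg.coords
    radii = cg.bead_radii(beads)
    R = tip.radius_A

    if grid is not None:
        ny, nx = grid.shape
        x0, y0 = grid.origin
    else:
        pad = afm.pad
        x0 = float(xyz[:, 0].min() - pad)
        y0 = float(xyz[:, 1].min() - pad)
        nx = int(np.ceil((xyz[:, 0].max() + pad - x0) / px)) + 1
        ny = int(np.ceil((xyz[:, 1].max() + pad - y0) / px)) + 1

    H = np.zeros((ny, nx))
    reach = radii + R
    win = int(np.ceil(reach.max() / px)) + 1
    off = np.arange(-win, win + 1)
    offx, offy = np.meshgrid(off, off)                       # (W, W)
    ix0 = np.round((xyz[:, 0] - x0) / px).astype(int)        # (N,)
    iy0 = np.round((xyz[:, 1] - y0) / px).astype(int)
    ix = ix0[:, None, None] + offx[None]                     # (N, W, W)
    iy = iy0[:, None, None] + offy[None]
    gx = x0 + ix * px
    gy = y0 + iy * px
    d2 = (gx - xyz[:, 0, None, None]) ** 2 + (gy - xyz[:, 1, None, None]) ** 2
    arg = reach[:, None, None] ** 2 - d2
    valid = (arg >= 0) & (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    h = np.where(valid, xyz[:, 2, None, None] + np.sqrt(np.maximum(arg, 0.0)) - R, 0.0)
    h = np.maximum(h, 0.0)
    np.maximum.at(H, (iy[valid], ix[valid]), h[valid])
    return AFMImage(H / A_PER_NM, px, (x0, y0))


def add_noise(img: AFMImage, level: float, rng_seed=None,
              truncation: str | None = None, afm: AFMConfig | None = None) -> AFMImage:
    """Add percentage Gaussian noise to a height image.

    ``level`` is the +/- percentage of the image's highest Z value that the
    2-sigma noise amplitude spans: sigma = (level/100) * max_height / 2.
    Samples are limited to +/- 2 sigma (``truncation``: "clip" folds the
    tails onto the bounds, "resample" redraws them, "none" leaves the
    Gaussian untouched).  The result is clipped at the mica plane (0).
    """
    afm = afm or DEFAULTS.afm
    truncation = truncation or afm.noise_truncation
    zmax = img.max_height
    if zmax < 0:
        raise ValueError("invalid image: negative maximum height")
    if level == 0 or zmax == 0:
        return img.copy()
    sigma = abs(level) / 100.0 * zmax / 2.0
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(0.0, sigma, size=img.shape)
    if truncation == "clip":
        noise = np.clip(noise, -2.0 * sigma, 2.0 * sigma)
    elif truncation == "resample":
        bad = np.abs(noise) > 2.0 * sigma
        while bad.any():
            noise[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
            bad = np.abs(noise) > 2.0 * sigma
    elif truncation != "none":
        raise ValueError(f"unknown truncation mode {truncation!r}")
    out = img.copy()
    out.heights = np.clip(out.heights + noise, 0.0, None)
    return out


NOISE_LADDER = (5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90, 100)


# --------------------------------------------------------------------------
# pseudoAFM text format
# --------------------------------------------------------------------------

def write_pseudoafm(img: AFMImage, path: str | Path) -> None:
    path = Path(path)
    header = (f"# pseudoAFM height grid\n"
              f"# pixel_size_A = {img.pixel_size:g}\n"
              f"# origin_A = {img.origin[0]:g} {img.origin[1]:g}\n"
              f"# units = nm\n")
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, img.heights, fmt="%.6g")


def read_pseudoafm(path: str | Path) -> AFMImage:
    """Read a whitespace-delimited height grid with '#' header lines.

    A missing pixel-size header falls back to the conventional 5 A/pixel
    with a warning.
    """
    path = Path(path)
    pixel_size = None
    origin = (0.0, 0.0)
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip().lower()
                if key.startswith("pixel_size"):
                    pixel_size = float(val)
                elif key.startswith("origin"):
                    parts = val.split()
                    origin = (float(parts[0]), float(parts[1]))
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: non-numeric grid entry") from e
    if not rows:
        raise FormatError(f"{path}: no grid data")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    if pixel_size is None:
        warnings.warn(f"{path}: no pixel_size header; assuming 5 A/pixel")
        pixel_size = 5.0
    return AFMImage(np.array(rows), pixel_size, origin)


# --------------------------------------------------------------------------
# profile analysis
# --------------------------------------------------------------------------

def corrugation_period(img: AFMImage, axis: str = "x") -> float:
    """Dominant spatial period (nm) of the height corrugation along an axis.

    Takes the scan line with the greatest mean height, trims the edge ramps
    of the molecular footprint, and tracks the deep once-per-turn minima
    (major grooves) by prominence-filtered peak finding with parabolic
    sub-pixel refinement; the period is the slope of minimum position vs
    minimum order.  Falls back to the autocorrelation maximum when fewer
    than two deep minima are visible.
    """
    from scipy.signal import find_peaks

    H = img.heights if axis == "x" else img.heights.T
    row = H[int(np.argmax(H.mean(axis=1)))]
    support = np.nonzero(row > 0.5 * row.max())[0]
    if len(support) < 8:
        raise ValueError("profile footprint too short for period analysis")
    trim = 3
    prof = row[support.min() + trim: support.max() + 1 - trim]
    px_nm = img.pixel_size / A_PER_NM

    neg = -prof
    peaks, _ = find_peaks(neg, prominence=0.3 * (prof.max() - prof.min()))
    refined = []
    for p in peaks:
        if 0 < p < len(neg) - 1:
            y0, y1, y2 = neg[p - 1: p + 2]
            den = y0 - 2 * y1 + y2
            refined.append(p + (0.5 * (y0 - y2) / den if den != 0 else 0.0))
    if len(refined) >= 2:
        slope = np.polyfit(np.arange(len(refined)), refined, 1)[0]
        return float(slope * px_nm)

    x = prof - prof.mean()
    n = len(x)
    ac = np.correlate(x, x, mode="full")[n - 1:]
    for k in range(2, n - 1):
        if ac[k] >= ac[k - 1] and ac[k] > ac[k + 1] and ac[k] > 0:
            y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
            den = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / den if den != 0 else 0.0
            return float((k + shift) * px_nm)
    raise ValueError("no corrugation detected")
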