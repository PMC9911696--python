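"""Dynamic fitting of coarse-grained RNA models to AFM molecular surfaces.

The objective couples image agreement and stereochemistry:

* an uncentered cross-correlation CC between experimental and simulated
  surface intensities, computed over the molecular footprint;
* a pseudopotential  V = theta_afm * N * kBT * (1 - CC)  that converts
  image disagreement into an energy over the molecule's N beads;
* a coarse-grained energy with covalent (length/angle/dihedral) and
  noncovalent (stacking, pairing, contact) terms, each with its own
  scaling factor.

The optimizer is an annealed Metropolis Monte-Carlo over helix-arm
rotations about junction pivots, global rigid-body moves and linker-bead
displacements, re-rendering the simulated surface after every proposal.
The reported structure is the trajectory frame of lowest total energy
within the top cross-correlation tier.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULTS, EnergyParams, FitSchedule, FitWeights
from .errors import RnatopoError
from .rna_cg import (CGStructure, SecondaryStructure, ROLE_BACKBONE,
                     helix_subtree, interaction_exclusion)
from .afm_sim import AFMImage, TipModel, render_surface

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# image scoring
# --------------------------------------------------------------------------

def cross_correlation(exp: AFMImage, sim: AFMImage,
                      height_floor: float | None = None) -> float:
    """Uncentered normalized cross-correlation of two height images.

    C = sum(I_exp * I_sim) / (sqrt(sum I_exp^2) * sqrt(sum I_sim^2)),
    summed over the molecular footprint: the union of pixels where either
    image exceeds the height floor (default from config, 0.1 nm).  The
    statistic is invariant to uniform intensity scaling of either image
    and lies in [0, 1] for non-negative images.
    """
    if not exp.same_grid(sim):
        raise ValueError("image grids differ in shape or pixel size")
    floor = DEFAULTS.afm.height_floor_nm if height_floor is None else height_floor
    a = exp.heights
    b = sim.heights
    mask = (a > floor) | (b > floor)
    if not mask.any():
        raise ValueError("cross-correlation undefined: no pixels above the height floor")
    av = a[mask]
    bv = b[mask]
    na = np.sqrt(np.sum(av * av))
    nb = np.sqrt(np.sum(bv * bv))
    if na == 0 or nb == 0:
        raise ValueError("cross-correlation undefined: an image is all zero on the footprint")
    return float(np.sum(av * bv) / (na * nb))


def afm_pseudopotential(cc: float, w: FitWeights, n_beads: int) -> float:
    """Image pseudopotential V = theta_afm * N * kBT * (1 - CC)."""
    if not (0.0 <= cc <= 1.0 + 1e-12):
        raise ValueError(f"cc must lie in [0, 1], got {cc}")
    return w.theta_afm * n_beads * w.kBT * (1.0 - cc)


# --------------------------------------------------------------------------
# coarse-grained energy
# --------------------------------------------------------------------------

@dataclass
class ReferenceGeometry:
    """Reference values for every energy tuple, taken from an ideal build.

    ``*_helix`` flags mark tuples fully inside one helix; these get the
    stiff force constants, junction/linker tuples the floppy ones.
    """

    bond_idx: np.ndarray          # (nb, 2)
    bond_ref: np.ndarray
    angle_idx: np.ndarray         # (na, 3)
    angle_ref: np.ndarray
    angle_helix: np.ndarray
    dih_idx: np.ndarray           # (nd, 4)
    dih_ref: np.ndarray
    dih_helix: np.ndarray
    pair_idx: np.ndarray          # (np, 2) base beads of paired nts
    pair_ref: np.ndarray
    stack_idx: np.ndarray         # (ns, 2) base beads of stacked nts
    stack_ref: np.ndarray
    exclusion: np.ndarray         # (n, n) bool — pairs outside the contact term

    @classmethod
    def from_structure(cls, cg: CGStructure, ss: SecondaryStructure,
                       kissing_pairs=()) -> "ReferenceGeometry":
        """Derive tuples and reference values from an ideally built model.

        ``kissing_pairs`` declares extra (i, j) nucleotide pairs (e.g. loop-
        loop tertiary contacts between chains) that get pairing wells at the
        canonical pairing distance.
        """
        xyz = cg.coords
        nt = cg.nt_index
        hel = cg.helix_id

        bond_idx = cg.bonds.astype(int)
        bond_ref = np.linalg.norm(xyz[bond_idx[:, 0]] - xyz[bond_idx[:, 1]], axis=1)
        # linker-involving bonds get conformation-independent reference
        # lengths, so the reference build's arbitrary loop paths carry no bias
        beads_cfg = DEFAULTS.beads
        bond_in_helix = _all_same_helix(hel, bond_idx)
        is_bb_bond = (cg.role[bond_idx[:, 0]] == ROLE_BACKBONE) & \
                     (cg.role[bond_idx[:, 1]] == ROLE_BACKBONE)
        bond_ref = np.where(bond_in_helix, bond_ref,
                            np.where(is_bb_bond, beads_cfg.link_step, 3.5))

        # backbone triples / quads along each chain
        bb = np.nonzero(cg.role == ROLE_BACKBONE)[0]
        order = np.argsort(nt[bb])
        bb = bb[order]
        chains = cg.chain_id[bb]
        angle_idx, dih_idx = [], []
        for k in range(len(bb) - 2):
            if chains[k] == chains[k + 2]:
                angle_idx.append((bb[k], bb[k + 1], bb[k + 2]))
        for k in range(len(bb) - 3):
            if chains[k] == chains[k + 3]:
                dih_idx.append((bb[k], bb[k + 1], bb[k + 2], bb[k + 3]))
        angle_idx = np.asarray(angle_idx, int).reshape(-1, 3)
        dih_idx = np.asarray(dih_idx, int).reshape(-1, 4)
        angle_ref = _angles(xyz, angle_idx)
        dih_ref = _dihedrals(xyz, dih_idx)
        angle_helix = _all_same_helix(hel, angle_idx)
        dih_helix = _all_same_helix(hel, dih_idx)

        pair_idx, stack_idx = [], []
        for i, j in ss.pairs:
            pair_idx.append((2 * i + 1, 2 * j + 1))
        for helix in ss.helices:
            for (i1, j1), (i2, j2) in zip(helix[:-1], helix[1:]):
                stack_idx.append((2 * i1 + 1, 2 * i2 + 1))
                stack_idx.append((2 * j1 + 1, 2 * j2 + 1))
        pair_idx = np.asarray(pair_idx, int).reshape(-1, 2)
        stack_idx = np.asarray(stack_idx, int).reshape(-1, 2)
        pair_ref = _dists(xyz, pair_idx)
        stack_ref = _dists(xyz, stack_idx)

        if len(kissing_pairs):
            canon = float(pair_ref.mean()) if len(pair_ref) else 5.0
            extra = np.asarray([(2 * i + 1, 2 * j + 1) for i, j in kissing_pairs], int)
            pair_idx = np.vstack([pair_idx, extra])
            pair_ref = np.concatenate([pair_ref, np.full(len(extra), canon)])

        return cls(bond_idx, bond_ref, angle_idx, angle_ref, angle_helix,
                   dih_idx, dih_ref, dih_helix, pair_idx, pair_ref,
                   stack_idx, stack_ref, interaction_exclusion(cg, ss))


def _dists(xyz, idx):
    if len(idx) == 0:
        return np.empty(0)
    return np.linalg.norm(xyz[idx[:, 0]] - xyz[idx[:, 1]], axis=1)


def _angles(xyz, idx):
    if len(idx) == 0:
        return np.empty(0)
    v1 = xyz[idx[:, 0]] - xyz[idx[:, 1]]
    v2 = xyz[idx[:, 2]] - xyz[idx[:, 1]]
    cosang = np.sum(v1 * v2, axis=1) / (np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals(xyz, idx):
    if len(idx) == 0:
        return np.empty(0)
    b1 = xyz[idx[:, 1]] - xyz[idx[:, 0]]
    b2 = xyz[idx[:, 2]] - xyz[idx[:, 1]]
    b3 = xyz[idx[:, 3]] - xyz[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    return np.arctan2(y, x)


def _all_same_helix(hel, idx):
    if len(idx) == 0:
        return np.empty(0, bool)
    h = hel[idx]
    return (h >= 0).all(axis=1) & (h == h[:, :1]).all(axis=1)


@dataclass
class EnergyBreakdown:
    """Raw (unweighted) energy terms plus the weighted total."""

    e_angle: float = 0.0
    e_length: float = 0.0
    e_dih: float = 0.0
    e_stacking: float = 0.0
    e_pairing: float = 0.0
    e_contact: float = 0.0
    v_afm: float = 0.0
    e_total: float = 0.0

    def weighted_total(self, w: FitWeights) -> float:
        return (self.v_afm
                + w.theta_c * (self.e_angle + self.e_length + self.e_dih)
                + w.theta_stacking * self.e_stacking
                + w.theta_pairing * self.e_pairing
                + w.theta_contact * self.e_contact)


def covalent_energy(cg: CGStructure, ref: ReferenceGeometry,
                    params: EnergyParams | None = None) -> tuple[float, float, float]:
    """Harmonic penalties about the reference bond lengths, angles and
    dihedrals (kBT units); zero at the reference geometry."""
    p = params or DEFAULTS.energy
    xyz = cg.coords
    d = _dists(xyz, ref.bond_idx)
    e_length = float(p.k_length * np.sum((d - ref.bond_ref) ** 2))
    ang = _angles(xyz, ref.angle_idx)
    ka = np.where(ref.angle_helix, p.k_angle_helix, p.k_angle_linker)
    e_angle = float(np.sum(ka * (ang - ref.angle_ref) ** 2))
    dih = _dihedrals(xyz, ref.dih_idx)
    delta = np.arctan2(np.sin(dih - ref.dih_ref), np.cos(dih - ref.dih_ref))
    kd = np.where(ref.dih_helix, p.k_dih_helix, p.k_dih_linker)
    e_dih = float(np.sum(kd * delta ** 2))
    return e_angle, e_length, e_dih


def noncovalent_energy(cg: CGStructure, ref: ReferenceGeometry,
                       params: EnergyParams | None = None) -> tuple[float, float, float]:
    """Stacking/pairing flat-bottom wells plus a soft-core contact term.

    The contact term combines a finite soft-core repulsion below the clash
    cutoff with a screened-charge (Debye-Hueckel-like) repulsion between
    backbone beads; it is finite for any geometry.
    """
    p = params or DEFAULTS.energy
    xyz = cg.coords

    def well(idx, refd, k):
        if len(idx) == 0:
            return 0.0
        d = _dists(xyz, idx)
        excess = np.maximum(np.abs(d - refd) - p.well_width, 0.0)
        return float(k * np.sum(excess ** 2))

    e_pairing = well(ref.pair_idx, ref.pair_ref, p.k_pairing)
    e_stacking = well(ref.stack_idx, ref.stack_ref, p.k_stacking)

    n = cg.n_beads
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    iu = np.triu_indices(n, k=1)
    keep = ~ref.exclusion[iu]
    dd = d[iu][keep]

    rc = p.repulsion_cutoff
    x2 = (dd / rc) ** 2
    rep = np.where(dd < rc,
                   p.k_repulsion * (1.0 - x2) ** 2 / (x2 + p.softcore_alpha),
                   0.0)
    bbm = cg.role == ROLE_BACKBONE
    is_bb_pair = (bbm[iu[0]] & bbm[iu[1]])[keep]
    el = np.where(is_bb_pair & (dd < p.electrostatic_cutoff) & (dd > 1e-9),
                  p.k_electrostatic * np.exp(-dd / p.debye_length) / np.maximum(dd, 1e-9),
                  0.0)
    e_contact = float(np.sum(rep) + np.sum(el))
    return e_stacking, e_pairing, e_contact


def total_energy(cg: CGStructure, img: AFMImage | None, ref: ReferenceGeometry,
                 w: FitWeights | None = None, tip: TipModel | None = None,
                 params: EnergyParams | None = None,
                 sim: AFMImage | None = None) -> EnergyBreakdown:
    """Assemble the total energy; with ``img`` None the image term is omitted.

    ``sim`` short-circuits re-rendering when the caller already holds the
    simulated image of ``cg`` on the experimental grid.
    """
    w = w or DEFAULTS.weights
    w.validate()
    bd = EnergyBreakdown()
    bd.e_angle, bd.e_length, bd.e_dih = covalent_energy(cg, ref, params)
    bd.e_stacking, bd.e_pairing, bd.e_contact = noncovalent_energy(cg, ref, params)
    if img is not None:
        if sim is None:
            sim = render_surface(cg, tip, grid=img)
        cc = cross_correlation(img, sim)
        bd.v_afm = afm_pseudopotential(cc, w, cg.n_beads)
    bd.e_total = bd.weighted_total(w)
    return bd


# --------------------------------------------------------------------------
# RMSD
# --------------------------------------------------------------------------

def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def rmsd(a: CGStructure, b: CGStructure, superpose: bool = True,
         backbone_only: bool = True) -> float:
    """Root-mean-square deviation between matched bead models (A).

    With ``superpose`` the optimal rigid transform (Kabsch) is removed
    first.  By default only backbone beads enter the measure.
    """
    if a.n_beads != b.n_beads:
        raise ValueError("bead counts differ")
    mask = a.backbone_mask if backbone_only else np.ones(a.n_beads, bool)
    P = a.coords[mask]
    Q = b.coords[mask]
    if superpose:
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        R = kabsch_rotation(Pc, Qc)
        P = Pc @ R.T
        Q = Qc
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


# --------------------------------------------------------------------------
# pose registration
# --------------------------------------------------------------------------

def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation_axis(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def default_orientation_grid(n_inplane: int = 12, tilts=(0.0,)) -> list[np.ndarray]:
    """SO(3) sample: in-plane rotations crossed with tilts about x."""
    grid = []
    for tilt in tilts:
        Rt = _rotation_axis((1.0, 0.0, 0.0), tilt)
        for k in range(n_inplane):
            grid.append(_rotation_z(2.0 * np.pi * k / n_inplane) @ Rt)
    return grid


def register_pose(cg: CGStructure, img: AFMImage, tip: TipModel | None = None,
                  orientations: list[np.ndarray] | None = None,
                  max_shift: int = 6) -> tuple[np.ndarray, tuple[int, int], float]:
    """Exhaustive pose search maximizing the cross-correlation.

    Scans the orientation grid and integer-pixel in-plane translations; the
    returned pose is (rotation matrix, (dy, dx) pixel shift, cc).  Ties keep
    the earliest grid entry, so the search is deterministic.
    """
    if img.max_height <= DEFAULTS.afm.height_floor_nm:
        raise ValueError("cannot register pose against an all-flat image")
    orientations = orientations if orientations is not None else default_orientation_grid()
    best = (-np.inf, None, None)
    center = cg.coords.mean(axis=0)
    for oi, R in enumerate(orientations):
        rot = cg.rotate(R, center=center)
        sim = render_surface(rot, tip, grid=img)
        for dy in range(-max_shift, max_shift + 1):
            for dx in range(-max_shift, max_shift + 1):
                shifted = _shift_image(sim.heights, dy, dx)
                try:
                    cc = cross_correlation(img, AFMImage(shifted, img.pixel_size, img.origin))
                except ValueError:
                    continue
                if cc > best[0] + 1e-12:
                    best = (cc, oi, (dy, dx))
    if best[1] is None:
        raise ValueError("pose registration failed: no overlap found")
    return orientations[best[1]], best[2], best[0]


def _shift_image(h: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(h)
    ny, nx = h.shape
    ys = slice(max(dy, 0), min(ny + dy, ny))
    xs = slice(max(dx, 0), min(nx + dx, nx))
    ys_src = slice(max(-dy, 0), min(ny - dy, ny))
    xs_src = slice(max(-dx, 0), min(nx - dx, nx))
    out[ys, xs] = h[ys_src, xs_src]
    return out


# --------------------------------------------------------------------------
# dynamic fitting
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    structure: CGStructure
    cc: float
    energy: EnergyBreakdown
    trajectory: pd.DataFrame
    seed: int | None
    converged: bool
    n_accepted: int
    n_steps: int


def perturb_structure(cg: CGStructure, ss: SecondaryStructure,
                      arm_angle_deg: float = 30.0, seed: int | None = 0) -> CGStructure:
    """Randomly rotate every helix arm about its junction pivot (seeded);
    used to generate distorted starting models for recovery tests."""
    rng = np.random.default_rng(seed)
    out = cg.copy()
    for hid in range(len(ss.helices)):
        idx, _ = helix_subtree(ss, out, hid)
        pivot = 0.5 * (out.coords[2 * ss.helix_span(hid)[0]]
                       + out.coords[2 * ss.helix_span(hid)[1]])
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.deg2rad(rng.normal(0.0, arm_angle_deg))
        R = _rotation_axis(axis, ang)
        out.coords[idx] = (out.coords[idx] - pivot) @ R.T + pivot
    return out


def perturb_to_rmsd(cg: CGStructure, ss: SecondaryStructure, target: float,
                    seed: int | None = 0, mags=None) -> CGStructure:
    """Perturb arms with increasing amplitude until the backbone RMSD to the
    input is closest to ``target`` (deterministic given the seed)."""
    mags = mags if mags is not None else np.arange(10.0, 155.0, 5.0)
    best = None
    for m in mags:
        p = perturb_structure(cg, ss, m, seed=seed)
        err = abs(rmsd(p, cg) - target)
        if best is None or err < best[0]:
            best = (err, p)
    return best[1]


def dynamic_fit(start: CGStructure, img: AFMImage, ss: SecondaryStructure,
                w: FitWeights | None = None,
                schedule: FitSchedule | None = None,
                seed: int | None = 0,
                tip: TipModel | None = None,
                ref: ReferenceGeometry | None = None,
                params: EnergyParams | None = None,
                kissing_pairs=()) -> FitResult:
    """Annealed Monte-Carlo fit of a model into an AFM image.

    The reference geometry defaults to a fresh ideal rebuild of ``ss`` so
    the covalent/noncovalent minima do not depend on how distorted the
    start model is.  The returned structure is the frame with the lowest
    total energy among those within ``schedule.cc_tier`` of the best
    cross-correlation seen.
    """
    from .rna_cg import assemble_topology

    w = w or DEFAULTS.weights
    schedule = schedule or DEFAULTS.schedule
    if ref is None:
        ideal = assemble_topology(ss, rng_seed=0)
        ref = ReferenceGeometry.from_structure(ideal, ss, kissing_pairs)
    rng = np.random.default_rng(seed)

    cur = start.copy()
    sim = render_surface(cur, tip, grid=img)
    cur_bd = total_energy(cur, img, ref, w, tip, params, sim=sim)
    cur_cc = cross_correlation(img, sim)

    best_frames: list[tuple[float, float, np.ndarray]] = [(cur_cc, cur_bd.e_total, cur.coords.copy())]
    max_cc = cur_cc
    traj = [(0, cur_cc, cur_bd.e_total)]
    n_acc = 0

    n_steps = schedule.n_steps
    if n_steps <= 0:
        bd = cur_bd
        return FitResult(cur, cur_cc, bd, pd.DataFrame(traj, columns=["step", "cc", "e_total"]),
                         seed, cur_cc >= schedule.cc_floor, 0, 0)

    n_helices = len(ss.helices)
    linker_beads = np.nonzero(cur.helix_id < 0)[0]
    cycle_len = max(n_steps // max(schedule.n_cycles, 1), 1)
    cool = (schedule.t_end / schedule.t_start) ** (1.0 / max(cycle_len - 1, 1))
    T = schedule.t_start
    p_moves = np.array([schedule.p_arm if n_helices else 0.0,
                        schedule.p_rot, schedule.p_trans,
                        schedule.p_bead if len(linker_beads) else 0.0])
    p_moves = p_moves / p_moves.sum()

    def propose(state: CGStructure, amp: float, jumps: bool = True) -> CGStructure:
        trial = state.copy()
        kind = rng.choice(4, p=p_moves)
        if kind == 0:
            hid = int(rng.integers(n_helices))
            idx, _ = helix_subtree(ss, trial, hid)
            i0, j0 = ss.helix_span(hid)
            pivot = 0.5 * (trial.coords[2 * i0] + trial.coords[2 * j0])
            if rng.random() < 0.5:
                # in-plane arm swing: adsorbed molecules rearrange mostly
                # parallel to the substrate
                axis = np.array([0.0, 0.0, 1.0])
            else:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
            if jumps and rng.random() < 0.15:
                # occasional large jump (basin escape), amplitude-independent
                ang = rng.uniform(-np.pi, np.pi)
            else:
                ang = np.deg2rad(rng.normal(0.0, schedule.arm_angle_deg * amp))
            R = _rotation_axis(axis, ang)
            trial.coords[idx] = (trial.coords[idx] - pivot) @ R.T + pivot
        elif kind == 1:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.deg2rad(rng.normal(0.0, schedule.rot_angle_deg * amp))
            R = _rotation_axis(axis, ang)
            c = trial.coords.mean(axis=0)
            trial.coords = (trial.coords - c) @ R.T + c
        elif kind == 2:
            shift = rng.normal(0.0, schedule.trans_step * amp, size=2)
            trial.coords = trial.coords + np.array([shift[0], shift[1], 0.0])
        else:
            bi = int(rng.choice(linker_beads))
            trial.coords[bi] += rng.normal(0.0, schedule.bead_step * amp, size=3)
        return trial

    for step in range(1, n_steps + 1):
        scale = T / schedule.t_start
        amp = max(scale, 0.02)
        trial = propose(cur, amp)

        sim_t = render_surface(trial, tip, grid=img)
        try:
            cc_t = cross_correlation(img, sim_t)
        except ValueError:
            T *= cool
            continue
        bd_t = total_energy(trial, img, ref, w, tip, params, sim=sim_t)
        dE = bd_t.e_total - cur_bd.e_total
        if dE <= 0 or rng.random() < np.exp(-dE / max(T, 1e-9)):
            cur, cur_bd, cur_cc = trial, bd_t, cc_t
            n_acc += 1
            traj.append((step, cur_cc, cur_bd.e_total))
            max_cc = max(max_cc, cur_cc)
            best_frames.append((cur_cc, cur_bd.e_total, cur.coords.copy()))
            if len(best_frames) > 400:
                # keep only frames that can still win the selection rule
                cut = max_cc - 2.0 * schedule.cc_tier
                best_frames = [f for f in best_frames if f[0] >= cut] or best_frames[-1:]
        if step % cycle_len == 0:
            # reheat from the best frame so far (elitist restart)
            T = schedule.t_start
            tier_now = [f for f in best_frames if f[0] >= max_cc - schedule.cc_tier]
            cc_e, e_e, coords_e = min(tier_now, key=lambda f: f[1])
            cur = cur.copy()
            cur.coords = coords_e.copy()
            sim_e = render_surface(cur, tip, grid=img)
            cur_bd = total_energy(cur, img, ref, w, tip, params, sim=sim_e)
            cur_cc = cross_correlation(img, sim_e)
        else:
            T *= cool

    # greedy multi-scale polish from the current best frame
    if schedule.n_polish > 0:
        tier_now = [f for f in best_frames if f[0] >= max_cc - schedule.cc_tier]
        _, _, coords_p = min(tier_now, key=lambda f: f[1])
        cur = cur.copy()
        cur.coords = coords_p.copy()
        sim_p = render_surface(cur, tip, grid=img)
        cur_bd = total_energy(cur, img, ref, w, tip, params, sim=sim_p)
        cur_cc = cross_correlation(img, sim_p)
        amps = np.array([0.5, 0.15, 0.05])
        for step in range(n_steps + 1, n_steps + schedule.n_polish + 1):
            trial = propose(cur, float(rng.choice(amps)), jumps=False)
            sim_t = render_surface(trial, tip, grid=img)
            try:
                cc_t = cross_correlation(img, sim_t)
            except ValueError:
                continue
            bd_t = total_energy(trial, img, ref, w, tip, params, sim=sim_t)
            if bd_t.e_total < cur_bd.e_total:
                cur, cur_bd, cur_cc = trial, bd_t, cc_t
                n_acc += 1
                traj.append((step, cur_cc, cur_bd.e_total))
                max_cc = max(max_cc, cur_cc)
                best_frames.append((cur_cc, cur_bd.e_total, cur.coords.copy()))

    tier = [f for f in best_frames if f[0] >= max_cc - schedule.cc_tier]
    cc_b, _, coords_b = min(tier, key=lambda f: f[1])
    out = cur.copy()
    out.coords = coords_b
    sim_b = render_surface(out, tip, grid=img)
    bd_b = total_energy(out, img, ref, w, tip, params, sim=sim_b)
    cc_b = cross_correlation(img, sim_b)
    converged = cc_b >= schedule.cc_floor
    if not converged:
        log.warning("dynamic_fit did not converge: final CC %.3f < floor %.3f",
                    cc_b, schedule.cc_floor)
    return FitResult(out, cc_b, bd_b,
                     pd.DataFrame(traj, columns=["step", "cc", "e_total"]),
                     seed, converged, n_acc, n_steps)


def validate_noise_ladder(truth: CGStructure, ss: SecondaryStructure,
                          levels=None, seeds=(0, 1, 2),
                          schedule: FitSchedule | None = None,
                          tip: TipModel | None = None,
                          perturb_deg: float = 20.0,
                          w: FitWeights | None = None) -> pd.DataFrame:
    """Fit statistics across a ladder of added-noise levels.

    Renders the ground truth once, adds percentage Gaussian noise at each
    level, refits from a perturbed start for every seed, and tabulates the
    mean and SD of the final cross-correlation against the fitted (noisy)
    image and of the backbone RMSD to the ground truth.
    """
    from .afm_sim import NOISE_LADDER, add_noise
    from .rna_cg import assemble_topology

    levels = list(NOISE_LADDER) if levels is None else list(levels)
    clean = render_surface(truth, tip)
    ideal_ref = ReferenceGeometry.from_structure(assemble_topology(ss, rng_seed=0), ss)
    rows = []
    for li, level in enumerate(levels):
        ccs, rmsds = [], []
        for si, sd in enumerate(seeds):
            noisy = add_noise(clean, level, rng_seed=1000 * li + sd)
            start = perturb_structure(truth, ss, perturb_deg, seed=sd)
            fit = dynamic_fit(start, noisy, ss, w=w, schedule=schedule, seed=sd,
                              tip=tip, ref=ideal_ref)
            ccs.append(fit.cc)
            rmsds.append(rmsd(fit.structure, truth))
        rows.append((level, np.mean(ccs), np.std(ccs), np.mean(rmsds), np.std(rmsds)))
    return pd.DataFrame(rows, columns=["noise_pct", "cc_mean", "cc_sd",
                                       "rmsd_mean", "rmsd_sd"])
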