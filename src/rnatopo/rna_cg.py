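"""Coarse-grained RNA model building.

Two beads per nucleotide (backbone "BB", base "BS"); duplex regions are
ideal A-form helices, unpaired regions are extensible bead chains.  The
builder places helices around junctions either from explicit per-helix
angles or from a seeded random draw, and guarantees a minimum non-bonded
separation between elements.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .config import BeadModel, HelixGeometry, DEFAULTS
from .errors import FormatError, GeometryError, ParseError, PseudoknotError

log = logging.getLogger(__name__)

ROLE_BACKBONE = 0
ROLE_BASE = 1

_OPEN = "([{<"
_CLOSE = ")]}>"


# --------------------------------------------------------------------------
# secondary structure
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondaryStructure:
    """Nested RNA secondary structure over one or more chains.

    ``pairs`` are 0-based (i, j) with i < j; ``helices`` partition the pairs
    into maximal stacks of consecutive pairs, ordered 5' to 3' by their
    outermost pair.  ``chain_breaks`` lists indices that start a new chain
    (for dimers); the default is a single chain.
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    helices: tuple[tuple[tuple[int, int], ...], ...]
    chain_breaks: tuple[int, ...] = (0,)

    @property
    def n_nt(self) -> int:
        return len(self.sequence)

    @property
    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    @property
    def unpaired(self) -> tuple[int, ...]:
        paired = set(self.partner)
        return tuple(i for i in range(self.n_nt) if i not in paired)

    def chain_of(self, nt: int) -> int:
        c = 0
        for k, start in enumerate(self.chain_breaks):
            if nt >= start:
                c = k
        return c

    def helix_span(self, helix_id: int) -> tuple[int, int]:
        """Sequence interval [i0, j0] closed by the helix's outermost pair."""
        (i0, j0) = self.helices[helix_id][0]
        return i0, j0

    @classmethod
    def from_pairs(cls, sequence: str, pairs, chain_breaks=(0,)) -> "SecondaryStructure":
        pairs = tuple(sorted((min(i, j), max(i, j)) for i, j in pairs))
        seen: set[int] = set()
        for i, j in pairs:
            if i == j or not (0 <= i < j < len(sequence)):
                raise ParseError(f"invalid pair ({i}, {j})")
            if i in seen or j in seen:
                raise ParseError(f"nucleotide in more than one pair: ({i}, {j})")
            seen.update((i, j))
        for (i1, j1) in pairs:
            for (i2, j2) in pairs:
                if i1 < i2 < j1 < j2:
                    raise PseudoknotError(
                        f"crossing pairs ({i1},{j1}) and ({i2},{j2}): pseudoknots unsupported")
        return cls(sequence=sequence, pairs=pairs, helices=_stack_helices(pairs),
                   chain_breaks=tuple(chain_breaks))


def _stack_helices(pairs) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Group sorted pairs into maximal stacks of consecutive pairs."""
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and p[0] == helices[-1][-1][0] + 1 and p[1] == helices[-1][-1][1] - 1:
            helices[-1].append(p)
        else:
            helices.append([p])
    return tuple(tuple(h) for h in helices)


def parse_dotbracket(db: str, seq: str) -> SecondaryStructure:
    """Parse a dot-bracket string against its sequence.

    Only nested structures are accepted; a second bracket layer that crosses
    the first (a pseudoknot) raises :class:`PseudoknotError`.
    """
    if len(db) != len(seq):
        raise ParseError(f"length mismatch: structure {len(db)} vs sequence {len(seq)}")
    bad = set(seq.upper()) - set("AUGCN")
    if bad:
        raise ParseError(f"non-RNA characters in sequence: {sorted(bad)}")
    stacks: dict[int, list[int]] = {k: [] for k in range(len(_OPEN))}
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(idx)
        elif ch in _CLOSE:
            layer = _CLOSE.index(ch)
            if not stacks[layer]:
                raise ParseError(f"unbalanced '{ch}' at position {idx}")
            pairs.append((stacks[layer].pop(), idx))
        else:
            raise ParseError(f"unexpected character {ch!r} at position {idx}")
    for layer, st in stacks.items():
        if st:
            raise ParseError(f"unbalanced '{_OPEN[layer]}' at position {st[-1]}")
    return SecondaryStructure.from_pairs(seq, pairs)


# --------------------------------------------------------------------------
# coarse-grained structure container
# --------------------------------------------------------------------------

@dataclass
class CGStructure:
    """Bead model: ordered beads, bonds, helix membership, chain ids.

    Beads are ordered by nucleotide, backbone before base, so bead
    ``2*k`` is the backbone and ``2*k + 1`` the base of nucleotide ``k``.
    """

    coords: np.ndarray                  # (n_beads, 3) float, A
    nt_index: np.ndarray                # (n_beads,) int
    role: np.ndarray                    # (n_beads,) 0 backbone / 1 base
    chain_id: np.ndarray                # (n_beads,) int
    helix_id: np.ndarray                # (n_beads,) int, -1 for none
    bonds: np.ndarray                   # (n_bonds, 2) int bead indices
    sequence: str = ""

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_nt(self) -> int:
        return int(self.nt_index.max()) + 1 if self.n_beads else 0

    @property
    def backbone_mask(self) -> np.ndarray:
        return self.role == ROLE_BACKBONE

    def copy(self) -> "CGStructure":
        return replace(self, coords=self.coords.copy())

    def translate(self, shift) -> "CGStructure":
        out = self.copy()
        out.coords = out.coords + np.asarray(shift, float)
        return out

    def rotate(self, R: np.ndarray, center=None) -> "CGStructure":
        out = self.copy()
        c = out.coords.mean(axis=0) if center is None else np.asarray(center, float)
        out.coords = (out.coords - c) @ np.asarray(R, float).T + c
        return out

    def bead_radii(self, beads: BeadModel | None = None) -> np.ndarray:
        b = beads or DEFAULTS.beads
        return np.where(self.role == ROLE_BACKBONE, b.radius_backbone, b.radius_base)

    def validate(self, beads: BeadModel | None = None) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")
        if self.n_beads != 2 * (self.n_nt if self.n_beads else 0):
            raise GeometryError("expected exactly 2 beads per nucleotide")
        if len(self.bonds):
            d = np.linalg.norm(self.coords[self.bonds[:, 0]] - self.coords[self.bonds[:, 1]], axis=1)
            if d.min() < 2.0 or d.max() > 12.0:
                raise GeometryError(
                    f"bonded distance outside [2, 12] A: min {d.min():.2f}, max {d.max():.2f}")


def _sequence_bonds(n_nt: int, chain_breaks: tuple[int, ...]) -> np.ndarray:
    """Backbone-backbone bonds along each chain plus backbone-base bonds."""
    starts = set(chain_breaks)
    bonds = []
    for k in range(n_nt):
        bonds.append((2 * k, 2 * k + 1))
        if k + 1 < n_nt and (k + 1) not in starts:
            bonds.append((2 * k, 2 * (k + 1)))
    return np.asarray(bonds, dtype=int)


# --------------------------------------------------------------------------
# ideal A-form helix
# --------------------------------------------------------------------------

def _helix_local(n_bp: int, geom: HelixGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Bead coordinates of an ideal duplex in its local frame (axis = +z).

    Returns (strand_a, strand_b), each (n_bp, 2, 3): backbone then base per
    base-pair level.  Strand A runs 5'->3' with increasing z; strand B is
    antiparallel.
    """
    twist = 2.0 * np.pi / geom.bp_per_turn
    phase = np.deg2rad(geom.strand_phase_deg)
    delta = np.deg2rad(geom.base_angle_offset_deg)
    k = np.arange(n_bp)
    theta = k * twist
    z = k * geom.rise

    def ring(angles, radius):
        return np.stack([radius * np.cos(angles), radius * np.sin(angles), z], axis=1)

    a = np.stack([ring(theta, geom.r_backbone), ring(theta + delta, geom.r_base)], axis=1)
    b = np.stack([ring(theta + phase, geom.r_backbone),
                  ring(theta + phase - delta, geom.r_base)], axis=1)
    return a, b


def _frame_from_axis(axis: np.ndarray, roll: float = 0.0) -> np.ndarray:
    """Rotation matrix sending local +z to ``axis`` with a roll about it."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise GeometryError("zero-length helix axis")
    w = axis / n
    ref = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    cr, sr = np.cos(roll), np.sin(roll)
    u, v = cr * u + sr * v, -sr * u + cr * v
    return np.stack([u, v, w], axis=1)


def build_aform_helix(n_bp: int, origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
                      roll: float = 0.0, sequence: str | None = None,
                      geom: HelixGeometry | None = None) -> CGStructure:
    """Build a standalone ideal A-form duplex of ``n_bp`` base pairs.

    The duplex is two antiparallel chains; strand A is 5'->3' along ``axis``.
    Defaults give ~11 bp/turn, ~30 A pitch and a ~25 A duplex width.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    geom = geom or DEFAULTS.helix
    a, b = _helix_local(n_bp, geom)
    R = _frame_from_axis(axis, roll)
    origin = np.asarray(origin, float)

    # chain A: bp 0..n-1; chain B antiparallel: its 5'->3' order is bp n-1..0
    coords = np.concatenate([a.reshape(-1, 3), b[::-1].reshape(-1, 3)], axis=0)
    coords = coords @ R.T + origin
    n_nt = 2 * n_bp
    if sequence is None:
        sequence = "G" * n_bp + "C" * n_bp
    nt = np.repeat(np.arange(n_nt), 2)
    role = np.tile([ROLE_BACKBONE, ROLE_BASE], n_nt)
    chain = np.repeat([0, 1], 2 * n_bp)
    pairs = [(k, 2 * n_bp - 1 - k) for k in range(n_bp)]
    cg = CGStructure(coords=coords, nt_index=nt, role=role, chain_id=chain,
                     helix_id=np.zeros(2 * n_nt, int),
                     bonds=_sequence_bonds(n_nt, (0, n_bp)), sequence=sequence)
    cg.pairs = tuple(pairs)   # convenience for energy setup on bare duplexes
    return cg


def _fit_cylinder_axis(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cylinder axis: direction and a point on the axis.

    PCA of the points initializes the direction; the fit then minimizes the
    spread of radial distances, which is exact for an ideal helix of any
    (non-integer) number of turns.
    """
    from scipy.optimize import least_squares

    center0 = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center0, full_matrices=False)
    w0 = vt[0]
    F = _frame_from_axis(w0)
    u0, v0 = F[:, 0], F[:, 1]

    def unpack(p):
        a, b, cu, cv = p
        w = w0 + a * u0 + b * v0
        w = w / np.linalg.norm(w)
        c = center0 + cu * u0 + cv * v0
        return w, c

    def resid(p):
        w, c = unpack(p)
        x = pts - c
        r = np.linalg.norm(x - np.outer(x @ w, w), axis=1)
        return r - r.mean()

    sol = least_squares(resid, np.zeros(4), method="lm")
    return unpack(sol.x)


def measure_helix(cg: CGStructure, helix_id: int = 0,
                  geom: HelixGeometry | None = None,
                  include_bead_radius: bool = True,
                  beads: BeadModel | None = None) -> tuple[float | None, float]:
    """Measure (pitch, width) of one helix from its backbone beads.

    The axis is the principal component of the backbone beads.  Pitch is the
    axial rise accumulated per 2*pi of unwrapped azimuth; it is ``None``
    (undefined) if the helix is shorter than one full turn.  Width is the
    duplex diameter: twice the maximal radial backbone distance from the
    axis, plus the backbone bead diameter when ``include_bead_radius`` —
    i.e. the surface-to-surface width an AFM tip senses.
    """
    beads = beads or DEFAULTS.beads
    mask = (cg.helix_id == helix_id) & cg.backbone_mask
    pts = cg.coords[mask]
    if len(pts) < 4:
        raise ValueError(f"helix {helix_id} has too few backbone beads")
    w, center = _fit_cylinder_axis(pts)
    x = pts - center
    axial = x @ w
    radial_vec = x - np.outer(axial, w)
    radial = np.linalg.norm(radial_vec, axis=1)
    width = 2.0 * radial.max()
    if include_bead_radius:
        width += 2.0 * beads.radius_backbone

    # accumulated twist along one strand
    chain0 = cg.chain_id[mask]
    strand = pts[chain0 == chain0[0]] - center
    if len(strand) < len(pts):                       # standalone duplex: use one chain
        sel = strand
    else:                                            # hairpin within one chain: first half
        sel = strand[: len(strand) // 2]
    ax = sel @ w
    order = np.argsort(ax)
    sel = sel[order]
    ax = ax[order]
    rv = sel - np.outer(sel @ w, w)
    u = _frame_from_axis(w)[:, 0]
    v = np.cross(w, u)
    phi = np.unwrap(np.arctan2(rv @ v, rv @ u))
    total_twist = abs(phi[-1] - phi[0])
    if total_twist < 2.0 * np.pi - 1e-9:
        return None, width
    pitch = 2.0 * np.pi * abs(ax[-1] - ax[0]) / total_twist
    return float(pitch), float(width)


# --------------------------------------------------------------------------
# topology tree and assembly
# --------------------------------------------------------------------------

@dataclass
class _Helix:
    hid: int
    pairs: tuple[tuple[int, int], ...]
    inner: list = field(default_factory=list)   # elements inside the innermost pair


@dataclass
class _Seg:
    nts: list[int]


def _build_tree(ss: SecondaryStructure) -> list:
    """Nested element list: top-level loop of _Seg and _Helix nodes."""
    helix_at = {h[0][0]: hid for hid, h in enumerate(ss.helices)}

    def walk(lo: int, hi: int) -> list:
        out: list = []
        seg: list[int] = []
        i = lo
        partner = ss.partner
        while i < hi:
            if i in helix_at and partner.get(i, -1) > i:
                if seg:
                    out.append(_Seg(seg))
                    seg = []
                hid = helix_at[i]
                hp = ss.helices[hid]
                node = _Helix(hid, hp)
                (ii, jj) = hp[-1]
                node.inner = walk(ii + 1, jj)
                out.append(node)
                i = hp[0][1] + 1
            else:
                seg.append(i)
                i += 1
        if seg:
            out.append(_Seg(seg))
        return out

    return walk(0, ss.n_nt)


def _bridge(p0: np.ndarray, p1: np.ndarray, n: int, bulge_dir: np.ndarray,
            beads: BeadModel) -> np.ndarray:
    """Positions for ``n`` linker nucleotides spanning p0 -> p1.

    Beads sit on a circular-arc-like path bulging toward ``bulge_dir`` so
    that adjacent spacing stays near the relaxed link step; raises
    :class:`GeometryError` if the anchors are too far apart to span.
    """
    from scipy.optimize import brentq

    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    span = np.linalg.norm(p1 - p0)
    max_span = (n + 1) * beads.link_max
    if span > max_span:
        raise GeometryError(
            f"linker of {n} nt cannot span {span:.1f} A (max {max_span:.1f} A)")
    contour = (n + 1) * beads.link_step
    bd = np.asarray(bulge_dir, float)

    if span >= contour * 0.999:
        t = np.linspace(0.0, 1.0, n + 2)[1:-1]
        return p0[None, :] + t[:, None] * (p1 - p0)[None, :]

    # circular arc from p0 to p1 with arc length = relaxed contour length,
    # bulging toward bulge_dir; beads at equal arc spacing
    if span > 1e-6:
        ex = (p1 - p0) / span
    else:
        ex = _frame_from_axis(bd if np.linalg.norm(bd) > 1e-9
                              else np.array([0.0, 0.0, 1.0]))[:, 0]
    ey = bd - (bd @ ex) * ex
    ny = np.linalg.norm(ey)
    ey = ey / ny if ny > 1e-9 else _frame_from_axis(ex)[:, 0]

    ratio = max(span / contour, 1e-6)
    theta = brentq(lambda th: np.sin(th / 2.0) / (th / 2.0) - ratio,
                   1e-9, 2.0 * np.pi - 1e-9)
    R = contour / theta
    mid = 0.5 * (p0 + p1)
    C = mid - R * np.cos(theta / 2.0) * ey
    phi = np.linspace(-theta / 2.0, theta / 2.0, n + 2)[1:-1]
    return C[None, :] + R * (np.sin(phi)[:, None] * ex[None, :]
                             + np.cos(phi)[:, None] * ey[None, :])


def _nt_block(cg_rows: dict, nt: int, bb: np.ndarray, bs: np.ndarray,
              chain: int, hid: int) -> None:
    cg_rows[nt] = (bb, bs, chain, hid)


def assemble_topology(ss: SecondaryStructure,
                      junction_geometry: dict[int, tuple[float, float, float]] | None = None,
                      rng_seed: int | None = 0,
                      geom: HelixGeometry | None = None,
                      beads: BeadModel | None = None,
                      max_retries: int = 50) -> CGStructure:
    """Realize a secondary structure as a 3D coarse-grained model.

    Each helix is an ideal A-form duplex; unpaired runs are extensible bead
    chains.  Helix directions come from ``junction_geometry`` — a mapping
    ``helix_id -> (polar_deg, azimuth_deg, roll_deg)`` relative to the
    incoming strand direction — or are drawn from the seeded RNG.  Builds
    are retried with fresh substreams until no two non-bonded beads sit
    closer than the clash distance.
    """
    geom = geom or DEFAULTS.helix
    beads = beads or DEFAULTS.beads
    master = np.random.default_rng(rng_seed)
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(master.integers(2**31)) if rng_seed is not None \
            else np.random.default_rng()
        try:
            cg = _assemble_once(ss, junction_geometry, rng, geom, beads)
        except GeometryError as e:
            if junction_geometry is not None and attempt == 0:
                raise            # explicit geometry: fail loudly, do not resample
            last_err = e
            continue
        if _min_nonbonded_distance(cg, ss) >= beads.clash_distance:
            cg.validate(beads)
            return cg
        if junction_geometry is not None:
            # explicit geometry that clashes is a caller error only if fully specified;
            # partially specified junctions may still be resampled
            if all(hid in junction_geometry for hid in range(len(ss.helices))):
                raise GeometryError("declared junction geometry produces steric clashes")
        last_err = GeometryError("clash between non-bonded beads")
    raise GeometryError(f"could not assemble clash-free structure: {last_err}")


def _assemble_once(ss, junction_geometry, rng, geom, beads) -> CGStructure:
    junction_geometry = junction_geometry or {}
    rows: dict[int, tuple[np.ndarray, np.ndarray, int, int]] = {}
    tree = _build_tree(ss)

    def draw_direction(node, d):
        """Helix axis direction relative to the incoming strand direction."""
        explicit_roll = None
        if node.hid in junction_geometry:
            polar, azim, roll = (np.deg2rad(a) for a in junction_geometry[node.hid])
            explicit_roll = roll
        else:
            polar = np.deg2rad(rng.uniform(30.0, 120.0))
            azim = rng.uniform(0.0, 2.0 * np.pi)
        F = _frame_from_axis(d)
        u, v, w = F[:, 0], F[:, 1], F[:, 2]
        hd = np.cos(polar) * w + np.sin(polar) * (np.cos(azim) * u + np.sin(azim) * v)
        return hd, explicit_roll

    def ensure_pose(node: _Helix, from_pos):
        """Fix the helix's rigid transform; roll (unless declared) orients
        the strand-A entry bead toward where the strand arrives from."""
        if hasattr(node, "_R"):
            return
        hd, explicit_roll = node._pose
        a, b = _helix_local(len(node.pairs), geom)
        if explicit_roll is None:
            want = np.asarray(from_pos, float) - node._axis_base
            want_p = want - (want @ hd) * hd
            if np.linalg.norm(want_p) > 1e-9:
                wp = want_p / np.linalg.norm(want_p)
                F = _frame_from_axis(hd)
                roll = np.arctan2(wp @ F[:, 1], wp @ F[:, 0])
            else:
                roll = 0.0
        else:
            roll = explicit_roll
        node._R = _frame_from_axis(hd, roll)
        node._entry_bead = node._axis_base + node._R @ a[0, 0]
        node._exit_bead = node._axis_base + node._R @ b[0, 0]

    def place_helix(node: _Helix):
        hd = node._pose[0]
        n_bp = len(node.pairs)
        a, b = _helix_local(n_bp, geom)
        R = node._R
        t = node._axis_base
        ag = a @ R.T + t
        bg = b @ R.T + t
        for lvl, (i, j) in enumerate(node.pairs):
            rows[i] = (ag[lvl, 0], ag[lvl, 1], ss.chain_of(i), node.hid)
            rows[j] = (bg[lvl, 0], bg[lvl, 1], ss.chain_of(j), node.hid)
        if node.inner:
            inner_return = bg[n_bp - 1, 0]
            place_loop(node.inner, ag[n_bp - 1, 0], hd, inner_return,
                       parent_axis=hd,
                       parent_inner_mid=t + hd * (n_bp - 1) * geom.rise)
        return bg[0, 0]     # exit bead position (strand-B outer backbone)

    def place_loop(elements, start_point, direction, end_anchor,
                   parent_axis=None, parent_inner_mid=None):
        """Lay out one loop: hairpins bridge directly; junctions use a star
        layout around a junction point so the strand can always close."""
        d = np.asarray(direction, float)
        pos = np.asarray(start_point, float)
        helix_nodes = [e for e in elements if isinstance(e, _Helix)]

        if not helix_nodes:
            # hairpin loop or plain tail
            seg = elements[0] if elements else _Seg([])
            if end_anchor is not None:
                pts = _bridge(pos, end_anchor, len(seg.nts), d, beads)
                for ntd, p in zip(seg.nts, pts):
                    _place_linker_nt(rows, ntd, p, d, ss, beads)
            else:
                for ntd in seg.nts:
                    pos = pos + d * beads.link_step
                    _place_linker_nt(rows, ntd, pos, d, ss, beads)
            return

        # star layout: helix axes emanate from a junction point just past
        # the loop opening, so the strand can always wrap around and close
        if parent_inner_mid is not None:
            J = parent_inner_mid + parent_axis * (beads.link_step + 2.0)
        else:
            J = pos + d * beads.link_step
        for node in helix_nodes:
            hd, explicit_roll = draw_direction(node, parent_axis if parent_axis is not None else d)
            node._pose = (hd, explicit_roll)
            node._axis_base = J + hd * beads.link_step

        def outward_dir(node, at_point):
            """Direction leading away from a helix end, for dangling tails."""
            hd = node._pose[0]
            ax_pt = node._axis_base + ((at_point - node._axis_base) @ hd) * hd
            er = at_point - ax_pt
            nr = np.linalg.norm(er)
            er = er / nr if nr > 1e-9 else _frame_from_axis(hd)[:, 0]
            v = -hd + er
            return v / np.linalg.norm(v)

        n_elem = len(elements)
        for idx, el in enumerate(elements):
            if isinstance(el, _Helix):
                ensure_pose(el, pos)
                exit_pos = place_helix(el)
                nxt_target = _next_attachment(elements, idx, end_anchor, pos, d)
                if nxt_target is None:
                    d = outward_dir(el, exit_pos)
                else:
                    dn = nxt_target - exit_pos
                    nd = np.linalg.norm(dn)
                    d = dn / nd if nd > 1e-9 else d
                pos = exit_pos
            else:
                nxt = elements[idx + 1] if idx + 1 < n_elem else None
                if isinstance(nxt, _Helix) and idx == 0 and end_anchor is None:
                    # leading 5' tail: anchor it to the helix entry, outward
                    ensure_pose(nxt, pos)
                    td = outward_dir(nxt, nxt._entry_bead)
                    m = len(el.nts)
                    for k, ntd in enumerate(el.nts):
                        p = nxt._entry_bead + td * beads.link_step * (m - k)
                        _place_linker_nt(rows, ntd, p, td, ss, beads)
                    pos = nxt._entry_bead
                elif isinstance(nxt, _Helix):
                    ensure_pose(nxt, pos)
                    pts = _bridge(pos, nxt._entry_bead, len(el.nts), d, beads)
                    for ntd, p in zip(el.nts, pts):
                        _place_linker_nt(rows, ntd, p, d, ss, beads)
                    pos = nxt._entry_bead
                elif end_anchor is not None:
                    pts = _bridge(pos, end_anchor, len(el.nts), d, beads)
                    for ntd, p in zip(el.nts, pts):
                        _place_linker_nt(rows, ntd, p, d, ss, beads)
                    pos = np.asarray(end_anchor, float)
                else:
                    for ntd in el.nts:
                        pos = pos + d * beads.link_step
                        _place_linker_nt(rows, ntd, pos, d, ss, beads)

    def _next_attachment(elements, idx, end_anchor, pos, d):
        """Where the strand goes after the helix at ``idx``."""
        for el in elements[idx + 1:]:
            if isinstance(el, _Helix):
                return el._axis_base
        if end_anchor is not None:
            return np.asarray(end_anchor, float)
        return None

    origin = np.zeros(3)
    place_loop(tree, origin, np.array([1.0, 0.0, 0.0]), None)

    if len(rows) != ss.n_nt:
        raise GeometryError("assembly did not place every nucleotide")
    n_nt = ss.n_nt
    coords = np.empty((2 * n_nt, 3))
    chain = np.empty(2 * n_nt, int)
    hel = np.empty(2 * n_nt, int)
    for nt in range(n_nt):
        bb, bs, c, h = rows[nt]
        coords[2 * nt] = bb
        coords[2 * nt + 1] = bs
        chain[2 * nt:2 * nt + 2] = c
        hel[2 * nt:2 * nt + 2] = h
    nt_idx = np.repeat(np.arange(n_nt), 2)
    role = np.tile([ROLE_BACKBONE, ROLE_BASE], n_nt)
    return CGStructure(coords=coords, nt_index=nt_idx, role=role, chain_id=chain,
                       helix_id=hel, bonds=_sequence_bonds(n_nt, ss.chain_breaks),
                       sequence=ss.sequence)


def _place_linker_nt(rows, nt, pos, d, ss, beads) -> None:
    side = _frame_from_axis(d)[:, 0]
    rows[nt] = (pos, pos + side * 3.5, ss.chain_of(nt), -1)


def junction_contact_sets(ss: SecondaryStructure) -> list[set[int]]:
    """Nucleotide sets that meet at one loop and may legitimately touch.

    Each set holds the loop's unpaired nucleotides plus the two terminal
    base pairs of every helix flanking that loop (coaxial helix ends stack
    against each other in folded RNA, so these contacts are not clashes).
    """
    sets: list[set[int]] = []

    def helix_end_nts(hid: int, inner: bool) -> set[int]:
        hp = ss.helices[hid]
        levels = hp[-3:] if inner else hp[:3]
        out: set[int] = set()
        for i, j in levels:
            out.update((i, j))
        return out

    def walk(elements, parent_hid):
        s: set[int] = set()
        if parent_hid is not None:
            s |= helix_end_nts(parent_hid, inner=True)
        for el in elements:
            if isinstance(el, _Seg):
                s.update(el.nts)
            else:
                s |= helix_end_nts(el.hid, inner=False)
                walk(el.inner, el.hid)
        sets.append(s)

    walk(_build_tree(ss), None)
    return sets


def interaction_exclusion(cg: CGStructure, ss: SecondaryStructure) -> np.ndarray:
    """Boolean (n_beads, n_beads) matrix of bead pairs whose proximity is
    structural (bonded, sequence-local, intra-helix, paired, or meeting at
    one loop) rather than a steric clash."""
    n = cg.n_beads
    excl = np.zeros((n, n), bool)
    nt = cg.nt_index
    same_chain = cg.chain_id[:, None] == cg.chain_id[None, :]
    excl |= same_chain & (np.abs(nt[:, None] - nt[None, :]) <= 3)
    hel = cg.helix_id
    excl |= (hel[:, None] == hel[None, :]) & (hel[:, None] >= 0)
    pair_excl = np.zeros((ss.n_nt, ss.n_nt), bool)
    for i, j in ss.pairs:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                a, b = i + di, j + dj
                if 0 <= a < ss.n_nt and 0 <= b < ss.n_nt:
                    pair_excl[a, b] = pair_excl[b, a] = True
    for s in junction_contact_sets(ss):
        idx = sorted(s)
        for a in idx:
            for b in idx:
                pair_excl[a, b] = True
    excl |= pair_excl[nt[:, None], nt[None, :]]
    return excl


def _min_nonbonded_distance(cg: CGStructure, ss: SecondaryStructure) -> float:
    """Smallest bead separation outside the structural-contact exclusions."""
    n = cg.n_beads
    if n < 4:
        return np.inf
    d = np.linalg.norm(cg.coords[:, None, :] - cg.coords[None, :, :], axis=2)
    iu = np.triu_indices(n, k=1)
    keep = ~interaction_exclusion(cg, ss)[iu]
    dd = d[iu]
    return float(dd[keep].min()) if keep.any() else np.inf


# --------------------------------------------------------------------------
# helix subtrees (used by the fitting move set)
# --------------------------------------------------------------------------

def helix_subtree(ss: SecondaryStructure, cg: CGStructure, helix_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Bead indices of a helix arm plus everything nested inside it,
    and the pivot point (midpoint of the outermost pair's backbone beads)."""
    i0, j0 = ss.helix_span(helix_id)
    mask = (cg.nt_index >= i0) & (cg.nt_index <= j0)
    idx = np.nonzero(mask)[0]
    pivot = 0.5 * (cg.coords[2 * i0] + cg.coords[2 * j0])
    return idx, pivot


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def write_pdb_cg(cg: CGStructure, path: str | Path) -> None:
    """Write the bead model as PDB ATOM records (names BB / BS)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = cg.n_beads
    arr = struc.AtomArray(n)
    arr.coord = cg.coords.astype(np.float32)
    seq = cg.sequence or "N" * cg.n_nt
    arr.atom_name = np.where(cg.role == ROLE_BACKBONE, "BB", "BS")
    arr.res_id = cg.nt_index + 1
    arr.res_name = np.array([seq[i] if i < len(seq) else "N" for i in cg.nt_index])
    arr.chain_id = np.array([_CHAIN_IDS[c % 26] for c in cg.chain_id])
    arr.element = np.where(cg.role == ROLE_BACKBONE, "P", "C")
    arr.hetero = np.zeros(n, bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


_BASE_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}
_NUC_NAMES = {"A", "U", "G", "C", "RA", "RU", "RG", "RC", "ADE", "URA", "GUA", "CYT"}


def read_pdb_cg(path: str | Path) -> CGStructure:
    """Read a PDB file as a bead model.

    Files written by :func:`write_pdb_cg` (atom names BB/BS) round-trip
    exactly at PDB precision.  All-atom nucleic files are reduced to two
    beads per nucleotide: P -> backbone (C4' fallback, with a warning) and
    the glycosidic nitrogen (or base-atom centroid) -> base.  Non-nucleic
    chains are skipped with a log message.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    text = path.read_text()
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise FormatError(f"no ATOM records in {path}")
    arr = PDBFile.read(str(path)).get_structure(model=1)

    names = set(arr.atom_name)
    if names <= {"BB", "BS"}:
        return _from_bead_array(arr)
    return _reduce_all_atom(arr)


def _from_bead_array(arr) -> CGStructure:
    order = np.lexsort((arr.atom_name != "BB", arr.res_id,
                        np.unique(arr.chain_id, return_inverse=True)[1]))
    arr = arr[order]
    chains = {c: k for k, c in enumerate(dict.fromkeys(arr.chain_id))}
    chain = np.array([chains[c] for c in arr.chain_id])
    key = chain * 10**6 + arr.res_id
    nt = np.unique(key, return_inverse=True)[1]
    role = np.where(arr.atom_name == "BB", ROLE_BACKBONE, ROLE_BASE)
    seq_map = {}
    for k, r in zip(nt, arr.res_name):
        seq_map[int(k)] = r[-1] if r[-1] in "AUGC" else "N"
    seq = "".join(seq_map[k] for k in sorted(seq_map))
    breaks = tuple(int(nt[np.argmax(chain == c)]) for c in sorted(set(chain)))
    return CGStructure(coords=arr.coord.astype(float), nt_index=nt, role=role,
                       chain_id=chain, helix_id=np.full(len(nt), -1),
                       bonds=_sequence_bonds(int(nt.max()) + 1, breaks), sequence=seq)


def _reduce_all_atom(arr) -> CGStructure:
    rows = []
    seq = []
    warned_p = False
    chain_ids = list(dict.fromkeys(arr.chain_id))
    breaks = [0]
    nt_counter = 0
    for ci, ch in enumerate(chain_ids):
        sub = arr[arr.chain_id == ch]
        res_ids = list(dict.fromkeys(sub.res_id))
        first = sub.res_name[0].strip()
        if first not in _NUC_NAMES:
            log.info("skipping non-nucleic chain %s (%s)", ch, first)
            continue
        if rows:
            breaks.append(nt_counter)
        for rid in res_ids:
            res = sub[sub.res_id == rid]
            rname = res.res_name[0].strip()
            letter = rname[-1] if rname[-1] in "AUGC" else "N"
            p = res.coord[res.atom_name == "P"]
            if len(p) == 0:
                p = res.coord[res.atom_name == "C4'"]
                if len(p) and not warned_p:
                    warnings.warn("missing P atoms; using C4' as backbone bead")
                    warned_p = True
            if len(p) == 0:
                continue
            bn = _BASE_N.get(letter)
            base = res.coord[res.atom_name == bn] if bn else np.empty((0, 3))
            if len(base) == 0:
                base_atoms = res.coord[np.isin(res.atom_name,
                                               ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"])]
                if len(base_atoms) == 0:
                    continue
                base = base_atoms.mean(axis=0, keepdims=True)
            rows.append((p[0], base[0], ci))
            seq.append(letter)
            nt_counter += 1
    if not rows:
        raise FormatError("no nucleic residues found")
    n_nt = len(rows)
    coords = np.empty((2 * n_nt, 3))
    chain = np.empty(2 * n_nt, int)
    for k, (p, b, ci) in enumerate(rows):
        coords[2 * k] = p
        coords[2 * k + 1] = b
        chain[2 * k:2 * k + 2] = ci
    return CGStructure(coords=coords, nt_index=np.repeat(np.arange(n_nt), 2),
                       role=np.tile([ROLE_BACKBONE, ROLE_BASE], n_nt),
                       chain_id=chain, helix_id=np.full(2 * n_nt, -1),
                       bonds=_sequence_bonds(n_nt, tuple(breaks)), sequence="".join(seq))
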