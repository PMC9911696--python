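"""Ground-truth generators for every pipeline stage.

Phantoms are multi-helix junction RNAs with known coordinates, rendered
into noisy AFM ladders, mixed into SAXS ensembles of known volume
fractions, and turned into two-component ITC thermograms.  Everything is
seeded and parameterized through a manifest so a scenario regenerates
bit-identically.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import afm_sim, itc, rna_cg, saxs
from .afm_sim import AFMImage, TipModel, NOISE_LADDER
from .errors import RnatopoError
from .itc import InjectionSchedule, Thermogram
from .rna_cg import CGStructure, SecondaryStructure


# --------------------------------------------------------------------------
# phantom structures
# --------------------------------------------------------------------------

def three_way_dotbracket(stem: int = 8, arm: int = 12, loop: int = 4,
                         link: int = 2, tail: int = 3) -> str:
    """Dot-bracket of a three-way-junction RNA: a closing stem and two
    hairpin arms joined by short junction linkers."""
    hp = "(" * arm + "." * loop + ")" * arm
    return ("." * tail + "(" * stem + "." * link + hp + "." * link + hp
            + "." * link + ")" * stem + "." * tail)


# per-helix (polar, azimuth, roll) degrees relative to the incoming strand;
# angles picked so each preset is clash-free and the three shapes are
# mutually distinct (pairwise backbone RMSD > 10 A at the default size)
JUNCTION_PRESETS: dict[str, dict[int, tuple[float, float, float]]] = {
    "Y": {0: (0, 0, 0), 1: (100, 90, 0), 2: (100, 270, 0)},
    "candy": {0: (0, 0, 0), 1: (30, 90, 0), 2: (100, 270, 0)},
    "compact": {0: (0, 0, 0), 1: (50, 60, 0), 2: (50, 300, 0)},
}


@dataclass
class PhantomSpec:
    """Recipe for a ground-truth phantom structure."""

    name: str = "phantom"
    preset: str = "Y"                    # key of JUNCTION_PRESETS or "random"
    stem: int = 8
    arm: int = 12
    loop: int = 4
    link: int = 2
    tail: int = 3
    chain_count: int = 1                 # 2 = dimer with a kissing-loop contact
    seed: int = 0

    def dotbracket(self) -> str:
        return three_way_dotbracket(self.stem, self.arm, self.loop,
                                    self.link, self.tail)

    def sequence(self) -> str:
        db = self.dotbracket()
        # alternating-purine filler; pairing identity is not used downstream
        return ("GC" * (len(db) // 2 + 1))[: len(db)]


def secondary_structure(spec: PhantomSpec) -> SecondaryStructure:
    return rna_cg.parse_dotbracket(spec.dotbracket(), spec.sequence())


def make_phantom(spec: PhantomSpec) -> CGStructure:
    """Deterministic ground-truth structure for a phantom spec.

    Presets yield visually distinct topologies; ``"random"`` draws the
    junction geometry from the spec seed.  ``chain_count == 2`` builds a
    dimer: two copies facing each other with their second-arm hairpin
    loops in contact (an intermolecular kissing-loop arrangement); the
    contact pairs are attached as ``cg.kissing_pairs``.
    """
    ss = secondary_structure(spec)
    if spec.preset == "random":
        jg = None
    elif spec.preset in JUNCTION_PRESETS:
        jg = JUNCTION_PRESETS[spec.preset]
    else:
        raise RnatopoError(f"unknown preset {spec.preset!r}")
    mono = rna_cg.assemble_topology(ss, junction_geometry=jg, rng_seed=spec.seed)
    if spec.chain_count == 1:
        return mono
    if spec.chain_count != 2:
        raise RnatopoError("chain_count must be 1 or 2")
    return _make_dimer(spec, ss, mono)


def _loop_nts(spec: PhantomSpec, which: int) -> np.ndarray:
    """Nucleotide indices of the ``which``-th hairpin loop (0 or 1)."""
    db = spec.dotbracket()
    loops = []
    run = []
    for i, ch in enumerate(db):
        if ch == ".":
            run.append(i)
        else:
            if run and 0 < i < len(db) and db[run[0] - 1] == "(" and ch == ")":
                loops.append(run)
            run = []
    return np.asarray(loops[which])


def _make_dimer(spec: PhantomSpec, ss: SecondaryStructure,
                mono: CGStructure) -> CGStructure:
    n = ss.n_nt
    loop_a = _loop_nts(spec, 1)          # second arm's loop on each monomer
    other = mono.copy()
    # face the copy toward the first: rotate 180 deg about z then translate
    Rz = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    other = other.rotate(Rz)
    ca = mono.coords[2 * loop_a].mean(axis=0)
    cb = other.coords[2 * loop_a].mean(axis=0)
    gap_dir = np.array([1.0, 0.0, 0.0])
    other = other.translate(ca - cb + 10.0 * gap_dir)
    coords = np.vstack([mono.coords, other.coords])
    cg = CGStructure(
        coords=coords,
        nt_index=np.concatenate([mono.nt_index, other.nt_index + n]),
        role=np.concatenate([mono.role, other.role]),
        chain_id=np.concatenate([np.zeros(mono.n_beads, int), np.ones(other.n_beads, int)]),
        helix_id=np.concatenate([mono.helix_id,
                                 np.where(other.helix_id >= 0,
                                          other.helix_id + len(ss.helices), -1)]),
        bonds=np.vstack([mono.bonds, other.bonds + mono.n_beads]),
        sequence=spec.sequence() * 2,
    )
    mid = len(loop_a) // 2
    cg.kissing_pairs = [(int(loop_a[mid]), int(n + loop_a[mid]))]
    return cg


# --------------------------------------------------------------------------
# AFM ladders
# --------------------------------------------------------------------------

def make_afm_ladder(cg: CGStructure, tip: TipModel | None = None,
                    levels=NOISE_LADDER, seed: int = 0,
                    pixel_size: float | None = None) -> tuple[AFMImage, dict[int, AFMImage]]:
    """Render once, then emit one noisy copy per ladder level.

    Returns (clean image, {level: noisy image}); the per-level noise seeds
    derive deterministically from ``seed``.
    """
    clean = afm_sim.render_surface(cg, tip, pixel_size=pixel_size)
    out = {}
    for li, level in enumerate(levels):
        out[level] = afm_sim.add_noise(clean, level, rng_seed=seed * 1000 + li)
    return clean, out


# --------------------------------------------------------------------------
# SAXS mixtures
# --------------------------------------------------------------------------

def make_saxs_mixture(structures: list[CGStructure], fractions,
                      rel_noise: float = 0.01, floor: float = 1e-4,
                      seed: int = 0, q_grid=None):
    """Per-structure Debye curves plus a noisy mixed "experimental" curve.

    The error model is sigma(q) = rel_noise * sqrt(I(q) * I(0)) + floor * I(0)
    (counting-statistics-like, with a constant floor); Gaussian noise of
    exactly that sigma perturbs the mixture, so the truth-vs-mixture
    reduced chi-square is ~1 by construction.
    """
    fractions = np.asarray(fractions, float)
    curves = [saxs.debye_profile(s, q_grid=q_grid) for s in structures]
    mix = saxs.synthesize_ensemble(curves, fractions)
    i0 = float(mix.I.max())
    sigma = rel_noise * np.sqrt(np.maximum(mix.I, 0.0) * i0) + floor * i0
    rng = np.random.default_rng(seed)
    noisy = mix.I + rng.normal(0.0, sigma)
    expt = saxs.SAXSProfile(mix.q, noisy, sigma)
    return curves, mix, expt


# --------------------------------------------------------------------------
# ITC thermograms
# --------------------------------------------------------------------------

DEFAULT_ITC_COMPONENTS = {
    # an exothermic 1:1 binding event ...
    "exothermic": {"model": "one_site", "N": 1.0, "Kd": 1e-6, "dH": -10.0},
    # ... plus an endothermic-then-exothermic two-site event
    "endo_exo": {"model": "two_site", "N1": 0.5, "Kd1": 1e-7, "dH1": 5.0,
                 "N2": 0.5, "Kd2": 1e-5, "dH2": -8.0},
}


def make_itc_two_component(components: dict | None = None,
                           weights=(0.7, 0.2), snr: float = 20.0,
                           schedule: InjectionSchedule | None = None,
                           m_samples: int = 120, dt: float = 1.0,
                           seed: int = 0):
    """Two-component thermogram: distinct pulse shapes, known heats.

    Each component contributes a rank-1 term: its per-injection heats (from
    its binding model) scale a fixed Gaussian power-pulse time profile
    whose center/width differ per component, so the components are
    separable by SVD.  White noise is added at the requested SNR (RMS
    signal over noise sigma); ``snr=None`` or ``inf`` leaves it noiseless.

    Returns (Thermogram, ground_truth dict).
    """
    schedule = schedule or InjectionSchedule(cell_conc=70e-6, syringe_conc=700e-6)
    components = components or DEFAULT_ITC_COMPONENTS
    names = list(components)
    if len(names) != len(weights):
        raise ValueError("one weight per component required")
    t = np.arange(m_samples) * dt
    pulse_params = [(0.30 * m_samples * dt, 0.07 * m_samples * dt),
                    (0.50 * m_samples * dt, 0.12 * m_samples * dt)]
    M = np.zeros((m_samples, schedule.n_injections))
    truth = {"weights": list(weights), "components": {}, "heats": {}}
    for k, (name, w) in enumerate(zip(names, weights)):
        comp = components[name]
        if comp["model"] == "one_site":
            heats = itc.one_site_heats(schedule, comp["N"], comp["Kd"], comp["dH"])
        elif comp["model"] == "two_site":
            heats = itc.two_site_heats(schedule, comp["N1"], comp["Kd1"], comp["dH1"],
                                       comp["N2"], comp["Kd2"], comp["dH2"])
        else:
            raise ValueError(f"unknown component model {comp['model']!r}")
        center, width = pulse_params[k % len(pulse_params)]
        g = np.exp(-0.5 * ((t - center) / width) ** 2)
        g /= np.trapezoid(g, t)          # unit area: column integral = heat
        moles = schedule.syringe_conc * schedule.volumes
        M += w * np.outer(g, heats * moles)
        truth["components"][name] = dict(comp)
        truth["heats"][name] = (w * heats).tolist()
    if snr is not None and np.isfinite(snr) and M.any():
        rms = float(np.sqrt(np.mean(M ** 2)))
        rng = np.random.default_rng(seed)
        M = M + rng.normal(0.0, rms / snr, size=M.shape)
    return Thermogram(M, dt, schedule), truth


# --------------------------------------------------------------------------
# full scenario bundles
# --------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """Everything one end-to-end validation needs, plus its manifest."""

    phantoms: dict[str, CGStructure]
    clean_image: AFMImage
    noisy_images: dict[int, AFMImage]
    saxs_curves: list
    saxs_mixture_truth: object
    saxs_expt: object
    itc_thermogram: Thermogram
    itc_truth: dict
    manifest: dict

    def digest(self) -> str:
        """Hash of all numeric content (regeneration check)."""
        h = hashlib.sha256()
        for name in sorted(self.phantoms):
            h.update(self.phantoms[name].coords.tobytes())
        h.update(self.clean_image.heights.tobytes())
        for lvl in sorted(self.noisy_images):
            h.update(self.noisy_images[lvl].heights.tobytes())
        for c in self.saxs_curves:
            h.update(c.I.tobytes())
        h.update(self.saxs_expt.I.tobytes())
        h.update(self.itc_thermogram.M.tobytes())
        return h.hexdigest()


def make_scenario(seed: int = 0, fractions=(0.2, 0.3, 0.5),
                  noise_levels=NOISE_LADDER) -> ScenarioBundle:
    """Generate the full validation scenario from one seed."""
    manifest = {
        "seed": int(seed),
        "fractions": list(map(float, fractions)),
        "noise_levels": list(noise_levels),
        "presets": list(JUNCTION_PRESETS),
        "phantom": asdict(PhantomSpec()),
    }
    phantoms = {name: make_phantom(PhantomSpec(name=name, preset=name, seed=seed))
                for name in JUNCTION_PRESETS}
    truth = phantoms["Y"]
    clean, noisy = make_afm_ladder(truth, seed=seed, levels=noise_levels)
    curves, mix, expt = make_saxs_mixture(list(phantoms.values()), fractions, seed=seed)
    thermo, itc_truth = make_itc_two_component(seed=seed)
    return ScenarioBundle(phantoms, clean, noisy, curves, mix, expt,
                          thermo, itc_truth, manifest)


def regenerate(manifest: dict) -> ScenarioBundle:
    """Rebuild a scenario bit-identically from its manifest."""
    return make_scenario(seed=manifest["seed"],
                         fractions=manifest["fractions"],
                         noise_levels=manifest["noise_levels"])
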