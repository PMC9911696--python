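"""Geometry, energy and analysis defaults, overridable from YAML.

All length units are Angstrom unless a field name says otherwise; energies
are in units of kBT.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class HelixGeometry:
    """Canonical A-form double-helix constants for the two-bead model.

    ``bp_per_turn`` and ``rise`` give the ~30 A pitch of A-form RNA;
    ``r_backbone`` plus the backbone bead radius gives the ~25 A duplex
    width sensed by an AFM tip.
    """

    bp_per_turn: float = 11.0
    rise: float = 2.73               # A per base pair
    r_backbone: float = 8.5          # radial distance of backbone beads from axis
    r_base: float = 2.5              # radial distance of base beads
    base_angle_offset_deg: float = 40.0   # azimuth of base bead relative to its backbone
    strand_phase_deg: float = 255.0  # azimuthal offset of the second strand (sets groove widths)


@dataclass
class BeadModel:
    radius_backbone: float = 4.0     # rendering radius, A
    radius_base: float = 3.5
    link_step: float = 6.0           # relaxed spacing of linker backbone beads
    link_max: float = 7.0            # maximum extension of one linker segment
    clash_distance: float = 6.0      # minimum allowed non-bonded bead separation


@dataclass
class EnergyParams:
    """Force constants (kBT-based) for the coarse-grained energy terms."""

    k_length: float = 5.0            # kBT / A^2
    k_angle_helix: float = 10.0      # kBT / rad^2
    k_angle_linker: float = 0.05
    k_dih_helix: float = 2.0
    k_dih_linker: float = 0.0
    k_pairing: float = 2.0           # flat-bottom well depth scale
    k_stacking: float = 2.0
    well_width: float = 0.5          # flat-bottom half-width, A
    k_repulsion: float = 20.0        # soft-core prefactor
    repulsion_cutoff: float = 6.0
    softcore_alpha: float = 0.01
    k_electrostatic: float = 0.2     # screened-charge prefactor, kBT*A
    debye_length: float = 10.0
    electrostatic_cutoff: float = 30.0


@dataclass
class FitWeights:
    """Scaling factors of the total-energy objective.

    ``theta_afm`` multiplies the image pseudopotential V = theta*N*kBT*(1-CC);
    ``theta_c`` the covalent sum; the remaining thetas the noncovalent terms.
    """

    theta_afm: float = 3.0
    theta_c: float = 1.0
    theta_stacking: float = 1.0
    theta_pairing: float = 1.0
    theta_contact: float = 0.5
    kBT: float = 1.0

    def validate(self) -> None:
        for name in ("theta_afm", "theta_c", "theta_stacking", "theta_pairing", "theta_contact"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kBT <= 0:
            raise ValueError("kBT must be > 0")


@dataclass
class AFMConfig:
    tip_radius_nm: float = 1.0
    pixel_size: float = 5.0          # A / pixel
    height_floor_nm: float = 0.1     # footprint threshold for the cross-correlation
    noise_truncation: str = "clip"   # "clip" | "resample" | "none"
    pad: float = 20.0                # empty margin around the molecule, A


@dataclass
class FitSchedule:
    """Annealed Monte-Carlo schedule for the dynamic fitting."""

    n_steps: int = 14000
    t_start: float = 2.0             # in kBT
    t_end: float = 0.01
    n_cycles: int = 2                # annealing cycles (reheats escape traps)
    n_polish: int = 3000             # greedy multi-scale steps after annealing
    p_arm: float = 0.45              # helix-arm rotation about its junction pivot
    p_rot: float = 0.15              # global rigid rotation
    p_trans: float = 0.15            # in-plane translation
    p_bead: float = 0.25             # single linker-bead displacement
    arm_angle_deg: float = 25.0      # move amplitudes at t_start; shrink with temperature
    rot_angle_deg: float = 10.0
    trans_step: float = 4.0
    bead_step: float = 1.5
    cc_tier: float = 0.002           # best frame: min energy within this CC of the max
    cc_floor: float = 0.5            # below this the result is flagged unconverged


@dataclass
class SAXSConfig:
    q_max: float = 0.50              # 1/A, profile calculation range
    n_q: int = 101
    bead_form_factor: float = 1.0
    guinier_qrg_max: float = 1.3
    # RNA power-law calibration of the correlation-volume mass estimate:
    # MW = (Vc^2 / Rg / c)^k  with MW in Da
    vc_mw_coefficient: float = 0.00934
    vc_mw_exponent: float = 0.808
    a_convention: str = "expnorm"    # "expnorm" | "lsq"
    offset_mode: str = "sequential"  # "sequential" | "joint"


@dataclass
class ITCConfig:
    autocorr_threshold: float = 0.75
    alpha: float = 0.05              # F-test level for one- vs two-site selection
    eigenfraction_power: int = 1     # sigma_i / sum sigma (1) or squared (2)
    temperature_K: float = 298.15
    R_kcal: float = 1.987204e-3      # gas constant, kcal/mol/K


@dataclass
class RunConfig:
    helix: HelixGeometry = field(default_factory=HelixGeometry)
    beads: BeadModel = field(default_factory=BeadModel)
    energy: EnergyParams = field(default_factory=EnergyParams)
    weights: FitWeights = field(default_factory=FitWeights)
    afm: AFMConfig = field(default_factory=AFMConfig)
    schedule: FitSchedule = field(default_factory=FitSchedule)
    saxs: SAXSConfig = field(default_factory=SAXSConfig)
    itc: ITCConfig = field(default_factory=ITCConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        for section, value in data.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section: {section}")
            target = getattr(cfg, section)
            if isinstance(value, dict):
                for k, v in value.items():
                    if not hasattr(target, k):
                        raise KeyError(f"unknown config key: {section}.{k}")
                    setattr(target, k, v)
            else:
                setattr(cfg, section, value)
        return cfg


DEFAULTS = RunConfig()
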