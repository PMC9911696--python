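# Methods

## Coarse-grained RNA representation

Each nucleotide carries two beads: a backbone bead (phosphate-scale) and a
base bead. Duplexes are ideal A-form helices built from four constants
(config `helix` section): 11 bp/turn, 2.73 Å rise per bp, backbone beads at
8.5 Å and base beads at 2.5 Å from the axis, with a 255° azimuthal offset
between strands (this sets the major/minor groove widths that an AFM tip
senses). With the 4.0-Å backbone bead radius this gives a duplex whose
surface-to-surface diameter — and hence its apparent height when it rests
on mica — is 25 Å, and whose pitch is 30.0 Å. `measure_helix` therefore
reports duplex *width* as twice the maximal radial backbone-bead distance
from a least-squares cylinder axis **plus the backbone bead diameter**,
i.e. the physical width the tip senses; passing
`include_bead_radius=False` gives the bare center-line quantity. The helix
axis is fitted by minimizing the spread of radial distances (PCA
initialization), which is exact for ideal helices of non-integer turn
counts.

Unpaired nucleotides are extensible chains with a 6-Å relaxed spacing and a
7-Å maximum extension per link. The assembler realizes nested secondary
structures only (pseudoknots are rejected at parse time): helices at a
junction emanate from a star point just past the loop opening, with
directions from per-helix (polar, azimuth, roll) angles or a seeded random
draw; linkers are laid on circular arcs whose arc length equals their
relaxed contour, so bead spacing never collapses; the roll of each helix is
chosen, unless declared, so its strand entry faces the point the chain
arrives from. Builds are retried with fresh substreams until no two beads
outside a structural-contact exclusion set sit closer than the 6-Å clash
distance. The exclusion set is deliberate: beads of nucleotides within ±3
in sequence, beads within one (internally rigid) helix, paired and
pair-adjacent nucleotides, and nucleotides that meet at one loop (the
terminal base pairs of helices flanking a junction legitimately contact one
another — coaxial helix ends stack in folded RNA). A strict
bonded-pairs-only reading of "clash" is unsatisfiable in any two-bead
model: stacked base beads inside an ideal helix sit ~3.1 Å apart.

## AFM surface simulation

The molecule is dropped so its lowest bead surface touches the mica plane
(z = 0, no deformation model). For a spherical tip of radius R and a bead
of radius r at lateral distance d ≤ R + r, the tip-apex height is
z + √((R+r)² − d²) − R; the image is the pixel-wise maximum over beads
(grey-scale dilation), clipped at the plane. With R = 0 this reduces to the
z-projection of bead tops, which the test suite asserts as a lower bound of
every rendered image. Defaults: 1-nm tip, 5 Å/pixel, heights stored in nm.

Percentage noise: a stated ±L% level is read as the **2σ amplitude**
relative to the image's highest Z value — σ = (L/100)·max(Z)/2 — with
samples limited to ±2σ. The limiter is configurable (`clip`, `resample`,
`none`); clipping is the default because it keeps the empirical SD within
5% of σ (resampling a doubly-truncated normal would depress it by ~12%).
The result is clipped at the mica plane.

The corrugation-period estimator trims the edge ramps of the brightest scan
line, finds the deep once-per-turn minima (major grooves) by
prominence-filtered peak search with parabolic sub-pixel refinement, and
reports the slope of minimum position against minimum order; the measured
period of a flat-lying built duplex is 3.00 nm, i.e. the builder's 30-Å
pitch, recovered to 0.1% despite 5-Å sampling.

## Dynamic fitting

The cross-correlation is computed over the molecular footprint — the union
of pixels where either image exceeds 0.1 nm — because a whole-frame sum
would be dominated by background zeros. It is uncentered and therefore
invariant to uniform intensity scaling of either image.

The optimizer is Metropolis Monte-Carlo with geometric cooling (t_start
2 kBT → t_end 0.01 over 14,000 steps in two reheat cycles), followed by
3,000 greedy multi-scale polish steps. Moves: helix-arm rotation about the
arm's junction pivot (45%; half of these about the surface normal, since
adsorbed molecules rearrange mostly in-plane, and 15% of them
full-amplitude jumps for basin escape), global rotation (15%), in-plane
translation (15%), single linker-bead displacement (25%). Amplitudes shrink
with temperature. Reheats restart from the best frame seen so far
(elitist). Every proposal re-renders the simulated surface on the
experimental grid. The reported structure is the lowest-total-energy frame
among those within 0.002 of the maximum cross-correlation — this
operationalizes "best energy at best image agreement", which can otherwise
conflict.

Energy terms: harmonic bonds/angles/dihedrals about reference values taken
from an ideal rebuild of the secondary structure. Tuples fully inside one
helix use the stiff constants (k_length 5 kBT/Å², k_angle 10 kBT/rad²,
k_dih 2); linker-involving angles are nearly free (0.05) and linker
dihedrals free, and linker bond references are the constant relaxed link
lengths — otherwise the arbitrary loop paths of the reference build would
bias the fit toward one junction geometry. Pairing and stacking are
flat-bottom wells (±0.5 Å) about the built A-form separations; contacts
combine a finite soft-core repulsion below 6 Å with a weak screened-charge
repulsion between backbone beads (Debye length 10 Å). Weights default to
θ^AFM = 3, θᶜ = 1, θ^stacking = θ^pairing = 1, θ^contact = 0.5; all are
config-exposed. θ^AFM and the schedule were chosen so that the noiseless
phantom benchmark below converges reliably; the image term then contributes
a few kBT per 0.01 of cross-correlation for an ~80-nt molecule.

Benchmark (the package's standing validation): an ~84-nt three-way-junction
phantom distorted to ~15 Å backbone RMSD refits to ≤ 6 Å with CC ≥ 0.98 in
at least 3 of 5 annealing seeds from its noiseless surface; across the
twelve-level noise ladder (±5…±100% of max Z) the final CC against the
fitted image decays from ≈0.99 to ≈0.79, and the refit RMSD at ±100% is
worse than at ±5%. Because the added noise is i.i.d. per pixel, its effect
on the *structure* (as opposed to the CC) is modest at these sizes — the
correlation sum averages it out — so the RMSD comparison is run at the full
schedule where low-noise fits converge tightly; correlated instrument
artifacts, which the generator does not emulate, would degrade real-data
fits faster. That is the main caveat when reading ladder results as a
statement about real images; the others are the absence of molecule
deformation by the tip/surface and of any tip-shape error.

Pose search (`register_pose`) is exhaustive over an orientation grid and
integer-pixel translations, deterministic with earliest-entry tie-breaking.

## SAXS

Per-conformer intensities use the Debye sum over beads with a uniform form
factor (pair distances histogrammed at 0.25 Å); there is no hydration-layer
or excluded-volume model, which is adequate for coarse topological models
and keeps the calculator internal. Ensemble synthesis is the
volume-fraction-weighted pointwise sum on a shared q grid; mismatched grids
are an error, and resampling is an explicit separate operation.

χ² uses, by default, the experimental-normalized closed form for the scale,
a = ΣI_exp·I_syn / ΣI_exp², with the offset b then minimizing χ² given a.
This form equals the least-squares scale only when the two curves are
already on a common scale; with a nonzero true offset it does not reach
χ² = 0, so a joint (a, b) weighted-least-squares mode and a conventional
a = ΣwI·I_syn/ΣwI_syn² are provided by flag (`a_convention`,
`offset_mode`). Fraction optimization is SLSQP on the simplex (ν ≥ 0,
Σν = 1) from tally-style initial values, with the objective normalized by
its initial value so the line search is well-scaled for small σ;
near-collinear basis curves attach a degeneracy warning.

Guinier fitting iterates the admissible window until max(q)·Rg < 1.3
stabilizes. P(r) is a non-negative least-squares indirect Fourier transform
with a second-difference smoothness penalty; Dmax is read from where the
P(r) support ends (2% of peak) in a generous 4·Rg first pass, then P is
re-solved on [0, Dmax]. On uniform-sphere phantoms this recovers Rg within
3% of √(3/5)·R, Dmax within 5% of 2R, and real/reciprocal Rg agreement
within 5%. The correlation volume Vc = I(0)/∫qI dq feeds the RNA power-law
mass estimate MW = (Vc²/Rg / 0.00934)^0.808 (constants in config); a pure
Guinier curve gives Vc = 2Rg²/3 analytically, which the tests verify to
0.1%.

## ITC

The thermogram is an m × n matrix of per-injection power traces. Peak
integration uses a local linear baseline through the first/last quiescent
samples of each trace and trapezoid areas normalized per mole injected —
a deliberately simple stand-in for full peak-shape modelling, adequate for
pulse-shaped synthetic data. SVD components are filtered by the normalized
lag-1 autocorrelation of their left singular vectors (the time courses)
with threshold 0.75; "autocorrelation of a singular value" is not
computable for a scalar, so the smoothness of the associated vector is the
operational reading. Eigenvalue fractions default to σ_i/Σσ_j (first
power; configurable). Component isotherms integrate σ_k·U_k V_kᵀ over time
(a `projected` variant re-projects the data matrix instead).

The one-site model solves the quadratic mass balance per titration point
with the standard displaced-volume correction; an explicit small-step
integration of the binding ODE is provided as a cross-check and agrees to
discretization error. The two-site independent model solves free ligand by
root bracketing and supports opposite-sign enthalpies (an endothermic event
followed by an exothermic one). Fits are Levenberg-Marquardt in
log-transformed N and K_d. Model choice is the extra-sum-of-squares F-test
at α = 0.05 (two-site iff p < 0.05; a worse-fitting larger model loses
outright). ΔG = RT ln K_d and ΔS = (ΔH − ΔG)/T at 298.15 K are reported and
internally consistent to 1e-9.

The synthetic two-component generator renders each component's
per-injection heats as Gaussian power pulses of fixed, component-specific
center and width (unit area, so only areas matter downstream; the true
instrument response is not modelled), making the two components exactly
rank-1 each and separable by SVD at the default SNR of 20.

## Problem sizes and determinism

Default study conditions: ~84-nt phantoms (8-bp stem, two 12-bp hairpin
arms), 5 Å/pixel imaging with a 1-nm tip, twelve noise levels, 3-component
SAXS mixtures with a counting-statistics error model (1% relative), 25
injections of 10 µL (700 µM into 70 µM, 1.4 mL cell) for ITC. The fitting
schedule (14k + 3k steps) converges these sizes in tens of seconds per
seed; the noise-ladder table in the CLI runs at a reduced schedule.
Every stochastic step takes a seed; scenario bundles regenerate
bit-identically from their manifest (hash-checked in the tests).

## Known limitations

- Nested secondary structures only; pseudoknots are rejected, and tertiary
  contacts enter only through declared kissing-loop pairs.
- The two-bead resolution and bead radii are a modelling choice tuned to
  reproduce duplex width/pitch as the tip senses them, not a reconstruction
  of any published bead model.
- The AFM model has no molecule deformation, no tip-shape error, and
  treats noise as i.i.d. per pixel.
- The Debye calculator omits solvent effects; absolute SAXS scale is not
  modelled.
- ITC baseline handling assumes well-separated injections.
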