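# Methods

This note documents the models behind `marct`, the defaults and why they
were chosen, the numerical decisions, and the limits of what the synthetic
experiment demonstrates.

## Physics fixtures

**Attenuation table.** All energy-dependent physics reads a packaged text
table (`marct/data/attenuation.txt`, generated once by
`scripts/make_attenuation_table.py`): mass attenuation and mass
energy-absorption coefficients for air, water, a solid-water surrogate,
four tissue surrogates (lung 0.30, adipose 0.92, liver 1.096, cortical
bone 1.819 g/cm³), titanium (4.540) and Cerrobend (9.760, fixed at
50% Bi / 26.7% Pb / 13.3% Sn / 10% Cd by mass — the standard alloy recipe)
on a 24-point log grid from 20 keV to 2 MeV, with log-log interpolation
between nodes.  The generator uses a two-term cross-section model —
Klein–Nishina Compton scattering (numerically integrated total and
energy-transfer cross sections) plus a photoelectric term
`C·Z^3.4 / (A·E^3.1)` calibrated so water's total at 30 keV equals
0.3756 cm²/g.  No K-edges, coherent scattering or pair production; this is
adequate for artifact genesis and megavoltage Compton-dominated dose, not
for spectroscopy.  The solid-water composition is calibrated (C↔Ca trade,
emulating the vendor's CaCO₃ loading) so the plastic is water-equivalent at
the reference energy; it reconstructs at ≈ +4 HU, consistent with its
1.004 g/cm³ density.

**Spectrum.** A 140 kVp tungsten-anode spectrum as a 12-bin fixture
(25–135 keV bin centers): Kramers bremsstrahlung filtered by 12 mm Al,
an on-axis inherent-plus-bowtie filtration typical of a clinical scanner.
The *reference energy* stored with the spectrum (61.1 keV) is the effective
energy of this spectrum through 16 cm of water — approximately the mean
chord of the phantom — and is used for HU conversion, the MAR
monochromatic target, and the density calibration anchor points.  A
monochromatic single-bin mode exists for oracle tests.

## Phantom and ground truth

A 20 cm water-equivalent cylinder (desk-scale stand-in for the 33 cm
physical ring phantom) carries two opposed insert slots A/B at ±5 cm and an
outer ring of four tissue surrogates.  Configuration 1 mounts 1 cm titanium
rods, configuration 2 mounts 3 cm Cerrobend rods, configuration 3 mounts
3 cm solid-water rods.  Voxelization is center-in-shape with no
partial-volume averaging (partial volume arises naturally from
reconstruction).  Default grid 256×256 at 1.5 mm with three 2.5 mm slices
for the phantom module; the end-to-end study default is 128×128 at 3 mm
and 180 views, chosen so the full two-metal, three-plan experiment runs in
well under a minute on one CPU.

Three 4 cm cylindrical PTVs probe different artifact regions: PTV1 at the
center (the streak corridor between the slots), PTV2 off-axis at
(0, 3.5 cm) in a streaked but metal-free area, PTV3 centered on slot A so
it contains metal.  The exact centers are package configuration, not
physics: only their topological relations (PTV3 overlaps metal, PTV1/PTV2
do not) are load-bearing.

The **ground truth** is built by software substitution: the
metal-free configuration-3 acquisition with the true slot voxel sets
overwritten by the substituted metal's HU (which saturates at 3071 for both
metals).  It therefore contains the same acquisition noise statistics as
the images it is compared against, but no metal artifacts.

## CT simulation

Parallel-beam geometry, `n_views` over 180°, detector with twice the image
width in bins.  Forward projection is an exact ray–voxel
intersection-length (Siddon) traversal accumulated per material, so
per-energy line integrals are exact for the voxelized object.  Expected
counts are `N0 · Σ_E w(E) exp(−p(E))`; observed counts are Poisson with a
per-slice derived seed.  Bins under 5 counts are flagged *starved*
(log floor 0.5 counts).  `N0 = 2×10⁶` photons per bin: the difference of two
independent metal-free scans then has a ≈ 9–13 HU standard deviation — a
clinical-CT-like noise floor that keeps low-Z artifacts measurable above
noise — while preserving the intended low-Z/high-Z contrast: expected
counts behind 3 cm of Cerrobend are < 1 (starved), behind 1 cm of titanium
≈ 10⁴ (clean).

Log-normalized projections pass through a **water linearization** (the
scanner's standard beam-hardening calibration): each measured value is
mapped to `μ_w(E_ref)·t_w` for the water thickness that would have produced
it.  Pure water then reconstructs flat at 0 HU; materials whose spectral
response differs from water — metal above all — leave residual artifacts.
Reconstruction is ramp-filtered (Ram-Lak; optional Hann) backprojection,
with HU clamped to the scanner range [−1024, 3071].  The no-calibration
path (`reconstruct_fbp` on raw log-normalized data) shows textbook cupping
and is kept for the beam-hardening oracle tests.

## The MAR algorithm

The method treats the two corruption mechanisms separately.

**Segmentation.** Low-Z (no starved bins): threshold at 2500 HU, discard
components under 3 voxels, refine each component to its half-peak contour
on an *unclamped* reconstruction (the saturated display range makes a
blurred edge bloom past any fixed threshold; the half-maximum crosses a
blurred step at the true boundary).  High-Z (starved bins present): the
starvation footprint itself delineates the metal — counts behind Cerrobend
vanish within a fraction of a millimetre of the true edge — so a voxel is
metal if the starved runs cover it in ≥ 70% of views (a visual-hull vote;
0.5 follows the slowly-decaying coverage outside a convex shadow, values
near 1 erode with run noise; 0.7 places the edge at sub-voxel accuracy on
a convex insert).  On the synthetic phantom both routes recover the true
insert voxel sets to within ≤ 3 voxels.

**Physics correction.** For each valid bin whose ray crosses segmented
metal, with metal path `t_m` from forward projection of the mask: invert
the precomputed two-material lookup `p(t_w, t_m)` — expressed in the same
water-linearized domain as the measurements — for the water-equivalent
thickness `t_w`, and rewrite the bin as `μ_w(E_ref)·t_w + μ_m(E_ref)·t_m`.
Bins whose measured value falls outside the lookup range are marked
*failed*.  The correction is also declared failed wherever
`μ_m(E_ref) > 4 cm⁻¹`: the corrected value carries an error of
`μ_m · δt_m`, ≈ 0.1 for titanium (1.7 cm⁻¹) but ≈ 3 per half-bin of
segmentation error for Cerrobend (≈ 40 cm⁻¹), so high-Z trace bins are
re-estimated instead.  The metal-material assignment defaults to a
starvation heuristic (starved ⇒ Cerrobend, else titanium) and can be
overridden.

**Completion.** Bins to re-estimate are the starved set plus the failed
set, dilated by 2 detector bins (rays grazing the sub-voxel shell outside
the voxelized mask still carry partial metal attenuation without being
flagged).  They are re-estimated by minimizing
`λ_s‖L x‖² + λ_c Σ_v (m_v − M̂)²` over the missing bins (5-point sinogram
Laplacian `L`, view mass `m_v`, defaults λ_s = 1, λ_c = 10, ≤ 200
iterations, relative-change tolerance 10⁻⁴), by gradient descent with a
backtracking step — the objective is non-increasing by construction.
`M̂` is the median mass of views with < 10% missing bins; when no view
qualifies (3 cm inserts shadow every view) it falls back to the median
initialized mass.  Initialization interpolates the *residual* against a
prior sinogram per view; after convergence each incomplete view's moment
is repaired exactly by a uniform shift over its missing bins, so the
mass-conservation constraint holds to machine precision on incomplete
views and to noise level (≪ 1%) on complete ones.

The completion runs twice: a first pass with plain interpolation
initialization, whose reconstruction supports a tissue-class **prior**
(air / lung-like / water / bone-like, with the metal neighborhood forced
to water and dark streaks unable to masquerade as air thanks to a
hole-filled body outline); a second pass then re-completes against the
forward-projected prior.  This prior-guided structure is standard in
normalized-interpolation MAR practice and removes the mass deficit plain
interpolation leaves across wide gaps.

**Reinsertion.** Before reconstruction the trusted metal bins' metal term
is replaced by water (`μ_w·(t_w+t_m)`), so the corrected image is
reconstructed *metal-free* and the segmented metal is painted back
afterwards at one HU per connected component — precisely the construction
of the ground truth itself, which avoids comparing a reconstructed
(ringing) metal edge against a painted one.  The literal monochromatic
variant (metal reconstructed from its own projections) remains available
as `metal_fill="metal"`.

## Dosimetry

**Calibration.** Piecewise-linear HU → relative electron density through
the packaged materials evaluated at the reference energy: air, lung,
adipose, water, liver, cortical bone, ending at (3071 HU, 3.76) — the
electron density of titanium, where clinical stoichiometric curves top
out.  A flat segment from −1000 to −950 HU maps reconstruction noise
around air to true air rather than rectifying it into an attenuating haze
(planning systems do the same).  Both metals saturate at 3071 HU, so
corrected, uncorrected and ground-truth volumes all receive the *same*
metal density and dose comparisons probe the artifact correction, not the
(unknowable from a clamped scan) metal composition.

**Primary engine.** Per beam, parallel subrays at half-voxel spacing carry
unit-fluence kerma dose `μ_en/ρ · exp(−μ_eff · t_rad)` with the
radiological path from the exact traversal; beamlets are 5 mm wide and
cover the target projection plus a 5 mm margin.  The beam is monoenergetic
2 MeV — a 6 MV-like surrogate with one parameter; `μ_eff` and `μ_en/ρ` are
water values from the table.  Dose is exactly linear in the fluence.  No
electron transport, no scatter: accepted kerma-approximation divergence
from a clinical Monte Carlo engine, documented as a desk-scale limit.

**Monte Carlo cross-check.** A Compton-only 2-D photon transport
(Woodcock tracking against the density maximum, Klein–Nishina angle
sampling by rejection, energy transferred at each collision binned as
kerma, photons killed below 20 keV).  It shares the primary engine's dose
scale and is used as an independent depth-dose cross-check and for energy
bookkeeping (deposited ≤ emitted), never for the study's headline numbers.

**Planning.** Candidate angles 0–359°; an angle is infeasible if any ray
from it to a target voxel crosses the metal (dilated by one voxel — the
partial-volume shell around an implant perturbs dose like the implant, so
beams keep a safety margin) on the upstream side.  Among feasible angles
the 5-subset maximizing the minimal circular gap is chosen (greedy over a
binary-searched gap; ties resolve to the lexicographically smallest set).
If fewer than five feasible angles exist — PTV3 contains the metal — the
most-spread subset of all candidates is returned flagged `unavoidable`.
Fluence weights solve a nonnegative least-squares objective (per-voxel
mean squared target error plus γ = 0.1 times the per-voxel mean squared
out-of-target dose) by projected gradient with a power-iteration 1/L step
and a fixed 500-iteration budget; the objective is monotone.  Plans are
optimized on the *uncorrected* density volume only and recomputed with
fixed fluence on the corrected and ground-truth volumes.

## Evaluation conventions

Population standard deviation (divide by n).  Image statistics default to
the body region excluding metal (both true and segmented), exposed as a
mask argument.  Cumulative DVHs use 0.05 Gy bins; `D_x` interpolates the
crossing of `V(d) = x/100` between bin edges and agrees with a sort-based
exact quantile within one bin; D100 is the minimum structure dose.
`Acc_x = |D_x − D_x^GT|/D_x^GT·100`, reported to two decimals in the CSV
table.  The Wilcoxon–Mann–Whitney test uses exact enumeration when
`min(n, m) ≤ 8` without ties, otherwise the tie- and continuity-corrected
normal approximation; per-voxel dose samples violate the independence
assumption, so p-values are descriptive context, not acceptance evidence.
Reports serialize with sorted keys and 6-decimal rounding, making a study
byte-reproducible from (configuration, master seed); every stochastic
stage derives its seed from the master seed by fixed offsets.

## What the synthetic experiment does and does not show

The generator reproduces the *mechanisms* — polychromatic beam hardening,
photon starvation, their low-Z/high-Z split, clinical-scale image noise, and the
planning-on-corrupted-images failure mode.  Passing tests therefore demonstrate that the algorithm
removes artifacts it is designed for under those mechanisms, with the
dose residual after correction bounded by a few percent of the
prescription while uncorrected high-Z errors exceed 10%.  They do not
demonstrate performance on clinical data: no scatter, no bowtie/AEC, no
helical or fan-beam geometry (the parallel mode makes the 0th-moment
consistency exact; fan-beam is declared in the geometry interface but not
implemented), coarser voxels than a clinical scanner, a surrogate
monoenergetic beam model without electron transport, and a phantom whose
background is homogeneous solid water.  Image-domain smoothness for the
completion (in place of the sinogram-domain Laplacian) is not implemented;
the sinogram-domain penalty was sufficient at this scale and keeps the
optimization linear-time per iteration.
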