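# Methods

This note records the models implemented in `aptafret`, their assumptions,
the defaults and why, and what the synthetic-data tests do and do not show
about real measurements.

## Corrected FRET output

The fluorometry module computes a sensitized-emission proximity ratio. Three
double-labelled readings enter: the transfer channel `I_DA(ex_D, em_A)`, the
acceptor channel `I_DA(ex_A, em_A)` and the donor channel `I_DA(ex_D,
em_D)`. Two contaminations of the transfer channel are removed using ratios
measured on single-labelled samples: donor emission bleeding into the
acceptor emission window (`D_Leak`) and direct excitation of the acceptor at
the donor excitation wavelength (`A_dir`). The corrected numerator over
itself plus donor emission is the reported statistic.

Assumptions and choices:

* **Channels.** Defaults are 460/505 nm (donor ex/em) and 585/620 nm
  (acceptor ex/em), the wavelengths at which the correction factors are
  defined. Acceptor excitation is sometimes performed at 580 nm on plate
  readers; the channel set is fully configurable and a reading within
  0.5 nm of the requested wavelength is accepted.
* **No gamma correction.** The statistic is not a photophysical transfer
  efficiency: detector sensitivity and quantum-yield ratios are not
  calibrated out. It is comparable across samples measured on the same
  instrument with the same channels, which is how it is used.
* **No clamping.** Noise can push the corrected numerator negative; the
  value is reported as-is with a `negative_flag`, because clamping at zero
  would bias replicate means upward near zero FRET.
* **Replicates.** Sample standard deviation with the n−1 denominator;
  sd = 0 for a single replicate. Intensities are assumed
  background-subtracted upstream.
* **Invariants.** The statistic is homogeneous of degree zero in the
  intensities (lane/gain scale drops out) and is ≤ 1 whenever the
  denominator is positive, with equality only when donor emission vanishes.

## Förster theory

Standard static-orientation Förster relations connect the geometric outputs
of the other modules to expected transfer: κ² from unit transition dipoles
and the separation direction; the overlap integral from the donor emission
spectrum (normalized by its own area) and the acceptor molar absorptivity,
resampled by linear interpolation to the finer grid and integrated by the
trapezoid rule; `R0 = 0.02108 (κ² n⁻⁴ Q_D J)^(1/6)` nm with J in
M⁻¹cm⁻¹nm⁴; `E = 1/(1+(r/R0)⁶)`.

Defaults `n = 1.4` and `Q_D = 0.6` are literature-typical placeholders for
an aqueous RNA-dye system — the Broccoli–Pepper pair has no published
quantum yield or R0 in this context — and both must be overridden for
quantitative use. No dynamic-averaging regimes beyond static κ² are
modelled.

## Coarse-grained tile model

The 3-helix origami tile is idealized as three parallel, coplanar A-form
helices: rise 2.81 Å/bp, 11 bp per helical turn, inter-axis spacing 22 Å.
Positions along a helix are measured in bp from the crossover (x = 0),
positive toward the tile's open end; the helical phase advances 360°/11 per
bp. Per-helix phase origins (0°, 180°, 180°) encode which side of the tile
plane each helix's zero-phase protrusion faces. An aptamer placed at offset
k protrudes at the phase azimuth of bp k, and its chromophore sits at a
fixed offset from the attachment point expressed in the local
(axial, radial, tangential) frame, the axial direction pointing away from
the crossover (so a negative-offset stem carries its aptamer outward on the
far side). Model transition dipoles are unit vectors in the same local
frame (default tangential).

**Chromophore offset calibration.** The offset vector
(axial 14.4, radial 12.0, tangential −4.3) Å, used for both fluorophores,
was fixed once by requiring the model to reproduce the two in-silico
placement distances reported for the published designs — ~2 nm for
1,3-B12P12 and ~16 nm for 1,3-B12P(-34) — under the A-form defaults above.
Its magnitude (~19 Å from stem attachment to chromophore centre) is
consistent with the dimensions of the scaffolded aptamers. With this single
calibration the model also orders all five published designs by distance
exactly opposite to their measured FRET outputs (0.64, 0.93, 1.78, 2.00,
16.00 nm against 37, 34, 29, ~10, 0 %), which was not fitted.

Limitations: the tile is ideal and planar — the central-helix curvature
seen by cryo-EM (which drops the acceptor aptamer below the tile plane) is
not modelled, because no quantitative bend parameters are published; helix
lengths are bounded at ±60 bp by default rather than taken from design
blueprints; distances at sub-nanometre range (adjacent-helix placements)
are outside the resolution claim of a rigid coarse-grained model, so the
package reports distance and κ² without adjudicating which limits FRET for
any given design.

## Ensemble analysis

Rigid-body superposition is Kabsch's SVD solution with a determinant guard
against reflections; it requires at least three non-collinear corresponded
points and is cross-checked in the tests against an independent
implementation. To compare ensemble members, every member receives a single
rigid transform computed on its acceptor-ligand atoms against a reference
member, which brings the acceptor chromophores into one frame while leaving
each member's internal donor–acceptor geometry exactly invariant (asserted
to 1e-9 Å in the tests).

Definitions: chromophore centre = centroid of the ligand's non-hydrogen
atoms (the deposited models do not identify a specific measurement atom);
per-fluorophore motion range = maximum pairwise centre distance across
members; dipole proxy = first principal axis of the ligand atoms,
sign-fixed by a reference atom pair so eigenvector sign flips do not read
as rotation; "positional variability" = max − min of the per-member
donor–acceptor distances, matching the convention in which extrema of
30.5 and 34.0 Å give 3.5 Å, with the unbiased statistical variance reported
separately under its own name. Atom correspondence across members is by
(residue name, atom name); ligand residue-name aliases are configurable
because chemical-component codes differ between depositions.

## SHAPE quantification

Band readout is the baseline-subtracted **peak height**: within a window of
±`window` px around the mapped band position, a straight line through the
profile values at the window edges is subtracted and the maximum residual
reported (floored at zero with a warning). Height matches manual
densitometry practice; an integrated-area mode exists behind
`quantify_bands_area`. Because the local baseline at the window edges
clips the band's own tails, a fixed fraction of every same-width band is
lost — which cancels exactly in the reference-normalized reactivities.

Each lane is normalized to its own reference nucleotide (default C28, a
stable tetraloop position far from the binding site), making reactivities
exposure-invariant with R(reference) ≡ 1. Classification against the apo
lane uses a fold threshold (default 2.0): protected when apo/bound ≥
threshold, enhanced when bound/apo ≥ threshold, ratios floored at 1e-3 to
avoid division blow-ups. Positions whose **mock-lane** normalized signal
reaches the stop threshold (default 0.3) are flagged as
reverse-transcriptase termination artifacts and excluded from
classification; they are reported separately with per-ligand intensities,
since differential stop strength tracks ligand binding affinity. The two
thresholds are tunable — no numeric reactivities are published for this
system, so the defaults were chosen to reproduce the qualitative
protection/enhancement calls on synthetic reconstructions. Nucleotides in
gel-compression regions can be marked unquantifiable and are skipped.

## Synthetic data

The generators define the test conditions end to end:

* **Spectra**: Gaussians on a 1 nm grid at the reported maxima (donor
  ex 485/em 505, acceptor ex 585/em 620 nm; widths 20/25 nm). Real spectra
  are asymmetric with vibronic shoulders; Gaussians are used so closed-form
  oracles exist.
* **Intensity tables**: the transfer channel is assembled by inverting the
  correction formula around a chosen true statistic, with consistent
  single-labelled rows and optional multiplicative Gaussian noise
  (measurement-style, per reading).
* **Ensembles**: a fixed acceptor and a donor perturbed per member by an
  isotropic Gaussian translation and a small-angle rotation (axis uniform,
  angle |N(0, σ)|) about its centroid — the rigid-pose analogue of
  near-Gaussian particle distributions along variability reaction
  coordinates. Ligands are rigid ~20-atom planar point clouds, anisotropic
  so the principal-axis dipole is well-conditioned; members are written as
  PDB (1e-3 Å round-trip precision) with a ground-truth JSON sidecar.
* **Gel lanes**: Gaussian bands (amplitude ∝ reactivity, reference band
  fixed in every lane including mock) on a smooth exponential background,
  with RT-stop bands injected into all lanes and optional additive noise.

Passing tests on these data show that the algorithms are correct under
their stated models (exact recovery noise-free, bias bounds under noise);
they do not validate instrument-specific effects absent from the forward
models — spectral asymmetry, gel smiling, band-shape heterogeneity,
detector nonlinearity, or real conformational ensembles beyond rigid
poses.

## Problem sizes and numerics

The test suite runs the stochastic checks at fixed seeds and moderate
sizes chosen for tight Monte-Carlo bounds at interactive runtimes:
500 random rigid-transform recoveries (0.5°/0.01 Å), 20 000 orientation
draws for the κ² isotropic mean (±4 SE), 1000 forward-modelled intensity
tables at 1 % noise for the bias bound (<0.005), 50-member synthetic
ensembles for the transform-level oracle. Wavelength lookups tolerate
0.5 nm; superposition treats point sets of rank < 2 as degenerate;
design-ranking ties break by input order.
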