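# Methods

## Damage model

The package assumes the standard cryo-crystallography global damage model:
the overall isotropic B-factor grows linearly with absorbed dose,
B(D) = B0 + β·D, attenuating shell-mean intensities by exp(−2·β·D·s²) with
s = sinθ/λ.  β is reported in Å² MGy⁻¹; the analysis estimates it relative
to the *nominal* dose scale (the dose computed with a default composition),
and a composition-correction factor converts it to the true scale.

## Dose model

The dose rate is the power absorbed in the illuminated crystal volume
divided by its mass.  Per element, the photoabsorption cross section is
derived from the Cromer–Liberman imaginary dispersion correction,
σ_pe = 2·r_e·λ·f″(E), evaluated by gemmi, plus a closed-form Klein–Nishina
Compton energy-transfer term (numerically integrated over the scattering
angle, Z free electrons per atom).  Fluorescence escape is neglected; for
H/C/N/O/S-dominated matter the resulting linear energy-absorption
coefficient agrees with tabulated water mass energy-absorption values to
about 4% across 5–20 keV (the supported range is 5–25 keV; outside it the
Cromer–Liberman evaluation and the no-edge assumption are not guaranteed).

Compositions are stored as element number densities.  The default "average
protein crystal" is 47% solvent (water + 300 mM sulfur) and 53% protein at
1.35 g cm⁻³ with the average residue stoichiometry C₄.₉H₇.₈N₁.₄O₁.₅ plus
0.05 S, ≈ 113.5 g mol⁻¹.  The exact average-residue formula matters little
because β-correction uses dose-rate *ratios*.  Heavy atoms enter as
concentrations (mM in crystal volume); a helper converts per-asymmetric-unit
counts given the cell volume.

Beam geometry: the beam travels along the crystal z-dimension; the
dose-averaging footprint is the FWHM box intersected with the crystal face.
A `uniform` profile is a top-hat of exactly the FWHM widths; a `gaussian`
profile contributes the photon fraction inside the footprint from its CDF.
Averaging over the FWHM region (rather than a wider truncation window) is
what reproduces conventional beamline dose-rate figures: with the uniform
profile, published dose rates for six known beamline setups are matched
within a factor of 2, which is as close as such single-scalar comparisons
can be expected to agree given unknown profile treatment and calibration
drift.  No depth-resolved dose field is computed — one scalar per
experiment, matching how such rates are quoted in practice.

## Protocol generation

Rules, in order:

1. **Resolution limit.**  d_min is the finest resolution at which the
   predicted last-shell ⟨J⟩/⟨σ_J⟩ reaches 5 within the 0.1 MGy collecting
   budget, floored at 2.0 Å.  The prediction combines the Wilson shell mean
   with the counting-noise model below; the link between invested dose and
   detector counts is the characterization constant `gain_per_mgy`
   (default 2500 counts per intensity unit per MGy, calibrated so that a
   unit-strength crystal with B0 = 15 Å² reaches the floor with last-shell
   signal-to-noise ≈ 7).
2. **Total dose.**  D_total = ln 3 / (2·β_assumed·s_min²): the last shell
   loses a factor of 3 under the assumed β (default 1 Å² MGy⁻¹).  8.79 MGy
   at 2.0 Å; larger for coarser limits (19.8 MGy at 3.0 Å).
3. **Schedule.**  11 collections of 0.1 MGy each; the remaining dose is
   split into 10 equal burns placed between them, so all planned doses sum
   exactly to D_total.  Equal burns produce the evenly spaced dose stamps a
   linear fit likes; the stamp of each wedge is the cumulative dose at its
   midpoint (unbiased for a linear model).
4. **Geometry.**  Every cycle (collect and burn) rotates over the same
   3–5° wedge (default 4°) centred on the characterization angle, keeping
   the illuminated volume constant.  Frame width is the largest divisor of
   the wedge below clip(1.5° − mosaicity, 0.1°, 1.0°): mosaic spread widens
   each reflection, shrinking the rotation a frame can cover without
   spatial overlap.
5. **Exposure/transmission.**  Transmission is maximal subject to the
   per-frame exposure minimum and rotation-speed cap; if the required
   transmission falls below the attenuator minimum the protocol is
   infeasible and says which constraint failed.  Burns run at full
   transmission.

With a 3× sensitivity error the last wedge's predicted last-shell
signal-to-noise is 5·exp(−3·D·s_min²) ≈ 0.97 — marginal but still a
monotone, essentially linear B series, which is what the tests assert; at
the assumed β the margin is 5/√3 ≈ 2.9.

## Simulator

What it emulates: Wilson-regime shell means scale0·exp(−2·B0·s²) with
acentric exponential intensity statistics; per-reflection decay
(1 + drift·D)·exp(−2·β·D·s²); gaussian counting noise with variance
(J·gain + background_var)/gain², σ_J set to the model value; gain
calibrated (closed form for zero background, quadrature + bisection
otherwise, capped by a detector dynamic range) so the first wedge's last
shell hits a target ⟨J⟩/⟨σ_J⟩, default 5.  Defaults: B0 = 15 Å²,
10 equal-s² shells to 2.0 Å, 100 reflections per shell (a realistic count
for a 4° wedge), zero background.

What it does not emulate: image-level effects (spot shape, mosaicity,
detector geometry), centric reflections and multiplicity corrections,
anisotropic decay, specific structural damage, within-wedge dose structure
(a ≤ 0.1 MGy collecting cycle makes it negligible), and variations of the
illuminated volume during rotation.  Passing recovery tests therefore show
the *statistical* soundness of the scaling/fitting chain under the assumed
noise model, not robustness to integration artefacts in real frames.
Reflections carry synthetic sequential ids; all analysis uses shell means,
so no space-group machinery is needed.

## Scaling

Per wedge, ln(⟨J⟩_wedge/⟨J⟩_ref) is regressed on s² (weighted least
squares), giving ln k and −2·ΔB.  Shell-mean weights are inverse summed
relative variances, relvar = (1 + (⟨σ⟩/⟨J⟩)²)/n — proportional to shell
count and discounted for measurement noise.  The reference curve is the
precision-weighted average of all wedges' shell means corrected to the
common scale, and reference construction and per-wedge fits alternate until
the largest B change is below 1e−10 Å² (the gauge — B = 0 for the first
wedge, max k = 1 — is re-fixed every iteration because the likelihood is
invariant under a common B shift absorbed by the reference).  Shells with
non-positive means (possible at high dose and noise) are excluded from the
log fit with a warning; empty shells are merged downward.  The reported
per-wedge se_B ignores the correlation between a wedge and the reference
through the shared underlying reflections, so it is conservative
(overestimated) in absolute terms; it is used only for relative weighting,
and the β standard error is rescaled by the empirical residual scatter of
the B-versus-dose fit, which calibrates it correctly.

This log-linear joint refinement replaces a full per-reflection
maximum-likelihood scaling target: the estimand (overall k and B per wedge)
is identical, and the shell-mean formulation admits exact closed-form
checks (two wedges and two shells determine k and ΔB exactly).

## β fit and summaries

B versus nominal dose is fit by weighted least squares (weights 1/se_B²,
falling back to unweighted when standard errors are unavailable), requiring
≥ 3 wedges and non-zero dose spread.  Anchoring B to the first wedge means
the intercept estimates ≈ 0, not B0.  Multi-position experiments report the
mean β and the *population* standard deviation (divisor n); a single
position is flagged NA.  Report tables round to 2 decimals, half away from
zero.  A known presentation edge case: three nearly identical positions can
give a population std of ~0.005, which the 2-decimal report shows as 0.00.
β_corrected = β / r with r the ratio of the true-composition to
default-composition dose rate; more absorbing compositions (r > 1) shrink
β, since the same nominal dose deposited more energy than assumed.

## Numerical choices and limitations

* Compton energy-transfer integral: 2001-point trapezoid over scattering
  angle; quadrature for ⟨σ_J⟩ over exponential intensities: 64-node
  Gauss–Laguerre.
* All randomness flows through `numpy.random.default_rng` seeded from a
  single integer (`SeedSequence.spawn` separates the reference draw from
  per-wedge noise), so identical seeds give bit-identical outputs and
  files.
* Monte-Carlo problem sizes in the test suite (100 reflections/shell, 50
  seeds for recovery, 500 replicates for unbiasedness) were chosen as the
  smallest sizes at which the sampling error of the checked statistic is
  several times smaller than the asserted tolerance.
* Crystals are axis-aligned boxes with the beam along z; no rotation of the
  illuminated volume, no multi-axis goniometry, no beamline control.
* The absolute dose scale is only as good as the flux/beam-size
  calibration; the analysis is exact only on the relative (nominal) scale,
  which is the quantity the protocol is designed to measure.
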