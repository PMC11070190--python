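# Methods

## The measurement and the model

`symbiotrace` quantifies metabolite exchange between a diatom host and its
obligate nitrogen-fixing endosymbiont ("diazoplast") from dual-label
stable-isotope tracing: cells incubated with ¹⁵N₂-enriched medium and
¹³C-bicarbonate are imaged by nanoSIMS, which records integer secondary-ion
counts per pixel for a small set of mass channels. Nitrogen is carried by the
CN⁻ isotopologues (¹²C¹⁴N⁻, ¹²C¹⁵N⁻), carbon by the C₂⁻ isotopologues
(¹²C₂⁻, ¹³C¹²C⁻), and ³²S⁻ tracks protein abundance.

The chain of inference is:

1. **Segmentation.** The CN⁻ raster partitions a cell into the diazoplast
   (highest CN⁻, compact and near-spherical), the nitrogen-containing host
   cytoplasm "host(N)", and nitrogen-depleted storage bodies "host(−N)"
   (background CN⁻ but high C₂⁻).
2. **Atom percent.** For each ROI, counts are pooled over pixels and the
   heavy-atom percentage estimated as the ratio of sums,
   atom% = 100·H/(H+L), with binomial standard error
   SE = 100·√(p(1−p)/(H+L)).
3. **Thresholding.** Unlabeled control ROIs calibrate natural abundance; an
   ROI is *enriched* when its atom% strictly exceeds the control mean plus
   three across-ROI standard deviations. A cell is nitrogen-fixing when its
   pooled diazoplast ROI is ¹⁵N-enriched, carbon-fixing when its pooled
   host(N) ROI is ¹³C-enriched.
4. **Transfer mass balance.** Across cells with both measurements, the
   through-origin regression slope s of host excess enrichment on diazoplast
   excess enrichment, combined with the diazoplast:host(N) volume ratio
   v = V_d/V_h, gives the fraction of newly fixed nitrogen residing in the
   host: f = s·V_h/(s·V_h + V_d) = s/(s+v). With s = 0.9 and v = 0.06,
   f = 0.9375.

Ancillary computations: δ-notation arithmetic for bulk IRMS
(R = R_std·(1+δ/1000), atom% = 100·R/(1+R)); acetylene-reduction rates
normalized per µg chlorophyll per hour with diel day/night contrasts and
treatment effects; efficiency-corrected relative expression
E^(Cq_ref − Cq_target) with geometric-mean fold changes (equal to 2^−ΔΔCt
at E = 2).

## Statistical assumptions

- **Counting model.** Each pixel's channel count is Poisson; the heavy/light
  split of a compartment's CN⁻ (or C₂⁻) count is binomial thinning at the
  compartment's true atom fraction. Under this model the ratio-of-sums
  estimator is the maximum-likelihood estimate and its binomial SE is exact.
  Mean-of-pixel-ratios is deliberately avoided: pixel ratios are undefined at
  zero counts and biased at low counts.
- **Calibration SD.** The 3-SD threshold uses the SD *across* control ROIs,
  not the counting-statistics SE, so instrument scatter is included. No
  multiple-testing correction is applied: the rule is a fixed cutoff, not a
  testing procedure.
- **Mass balance.** f = s/(s+v) assumes equal nitrogen density per volume
  across compartments, so newly fixed N in a compartment is proportional to
  excess atom fraction × volume. This is an explicit assumption, not a
  measurement.
- **Regression.** Through-origin by default (a cell whose diazoplast fixed
  nothing has nothing to transfer); an intercept is available. R² is
  uncentered for the through-origin fit. Excess enrichments (atom fraction
  above the calibrated control mean) enter the fit, so the natural-abundance
  baseline cancels. Uncertainty on f comes from a percentile bootstrap over
  cells (default B = 1000), which the underlying study did not report.

## The synthetic-data generator

No raw rasters are available, so the generator *is* the study-condition
definition for all tests:

- **Geometry.** One focal cell per raster: a prolate-spheroid host with
  semi-axes 10 × 5 µm (≈20 µm long) holding four spherical diazoplasts of
  radius 1.55 µm — giving a diazoplast:host volume ratio
  4·r³/(a·b²) = 0.0596 ≈ 6% — plus storage discs covering 8% of the
  projected host area. Discs are placed by seeded rejection sampling (100
  tries per disc, up to 10 whole-layout restarts) strictly inside the
  ellipse with a ≈3-px cytoplasm margin; volumes are analytic
  (spheroid/spheres). Default raster 128×128 at 0.2 µm/px.
- **Counts.** Depth-accumulated expected counts per pixel: CN⁻ 2000
  (diazoplast), 800 (host(N)), 40 (host(−N)), 20 (background); C₂⁻
  500/500/1500/20; ³²S⁻ at 0.5× the CN⁻ density. Depth was chosen so the
  across-ROI control scatter is small relative to labeled enrichment, as in
  the measured controls (0.377 ± 0.012 atom% ¹⁵N); much shallower counting
  inflates the 3-SD threshold through low-count storage ROIs.
- **Isotopes.** Physical natural abundances (¹⁵N 0.003663, ¹³C 0.0111 atom
  fraction) plus constant instrument offsets place unlabeled material at the
  measured baselines 0.377 atom% ¹⁵N and 1.74 atom% ¹³C.
- **Population.** Each cell is active with probability 0.7 (the 12-h
  prevalence); active cells draw a lognormal diazoplast excess (mean 0.01
  atom fraction, CV 0.5 — strictly positive and right-skewed), and the host
  receives 0.9× the diazoplast excess. Carbon fixing is independent at
  probability 0.9, with host(N) excess ¹³C lognormal (mean 0.01), storage at
  2× (fixed carbon accumulates in storage) and diazoplast at 0.5× (carbon
  arrives only by transfer).
- **Assays.** Bulk IRMS replicates are Gaussian around a true δ; diel ARA
  series carry multiplicative Gaussian noise with a treated mean at
  `treatment_factor` × control; qPCR offsets the night target Cq by
  −log_E(fold) with Gaussian cycle noise.

What the generator does **not** emulate: sputtering depth profiles, detector
dead time, quasi-simultaneous-arrival effects, raster drift, multi-cell
fields, irregular organelle shapes, or spatial gradients within a
compartment. Passing tests therefore demonstrate that the *estimators and
rules* recover known truth under the stated counting model — not that
segmentation would match a manually curated analysis of real acquisitions.

## Numerical and design choices

- **Smoothing/thresholds.** Gaussian smoothing (σ = 1 px) precedes all
  thresholding; Otsu separates cell from background (after a binary closing
  that bridges storage bodies abutting the cell edge, then hole filling;
  largest component kept). The diazoplast threshold is Otsu *within* the
  cell: with four 1.55-µm diazoplasts in a 10 × 5 µm host they cover ~19% of
  the projected cell area, so a fixed high quantile (the available
  `quantile` option, default 0.90) falls inside the diazoplast intensity
  mode and degenerates; Otsu adapts to the bimodal split regardless of area
  fraction.
- **Candidate filtering.** Diazoplast candidates must stand out against the
  within-cell median CN (contrast ≥ 1.5 — otherwise a cell with no
  diazoplast is split on noise), pass area (≥ 20 px) and circularity
  (4πA/P² ≥ 0.6) filters, and touching candidates are separated by a
  distance-transform watershed before filtering (two abutting spheres
  otherwise merge into a dumbbell that fails circularity).
- **Storage rule.** host(−N) = within-cell pixels with smoothed CN below
  0.5× the cell median *and* smoothed C₂ at least 1.5× the cell median.
  Boundary pixels follow whichever smoothed rule fires; no morphological
  tie-breaking, so segmentation is deterministic.
- **Degenerate inputs.** Zero-total-count ROIs yield flagged undefined atom%
  (never an exception); constant ³²S yields an "undefined" correlation
  status; a cell without diazoplasts is a valid segmentation with zero
  diazoplast ROIs; transfer_fraction(0, 0) and a zero control mean in the
  treatment effect are errors.
- **Determinism.** Every stochastic routine takes a seed; cell i of a
  population uses seed sequence (seed, i) so prefixes coincide across
  population sizes; the pipeline fans one global seed into per-stage seeds
  via SHA-256. Reruns are bit-identical, and the run manifest records
  config hash and per-output checksums.
- **Open choices resolved.** Control calibration uses the unweighted mean
  across compartment ROIs (the weighting used originally is unstated);
  regression uses excess enrichment through the origin (option retained for
  an intercept on raw atom%); the volume ratio is an input parameter
  (default 0.06) rather than being estimated from projected areas, though
  ROI equivalent radii are provided for that purpose; ARA inputs are
  already-converted ethylene amounts; qPCR efficiencies are user inputs.
  The 3-SD convention is reused for bulk IRMS condition calls as an internal
  consistency convention, with Welch tests as annotation only.

## Problem sizes

Default analyses run single-cell rasters of 128×128 px; recovery checks use
50 paired cells (regression), 200 labeled + 50 control cells (activity
classification), 30 ROIs at 10⁶ counts (calibration), and 6 replicates
(treatment effect) — the scales at which the corresponding sampling noise is
comfortably within each check's tolerance.

## Known limitations

- Segmentation is tuned for compact inclusions in a convex cell; it is a
  reproducible automated surrogate, not a replication of manual ROI drawing.
- The transfer fraction ignores isotope dilution, turnover, and multi-
  timepoint kinetics; it is a snapshot mass balance.
- Bulk δ values and single-cell atom% are linked only through exact ratio
  conversions; no per-cell/bulk reconciliation model is attempted.
- Acetylene-reduction rates are not converted to N₂-fixation rates.
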