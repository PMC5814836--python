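# Methods

## Isotope arithmetic (`diazosip.isotope`)

All conversions are exact algebra on the ¹⁵N/¹⁴N ratio *R*:
δ¹⁵N = (R/R_ref − 1)·1000 ‰ and atom-% = 100·R/(1+R), with
R_ref = 0.0036765 for atmospheric N₂ (configurable). Atom-percent excess is
the difference of sample and control atom-%; negative APEs (possible under
measurement noise) are reported unclamped with a warning so control
distributions stay unbiased.

Spike unmixing inverts two-pool mass-weighted mixing:
δ_sample = (δ_total·N_total − δ_spike·N_spike)/(N_total − N_spike). It is
the exact algebraic inverse of the forward mixture, which the tests verify
to 1e-12.

The ARA equivalence converts a bulk incorporation measurement into the
ethylene signal an acetylene-reduction assay would have produced: fixation
rate = soil N content × APE/100 / incubation time, ethylene rate = fixation
rate × the nominal 3:1 C₂H₂:N stoichiometry, and the ppmv mixing ratio
assumes an ideal gas at a configurable molar volume (default 24.465 L/mol,
25 °C, 1 atm) and a dry-mass basis for soil N. Headspace volume,
temperature, the mass basis and the stoichiometric convention materially
change the ppmv figure and are deliberately exposed as parameters rather
than hard-wired; the function is an order-of-magnitude bridge between the
two assays, not a calibration.

## The SIP enrichment caller (`diazosip.sip`)

**Design.** Fractions of one gradient inside the labelled and unlabelled
density windows are treated as independent replicate count samples of two
conditions; no density covariate enters the model. This mirrors the
two-group comparison design of gradient-resolved SIP: in an RNA gradient
without labelling, each OTU's read *proportion* is approximately constant
across fractions, so labelling shows up as a group difference rather than a
trend.

**Windows.** RNA–CsTFA defaults: labelled (heavy) 1.785–1.820 g/ml,
unlabelled (light) 1.740–1.785 g/ml. Secondary DNA gradient defaults:
labelled (light) 1.665–1.695 g/ml, unlabelled 1.695–1.750 g/ml. Windows
are half-open [lo, hi) with the outermost boundary of the pair closed, so a
fraction sitting exactly on the shared boundary belongs to the denser
window and the extreme fraction is never dropped. Fewer than two fractions
in either class is an error naming the gradient.

**Sparse filtering.** Applied jointly across all fractions of all gradients
before any modelling: an OTU is removed when its total count is below 10
*or* its prevalence (share of samples with a nonzero count) is below 20%;
both boundaries pass. Prevalence is computed over all samples in the run —
whether to stratify it by nucleic-acid type is a judgement call we resolve
by not stratifying, which is the stricter reading when media are analysed
together.

**Normalization.** Median-of-ratios size factors: each sample's factor is
the median over reference OTUs (those detected in every sample) of its
count divided by the OTU's geometric mean, rescaled to geometric mean 1.
If no OTU is detected everywhere — common in sparse fraction data — the
geometric means fall back to positive counts only, with a warning.

**Dispersion.** Per-OTU method-of-moments on normalized counts,
α̂ = max(0, (s² − m̄)/m̄²), shrunk in log space toward a trend
α(μ) = a/μ + b fitted by least squares over OTUs with positive raw
estimates, with weight 0.5 on the raw estimate; the floor is 1e-8. OTUs at
or below Poisson variability (raw estimate 0) keep the floor rather than
being pulled up to the trend, and zero-mean OTUs are flagged untestable.
This estimator is deliberately simple and monotone; it is a documented
stand-in for heavier empirical-Bayes machinery and is validated by
parameter-recovery simulations in the tests (Poisson data lands at the
floor; NB data with α = 0.5 is recovered within [0.3, 0.7] at n = 40).

**Test.** Per OTU, a two-group NB GLM with log link and log size factors as
offset, fitted by vectorized Fisher scoring over all OTUs simultaneously
(linear predictors clamped at ±30 so all-zero groups degenerate gracefully).
One-sided Wald p for β₁ > 0; BH correction within each gradient separately.
`model_enriched` requires p_adj < 0.1 *and* log₂FC > 0.25 — the fold-change
threshold is a post-hoc filter on the estimate, not part of the null
hypothesis, since FDR and fold-change are stated as two separate criteria;
a threshold-based composite null would be the alternative reading. For an
OTU with a group entirely at zero the reported log₂FC falls back to the
ratio of group means with 0.5 pseudo-counts; the test itself always uses
the NB likelihood. The fit agrees with `statsmodels` GLM coefficients and
standard errors to 1e-6, and Wald p-values agree with a 5000-resample
parametric bootstrap within 10% (plus Monte-Carlo error) on desk-scale
instances — both are test-suite checks, keeping the implementation and its
oracles on separate routes.

**Confirmation.** Two post-model gates formalize the visual checks used in
gradient-resolved SIP. (1) Abundance: mean normalized count ≥ 1.25.
(2) Hump shape: the OTU's normalized density profile, smoothed with a
3-fraction moving average, must peak inside the labelled window and exceed
twice the profile's median (both parameters config-exposed; the factor-2
prominence rule is our formalization of "a visible hump", chosen so a flat
profile can never pass). `confirmed` = model ∧ abundance ∧ hump in at
least one gradient.

**Control gradients** are analysed identically and their model-enriched
count is reported (expected 0). The alternative `vs-control` mode compares
the labelled-window fractions of a ¹⁵N gradient against the same window of
a control gradient with the same machinery; it is more exposed to
between-vial effects and exists for comparison.

## Diversity (`diazosip.diversity`)

Morisita–Horn dissimilarity per its standard formula (abundance-weighted,
depth-insensitive, in [0, 1]); classical PCoA by double-centering −½D²,
eigendecomposition, and scaling the top-k positive eigenvectors by √λ.
Negative eigenvalues are returned but never embedded; k is truncated with a
warning when fewer positive eigenvalues exist. Cross-checked against
scikit-bio's PCoA in the tests.

## Raman harness (`diazosip.raman`)

Preprocessing order is fixed: alignment check → baseline correction →
normalization. The alignment check requires a local maximum within
±3 cm⁻¹ of the 1003 cm⁻¹ phenylalanine reference. Baseline correction is
the iterative modified-polyfit scheme: fit a sixth-degree polynomial,
clip intensities to the fit, repeat until the relative RMS change of the
fitted baseline drops below 0.01 (our convergence functional; the
tolerance could equally be defined on coefficients) or 100 iterations.
Normalization divides by the sum of absolute intensities. Spectra on
different grids are linearly resampled to a common 2 cm⁻¹ grid first.

Classification uses random forests (500 trees by default, √p features,
no depth limit, seedable; chosen for stability, not tuned). The two-class
mapping is exact: {0, 5} at% → unlabelled, {10, 25, 50, 100} at% →
labelled. Out-of-bag votes provide the internal confusion matrix; samples
never out-of-bag (only possible with very few trees) are counted as
errors, with a warning. Leave-one-strain-out trains on all strains but
one and predicts every cell of the held-out strain.

Metric definitions follow the SIP-Raman literature: the "false positive
rate" divides by *predicted-labelled* (a false-discovery rate) and the
"false negative rate" by *predicted-unlabelled* (a false-omission rate).
Both are implemented exactly as defined; the conventional miss rate
(1 − sensitivity) is reported separately as `miss_rate` to avoid
ambiguity. Zero denominators yield NaN, never an exception.

## Synthetic data (`diazosip.synthetic`)

**Gradients.** 20 equal-width density bins spanning 1.740–1.835 g/ml (RNA;
fraction density = bin midpoint, i.e. a linear gradient assumption). Each
OTU's template mass is a Gaussian band: unlabelled RNA centres at
1.773 g/ml (inside the 1.760–1.786 g/ml range where unlabelled RNA
concentrates) with SD 0.008 g/ml, shifted by 0.015 g/ml × label fraction
when labelled. A background component (default 5%) spreads mass uniformly
across the gradient, since some template is always recovered everywhere.
In DNA mode the unlabelled centre follows the classic linear G+C relation
1.660 + 0.00098·GC%, compressed into the secondary gradient's recovery
range above the light window, and labelling re-centres the band into the
1.665–1.695 g/ml light window. Reads are multinomial draws per fraction
over OTUs from the expected mass shares, optionally multiplied by a
per-(OTU, fraction) Gamma factor with dispersion 0.1 so downstream NB
modelling is well specified. Read depth defaults to 3000 per fraction,
the per-sample scale of a post-filter MiSeq SIP run; exact depths are not
knowable and are parameters. Community relative abundances are lognormal
(μ = 0, σ = 1.5 — a typical rank-abundance steepness for soil);
`fixed_abundances` pins chosen OTUs for detection-threshold experiments.
The qPCR profile is the expected per-fraction share of total template.

What this generator does *not* emulate: centrifugation physics, diffusion,
rotor geometry, chimeras, sequencing error, taxon-specific amplification
bias, or between-vial ("bottle") community differences — labelled and
control gradients share one community. Passing tests therefore show the
inference is correct *given* the band-plus-background count model, not
that every real-data failure mode is covered.

**Spectra.** 400–1914 cm⁻¹ in 2 cm⁻¹ steps; Gaussian peaks (width
8 cm⁻¹); indicative peaks at 728, 783, 1174, 1247, 1340, 1480 and
1577 cm⁻¹ shift by −6 cm⁻¹ × at%/100 by default (so the 0 vs 5 at%
difference is a sub-grid 0.3 cm⁻¹); 1003 cm⁻¹ never shifts. The default
eight-strain panel mirrors a phylogenetically diverse collection: four
strains with the full repertoire, one lacking 728, one lacking 1174/1480,
and two cyanobacteria-like strains with only 1247/1340/1480, broader
peaks, and centres offset by 3–4 cm⁻¹ — the offset is what makes
leave-one-strain-out collapse for them, emulating how a spectrally
divergent taxon defeats a classifier trained on other strains. A
polynomial baseline (degree ≤ 6) stands in for fluorescence background,
plus per-cell intensity scaling (±20%) and Gaussian noise (SD 0.01).
Real strain-specific performance numbers are not reproducible from
synthetic spectra; only the qualitative behaviours (chance at zero shift,
low error at large shift, strain-dependent degradation) are claimed.

**Timecourses.** Printed mean ± SEM summaries are treated as draw
parameters: per-replicate SD = SEM·√n, so the simulated sample mean has
the configured SEM in expectation.

## Problem sizes and determinism

Stochastic checks use 100 seeded null gradients and 50 seeds per
spiked-abundance condition (300 OTUs, 20 fractions, 3000 reads/fraction),
and Raman runs with 10 cells per strain × level and 200 trees — sizes at
which the Monte-Carlo error of the reported rates is a few percent. Every
generator and model takes an explicit seed; fixed seeds give bit-identical
outputs, and pipeline outputs embed the configuration hash and seed.

## Known limitations

- The dispersion estimator is a simple shrinkage scheme, not an
  empirical-Bayes posterior; no numerical parity with any existing
  differential-abundance package is intended.
- Wald inference is asymptotic; with very few fractions per window
  (minimum 2) p-values become approximate. The bootstrap agreement check
  covers the default window sizes (7–10 fractions per class).
- The hump diagnostic is a formalized heuristic; its smoothing width and
  prominence factor are exposed and their defaults are conventions.
- BIOM containers are not read or written; count tables travel as TSV.
- No read QC, OTU picking, chimera removal or taxonomic classification:
  the pipeline starts from a count table.
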