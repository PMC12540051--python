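# Methods

This note documents the models, estimators and numerical choices behind
`agscope`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Single-cell activity scoring

A cell's deuterium uptake is scored as
`%CD = 100·I_CD/(I_CD + I_CH)`, with band integrals over the C–D stretch
(2,040–2,300 cm⁻¹) and C–H stretch (2,800–3,100 cm⁻¹). Band integration
is trapezoidal after subtracting a straight baseline and clipping
negative residuals to zero. The baseline is anchored on the *averaged*
outer 10 % of points at each window edge rather than the two endpoint
samples alone: a single noisy endpoint shifts the fitted line — and hence
the whole window's integral — by an amount proportional to the window
width, which at 1 % relative noise is enough to move %CD by several
percentage points. Averaging the edge regions suppresses that propagation
(observed worst-case recovery error drops from ≈4.5 to ≈1.1 percentage
points at 1 % of C–H peak-height noise) while keeping the two properties
the score relies on exact: invariance to multiplying all intensities by a
positive constant, and invariance to adding any linear baseline (the mean
of a line over an edge region equals the line at the region's centroid,
so linear drift is interpolated exactly).

Spectrum validity requires both the C–H and phenylalanine (990–1,015
cm⁻¹, around the ~1,000 cm⁻¹ ring-breathing mode) peak heights to exceed
`snr_min = 3` times a robust noise scale, estimated as 1.4826·MAD of the
detrended 1,850–1,900 cm⁻¹ silent region. Three-sigma is the conventional
detection limit; a flat or empty spectrum is invalid, never an error.

The activity threshold is `mean + 3·SD` of water-control %CD values,
with the sample SD (n−1). Classification is strict (`%CD > threshold`),
the conservative reading at the boundary. Controls are pooled across
donors by default (per-donor thresholds are a configuration option).
Note that this threshold is *not* monotone in every control value: raising
a control that lies below the control mean can shrink the SD faster than
it raises the mean. It is monotone in the largest control value, which is
the property the tests assert.

Condition comparisons pool cells over donors into a one-way ANOVA. This
deliberately ignores the donor hierarchy (cells within donors are not
independent); it mirrors common practice for per-cell activity panels and
is reported as F and p only.

## In-silico RACS

The sorter's two real-time indices use **raw** (non-baseline-subtracted)
trapezoidal integrals, as a real-time instrument computes them:
`Pc = I_1620–1670(cell)/I_1620–1670(medium)` (≈1 when no cell is in the
measurement volume; the 1,620–1,670 cm⁻¹ window covers the amide I band)
and `PL = I_CD/I_1850–1900`. Baseline subtraction would change the scale
on which the control-derived thresholds (Pc = 1.1, PL = 6.0) were set,
which is why the indices and the %CD score use different integral
conventions. Denominators are floored at 1e−12 intensity-area units; a
non-positive medium integral is an error since there is no background to
normalize against. The collect decision is conjunctive and strict:
`Pc > 1.1 AND PL > 6.0`.

Because PL is a raw ratio of a 260 cm⁻¹ window to a 50 cm⁻¹ window, any
additive background inflates the numerator ≈5× faster than the
denominator. This is a genuine property of raw-ratio sorting indices, not
an artifact: unlabeled cells on a bright background drift toward the PL
threshold, which is why the demo cohort shows a small borderline-collect
fraction among unamended cells.

The run simulator misdirects each decided cell independently with
probability `1 − accuracy` (default accuracy 0.983). The reported
run-to-run accuracy spread (0.017) is carried as metadata but not applied
as per-run jitter: the per-cell Bernoulli model is what the binomial
consistency checks assume, and adding jitter would change only the
variance, not the mean, of misdirection counts. Duration is
`n/throughput` (500 cells h⁻¹ default); colonies are
Binomial(n_collected, cultivation_p); the cultivation success rate is
`100·colonies/sorted`. Cells are conserved by construction.

## Enrichment analysis

`EF = 2A/(A+B) − 1 = (A−B)/(A+B)` per genus and donor, with A the treated
and B the donor-matched no-amendment relative abundance at the same
timepoint. `EF(0,0) := 0`: the formula is 0/0 there, and zero (no
evidence of change) is the only antisymmetric choice. Note the endpoint
+1 is attained only when B = 0; a genus that comes to dominate the
treated sample plateaus at `(1−B)/(1+B)`.

Significance is a one-sample z of the per-donor EFs against zero
(`z = mean/(SD/√n)`, two-sided normal p), BH-adjusted across the genera
of one (treatment, timepoint) stratum, with the call requiring mean
EF > 0 and adjusted p < 0.05. The SD is floored at 1e−8 so unanimous
effects yield a finite, extreme z. Two consequences worth knowing:
with 10 donors the normal (rather than t₉) tail rejects ≈8 % of true
nulls at nominal 5 % — the per-donor t alternative is a one-line change
but the z form is the documented default — and BH operates on those
slightly anti-conservative p-values, so the realized false-call rate is
controlled empirically (≈1 % per genus in the null simulations) rather
than by the BH guarantee alone.

Bray–Curtis dissimilarity is `Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)` on relative abundances;
no rarefaction or depth correction is applied anywhere (all analysis is
on proportions). PERMANOVA partitions the Gower-centered squared
dissimilarity matrix by sequential (Type I) sums of squares —
`tr(H_k G) − tr(H_{k−1} G)` over cumulative QR-orthonormalized design
matrices — with donor entered before treatment, free (unrestricted) row
permutations, and `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)` (999
permutations default). This matches vegan's `adonis2(…, by="terms")` to
numerical precision on shared inputs. When a design separates groups
perfectly the residual SS cancels to rounding error; it is floored at
1e−12·SS_total and F reported as +∞. Permutations that map the group
partition onto itself then tie with the observed statistic, so the
attainable minimum p is `(1 + #ties)/(1 + n_perm)`, not always
`1/(1 + n_perm)` — the tests account for this exactly. PCoA is classical
scaling (double-centering, symmetric eigendecomposition) with
non-positive-eigenvalue axes dropped.

## Growth and coculture

Replicate growth curves are summarized by trapezoidal AUC of
blank-corrected OD₆₀₀ (per-replicate first-timepoint blank by default;
plate-blank handling upstream is out of scope). The growth boost is the
**ratio** of mean AUCs (treated/control) — the only dimensionless reading
of "relative to control" — with a two-sided equal-variance Student's
t-test on the 3+3 replicate AUCs (Welch available by flag). A zero mean
control AUC leaves the boost undefined (NaN) rather than infinite.

qPCR standard curves are ordinary least squares of Cq on log₁₀ copies
over ≥3 dilution levels; efficiency is `10^(−1/slope) − 1` (the ideal
slope −3.3219 = −1/log₁₀2 gives 100 %); a non-negative slope is rejected
as an invalid assay. Quantification inverts the curve,
`copies = 10^((Cq−intercept)/slope)`.

Coculture cross-feeding reports three log₂ fold changes, because a single
contrast cannot serve both purposes: the within-arm L2FC (24 h vs 0 h, on
replicate means) for each arm, and the cross-arm L2FC (coculture vs
monoculture at 24 h) whose replicate-level Student's t-test (3+3) carries
the significance call. The pseudocount defaults to the smallest positive
quantified value in the run, avoiding −∞ on zero wells while staying on
the data's own scale. When the degrader strain's own coculture
quantifications are supplied, its within-coculture L2FC is reported to
flag growth suppression of the degrader.

## Isolate census

Species and phylum counts with fractions of the total; every species must
map to exactly one phylum (violations are listed in the error). The
species→phylum table for the 16 reference species ships with the package
and is user-extensible via TSV. Representative selection is one isolate
per species with a deterministic tie-break (lexicographically lowest
isolate id) — a documented, reproducible stand-in for the study's
frequency-and-growth-based choice.

## Synthetic data: what it does and does not emulate

* **Spectra** are sums of Gaussian bands — C–D at 2,170 cm⁻¹ and C–H at
  2,950 cm⁻¹ (FWHM 40 cm⁻¹), phenylalanine at 1,003 cm⁻¹ (FWHM 12), amide
  at 1,650 cm⁻¹ (FWHM 30) — on a linear baseline with white Gaussian
  noise, sampled at 1 cm⁻¹ over 400–3,200 cm⁻¹. The C–D/C–H areas are
  split so the noise-free integral ratio equals the requested true %CD
  (relative error < 1e−6). Gaussians are the simplest testable lineshape;
  real spectra have Voigt-like bands, cosmic-ray spikes, detector
  etaloning and structured autofluorescence, none of which are modeled —
  so passing recovery tests demonstrates correctness of the estimator,
  not robustness to every instrument artifact.
* **Count tables** draw per-genus log-abundances Normal(0,1) shared
  across donors plus Normal(0, donor_logmean_sd=1) donor offsets,
  softmax-normalized; treated samples multiply planted genera by the
  effect multiplier and renormalize; every sample is Multinomial(depth).
  Defaults (10 donors, 30 genera, depth 50,000, multiplier 4 for planted
  effects) reflect a 10-donor treated-vs-NA incubation design with strong
  inter-individual variation. Real 16S data add compositional zero
  inflation, overdispersion beyond multinomial, and taxon correlations.
* **Growth curves** are logistic `K/(1+e^{−r(t−lag)})` (defaults K = 1
  OD, r = 0.5 h⁻¹, lag = 5 h) sampled every 0.5 h for 48 h with OD noise
  0.01, three replicates — matching a 48 h plate-reader run read every
  30 min; the unboosted condition is a flat 0.05 OD baseline.
* **qPCR** wells are `Cq = slope·log₁₀(copies) + intercept + noise` in
  triplicate per 10-fold dilution.
* **Census** records default to the reference 98-isolate, 16-species
  composition; the seed shuffles record order only, leaving every summary
  invariant.

All generators are bit-reproducible for a fixed seed (PCG64).

## Problem sizes

The test suite and acceptance checks run at desk scale, chosen so each
Monte-Carlo assertion has adequate resolution: 100 seeds for %CD
recovery, 200 runs of 1,000 cells for the sorting-accuracy binomial
check, 50 simulations each for null and planted enrichment (10 donors ×
30 genera × 50,000 reads), 500 null PERMANOVA simulations of 12 samples
at 199 permutations, and a 2,001² grid for the EF bound. The full suite
completes in well under a minute.

## Known limitations

* The enrichment z-test's normal tail is anti-conservative at small donor
  counts (see above); interpret per-genus p-values at n ≤ 10 donors
  accordingly.
* PERMANOVA permutations are free; restricted (within-donor) permutation
  schemes are not implemented, so treatment p-values lean on the donor
  term absorbing donor structure.
* Pc/PL thresholds are instrument-calibrated constants; the package
  applies them but provides no recalibration routine.
* The ANOVA on pooled cells ignores donor-level clustering.
* No absolute abundance for communities (no spike-ins); EF is strictly a
  relative, within-donor statistic.
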