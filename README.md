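# agscope

Analysis toolkit for studies of **arabinogalactan (AG) responsiveness in
gut microbiota** that combine single-cell Raman stable-isotope probing,
Raman-activated cell sorting (RACS), 16S community profiling, and isolate
physiology. It is aimed at microbiome researchers who want the complete
downstream analysis — from raw per-cell spectra and genus count tables to
enrichment calls and cross-feeding statistics — as a tested, scriptable
Python library with a matching synthetic-data generator, so every stage
can be exercised and validated without access to instrument or sequencing
data.

## What it computes

**Single-cell activity (%CD).** Cells incubated in heavy water form C–D
bonds in proportion to their metabolic activity. Per cell,

```
%CD = 100 · I_CD / (I_CD + I_CH)
```

where `I_CD` and `I_CH` are baseline-corrected trapezoidal band integrals
over 2,040–2,300 cm⁻¹ (C–D stretch) and 2,800–3,100 cm⁻¹ (C–H stretch).
Spectra are valid only if the C–H band and the phenylalanine peak
(~1,000 cm⁻¹) are clear above noise. Cells are *active* when %CD exceeds
`mean + 3·SD` of water-control cells (no D₂O). Conditions are compared by
one-way ANOVA.

**In-silico RACS.** Each cell gets a cell index
`Pc = I_1620–1670(cell) / I_1620–1670(medium)` and a labeling index
`PL = I_CD / I_1850–1900` (raw integrals); a cell is collected iff
`Pc > 1.1` and `PL > 6.0`. The run simulator applies the platform model —
sorting accuracy 98.3 % (each decided cell misdirected independently),
throughput 500 cells h⁻¹, binomial post-sort cultivation — and reports the
cultivation success rate `100 · colonies / cells sorted`.

**Community enrichment.** For treated relative abundance *A* and the
donor-matched no-amendment control *B* at the same timepoint,

```
EF = 2A / (A + B) − 1   ∈ [−1, 1]
```

per genus and donor. A genus is significantly enriched when its mean EF
across donors is positive and the Benjamini–Hochberg-adjusted *p* of a
one-sample z-test falls below α = 0.05. Community structure is assessed by
Bray–Curtis dissimilarity with a sequential (Type I, adonis-style)
PERMANOVA over donor + treatment, and PCoA ordination.

**Growth & coculture.** Substrate response is the AUC growth boost
`mean AUC(AG) / mean AUC(NA)` over replicate OD₆₀₀ curves with a two-sided
Student's *t*-test (n = 3 + 3). Cross-feeding is quantified by
strain-specific qPCR against a 10-fold dilution standard curve
(`Cq = slope·log₁₀ copies + intercept`, efficiency `10^(−1/slope) − 1`)
and reported as log₂ fold changes.

**Isolate census.** Species/phylum tabulation of sorted-and-cultivated
isolates with deterministic one-per-species representative selection.

## Worked example

The all-synthetic demo simulates every input with known ground truth and
runs the full pipeline:

```bash
agscope demo --seed 7 --out demo_run
```

From `demo_run/run_manifest.json` (80 cells: 40 AG-stimulated at ~18 %CD,
40 unamended at ~2 %CD, thresholded on 30 water controls):

```
raman      threshold = 1.09 %CD, ANOVA F = 300.1, p = 1.9e-28, n = 80
sort       80 analyzed, 44 collected, 1 misdirected, 0.16 h at 500 cells/h
census     98 isolates, 16 species, phyla {Actinomycetota: 72, Bacteroidota: 16, Bacillota: 10}
enrichment 3 genera called enriched (the 3 planted); PERMANOVA R²: donor 0.94, treatment 0.06
growth     AUC boost = 208.6 vs a no-growth control, p = 1.3e-07
coculture  L2FC(co, 24 h vs 0 h) = 2.23, p = 3.0e-07, qPCR efficiency 100.0 %
```

Reading the numbers: the activity threshold separates labeled from
unlabeled cells two orders of magnitude below the stimulated signal; the
sorter collects the AG-responsive subpopulation (44/80, with a handful of
borderline unlabeled cells — Pc/PL thresholds are deliberately close to
the unlabeled distribution); the enrichment stage recovers exactly the
three genera planted at 4-fold enrichment while donor identity dominates
community variance; and the coculture arm grows ~4.7-fold (2.23 log₂)
over its monoculture baseline.

Individual stages run on files via `agscope simulate|raman|sort|census|
enrich|growth|coculture --help`, or directly from Python:

```python
from agscope import SpectrumSimSpec, gen_spectrum, compute_cd_fraction
spec = gen_spectrum(SpectrumSimSpec(cd_fraction_true=30.0, noise_sd=0.05, seed=1))
print(compute_cd_fraction(spec))   # 30.03
```

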