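# bloodsrna

A pipeline for building and analysing small-RNA (sRNA) expression atlases of
purified blood components — plasma, erythrocytes, thrombocytes, monocytes,
neutrophils, eosinophils, basophils, NK cells, CD4+ / CD8+ T cells and B
cells. Circulating sRNAs are promising minimally invasive biomarkers, but a
whole-blood measurement cannot say *which* cell type a signal comes from:
cells are lysed on collection and the mixture is all that remains. Sorting
the major blood components first, sequencing each fraction, and recording
matched cell counts and extraction metrics makes the attribution problem
tractable. This package implements the computational side of that design
for bioinformaticians working with such data: annotation collapsing, sample
QC, normalization, content-weighted deconvolution and marker statistics,
plus a seeded synthetic-cohort generator that provides ground truth for
recovery testing.

## The model

Sequences mapping to several reference classes are resolved by the priority
miRNA > tRNA > rRNA > Y RNA > snoRNA > lncRNA > snRNA > piRNA; rRNA- and
Y-RNA-derived fragments are subcategorized by the 25-nt bin of their start
position on the parent transcript (label `PARENT-bin⌈start/25⌉`). Reads are
collapsed per label, filtered (length > 17 nt; detected in ≥ 3 samples of
some component; ≥ 2 RPM somewhere), and normalized to reads per million.

The core quantity is the **sRNA content** α — the sRNA mass per µl of whole
blood attributable to one purified component of one donor. For a cellular
fraction of cell type *c* from donor *d*:

    α_{c,d} = c_sRNA · V_elution · n_blood_count / n_sorted_count

(eluted concentration × elution volume gives eluted mass; divided by sorted
cells gives mass per cell; multiplied by the donor's blood count gives mass
per µl blood). For plasma, with V_input µl of plasma extracted and an
assumed plasma volume fraction of 0.5:

    α_d = c_sRNA · V_elution / V_input · 0.5

Per component *b* and sRNA *s*, RPM expression x_{b,s,d} is scaled by the
sample's content and averaged over the D_b usable donors,

    x̄_{b,s} = (1/D_b) Σ_d x_{b,s,d} · α_{b,d}

and each sRNA's scaled means are normalized across the B components:

    P_{b,s} = x̄_{b,s} / Σ_{b'} x̄_{b',s}

P_{b,s} is the proportional contribution of component *b* to the
whole-blood signal of sRNA *s*; rows sum to 1 and are invariant to global
rescaling of α. Overrepresented sRNAs per component are called by a
one-vs-rest Wilcoxon rank-sum test on log2(RPM+1) with Benjamini–Hochberg
adjustment (passing: adjusted p < 0.05, increased fold change, expressed in
every sample of the component).

## Worked example

The numbered scripts under `analysis/` run the full study design on a
synthetic cohort (52 donors × 11 components, 539 fractions after
volume-driven dropout):

```
$ python analysis/01_simulate_cohort.py --seed 1
cohort: 52 donors, 539 sorted fractions (496 cellular), 331 sequences, 4 planted mislabeled samples

$ python analysis/02_annotate_and_normalize.py
collapsed to 300 annotation labels x 539 samples

$ python analysis/03_quality_control.py --seed 1
539 fractions in; 25 excluded for purity <= 70% (4.6%), 514 remain
4 excluded as embedding outliers (0.8%), 510 samples pass QC

$ python analysis/04_deconvolve.py
510 QC-passed samples, 15 skipped (no sRNA content); contributions for 300 features
mean contribution per component:
  erythrocytes    0.470
  thrombocytes    0.176
  neutrophils     0.097
  ...
recovery vs simulated truth: mean abs error 0.0005, max 0.0177
```

The QC lines show the two exclusion stages: impure fractions (purity ≤ 70%
by flow cytometry) and samples that do not cluster with their own component
in a 2-D t-SNE embedding (operationalized as a k-nearest-neighbour majority
rule). The deconvolution output says erythrocytes dominate the simulated
whole-blood sRNA mass — they are by far the most numerous cells — and that
the estimated contribution matrix recovers the generator's ground truth to
within half a percentage point on average. `05_profiles_and_markers.py` and
`06_whole_blood_correlation.py` add relative profiles (features < 2% pooled
as 'others'), class-aggregated profiles, marker calls, and per-donor
correlations between whole-blood expression and blood counts.

The same stages are available as a CLI (`bloodsrna simulate | annotate |
prefilter | qc | normalize | deconvolve | profile | markers | correlate |
run-all`) for file-to-file use.

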