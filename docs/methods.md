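# Methods

## Annotation model

A sequenced fragment may map to references of several RNA classes. The
pipeline keeps one annotation per sequence, chosen by the fixed class
priority miRNA > tRNA > rRNA > Y RNA > snoRNA > lncRNA > snRNA > piRNA.
Within a class, ties are broken by the lexicographically smallest
synthesized label; this convention is declared rather than inferred — it
makes resolution deterministic and independent of candidate order, which a
"first match wins" rule would not be.

rRNA- and Y-RNA-derived fragments are binned on their parent transcript:
bin k covers 1-based positions [25(k−1)+1, 25k], the label is
`PARENT-bink`, bin numbering starts at 1 and the last bin may be short.
Exactly 25 nt was fixed as the bin width; the bins tile any parent length
without gaps or overlaps (property-tested). Collapsing sums sequence counts
per resolved label and conserves per-sample totals exactly.

## Filters and normalization

Canonical stage order: sequence prefilter → collapse → purity QC →
RPM → embedding QC → low-expression filter. The prefilter keeps sequences
longer than 17 nt (strict) that have ≥ 1 read in ≥ 3 samples of at least
one blood component. RPM divides each sample by its post-prefilter library
and multiplies by 10⁶; freshly normalized columns sum to 10⁶ within 1e-6
relative. The low-expression rule discards a *feature* whose maximum RPM
across samples is < 2 (strictly); removal rather than per-cell masking
keeps matrices rectangular, since masked zeros would be indistinguishable
from non-detection. A mean-based variant is available
(`low_expression_filter(..., statistic="mean")`). Library size is not
recomputed after the low-expression discard, so surviving features keep
their RPM values; the filters are idempotent.

## Sample QC

Two sequential gates:

1. **Purity**: cellular fractions pass iff flow-cytometry purity > 70%
   (strict; a fraction at exactly 70% fails). Plasma has no purity value
   and bypasses the gate.
2. **Embedding outliers**: log2(RPM+1) expression of the survivors is
   PCA-reduced (≤ 50 components) and embedded by t-SNE (perplexity 30,
   auto-reduced to (n−1)/3 for small cohorts, fixed random state). "Does
   not cluster with its own component" is operationalized as a kNN majority
   rule: a sample is excluded when fewer than half (`min_same_frac = 0.5`)
   of its k = 15 nearest neighbours in the 2-D embedding share its
   component label. Both parameters are exposed; k must stay below the
   per-component cluster size, so small cohorts need a smaller k (the unit
   tests use k = 4–5 at 5–8 donors). Visual cluster inspection has no
   unique formalization; other (k, frac) choices can flag different
   samples, and nothing is claimed about matching any particular manual
   exclusion beyond the simulated setting.

## Deconvolution

The contribution of component b to sRNA s is a forward apportioning, not a
regression on measured whole blood:

- cellular content: α_{c,d} = c_sRNA · V_elution · n_blood_count / n_sorted_count
  (pg per µl blood; pg/µl × µl × cells/µl ÷ cells),
- plasma content: α_d = c_sRNA · V_elution / V_input · plasma_fraction,
  with plasma_fraction = 0.5 by default (a configuration knob; no
  donor-specific hematocrit correction is implemented, so plasma's
  contribution may be overestimated for low-hematocrit donors),
- x̄_{b,s} = mean over D_b samples of x_{b,s,d} · α_{b,d}, where D_b counts
  only that component's QC-passed samples with a defined content — samples
  whose sRNA concentration could not be measured are skipped and reported,
  and a component with no content-bearing sample at all is an error,
- P_{b,s} = x̄_{b,s} / Σ_b x̄_{b,s}; all-zero features get undefined (NaN)
  rows and are counted, not silently zeroed.

P is invariant under global rescaling of α (units cancel), rows sum to 1
within 1e-9, and raising one component's α never lowers its proportions.
Whole-blood samples are never inputs to these equations; the method
predicts whole blood from fractions.

## Marker statistics

One-vs-rest comparison per component on log2(RPM+1): two-sided Wilcoxon
rank-sum via the tie-corrected normal approximation (scipy's
`mannwhitneyu`), Benjamini–Hochberg adjustment across features *within*
each component (standard for marker scans; no magnitude threshold beyond
fold change > 0, configurable). The fold change is
log2((mean_group RPM + 1)/(mean_rest RPM + 1)) — means on the linear scale,
+1 pseudocount for stability at zeros, since no canonical definition exists
for rank-based tests. A feature must additionally be expressed (RPM > 0) in
every sample of its component. Tests cross-check the p-values against an
exact permutation enumeration for group sizes ≤ 8 and against scanpy's
`rank_genes_groups` (tie-corrected Wilcoxon) as an independent
implementation; testing runs on the log layer, which is documented rather
than assumed.

Profiles divide each component's mean RPM per feature by the summed means;
entries below 2% pool into 'others'. Class-aggregated profiles sum RPM
within class *per sample* before averaging — with unequal per-sample
compositions this differs from averaging per-sample fractions, and the
order is tested. Detection sets (for cross-dataset comparison) require a
nonzero count in *every* sample of a component. Whole-blood correlation is
plain Pearson r of RPM versus cells/µl across donors, with zero-variance
pairs reported as missing.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- **Cohort**: 52 donors by default (12 healthy / 19 lung cancer / 21
  non-malignant lung disease, ages and sexes echoing that mix — cosmetic
  metadata), 11 components, one fraction per donor × component minus a
  configurable `dropout` applied only to thrombocyte/eosinophil/basophil/
  plasma fractions (mimicking lymphocyte prioritization under limited blood
  volume; 33 dropped gives the study-scale 539 fractions).
- **Blood counts**: log-normal per donor around textbook values (e.g.
  5·10⁶ erythrocytes/µl, 4000 neutrophils/µl). A helper converts relative
  subpopulation frequencies to absolute counts by multiplying the parent
  population's count.
- **Expression**: 300 features across the eight RNA classes (binned-class
  features drawn from real parent transcripts so labels are well-formed); a
  `marker_fraction` (default 0.2) of features is exclusive to one
  component, and each component's own markers jointly carry half its
  profile mass, giving the strong separation the embedding QC assumes.
  Counts are multinomial draws of `library_size` reads from the sample's
  profile, optionally Dirichlet-perturbed (`noise_dispersion`; 0 = pure
  multinomial) — the simplest model for relative-abundance sequencing.
  `exact_counts=True` substitutes the expectation, the noise-free limit
  used for closure checks. Fractions of sequences get split records or
  lower-priority decoy candidates so collapsing and resolution are
  genuinely exercised.
- **Metrics**: per-cell sRNA masses are free parameters (not calibrated to
  any measurement); concentrations are back-computed from them with
  log-normal noise (`content_noise_sd`), V_elution = 14 µl and
  V_input = 200 µl fixed — only the products enter the analysis.
- **Defects**: purity failures (≤ 70), mislabeled samples (a wrong
  component's profile under the original label), and missing content
  metrics are planted at configurable rates; integer overrides
  (`n_purity_fail`, `n_outliers`) pin exact counts where a scenario needs
  them, since rounding a rate cannot hit a fixed tally across seeds.
- **Truth**: `true_contributions` is the expected proportion matrix over
  exactly the samples deconvolution will use (purity-passing, non-outlier,
  content-bearing), computed from the realized per-sample contents and the
  noise-free expression expectation. The deconvolution path recomputes
  everything from the written metrics, so truth and estimate meet only if
  the content formulas, scaling, averaging and normalization are all
  correct.
- **Whole blood**: per donor, the expected mixture Σ_b α_b·x_{b,s}
  (normalized) sampled at `library_size`, with α from the donor's blood
  counts and the assumed per-cell masses.

What passing tests on this generator do *not* show: real fractions are not
pure draws from a fixed component profile (sorting impurity leaks other
components in), real library sizes and content metrics are far noisier and
correlated, mislabeled real samples are rarely wholesale profile swaps, and
real feature spaces are ~16× larger with heavy-tailed abundance. Recovery
results here validate the arithmetic and the code paths, not field
performance.

## Problem sizes and numerics

The test suite and the acceptance harness run cohorts of 5–52 donors, 300
features, and libraries of 2·10⁴–10⁶ reads; closure checks use 40 donors ×
11 components, recovery scenarios run 10 seeds each. Tolerances: profile
and contribution row sums 1e-9; noise-free closure 1e-3 (measured ~1e-16);
multinomial closure 0.02 mean absolute error (measured ~2·10⁻⁴ at depth
10⁶). Determinism comes from a single integer seed per run: the simulator
derives independent substreams for cohort, counts and whole blood via seed
sequences, and t-SNE/PCA carry fixed random states recorded in the QC
report. Degenerate inputs fail loudly: all-zero libraries, components
without content, sub-minimum group sizes and malformed table cells raise
typed errors naming the offending sample, component or cell.
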