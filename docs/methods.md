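# Methods

## Dosage model

The steady-state copy number of a marker at relative ori→ter position
*m* in an exponential culture is `N(m)/N(ter) = 2^((C/τ)(1−m))`, with C the
replication period and τ the doubling time. The post-termination period D
multiplies all copy numbers by `2^(D/τ)` and cancels from every ratio the
package reports, so D defaults to 0 and is retained in `CellCycleParams`
only for completeness. Replichores are treated as exactly symmetric: the
terminus is placed diametrically opposite the origin, and mirror positions
share one *m*. Asymmetric replichores would need a per-arm length in the
layout; none of the analyses here require it.

Chr2 initiates when two thirds of Chr1 has been replicated
(`crts_fraction = 2/3`) and terminates synchronously with Chr1, so it is
modelled as a chromosome with `C2 = C1(1 − crts_fraction)` whose terminus
copy number equals Chr1's. With genome-wide read normalisation this makes
ori2/ter2 = `2^((C1/3)/τ)` and ter1 = ter2 in expectation.

The Monte-Carlo oracle (`montecarlo_copy_number`) is an independent check
of the closed form, not a faster path to it: cell ages are drawn from the
exponential-culture age density `p(a) = (2 ln2/τ)·2^(−a/τ)` by inverse CDF,
and a cell of age *a* carries `2^floor((C(1−m)+D+a)/τ)` copies — each
replication round passes the marker `C(1−m)+D` minutes before the division
it precedes. The ratio to the terminus is estimated on paired ages with a
delta-method standard error; pairing removes most of the shared age
variance.

No value of τ, C or fork speed is asserted for real *V. cholerae*; the
fixture defaults τ = 30 min, C1 = 40 min were fixed once, giving
C/τ = 4/3 and an ori1/ter1 ratio of ~2.52, within the range MFA studies of
fast-growing vibrios report. Every analysis is written in terms of the
dimensionless C/τ, which is what the data identify.

## Coverage simulation and MFA

`simulate_mfa_coverage` draws independent Poisson window counts with mean
`depth·f_i/Σf`, where `f_i` is the expected profile (exponential phase) or
constant (stationary phase). "Coverage 100×" means an expected 100 counts
per 1-kb window, treating one count as one window-length equivalent of
sequence; only ratios of counts enter any downstream statistic, so the
read-length convention is immaterial. Poisson noise understates the
overdispersion of real libraries; GC bias, mappability structure and
repeat masking are absent, so passing recovery tests demonstrates
correctness of the estimators under the model, not robustness to every
artefact of real sequencing.

MFA normalises exponential coverage to the stationary control window by
window on total-count fractions, masking (never imputing) windows where
either track is zero — mirroring the removal of repeated sequences rather
than smoothing. For multi-replicon genomes the totals are genome-wide
(`normalize_genome`), which is what makes cross-replicon ratios (a Chr2
locus over ter1) meaningful. The profile is rotated into *ter–ori–ter*
order (a pure bijection; the window containing the terminus comes first)
and each replichore is fitted by OLS of log₂ frequency vs kb, slopes
reported positive toward the origin. R² < 0.95 raises a QC flag without
discarding the fit, so degraded inputs stay inspectable.

Zone statistics average the *linear-scale* frequency over 50 contiguous
1-kb windows centred on the zone midpoint, wrapping around the axis ends
(the terminus zone straddles both); ties at zone edges resolve toward the
origin side. Averaging `2^x` over a finite zone biases ori/ter ratios
~1–2% below `2^(C/τ)` at C/τ = 4/3 — a property of the zone definition
itself, reproduced rather than corrected. S10 dosage averages all windows
overlapping the annotated 13.4-kb interval (not just its end windows) over
the ter1 zone. `estimate_C_over_tau` is the exact inverse of the slope
relation and recovers C/τ within ~1% at 100× coverage (mean over seeds).

## The seven-strain relocation set

Strain names encode the S10 offset in kb from the origin of the named
replicon; the parental locus sits at 190 kb on Chr1. Chr2 placements are
mapped to an "effective" Chr1 position with equal expected dosage
(`(C1/τ)(1−m_eff) = (C2/τ)(1−m2)`), which orders the set the way the
relocation series is plotted: the Chr2-terminus strain falls beyond the
most distal Chr1 movant.

The dosage→growth mapping is synthetic and labelled as such: relative µ
declines linearly with effective distance beyond the parental position,
clamped at the parental value (movants closer to the origin gain nothing),
with the slope fixed so the most distal Chr1 movant grows 12% slower —
the magnitude reported for the most affected relocations. The mapping
exists to give end-to-end tests a known effect sign; the real functional
form is unknown, so only sign structure and monotonicity of the resulting
correlations are meaningful, not their magnitudes. Slower growth raises τ
with C fixed, which simultaneously lowers the slope, the ori/ter ratio and
S10 dosage — the coupling the association analysis is built to detect.
Per-strain MFA statistics average four independent simulated experiments,
as the strain summaries in the source experiments averaged at least four.

## Transcriptome summaries

NEV (normalized expression values) are total-count fractions scaled by
10⁶; the plotted scale is arbitrary since only ratios are used. Activity
of the 400-kb ori1-flanking region is its NEV sum; significance of the
difference vs the parental track is a two-sided permutation test (10,000
seeded shuffles of the region label across windows). The permutation
choice is this package's own procedure for a step whose original
significance calculation is not specified in reusable form.

Altered genes are `padj < 0.05` strict; direction is the sign of log₂FC,
with log₂FC = 0 counted in neither direction and tallied separately;
">2-fold" is `|log₂FC| > 1` strict. Mean up/down log₂FC is reported over
all significant genes of that direction (the alternative — restricting to
>2-fold genes — can be computed from the table but is not the default).
The generated DE tables reproduce the published marginal structure
exactly (8 / 111 / 662 / 742 altered genes; the text's 664 for the third
strain disagrees with its own table, and the table's 361+301 arithmetic is
used). Adjusted p-values are generated directly rather than via raw-p
simulation, since the pipeline consumes DESeq2-style adjusted tables.

## Enrichment

One best category per gene, ≤25 labels. Each category is tested with a
2×2 Pearson chi-square (no Yates correction) of DE status × membership;
expected cell counts < 5 are flagged, zero-margin categories are emitted
as degenerate rather than dropped. BH adjustment runs across categories.
The subsample validation redraws 30% of the altered genes without
replacement, reruns the full test *including BH re-correction* (the
original procedure does not state whether it re-corrected; re-correction
keeps every replicate identical in form to the main test) and reports the
fraction of replicates in which each category stays significant. The
default is 10,000 replicates; the test suite and acceptance script run
500, recorded in the output metadata — stability fractions converge well
before that.

## FRAP

"Half-time" is parameterised directly as the base-2 time constant:
`F(t) = F_inf − (F_inf − F_bleach)·2^(−t/τ½)` reaches halfway to plateau
at t = τ½. For single-exponential recovery from a stable baseline this
coincides with the literal time-to-half-recovery; the two diverge for
multi-component recovery, which this package does not model. Fits use the
post-bleach frames only; the pre-bleach level is the mean of all
pre-bleach frames. Non-convergent fits return flagged estimates instead of
raising. Acceptance requires R² > 0.8 and cell length < 6 µm; filters only
ever remove estimates, never alter them. The immobile fraction is
reported but never filtered on. Imaging decay shared with unbleached
neighbours is removed by subtracting the controls' mean drift relative to
their first frame, preserving the bleached cell's baseline. Dunn's
post-hoc z-tests (tie-corrected rank variance) follow Kruskal–Wallis;
multiplicity uses the same BH routine as the enrichment module, since the
original comparisons name Dunn's procedure but not a correction.

## Growth

µ is the steepest 8-point (40 min at 5-min sampling) sliding-window OLS
slope of ln(OD600), converted to natural-log h⁻¹; readings at or below
OD 0.02 are excluded as below-detection. Units are a package convention,
documented here because only ratios and correlations are consumed
downstream. The logistic generator applies multiplicative log-normal
noise. Correlations in `strain_association` are Pearson r with two-sided
t-distribution p-values (n−2 df) of the mean slope against unsigned
effective S10 distance, dosage, ori/ter ratio and µ.

## Numerical and design notes

- All generators take explicit integer seeds and are bit-reproducible;
  composite drivers derive child seeds by fixed offsets from one root seed.
- Window grids are 0-based half-open everywhere, 1000 bp by default; the
  GFF3 reader/writer converts to and from 1-based inclusive coordinates.
- Degenerate inputs fail loudly (all-zero control, zero-variance
  correlation vectors, constant association columns, sub-minimum window
  or frame counts) except where a flagged result is more useful than an
  exception (FRAP non-convergence, zero-margin categories).
- Problem sizes in the test suite and acceptance script (10–20 simulation
  seeds, 200 calibration replicates, 500 subsample draws) were chosen as
  the smallest sizes at which the Monte-Carlo error of each check is
  comfortably below its tolerance.

## Limitations

- No fork stalling, asynchronous initiation, rifampicin run-out, cell-size
  or division modelling; the dosage model is the steady-state multifork
  picture only.
- The synthetic data carry none of the biological couplings between
  stages (e.g. DE tables are independent of the simulated dosage), so
  cross-stage tests check plumbing and sign conventions, not biology.
- No read-level simulation (FASTQ/alignment), no DESeq2 re-implementation,
  no eggNOG alignment, no image segmentation; those stages are consumed as
  their tabular outputs.
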