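# s10pos

Analyses linking the genomic position of the **S10 ribosomal-protein locus**
(*s10-spc-α*, 13.4 kb, normally 0.19 Mb from *ori1*) in *Vibrio cholerae* to
replication-associated gene dosage, genome-wide transcription, cytoplasmic
fluidity and growth rate — for microbial genomicists studying how gene order
along the *ori–ter* axis shapes cell physiology.

## The model

In a culture doubling every τ minutes with a chromosome replication period of
C minutes, overlapping replication rounds (multifork replication) give a
marker at relative *ori→ter* position *m* ∈ [0, 1] the steady-state copy
number

```
N(m) / N(ter) = 2^((C/τ)·(1 − m))
```

so log₂ read coverage of exponentially growing cells falls linearly from
*ori* to *ter* with slope (C/τ)/L per kb of replichore (marker frequency
analysis, MFA). *V. cholerae* carries two replicons: Chr1 (2.96 Mb) and the
late-firing Chr2 (1.07 Mb), whose origin fires once two thirds of Chr1 has
been replicated (*crtS* licensing), so Chr2 behaves as a chromosome with
C₂ = C₁/3 and both termini share one copy number.

Moving S10 away from *ori1* lowers its dosage `2^((C/τ)(1 − m_S10))`. The
package quantifies the downstream readouts for a seven-strain relocation
series (parental + six movants, two on Chr2):

- **mfa** — coverage normalised to a stationary-phase control, *ter–ori–ter*
  axis layout, per-replichore log₂ slopes (QC: R² > 0.95), 50-window
  ori/ter zone ratios and S10 dosage;
- **transcriptome** — normalized expression values (NEV), activity of the
  400-kb *ori1*-flanking region with a permutation test, altered-gene
  bookkeeping (padj < 0.05, >2-fold splits), cross-strain overlap and
  log₂FC correlation;
- **enrichment** — per-category 2×2 Pearson chi-square with
  Benjamini–Hochberg correction and the 10,000×30% subsample stability
  validation;
- **frap** — imaging-decay correction, percent recovery, single-exponential
  recovery half-time `F(t) = F_inf − (F_inf − F_bleach)·2^(−t/τ½)` with
  acceptance filters (R² > 0.8, cell < 6 µm), Kruskal–Wallis + Dunn group
  comparisons;
- **growth** — sliding-window ln(OD600) fits for the maximum specific
  growth rate µ and the strain-level correlation matrix (slope vs position,
  dosage, ori/ter, µ);
- **genome / simulate** — the dosage model (closed form plus a Monte-Carlo
  cell-age oracle) and seeded generators for every input the pipeline
  consumes.

## Worked example

`analysis/` holds the numbered drivers. The strain-set analysis simulates
the full relocation series (four replicate MFA experiments per strain at
100× coverage, 1-kb windows) and prints:

```
$ python analysis/03_strain_set_associations.py --seed 1
   strain_id  s10_position_kb  s10_dosage  ori_ter_ratio  mean_slope  mu_per_h  mu_pct_of_parental
    Parental         190.0000      2.1747         2.4146      0.0009    1.3470            100.0000
   S10Tnp-35          35.0000      2.4335         2.4715      0.0009    1.3670            101.4846
  S10Tnp+166         166.0000      2.2064         2.5005      0.0009    1.3600            100.9604
  S10Tnp-510         510.0000      1.7048         2.3525      0.0009    1.3137             97.5276
 S10Tnp-1120        1120.0000      1.2285         2.2387      0.0008    1.2068             89.5875
 S10TnpC2+37        1020.7850      1.2879         2.2691      0.0008    1.2390             91.9830
S10TnpC2+479        1428.3614      1.0254         2.1459      0.0008    1.1443             84.9467

       variable       r      p  n
s10_position_kb -0.9912 0.0000  7
     s10_dosage  0.9705 0.0003  7
  ori_ter_ratio  0.9741 0.0002  7
       mu_per_h  0.9881 0.0000  7
```

Reading the table: S10 dosage falls from ~2.2 copies per terminus
equivalent (parental) to ~1.0 when the locus sits near the Chr2 terminus;
the replication slope and growth rate decline with it. The correlation
block shows the replication slope anti-correlated with S10 distance from
*ori1* and positively correlated with dosage, ori1/ter1 ratio and µ. Chr2
positions are reported as the Chr1-equivalent distance with the same
expected dosage, which places them beyond the distal Chr1 movants.

The other drivers cover the dosage-model oracle (`01`), MFA parameter
recovery and the stationary null (`02`), differential-expression
bookkeeping (`04`), enrichment calibration (`05`) and FRAP/growth
population comparisons (`06`). Each writes its tables under `results/`.

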