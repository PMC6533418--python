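# proteofix

Analysis pipeline for multiplex protein quantification by antibody
barcoding (nCounter-style counting of photocleavable oligonucleotide
tags), built for a question that matters in clinical breast-cancer
research: **can protein measurements from routinely fixed surgical
excisions be compared with those from immediately fixed core-cut
biopsies?** Formalin penetrates tissue at roughly 1 mm/h, so the
interior of an excision specimen spends hours unfixed; phospho-epitopes
decay during that window while stress-response proteins are induced.
Window-of-opportunity trials that compare a diagnostic core against the
post-treatment excision can mistake this pre-analytical artefact for
drug effect.

`proteofix` provides, as a library plus a thin CLI:

* **Normalization** of probe × lane count tables through the standard
  control chain: geometric-mean scaling on the 6 ERCC positive
  spike-ins, background subtraction of the 6 ERCC negatives and then
  the 2 IgG non-specific controls (with the IgG step toggleable for IHC
  comparison), Histone H3 housekeeping normalization (lowest-CV
  confirmation), exclusion of probes below the IgG level in every lane,
  half-minimum zero imputation, log2.
* **Paired statistics** per protein on the difference
  `log2(excision) − log2(core)`: exact Wilcoxon signed-rank tests,
  linear-scale percent changes with >50%/>75% reduction and >100%
  increase counts, Spearman association with tumour size, Mann–Whitney
  comparison by surgery type, phospho vs non-phospho difference
  coupling, and Spearman concordance with IHC scores (H-score, Ki67
  percent, 0–3+ ordinal), pooled and per specimen type. All three tests
  use exact small-sample p-values (full enumeration oracles in the test
  suite).
* **Two-way hierarchical clustering** (average linkage on 1 − Spearman
  rho after row-centring) with Newick export, and a dilution-replicate
  QC that checks each sample's dilution lanes cluster together.
* **A synthetic cohort generator** that emulates the study design — 16
  core/excision pairs, 26 targets (half phospho), fixation-delay-driven
  phospho decay and stress induction, negative-binomial counts, lane and
  input nuisance factors, paired IHC read-outs — with the latent truth
  returned for parameter-recovery testing.

## Worked example

```bash
python examples/02_paired_differences.py
```

simulates a 16-pair cohort, normalizes it and prints:

```
strongest reductions (phospho loss under delayed fixation):
protein  mean_percent_change  n_over_50pct_reduction  n_over_100pct_increase wilcoxon_p
 pGSK3B               -96.76                      16                       0   3.05e-05
pERK1-2               -96.33                      16                       0   3.05e-05
   pAKT               -84.85                      16                       0   3.05e-05
 p4EBP1               -84.14                      16                       0   3.05e-05
 pAMPKa               -80.48                      16                       0   3.05e-05

strongest increases (stress-response induction):
protein  mean_percent_change  n_over_50pct_reduction  n_over_100pct_increase wilcoxon_p
pan-KRT               133.06                       0                      12   3.05e-05
  4EBP1                61.73                       0                       3   3.05e-05
 ERK1-2                47.94                       0                       2   6.10e-05

proteins whose difference correlates negatively with tumour size (penetration-limited delays): 8
  pAKT: rho=-0.841, p=0.0000
  p4EBP1: rho=-0.782, p=0.0003
  ...
mean phospho vs mean non-phospho difference: rho=0.550, p=2.73e-02
```

Reading this: labile phospho-epitopes lose most of their signal in the
slowly fixed excisions (p = 3.05e-05 is the smallest two-sided p an
exact 16-pair signed-rank test can produce, 2/2^16); pan-keratin more
than doubles in most patients (stress induction); the loss grows with
tumour size when fixation is penetration-limited; and the mean phospho
and non-phospho differences are positively coupled across patients
because both trace the same per-patient delay. The other examples cover
normalization (`01`), IHC concordance (`03`, pooled Spearman exceeding
the within-specimen correlations) and clustering/dilution QC (`04`, the
lane 2-cut separating all 16 cores from all 16 excisions).

The same steps are available as shell commands:

```bash
proteofix simulate --seed 1 --out cohort/
proteofix normalize --counts cohort/counts.tsv --probes cohort/probes.tsv \
    --samples cohort/samples.tsv --out norm/
proteofix compare --expr norm/normalized.tsv --probes cohort/probes.tsv \
    --samples cohort/samples.tsv --out results/
proteofix run-all --config config.yaml   # one-command orchestration
```

All interchange is plain tab-delimited text (`counts.tsv`,
`probes.tsv`, `samples.tsv`, `ihc.tsv`); matrix files carry their
normalization stage in a header comment and round-trip to 12
significant digits.

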