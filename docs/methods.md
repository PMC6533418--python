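# Methods

`proteofix` analyses multiplex protein quantification data produced by
antibody–barcode assays (nCounter-style counting of photocleavable
oligonucleotide tags), with a focus on comparing paired FFPE specimens:
a core-cut biopsy fixed almost immediately and a surgical excision whose
interior fixes only as formalin penetrates the tissue. This note
documents the statistical model behind each component, the defaults and
why they were chosen, and what the synthetic validation does and does
not demonstrate.

## Normalization chain

Raw counts `x_pl` (probe `p`, lane `l`) pass through five stages, in a
fixed order recorded on the matrix as stage provenance:

1. **Positive-control (spike-in) normalization.** Each lane is scaled by
   `f_l = G / g_l`, where `g_l` is the geometric mean of the lane's six
   ERCC positive probes and `G` the geometric mean of the `g_l`. This
   removes hybridization-efficiency lane effects; choosing `G` as the
   reference makes the factors multiply to one. Any other fixed
   reference differs by one global constant that cancels in every
   within-matrix contrast (log2 differences, correlations, clustering);
   the constant itself is therefore not meaningful and not configurable.
   A zero spike-in count is an assay failure and raises an error naming
   the lane.
2. **Background correction.** Per lane, the geometric mean of the six
   ERCC negative probes is subtracted from endogenous and housekeeping
   counts, flooring at zero; then, unless disabled, the geometric mean
   of the two IgG probes — themselves negative-subtracted first — is
   subtracted likewise. Negative abundances are meaningless, hence the
   floor; zeros among negative/IgG control counts are lifted to 0.5
   before the log so a lane's background stays estimable. The
   IgG-subtraction toggle exists because the IHC comparison uses the
   branch without it; the pipeline always produces both branches when
   concordance is requested so the two analyses can never silently share
   the wrong matrix.
3. **Housekeeping normalization.** Counts are divided by
   `h_l / geomean(h)`, the lane's Histone H3 level relative to its
   across-lane geometric mean, correcting for sample input amount. With
   several housekeeping candidates, the one with the lowest coefficient
   of variation of log2 counts across lanes is selected ("lowest
   variation" operationalized as CV of log2 on background-corrected
   counts); the full CV table is reported.
4. **Undetected-probe exclusion.** An endogenous probe whose counts sit
   below the lane's IgG geometric mean in *every* lane is flagged and
   excluded from statistics. The check runs on the spike-in-normalized
   stage so endogenous and IgG counts are compared like for like, before
   either is background-subtracted.
5. **Half-minimum imputation and log2.** Per protein, zeros are replaced
   by half the smallest strictly positive value of that protein across
   all lanes jointly (not per specimen type), every imputation is
   logged, and values are log2 transformed. A protein that is zero
   everywhere must have been excluded at stage 4; reaching stage 5 in
   that state is an error.

A lane-wide multiplicative error is absorbed exactly (up to the global
constant above): scaling one lane by `c` shifts the final log2 matrix by
`log2(c)/n` uniformly and leaves all contrasts unchanged, which the test
suite asserts.

## Small-sample tests

Sixteen pairs is small enough that asymptotic p-values are avoidable,
so the three tests compute exact conditional p-values by default:

* **Wilcoxon signed-rank** (paired comparisons): zero differences are
  dropped (Wilcoxon's original treatment — consequential at this n and
  therefore documented), absolute differences get mid-ranks, and the
  null distribution of the positive-rank sum is computed exactly,
  conditional on the observed rank multiset, via the characteristic
  polynomial `prod(1 + z^{2r_i}) / 2^n` over doubled mid-ranks
  (identical to enumerating all `2^n` sign patterns, feasible to
  `n = 25`). Beyond 25 pairs: normal approximation with tie correction,
  no continuity correction.
* **Mann–Whitney U** (surgery-type comparisons): exact by enumerating
  all `C(n, n_a)` labelings of the pooled mid-ranks for `n <= 12`, else
  tie-corrected normal approximation.
* **Spearman correlation**: Pearson correlation of mid-ranks; for
  `n <= 9` the two-sided p enumerates all `n!` permutations, else the
  t approximation with `n - 2` degrees of freedom. Constant input yields
  a flagged result (`ok=False`) instead of an exception so batch
  analyses continue.

Two-sided p-values are `min(1, 2·min(lower tail, upper tail))` with
tails inclusive of the observed statistic, giving `p = 1` at the null's
centre and `p > 0` always. The exact thresholds were chosen so the
16-pair design always takes the exact Wilcoxon path. No multiple-testing
correction is applied by default (mirroring the exploratory design this
pipeline targets); a Benjamini–Hochberg helper is provided for
reporting.

Quartiles use linear interpolation of order statistics; the IQR
convention matters little and is documented rather than configurable.

## Paired analyses

The central statistic is `difference = log2(excision) − log2(core)` per
patient and protein, computed only for patients with both specimens
(others are listed as dropped). When a specimen has dilution-replicate
lanes, the untagged lane — else the canonical 10× working-dilution
lane — is the analysis lane; other replicates feed only the dilution QC.

Percent changes are computed per pair on the **linear** scale,
`100·(excision/core − 1)`, then averaged; the alternative convention
(change of the means) is reported alongside but is not the default.
Threshold counts use strict inequalities on the per-pair linear ratio:
ratio < 0.5 (>50% reduction), < 0.25 (>75%), > 2 (>100% increase), so a
pair at exactly half counts as neither.

Tumour-size association is the Spearman correlation of the difference
with size, listwise-excluding patients without a recorded size; surgery
comparison is Mann–Whitney on per-patient differences, excluding
unknown-surgery patients. The phospho/non-phospho analysis averages the
difference over phospho and over non-phospho proteins per patient and
correlates the two patient vectors (plus the mean phospho difference
against each individual non-phospho protein).

IHC concordance correlates the log2 matrix from the no-IgG branch with
IHC scores, pooled over both specimen types and within each type.
Ordinal scores (0–3+) enter through mid-ranks; no dichotomization is
attempted. IHC proteins that map to no panel target are reported as
skipped, not errors.

## Clustering and dilution QC

Heatmap scaling subtracts each protein's mean log2 value (row-centring).
Distances are `1 − rho` with mid-rank Spearman correlation — invariant
under any strictly monotone per-item transform — and trees use average
linkage, the common default for correlation-distance expression
heatmaps (configurable). Items are pre-sorted lexicographically so
distance ties resolve identically on every platform, and the two main
groups are read off structurally by removing the final merge rather
than by a height threshold. Constant items have undefined correlation
and are excluded with a notice. Trees are exported as Newick with merge
heights as branch lengths.

The dilution QC clusters replicate lanes on `log2(raw endogenous counts
+ 0.5)`: Spearman distance is invariant to the per-lane dilution
scaling, so normalization is unnecessary (and diluted spike-in ladders
can legitimately contain zero counts, which the normalization would
refuse). A sample passes when the smallest subtree containing all its
replicates contains no other sample's lane.

## Synthetic cohort generator

The generator produces the statistical structure the analyses assume;
it is a measurement-error model on top of a mechanistic delay model, not
a biochemical simulation.

**Latent layer.** Patient `i` has abundance `A_ip = base_p ·
LogNormal(0, 0.45)` for each of 26 panel proteins (13 phospho) and a
Histone H3 level (LogNormal sd 0.1 — stable by construction, which is
why it works as the input normalizer). Tumour sizes are log-normal with
median 33.5 mm (sd 0.45 on the log scale, giving quartiles near
25/45 mm); sizes above 30 mm are treated by mastectomy, giving the
designed 50/50 split.

**Delay model.** The core-cut fixes after 0.05 h. The excision interior
fixes after `d_i = half-thickness / penetration rate + handling offset`,
with formalin penetrating at 1 mm/h. In the default `surgery` mode,
lumpectomy specimens (left unsliced overnight) get half-thickness
`size/2` plus an 18 h offset; mastectomy specimens (sliced at ~10 mm)
get half-thickness capped at 5 mm plus a 12 h pre-slicing
transport/grossing offset, so typical delays are ~17 h (mastectomy) and
~22–33 h (lumpectomy). Two further modes exist because different
analyses isolate different mechanisms: `size_proportional`
(`d = size/2`, the penetration-limited configuration in which the
size coupling of the difference statistic is cleanest) and `constant`
(its no-coupling control, also used for exact-effect-size cohorts).

**Artefact layer.** During delay `d` a protein's immunoreactive
abundance becomes

    A · exp(−λ_p d) · (1 + γ_p (1 − exp(−d / τ)))

with lability `λ_p` (per hour), stress gain `γ_p` and stress time-scale
`τ = 2 h` (pre-fixation stress responses act within tens of minutes, so
the induction saturates early while decay keeps accruing). Phospho
targets carry the large labilities (pERK1/2 and pGSK3B at 0.2/h down to
pH3 at 0.0075/h) and no stress gain; non-phospho targets carry mild
lability (~0.02/h) plus stress gains from 0.3 up to 2.5 (pan-KRT). This
combination is what produces, at once: strong losses for most phospho
proteins, net increases for a few stress responders (>100% for pan-KRT
in most patients), near-zero net change for the remaining non-phospho
targets, and — because both phospho loss and net non-phospho change
decrease with the shared delay — a strongly *positive* correlation
between mean phospho and mean non-phospho differences across patients
(~0.8 at the defaults). A stress-only non-phospho model would flip that
correlation's sign and was therefore rejected. The per-protein rates
are not measurements; they were fixed once, at design time, to place
the generator in the regime the assay literature describes (fixation
artefact variance dominating between-patient variance), and the
acceptance studies characterize the pipeline *given* this mechanism.

**Measurement layer.** Expected counts per lane:
endogenous `lane · (input · (12·A_eff + ns_p) + 12)`, IgG
`lane · (input · 40 + 12)`, negatives `lane · 12`, spike-ins
`lane · ladder` with ladder (6400, 1600, 400, 100, 50, 25), housekeeping
like endogenous. `lane` is a log-normal hybridization-efficiency factor
(sd 0.15) shared by all probes of a lane; `input` a log-normal sample
input factor (sd 0.25) applied to tissue-derived signal only (spike-ins
and hybridization background are independent of input, which is exactly
why the chain needs both a spike-in and a housekeeping stage).
Non-specific antibody binding `ns_p` defaults to the IgG level (40), so
IgG subtraction removes it exactly in expectation; pEGFR is the
deliberate exception (`ns = 12`, abundance ≈ 0), which keeps its counts
below the IgG level in every lane and exercises the undetected-probe
exclusion on every default cohort. Counts are negative binomial with
variance `μ + 0.01 μ²`; dispersion 0 is the documented noiseless limit
(counts equal their means exactly), under which the chain provably
returns log2 abundance up to a per-protein constant — asserted to 1e-6
in the tests. IHC read-outs apply a saturating (Hill) transform of the
same latent abundance with Gaussian noise, clipped to the scale bounds;
the 0–3+ ordinal score bins the transform at quarters of its maximum.

A single generator stream, seeded once, produces all draws in a
documented order (sizes, abundances, housekeeping, lane effects, input
amounts, counts, IHC noise). Equal seeds give byte-identical cohorts
within this implementation; cross-implementation equality is not
promised, only distributional equivalence.

**What the generator does not emulate.** Spatial diffusion within
tissue (delay is a single number per specimen), cartridge/batch
effects, antibody cross-reactivity, isoform mismatches between
platforms (e.g. a probe seeing one isoform where IHC sees two),
inter-observer IHC variability, and section-to-section heterogeneity.
Passing the synthetic studies therefore shows the *pipeline* is
correct and well calibrated under the stated mechanism; it does not
validate the mechanism against real tissue.

## Validation studies and problem sizes

The acceptance studies (also runnable via `scripts/acceptance.py`) use:
a hand-worked 12-probe × 3-lane fixture checked to 1e-9; 200 random
tied instances per exact test (100 for the Spearman permutation,
`n ≤ 7`) against literal enumeration; 2,000 independent
single-protein 16-pair null cohorts for type-I error (the single-protein
design keeps the 2,000 tests independent — housekeeping noise is shared
within a cohort and would otherwise correlate them); 200 cohorts at a
true 50% reduction for power and bias; 100 cohorts each for the
size-coupling, clustering-separation and concordance studies; 50
dilution series of 6 samples × 3 dilutions. Everything runs in about a
minute on one CPU.

Observed at the defaults: null rejection ≈ 0.04–0.05 at α = 0.05
(slightly conservative, as expected for a discrete exact test); power
≈ 1.0 at a 50% reduction with mean estimated change ≈ −47% (the ~3-point
attenuation is the convexity of the linear-ratio mean under count
noise, visible only because the truth is known); perfect or near-perfect
specimen separation in the lane 2-cut; pooled IHC concordance ≈ 0.8
versus ≈ 0.6–0.75 within specimen types.

## Known limitations

* Background subtraction with flooring biases very-low-abundance
  proteins upward; their percent changes are dominated by the imputation
  rule, as the logged imputation events make visible.
* The exact Mann–Whitney enumeration is limited to pooled n ≤ 12; a
  16-patient surgery comparison (8 vs 8) uses the tie-corrected normal
  approximation.
* The ordinal IHC scale carries little rank information when most
  patients fall in one category; concordance for such markers is noisy.
* The generator's rate constants are design choices, not estimates; any
  quantitative statement about real specimens requires fitting them to
  data, which is out of scope here.
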