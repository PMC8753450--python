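# Methods

## The differential-abundance model

A bulk TCRβ sample is a vector of template counts over clonotypes
(clonotype = CDR3β nucleotide junction + gene-level V/J calls; allele
suffixes are stripped because allele calls are unstable across samples).
All frequencies are *productive* frequencies: unproductive rearrangements
are retained in files but excluded from every statistic.

Between two samples of the same repertoire, clone counts vary more than
multinomial sampling predicts. We model a clone's count as beta-binomial:
`x ~ BB(N, μ, φ)` with mean `Nμ` and variance `Nμ(1−μ)(1+(N−1)φ)`, where
`φ = 1/(α+β+1)` is the overdispersion; `φ = 0` recovers the binomial.

The per-clone test conditions on the total `s = x₁+x₂` and uses the
allocation null

    w(k) ∝ BB(k; N₁, μ̂, φ) · BB(s−k; N₂, μ̂, φ),  μ̂ = s/(N₁+N₂),
    k ∈ [max(0, s−N₂), min(s, N₁)],

normalized over the support. The two-sided p-value is the summed mass of
all allocations with `w(k) ≤ w(x₁)·(1+10⁻¹²)`; the tolerance multiplier
makes tie inclusion reproducible across floating-point platforms. At
`φ = 0` the construction reduces *exactly* to the two-sided Fisher exact
(hypergeometric) test — this degeneracy is the design anchor, and the test
suite verifies it against full hypergeometric enumeration over all tables
with margins up to 50.

Numerical choices:

- The beta-binomial log-pmf is computed with `betaln`/`gammaln`
  differences, except below `φ = 10⁻⁶` where `α, β` are so large that
  those differences lose ~10⁻³ absolute accuracy; there an exact product
  form via cumulative log sums is used instead.
- `clone_test` snaps `φ < 10⁻⁷` to the exact `φ = 0` path. At such φ the
  dispersion changes p-values by under ~10⁻⁴ relative at survey depth,
  while its numerical perturbation would break exact hypergeometric ties
  (tied tables would lose half their two-sided mass).
- Degenerate inputs: a clone absent from both samples is a no-information
  error; `μ̂` is clipped into `(0, 1)`; p-values are clipped into `(0, 1]`.

**A regime limitation worth knowing.** With a single constant φ, a clone
whose pooled frequency `μ̂` is below `φ/(1−φ)` has `α < 1`: the conditional
null becomes U-shaped and the test loses essentially all power (a clone
going 0 → 40 of 20,000 templates has p ≈ 1 at φ = 0.005 but p ≈ 3·10⁻⁶ at
φ = 10⁻⁴). Production immunosequencing nulls tie dispersion to clone size;
here φ is a single number, so it should be fitted on (or chosen for) the
frequency range of interest. The end-to-end defaults use φ = 10⁻⁴, a
realistic same-specimen technical overdispersion that keeps novel
expansions at survey depth callable.

### Dispersion fitting

`fit_dispersion` maximizes, over clones shared by both members of each
control pair (technical replicates or same-subject unperturbed pairs), the
conditional likelihood of the observed allocation given the clone total,
with a bounded scalar search on log-φ ∈ [10⁻⁸, 0.5]; a fit at the lower
boundary (no detectable excess variance) is flagged. A moments fallback
matches the excess of `Var(f₁−f₂)` over its binomial expectation.

The conditional-on-shared construction is systematically low by a factor of
~0.6 at φ ∈ [0.005, 0.05]: restricting to clones present in both samples
discards the dropout events that carry much of the overdispersion signal,
and the per-clone `μ̂` plug-in absorbs part of the variance. We verified
this against an oracle of truly independent beta-binomial pairs (no
compositional coupling), which shows the same bias — it is a property of
the estimator, not of the generator. Recovery within a factor of two holds
robustly; fits should be read as lower bounds on φ.

### Multiple testing and classification

The BH step-up `q_(i) = min_{j≥i} m·p_(j)/j` runs over one comparison's
tested family: the union of productive clones with `x₁+x₂ ≥ 2` (singletons
carry no testable signal and only inflate the family). Classes: expanded
(`q < 0.01`, `f₂ > f₁`), contracted (`q < 0.01`, `f₂ < f₁`), else
unchanged. Novel = expanded from baseline productive frequency strictly
below 0.1% (absent included). Fold changes use the pseudo-frequency
`1/(2N)` for zero counts and are descriptive only.

## Clonality

`clonality = 1 − H/ln R` (natural-log Shannon entropy over productive
clone frequencies, normalized by log-richness), the immunosequencing-
industry convention; a single-clone sample is defined as clonality 1.
Single-cell clonality uses cells-per-clonotype as counts (one cell = one T
cell, the analogue of one template), restricted to TRB-bearing cells, with
subsets below 20 cells reported undefined.

Clonality is depth-dependent: subsampling a repertoire loses rare clones,
and `H` and `ln R` do not shrink proportionally. Under the default
generator the single-cell-vs-bulk difference is ≈0.07 at 3,000 cells and
≈0.04 at the 6,000–8,000-cell capture that 5' single-cell assays target;
the concordance study therefore couples 7,000 cells to a 20,000-template
bulk sample. Comparisons of clonality across samples should hold depth
roughly constant.

## Single-cell layer

**Gating** is cytometry-style on log1p-transformed raw ADT counts: a
per-marker cutoff yields positive/negative calls; CD3+ is required; CD4+
and CD8+ are mutually exclusive (double-positive/negative cells stay
unassigned); CCR7 × CD45RA gives naive (+/+), CM (+/−), EM (−/−), TE
(−/+); CD4+CD127loCD25hi cells are relabelled Treg over any memory label.
"auto" cutoffs use exact Otsu two-component separation per marker with the
median across a subject's samples as consensus. Gating is deterministic
given data and scheme. Note the between-class variance is flat across a
data-free gap, so any threshold inside the gap is equivalent; ours takes
the sample-split argmax.

**Linkage** matches bulk clones into cells by CDR3β nucleotide junction,
falling back to (CDR3β amino acid, V gene) with a logged downgrade; clones
with fewer than 5 matched cells are flagged under-covered and excluded
from group statistics by default (clone-level statements need a minimum of
cells). The comparator group is the 10 most abundant lineage-matched bulk
clones (ties broken lexicographically on the junction), excluding the
clones of interest.

**Differential signatures** are per-cell two-sided Wilcoxon rank-sum tests
per feature with Bonferroni correction by the total feature count of the
modality; genes are CP10K-log1p normalized, ADT is CLR-transformed per
cell. Tiers: `**` adjusted p < 0.01, `*` < 0.05, `.` otherwise. Per-clone
mean matrices are exported for heatmaps; tests are per-cell, matching the
units the tier annotations describe.

**Module scores** subtract, per cell, the mean normalized expression of a
control set drawn from expression-matched bins (25 bins by dataset-average
expression, up to 100 control genes per module gene, seeded). The score is
exactly zero-mean only when module and control genes are identically
distributed; with heterogeneous rates each fixed module carries an offset
of order (within-bin spread)/√(module size) — scores should be compared
between cell groups, not read as absolute activation levels.

**Phenotype stability** of a clone is the maximum total-variation distance
between its subset composition at baseline and at any later timepoint,
over clones with ≥5 gated cells per timepoint.

## Subsampling analyses

The overlap curve draws, per size, two *independent* subsamples without
replacement from the same cell population (modelling two hypothetical
experiments on one specimen; the draws may share cells) and reports the
Jaccard fraction of the clonotype sets. The denominator is configurable to
"fraction of A found in B" because "percentage of overlapping clones" is
ambiguous between the two; Jaccard is the symmetric, bounded default.

The emergence audit defines candidates as clonotypes with ≥1 cell at the
query timepoint and 0 cells at every earlier single-cell timepoint, then
checks each against bulk: *corroborated* requires the bulk test to flag it
expanded from a baseline below the novelty threshold; everything else —
present at baseline in bulk, or never significant — is *false emergent*.
When the generator creates no true emergence, every candidate is false
emergent, and the candidate count grows as the earlier single-cell
sampling gets shallower: clone "emergence" read off single-cell presence
alone is dominated by sampling depth.

## The synthetic-data generator

Bulk: clone base frequencies are iid Pareto(α = 2) sizes normalized to the
simplex, truncated so no single clone can swamp the sample (patient
repertoires are dominated-but-diverse, not monoclonal); a rank-frequency
`i^{−2}` law would put >60% of templates in one clone. Defaults: 5,000
clones, N = 20,000 templates per sample, echoing survey-depth
immunosequencing (the study this emulates sequenced a median of ~24,000 T
cells per timepoint and intended 6,000–8,000 cells per single-cell run).
Per timepoint, frequencies are spiked (multiplied by the programmed fold;
novel clones enter at fold/N from a zero baseline), renormalized,
beta-perturbed at dispersion φ (`Beta` with mean f and concentration
`(1−φ)/φ`), renormalized again, and sampled as one multinomial — the one
place marginals are only approximately beta-binomial, which the
distributional property test tolerances reflect. Clone identities are
synthetic in-frame CDR3 junctions (uppercase ACGT, translated with the
standard code) with gene-level V/J calls; no V(D)J recombination model or
generation probabilities are attempted.

Single cell: subsets are drawn from configurable proportions (defaults
spanning naive/CM/EM/TE/Treg in both lineages); ADT counts are negative
binomial around a positive mean of 160 and negative mean of 10 (16-fold
separation; NB size 12 keeps the modes cleanly resolved — at size 8 the
positive tail alone costs ~1.5% gating accuracy), with a 2% CD3-negative
contaminant emulating imperfect FACS enrichment. TRB clonotypes are drawn
from the coupled bulk's productive frequencies with 90% recovery. Gene
counts are Poisson with lognormal per-gene rates and a lognormal per-cell
size factor; the designated activation module consists of *expressed*
genes (lognormal(0, 0.5) rates) — a fold change on a never-expressed gene
is not an activation signal — elevated `module_fold`-fold in cells of the
designated activated clones, whose surface phenotype also gains the
activation markers (PD-1, TIM-3, HLA-DR, 4-1BB, CD27).

What the generator does *not* emulate: sequence-level realism, doublets
and droplet capture efficiency, ambient RNA, batch effects, clone-subset
frequency coupling beyond the activated clones, or frequency-dependent
overdispersion. Passing tests therefore demonstrate correctness of the
statistics under the stated noise model, not robustness to every artifact
of real data.

## Study conditions used by the benchmark experiments

All studies run single-threaded in seconds to ~1 minute each; sizes were
chosen as the smallest that make the measured property stable.

- Fisher limit: all tables with margins in {1,2,3,5,8,13,21,34,50} (tests)
  and 2,000 random tables with margins ≤ 50 (script), vs hypergeometric
  enumeration; agreement within 10⁻⁶.
- Null FDR: 200 pairs, 1,000 clones, N = 5,000, φ = 0.01 generated and
  tested; mean flagged fraction at q < 0.01.
- Dispersion recovery: φ ∈ {0.005, 0.02, 0.05}, 20 replicates each; every
  fit accumulates 500-clone control pairs at N = 20,000 until ≥500 clones
  are shared (constant-φ dropout means one pair shares far fewer).
- Spike recovery: 10 clones pinned at baseline 10⁻⁴, folds 10 and 20,
  N = 20,000, 5,000 clones, φ = 0 matched, 20 replicates; sensitivity and
  empirical FDR at q < 0.01. Fold-20 spikes are recovered essentially
  completely; fold-10 spikes (≈2 vs ≈20 templates) sit near the detection
  floor of a two-sided exact test after BH and yield partial sensitivity.
- Clonality: closed forms, plus 7,000 coupled cells vs 20,000-template
  bulk, 5 replicates.
- Gating: 3,000 cells at the default 16-fold ADT separation.
- Differential expression: 20 module genes at 4-fold, 200 cells/group,
  2,000 genes; null FWER over 100 two-iid-group runs at 100 cells/group,
  1,000 genes.
- Overlap/audit: sizes 100–2,000 at 200 repetitions on 4,000 coupled
  cells; audit on a no-emergence series.

## Known limitations

- Constant φ (see above): power vanishes for clones with μ̂ < φ; fit φ on
  the frequency range you care about.
- The dispersion estimator is shared-clone-conditional and biased low by
  ~0.6×; treat fitted φ as a floor.
- Clonality comparisons are depth-confounded; compare at matched depth.
- Module scores are relative, not absolute.
- The trajectory "transient expansion" flag is descriptive; no claim about
  event timing is made beyond the at-event/preceding/following partition.
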