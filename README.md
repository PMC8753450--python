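# clonodyn

Longitudinal T-cell clonal dynamics from bulk TCRβ immunosequencing and
CITE-seq-style single-cell data: statistically rigorous detection of
expanded and contracted clonotypes under a beta-binomial noise model, clone
tracking across blood and bone marrow, linkage of bulk-identified clones
into single-cell ADT/expression data, subset-resolved clonality, and a
subsampling audit showing why single-cell-only clone discovery is biased.

## Who this is for

Immunogenomics analysts working with serial TCRβ repertoire samples — for
example from checkpoint-blockade trials, where clonal T-cell expansions
coincide with immune-related adverse events — who need the clone-level
statistics (which clonotypes expanded, from what baseline, in which
compartment, with what phenotype) rather than only repertoire summaries.

## The statistics at the core

**Differential clonotype abundance.** For a clone with template counts
`x₁ / N₁` at baseline and `x₂ / N₂` at follow-up, condition on the total
`s = x₁ + x₂` and test the allocation against a beta-binomial null:

    w(k) ∝ BB(k; N₁, μ, φ) · BB(s−k; N₂, μ, φ),   μ = s/(N₁+N₂)

with overdispersion `φ = 1/(α+β+1)`; the two-sided p-value sums all
allocations no more probable than the observed one. At `φ = 0` this is
exactly Fisher's exact test; `φ > 0` widens the null to absorb the
between-sample variance repertoires show beyond multinomial sampling. `φ`
is fitted from user-designated control pairs by conditional maximum
likelihood. Per comparison, p-values are Benjamini–Hochberg corrected;
clones are called expanded/contracted at `q < 0.01`, and expansions from a
baseline productive frequency strictly below 0.1% (including absent) are
flagged *novel*.

**Clonality.** `1 − H/ln R` with `H` the Shannon entropy (nats) of the
productive clone frequencies and `R` the richness: 0 = maximally diverse,
1 = monoclonal. Computed for bulk samples and, as cells-per-clonotype, for
ADT-gated single-cell subsets (naive / CM / EM / TE / Treg by CD4, CD8,
CCR7, CD45RA, CD127, CD25 cutoffs on log1p ADT counts).

**Single-cell linkage.** Cells carrying the CDR3β of bulk-flagged clones
are grouped (≥5 cells per clone) and compared with the ten most abundant
lineage-matched clones by per-cell Wilcoxon rank-sum tests with Bonferroni
correction over all features (genes: CP10K-log1p; proteins: CLR), with
`**`/`*`/`.` significance tiers and per-clone mean matrices for heatmaps.
Gene-module scores subtract an expression-matched control-gene background.

**Subsampling audit.** Jaccard clone overlap between two independent
equal-sized subsamples as a function of depth, and an audit of clones that
look "emergent" in single-cell data at a timepoint: each is checked against
bulk, and counted *false emergent* unless bulk called it significantly
expanded from a sub-novelty baseline.

A synthetic-data module generates all of the above with known ground truth
(power-law clone sizes, beta-binomial noise, programmed spikes,
subset-structured ADT, gene-module activation), so every stage is testable
without patient data.

## Worked example

```python
from clonodyn import differential_abundance
from clonodyn.synthetic_data import (
    RepertoireGeneratorConfig, Spike, generate_repertoire_series,
)

cfg = RepertoireGeneratorConfig(
    n_clones=5000, n_templates=20_000, phi=1e-4,
    timepoints=("Day0", "EOC2"),
    spikes=tuple(Spike("new", 60.0, "EOC2") for _ in range(5)),
    seed=7,
)
reps, truth = generate_repertoire_series(cfg)
res = differential_abundance(reps["Day0"], reps["EOC2"], 1e-4)
print(len(res.records), res.n_expanded, res.n_contracted)
novel = res.records[res.records["novel"]]
print(novel[["cdr3_nt", "x1", "x2", "f2", "q_value"]].to_string(index=False))
```

prints

```
2743 5 0
                                         cdr3_nt  x1  x2      f2      q_value
   TGCAACTGCTCTGTTCAGGAGATTCTGGCAAGGCTAAACGACTTT   0  53 0.00265 5.528206e-05
         TGCACTAAGGTTTTAGGGTTCCTGCAACAGGTCTTTTTT   0  50 0.00250 5.944162e-05
         TGCACTCTTCTGTTATTTGTAAAAATCACCGGGGGCTTT   0  92 0.00460 2.866683e-10
            TGCCACGCGTGCCGTCTTATACTGCTAACGGCGTTT   0  50 0.00250 5.944162e-05
TGCGGGCGTCGTATCTTGGTGAGTCTGTACTTTATTATCGCTGTCTTT   0  50 0.00250 5.944162e-05
```

— 2,743 clones tested, and exactly the five programmed novel expansions
flagged (each absent at baseline, ~0.25–0.5% productive frequency at
follow-up, `q ≪ 0.01`), with no false positives.

The same pipeline runs end to end from a shell:

```
clonodyn run-all --seed 7 -o out/
clonodyn diffabund --baseline day0.tsv --followup eoc2.tsv --phi 1e-4 -o diff.tsv
clonodyn clonality repertoire.tsv
```

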