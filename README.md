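# chordwgs

Somatic-genome characterization for low-mutation-burden tumor WGS cohorts,
built around the genomic landscape of skull-base chordoma: a rare bone
tumor with very few point mutations (median tumor mutational burden about
0.5/Mb) whose biology is instead dominated by large somatic copy-number
alterations (SCNAs), occasional chromothripsis, and a small set of driver
markers (*PBRM1*, *SETD2*, *CDKN2A/B*, chromosome 22q loss) that stratify
patient outcomes.

The package is aimed at analysts who have per-sample allele-specific
copy-number segments, somatic variant tables, SV breakpoint lists, and
clinical follow-up — and who want the downstream characterization layer:
filtering, purity, SCNA landscape, chromothripsis, and survival modeling.
Because real cohorts of this kind are controlled-access, a first-class
synthetic-cohort generator reproduces the statistical structure of such a
study (~80 tumors, purity 0.2–0.9, ~76× depth, five SCNA archetypes,
~38 SVs/tumor, marker-dependent hazards) so every stage is testable end
to end.

## What it computes

- **Variant filtering and TMB** (`chordwgs.filters`). A variant is kept iff
  it has ≥2 supporting callers, tumor VAF ≥ 0.07, normal VAF ≤ 0.02,
  ≥3 alt reads, tumor depth ≥ 8, normal depth ≥ 6, and population
  MAF ≤ 0.1%; every rejection is labeled with the first failing rule.
  TMB = kept coding mutations / coding megabases.
- **Tumor purity** (`chordwgs.purity`). For SNVs in copy-neutral segments
  (total CN 2, minor CN 1) the alt count follows an ordered binomial
  mixture

      x_i ~ Σ_k π_k · Binom(x_i; N_i, θ_k),   θ_K < … < θ_1 ≤ 0.5,

  fitted by EM with multi-start; K is chosen by BIC (p = 2K − 1), and
  purity = 2·θ₁.
- **SCNA landscape** (`chordwgs.scna`). Five-state classification
  (homozygous deletion / hemizygous deletion / neutral / LOH /
  amplification); arm-level events when a gain or loss covers ≥90% of an
  arm; whole-genome doubling when major CN ≥ 2 over >50% of the covered
  autosome; base-pair-weighted CN-state distance between tumors;
  average-linkage clustering with the group count picked at the
  maximum-curvature elbow of the within-cluster dispersion.
- **Chromothripsis** (`chordwgs.chromothripsis`). High-confidence regions
  from interleaved intra-chromosomal SV clusters: ≥6 interleaved SVs,
  ≥7 segments oscillating between two CN states, a fragment-joins
  goodness-of-fit test, and breakpoint enrichment / exponential-spacing
  tests (criteria set 1), or ≥3 interleaved + ≥4 inter-chromosomal SVs
  with oscillation and the joins test (set 2).
- **Outcome models** (`chordwgs.survival`). Driver-marker assembly
  (mutation OR SV breakend OR focal deletion), one-sided Fisher mutual
  exclusivity, Cox proportional-hazards fits adjusted for age, sex and
  pre-/post-surgery radiotherapy (Efron ties), Bonferroni control across
  arm-event scans, and paired primary/recurrence shared-alteration
  fractions.
- **Synthetic cohorts** (`chordwgs.simulate`). Archetype CN profiles,
  binomial VAFs, background and planted-chromothripsis SVs, exponential
  proportional-hazards outcomes, plus a separate ground-truth table that
  analysis stages never read.

## Worked example

```bash
chordwgs simulate --out cohort --seed 7 --n-samples 80
chordwgs scna --segments cohort/segments.tsv --out scna_out
```

prints

```
wrote cohort bundle to .../cohort (80 samples)
  segments: cohort/segments.tsv
  variants: cohort/variants.tsv
  svs: cohort/svs.bedpe
  metadata: cohort/metadata.tsv
  truth: cohort/truth/truth.tsv
chosen k = 5; outputs in scna_out
```

The elbow statistic selected five SCNA groups — the cohort's archetype
structure (two extensive-SCNA groups, a scattered-deletion group, a
near-diploid group, and a whole-genome-doubled group). `scna_out/` holds
the per-sample arm events, WGD calls (flag plus the fraction of the
autosome at major CN ≥ 2), the pairwise distance matrix, and group labels.

The same stages are available as library calls:

```python
import chordwgs as cw

cohort = cw.simulate_cohort(cw.SimulationConfig(n_samples=80, seed=7))
kept, rejected = cw.apply_filters(cohort.variants)
tmb = cw.compute_tmb(kept)                       # median 0.457 mutations/Mb
call = cw.estimate_purity(
    [v for v in kept if v.sample_id == "S001"],
    cohort.profiles[0],
)
print(call.purity, call.fit.K)                   # 0.3226 1  (truth 0.3347)
```

A full pipeline run over a bundle: `chordwgs run-all --bundle cohort --out out/`.

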