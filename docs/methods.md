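# Methods

This note documents the statistical models, rules, and design choices
behind `chordwgs`, and what the synthetic-data generator does and does not
emulate.

## Data model and coordinates

All intervals are 0-based half-open in memory. On disk the segment TSV is
1-based inclusive (the usual SEG convention), BEDPE is 0-based half-open,
and variant positions are 1-based. Chromosome names are normalized to the
`chr` prefix. The genome is data, not code: a TSV of arm intervals
(chrom, arm, start, end); an hg19 table with UCSC gap-track centromeres is
packaged, and any build can be supplied. Coverage gaps in a copy-number
profile are treated as missing and excluded from every denominator.

## Variant retention filter and TMB

A somatic call survives iff: supporting callers ≥ 2, tumor VAF ≥ 0.07,
normal VAF ≤ 0.02, tumor alt reads ≥ 3, tumor depth ≥ 8, normal depth ≥ 6,
population MAF ≤ 0.001. The thresholds describe what is *excluded*
("VAF < 0.07 in tumor"), so records sitting exactly on a boundary are
kept. Rejections are labeled with the first failing rule in a fixed order
(callers, tumor VAF, normal VAF, alt reads, tumor depth, normal depth,
MAF) so filter output is reproducible record by record; zero-depth records
fall through to the read-count rules rather than raising a division error.
TMB divides kept coding mutations by a configurable coding territory
(default 35 Mb — estimates of the human coding footprint vary and the
denominator is a convention, not a measurement).

## Purity from copy-neutral SNVs

In a tumor of purity ρ, a clonal heterozygous SNV in a (2,1) segment has
expected VAF ρ/2; subclones contribute components at lower means. The alt
count at site *i* is modeled as an ordered binomial mixture
x_i ~ Σ_k π_k Binom(N_i, θ_k) with θ_K < … < θ_1 ≤ 0.5 and purity = 2θ₁.

EM details: responsibilities from binomial log-PMFs via logsumexp;
M-step θ_k = Σγ_ik x_i / Σγ_ik N_i and π_k = mean γ_ik; after each M-step
components are sorted by θ descending and θ is clipped into [0, 0.5]
(a projection — the ascent property is asserted per run to 1e-9).
Initialization is at K evenly spaced quantiles of x/N with uniform
weights, plus 9 jittered restarts whose jitter depends only on the restart
index, keeping the fit invariant under permutation of the input.
Convergence: |Δ log L| < 1e-8, at most 500 iterations. K = 1..K_max
(default 4) is scored by BIC = −2 log L + (2K−1) ln n; ties break toward
the smaller K, and K_max is truncated so the parameter count stays below
the variant count. Samples with fewer than 20 copy-neutral SNVs are
no-calls with a stated reason. Estimates are clipped at purity 1.

## SCNA landscape

Five states as a total function of (total CN, minor CN): HOMDEL (0),
HEMIDEL (1), LOH (2, minor 0), NEUTRAL (2, minor ≥ 1), AMP (≥3).
Amplification takes precedence over LOH for tcn ≥ 3 with minor 0, since a
gain is the more specific event in this state list.

Arm events are directional: per arm, the gained (tcn > 2) and lost
(tcn < 2) base pairs are each divided by the full arm length — uncovered
territory counts in the denominator only — and an event fires at ≥ 90%.
WGD is called when major CN ≥ 2 over strictly more than 50% of the
*covered* autosomal genome (covered length, not total length, so sparse
profiles are judged on what they report).

The tumor–tumor distance is the fraction of jointly covered base pairs at
which the five-state classifications disagree, computed interval-wise
over the union of segment boundaries (equivalent to the literal per-bp
sum; verified against a per-bp oracle on toy genomes). Base pairs covered
in only one sample are excluded; an unnormalized variant (raw disagreeing
bp) is available via a flag.

Clustering is agglomerative (average linkage by default; complete and
Ward are accepted) on that distance. For k = 1..k_max the pooled
within-cluster mean pairwise distance W(k) is computed, and the chosen k
maximizes the discrete second difference of **log** W. The log scale is a
deliberate choice: while true groups are still being separated W decays
roughly geometrically and flattens abruptly at the real group count, so
curvature on the raw scale always peaks at k = 2 regardless of structure,
whereas curvature of log W peaks where the relative improvement collapses.
Cohorts with (near-)zero dispersion degenerate to k = 1. Labels are
deterministic: 1 = largest cluster.

## Chromothripsis

Two intra-chromosomal SVs interleave iff their breakpoint intervals
overlap and neither nests inside the other; clusters are connected
components of the interleaving relation, and a candidate region is the
breakpoint hull of a cluster (no padding). The oscillation statistic is
the longest run of adjacent segments whose total CN alternates strictly
between exactly two values; total CN (not the five-state classification)
is used because oscillation is defined on copy number levels.

Statistical tests per region:

- **Fragment joins**: goodness-of-fit of the four intra-chromosomal join
  classes (deletion-like +/−, duplication-like −/+, head-to-head +/+,
  tail-to-tail −/−) against equal proportions; chi-square (df 3) for
  n ≥ 20, exact multinomial (full enumeration of outcomes no more
  probable than the observed one) below that. With only 3 joins the exact
  p can never drop below 4/64 ≈ 0.0625 — an intrinsic floor of the
  discrete test.
- **Chromosomal enrichment**: one-sided binomial tail P(X ≥ obs) with
  X ~ Binom(total breakends genome-wide, chrom length / genome length).
- **Exponential spacing**: one-sample KS test of inter-breakpoint gaps
  against an exponential with the region's empirical rate (n−1)/span.
  Because the rate is estimated from the same gaps, the p-values are
  conservatively biased (Lilliefors effect); the test holds its nominal
  level, which is what the criterion consumes.

A region is high-confidence under criteria set 1 (≥6 interleaved intra
SVs, oscillation run ≥ 7, joins p < 0.05, and enrichment or spacing
p < 0.05) or set 2 (≥3 interleaved intra SVs, ≥4 inter-chromosomal SVs
with a breakend in the region, oscillation ≥ 7, joins p < 0.05). The
joins-test direction is applied exactly as stated (small p qualifies);
because a chromothripsis mechanism with purely random rejoining would
instead produce *large* joins p, `joins_direction="greater"` flips the
criterion without changing anything else. There is no manual-curation
stage; all per-region diagnostics are emitted instead.

## Outcome models

Marker flags per sample: gene+ = nonsynonymous kept variant in the gene
OR an SV breakend inside the gene footprint (packaged hg19 footprints for
PBRM1, SETD2, CDKN2A/B, SMARCB1, TBXT, LYST), plus homozygous deletion
overlapping the locus for CDKN2A/B; del22q from the arm-level rule;
del9q21_focal = any deletion segment overlapping a configurable 9q21.11
window (default chr9:71.0–71.7 Mb, a band approximation). Combined
markers are exact ORs (CSS: PBRM1+ or del22q; RFS: PBRM1+ or del9q21 or
del22q).

Mutual exclusivity uses a one-sided Fisher exact test (alternative: fewer
co-occurrences than expected); an absent marker yields p = 1 with a
warning. Survival uses Cox proportional hazards with Efron tie handling
(lifelines), adjusted for age, sex, and pre-/post-surgery radiotherapy;
Wald HR, 95% CI and p are reported, with explicit no-fit outcomes for
constant markers, eventless strata, or non-convergence. CSS events are
disease deaths; RFS events are first recurrences. Arm scans apply
Bonferroni p_adj = min(1, m·p); m defaults to the number of events tested
and is exposed because the multiplicity budget may be defined per endpoint
or jointly. Paired-sample comparisons use the union convention: for
variants, shared = |P ∩ R| / |P ∪ R| per class (SNV/indel by exact
(chrom, pos, ref, alt) identity); for SCNAs the altered union of the
jointly covered genome is partitioned into shared (identical non-neutral
state), primary-only (altered in primary, recurrence differs), and
recurrence-only, so the three fractions always sum to one.

## Synthetic cohort generator

Defaults emulate the targeted study design: 80 tumors, purity U(0.2, 0.9),
tumor depth Poisson(76) and normal depth Poisson(41), ~200 SNVs per tumor
of which Poisson(18) are coding (median TMB ≈ 0.5/Mb at 35 Mb), 25%
subclonal (CCF U(0.2, 0.7)), Poisson(38) background SVs (80%
intra-chromosomal, spans log-normal with ~0.4 Mb median), chromothripsis
in 8.75% of tumors, and five SCNA archetype groups drawn at proportions
(0.200, 0.3125, 0.1625, 0.2375, 0.0875).

Archetypes are fixed arm plans applied with high per-arm inclusion
probability (0.95/0.95/0.9/0.01 for groups 1–4): group 1 gains 1q/7p/7q
and loses the recurrent loss arms except chromosomes 4, 9, 14; group 2
loses the full recurrent set with no gains; group 3 carries scattered
deletions; group 4 is near-diploid; group 5 is whole-genome doubled, with
(4,2) arms taken in a fixed size order until a target fraction drawn from
U(0.55, 0.9) of the autosome is covered. The fixed plans and fixed WGD
arm order are essential: fully random per-arm draws make within-group
distances exceed between-group distances and no clustering method could
recover the groups. Planted marker lesions (mutation or SV for
PBRM1/SETD2/TBXT/LYST, homozygous CDKN2A/B deletion, focal 9q21 deletion)
follow the cohort prevalences of the targeted study design; truth flags
are derived from the *final* simulated data (including background SVs that
happen to hit a footprint), so the emitted truth table is exactly what a
correct caller should recover.

Clonal SNVs in copy-neutral segments draw t_alt ~ Binom(depth,
purity·CCF/2); variants are only placed in copy-neutral territory, since
those are the sites the purity model consumes — modeling allele counts in
aberrant regions would require CN-aware CCF machinery that is explicitly
out of scope. Planted filter-failing records (single-caller calls,
common-MAF records) exercise the filter deterministically.

Planted chromothripsis draws 2n sorted breakpoints (n ~ U{12..18}) in a
40 Mb q-arm window and pairs breakpoint j with j+n, which makes every
pair of intervals interleave (one cluster of size n by construction); the
window's copy number is rewritten to oscillate between the local state
and one copy below it across 2n−1 fragments, emulating ~50% fragment
loss. Join classes are drawn deletion-heavy (0.85/0.05/0.05/0.05):
retained adjacent fragments rejoined in their original orientation
produce deletion-like joins, and this is what makes planted events
satisfy the small-p joins criterion as stated.

Survival times are exponential proportional hazards h(t) = h0·exp(βᵀx)
with uniform censoring; default log-HRs follow the targeted effect sizes
(PBRM1+: CSS 4.79 / RFS 5.72; del22q: CSS 5.88 / RFS 3.74; del9q21: RFS
3.63) with baseline hazards 0.0025 (CSS) and 0.018 (RFS) per month chosen
to give event counts in the range of a ~50-month follow-up cohort. The
two endpoints are drawn independently; the generator does not enforce
recurrence-before-death ordering.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: read-level noise and mapping artifacts,
segmentation error (segments are taken as given), mutational-signature
structure, focal-SCNA significance landscapes, germline variation, and
correlated censoring. Results on synthetic cohorts validate the
*estimators and rules*, not biological discovery.

## Numerical and reproducibility choices

All randomness flows from integer-seeded `numpy` generators; the same
seed reproduces a byte-identical cohort bundle. Writers sort
deterministically. θ is floored at 1e-9 inside binomial logs; mixture
weights are floored at 1e-12 before normalization. Distance matrices are
validated for symmetry and zero diagonal; degenerate inputs (all-zero alt
counts, eventless strata, arms with no coverage, pairs with disjoint
coverage) take explicit, tested paths. The acceptance script scales each
check to its stated study condition (50 tumors / 50 seeds / 20 cohorts /
100 null genomes / 200 Cox replicates), which keeps a full run at a few
minutes on one CPU.

## Known limitations

- Purity estimates inherit the filter's VAF truncation: in very low-purity
  tumors the tumor-VAF floor removes the lower binomial tail and biases
  2θ₁ upward slightly.
- The elbow requires k_max ≥ chosen k + 1 by construction; structures
  whose dispersion decays smoothly (no real groups) still return some k,
  as any elbow heuristic does.
- The exact multinomial joins test is conservative at small n (discrete
  support), and no cluster of 3 joins can ever reach p < 0.05.
- Cox fits use complete-case covariates and assume proportional hazards;
  no competing-risk or multi-state structure is modeled.
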