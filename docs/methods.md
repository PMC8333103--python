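# Methods

This note documents the models, conventions and numerical choices behind
`canpancan`, and what the synthetic-cohort benchmarks do and do not show
about real data.

## Synthetic cohort generator

The generator (`canpancan.simulate`) emulates the variant-level structure of
a multi-study canine tumor/normal exome cohort. All randomness flows from one
integer seed through named child streams (CRC32-keyed `SeedSequence`
children), so each component's output is independent of whether the others
ran first, and identical configurations reproduce byte-identical tables.

**Germline.** Each dog contributes one normal and one tumor sample. Sites are
of two kinds: cohort-shared sites with population carrier frequencies drawn
uniformly from 0.10–0.40 (keeping cross-dog germline sharing below ~40%, the
regime in which pairing verification is informative), and breed-specific
sites carried with probability `carrier_fraction` (default 0.8, satisfying
the ≥40% discovery rule with margin) only by dogs of the target breed.
Carriers are heterozygous with probability 0.7 (allele dose 0.5) else
homozygous (dose 1.0). Read depth per site is negative binomial
(mean 60, dispersion 3), truncated at 1, which yields a realistic coverage
spread including sub-10× sites that exercise the ND state; variant-supporting
reads are binomial in the allele dose. The tumor inherits each normal variant
with probability 0.99 (`germline_sharing`; the within-dog sharing rate is a
free simulator parameter, not an empirical value) plus a Poisson(3) handful
of tumor-private noise sites. Tumor–normal swaps are realized as a cyclic
permutation of the chosen cases' tumor content, so every chosen case is truly
mispaired; `n_swaps = 1` is rejected because a 1-cycle is the identity.

**Somatic.** Per-tumor true mutation counts are Poisson with mean
rate × callable Mb, doubled (`tp53_effect`, default 2.0) in TP53-mutant
tumors; the TP53-mutant fraction is a generator parameter
(`tp53_mut_fraction`, default 0.5, chosen to give balanced association
groups). Channels are drawn from the tumor type's mixture over synthetic
96-channel signatures; the three defaults occupy nearly disjoint channel
blocks (C>T-, C>A- and T>C/T>G-dominated) with a deterministic within-block
ripple that makes factor recovery identifiable. True mutations receive
symmetric read orientations (each read F1R2 with probability 0.5) and MAF
uniform in 0.2–0.6. Injected artifacts are C>T in FFPE tumors and G>T
(oxoG-like) in frozen tumors, with low MAF (2–6%), 5 + Poisson(25) mutant
reads and 90–100% of mutant reads in one orientation class — strong enough
asymmetry that the orientation Fisher test is the discriminating statistic,
which is the point of the injection.

**Annotation.** Emits named multi-exon genes, named single-exon genes (not
problematic), identifier-only single-exon genes (problematic), and
retrogenes: identifier-only single-exon entries whose exon is an intronless
copy spanning a named parent's locus. Coordinate overlap with the parent's
exons stands in for the sequence homology a production retrogene caller
would use; parents designated for retrogenes are built with short introns so
the exon union covers ≥80% of the span by construction. Internal coordinates
are 0-based half-open; GTF is written 1-based inclusive, BED 0-based
half-open.

**CNA.** True segments tile each tumor's binned genome without overlap, with
means of 0 (≈40%), ±0.3–0.6 (shallow, 20%) or ±1.1–2.0 (true CNAs, 40%);
bins add N(0, noise_sd) noise, default 0.2.

**What passing benchmarks do not show.** The generator draws sites
independently (no linkage disequilibrium within breeds), uses a single
substitution-type-independent MAF distribution, gives every case the same
callable territory, and injects artifacts with idealized orientation
asymmetry. Recovery rates on real cohorts — where breed structure is
admixed, artifact asymmetry is milder and callable bases vary per case —
will be lower than the synthetic figures; the benchmarks validate the
machinery, not cohort-level performance claims.

## Pairing verification

F(i,j) = |T_i ∩ N_j| / min(|T_i|, |N_j|) over (chrom, pos, ref, alt) keys,
never symmetrized; Best nonself takes max(F(i,j), F(j,i)) over j ≠ i within
the same study, and a case is flagged when Self − Best nonself < 0. By
default only variants seen in both tumor and normal of at least one case
enter the sets (a pre-filter that discards private call noise). Single-case
studies are reported not evaluable rather than silently passed.

## Coverage RMSE

Empirical and Poisson(λ = mean depth) distributions are compared as
probabilities per integer depth over 0 … the 99.9th-percentile of whichever
support reaches further. The evaluation grid is a convention: absolute RMSE
values are comparable only within one convention, relative ordering of
samples is the meaningful output.

## Breed assignment

Site states and discovery rules follow the thresholds listed in the README.
The dendrogram side is a documented convention, since "standard hierarchical
clustering" underdetermines the procedure:

- Agglomerative clustering, average linkage, Euclidean distance on the VAF
  matrix over the combined panel; sites with depth < 10 receive a random
  uniform(0,1) VAF from the seeded stream.
- The tree is cut at the smallest height at which every reference breed
  "owns" a cluster: the cluster holding the plurality of its labeled dogs
  contains ≥80% of them, and they are ≥80% of the *reference* dogs there
  (query dogs are excluded from both denominators, otherwise a large
  prediction cohort could never validate).
- A query in an owned cluster takes its breed. A query outside any owned
  cluster is rescued only if it lies within 1.3× the owned block's own
  centroid radius — random-VAF imputation at a handful of uncovered sites
  inflates distances enough that rigid cluster membership strands genuine
  breed members merging just above the cut.
- Admixture guard: no dog is assigned breed X if its covered mean VAF at a
  second breed's panel sites reaches 0.1 (half the non-reference cutoff).
  Panel sites are reference in other breeds by construction, so systematic
  half-dose VAF at two breeds' site sets is the defining signature of mixed
  ancestry; this is what routes mixed dogs to `unknown` rather than to the
  nearer parent breed.

Outcomes are validated / corrected / predicted / unknown / not evaluable
(coverage ≤80% of panel sites).

## Somatic filters

The depth/MAF ladder defaults to: mutant reads ≥3; MAF ≥0.05; tumor depth
≥8 (normal depth ≥6 and normal mutant reads ≤1 when normal counts are
supplied); MAF ≥0.10 when depth <20. The ladder generalizes published
multi-step coverage/MAF screens; every rung is a config field and the rungs
referencing the matched normal disengage when the input carries no normal
counts. The orientation test is a two-sided Fisher exact on
[[F1R2 ref, F1R2 alt], [F2R1 ref, F2R1 alt]] (sidedness configurable; an
all-zero table keeps the call with p = 1). The cutoff filter applies only to
routed classes — G>T/C>A in frozen tumors of routed studies, C>T/G>A in
FFPE tumors — and requires, within *each* orientation class separately,
total reads ≥4 of which ≥5% mutant; "≥4 in total" is read per orientation
class because the rule is applied "for both F1R2 and F2R1 reads". Indels
bypass both orientation filters (the artifact classes are
substitution-specific) and the 96-channel annotation.

## TMB and associations

TMB uses exact de-duplication by (sample, locus, alleles) before counting,
excludes mutations in problematic genes from the numerator, and classes
hypermutation at TMB > 10 and > 100 (strict inequalities). Gene–TMB screens
test genes mutated in ≥5 tumors of the scope, Wilcoxon two-sided; exact null
distribution when both groups have n ≤ 25 without ties, else the normal
approximation with tie correction. Tumor-type scopes use raw TMB; breed
scopes divide by the tumor-type median first so breed effects are not
confounded by tumor-type composition. S1-high tumors (≥15 attributed
mutations) are excluded from association analyses. "Strong association"
annotates p < 0.05 with median fold > 1.5.

## Recurrence machinery

All recurrence hypotheses are Fisher exact tests with BH correction applied
within each (entity class × scope) family — the least surprising reading of
per-test correction, configurable by passing different families. The
mutation-level background is all MAF-significant mutations within the scope
(stated in output metadata; the source procedure is ambiguous on this
point). Odds ratios for display use the Haldane–Anscombe 0.5 correction when
a cell is zero; p values remain exact. Enrichment scores are −log10(q)
signed by odds direction, positive at an odds ratio of exactly 1, capped at
300. Swapping a scope with its complement flips the sign but may change the
magnitude, because q is recomputed within the new family.

## Copy number

Segmentation is recursive binary splitting: within an interval the maximal
standardized mean-shift statistic |mean_L − mean_R| / √(1/n_L + 1/n_R) over
all split points is compared to its permutation null (10,000 seeded
permutations by default, matching the upstream convention; α = 0.01); the
statistic needs no variance estimate because permutation preserves scale.
Intervals with zero range are never split, which also makes zero-noise
piecewise tracks exact. Bin-count-weighted segment means conserve the track
mean to 1e-9 by construction. The two-caller concordance contract accepts an
external secondary segment table and retains a non-neutral gene call only
when both sources support the class; without one, calls carry a
`single_source` flag. The per-tumor Z-test uses the within-tumor empirical
distribution of per-gene mean log ratios as the null — a minimal documented
convention, since the source procedure names only "Z-tests at q ≤ 0.01".

## Signatures

Catalogs follow the fixed channel order (C>A, C>G, C>T, T>A, T>C, T>G) × 16
flank pairs, alphabetical within. Extraction runs `n_iterations` (default
40) independent seeded NMF fits per rank over the rank range
(multiplicative updates, KL divergence, random initialization, 600
iterations — a fixed budget, convergence warnings deliberately silenced);
each run votes for the rank minimizing 2·KL + rank·(n_tumors + 96)·log(total
mutations), the modal rank wins (ties to the smaller rank), and the best-KL
run at that rank supplies the result, with signature rows normalized to sum
1 and exposures rescaled accordingly. On catalogs of ~500 mutations/tumor
this recovers three generating signatures at cosine ≥ 0.99 with 40/40 votes;
on shallow desk-scale catalogs (~30 mutations/tumor) the penalty correctly
refuses ranks the data cannot support and returns one signature — a power
statement, not a defect. Background adjustment multiplies each channel by
(target/source) frequency of its reference trinucleotide (32
pyrimidine-collapsed trinucleotides) and renormalizes; a zero source
frequency under a supported channel is an error. Mutation attribution is
maximum-posterior: argmax_k exposure[t,k]·signature[k,c]; the attribution
rule is a convention, the source counts "S1 mutations" without stating one.

## Power

Binomial detection power is the closed form 1 − (1−p)^n. Fisher power
simulation draws Binomial(n1, p1), Binomial(n2, p2) per replicate
(p1 = p2 × OR; if p1 > 1 then p1 = 1 and p2 = 1/OR) and tests two-sided at
α; p values are cached per distinct count pair, which makes 100,000-replicate
runs cheap. The exact test is conservative on discrete tables, so its null
rejection rate sits below α (~0.015 at n = 50, p = 0.1) — calibration is
checked against a large-replicate oracle, not against α itself. Wilcoxon
power simulation draws N(effect, 1) vs N(0, 1) and applies the two-sided
rank-sum normal approximation vectorized across replicates (continuous draws
make ties measure-zero); it is calibrated to α under the null within Monte
Carlo error. Both simulators are seed-deterministic; the pooled SD in the
standardized effect size uses (n1−1, n2−1) weighting.

## Benchmark problem sizes

The benchmark experiments (`canpancan.experiments`) use: 20 seeds × 60-case
cohorts with 5 swaps (pairing); 8 breeds × 15 dogs with 30 sites/breed,
5 hold-outs/breed and 10 mixed dogs (breed); ~14,000 candidates with ~30
artifacts/tumor (filters); 100 tumors/type at rates 0.4 and 1.0/Mb with 1000
null-gene replicates (TMB); all 2×2 tables with total ≤16, 1000 random
p-vectors and 20 rank-sum enumerations (kernels); 10,000-replicate null
calibrations with a 100,000-replicate oracle (power); 200 tumors × ~500
mutations × 40 NMF runs (signatures); 12 tumors × 300 bins at noise 0.2 with
10,000 permutations (CNA). The TMB-median check compares each of the four
(type × TP53) stratum medians to a Monte-Carlo band of the sample median
under the Poisson truth, with Bonferroni-adjusted quantiles so the four
comparisons form one joint 95% statement.

## Known limitations

- Retrogene detection is coordinate-overlap only; retrogenes annotated away
  from their parent locus (the common real case) require sequence homology
  and are out of scope.
- The secondary CNA segmenter is consumed as an external file, never
  re-implemented; single-source calls are flagged, not suppressed.
- The breed caller outputs categorical assignments only — no admixture
  fractions.
- Human comparisons consume user-supplied summary tables; nothing is
  downloaded.
- The MAF-outlier and recurrence backgrounds are conventions where the
  source procedure is ambiguous; both are stated in output metadata and are
  configurable.
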