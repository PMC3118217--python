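# Methods

## Scope and model overview

`capsnv` analyses aligned long reads over declared target regions of a
genome in which some regions are present at elevated copy number (CN). All
coordinates are 0-based half-open internally; emitted variant tables are
1-based; BED stays half-open on disk. Indels and complex events are out of
scope throughout: reads are treated as gap-free substitution-only
alignments, which matches both the synthetic generator and the analysis
the package reimplements.

## Candidate calling

At each pileup column the most-supported non-reference base (ties broken
by higher support, then base order A<C<G<T) is tested against a
minimal-evidence rule: at least 3 variant-supporting reads with base
quality ≥ Q20 in each orientation, or at least 5 such reads in one
orientation. The one-orientation clause is implemented as
`max(forward, reverse) ≥ 5` rather than "≥5 with zero on the other
strand": the two readings agree on every documented example, but only the
former is monotone — with the literal reading, a site supported by five
forward reads would become *uncalled* upon gaining one reverse supporting
read, which no sensible evidence rule should do. The Q20 gate is applied
uniformly to both clauses.

Depth *n* counts every read spanning the site, regardless of base quality
or N status, so that it equals the local coverage the error model uses.
The Phred gate applies only to variant support inside the rule; N bases
never support a variant. VAF = 100 · d / n uses *all* variant-supporting
reads d (not just quality-passing ones), keeping `alt_count`,
`alt_forward + alt_reverse` and VAF mutually consistent. Calls with
VAF < 10 % are suppressed, mirroring the 10–100 % reporting range of the
upstream mapping software whose output this pipeline models. VAFs are
kept at full precision internally and rounded half-up to one decimal only
at reporting.

## Error model

The global per-site error frequency *p* pools evidence over control sites
known (from an external genotype resource) to be homozygous for a variant
allele: every non-N read base different from the expected allele is an
error. N bases are excluded from numerator and denominator — a no-call is
not an "identical deviation". All mismatching bases are pooled, not just
the modal erroneous base per site. If no mismatch is observed at all, a
floor of 10⁻⁴ is substituted with a warning so the test stays defined.

For a call with depth n and d reads supporting one specific alternate
allele, the posterior error probability is the inclusive upper binomial
tail P(X ≥ d), X ~ Binomial(n, p), evaluated through the survival
function (regularised incomplete beta). The survival function underflows
to zero for tails below roughly 10⁻²⁹⁰, far above the smallest normal
double, so tails below 10⁻²⁵⁰ are re-summed in log space
(`logsumexp` over `logpmf`); agreement with a direct pmf-recurrence
summation is verified to 10⁻¹² relative for all n ≤ 200. Calls with
P > 10⁻³ (configurable) are discarded. d is the count of reads supporting
the *specific* candidate allele, not all mismatches, because only
identical deviations mimic a variant.

The model also simulates expected VAF distributions for a genotype
(copies_variant cv of copies_total ct): each replicate draws a depth from
a supplied empirical depth distribution and a variant-read count from
Binomial(n, q) with q = f(1−p) + (1−f)·p/3, f = cv/ct — true variant
bases may be misread away at rate p, and each of the three non-reference
bases receives p/3 of the other copies' errors.

## Filtering and genotype classification

Two successive filters: calls inside mask intervals (near-identical
segmental duplications whose paralogs co-enrich during capture) are
marked `masked` and never resurrected; remaining calls are `filtered` or
`passed` by the binomial threshold. Both operations are idempotent.

Genotype bands partition the reportable VAF range [10, 100] for every
copy number:

* CN 2 — homref [10, 25), het [25, 75] (75 belongs to het), homvar
  (75, 100];
* CN 6 — the six documented integer bands [10,25), [25,43), [43,59),
  [59,76), [76,93), [93,100], labelled `1_of_6` … `6_of_6` (the printed
  integer ranges are read as half-open shorthand, closing the 24→25-style
  gaps);
* any other CN — our generalisation: band boundaries at midpoints between
  consecutive expected VAFs 100·k/CN (k = 0…CN), floored at 10 %; bands
  pushed entirely below the floor collapse away. A property test verifies
  the partition (disjoint, ordered, covering, each boundary owned exactly
  once) for CN 2–12.

Known/novel annotation matches a SNP table by position by default; an
allele-aware mode additionally requires the listed alternate allele.

## Haplotyping and copy number

Haplotyping candidate regions (HTCRs) are windows of high SNV density:
a 1-kb window anchored at a passed call qualifies when it holds ≥9 SNVs;
overlapping qualifying windows merge, and the merged window is trimmed to
its first and last SNV. This anchored-window construction is an
operational surrogate for "every sliding 1-kb sub-window is dense": it is
exact for isolated dense blocks (the tested cases) and can admit brief
local dips inside long merged windows, which is harmless because
combinations are re-screened by read support.

Within an HTCR, combinations are greedy non-overlapping runs of 2–7
consecutive SNVs spanning ≤ 200 bp (default; combinations must sit well
inside a read, and with 330-bp reads a 200-bp span leaves ≈ 40 % of
covering reads usable). A read contributes to a combination only if it
spans every position with a non-N, ≥ Q20 base. Haplotypes with < 5
supporting reads are dropped; a tally is used only if the surviving total
reaches the working threshold (10 reads for 2-copy loci, 30 for 6-copy,
50 in the high-depth recovery tests — all configurable).

The integer-ratio search formalises what was historically done by eye.
Totals T are tried from the number of distinct haplotypes upward; for
each T the best assignment of T copies (every haplotype ≥ 1) is found by
exact search over positive integer compositions — with ≤ 7 haplotypes and
T ≤ 16 this is at most a few thousand candidates, so no apportionment
heuristic is needed — and scored by chi-square goodness of fit
(df = k−1) against expected counts total·cᵢ/T. The smallest T not
rejected at level α is accepted; if none is, the best-fitting assignment
is returned with its (small) p-value as a diagnostic. The default
α = 0.30 is deliberately anti-conservative: acceptance is used here as a
*parsimony brake*, and at conventional α = 0.05 the search systematically
stops one total short of truth for count vectors like (16, 62, 11),
whose published assignment 1:4:1 is only reached once the intermediate
1:3:1 (p ≈ 0.13) is rejected. α = 0.30 reproduces the documented
multi-haplotype assignments and keeps simulated 6-copy recovery unbiased;
it remains configurable. Some published per-locus assignments (e.g.
63:26 → 3:1) are not reproducible by *any* single goodness-of-fit rule
and are not targeted.

Diploid CN = scale · Σ ratio. With ≥3 distinct haplotypes the scale is 1
and the estimate stands on its own. With exactly two haplotypes the ratio
only fixes CN up to an integer multiple (1:1 fits CN 2, 4, 6 …); the
haploid multiplicity must come from external knowledge, and estimates
with a defaulted scale are flagged ambiguous and excluded from CN
averaging by the pipeline. Aggregation reports count, mean, min, max and
sample SD of the diploid CNs plus the pooled two-haplotype read ratio
(counts summed across loci before dividing, first over second as
tallied).

## Evaluation conventions

Concordance tables assign every truth site to exactly one category:
`not_covered` when local depth < 6 (echoing the "covered by more than 5
sequences" working definition; configurable), else the genotype band of
the passed call there, else `no_hcdiff`. Sensitivity is concordant calls
over the truth-class total; "specificity" keeps the source table's own
arithmetic — concordant calls over all same-class calls at
truth-annotated sites — which is a precision-style measure, documented as
such rather than replaced by the textbook true-negative definition.
Percentages and densities are rounded half-up to one decimal; the
multi-copy sensitivity extrapolation (observed single-copy count /
single-copy sensitivity, rounded, × copy multiple; observed multi-copy
count as an integer percentage of that) reproduces the published 56 %
six-copy figure exactly.

## Synthetic data generator

The generator emulates the study conditions: uniform-random reference
regions; planted SNVs at a Poisson-distributed density (elevated to
16/kb inside designated 1-kb HTCR windows, ≥9/kb by construction), each
assigned copies_variant ~ Uniform{1..CN} and placed on a random copy
subset so that neighbouring SNVs induce genuine multi-copy haplotype
structure; reads of Normal(330, 30) bp (truncated at 50 bp and at the
region), drawn uniformly per haploid copy at a per-copy target depth so
coverage scales with CN (an optional per-region saturation factor damps
this, mimicking capture-probe saturation at high CN — a free parameter,
not fitted, as no quantitative saturation curve is documented);
i.i.d. substitution errors at 2.3 % per base, uniform over the three
non-reference bases; Bernoulli(½) orientation; constant Q30 base
qualities. Identical configurations (including the seed) produce
byte-identical outputs; stage-specific child streams of one seed keep
reference, truth and reads independently reproducible.

What it does *not* emulate — and what passing tests therefore do not
demonstrate about real data: homopolymer indel errors characteristic of
pyrosequencing flowgrams, quality-score variation along reads, mapping
ambiguity and chimeric alignments from real segmental duplications
(masking is exercised with explicit BED masks, not emergent paralogy),
capture-probe efficiency variation along the target, and linkage between
planted SNVs beyond the random copy assignment.

## Problem sizes and numerical choices

The statistical guarantees are exercised at desk scale, chosen to make the
relevant statistics well-resolved: binomial-tail exactness over all
n ≤ 200 at p ∈ {0.001, 0.023, 0.1}; false-positive calibration on a
100-kb pure-error region at 50× (bound: threshold × sites + 3 Poisson
SDs); 2-copy recall/precision on a 210-kb region with ≈500 planted
heterozygotes at 50×; 6-copy CN recovery on a 40-kb region with ten dense
windows at 150× and ≥50 reads per combination, where the mean over ≥20
unambiguous loci lies within ±1 of 6. Reporting-style rounding uses
decimal half-up (never banker's rounding) so printed-table arithmetic
reproduces exactly.

## Known limitations

* Calling quality is only as good as the alignments; the package does not
  re-map reads, and mapper-specific artefacts (e.g. missed calls at
  adjacent variant positions) are outside its control.
* Two-haplotype loci cannot resolve their own scale; without external
  multiplicity information they are excluded from CN means.
* Haplotype configurations in which every distinct haplotype occupies the
  same number of copies (e.g. three haplotypes on 2+2+2 of 6 copies) are
  inherently reported at the reduced total — the read ratios carry no
  information to distinguish them. Such loci bias per-locus CN downward;
  averaging over many windows with diverse haplotype structure is the
  mitigation, as in the source analysis.
* The generalized VAF-band scheme for CN ∉ {2, 6} is this package's
  extension and has no published counterpart.
* At high CN the VAF of single-copy variants approaches the 10 % floor
  and the binomial filter removes a growing share of true variants; the
  extrapolation operation quantifies exactly this sensitivity loss.
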