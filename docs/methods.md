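# Methods

## Cohort model

The package analyses a diploid cohort partitioned into four populations:
wild and domesticated accessions of two divergent gene pools (AI, MI).
All statistics are computed from unphased genotype codes
{0 hom-ref, 1 het, 2 hom-alt, −1 missing}; coordinates are 0-based
half-open internally and converted at the VCF/GFF3/BED boundaries.

## Synthetic cohort generator

The generator exists so that every downstream stage can be validated
against a known truth. It emulates the statistical structure the
inference assumes, not sequence-level realism.

**Allele frequencies.** Each SNP draws an ancestral frequency
`p ~ Uniform(0.05, 0.95)` (keeping the curation filters exercised
rather than dominated by near-monomorphic sites). Pool frequencies come
from a Balding–Nichols drift kernel
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with `pool_divergence_F` (default 0.3),
chosen because the expected Hudson FST between pools is ≈ F, giving a
closed-form check. Wild-population frequencies equal the pool
frequencies; domesticated frequencies drift once more with
`bottleneck_F` (default 0.1), the founder-effect analogue.

**Selfing.** Genotypes are drawn with a within-individual inbreeding
coefficient `inbreeding_F` (F_IS, default 0.95): with that probability
the two alleles are identical by descent, otherwise a random
Hardy–Weinberg union. The emulated species is predominantly selfing;
without this the observed-heterozygosity curation rule (≤ 0.1), which
in a selfer flags paralogous mis-mapping rather than real
heterozygotes, would discard most simulated sites and distort every
window statistic.

**Planted sweeps.** Sweep regions are evenly spaced intervals (default
four, 50 kbp wide, alternating gene pools; configurable to both pools).
Inside a sweep, domesticated frequencies of the affected pool are
pushed toward fixation of the wild major allele:
`p' = (1−λ)p_dom + λ·1[p_wild ≥ 0.5]`, with λ found by ≤ 20 bisection
steps so the expected heterozygosity ratio matches the target
diversity reduction (default 0.8). A target of 1.0 forces exact
fixation. Sweeps narrower than the scan window cannot carry undiluted
signal in any window — the recovery benchmarks therefore plant sweeps
at least one window wide, which is the scale a 50 kbp window scan is
designed to detect.

**TE deletion polymorphism.** Non-overlapping TE intervals (lengths
uniform in 200–4,000 bp by default, ~50% genome occupancy, as in
TE-rich plant genomes) receive superfamily labels (Gypsy-dominated mix)
and a deletion-frequency class per TE:

| class | default share | absence frequency |
|---|---|---|
| invariant | 0.35 | 0 everywhere |
| shared-polymorphic | 0.25 | one Uniform(0.1, 0.5) draw, all populations |
| pool-diagnostic | 0.15 | 1.0 in one pool, 0.0 in the other |
| domestication | 0.05 | 0.70 DOM_MI, 0.05 WILD_MI, 0.02 elsewhere |
| singleton | 0.20 | exactly one random accession |

Class shares are free parameters, not estimates — the real study
reports only headline counts per category. Pool-diagnostic TEs are
fully diagnostic by definition of the class ("absent in one pool,
present in the other"); a noisy variant (e.g. 0.97/0.03) leaves ~2% of
such TEs below the 1e-10 Fisher threshold at 29-vs-29 cohort sizes,
contradicting the semantics the differentiation analysis assumes.

Each truth deletion covers a fraction f ∈ [0.85, 1] of its TE (60% of
deletions cover it fully). Genotyping at the generating threshold 0.85
therefore reproduces the truth matrix exactly, while the 100/95/90/85%
matrices genuinely differ, exercising threshold monotonicity.

**Read-pair evidence.** Fragments are placed uniformly on each
accession's deletion-carrying genome with physical length
`~ Normal(insert_mean, insert_sd)` (defaults 600/60 bp, a typical
PCR-free library; reads 150 bp; coverage 10×), then projected to
reference coordinates, so pairs spanning a homozygous deletion of
length L show predicted length `~ Normal(insert_mean + L, insert_sd)`.
Reads that would straddle a deletion breakpoint are dropped, as an
aligner would clip them. Expected pair count is
`coverage · genome / (2 · read_len)`. The caller's sensitivity scales
with the expected number of pairs whose inner gap spans a point,
`coverage · (insert_mean − 2·read_len) / (2·read_len)` (= 10 at the
defaults), so min_support = 3 is comfortably exceeded at 10×.

**Determinism.** One root seed feeds named child streams (SNPs, TEs,
read pairs, XP-CLR scores) via `numpy.random.SeedSequence.spawn`; a
fixed seed fixes every output byte-for-byte.

**XP-CLR-style scores.** The generator also emits per-pool raw score
tables shaped like an XP-CLR scan (Exp(1) background, Uniform(40, 80)
in swept windows) so the three-approach consensus can run end-to-end
on synthetic data. The scores are synthetic stand-ins for an external
scan, not a composite-likelihood computation. Note that
mean-normalization makes the ≥ 5 cutoff self-referential: if a large
fraction of the genome is swept, the mean rises and normalized scores
fall — realistic behaviour of normalized scans.

## Curation

Sites are kept when MAF ≥ 0.05, observed heterozygosity ≤ 0.1 and
≥ 40 genotyped samples (all thresholds configurable). MAF uses allele
counts from genotyped individuals only; heterozygosity is the fraction
of heterozygous calls among genotyped calls (the denominator choice is
not fixed by convention; genotyped-only matches standard VCF-stats
semantics). Multi-allelic records are excluded at read time with a
logged count; sites with zero genotyped calls fail unconditionally.
The upstream genotype-quality filter of the original variant caller is
a pass-through assumption — it needs the caller's likelihoods, which a
genotype matrix no longer carries. Under this generator the curated
spectrum shows the expected structural signature: an excess of
high-frequency minor alleles (fixed differences between pools pile up
near MAF 0.5), although raw mean MAF *decreases* with drift because
the Balding–Nichols kernel also spreads frequencies toward the
extremes.

## Diversity, FST, windows, trees

π uses the unbiased per-site estimator `[n/(n−1)]·2p̂(1−p̂)` — exactly
the mean pairwise difference among the 2n observed alleles — summed
over sites and divided by interval length; sites with fewer than two
alleles are skipped. FST is Hudson's ratio-of-sums (robust to unequal
sample sizes; a per-window Weir–Cockerham variant was considered and
rejected as the default because the choice is not fixed by the
analysis design). Windows are anchored at coordinate 0 per chromosome
(default 50 kbp / 5 kbp); a trailing partial window is off by default.
Windows with π_wild = 0 have an undefined reduction ratio and are
excluded from decile ranking rather than coded 0 or 1.

Genetic distances are 1 − IBS share for SNPs and mismatch fraction
over co-called TEs for PAV. Neighbor joining is the Saitou–Nei
algorithm with deterministic tie-breaking (lexicographically smallest
label pair) and negative branch lengths clamped to zero with a
warning; on additive distances it provably recovers the generating
topology and branch lengths, which the tests verify for all 15
labeled 5-taxon topologies and against scikit-bio's implementation.

## Sweep calling

Quantiles are type-7 (linear interpolation); windows exactly at the
cutoff are included (≥ semantics), so call counts can slightly exceed
q·N. The gene-based approach ranks "low diversity" on the domesticated
subset by default (the founder-effect signal); the subset is
configurable since the convention is ambiguous. Per-pool analyses are
fully independent. XP-CLR normalization divides by the genome-wide
mean (common practice when a scan reports "normalized" scores); a
z-score option exists behind a flag.

## PAV genotyping and statistics

Deletion calling clusters discordant pairs (predicted length
> mean + 4 sd) whose inner intervals mutually overlap, keeping a
running intersection; clusters with ≥ 3 pairs emit a deletion spanning
the intersection with estimated length median(fragment) − mean.
Overlap genotyping uses the union of an accession's deletions
(fragmented calls of one true deletion are common); "at least 85%" is
inclusive. Per-TE Fisher tests are exact two-sided
(minimum-likelihood convention) with no multiple-testing correction —
error control is via the fixed stringent thresholds (1e-10 pools,
1e-5 wild/dom MI). Wilcoxon rank-sum is exact for untied groups of
≤ 12, otherwise a tie-corrected normal approximation. Superfamily
enrichment is a chi-square goodness-of-fit against background
proportions with df = k − 1. PAV is strictly binary (presence = the
reference allele); partial evidence can optionally be coded missing,
off by default.

## Gene–TE associations

TEs link to a gene when they overlap its body or lie within 10 kbp of
its ends (boundary inclusive, measured from the gene body, not the
strand-resolved TSS). With exon structure available, body overlaps
refine to exonic/intronic. Allele enumeration uses the binary pattern
over a gene's variable TEs in coordinate order; accessions with any
missing code are excluded rather than imputed (alleles are exact
configurations); the all-present reference pattern is listed first,
the rest by descending carrier count.

## Benchmark problem sizes

The validation experiments (`sweeptepop.evaluation`, backing both the
acceptance tests and `scripts/acceptance.py`) use: a 60-accession ×
2,000-TE cohort on 20 Mbp for PAV identity/monotonicity; 8 accessions,
300 TEs of 600–3,000 bp on 4 Mbp at 10× for deletion-caller recovery;
200 random matrices (≤ 10 diploids × ≤ 50 sites) plus an 18k-table
2×2 grid for the statistic oracles; 60 accessions, 12,000 SNPs, ten
50 kbp sweeps on 4 Mbp for sweep recovery; twenty 20-accession
replicates for structure recovery; and 50,000 sites with 20% missing
data for filter determinism. These sizes give stable estimates while
keeping each experiment in the seconds-to-a-minute range.

## Known limitations

No coalescent realism: sites are independent (no linkage), there is no
recombination graph or mutation-rate calibration, and read-pair
simulation stops at fragment geometry (no sequences, errors, or
mapping ambiguity). Deletions are homozygous by construction —
heterozygous deletions, split-read and depth evidence are out of
scope, as are TE discovery/classification and non-reference TE
insertions. Passing recovery benchmarks on this generator shows the
statistics and thresholds behave as designed under the assumed
frequency model; it does not certify performance on real short-read
data, where mapping artefacts and linkage dominate the error budget.
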