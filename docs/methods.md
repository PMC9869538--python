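# Methods

## Coordinates and annotation model

All intervals are BED-convention: 0-based, half-open. The TSS of a
minus-strand gene is `end − 1`; strand "." is treated as "+" for windowing
(peaks are unstranded). Gene models come from BED12 only: exons from the
block columns, introns as the gaps between blocks, the CDS from
thickStart/thickEnd (UTRs are the exonic regions outside the CDS,
strand-aware; genes with an empty CDS have no UTRs).

Feature assignment uses the **peak midpoint**, `floor((start+end)/2)`, not
any-overlap — this makes the category assignment a true partition (fractions
sum to 1 exactly) and matches the behaviour of midpoint-based annotators
commonly used for this task. Category priority when windows overlap:
promoter > TTS > 5′UTR > 3′UTR > exon > intron > intergenic. The promoter
window is the strand-aware `[TSS−1000, TSS+100)`; the TTS window mirrors it
(`[TTS−100, TTS+1000)`) — the mirror size is a configurable default, since
only the promoter window is dictated by the analysis definition. Ties
between genes break by smaller |distance to TSS|, then lexicographic gene
id, so output is deterministic. "Unknown" is reserved for peaks on
chromosomes absent from the annotation. The reported `distance_to_tss` is
to the nearest TSS on the chromosome (signed, negative upstream of that
gene's TSS).

## Consensus peaks

A consensus peak is one peak from *every* input sample with a common
intersection of at least `min_overlap_bp` (default 1 bp). Each input peak
contributes to at most one consensus peak; candidate tuples are selected
greedily by (chromosome, core start, longest core first), which keeps the
result deterministic and makes the per-sample Venn accounting consistent.
Venn counts assign each input peak once, to its maximal membership region
(the set of samples with ≥ 1 overlapping peak), so per-sample region counts
always sum to that sample's peak count. Both the union span and the common
core of each consensus peak are emitted, since a published "shared sites"
count may be expressed in either coordinate system.

## Motif scanning and co-occurrence

Motifs are degenerate IUPAC consensus strings matched exactly (no PWM
scoring): the analysis this package reproduces is defined in terms of
bracketed consensus sites, and exact matching keeps a per-position oracle
trivial. Both strands are scanned; reverse-complement hits are reported on
"−", and a position matching on both strands (always true for palindromes
such as AACCGGTT) is deduplicated to a single "+" hit, so the expected hit
count on i.i.d. uniform sequence is `(n−k+1)·p_match·(2−is_palindrome)`.
Flank co-occurrence flags a peak when ≥ 1 site interval overlaps
`[start−flank, end+flank)` with flank = 1000 bp by default; motif hits and
external peak lists are treated identically. The motif-centered coverage
matrix is *binary* per 50-bp bin (±2 kb default): the pipeline consumes
peak calls, not alignments, so read-level coverage is out of reach by
design and the binary analogue is reported instead.

## Knockout time-course model

Counts are normalised as RPKM. Per guide line, each treated day t is
compared with that line's own day-0 sample (per-guide day 0; the design
does not share untreated samples across lines):

* `FC = (RPKM_t + ε) / (RPKM_0 + ε)` with ε = 0.1 RPKM (configurable) for
  stability at zero counts;
* p-values from a two-sided test of equal count proportions between the two
  libraries: exact conditional binomial (conditioning on the count total,
  success probability `N_t/(N_0+N_t)`) when the smaller count is < 25, the
  pooled normal approximation otherwise. No replicate-variance model is
  attempted: with one library per (guide, day) the inter-sample proportion
  test is the natural choice, and the exact conditional form admits a
  brute-force enumeration oracle.

A gene is **regulated** when both knockout guides pass
(`p < 0.05` and `FC > 2` or `FC < 0.5`) at ≥ 1 timepoint each while the
control guide passes at none. Direction is `up`/`down` when all passing
fold changes agree, else `mixed`.

**AFC** is the geometric mean of the two guides' FC (i.e. the mean in log2
space), which is symmetric for induction and repression. Classification
evaluates, in order: sustained induction (AFC > 2, significant at all of
days 2/4/8/16), sustained repression (AFC < 0.5, significant at all),
induction reset (AFC > 2 and significant at all *early* days 2/4/8, then
1 < AFC < 2 at day 16), repression reset (mirrored, 0.5 < AFC < 1 at day
16), dynamic (significant AFC > 2 at some day and AFC < 0.5 at another),
else `other`. "Significant at t" means p < 0.05 in both guides. "Early"
is read strictly as *all* of days 2, 4 and 8 — the strictest consistent
reading of "at early time points" — and the day-16 reset bands are open
intervals. Classes are computed for every gene from its AFC profile; the
regulated flag is an independent filter (a gene can show a clean class
pattern yet be excluded because the control line also moved).

The cluster count for the regulated-gene heatmap is chosen from the k-means
within-cluster sum of squares (25 restarts, fixed seed), taking the elbow
at the **maximum second difference of log WSS**. The curvature is measured
on the log scale because on raw WSS the first split dominates the second
difference and the elbow collapses to k = 2 even for clearly separated
clusters; on the log scale the sharp relative drop at the true cluster
count dominates. Identical rows (WSS ≈ 0 at k = 1) return k = 1.

ChIP-qPCR arithmetic is included for completeness: percent input
`100 · 2^(Ct_input − log2(dilution) − Ct_IP)` and relative quantification
`2^−ΔΔCt`.

## Signature clusters and cohort validation

The positively associated cluster (down upon knockout) contains genes whose
control-guide FC stays inside (0.75, 1.5) at *every* timepoint while both
knockout guides give FC < 0.75 at ≥ 3 of 4 timepoints; the negatively
associated cluster mirrors it with FC > 1.5. In the cohort, patients are
ranked by driver (GRHL2) log2 expression — stable ties by patient id — and
split into four quartiles whose sizes differ by at most one (Q1 lowest).
The per-patient cluster score is the unweighted mean log2 expression over
the cluster genes (no per-gene centering; the analysis reports raw average
expression). Q1 vs Q4 is compared with a two-sided **Welch** t-test (the
safer default when only "t test" is specified; a pooled test is a
one-line change). Per-gene association is Pearson R against the driver
with two-sided p and Benjamini–Hochberg q-values across the queried list;
constant expression vectors are reported as missing and excluded from the
correction.

## Synthetic data: what is emulated, and what is not

The generator plants ground truth for every stage under controlled
geometry:

* **Genome** — genes on a slot grid (≥ 6 kb apart edge to edge, 1–10 exons,
  2–10 kb long) so neighbouring promoter/TTS windows never collide;
  optional uniform random sequence with planted motif copies.
* **Peak sets** — shared peaks identical across samples up to ± jitter
  (≤ 50 bp); promoter peaks are a subset of the shared peaks with midpoint
  planted inside the promoter window (jitter-safe margins); all other peaks
  sit on a background grid that avoids promoter windows and keeps peaks
  > 2 kb apart, so (a) the three-way consensus count equals the planted
  shared count exactly, (b) the recovered promoter fraction equals the
  planted fraction exactly, and (c) a flanking site planted for one peak
  can never flag a neighbour.
* **Counts** — negative binomial with `Var = μ + φμ²` around
  μ = baseline-RPKM × length(kb) × depth(millions) × planted FC; baseline
  RPKM is log-normal (median 30), depth defaults to 2×10⁷ mapped reads
  (the order of the real libraries) and dispersion φ defaults to 0.05.
  `φ = 0` switches to deterministic rounded means so noise-free recovery is
  exact. The two knockout guides realise the same planted pattern
  independently; the control guide stays null except for
  `control_responsive` genes, which respond in every guide. Planted
  patterns at days 2/4/8/16: sustained induction (4,4,4,4), sustained
  repression (0.25,…), induction reset (4,4,4,1.4), repression reset
  (0.25,0.25,0.25,0.7), dynamic (4,0.25,4,0.25). The reset day-16 values
  sit at the geometric centre of the open return bands (1,2) and (0.5,1) —
  a value on the band boundary would make noise-free recovery undefined.
* **Cohort** — driver log2 expression ~ N(8,1); each gene is
  ρ·z_driver + √(1−ρ²)·noise plus a gene-specific offset, so the planted ρ
  is the population Pearson correlation exactly; ER status is
  Bernoulli(0.75).

What the generator does **not** emulate: read-level data and mapping
artefacts, chromatin background and peak-width/score structure, correlated
gene–gene expression beyond the single driver factor, batch effects, and
RNA-stability (post-transcriptional) regulation. Passing recovery tests
therefore demonstrates the correctness of the pipeline's logic under its
stated statistical assumptions, not performance on raw sequencing data.

With dispersion 0.05 the planted-class recovery is ~94%, not 100%: the
irreducible fold-change noise (sd of log AFC ≈ √φ) occasionally pushes a
reset gene's day-16 AFC out of its open return band. Likewise the control
exclusion removes a planted gene whenever the control line's FC drifts
past 2 or 0.5 with an (always tiny) proportion-test p — roughly 8% of
genes at φ = 0.05 — which is the faithful behaviour of the published
filter under over-dispersed noise, not a defect.

## Numerical and design choices

* Sorting of intervals is stable and total on (chrom, start, end); all
  interval I/O preserves half-open coordinates and round-trips.
* Floats in TSV outputs are rendered as `%.6g`, making reruns with the same
  seed byte-identical.
* All randomness flows from a single integer seed; stage sub-seeds are
  derived deterministically.
* The two-sided exact binomial p-value uses the minimum-likelihood rule
  (sum of outcome probabilities ≤ the observed one, with a 1+1e−7 tie
  tolerance), matching the enumeration oracle used in the tests.
* Degenerate inputs: empty peak lists are errors where a fraction would be
  undefined (feature fractions, flank co-occurrence) and valid empties
  elsewhere (empty site list → fraction 0; no peak near any TSS → zero
  profile); constant cohort genes → missing correlation; identical AFC
  rows → k = 1.

## Problem sizes

The bundled tests and the acceptance script run entirely on synthetic data
at desk scale: 3 × 100–2000 peaks on 4–18 Mb toy genomes, 250–300 genes
with 15 samples (3 guides × 5 days), and cohorts of 800–2000 patients.
These sizes keep every oracle (O(n³) triple enumeration, per-position motif
scan, exact binomial enumeration) exact while completing in seconds.

## Known limitations

* Exact IUPAC matching cannot express graded motif affinity; a PWM scanner
  would be needed to rank degenerate sites.
* The proportion test treats libraries as binomial samples; it has no
  between-replicate dispersion term, so with over-dispersed input its
  p-values are anti-conservative (mitigated here by the fold-change
  thresholds, as in the original filter).
* Consensus chaining is single-use and greedy; pathological nested peak
  configurations could admit a different maximal matching.
* The cohort model plants a single latent factor (the driver); it does not
  reproduce co-expression structure among signature genes beyond that
  factor.
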