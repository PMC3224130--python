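# Methods

`matzyg` re-implements, as a tested pipeline on synthetic data with complete
ground truth, a comparative maternal/zygotic transcriptome analysis between a
de-novo-sequenced fly species (the *focal* species, "A") and a well-annotated
reference species ("B").  This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic study can and cannot
show about real data.

## Study design being emulated

Two cDNA libraries are sampled from the focal species: a **maternal** pool
(eggs collected before zygotic genome activation, 0–0.5 h) and a **zygotic**
pool (blastoderm/gastrulation stages, 3–6 h).  Libraries are normalized with
duplex-specific nuclease (DSN) and sequenced with long-read pyrosequencing
chemistry.  Raw reads are contaminated with sequences of a second organism
(aphid bycatch from egg collection).  The reference species contributes an
annotated transcriptome/proteome and a deep per-base coverage track of an
equivalent early stage.  The analysis asks, per orthologous gene pair, whether
the gene is maternally expressed in one species, the other, or both.

## Synthetic data generator

The generator's defaults are the study conditions; every downstream accuracy
claim in the test suite is a claim about these conditions.

**Transcripts.**  Each gene is 5'UTR + ORF + 3'UTR with region-controlled GC:
ORFs target GC 0.43, UTRs 0.20 (the AT-rich-UTR contrast that drives the
priming-bias model).  Regions are built with exact GC counts (a random
permutation of a fixed composition), ORFs start with ATG, end with a stop,
contain no internal stop and are a multiple of three.  Default sizes: 5'UTR
100–300 nt, ORF 300–600 codons, 3'UTR 200–600 nt.  Reference-species
orthologues are mutated copies at 10% nucleotide divergence; substitutions
draw the replacement base from the region's target composition (so regional
GC is preserved in expectation) and never create in-frame stops.  Planted
events: lineage-specific duplications (an extra focal copy at 25% divergence)
and losses (families with a reference member but no focal member).

**Abundances.**  Relative abundances are log-uniform over a configurable
number of decades (default 5.5), with the minimum non-zero abundance pinned
to 1 and the maximum to `10^range` exactly.  Maternal-library truth classes
are planted as disjoint strata of the spectrum — *maternal* genes in the top
20% of the log-range, *not_maternal* in the bottom 40%, *absent* at zero —
so the downstream level-1 classification threshold falls in the planted gap.
Every gene is expressed in the zygotic library (absent-in-maternal genes
re-enter high, the zygotically activated case).

**DSN normalization** is modeled as the rank-preserving power law
`a → a^alpha`.  The paper-gap here is real: only before/after decade spreads
are observable, so `alpha` is a free parameter.  The demo uses
`alpha = 3.6/5.5` so a 5.5-decade input spectrum leaves exactly 3.6 decades;
the one-off `LibraryConfig` default is 0.65.  Under the model the log-range
contracts exactly by `alpha` and Spearman rank correlation is exactly 1 —
both are asserted, not assumed.

**Reads.**  Per-gene expected read counts are proportional to
`abundance × length × mean priming efficiency`.  Priming efficiency is a
logistic in the windowed GC of the fragment starting at each position
(window 100 nt, midpoint 0.32, slope 15 by default); with region GC at
0.43/0.20 this gives an ORF:UTR efficiency ratio around 6:1, reproducing the
order-of-magnitude ORF-vs-UTR coverage contrast such libraries show.  Read
lengths come from a two-component lognormal mixture with modes 400 nt
(weight 0.8, sigma 0.25) and 80 nt (weight 0.2, sigma 0.35) — the bimodal
length profile of a partially size-selected long-read library.  Reads
running over the transcript end are truncated; substitution errors are
applied at 1% per base (drawn against the realized fragment length);
homopolymer indels are deliberately out of scope because the downstream
thresholds under test are identity thresholds, not error-model inference.
A fixed fraction of reads (default 22%) is drawn from a separate contaminant
reference set (GC 0.30) with the same length and error model.  Read order is
shuffled and everything is truth-labelled.

**Margin repair.**  Whether a planted class is recoverable depends on where
the level-1 threshold lands, which the generator can compute analytically:
under the sampling model the expected level of gene *g* is depth-independent,

    E[level_g] = 1e6 · a_g · eff_g / Σ_h a_h L_h eff_h .

`design_study` evaluates this expectation for every gene and moves any gene
whose expected level sits within a factor 3 of the threshold out of the
ambiguous band before any read is drawn.  Planted truth is therefore
"class under the model's own expectation, with a 3× margin", which is what a
classifier reading noisy coverage can actually be held to.

**Reference-species expression** arrives as a per-base Poisson coverage
track per locus (uniform across the locus), with per-class target levels —
maternal 10^0.7–10^2, not_maternal 10^-2–10^-0.7 — times a configurable
track size (10 Mb-equivalents by default), so reference classes are planted
with ≥5× margins of their own.

## Read QC

Raw reads shorter than 50 nt are dropped first (they are below the minimum
alignment length and could never be screened); remaining reads are removed
iff their best alignment to any contaminant reference reaches **identity ≥
0.95 over ≥ 50 aligned columns**.  Identity is matches ÷ alignment columns
with gaps counting as columns — the conservative convention, declared because
the operational definition matters at a 5% tolerance.  Contig-level filtering
uses a separate, boundary-inclusive 100-nt cutoff.  The three-way partition
(kept / contaminant / short) is exhaustive and a report closes the
arithmetic exactly.

The screen itself runs on a k-mer index (k = 14, sampled every 5 positions)
for candidate lookup followed by bit-parallel infix alignment (edlib), with
identity recomputed from the CIGAR under the convention above.  The full
Smith–Waterman implementation is the reference path; tests cross-check the
screen's decisions against planted truth at the study's contamination rate.

## Orthology and annotation

**Alignment** is affine-gap Smith–Waterman (numba-compiled full dynamic
programming; a gap of length L costs `open + L·extend`).  Translated search
scans all six reading frames of the nucleotide query against a protein
target; stop codons are scored at −1000 so they never appear inside a local
alignment.  Schemes: nucleotide match 2 / mismatch −3, gap 5/2; protein
BLOSUM62, gap 11/1.

**E-values** use Karlin–Altschul statistics `E = K·m·n·e^(−λS)` with fixed,
declared constants per scheme (protein gapped BLOSUM62: λ = 0.267,
K = 0.041; nucleotide: λ = 0.625, K = 0.41) and raw sequence lengths for
`m`, `n` (no edge correction).  Declared constants keep desk-scale runs
deterministic and make the two working thresholds — 10 for a permissive
screen, 1e-10 for high-confidence orthologues — interpretable.

**Best hits** break ties by highest score, then longest alignment, then
lexicographically smallest target id, so output is order-independent.
Reciprocal best hits pair (a, b) iff each is the other's best hit with both
E-values under threshold; the map is one-to-one by construction.  For large
all-vs-all problems a word prefilter (protein 5-mers across all six frames,
≥3 shared; nucleotide 12-mers) restricts which pairs are aligned; every
reported hit is still scored by full DP, so reported scores are exact.  The
prefilter can in principle miss a best hit weaker than the word threshold;
at the conservative 1e-10 working threshold such hits are far below
significance.

**Family search** walks a strictly increasing E-value schedule (default
1e-3, 1e-1, 10).  At each cutoff, pool sequences hitting a family seed are
candidates; a candidate is accepted iff its best hit in the full reference
proteome is itself a family seed — the mechanical version of "stop when new
hits match clearly non-orthologous sequences".  Once a member exists, the
first cutoff adding none terminates the walk (cutoffs before the first
acceptance never terminate it, so members missed at stringent cutoffs are
still found); `stop_evalue` records the cutoff at which the final member
entered.  The reference check compares the candidate's best seed score
against every non-seed protein in the proteome, walking word-sharing rivals
first with an early exit on the first protein that outscores the seed (a
rival scoring exactly equal does not reject: the seed retains best-hit
status on ties).  Ordinary candidates are rejected by their own orthologue
after a single alignment; genuinely seed-related candidates — including
relatives too diverged to share exact words — pay one full scan, so the
laxest cutoff stays tractable without silently missing diverged members.

**Gap pruning** for downstream tree building removes exactly the alignment
columns where more than half the rows carry a gap (a column at exactly half
stays), preserving row and residue order; the operation is idempotent.

## Coverage, levels and classification

Reads map to their single best reference at the same ≥95%/≥50-column rule;
reads tying across references are discarded (counted, not assigned), which
keeps coverage conservation exact: summed per-base coverage equals summed
aligned bases, checked on every run.  Per-base coverage counts reads
overlapping each position (for substitution-only reads this equals
base-level coverage).

The expression level of a gene is its **mean fold-coverage divided by the
post-filter library size in megabases** — an RPKM-like quantity chosen
because it is scale-invariant under uniform library duplication and halves
when the library doubles at fixed counts (both asserted).  Classification:
level > 1 → maternal, 0 < level ≤ 1 → not maternal, 0 → absent; the
boundary case (exactly 1) is not maternal because the rule is strict.
The divisor is "bases kept after QC", the one reading under which a unit
threshold separates well-covered from marginal genes in this design; it is
an interpretive choice and is surfaced as an explicit parameter.

Reference-species levels are read from the coverage track through the
mis-annotation guard: a gene's level is the strongest exon **strictly longer
than 500 nt**, or the strongest transcript variant (length-weighted mean over
its exons), whichever is higher; when no exon clears the bar the exon term
is simply absent.

Maternal/zygotic **fold change** is the plain ratio of mean coverages with
sentinels (`zygotic_only`, `undetected`) instead of pseudocounts, because
read absence is reported separately from ratios.  **Cross-species
discordance** is defined on maternal status alone: a pair is `A_only` or
`B_only` iff exactly one species is maternal, otherwise concordant — a
not_maternal-vs-absent pair is not a maternal-expression difference, and the
call stays robust at the detection floor.  The comparison is antisymmetric
under species swap.

## Demo study conditions and problem sizes

The demo configuration — what `run_pipeline(demo_config())`, the end-to-end
acceptance test and `scripts/acceptance.py` execute — is 200 gene families,
two libraries of 4×10^5 reads each (22% contaminants, 1% error), 10 planted
discordances (5 per direction), 3 family losses, 1 duplication, abundance
spectrum 5.5 decades compressed to 3.6.  At these sizes the mean reference
depth is far above 20×, and the expected number of planted-class failures
from sampling alone (genes at the pinned spectrum floor drawing zero reads)
is below one gene; the test suite's smaller fixtures (12–50 genes, 10^4–10^5
reads) exercise the same code paths at reduced depth where a boundary gene
may occasionally sit at the detection floor.

## Known limitations

* The generator draws independent random sequences per family: no repeats,
  no paralogous families beyond the planted duplications, no shared domains —
  so the orthology problem is easier than in real transcriptomes, and the
  reported recovery rates are upper bounds for real data.
* No assembly stage: the pipeline consumes transcripts directly, whereas the
  emulated workflow assembled reads first.  Isoform structure exists only on
  the reference side, and only as far as the exon-max heuristic needs it.
* 454-specific homopolymer indel errors, quality scores and paired ends are
  not modeled; identity thresholds are exercised under substitution noise
  only.
* DSN normalization as a pure power law preserves ranks by construction;
  real normalization adds re-amplification noise that can reorder genes.
* Karlin–Altschul constants are declared, not estimated; absolute E-values
  are therefore approximate, while their ordering (which drives every
  decision in the pipeline) is exact given the scores.
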