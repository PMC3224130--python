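# matzyg

Comparative **mat**ernal/**zyg**otic transcriptome profiling between a
de-novo-sequenced species and an annotated reference, exercised end to end on
simulated long-read (454-style) libraries with complete ground truth.

## The problem

Early fly embryos run on maternally deposited mRNA until the zygotic genome
switches on.  Given two embryonic cDNA libraries from a non-model species — a
maternal pool (0–0.5 h) and a zygotic pool (3–6 h) — and the annotated
transcriptome of a reference species, one can ask, gene by gene, *is this
gene maternally provided in one species but not the other?*  Answering that
from raw pyrosequencing reads requires a chain of unglamorous steps, each
with thresholds that matter: screening out contaminant reads (eggs collected
from aphid-infested plants carry aphid RNA), orthology assignment by
reciprocal best hits, per-base read coverage, a length- and depth-normalized
expression level, and a classification rule with a fixed cutoff.

`matzyg` implements that chain as a tested library, together with a
synthetic-data generator that plants every quantity the pipeline is supposed
to recover — contaminant labels, orthologous pairs, gene duplications and
losses, expression classes, cross-species discordances — so the whole
analysis can be validated against truth without any downloads.  It is aimed
at people building or sanity-checking comparative EST/RNA-seq pipelines and
at anyone who wants a controlled testbed for identity-threshold heuristics.

## The methods at the core

* **Local alignment & E-values.**  Affine-gap Smith–Waterman (full dynamic
  programming, numba-compiled), six-frame translated search against protein
  targets (stops never align), and Karlin–Altschul expectation values
  `E = K·m·n·e^(−λS)` with declared constants.  Two working thresholds:
  E ≤ 10 (permissive screen) and E ≤ 1e-10 (high-confidence orthologues).
* **Reciprocal best hits.**  (a, b) are orthologues iff each is the other's
  best hit under threshold; ties break by score, then alignment length, then
  id, so output is deterministic.
* **Read screens.**  A read is contaminant iff it aligns to a contaminant
  reference at ≥ 95% identity (matches/columns, gaps count) over ≥ 50
  columns; the same rule maps reads back to gene references.
* **Expression level.**  `level = mean fold-coverage / library megabases`
  (an RPKM-like quantity); `level > 1` → maternal, `0 < level ≤ 1` → not
  maternal, `0` → absent.  Reference-species levels come from a coverage
  track via the strongest exon > 500 nt or the strongest transcript variant,
  whichever is higher.
* **Gene-family search.**  Iteratively relaxed E-value cutoffs
  (1e-3 → 1e-1 → 10); new candidates are accepted only while their best hit
  in the full reference proteome is still a family seed.
* **DSN normalization model.**  `a → a^α` (rank-preserving), so a 5.5-decade
  abundance spectrum compresses to exactly `5.5·α` decades.

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Run the demo study — 200 gene families in two species, two libraries of
4×10⁵ reads (22% planted contaminants, 1% error), abundance spectrum of 5.5
decades DSN-compressed to 3.6, with 10 planted maternal-expression
discordances, 3 family losses and 1 duplication:

```python
from matzyg import demo_config, run_pipeline, evaluate_run

result = run_pipeline(demo_config(seed=11))
for k, v in evaluate_run(result).items():
    print(f"{k}: {v}")
```

which prints (seed 11):

```
contaminant_sensitivity: 0.9991454069927503
contaminant_specificity: 1.0
n_reads_screened: 786606
mapping_accuracy: 0.9992650109268375
n_reads_mapped: 612254
rbh_recall: 1.0
rbh_precision: 1.0
class_accuracy_a: 0.9949494949494949
class_accuracy_b: 1.0
discordances_planted: 10
discordances_recovered: 10
false_discordances: 0
family_calls_total: 10
family_calls_correct: 10
coverage_conservation_fraction: 1.0
orf_exceeds_utr_fraction: 0.8983050847457628
dsn_log10_range_maternal: 3.6
raw_log10_range_maternal: 5.5
```

Reading this: the 95%-identity screen removed 99.9% of planted contaminant
reads with no false removals; every one of the 197 planted orthologous pairs
was recovered by reciprocal best hits at E ≤ 1e-10 with nothing spurious;
99.5% of the 198 focal genes got their planted maternal/not-maternal/absent
class back from read coverage alone (the stragglers sit at the pinned floor
of the 3.6-decade spectrum, where a gene expects only a handful of reads);
all 10 planted cross-species discordances were called with zero false
discordances among the concordant pairs; the three lost families came back
`not_detected` and the duplicated family `duplicated`.  Coverage bookkeeping
is exact (summed per-base coverage equals summed aligned bases), and ~90% of
covered genes show the ORF-above-UTR coverage contrast that the GC-dependent
priming bias produces.  The run takes a few minutes on one core.

`run_pipeline(cfg, outdir=...)` additionally writes every stage artifact
(FASTA/GFF3 inputs, truth tables, QC reports, orthology pairs, per-base
coverage in wiggle-like text, expression/class/discordance tables, the
log2-level scatter table, family calls, category recovery, provenance with
sha256 digests) — byte-identical across reruns with the same config and
seed.  The same stages are exposed as subcommands of the `matzyg` CLI
(`simulate`, `qc`, `annotate`, `coverage`, `express`, `pcr`, `run`, ...).

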