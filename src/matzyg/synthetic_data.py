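"""Synthetic paired-species transcriptomes and normalized 454-style read libraries.

This module builds the fully ground-truthed inputs that the downstream QC,
orthology, coverage and classification stages are tested against.  It emulates
an early-embryo EST study design: two libraries per focal species (a maternal
0-0.5 h pool sampled before zygotic genome activation, and a zygotic 3-6 h
pool), sequenced with long-read pyrosequencing chemistry after duplex-specific
nuclease (DSN) normalization of the cDNA.

The generative model, briefly:

* **Transcripts** are built from three regions - 5'UTR, ORF, 3'UTR - with
  independently controlled GC content (AT-rich UTRs, GC ~0.20, vs ORFs at
  GC ~0.43).  ORFs start with ATG, end with a stop codon, contain no internal
  stop, and have length divisible by three.  The reference species carries an
  exon/transcript-variant structure on top of the same sequence.
* **Orthology** between the two species is created by copying each focal-species
  ORF and mutating it at a configurable nucleotide divergence (stops are never
  introduced), so reciprocal-best-hit truth is recoverable by construction.
  Lineage-specific duplications (an extra, more diverged focal-species copy)
  and losses (families absent from one species) are planted and recorded.
* **Abundances** span a configurable number of decades (log-uniform), with the
  minimum non-zero abundance pinned to 1 and the maximum to ``10**log10_range``.
  Maternal/not-maternal/absent classes are planted as disjoint strata of the
  spectrum so a coverage-derived expression threshold can separate them.
* **DSN normalization** is modeled as the rank-preserving power law
  ``a -> a**alpha``; the log-dynamic range contracts exactly by ``alpha``.
* **Reads** are drawn per gene with probability proportional to
  ``abundance x length x priming_efficiency(GC)``; start positions follow the
  same logistic priming-efficiency weight evaluated on the local (windowed) GC
  of the fragment, which reproduces the empirical under-coverage of AT-rich
  UTRs.  Read lengths come from a two-component lognormal mixture (modes near
  400 nt and 80 nt); substitution errors are applied at a configurable rate.
  A configurable fraction of reads is drawn from a contaminant reference set
  instead (aphid-like bycatch), truth-labelled per read.

All randomness flows through a single integer seed; identical seeds and
configurations produce byte-identical libraries.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

NT = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_CODON_TABLE = {}


def _build_codon_table():
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for c in STOP_CODONS:
        _CODON_TABLE[c] = "*"


_build_codon_table()


def translate(seq: str) -> str:
    """Translate a DNA sequence in frame +1 (standard code, '*' for stops)."""
    return "".join(
        _CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TranscriptSpec:
    """A reference mRNA with region structure.

    Coordinates are 0-based half-open on the plus strand.  ``utr5``, ``orf``
    and ``utr3`` partition ``[0, len(sequence))`` in that order; the ORF length
    is divisible by 3 and includes the stop codon.  For the annotated reference
    species, ``exons`` (half-open intervals) and ``variants`` (lists of exon
    indices) describe the locus structure used by the exon-level expression
    heuristic.
    """

    gene_id: str
    sequence: str
    orf: tuple[int, int]
    utr5: tuple[int, int]
    utr3: tuple[int, int]
    gc_orf_target: float = 0.43
    gc_utr_target: float = 0.20
    exons: list[tuple[int, int]] | None = None
    variants: list[list[int]] | None = None

    def __post_init__(self):
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def orf_seq(self) -> str:
        return self.sequence[self.orf[0] : self.orf[1]]

    @property
    def protein(self) -> str:
        """Encoded peptide, without the terminal stop."""
        return translate(self.orf_seq).rstrip("*")

    def region_gc(self) -> dict[str, float]:
        s = self.sequence
        return {
            "utr5": gc_fraction(s[self.utr5[0] : self.utr5[1]]),
            "orf": gc_fraction(s[self.orf[0] : self.orf[1]]),
            "utr3": gc_fraction(s[self.utr3[0] : self.utr3[1]]),
        }

    def validate(self):
        u5, o, u3 = self.utr5, self.orf, self.utr3
        if not (u5[0] == 0 and u5[1] == o[0] and o[1] == u3[0] and u3[1] == self.length):
            raise ValueError(
                f"{self.gene_id}: utr5/orf/utr3 must partition [0,{self.length}) in order"
            )
        if (o[1] - o[0]) % 3 != 0:
            raise ValueError(f"{self.gene_id}: ORF length not divisible by 3")
        if self.exons is not None:
            prev = 0
            for a, b in self.exons:
                if a < prev or b <= a or b > self.length:
                    raise ValueError(f"{self.gene_id}: exons must be ordered, disjoint, in bounds")
                prev = b


TranscriptSet = dict[str, TranscriptSpec]


@dataclass
class OrthologyTruth:
    """Planted orthology: 1:1 pairs plus duplication/loss events."""

    pairs: list[tuple[str, str]]
    duplications: dict[str, set[str]] = field(default_factory=dict)
    losses: dict[str, set[str]] = field(default_factory=dict)  # species -> family ids
    families: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # families: family_id -> {"A": [gene ids], "B": [gene ids]}

    def validate(self):
        seen_a, seen_b = set(), set()
        for a, b in self.pairs:
            if a in seen_a or b in seen_b:
                raise ValueError("a gene may appear in at most one orthologous pair")
            seen_a.add(a)
            seen_b.add(b)


@dataclass
class ExpressionProfile:
    """Per-library relative abundances with planted expression classes.

    ``abundance`` maps library name ("maternal", "zygotic") to
    ``{gene_id: relative abundance}``.  Abundance 0 encodes absence from that
    library.  ``classes`` holds the planted maternal-library class per gene
    (maternal / not_maternal / absent).
    """

    abundance: dict[str, dict[str, float]]
    classes: dict[str, str] = field(default_factory=dict)

    def log10_range(self, library: str = "maternal") -> float:
        vals = [v for v in self.abundance[library].values() if v > 0]
        if not vals:
            return 0.0
        return math.log10(max(vals) / min(vals))


@dataclass
class LibraryConfig:
    """Study conditions for one simulated read library."""

    n_reads: int = 100_000
    length_modes: tuple[float, float] = (400.0, 80.0)
    length_sigmas: tuple[float, float] = (0.25, 0.35)
    length_weight_long: float = 0.8
    min_read_length: int = 20
    dsn_alpha: float = 0.65
    gc_bias_strength: float = 15.0
    gc_bias_midpoint: float = 0.32
    gc_window: int = 100
    contaminant_fraction: float = 0.22
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0 < self.dsn_alpha <= 1:
            raise ValueError("dsn_alpha must lie in (0, 1]")
        for name, frac in (
            ("contaminant_fraction", self.contaminant_fraction),
            ("error_rate", self.error_rate),
        ):
            if not 0 <= frac < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 < self.length_weight_long <= 1:
            raise ValueError("length_weight_long must lie in (0, 1]")


@dataclass
class Read:
    read_id: str
    sequence: str
    truth_gene: str | None  # source gene, or contaminant reference id
    is_contaminant: bool


@dataclass
class ReadLibrary:
    """A truth-labelled read set from one time point."""

    library_id: str
    reads: list[Read]

    @property
    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)

    def __len__(self):
        return len(self.reads)


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------


def random_region(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence whose GC count is exactly round(gc * length)."""
    n_gc = int(round(gc * length))
    arr = np.empty(length, dtype="U1")
    gc_pos = rng.permutation(length)
    arr[gc_pos[:n_gc]] = rng.choice(["G", "C"], size=n_gc)
    arr[gc_pos[n_gc:]] = rng.choice(["A", "T"], size=length - n_gc)
    return "".join(arr)


def _make_locus_structure(total: int, rng: np.random.Generator):
    """Exon intervals plus transcript variants for a locus of given length."""
    margin = min(200, total // 4)
    n_ex = int(rng.integers(2, 5))
    span = np.arange(margin, total - margin)
    n_ex = min(n_ex, len(span) + 1)
    if n_ex < 2:
        return [(0, total)], [[0]]
    cuts = sorted(rng.choice(span, size=n_ex - 1, replace=False))
    bounds = [0, *map(int, cuts), total]
    exons = [(bounds[i], bounds[i + 1]) for i in range(n_ex)]
    variants = [list(range(n_ex))]
    if n_ex > 2:
        variants.append(list(range(n_ex - 1)))
    return exons, variants


def _fix_stop(codon: str, rng: np.random.Generator) -> str:
    # swap the third base to break the stop while touching GC as little as possible
    choices = {"TAA": "TAC", "TAG": "TAT", "TGA": "TGC"}
    return choices[codon]


def make_orf(n_codons: int, gc: float, rng: np.random.Generator) -> str:
    """ATG ... stop, no internal stops, length 3*n_codons, GC near target."""
    if n_codons < 3:
        raise ValueError("ORF needs at least start + one codon + stop")
    body = random_region(3 * (n_codons - 2), gc, rng)
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    codons = [(_fix_stop(c, rng) if c in STOP_CODONS else c) for c in codons]
    stop = rng.choice(list(STOP_CODONS))
    return "ATG" + "".join(codons) + stop


def _make_transcript(
    gene_id: str,
    rng: np.random.Generator,
    length_params: dict | None = None,
    with_structure: bool = False,
) -> TranscriptSpec:
    p = {
        "utr5_range": (100, 300),
        "orf_codons_range": (300, 600),
        "utr3_range": (200, 600),
        "gc_orf": 0.43,
        "gc_utr": 0.20,
    }
    if length_params:
        p.update(length_params)
    u5 = int(rng.integers(*p["utr5_range"]))
    nc = int(rng.integers(*p["orf_codons_range"]))
    u3 = int(rng.integers(*p["utr3_range"]))
    seq = (
        random_region(u5, p["gc_utr"], rng)
        + make_orf(nc, p["gc_orf"], rng)
        + random_region(u3, p["gc_utr"], rng)
    )
    orf = (u5, u5 + 3 * nc)
    total = len(seq)
    exons = variants = None
    if with_structure:
        exons, variants = _make_locus_structure(total, rng)
    return TranscriptSpec(
        gene_id=gene_id,
        sequence=seq,
        orf=orf,
        utr5=(0, u5),
        utr3=(orf[1], total),
        gc_orf_target=p["gc_orf"],
        gc_utr_target=p["gc_utr"],
        exons=exons,
        variants=variants,
    )


def mutate_transcript(
    spec: TranscriptSpec,
    divergence: float,
    rng: np.random.Generator,
    gene_id: str | None = None,
    with_structure: bool = False,
) -> TranscriptSpec:
    """Substitute a ``divergence`` fraction of positions; never create stops.

    Substitutions inside the ORF that would introduce an in-frame stop codon
    (or destroy the start/stop) are re-drawn, so the reading frame of the copy
    stays intact; UTR positions mutate freely.
    """
    if not 0 <= divergence < 0.8:
        raise ValueError(
            f"divergence {divergence} too high: reading frames cannot be preserved"
        )
    seq = list(spec.sequence)
    o0, o1 = spec.orf
    n_mut = rng.binomial(len(seq), divergence)
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        pos = int(pos)
        if o0 <= pos < o0 + 3 or o1 - 3 <= pos < o1:
            continue  # keep start and stop codons
        old = seq[pos]
        in_orf = o0 <= pos < o1
        t = spec.gc_orf_target if in_orf else spec.gc_utr_target
        # replacement drawn from the region's target composition so the
        # copy's regional GC stays on target: P(new in GC) = t exactly
        if rng.random() < t:
            first = "C" if old == "G" else "G" if old == "C" else ("G", "C")[int(rng.integers(2))]
        else:
            first = "T" if old == "A" else "A" if old == "T" else ("A", "T")[int(rng.integers(2))]
        alts = [first] + [b for b in NT if b != old and b != first]
        for new in alts:
            seq[pos] = new
            if in_orf:
                ci = o0 + 3 * ((pos - o0) // 3)
                if "".join(seq[ci : ci + 3]) in STOP_CODONS:
                    seq[pos] = old
                    continue
            break
    out = replace(
        spec,
        gene_id=gene_id or spec.gene_id,
        sequence="".join(seq),
        exons=None,
        variants=None,
    )
    if with_structure:
        out.exons, out.variants = _make_locus_structure(out.length, rng)
    return out


def generate_transcript_pair_set(
    n_genes: int,
    duplication_rate: float = 0.0,
    loss_rate: float = 0.0,
    length_params: dict | None = None,
    seed: int = 0,
    divergence: float = 0.10,
    dup_divergence: float = 0.25,
    n_duplications: int | None = None,
    n_losses: int | None = None,
) -> tuple[TranscriptSet, TranscriptSet, OrthologyTruth]:
    """Two-species transcript sets with recorded orthology truth.

    Each of ``n_genes`` families starts from a focal-species (A) transcript;
    the reference-species (B) member is a mutated copy at ``divergence``
    nucleotide substitutions per site, carrying exon/variant structure.
    Duplication events add an extra A copy at ``dup_divergence``; loss events
    drop the A member entirely (the family survives only in B).  Event counts
    are drawn binomially from the rates unless given explicitly.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name, r in (("duplication_rate", duplication_rate), ("loss_rate", loss_rate)):
        if not 0 <= r < 1:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = np.random.Generator(np.random.PCG64(seed))
    if n_duplications is None:
        n_duplications = int(rng.binomial(n_genes, duplication_rate))
    if n_losses is None:
        n_losses = int(rng.binomial(n_genes, loss_rate))
    if n_duplications + n_losses > n_genes:
        raise ValueError("more planted events than families")
    order = rng.permutation(n_genes)
    loss_fams = set(int(i) for i in order[:n_losses])
    dup_fams = set(int(i) for i in order[n_losses : n_losses + n_duplications])

    set_a: TranscriptSet = {}
    set_b: TranscriptSet = {}
    truth = OrthologyTruth(pairs=[])
    for i in range(n_genes):
        fam = f"fam{i:04d}"
        ga, gb = f"A{i:04d}", f"B{i:04d}"
        base = _make_transcript(ga, rng, length_params)
        b_copy = mutate_transcript(base, divergence, rng, gene_id=gb, with_structure=True)
        set_b[gb] = b_copy
        members_a = []
        if i not in loss_fams:
            set_a[ga] = base
            members_a.append(ga)
            truth.pairs.append((ga, gb))
        else:
            truth.losses.setdefault("A", set()).add(fam)
        if i in dup_fams:
            gd = f"A{i:04d}d"
            set_a[gd] = mutate_transcript(base, dup_divergence, rng, gene_id=gd)
            members_a.append(gd)
            truth.duplications[fam] = set(members_a)
        truth.families[fam] = {"A": members_a, "B": [gb]}
    truth.validate()
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# Abundance profiles and DSN normalization
# ---------------------------------------------------------------------------

MATERNAL_STRATUM = (0.80, 1.0)  # fraction of the log-range occupied by maternal genes
NOT_MATERNAL_STRATUM = (0.0, 0.40)


def simulate_abundances(
    gene_ids: list[str],
    log10_range: float = 5.5,
    maternal_fraction: float = 0.30,
    seed: int = 0,
    absent_fraction: float = 0.20,
) -> ExpressionProfile:
    """Plant per-library relative abundances spanning ``log10_range`` decades.

    Maternal-library abundances are log-uniform within disjoint strata of the
    spectrum: planted *maternal* genes occupy the top of the range, planted
    *not_maternal* genes the bottom, and *absent* genes get abundance 0, so a
    downstream expression threshold can fall in the gap between strata.  The
    minimum non-zero abundance is pinned to 1 and the maximum to
    ``10**log10_range`` exactly.  Every gene is expressed in the zygotic
    library (absent-in-maternal genes re-enter high, echoing zygotically
    activated genes); zygotic abundances are jittered around the maternal ones
    otherwise.
    """
    if not gene_ids:
        raise ValueError("empty gene list")
    if log10_range < 0:
        raise ValueError("log10_range must be >= 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    n = len(gene_ids)
    u = rng.random(n)
    classes = np.where(
        u < maternal_fraction,
        "maternal",
        np.where(u < maternal_fraction + absent_fraction, "absent", "not_maternal"),
    )
    if n == 1:
        classes[:] = "maternal"
    mat_idx = np.flatnonzero(classes == "maternal")
    nm_idx = np.flatnonzero(classes == "not_maternal")

    t = np.zeros(n)
    both_strata = len(mat_idx) > 0 and len(nm_idx) > 0
    if both_strata:
        t[mat_idx] = rng.uniform(*MATERNAL_STRATUM, size=len(mat_idx))
        t[nm_idx] = rng.uniform(*NOT_MATERNAL_STRATUM, size=len(nm_idx))
        t[mat_idx[int(rng.integers(len(mat_idx)))]] = 1.0  # pin the maximum
        t[nm_idx[int(rng.integers(len(nm_idx)))]] = 0.0  # pin the minimum
    else:
        present = np.flatnonzero(classes != "absent")
        t[present] = rng.uniform(0.0, 1.0, size=len(present))
        if len(present) >= 2:
            t[present[0]], t[present[-1]] = 0.0, 1.0
        else:
            t[present] = 0.0  # single gene: abundance 1, range 0

    maternal = {}
    zygotic = {}
    for i, g in enumerate(gene_ids):
        if classes[i] == "absent":
            maternal[g] = 0.0
            tz = rng.uniform(0.55, 1.0)
        else:
            maternal[g] = 10.0 ** (t[i] * log10_range)
            tz = float(np.clip(t[i] + rng.uniform(-0.1, 0.1), 0.0, 1.0))
        zygotic[g] = 10.0 ** (tz * log10_range)
    return ExpressionProfile(
        abundance={"maternal": maternal, "zygotic": zygotic},
        classes={g: str(classes[i]) for i, g in enumerate(gene_ids)},
    )


def apply_dsn_normalization(profile: ExpressionProfile, dsn_alpha: float) -> ExpressionProfile:
    """Duplex-specific-nuclease normalization as a power-law compression.

    Abundances map to ``a**alpha`` library-wise, which preserves ranks exactly
    and contracts the log-dynamic range by exactly ``alpha`` (a 5.5-decade
    spectrum becomes ``5.5 * alpha`` decades).
    """
    if not 0 < dsn_alpha <= 1:
        raise ValueError("dsn_alpha must lie in (0, 1]")
    out = {
        lib: {g: (a ** dsn_alpha if a > 0 else 0.0) for g, a in amap.items()}
        for lib, amap in profile.abundance.items()
    }
    return ExpressionProfile(abundance=out, classes=dict(profile.classes))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def priming_efficiency(gc: np.ndarray | float, strength: float, midpoint: float):
    """Logistic hexamer-priming efficiency as a function of fragment GC."""
    return 1.0 / (1.0 + np.exp(-strength * (np.asarray(gc, dtype=float) - midpoint)))


def windowed_gc(seq: str, window: int = 100) -> np.ndarray:
    """GC fraction of the ``window``-nt fragment starting at each position."""
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(np.float64)
    prefix = np.concatenate([[0.0], np.cumsum(is_gc)])
    n = len(seq)
    starts = np.arange(n)
    ends = np.minimum(starts + window, n)
    return (prefix[ends] - prefix[starts]) / (ends - starts)


def start_weights(seq: str, config: LibraryConfig) -> np.ndarray:
    if config.gc_bias_strength == 0:
        return np.ones(len(seq))
    return priming_efficiency(
        windowed_gc(seq, config.gc_window), config.gc_bias_strength, config.gc_bias_midpoint
    )


def mean_priming_efficiency(seq: str, config: LibraryConfig) -> float:
    return float(np.mean(start_weights(seq, config)))


def _sample_lengths(n: int, config: LibraryConfig, rng: np.random.Generator) -> np.ndarray:
    """Two-component lognormal mixture; ``length_modes`` are the modal lengths."""
    long = rng.random(n) < config.length_weight_long
    mode = np.where(long, config.length_modes[0], config.length_modes[1])
    sigma = np.where(long, config.length_sigmas[0], config.length_sigmas[1])
    mu = np.log(mode) + sigma**2  # lognormal mode = exp(mu - sigma^2)
    lengths = np.exp(rng.normal(mu, sigma))
    return np.maximum(lengths.astype(int), config.min_read_length)


def _apply_errors(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_err, len(chars)), replace=False):
        old = chars[pos]
        alts = [b for b in NT if b != old]
        chars[pos] = alts[int(rng.integers(3))]
    return "".join(chars)


def simulate_reads(
    transcripts: TranscriptSet,
    profile: ExpressionProfile,
    contaminant_refs: TranscriptSet | dict[str, str] | None,
    config: LibraryConfig,
    library: str = "maternal",
) -> ReadLibrary:
    """Draw a truth-labelled read library from one time point.

    The per-gene expected read count is proportional to
    ``abundance x length x mean priming efficiency``; within a gene, read
    start positions are weighted by the logistic priming efficiency of the
    local fragment GC.  Reads running over the transcript end are truncated.
    Exactly ``round(n_reads * contaminant_fraction)`` reads are drawn
    uniformly from the contaminant references instead, with the same length
    and error model.
    """
    amap = profile.abundance[library]
    missing = [g for g in transcripts if g not in amap]
    if missing:
        raise ValueError(f"profile does not cover transcript ids: {missing[:3]}...")
    n_contam = int(round(config.n_reads * config.contaminant_fraction))
    if n_contam > 0 and not contaminant_refs:
        raise ValueError("contaminant_fraction > 0 requires a non-empty contaminant set")

    rng = np.random.Generator(
        np.random.PCG64([config.seed, zlib.crc32(library.encode()) & 0x7FFFFFFF])
    )
    gene_ids = sorted(transcripts)
    weights = np.array(
        [
            amap[g] * transcripts[g].length * mean_priming_efficiency(transcripts[g].sequence, config)
            for g in gene_ids
        ]
    )
    n_gene_reads = config.n_reads - n_contam
    reads: list[Read] = []
    if weights.sum() > 0 and n_gene_reads > 0:
        p = weights / weights.sum()
        counts = rng.multinomial(n_gene_reads, p)
    else:
        counts = np.zeros(len(gene_ids), dtype=int)

    for gi, g in enumerate(gene_ids):
        k = int(counts[gi])
        if k == 0:
            continue
        spec = transcripts[g]
        w = start_weights(spec.sequence, config)
        starts = rng.choice(spec.length, size=k, p=w / w.sum())
        lengths = _sample_lengths(k, config, rng)
        frags = [
            spec.sequence[int(starts[j]) : int(starts[j]) + int(lengths[j])]
            for j in range(k)
        ]
        errs = rng.binomial([len(f) for f in frags], config.error_rate)
        for j in range(k):
            reads.append(Read("", _apply_errors(frags[j], int(errs[j]), rng), g, False))

    if n_contam > 0:
        cseqs = {
            k: (v.sequence if isinstance(v, TranscriptSpec) else v)
            for k, v in contaminant_refs.items()
        }
        cids = sorted(cseqs)
        pick = rng.integers(len(cids), size=n_contam)
        lengths = _sample_lengths(n_contam, config, rng)
        frags = []
        for j in range(n_contam):
            seq = cseqs[cids[int(pick[j])]]
            s = int(rng.integers(max(1, len(seq) - 50)))
            frags.append(seq[s : s + int(lengths[j])])
        errs = rng.binomial([len(f) for f in frags], config.error_rate)
        for j in range(n_contam):
            reads.append(
                Read("", _apply_errors(frags[j], int(errs[j]), rng), cids[int(pick[j])], True)
            )

    order = rng.permutation(len(reads))
    out = [reads[int(i)] for i in order]
    for i, r in enumerate(out):
        r.read_id = f"{library}_{i:07d}"
    return ReadLibrary(library_id=library, reads=out)


def generate_contaminants(
    n_refs: int = 20,
    length_range: tuple[int, int] = (800, 3000),
    gc: float = 0.30,
    seed: int = 0,
) -> dict[str, str]:
    """Aphid-like contaminant reference sequences (plain id -> sequence map)."""
    rng = np.random.Generator(np.random.PCG64([seed, 9151]))
    return {
        f"contam{i:03d}": random_region(int(rng.integers(*length_range)), gc, rng)
        for i in range(n_refs)
    }


# ---------------------------------------------------------------------------
# Expected expression levels under the sampling model (analytic)
# ---------------------------------------------------------------------------


def expected_levels(
    transcripts: TranscriptSet,
    abundance: dict[str, float],
    config: LibraryConfig,
) -> dict[str, float]:
    """Expected normalized expression level per gene, in the study's units.

    A gene's level is mean fold-coverage divided by the post-filter library
    size in megabases.  Under the sampling model this expectation is
    independent of sequencing depth:

        level_g = 1e6 * a_g * effbar_g / sum_h(a_h * L_h * effbar_h)

    where ``effbar`` is the mean priming efficiency over start positions.
    Used to plant truth classes with a margin around the level-1 threshold.
    """
    eff = {g: mean_priming_efficiency(t.sequence, config) for g, t in transcripts.items()}
    total = sum(abundance[g] * t.length * eff[g] for g, t in transcripts.items())
    if total == 0:
        return {g: 0.0 for g in transcripts}
    return {g: 1e6 * abundance[g] * eff[g] / total for g in transcripts}


# ---------------------------------------------------------------------------
# Whole-study design (the demo's ground truth)
# ---------------------------------------------------------------------------


@dataclass
class StudyTruth:
    """Complete planted truth for one simulated two-species study."""

    transcripts_a: TranscriptSet
    transcripts_b: TranscriptSet
    orthology: OrthologyTruth
    profile_raw: ExpressionProfile  # before DSN
    profile: ExpressionProfile  # after DSN (what reads are drawn from)
    classes_a: dict[str, str]
    classes_b: dict[str, str]
    level_targets_b: dict[str, float]
    discordances: dict[tuple[str, str], str]  # pair -> A_only / B_only
    family_truth: dict[str, str]  # family id -> present / duplicated / not_detected
    expected_levels_a: dict[str, float]


B_MATERNAL_LEVELS = (0.7, 2.0)  # log10 target level strata for the reference species
B_NOT_MATERNAL_LEVELS = (-2.0, -0.7)


def design_study(
    n_genes: int = 200,
    n_discordant: int = 10,
    n_losses: int = 3,
    n_duplications: int = 1,
    config: LibraryConfig | None = None,
    log10_range: float = 5.5,
    dsn_alpha: float = 3.6 / 5.5,
    maternal_fraction: float = 0.30,
    seed: int = 0,
    class_margin: float = 3.0,
) -> StudyTruth:
    """Assemble a full ground-truthed study: sequences, truth, profiles, classes.

    Focal-species classes are planted by :func:`simulate_abundances` and then
    checked against the analytic expected level under the read-sampling model;
    any gene whose expected level falls within ``class_margin`` of the
    classification threshold (level 1) has its abundance moved to the margin
    boundary, so planted classes are recoverable at the simulated depth.
    Cross-species discordances are planted by assigning the reference species
    the opposite maternal status for ``n_discordant`` orthologous pairs (half
    in each direction).
    """
    config = config or LibraryConfig()
    rng = np.random.Generator(np.random.PCG64([seed, 733]))
    ta, tb, truth = generate_transcript_pair_set(
        n_genes,
        seed=seed,
        n_duplications=n_duplications,
        n_losses=n_losses,
    )
    gene_ids = sorted(ta)
    raw = simulate_abundances(
        gene_ids, log10_range=log10_range, maternal_fraction=maternal_fraction, seed=seed
    )
    profile = apply_dsn_normalization(raw, dsn_alpha)

    # margin repair: keep every planted class at least class_margin away from level 1
    for lib in ("maternal",):
        amap = profile.abundance[lib]
        for _ in range(3):
            lev = expected_levels(ta, amap, config)
            moved = 0
            for g in gene_ids:
                cls = profile.classes[g]
                if cls == "maternal" and lev[g] < class_margin:
                    amap[g] *= class_margin * 1.5 / max(lev[g], 1e-12)
                    moved += 1
                elif cls == "not_maternal" and lev[g] > 1.0 / class_margin:
                    amap[g] *= 1.0 / (class_margin * 1.5 * lev[g])
                    moved += 1
            if moved == 0:
                break

    classes_a = dict(profile.classes)
    expected_a = expected_levels(ta, profile.abundance["maternal"], config)

    # choose discordant pairs: A_only needs a maternal A gene, B_only a not_maternal A gene
    pair_of = dict(truth.pairs)
    mat_pairs = [g for g in gene_ids if classes_a[g] == "maternal" and g in pair_of]
    nm_pairs = [g for g in gene_ids if classes_a[g] == "not_maternal" and g in pair_of]
    n_a_only = n_discordant // 2
    n_b_only = n_discordant - n_a_only
    if len(mat_pairs) < n_a_only or len(nm_pairs) < n_b_only:
        raise ValueError("not enough eligible pairs to plant the requested discordances")
    a_only = [mat_pairs[int(i)] for i in rng.choice(len(mat_pairs), n_a_only, replace=False)]
    b_only = [nm_pairs[int(i)] for i in rng.choice(len(nm_pairs), n_b_only, replace=False)]
    discordances = {}
    classes_b: dict[str, str] = {}
    for ga, gb in truth.pairs:
        cls = classes_a[ga]
        if ga in a_only:
            classes_b[gb] = "not_maternal"
            discordances[(ga, gb)] = "A_only"
        elif ga in b_only:
            classes_b[gb] = "maternal"
            discordances[(ga, gb)] = "B_only"
        else:
            classes_b[gb] = cls
    for gb in tb:
        classes_b.setdefault(gb, "not_maternal")  # loss-family genes, outside comparison

    level_targets_b = {}
    for gb, cls in classes_b.items():
        if cls == "maternal":
            level_targets_b[gb] = 10.0 ** rng.uniform(*B_MATERNAL_LEVELS)
        elif cls == "not_maternal":
            level_targets_b[gb] = 10.0 ** rng.uniform(*B_NOT_MATERNAL_LEVELS)
        else:
            level_targets_b[gb] = 0.0

    family_truth = {}
    for fam, members in truth.families.items():
        if not members["A"]:
            family_truth[fam] = "not_detected"
        elif len(members["A"]) >= 2:
            family_truth[fam] = "duplicated"
        else:
            family_truth[fam] = "present"

    return StudyTruth(
        transcripts_a=ta,
        transcripts_b=tb,
        orthology=truth,
        profile_raw=raw,
        profile=profile,
        classes_a=classes_a,
        classes_b=classes_b,
        level_targets_b=level_targets_b,
        discordances=discordances,
        family_truth=family_truth,
        expected_levels_a=expected_a,
    )


def simulate_coverage_track(
    transcripts_b: TranscriptSet,
    level_targets: dict[str, float],
    library_megabases: float = 10.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-base coverage tracks for the reference species' loci.

    Each gene's per-base counts are Poisson with mean
    ``target_level * library_megabases``, emulating a deep short-read
    coverage track mapped onto the locus (uniform across exons).
    """
    rng = np.random.Generator(np.random.PCG64([seed, 4177]))
    tracks = {}
    for g in sorted(transcripts_b):
        lam = level_targets.get(g, 0.0) * library_megabases
        tracks[g] = rng.poisson(lam, size=transcripts_b[g].length).astype(np.int64)
    return tracks


# ---------------------------------------------------------------------------
# Writers (FASTA / GFF3-like / truth TSV)
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str] | TranscriptSet, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            seq = sequences[name]
            if isinstance(seq, TranscriptSpec):
                seq = seq.sequence
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(transcripts: TranscriptSet, path) -> None:
    """ORF/UTR (and exon) features, 1-based inclusive per GFF convention."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(transcripts):
            t = transcripts[g]
            rows = [("five_prime_UTR", t.utr5), ("CDS", t.orf), ("three_prime_UTR", t.utr3)]
            if t.exons:
                rows += [("exon", e) for e in t.exons]
            for ftype, (a, b) in rows:
                if b <= a:
                    continue
                fh.write(
                    f"{g}\tmatzyg\t{ftype}\t{a + 1}\t{b}\t.\t+\t.\tID={g}:{ftype}:{a}\n"
                )


def write_reads_fasta(lib: ReadLibrary, fasta_path, truth_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for r in lib.reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
    if truth_path:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tsource_gene\tis_contaminant\n")
            for r in lib.reads:
                fh.write(f"{r.read_id}\t{r.truth_gene}\t{int(r.is_contaminant)}\n")


def write_wiggle(tracks: dict[str, np.ndarray], path) -> None:
    """Fixed-step wiggle-like text: one block per locus, step 1."""
    with open(path, "w") as fh:
        for g in sorted(tracks):
            fh.write(f"fixedStep chrom={g} start=1 step=1\n")
            fh.write("\n".join(str(int(v)) for v in tracks[g]))
            fh.write("\n")


def read_wiggle(path) -> dict[str, np.ndarray]:
    tracks: dict[str, list[int]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                current = fields["chrom"]
                tracks[current] = []
            else:
                tracks[current].append(int(line))
    return {g: np.array(v, dtype=np.int64) for g, v in tracks.items()}
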