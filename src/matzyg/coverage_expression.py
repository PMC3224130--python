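"""Read-to-reference coverage, normalized expression levels and maternal calls.

Reads are mapped to reference gene sequences at >= 95% identity over >= 50
aligned columns and assigned to their single best reference (ties discarded,
with a count, to keep the coverage-conservation invariant exact).  Per-base
coverage counts the reads overlapping each reference position; region means
split it by 5'UTR / ORF / 3'UTR.

Expression levels follow an RPKM-like convention: a gene's level is its mean
fold-coverage divided by the post-filter library size in megabases.  On that
scale, level > 1 calls a gene maternally expressed, 0 < level <= 1 not
maternal, level 0 absent (the "plotted outside the scale" case).  For the
annotated reference species - whose expression arrives as a per-base coverage
track over each locus rather than as reads - a gene's level is approximated
by the strongest exon longer than 500 nt or the strongest transcript variant,
whichever is higher, guarding against mis-annotated exon-intron structures.

Cross-species comparison marks each orthologous pair concordant, A_only
(maternal in the focal species only) or B_only (the converse); the maternal /
zygotic fold change is the plain ratio of mean coverages, with sentinels for
genes undetected in the maternal pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .orthology import KmerIndex, OrthologyMap, best_identity_hit
from .synthetic_data import ReadLibrary, TranscriptSet, TranscriptSpec, gc_fraction

ZYGOTIC_ONLY = "zygotic_only"
UNDETECTED = "undetected"


@dataclass
class ReadAssignment:
    read_id: str
    gene_id: str
    identity: float
    aligned_interval: tuple[int, int]
    aligned_length: int


@dataclass
class MappingResult:
    assignments: list[ReadAssignment]
    n_unassigned: int = 0
    n_ambiguous: int = 0  # discarded multi-mapping ties


def map_reads(
    reads: ReadLibrary | list,
    references: TranscriptSet | dict[str, str],
    min_identity: float = 0.95,
    min_hit_length: int = 50,
    index: KmerIndex | None = None,
) -> MappingResult:
    """Assign each read to its best qualifying reference, or to none.

    A read qualifies on a reference when its best infix alignment reaches
    ``min_identity`` (matches / columns) over at least ``min_hit_length``
    columns.  Reads whose best score is shared by several references are
    discarded as ambiguous rather than double-counted.
    """
    if min_identity <= 0 or min_hit_length <= 0:
        raise ValueError("thresholds must be positive")
    if not references:
        raise ValueError("empty reference set")
    seqs = {
        g: (r.sequence if isinstance(r, TranscriptSpec) else r)
        for g, r in references.items()
    }
    if index is None:
        index = KmerIndex(seqs)
    items = reads.reads if isinstance(reads, ReadLibrary) else reads
    out = MappingResult(assignments=[])
    for r in items:
        rid, seq = (r.read_id, r.sequence) if hasattr(r, "read_id") else r
        hit = best_identity_hit(seq, index, min_identity, min_hit_length)
        if hit is None:
            out.n_unassigned += 1
        elif hit.tied:
            out.n_ambiguous += 1
        else:
            out.assignments.append(
                ReadAssignment(rid, hit.target_id, hit.identity,
                               hit.target_interval, hit.aligned_cols)
            )
    return out


@dataclass
class CoverageProfile:
    """Per-position read counts over one reference in one library."""

    gene_id: str
    library_id: str
    per_base: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.per_base.mean()) if len(self.per_base) else 0.0

    @property
    def total_aligned_bases(self) -> int:
        return int(self.per_base.sum())


def per_base_coverage(
    assignments: list[ReadAssignment],
    reference_length: int,
    gene_id: str = "",
    library_id: str = "",
) -> CoverageProfile:
    """Count, for every reference position, the assigned reads covering it.

    The conservation invariant holds exactly: the vector sums to the total
    number of aligned bases across assignments.
    """
    cov = np.zeros(reference_length + 1, dtype=np.int64)
    for a in assignments:
        s, e = a.aligned_interval
        if s < 0 or e > reference_length or e <= s:
            raise ValueError(f"interval {a.aligned_interval} out of bounds for {gene_id}")
        cov[s] += 1
        cov[e] -= 1
    return CoverageProfile(gene_id, library_id, np.cumsum(cov[:-1]))


def region_summary(profile: CoverageProfile, spec: TranscriptSpec) -> dict:
    """Mean fold-coverage and GC per region (ORF, 5'UTR, 3'UTR).

    Empty regions report NaN means rather than zero.
    """
    if len(profile.per_base) != spec.length:
        raise ValueError("coverage vector does not match the reference length")
    out = {}
    for name, (a, b) in (("utr5", spec.utr5), ("orf", spec.orf), ("utr3", spec.utr3)):
        if b <= a:
            out[f"mean_{name}"] = float("nan")
            out[f"gc_{name}"] = float("nan")
        else:
            out[f"mean_{name}"] = float(profile.per_base[a:b].mean())
            out[f"gc_{name}"] = gc_fraction(spec.sequence[a:b])
    return out


def fold_change_mz(maternal: CoverageProfile, zygotic: CoverageProfile):
    """Zygotic / maternal ratio of mean coverage, with division sentinels."""
    if maternal.gene_id != zygotic.gene_id:
        raise ValueError(
            f"gene id mismatch: {maternal.gene_id} vs {zygotic.gene_id}"
        )
    m, z = maternal.mean, zygotic.mean
    if m == 0 and z == 0:
        return UNDETECTED
    if m == 0:
        return ZYGOTIC_ONLY
    return z / m


def normalized_level(
    profile: CoverageProfile,
    gene_length: int,
    library_total_megabases: float,
) -> float:
    """Expression level: mean fold-coverage per megabase of library.

    ``(total aligned bases / gene_length) / library_total_megabases``; zero
    iff the gene attracted no reads.
    """
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    if library_total_megabases <= 0:
        raise ValueError("library size must be positive")
    return profile.total_aligned_bases / gene_length / library_total_megabases


def exon_max_level(
    exon_levels: list[tuple[int, float]],
    variant_levels: list[float],
    min_exon_length: int = 500,
) -> float:
    """Locus-level expression from exon and transcript-variant levels.

    Returns the maximum of (a) the strongest exon strictly longer than
    ``min_exon_length`` nt and (b) the strongest transcript variant.  When no
    exon exceeds the length bar, the exon term is simply absent.
    """
    if not exon_levels and not variant_levels:
        raise ValueError("no exons or variants given")
    terms = [lvl for length, lvl in exon_levels if length > min_exon_length]
    terms += list(variant_levels)
    if not terms:
        raise ValueError("no exon above the length cutoff and no variants")
    return max(terms)


MATERNAL, NOT_MATERNAL, ABSENT = "maternal", "not_maternal", "absent"


def classify_maternal(
    levels: dict[str, float] | pd.Series, threshold: float = 1.0
) -> dict[str, str]:
    """level > threshold -> maternal; 0 < level <= threshold -> not_maternal; 0 -> absent.

    The boundary sits exactly at the threshold: a level equal to it is
    not_maternal ("higher than" is strict).
    """
    out = {}
    for g, lvl in levels.items():
        if lvl < 0:
            raise ValueError(f"negative level for {g}")
        out[g] = MATERNAL if lvl > threshold else (NOT_MATERNAL if lvl > 0 else ABSENT)
    return out


def expression_table(
    levels: dict[str, float],
    classes: dict[str, str] | None = None,
    fold_changes: dict | None = None,
) -> pd.DataFrame:
    classes = classes or classify_maternal(levels)
    rows = [
        {
            "gene_id": g,
            "level": levels[g],
            "class": classes[g],
            "fold_change_mz": (fold_changes or {}).get(g, float("nan")),
        }
        for g in sorted(levels)
    ]
    return pd.DataFrame(rows)


CONCORDANT, A_ONLY, B_ONLY = "concordant", "A_only", "B_only"


def compare_species(
    omap: OrthologyMap,
    levels_a: pd.DataFrame,
    levels_b: pd.DataFrame,
) -> pd.DataFrame:
    """Per orthologous pair, call maternal-expression discordance.

    A pair is A_only when the focal species is maternal (level > 1) and the
    reference species is not, B_only for the converse, otherwise concordant.
    Genes without an orthologue are excluded (they appear in neither row).
    """
    ca = dict(zip(levels_a["gene_id"], levels_a["class"]))
    cb = dict(zip(levels_b["gene_id"], levels_b["class"]))
    la = dict(zip(levels_a["gene_id"], levels_a["level"]))
    lb = dict(zip(levels_b["gene_id"], levels_b["level"]))
    rows = []
    for a, b, *_ in omap.pairs:
        if a not in ca:
            raise KeyError(f"gene {a} missing from the focal-species table")
        if b not in cb:
            raise KeyError(f"gene {b} missing from the reference-species table")
        mat_a = ca[a] == MATERNAL
        mat_b = cb[b] == MATERNAL
        disc = CONCORDANT if mat_a == mat_b else (A_ONLY if mat_a else B_ONLY)
        rows.append(
            {
                "gene_a": a, "gene_b": b,
                "level_a": la[a], "level_b": lb[b],
                "class_a": ca[a], "class_b": cb[b],
                "discordance": disc,
                "log2_level_a": np.log2(la[a]) if la[a] > 0 else float("-inf"),
                "log2_level_b": np.log2(lb[b]) if lb[b] > 0 else float("-inf"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference-species ingestion: coverage track -> per-gene levels
# ---------------------------------------------------------------------------


def levels_from_track(
    track: np.ndarray,
    spec: TranscriptSpec,
    library_total_megabases: float,
) -> float:
    """Locus-level expression from a per-base coverage track.

    Exon levels are each exon's mean coverage per megabase; variant levels are
    length-weighted means over the variant's exons.  The exon-max heuristic
    then yields the gene level.
    """
    if len(track) != spec.length:
        raise ValueError("track length does not match the locus")
    exons = spec.exons or [(0, spec.length)]
    exon_levels = []
    exon_means = []
    for a, b in exons:
        mean = float(track[a:b].mean()) if b > a else 0.0
        exon_means.append((b - a, mean))
        exon_levels.append((b - a, mean / library_total_megabases))
    variants = spec.variants or [list(range(len(exons)))]
    variant_levels = []
    for idxs in variants:
        tot_len = sum(exon_means[i][0] for i in idxs)
        tot_cov = sum(exon_means[i][0] * exon_means[i][1] for i in idxs)
        variant_levels.append((tot_cov / tot_len if tot_len else 0.0) / library_total_megabases)
    return exon_max_level(exon_levels, variant_levels)


def coverage_summary_table(
    profiles: dict[str, CoverageProfile],
    transcripts: TranscriptSet,
    library_total_megabases: float,
) -> pd.DataFrame:
    rows = []
    for g in sorted(profiles):
        prof = profiles[g]
        spec = transcripts[g]
        summary = region_summary(prof, spec)
        rows.append(
            {
                "gene_id": g,
                "library": prof.library_id,
                "mean_coverage": prof.mean,
                "total_aligned_bases": prof.total_aligned_bases,
                "level": normalized_level(prof, spec.length, library_total_megabases),
                **summary,
            }
        )
    return pd.DataFrame(rows)
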