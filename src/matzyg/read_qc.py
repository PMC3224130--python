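"""Raw-read and contig pre-processing: contaminant screen, length cutoffs.

The focal species' eggs are collected from aphid-infested material, so a
substantial fraction of the raw reads is aphid bycatch.  The screen removes
every read whose best local alignment to any contaminant reference reaches
95% identity (matches / alignment columns, gaps counting as columns) over at
least 50 aligned columns; everything below either bar is kept.  Short-sequence
cutoffs are separate and boundary-inclusive: raw reads need >= 50 nt,
assembled contigs >= 100 nt.

The three-way partition (kept / removed-contaminant / removed-short) is
exhaustive and exact; a FilterReport closes the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .orthology import KmerIndex, best_identity_hit
from .synthetic_data import Read, ReadLibrary, TranscriptSpec


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_contaminant: int = 0
    n_removed_short: int = 0
    n_kept: int = 0
    bases_input: int = 0
    bases_kept: int = 0
    warning: str = ""

    def validate(self):
        if self.n_input != self.n_removed_contaminant + self.n_removed_short + self.n_kept:
            raise ValueError("filter report does not partition the input")
        if self.bases_kept > self.bases_input:
            raise ValueError("kept bases exceed input bases")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _as_seq_map(refs) -> dict[str, str]:
    return {
        k: (v.sequence if isinstance(v, TranscriptSpec) else v) for k, v in refs.items()
    }


def remove_contaminants(
    reads: ReadLibrary,
    contaminant_refs: dict,
    min_identity: float = 0.95,
    min_hit_length: int = 50,
    index: KmerIndex | None = None,
) -> tuple[ReadLibrary, ReadLibrary, FilterReport]:
    """Partition reads into (kept, removed) by the contaminant identity screen.

    A read is removed iff its best local alignment to any contaminant
    reference has identity >= ``min_identity`` over >= ``min_hit_length``
    columns.  An empty contaminant set is a warning, not an error: nothing is
    removed.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must lie in (0, 1]")
    report = FilterReport(n_input=len(reads), bases_input=reads.total_bases)
    if not contaminant_refs:
        report.n_kept = len(reads)
        report.bases_kept = reads.total_bases
        report.warning = "empty contaminant set: screen skipped"
        report.validate()
        return reads, ReadLibrary(reads.library_id, []), report
    if index is None:
        index = KmerIndex(_as_seq_map(contaminant_refs))
    kept, removed = [], []
    for r in reads.reads:
        hit = best_identity_hit(r.sequence, index, min_identity, min_hit_length)
        (removed if hit is not None else kept).append(r)
    report.n_removed_contaminant = len(removed)
    report.n_kept = len(kept)
    report.bases_kept = sum(len(r.sequence) for r in kept)
    report.validate()
    return (
        ReadLibrary(reads.library_id, kept),
        ReadLibrary(reads.library_id, removed),
        report,
    )


def filter_min_length(sequences, min_length: int = 100):
    """Keep exactly the sequences of length >= ``min_length``, order preserved.

    Accepts a ReadLibrary, a dict of id -> sequence, or a list of (id, seq) /
    Read objects; returns the matching kind.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if isinstance(sequences, ReadLibrary):
        kept = [r for r in sequences.reads if len(r.sequence) >= min_length]
        return ReadLibrary(sequences.library_id, kept)
    if isinstance(sequences, dict):
        return {
            k: v
            for k, v in sequences.items()
            if len(v.sequence if isinstance(v, TranscriptSpec) else v) >= min_length
        }
    out = []
    for item in sequences:
        seq = item.sequence if isinstance(item, (Read, TranscriptSpec)) else item[1]
        if len(seq) >= min_length:
            out.append(item)
    return out


def length_histogram(sequences, bin_width: int = 200) -> pd.DataFrame:
    """Sequence counts per length bin ``[k*w, (k+1)*w)``; counts sum to n."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if isinstance(sequences, ReadLibrary):
        lengths = [len(r.sequence) for r in sequences.reads]
    elif isinstance(sequences, dict):
        lengths = [
            len(v.sequence if isinstance(v, TranscriptSpec) else v)
            for v in sequences.values()
        ]
    else:
        lengths = [
            len(s.sequence if isinstance(s, (Read, TranscriptSpec)) else s[1])
            for s in sequences
        ]
    counts: dict[int, int] = {}
    for L in lengths:
        counts[L // bin_width] = counts.get(L // bin_width, 0) + 1
    rows = [
        {"bin_start": k * bin_width, "bin_end": (k + 1) * bin_width, "count": c}
        for k, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "count"])


def qc_library(
    reads: ReadLibrary,
    contaminant_refs: dict,
    min_identity: float = 0.95,
    min_read_length: int = 50,
    min_hit_length: int = 50,
    index: KmerIndex | None = None,
) -> tuple[ReadLibrary, ReadLibrary, ReadLibrary, FilterReport]:
    """Full read QC: length cutoff, then contaminant screen.

    Returns (kept, removed_contaminant, removed_short, report).  The length
    cutoff runs first - reads below the minimum alignment length could never
    be screened anyway - so the partition is unambiguous.
    """
    short = [r for r in reads.reads if len(r.sequence) < min_read_length]
    long_enough = ReadLibrary(
        reads.library_id, [r for r in reads.reads if len(r.sequence) >= min_read_length]
    )
    kept, removed, sub_report = remove_contaminants(
        long_enough, contaminant_refs, min_identity, min_hit_length, index=index
    )
    report = FilterReport(
        n_input=len(reads),
        n_removed_contaminant=sub_report.n_removed_contaminant,
        n_removed_short=len(short),
        n_kept=len(kept),
        bases_input=reads.total_bases,
        bases_kept=kept.total_bases,
        warning=sub_report.warning,
    )
    report.validate()
    return kept, removed, ReadLibrary(reads.library_id, short), report
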