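"""Pipeline orchestration, summary artifacts and the in-silico PCR check.

``run_pipeline`` executes the whole study on synthetic data with complete
ground truth: simulate -> QC -> annotate (RBH) -> coverage -> expression
classification -> cross-species comparison -> gene-family search -> report.
Every stage's output is reproducible byte-for-byte from (config, seed), and a
provenance log records parameters, counts and artifact digests.

``insilico_pcr`` locates a primer pair on a template (exact matches by
default, both strands) and reports the predicted amplicon length, the check
used to pick normalization-assessment amplicons.  ``category_recovery``
tabulates, per functional category, how many reference genes were recovered
by the orthology annotation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import coverage_expression as ce
from . import orthology as ortho
from . import read_qc as qc
from . import synthetic_data as sd

logger = logging.getLogger("matzyg")

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


class PCRError(ValueError):
    """Base class for in-silico PCR failures."""


class NoBindingSite(PCRError):
    pass


class MultipleProducts(PCRError):
    pass


class PrimersOutOfOrder(PCRError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{label} primer is empty")
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"{label} primer contains ambiguous characters")


def _exact_sites(template: str, probe: str) -> list[int]:
    sites = []
    start = template.find(probe)
    while start != -1:
        sites.append(start)
        start = template.find(probe, start + 1)
    return sites


def _strand_products(template: str, fwd: str, rev_rc: str) -> list[tuple[int, int]]:
    """(start, end) plus-coordinate intervals of all products on one strand."""
    products = []
    f_sites = _exact_sites(template, fwd)
    r_sites = _exact_sites(template, rev_rc)
    for i in f_sites:
        for j in r_sites:
            if j >= i + len(fwd):
                products.append((i, j + len(rev_rc)))
    return products, bool(f_sites), bool(r_sites)


def insilico_pcr(
    template: str,
    primers: PrimerPair,
    search_both_strands: bool = True,
) -> int:
    """Predicted amplicon length for an exact-matching primer pair.

    The forward primer must match the template exactly and the reverse
    primer's reverse complement must match downstream of it; the amplicon
    runs from the forward primer's 5' end through the reverse primer's
    binding 3' end, both primers included.  Both strands are searched;
    products identical in template coordinates (palindromic layouts) count
    once.  Anything other than exactly one product raises.
    """
    if not template:
        raise ValueError("empty template")
    template = template.upper()
    fwd = primers.forward.upper()
    rev_rc = ortho.revcomp(primers.reverse.upper())
    plus, f_ok, r_ok = _strand_products(template, fwd, rev_rc)
    intervals = {(s, e, "+") for s, e in plus}
    if search_both_strands:
        minus, f_ok2, r_ok2 = _strand_products(ortho.revcomp(template), fwd, rev_rc)
        L = len(template)
        for s, e in minus:
            iv = (L - e, L - s)
            if (iv[0], iv[1], "+") not in intervals:
                intervals.add((iv[0], iv[1], "-"))
        f_ok, r_ok = f_ok or f_ok2, r_ok or r_ok2
    if not intervals:
        if not f_ok or not r_ok:
            missing = []
            if not f_ok:
                missing.append("forward")
            if not r_ok:
                missing.append("reverse")
            raise NoBindingSite(
                f"{primers.name}: no binding site for {' and '.join(missing)} primer"
            )
        raise PrimersOutOfOrder(
            f"{primers.name}: primer sites overlap or are out of order"
        )
    if len(intervals) > 1:
        raise MultipleProducts(
            f"{primers.name}: {len(intervals)} distinct products predicted"
        )
    s, e, _ = next(iter(intervals))
    return e - s


# ---------------------------------------------------------------------------
# Category recovery
# ---------------------------------------------------------------------------

OVERALL_CATEGORY = "all_annotated"


def category_recovery(
    omap: ortho.OrthologyMap,
    categories: dict[str, str],
) -> pd.DataFrame:
    """Per-category annotation recovery of reference genes.

    ``categories`` maps reference gene ids to one functional label each.  A
    gene counts as recovered when it appears in an orthologous pair.  The
    overall annotation rate is appended as a pseudo-category.
    """
    paired_b = {b for _, b, *_ in omap.pairs}
    rows = []
    labels = sorted(set(categories.values()))
    for label in labels + [OVERALL_CATEGORY]:
        genes = (
            list(categories)
            if label == OVERALL_CATEGORY
            else [g for g, lab in categories.items() if lab == label]
        )
        n_ref = len(genes)
        n_rec = sum(g in paired_b for g in genes)
        rows.append(
            {
                "category": label,
                "n_reference": n_ref,
                "n_recovered": n_rec,
                "percent": (100.0 * n_rec / n_ref) if n_ref else float("nan"),
            }
        )
    return pd.DataFrame(rows)


DEFAULT_CATEGORIES = [
    "transcription factor - strict",
    "transcription factor - putative",
    "enzyme",
    "transducer",
    "structure",
    "translational control",
]


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All study conditions and thresholds, with defaults from the study design."""

    seed: int = 0
    # simulation
    n_genes: int = 200
    n_discordant: int = 10
    n_losses: int = 3
    n_duplications: int = 1
    n_reads: int = 400_000
    contaminant_fraction: float = 0.22
    error_rate: float = 0.01
    log10_range: float = 5.5
    dsn_alpha: float = 3.6 / 5.5
    maternal_fraction: float = 0.30
    gc_bias_strength: float = 15.0
    library_megabases_b: float = 10.0
    # thresholds (held at the study's working values)
    min_identity: float = 0.95
    min_read_length: int = 50
    min_contig_length: int = 100
    min_hit_length: int = 50
    e_screen: float = 10.0
    e_confident: float = 1e-10
    e_schedule: tuple = (1e-3, 1e-1, 10.0)
    min_exon_length: int = 500
    level_threshold: float = 1.0
    n_family_sample: int = 6

    def library_config(self, **overrides) -> sd.LibraryConfig:
        kw = dict(
            n_reads=self.n_reads,
            dsn_alpha=self.dsn_alpha,
            gc_bias_strength=self.gc_bias_strength,
            contaminant_fraction=self.contaminant_fraction,
            error_rate=self.error_rate,
            seed=self.seed,
        )
        kw.update(overrides)
        return sd.LibraryConfig(**kw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["e_schedule"] = list(d["e_schedule"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "e_schedule" in d:
            d["e_schedule"] = tuple(d["e_schedule"])
        return cls(**d)


def demo_config(seed: int = 0, **overrides) -> PipelineConfig:
    """The default demo study: 200 families, two 4x10^5-read libraries."""
    return PipelineConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Pipeline result and orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: sd.StudyTruth
    libraries: dict[str, sd.ReadLibrary]
    kept: dict[str, sd.ReadLibrary]
    removed_contaminant: dict[str, sd.ReadLibrary]
    removed_short: dict[str, sd.ReadLibrary]
    qc_reports: dict[str, qc.FilterReport]
    mappings: dict[str, ce.MappingResult]
    coverage: dict[str, dict[str, ce.CoverageProfile]]
    library_megabases: dict[str, float]
    omap: ortho.OrthologyMap
    levels_a: pd.DataFrame
    levels_b: pd.DataFrame
    fold_changes: dict[str, object]
    discordance: pd.DataFrame
    family_calls: dict[str, ortho.FamilyCall]
    categories: dict[str, str]
    category_table: pd.DataFrame
    tracks_b: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute the full study on simulated data; optionally write artifacts.

    Stages: simulate the two-species truth and both read libraries; QC each
    library (length cutoff, contaminant screen); annotate the focal
    transcriptome against the reference proteome by reciprocal best hits at
    the conservative threshold; map kept reads back to the focal references
    and compute per-base coverage; derive normalized expression levels and
    maternal classes in both species; call cross-species discordances; run
    the iterative family search for the planted loss/duplication families
    plus a sample of ordinary ones; tabulate category recovery.
    """
    logger.info("stage=simulate seed=%d n_genes=%d", config.seed, config.n_genes)
    lib_cfg = config.library_config()
    truth = sd.design_study(
        n_genes=config.n_genes,
        n_discordant=config.n_discordant,
        n_losses=config.n_losses,
        n_duplications=config.n_duplications,
        config=lib_cfg,
        log10_range=config.log10_range,
        dsn_alpha=config.dsn_alpha,
        maternal_fraction=config.maternal_fraction,
        seed=config.seed,
    )
    contaminants = sd.generate_contaminants(seed=config.seed)
    libraries = {
        lib: sd.simulate_reads(truth.transcripts_a, truth.profile, contaminants, lib_cfg, lib)
        for lib in ("maternal", "zygotic")
    }
    tracks_b = sd.simulate_coverage_track(
        truth.transcripts_b, truth.level_targets_b, config.library_megabases_b, config.seed
    )

    # --- QC ---------------------------------------------------------------
    contam_index = ortho.KmerIndex({k: v for k, v in contaminants.items()})
    kept, rm_contam, rm_short, reports = {}, {}, {}, {}
    for lib, reads in libraries.items():
        k, rc, rs, rep = qc.qc_library(
            reads, contaminants,
            min_identity=config.min_identity,
            min_read_length=config.min_read_length,
            min_hit_length=config.min_hit_length,
            index=contam_index,
        )
        kept[lib], rm_contam[lib], rm_short[lib], reports[lib] = k, rc, rs, rep
        logger.info(
            "stage=qc library=%s in=%d contaminant=%d short=%d kept=%d",
            lib, rep.n_input, rep.n_removed_contaminant, rep.n_removed_short, rep.n_kept,
        )

    # --- annotation -------------------------------------------------------
    seqs_a = {g: t.sequence for g, t in truth.transcripts_a.items()}
    prots_b = {g: t.protein for g, t in truth.transcripts_b.items()}
    scheme = ortho.ScoringScheme.translated()
    omap = ortho.reciprocal_best_hits(seqs_a, prots_b, scheme, config.e_confident)
    logger.info("stage=annotate pairs=%d threshold=%g", len(omap.pairs), config.e_confident)

    # --- coverage ---------------------------------------------------------
    ref_index = ortho.KmerIndex(seqs_a)
    mappings, coverage, lib_mb = {}, {}, {}
    for lib in libraries:
        m = ce.map_reads(
            kept[lib], truth.transcripts_a,
            min_identity=config.min_identity,
            min_hit_length=config.min_hit_length,
            index=ref_index,
        )
        mappings[lib] = m
        by_gene: dict[str, list[ce.ReadAssignment]] = {g: [] for g in seqs_a}
        for a in m.assignments:
            by_gene[a.gene_id].append(a)
        coverage[lib] = {
            g: ce.per_base_coverage(by_gene[g], len(seqs_a[g]), g, lib) for g in seqs_a
        }
        lib_mb[lib] = kept[lib].total_bases / 1e6
        logger.info(
            "stage=coverage library=%s assigned=%d ambiguous=%d unassigned=%d mb=%.2f",
            lib, len(m.assignments), m.n_ambiguous, m.n_unassigned, lib_mb[lib],
        )

    # --- expression -------------------------------------------------------
    levels_a_map = {
        g: ce.normalized_level(coverage["maternal"][g], len(seqs_a[g]), lib_mb["maternal"])
        for g in seqs_a
    }
    classes_a = ce.classify_maternal(levels_a_map, config.level_threshold)
    fold = {
        g: ce.fold_change_mz(coverage["maternal"][g], coverage["zygotic"][g]) for g in seqs_a
    }
    levels_a = ce.expression_table(levels_a_map, classes_a, fold)

    levels_b_map = {
        g: ce.levels_from_track(tracks_b[g], truth.transcripts_b[g], config.library_megabases_b)
        for g in truth.transcripts_b
    }
    classes_b = ce.classify_maternal(levels_b_map, config.level_threshold)
    levels_b = ce.expression_table(levels_b_map, classes_b)

    discordance = ce.compare_species(omap, levels_a, levels_b)
    logger.info(
        "stage=compare pairs=%d discordant=%d",
        len(discordance), int((discordance["discordance"] != ce.CONCORDANT).sum()),
    )

    # --- family search ----------------------------------------------------
    fams = truth.orthology.families
    of_interest = sorted(truth.orthology.losses.get("A", set()))
    of_interest += sorted(truth.orthology.duplications)
    rng = np.random.Generator(np.random.PCG64([config.seed, 271]))
    ordinary = [f for f in sorted(fams) if f not in of_interest]
    if ordinary and config.n_family_sample:
        pick = rng.choice(len(ordinary), size=min(config.n_family_sample, len(ordinary)),
                          replace=False)
        of_interest += [ordinary[int(i)] for i in sorted(pick)]
    family_calls = {}
    for fam in of_interest:
        seeds = {g: prots_b[g] for g in fams[fam]["B"]}
        family_calls[fam] = ortho.iterative_family_search(
            fam, seeds, seqs_a, scheme, list(config.e_schedule), prots_b
        )
    logger.info("stage=families n=%d", len(family_calls))

    # --- report -----------------------------------------------------------
    cat_rng = np.random.Generator(np.random.PCG64([config.seed, 631]))
    cats = sorted(DEFAULT_CATEGORIES)
    categories = {
        g: cats[int(cat_rng.integers(len(cats)))] for g in sorted(truth.transcripts_b)
    }
    category_table = category_recovery(omap, categories)

    result = PipelineResult(
        config=config, truth=truth, libraries=libraries, kept=kept,
        removed_contaminant=rm_contam, removed_short=rm_short, qc_reports=reports,
        mappings=mappings, coverage=coverage, library_megabases=lib_mb, omap=omap,
        levels_a=levels_a, levels_b=levels_b, fold_changes=fold,
        discordance=discordance, family_calls=family_calls, categories=categories,
        category_table=category_table, tracks_b=tracks_b,
    )
    result.provenance = _provenance(result)
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def _provenance(result: PipelineResult) -> dict:
    cfg = dataclasses.asdict(result.config)
    cfg["e_schedule"] = list(cfg["e_schedule"])
    return {
        "package": "matzyg",
        "version": __version__,
        "config": cfg,
        "counts": {
            "genes_a": len(result.truth.transcripts_a),
            "genes_b": len(result.truth.transcripts_b),
            "rbh_pairs": len(result.omap.pairs),
            **{
                f"{lib}_{k}": v
                for lib, rep in result.qc_reports.items()
                for k, v in (
                    ("input", rep.n_input),
                    ("kept", rep.n_kept),
                    ("removed_contaminant", rep.n_removed_contaminant),
                    ("removed_short", rep.n_removed_short),
                )
            },
        },
    }


def write_artifacts(result: PipelineResult, outdir) -> dict[str, str]:
    """Write every stage's output; returns {relative path: sha256 digest}."""
    os.makedirs(outdir, exist_ok=True)
    t = result.truth
    p = lambda name: os.path.join(outdir, name)
    sd.write_fasta(t.transcripts_a, p("transcripts_a.fasta"))
    sd.write_fasta(t.transcripts_b, p("transcripts_b.fasta"))
    sd.write_fasta({g: s.protein for g, s in t.transcripts_b.items()}, p("proteins_b.fasta"))
    sd.write_gff3(t.transcripts_a, p("annotation_a.gff3"))
    sd.write_gff3(t.transcripts_b, p("annotation_b.gff3"))
    for lib, reads in result.libraries.items():
        sd.write_reads_fasta(reads, p(f"reads_{lib}.fasta"), p(f"reads_{lib}.truth.tsv"))
        sd.write_reads_fasta(result.kept[lib], p(f"kept_{lib}.fasta"))
        result.qc_reports[lib].to_frame().to_csv(p(f"qc_report_{lib}.tsv"), sep="\t", index=False)
        cov = pd.DataFrame(
            {
                "gene_id": list(result.coverage[lib]),
                "mean_coverage": [c.mean for c in result.coverage[lib].values()],
                "total_aligned_bases": [
                    c.total_aligned_bases for c in result.coverage[lib].values()
                ],
            }
        )
        cov.to_csv(p(f"coverage_{lib}.tsv"), sep="\t", index=False)
        sd.write_wiggle(
            {g: c.per_base for g, c in result.coverage[lib].items()}, p(f"coverage_{lib}.wig")
        )
        qc.length_histogram(result.kept[lib]).to_csv(
            p(f"length_histogram_{lib}.tsv"), sep="\t", index=False
        )
    sd.write_wiggle(result.tracks_b, p("coverage_b.wig"))
    result.omap.to_frame().to_csv(p("orthology_pairs.tsv"), sep="\t", index=False)
    result.levels_a.to_csv(p("expression_a.tsv"), sep="\t", index=False)
    result.levels_b.to_csv(p("expression_b.tsv"), sep="\t", index=False)
    result.discordance.to_csv(p("discordance.tsv"), sep="\t", index=False)
    scatter = result.discordance[
        ["gene_a", "gene_b", "log2_level_a", "log2_level_b", "discordance"]
    ]
    scatter.to_csv(p("scatter_log2_levels.tsv"), sep="\t", index=False)
    fam = pd.DataFrame(
        [
            {
                "family_id": f, "status": c.status,
                "members": ",".join(sorted(c.members)), "stop_evalue": c.stop_evalue,
            }
            for f, c in sorted(result.family_calls.items())
        ]
    )
    fam.to_csv(p("family_calls.tsv"), sep="\t", index=False)
    result.category_table.to_csv(p("category_recovery.tsv"), sep="\t", index=False)
    result.config.to_yaml(p("config.yaml"))

    digests = {}
    for name in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, name)
        if os.path.isfile(path) and name != "provenance.json":
            with open(path, "rb") as fh:
                digests[name] = hashlib.sha256(fh.read()).hexdigest()
    result.provenance["artifact_digests"] = digests
    with open(p("provenance.json"), "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
    return digests


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------


def evaluate_run(result: PipelineResult) -> dict:
    """Score every recovered quantity against the planted ground truth."""
    t = result.truth
    cfg = result.config
    metrics: dict[str, float] = {}

    # contaminant screen, over reads long enough to be screened
    tp = fp = fn = tn = 0
    for lib in result.libraries:
        removed_ids = {r.read_id for r in result.removed_contaminant[lib].reads}
        for r in result.libraries[lib].reads:
            if len(r.sequence) < cfg.min_read_length:
                continue
            removed = r.read_id in removed_ids
            if r.is_contaminant:
                tp += removed
                fn += not removed
            else:
                fp += removed
                tn += not removed
    metrics["contaminant_sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    metrics["contaminant_specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    metrics["n_reads_screened"] = tp + fp + fn + tn

    # read mapping accuracy over kept non-contaminant reads
    correct = total = 0
    for lib in result.libraries:
        truth_gene = {r.read_id: r.truth_gene for r in result.kept[lib].reads
                      if not r.is_contaminant}
        assigned = {a.read_id: a.gene_id for a in result.mappings[lib].assignments}
        total += len(truth_gene)
        correct += sum(assigned.get(rid) == g for rid, g in truth_gene.items())
    metrics["mapping_accuracy"] = correct / total if total else float("nan")
    metrics["n_reads_mapped"] = total

    # orthology recovery
    truth_pairs = set(t.orthology.pairs)
    found_pairs = result.omap.pair_set
    metrics["rbh_recall"] = len(truth_pairs & found_pairs) / len(truth_pairs)
    metrics["rbh_precision"] = (
        len(truth_pairs & found_pairs) / len(found_pairs) if found_pairs else float("nan")
    )

    # maternal classification
    measured_a = dict(zip(result.levels_a["gene_id"], result.levels_a["class"]))
    ok_a = sum(measured_a[g] == t.classes_a[g] for g in t.classes_a)
    metrics["class_accuracy_a"] = ok_a / len(t.classes_a)
    measured_b = dict(zip(result.levels_b["gene_id"], result.levels_b["class"]))
    in_cmp = {b for _, b in t.orthology.pairs}
    ok_b = sum(measured_b[g] == t.classes_b[g] for g in in_cmp)
    metrics["class_accuracy_b"] = ok_b / len(in_cmp)

    # discordance calls
    planted = {(a, b): d for (a, b), d in t.discordances.items()}
    measured = {
        (r.gene_a, r.gene_b): r.discordance
        for r in result.discordance.itertuples()
        if r.discordance != ce.CONCORDANT
    }
    metrics["discordances_planted"] = len(planted)
    metrics["discordances_recovered"] = sum(
        measured.get(pair) == d for pair, d in planted.items()
    )
    metrics["false_discordances"] = len([p for p in measured if p not in planted])

    # family calls
    fam_ok = sum(
        call.status == t.family_truth[f] for f, call in result.family_calls.items()
    )
    metrics["family_calls_total"] = len(result.family_calls)
    metrics["family_calls_correct"] = fam_ok

    # coverage conservation and region contrast
    exact = 0
    n_prof = 0
    orf_gt_utr = 0
    n_regions = 0
    for lib in result.coverage:
        by_gene: dict[str, int] = {}
        for a in result.mappings[lib].assignments:
            by_gene[a.gene_id] = by_gene.get(a.gene_id, 0) + (
                a.aligned_interval[1] - a.aligned_interval[0]
            )
        for g, prof in result.coverage[lib].items():
            n_prof += 1
            exact += prof.total_aligned_bases == by_gene.get(g, 0)
            if prof.mean > 0:
                s = ce.region_summary(prof, t.transcripts_a[g])
                if np.isfinite(s["mean_orf"]) and np.isfinite(s["mean_utr5"]):
                    n_regions += 1
                    orf_gt_utr += s["mean_orf"] > max(s["mean_utr5"], s["mean_utr3"])
    metrics["coverage_conservation_fraction"] = exact / n_prof if n_prof else float("nan")
    metrics["orf_exceeds_utr_fraction"] = orf_gt_utr / n_regions if n_regions else float("nan")

    # normalization model observables
    metrics["dsn_log10_range_maternal"] = t.profile.log10_range("maternal")
    metrics["raw_log10_range_maternal"] = t.profile_raw.log10_range("maternal")
    return metrics
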