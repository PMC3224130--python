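"""Aligner optimality vs naive DP, E-value arithmetic, RBH properties,
family-search behaviour and gap-column pruning."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from matzyg import (
    ScoringScheme,
    best_hits,
    evalue,
    generate_transcript_pair_set,
    iterative_family_search,
    prune_gap_columns,
    reciprocal_best_hits,
    smith_waterman,
    translated_search,
)
from matzyg.orthology import revcomp
from matzyg.synthetic_data import mutate_transcript, translate

from _oracles import (
    blosum62_score_fn,
    naive_local_affine,
    naive_translated_best,
    nt_score_fn,
    oracle_translate,
)


class TestSmithWaterman:
    def test_self_alignment(self, unit_scheme):
        h = smith_waterman("ACGT", "ACGT", unit_scheme)
        assert h.score == 4.0
        assert h.identity == 1.0
        assert h.query_interval == (0, 4)

    def test_single_match(self, unit_scheme):
        assert smith_waterman("ACGT", "TTTT", unit_scheme).score == 1.0

    def test_gap_cost_convention(self, unit_scheme):
        # ACGTT vs ACG-T: deletion of length 1 costs open+extend = 3
        h = smith_waterman("ACGTACGT", "ACGTCGT", unit_scheme)
        # 8 matches minus one length-1 gap: 8 - 3 = 5... local alignment may
        # instead take the best exact block; the naive oracle is authoritative
        oracle = naive_local_affine("ACGTACGT", "ACGTCGT", nt_score_fn(1, -1), 2, 1)
        assert h.score == oracle

    def test_empty_sequence_rejected(self, unit_scheme):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT", unit_scheme)

    def test_alphabet_mismatch_rejected(self, unit_scheme):
        with pytest.raises(ValueError):
            smith_waterman("MKWVLLLQR", "ACGT", unit_scheme)

    def test_matches_naive_dp_on_random_pairs(self, nt_scheme, rng):
        fn = nt_score_fn(nt_scheme.match, nt_scheme.mismatch)
        for _ in range(40):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 60))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 60))))
            got = smith_waterman(a, b, nt_scheme).score
            want = naive_local_affine(a, b, fn, nt_scheme.gap_open, nt_scheme.gap_extend)
            assert got == want


class TestTranslatedSearch:
    def test_exact_cds_identity_one_frame_plus_one(self, aa_scheme, small_pair_set):
        a, _, _ = small_pair_set
        spec = a["A0000"]
        h = translated_search(spec.orf_seq[:-3], spec.protein, aa_scheme)
        assert h.frame == 1
        assert h.identity == 1.0

    def test_reverse_complement_same_score_frame_minus_one(self, aa_scheme, small_pair_set):
        a, _, _ = small_pair_set
        spec = a["A0000"]
        cds = spec.orf_seq[:-3]
        fwd = translated_search(cds, spec.protein, aa_scheme)
        rev = translated_search(revcomp(cds), spec.protein, aa_scheme)
        assert rev.score == fwd.score
        assert rev.frame == -1
        assert rev.strand == "-"

    def test_synonymous_change_score_unchanged(self, aa_scheme, small_pair_set):
        a, _, _ = small_pair_set
        spec = a["A0001"]
        cds = spec.orf_seq[:-3]
        # CTT -> CTG both encode Leu; find a Leu codon to swap
        idx = next(i for i in range(0, len(cds), 3) if translate(cds[i : i + 3]) == "L")
        mutated = cds[:idx] + {"CTT": "CTG", "CTC": "CTG", "CTA": "CTG", "CTG": "CTA",
                               "TTA": "TTG", "TTG": "TTA"}[cds[idx : idx + 3]] + cds[idx + 3 :]
        base = translated_search(cds, spec.protein, aa_scheme)
        mut = translated_search(mutated, spec.protein, aa_scheme)
        assert mut.score == base.score
        assert mut.identity == 1.0

    def test_stops_never_align(self, aa_scheme):
        # query translating to a peptide interrupted by a stop: the local hit
        # must sit entirely on one side of it
        pep = "MKWVLLLQRMD"
        codon = {"M": "ATG", "K": "AAA", "W": "TGG", "V": "GTT", "L": "CTT",
                 "Q": "CAA", "R": "CGT", "D": "GAT"}
        cds = "".join(codon[c] for c in pep[:5]) + "TAA" + "".join(codon[c] for c in pep[5:])
        h = translated_search(cds, pep, aa_scheme)
        assert h.identity > 0
        assert h.score < smith_waterman(pep, pep, aa_scheme).score

    def test_too_short_query_rejected(self, aa_scheme):
        with pytest.raises(ValueError):
            translated_search("AC", "MKWV", aa_scheme)

    def test_matches_six_frame_oracle(self, aa_scheme, rng):
        fn = blosum62_score_fn()
        for _ in range(20):
            nt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 60))))
            pep = oracle_translate(
                "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 60))))
            ).replace("*", "S")
            got = translated_search(nt, pep, aa_scheme).score
            want = naive_translated_best(nt, pep, fn, aa_scheme.gap_open, aa_scheme.gap_extend)
            assert got == want


class TestEvalue:
    def test_closed_form_unity(self, aa_scheme):
        m, n = 300, 10**5
        s = math.log(aa_scheme.karlin_k * m * n) / aa_scheme.karlin_lambda
        assert evalue(s, m, n, aa_scheme) == pytest.approx(1.0, rel=1e-12)

    def test_linear_in_database_size(self, aa_scheme):
        e1 = evalue(80.0, 300, 10**5, aa_scheme)
        e2 = evalue(80.0, 300, 2 * 10**5, aa_scheme)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_direct_arithmetic(self):
        scheme = ScoringScheme.translated(karlin_k=0.041, karlin_lambda=0.267)
        got = evalue(100.0, 300, 10**5, scheme)
        want = 0.041 * 300 * 1e5 * math.exp(-0.267 * 100.0)
        assert got == pytest.approx(want, rel=1e-12)

    @given(s1=st.floats(0, 200), s2=st.floats(0, 200))
    def test_strictly_decreasing_in_score(self, aa_scheme, s1, s2):
        lo, hi = sorted((s1, s2))
        if hi - lo > 1e-6:
            assert evalue(hi, 100, 100, aa_scheme) < evalue(lo, 100, 100, aa_scheme)

    def test_invalid_search_space(self, aa_scheme):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, aa_scheme)


@pytest.fixture(scope="module")
def protein_pairs():
    """Proteins of a 12-family synthetic pair set (one dup, one loss)."""
    a, b, truth = generate_transcript_pair_set(12, seed=11, n_duplications=1, n_losses=1)
    prots_a = {g: s.protein for g, s in a.items()}
    prots_b = {g: s.protein for g, s in b.items()}
    return a, b, truth, prots_a, prots_b


class TestBestHits:
    def test_identical_singletons(self, aa_scheme, protein_pairs):
        *_, prots_a, _ = protein_pairs
        g = sorted(prots_a)[0]
        table = best_hits({g: prots_a[g]}, {g: prots_a[g]}, aa_scheme, 10.0)
        assert list(table["target"]) == [g]
        assert table["evalue"].iloc[0] < 1e-50

    def test_weak_hit_omitted_at_conservative_threshold(self, aa_scheme, rng):
        q = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=40))
        t = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=40))
        lax = best_hits({"q": q}, {"t": t}, aa_scheme, 10.0, prefilter=False)
        strict = best_hits({"q": q}, {"t": t}, aa_scheme, 1e-10, prefilter=False)
        assert len(strict) == 0
        if len(lax):  # random proteins usually score somewhere under E=10
            assert lax["evalue"].iloc[0] > 1e-10

    def test_empty_target_set_rejected(self, aa_scheme):
        with pytest.raises(ValueError):
            best_hits({"q": "MKWV"}, {}, aa_scheme)

    def test_equals_exhaustive_scan(self, aa_scheme, protein_pairs, rng):
        *_, prots_a, prots_b = protein_pairs
        queries = {g: prots_a[g] for g in sorted(prots_a)[:8]}
        got = best_hits(queries, prots_b, aa_scheme, 10.0, prefilter=False)
        score_cache = {}

        def score_of(q, t):
            if (q, t) not in score_cache:
                h = smith_waterman(queries[q], prots_b[t], aa_scheme)
                score_cache[(q, t)] = (h.score, h.aligned_cols)
            return score_cache[(q, t)]

        from _oracles import naive_best_hit_table

        want = naive_best_hit_table(sorted(queries), sorted(prots_b), score_of)
        assert dict(zip(got["query"], got["target"])) == {
            q: t for q, t in want.items()
        }


class TestReciprocalBestHits:
    def test_identical_singleton_sets(self, aa_scheme):
        pep = "MKWVLLLQRMDAAGHKLV"
        omap = reciprocal_best_hits({"a": pep}, {"b": pep}, aa_scheme, 10.0)
        assert omap.pair_set == {("a", "b")}

    def test_planted_duplication_leaves_diverged_copy_unpaired(self, aa_scheme, protein_pairs):
        a, b, truth, prots_a, prots_b = protein_pairs
        omap = reciprocal_best_hits(prots_a, prots_b, aa_scheme, 10.0)
        for fam, members in truth.duplications.items():
            main = [m for m in members if not m.endswith("d")][0]
            dup = [m for m in members if m.endswith("d")][0]
            assert main in {p[0] for p in omap.pair_set}
            assert dup in omap.unpaired_a

    def test_recovers_planted_truth_at_conservative_threshold(self, aa_scheme, protein_pairs):
        _, _, truth, prots_a, prots_b = protein_pairs
        omap = reciprocal_best_hits(prots_a, prots_b, aa_scheme, 1e-10)
        assert omap.pair_set == set(truth.pairs)

    def test_symmetry_under_species_swap(self, aa_scheme, protein_pairs):
        *_, prots_a, prots_b = protein_pairs
        ab = reciprocal_best_hits(prots_a, prots_b, aa_scheme, 1e-10)
        ba = reciprocal_best_hits(prots_b, prots_a, aa_scheme, 1e-10)
        assert {(b_, a_) for a_, b_ in ab.pair_set} == ba.pair_set

    def test_threshold_monotonicity(self, aa_scheme, protein_pairs):
        *_, prots_a, prots_b = protein_pairs
        strict = reciprocal_best_hits(prots_a, prots_b, aa_scheme, 1e-10).pair_set
        lax = reciprocal_best_hits(prots_a, prots_b, aa_scheme, 10.0).pair_set
        assert strict <= lax

    def test_self_annotation_completeness(self, aa_scheme, protein_pairs):
        *_, prots_a, _ = protein_pairs
        subset = {g: prots_a[g] for g in sorted(prots_a)[:6]}
        omap = reciprocal_best_hits(subset, subset, aa_scheme, 10.0)
        assert omap.pair_set == {(g, g) for g in subset}


class TestFamilySearch:
    def test_absent_family_not_detected(self, aa_scheme, protein_pairs):
        a, b, truth, prots_a, prots_b = protein_pairs
        lost = sorted(truth.losses["A"])[0]
        seeds = {g: prots_b[g] for g in truth.families[lost]["B"]}
        pool = {g: s.sequence for g, s in a.items()}
        call = iterative_family_search(lost, seeds, pool, aa_scheme,
                                       [1e-3, 1e-1, 10.0], prots_b)
        assert call.status == "not_detected"
        assert call.members == set()
        assert call.stop_evalue == 10.0

    def test_duplicated_family(self, aa_scheme, protein_pairs):
        a, b, truth, prots_a, prots_b = protein_pairs
        fam = sorted(truth.duplications)[0]
        seeds = {g: prots_b[g] for g in truth.families[fam]["B"]}
        pool = {g: s.sequence for g, s in a.items()}
        call = iterative_family_search(fam, seeds, pool, aa_scheme,
                                       [1e-3, 1e-1, 10.0], prots_b)
        assert call.status == "duplicated"
        assert call.members == set(truth.families[fam]["A"])

    def test_distant_member_found_only_at_relaxed_cutoff(self, aa_scheme):
        # plant a short, diverged family member whose seed E-value sits
        # between the first and second cutoffs; it must enter at the second
        # and stop_evalue must record that cutoff
        a, b, truth = generate_transcript_pair_set(
            6, seed=31, length_params={"orf_codons_range": (60, 80)}
        )
        prots_b = {g: s.protein for g, s in b.items()}
        fam = "fam0000"
        seed_gene = truth.families[fam]["B"][0]
        member_gene = truth.families[fam]["A"][0]
        spec = a[member_gene]
        rng = np.random.Generator(np.random.PCG64(77))
        diverged = mutate_transcript(spec, 0.42, rng, gene_id="far")
        pool = {"far": diverged.sequence}
        seeds = {seed_gene: prots_b[seed_gene]}
        table = best_hits(pool, seeds, aa_scheme, 1e10, prefilter=False)
        e = table["evalue"].iloc[0]
        schedule = [e / 100.0, e * 10.0, e * 1e4]
        call = iterative_family_search(fam, seeds, pool, aa_scheme, schedule, prots_b)
        assert call.status == "present"
        assert call.members == {"far"}
        assert call.stop_evalue == schedule[1]

    def test_schedule_validation(self, aa_scheme, protein_pairs):
        *_, prots_b = protein_pairs
        with pytest.raises(ValueError):
            iterative_family_search("f", {"s": "MKWV"}, {"p": "ATGAAA"},
                                    aa_scheme, [], prots_b)
        with pytest.raises(ValueError):
            iterative_family_search("f", {"s": "MKWV"}, {"p": "ATGAAA"},
                                    aa_scheme, [1e-1, 1e-3], prots_b)


class TestGapColumnPruning:
    def test_strict_majority_rule(self):
        block = [
            "A-CA-",
            "A-CA-",
            "AAC--",
            "A-C-A",
            "AACAA",
        ]
        # col1: 3/5 gaps -> removed; col3: 2/5 gaps -> kept; col4: 3/5 -> removed
        pruned = prune_gap_columns(block)
        assert pruned == ["ACA", "ACA", "AC-", "AC-", "ACA"]

    def test_gap_free_block_unchanged(self):
        block = ["MKWV", "MKWV", "MQWV"]
        assert prune_gap_columns(block) == block

    def test_exact_half_gaps_kept(self):
        block = ["A-", "A-", "AA", "AA"]
        assert prune_gap_columns(block) == block

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            prune_gap_columns(["AC", "ACG"])

    @given(st.lists(st.integers(0, 1), min_size=4, max_size=40))
    def test_idempotence(self, bits):
        rng = np.random.Generator(np.random.PCG64(sum(bits) + len(bits)))
        rows = [
            "".join("-" if rng.random() < 0.4 else "A" for _ in range(len(bits)))
            for _ in range(5)
        ]
        once = prune_gap_columns(rows)
        assert prune_gap_columns(once) == once

    def test_biopython_alignment_roundtrip(self):
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=f"r{i}") for i, s in enumerate(["A--A", "AA-A", "AAAA"])]
        )
        pruned = prune_gap_columns(msa)
        assert [str(r.seq) for r in pruned] == ["A-A", "AAA", "AAA"]
        assert [r.id for r in pruned] == ["r0", "r1", "r2"]
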