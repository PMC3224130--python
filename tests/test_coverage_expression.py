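"""Mapping thresholds, coverage conservation, normalization arithmetic,
classification boundaries and cross-species comparison."""

import numpy as np
import pandas as pd
import pytest

from matzyg import (
    CoverageProfile,
    LibraryConfig,
    ReadAssignment,
    classify_maternal,
    compare_species,
    exon_max_level,
    expression_table,
    fold_change_mz,
    generate_transcript_pair_set,
    levels_from_track,
    map_reads,
    normalized_level,
    per_base_coverage,
    region_summary,
    simulate_abundances,
    simulate_reads,
)
from matzyg.coverage_expression import UNDETECTED, ZYGOTIC_ONLY
from matzyg.orthology import OrthologyMap
from matzyg.synthetic_data import TranscriptSpec


@pytest.fixture(scope="module")
def refs():
    a, _, _ = generate_transcript_pair_set(10, seed=17)
    return a


class TestMapReads:
    def test_exact_60nt_read_assigned(self, refs):
        g = sorted(refs)[0]
        read = refs[g].sequence[100:160]
        res = map_reads([("r1", read)], refs)
        assert len(res.assignments) == 1
        a = res.assignments[0]
        assert a.gene_id == g
        assert a.identity == 1.0
        assert a.aligned_interval == (100, 160)

    def test_49nt_perfect_read_unassigned(self, refs):
        g = sorted(refs)[0]
        read = refs[g].sequence[100:149]
        res = map_reads([("r1", read)], refs, min_hit_length=50)
        assert len(res.assignments) == 0
        assert res.n_unassigned == 1
        # the same read passes once the length bar drops to its size
        res2 = map_reads([("r1", read)], refs, min_hit_length=49)
        assert len(res2.assignments) == 1

    def test_low_identity_read_unassigned(self, refs, rng):
        read = "".join(rng.choice(list("ACGT"), size=80))
        res = map_reads([("r1", read)], refs)
        assert len(res.assignments) == 0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            map_reads([("r", "ACGT" * 20)], {})

    def test_simulated_library_maps_to_truth(self, refs):
        prof = simulate_abundances(sorted(refs), log10_range=1.5,
                                   absent_fraction=0.0, seed=17)
        cfg = LibraryConfig(n_reads=5000, contaminant_fraction=0.0, seed=17)
        lib = simulate_reads(refs, prof, None, cfg)
        eligible = [r for r in lib.reads if len(r.sequence) >= 50]
        res = map_reads(eligible, refs)
        assigned = {a.read_id: a.gene_id for a in res.assignments}
        truth = {r.read_id: r.truth_gene for r in eligible}
        correct = sum(assigned.get(rid) == g for rid, g in truth.items())
        assert correct / len(truth) >= 0.99


class TestPerBaseCoverage:
    def test_single_read_interval(self):
        prof = per_base_coverage([ReadAssignment("r", "g", 1.0, (10, 60), 50)], 100, "g")
        assert prof.per_base[9] == 0
        assert prof.per_base[10] == 1
        assert prof.per_base[59] == 1
        assert prof.per_base[60] == 0
        assert prof.total_aligned_bases == 50

    def test_conservation(self, rng):
        asg = []
        L = 500
        for i in range(10_000):
            s = int(rng.integers(0, L - 60))
            e = s + int(rng.integers(20, 60))
            asg.append(ReadAssignment(f"r{i}", "g", 1.0, (s, e), e - s))
        prof = per_base_coverage(asg, L, "g")
        assert prof.total_aligned_bases == sum(a.aligned_length for a in asg)

    def test_matches_naive_recount(self, rng):
        L = 300
        asg = [
            ReadAssignment(f"r{i}", "g", 1.0, (int(s), int(s) + 40), 40)
            for i, s in enumerate(rng.integers(0, L - 40, size=2000))
        ]
        prof = per_base_coverage(asg, L, "g")
        naive = np.zeros(L, dtype=int)
        for a in asg:
            for p in range(*a.aligned_interval):
                naive[p] += 1
        assert np.array_equal(prof.per_base, naive)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            per_base_coverage([ReadAssignment("r", "g", 1.0, (10, 200), 190)], 100)


class TestRegionSummary:
    def test_uniform_coverage(self, refs):
        g = sorted(refs)[0]
        spec = refs[g]
        prof = CoverageProfile(g, "m", np.full(spec.length, 5))
        s = region_summary(prof, spec)
        assert s["mean_orf"] == s["mean_utr5"] == s["mean_utr3"] == 5.0

    def test_gc_direct_count(self):
        spec = TranscriptSpec("g", "A" * 10 + "ATGCGC" + "TAA" + "T" * 11,
                              orf=(10, 19), utr5=(0, 10), utr3=(19, 30))
        prof = CoverageProfile("g", "m", np.zeros(30))
        s = region_summary(prof, spec)
        assert s["gc_orf"] == pytest.approx((4 + 0) / 9)  # ATGCGC TAA: 4 GC of 9

    def test_empty_region_is_nan(self):
        spec = TranscriptSpec("g", "ATG" + "AAA" * 3 + "TAA" + "TTTT",
                              orf=(0, 15), utr5=(0, 0), utr3=(15, 19))
        prof = CoverageProfile("g", "m", np.ones(19))
        s = region_summary(prof, spec)
        assert np.isnan(s["mean_utr5"])
        assert s["mean_orf"] == 1.0

    def test_gc_bias_simulation_orf_exceeds_utr(self):
        a, _, _ = generate_transcript_pair_set(40, seed=23)
        prof_a = simulate_abundances(sorted(a), log10_range=1.0,
                                     absent_fraction=0.0, maternal_fraction=0.5, seed=23)
        cfg = LibraryConfig(n_reads=60_000, contaminant_fraction=0.0, seed=23)
        lib = simulate_reads(a, prof_a, None, cfg)
        res = map_reads([r for r in lib.reads if len(r.sequence) >= 50], a)
        by_gene = {g: [] for g in a}
        for asg in res.assignments:
            by_gene[asg.gene_id].append(asg)
        wins = total = 0
        for g, spec in a.items():
            prof = per_base_coverage(by_gene[g], spec.length, g)
            if prof.mean == 0:
                continue
            s = region_summary(prof, spec)
            total += 1
            wins += s["mean_orf"] > max(s["mean_utr5"], s["mean_utr3"])
        assert total >= 35
        assert wins / total >= 0.95


class TestFoldChange:
    def _prof(self, mean, L=100):
        return CoverageProfile("g", "x", np.full(L, mean))

    def test_plain_ratio(self):
        assert fold_change_mz(self._prof(2.0), self._prof(8.0)) == pytest.approx(4.0)

    def test_zygotic_only_sentinel(self):
        z = CoverageProfile("g", "z", np.array([3, 4, 3, 2]))
        m = CoverageProfile("g", "m", np.zeros(4))
        assert fold_change_mz(m, z) == ZYGOTIC_ONLY

    def test_undetected_sentinel(self):
        assert fold_change_mz(self._prof(0), self._prof(0)) == UNDETECTED

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fold_change_mz(CoverageProfile("g1", "m", np.ones(4)),
                           CoverageProfile("g2", "z", np.ones(4)))

    def test_planted_18fold_increase_recovered_at_depth(self, rng):
        # maternal 20x, zygotic 360x planted on a 1.5 kb gene; the sampled
        # estimate must land within +-50% of the planted 18-fold change
        L, read_len = 1500, 300
        def sample(depth):
            n = int(depth * L / read_len)
            return per_base_coverage(
                [
                    ReadAssignment(f"r{i}", "g", 1.0, (int(s), int(s) + read_len), read_len)
                    for i, s in enumerate(rng.integers(0, L - read_len, size=rng.poisson(n)))
                ],
                L, "g",
            )
        fc = fold_change_mz(sample(20), sample(20 * 18))
        assert 12 <= fc <= 27


class TestNormalizedLevel:
    def _prof(self, per_base):
        return CoverageProfile("g", "m", np.asarray(per_base))

    def test_library_duplication_invariance(self):
        prof1 = self._prof([2, 2, 4, 0])
        prof2 = self._prof([4, 4, 8, 0])
        assert normalized_level(prof1, 4, 10.0) == normalized_level(prof2, 4, 20.0)

    def test_direct_arithmetic(self):
        # mean coverage 7.4 against a 74 Mb library: level 0.1
        prof = self._prof(np.full(100, 7.4))
        assert normalized_level(prof, 100, 74.0) == pytest.approx(0.1)

    def test_no_reads_level_zero_class_absent(self):
        prof = self._prof(np.zeros(50))
        lvl = normalized_level(prof, 50, 74.0)
        assert lvl == 0.0
        assert classify_maternal({"g": lvl})["g"] == "absent"

    def test_halves_when_library_doubles(self):
        prof = self._prof(np.full(10, 6))
        assert normalized_level(prof, 10, 20.0) == normalized_level(prof, 10, 10.0) / 2

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            normalized_level(self._prof([1]), 0, 10.0)


class TestExonMaxLevel:
    def test_short_exon_excluded(self):
        assert exon_max_level([(300, 50.0), (600, 10.0)], [20.0]) == 20.0

    def test_single_long_exon(self):
        assert exon_max_level([(800, 7.0)], [7.0]) == 7.0

    def test_all_exons_short_variant_wins(self):
        assert exon_max_level([(400, 50.0), (200, 40.0)], [5.0]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exon_max_level([], [])


class TestClassification:
    def test_boundaries(self):
        classes = classify_maternal({"hi": 2.3, "edge": 1.0, "off": 0.0, "low": 0.4})
        assert classes == {
            "hi": "maternal", "edge": "not_maternal", "off": "absent", "low": "not_maternal"
        }

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_maternal({"g": -0.1})


def _levels_frame(d):
    return expression_table(d, classify_maternal(d))


class TestCompareSpecies:
    def _map(self, pairs):
        return OrthologyMap(pairs=[(a, b, 1e-20, 1e-20) for a, b in pairs], threshold=1e-10)

    def test_a_only_pattern(self):
        omap = self._map([("a1", "b1")])
        table = compare_species(omap, _levels_frame({"a1": 5.0}), _levels_frame({"b1": 0.2}))
        assert list(table["discordance"]) == ["A_only"]

    def test_concordant_maternal(self):
        omap = self._map([("a1", "b1")])
        table = compare_species(omap, _levels_frame({"a1": 3.0}), _levels_frame({"b1": 4.0}))
        assert list(table["discordance"]) == ["concordant"]

    def test_antisymmetry_under_swap(self):
        omap = self._map([("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
        la = _levels_frame({"a1": 5.0, "a2": 0.2, "a3": 2.0})
        lb = _levels_frame({"b1": 0.5, "b2": 7.0, "b3": 9.0})
        fwd = compare_species(omap, la, lb)
        swapped = OrthologyMap(
            pairs=[(b, a, 1e-20, 1e-20) for a, b, *_ in omap.pairs], threshold=1e-10
        )
        rev = compare_species(swapped, lb, la)
        flip = {"A_only": "B_only", "B_only": "A_only", "concordant": "concordant"}
        assert [flip[d] for d in fwd["discordance"]] == list(rev["discordance"])

    def test_missing_gene_rejected(self):
        omap = self._map([("a1", "b1")])
        with pytest.raises(KeyError):
            compare_species(omap, _levels_frame({"a1": 1.0}), _levels_frame({"zz": 1.0}))


class TestTrackIngestion:
    def test_uniform_track_level(self):
        a, b, _ = generate_transcript_pair_set(2, seed=3)
        spec = next(iter(b.values()))
        track = np.full(spec.length, 30.0)
        lvl = levels_from_track(track, spec, 10.0)
        assert lvl == pytest.approx(3.0)

    def test_strongest_long_exon_wins_over_diluted_variant(self):
        spec = TranscriptSpec(
            "g", "A" * 100 + "ATG" + "A" * 594 + "TAA" + "T" * 900,
            orf=(100, 700), utr5=(0, 100), utr3=(700, 1600),
            exons=[(0, 800), (800, 1600)], variants=[[0, 1]],
        )
        track = np.concatenate([np.full(800, 40.0), np.full(800, 2.0)])
        lvl = levels_from_track(track, spec, 1.0)
        # exon 0 (800 nt, mean 40) beats the full-variant mean of 21
        assert lvl == pytest.approx(40.0)

    def test_track_length_mismatch_rejected(self):
        a, b, _ = generate_transcript_pair_set(2, seed=3)
        spec = next(iter(b.values()))
        with pytest.raises(ValueError):
            levels_from_track(np.zeros(5), spec, 1.0)
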