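"""Candidate selection, perfect-match mapping, genotype calling, and
novel-variant detection."""

import numpy as np
import pytest

from multihla.allele_db import (
    AlleleDatabase,
    AlleleRecord,
    Feature,
    parse_allele_name,
    render_allele_set,
)
from multihla.evaluation import call_matches_truth
from multihla.fixtures import FAST_READ_PROFILE, make_barcodes, plant_substitution
from multihla.genotyping import (
    TypingParams,
    call_genotype,
    detect_novel_variant,
    perfect_match_map,
    select_candidates,
)
from multihla.insilico_pcr import SimConfig, reverse_complement, simulate_reads
from multihla.readqc import Read, ReadBatch, demultiplex, trim_batch


def _simulate_locus(db, primers, locus, alleles, reads=900, seed=5, **overrides):
    genotype = {locus: tuple(parse_allele_name(a) for a in alleles)}
    kwargs = dict(FAST_READ_PROFILE)
    kwargs.update(overrides)
    config = SimConfig(
        genotypes={"S01": genotype},
        barcodes={"S01": make_barcodes(1)[0]},
        reads_per_sample=reads,
        seed=seed,
        **kwargs,
    )
    run = simulate_reads(config, db, primers)
    reads_list = [Read(r.read_id, r.sequence, r.quality) for r in run.reads]
    batches, _ = demultiplex(reads_list, config.barcodes, 1)
    return trim_batch(batches["S01"], 10, 30)


class TestSelectCandidates:
    def test_simulated_allele_ranks_first(self, fast_ref):
        db, primers = fast_ref
        batch = _simulate_locus(db, primers, "A", ["A*24:02:01", "A*24:02:01"])
        cands = select_candidates(batch, db)
        assert cands["A"].alleles[0] == "A*24:02:01"

    def test_alleles_sharing_no_kmer_excluded(self, fast_ref):
        db, primers = fast_ref
        batch = _simulate_locus(db, primers, "A", ["A*01:01:01", "A*02:01:01"])
        cands = select_candidates(batch, db)
        # the unrelated loci see no reads at all, so no shared k-mers
        assert cands["DQB1"].alleles == ()

    def test_identical_scores_preserve_tie(self):
        rec1 = AlleleRecord(parse_allele_name("B*07:02"), "ACGTACGTACGTACGTACGTA", ())
        rec2 = AlleleRecord(parse_allele_name("B*07:05"), "ACGTACGTACGTACGTACGTA", ())
        db = AlleleDatabase([rec1, rec2])
        batch = ReadBatch("S", [Read("r", "ACGTACGTACGTACGT", "I" * 16)])
        cands = select_candidates(batch, db)
        assert cands["B"].scores[0] == cands["B"].scores[1]

    def test_small_k_rejected(self, fast_ref):
        db, _ = fast_ref
        with pytest.raises(ValueError):
            select_candidates(ReadBatch("S", []), db, k=4)


def _brute_force_map(batch, names, db):
    """Independent oracle: exhaustive substring comparison, both strands."""
    expected = {}
    for read in batch.reads:
        hits = set()
        for name in names:
            target = db.records[name].sequence
            for oriented, strand in ((read.seq, "+"), (reverse_complement(read.seq), "-")):
                start = target.find(oriented)
                while start != -1:
                    hits.add((name, start, strand))
                    start = target.find(oriented, start + 1)
        if hits:
            expected[read.id] = tuple(sorted(hits))
    return expected


class TestPerfectMatchMap:
    def test_exact_substring_maps(self, fast_ref):
        db, _ = fast_ref
        target = db["A*01:01:01"].sequence
        batch = ReadBatch("S", [Read("r", target[100:160], "I" * 60)])
        m = perfect_match_map(batch, ["A*01:01:01"], db)
        assert m.by_read["r"] == (("A*01:01:01", 100, "+"),)

    def test_single_mismatch_unmapped(self, fast_ref):
        db, _ = fast_ref
        frag = list(db["A*01:01:01"].sequence[100:160])
        frag[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[30]]
        batch = ReadBatch("S", [Read("r", "".join(frag), "I" * 60)])
        m = perfect_match_map(batch, ["A*01:01:01"], db)
        assert "r" not in m.by_read
        assert [r.id for r in m.unmapped] == ["r"]

    def test_reverse_complement_maps_on_minus_strand(self, fast_ref):
        db, _ = fast_ref
        target = db["A*01:01:01"].sequence
        batch = ReadBatch("S", [Read("r", reverse_complement(target[100:160]), "I" * 60)])
        m = perfect_match_map(batch, ["A*01:01:01"], db)
        assert m.by_read["r"] == (("A*01:01:01", 100, "-"),)

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Seed-index mapping equals exhaustive substring comparison on
        small randomized databases, mutated/reversed reads included."""
        rng = np.random.default_rng(77)
        loci = ["A", "B", "C", "DQB1"]
        for _ in range(150):
            n_alleles = int(rng.integers(2, 6))
            names = []
            records = []
            for i in range(n_alleles):
                name = f"{loci[i % 4]}*{i + 1:02d}:01"
                seq = "".join("ACGT"[b] for b in rng.integers(0, 4, int(rng.integers(80, 250))))
                records.append(AlleleRecord(parse_allele_name(name), seq, ()))
                names.append(name)
            db = AlleleDatabase(records)
            reads = []
            for j in range(8):
                src = records[int(rng.integers(n_alleles))].sequence
                ln = int(rng.integers(16, min(60, len(src))))
                start = int(rng.integers(0, len(src) - ln + 1))
                frag = list(src[start : start + ln])
                if rng.random() < 0.4:  # mutate
                    p = int(rng.integers(ln))
                    frag[p] = "ACGT"[int(rng.integers(4))]
                frag = "".join(frag)
                if rng.random() < 0.5:
                    frag = reverse_complement(frag)
                reads.append(Read(f"r{j}", frag, "I" * len(frag)))
            batch = ReadBatch("S", reads)
            m = perfect_match_map(batch, names, db)
            assert m.by_read == _brute_force_map(batch, names, db)


class TestCallGenotype:
    def test_heterozygote_recovered(self, fast_ref):
        db, primers = fast_ref
        truth = ("B*39:01:01", "B*51:01:01")
        batch = _simulate_locus(db, primers, "B", truth)
        m = perfect_match_map(batch, select_candidates(batch, db), db)
        call = call_genotype("S01", "B", m, db, TypingParams())
        assert call_matches_truth(call, tuple(parse_allele_name(a) for a in truth))

    def test_homozygote_called_as_equal_sets(self, fast_ref):
        db, primers = fast_ref
        batch = _simulate_locus(db, primers, "C", ["C*04:01:01", "C*04:01:01"])
        m = perfect_match_map(batch, select_candidates(batch, db), db)
        call = call_genotype("S01", "C", m, db, TypingParams())
        assert call.allele1 == call.allele2
        assert str(call.allele1[0]) == "C*04:01:01"
        assert call.metrics.ratio == 1.0

    def test_amplicon_identical_alleles_reported_slash_joined(self, fast_ref):
        db, primers = fast_ref
        batch = _simulate_locus(db, primers, "DPB1", ["DPB1*13:01", "DPB1*05:01:01"])
        m = perfect_match_map(batch, select_candidates(batch, db), db)
        call = call_genotype("S01", "DPB1", m, db, TypingParams())
        rendered = sorted(
            render_allele_set(s) for s in (call.allele1, call.allele2)
        )
        assert "DPB1*107:01/*13:01" in rendered
        assert "ambiguous" in call.flags

    def test_empty_mapping_is_no_call(self, fast_ref):
        db, _ = fast_ref
        m = perfect_match_map(ReadBatch("S", []), [], db)
        call = call_genotype("S01", "A", m, db, TypingParams())
        assert call.is_no_call
        assert call.flags == {"no_call"}

    def test_raising_min_depth_never_creates_a_call(self, fast_ref):
        db, primers = fast_ref
        batch = _simulate_locus(db, primers, "A", ["A*01:01:01", "A*11:01:01"], reads=300)
        m = perfect_match_map(batch, select_candidates(batch, db), db)
        was_called = True
        for min_depth in (5, 25, 50, 80, 200, 10**6):
            call = call_genotype("S01", "A", m, db, TypingParams(min_depth=min_depth))
            if not was_called:
                assert call.is_no_call  # monotone: no resurrection
            was_called = not call.is_no_call
        assert call.is_no_call  # astronomically high threshold


class TestNovelVariant:
    def test_planted_substitution_recovered(self, fast_ref):
        db, primers = fast_ref
        sim_db, pos, ref, alt = plant_substitution(db, "C*07:04:01", "exon", 4)
        batch = _simulate_locus(sim_db, primers, "C", ["C*07:04:01", "C*07:02:01"])
        m = perfect_match_map(batch, select_candidates(batch, db), db)
        call = call_genotype("S01", "C", m, db, TypingParams())
        variants = detect_novel_variant(call, m, db)
        assert any(v.position == pos and v.ref == ref and v.alt == alt for v in variants)
        assert "novel_variant_candidate" in call.flags

    def test_error_free_known_alleles_give_nothing(self, fast_ref):
        db, primers = fast_ref
        batch = _simulate_locus(
            db, primers, "C", ["C*07:04:01", "C*07:02:01"],
            substitution_rate=0.0, homopolymer_indel_rate=0.0,
        )
        m = perfect_match_map(batch, select_candidates(batch, db), db)
        call = call_genotype("S01", "C", m, db, TypingParams())
        assert detect_novel_variant(call, m, db) == []

    def test_scattered_sequencing_errors_stay_below_threshold(self, fast_ref):
        db, primers = fast_ref
        for seed in range(5):
            batch = _simulate_locus(
                db, primers, "C", ["C*07:04:01", "C*07:02:01"], seed=100 + seed
            )
            m = perfect_match_map(batch, select_candidates(batch, db), db)
            call = call_genotype("S01", "C", m, db, TypingParams())
            assert detect_novel_variant(call, m, db) == []
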