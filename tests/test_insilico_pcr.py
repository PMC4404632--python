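"""In-silico PCR, virtual gel, and the read simulator."""

import numpy as np
import pytest
from scipy import stats as sps

from multihla.allele_db import AlleleDatabase, AlleleRecord, Feature, parse_allele_name
from multihla.fixtures import (
    DEFAULT_LOCUS_WEIGHTS,
    FAST_READ_PROFILE,
    make_barcodes,
    panel_config,
    toy_amplicons,
)
from multihla.insilico_pcr import (
    Amplicon,
    Primer,
    SimConfig,
    find_primer_sites,
    predict_amplicons,
    read_length_pmf,
    reverse_complement,
    simulate_reads,
    virtual_gel,
)


class TestPrimerSites:
    def test_exact_match_position(self):
        p = Primer("f", "A", "forward", "ACCT")
        assert find_primer_sites(p, "TTACCTGG") == [(2, "+")]

    def test_iupac_degeneracy(self):
        p = Primer("f", "A", "forward", "AARCC")
        assert find_primer_sites(p, "TTAAGCCTT") == [(2, "+")]
        assert find_primer_sites(p, "TTAAACCTT") == [(2, "+")]

    def test_absent_primer_gives_empty_list(self):
        p = Primer("f", "A", "forward", "AAAAAA")
        assert find_primer_sites(p, "CGCGCGCG") == []

    def test_minus_strand_site(self):
        p = Primer("r", "A", "reverse", "ACCT")
        # revcomp(ACCT) == AGGT at position 4
        assert find_primer_sites(p, "TTTTAGGT") == [(4, "-")]


def _toy_template_db():
    fwd = "AACCGGTTAACCGGTTAA"
    rev_site = "TTGGCCAATTGGCCAATT"
    middle = "ACGCTAGCTAGGATCCAT" * 4
    seq = "TTTTTTTTTT" + fwd + middle + rev_site + "GGGGGGGGGG"
    rec = AlleleRecord(
        parse_allele_name("A*01"), seq, (Feature("exon", 2, 30, 50), Feature("exon", 3, 55, 70))
    )
    primers = [
        Primer("A-F", "A", "forward", fwd),
        Primer("A-R", "A", "reverse", reverse_complement(rev_site)),
    ]
    return AlleleDatabase([rec]), primers, seq


class TestPredictAmplicons:
    def test_coordinates_and_length(self):
        db, primers, seq = _toy_template_db()
        amps = predict_amplicons(primers, db)
        assert len(amps) == 1
        amp = amps[0]
        assert amp.start == 10
        assert amp.length == len(seq) - 20
        assert amp.locus == "A"

    def test_two_forward_primers_give_nothing(self):
        db, primers, _ = _toy_template_db()
        both_fwd = [primers[0], Primer("A-F2", "A", "forward", "ACGCTAGCTAGGATCCAT")]
        with pytest.raises(ValueError, match="forward and >=1 reverse"):
            predict_amplicons(both_fwd, db)

    def test_unproductive_group_warns(self):
        db, primers, _ = _toy_template_db()
        extra = [
            Primer("B-F", "B", "forward", "TTTTTTTTTTTTTTTTTT"),
            Primer("B-R", "B", "reverse", "CCCCCCCCCCCCCCCCCC"),
        ]
        with pytest.warns(UserWarning, match="'B'"):
            amps = predict_amplicons(primers + extra, db)
        assert len(amps) == 1

    def test_full_scale_product_sizes(self):
        """The synthetic reference reproduces the multiplex design's
        product sizes: 5.5/4.6/4.8 kb class I, 4.0-5.2 kb DRB1 with the
        DR4 family at 5.2 kb, 4.1/4.5/4.1 kb DRB3/4/5, 3.9-4.3 kb DQB1,
        7.2 kb DPB1."""
        sizes = {}
        for amp in toy_amplicons(1.0):
            sizes.setdefault(amp.locus, set()).add(amp.length)
        assert sizes["A"] == {5500}
        assert sizes["B"] == {4600}
        assert sizes["C"] == {4800}
        assert sizes["DRB1"] == {4000, 4100, 5200}
        assert sizes["DRB3"] == {4100}
        assert sizes["DRB4"] == {4500}
        assert sizes["DRB5"] == {4100}
        assert sizes["DQB1"] == {3900, 4300}
        assert sizes["DPB1"] == {7200}

    def test_dr4_product_larger_than_other_dr_subtypes(self):
        by_allele = {str(a.allele): a.length for a in toy_amplicons(1.0) if a.locus == "DRB1"}
        assert by_allele["DRB1*04:05:01"] == 5200
        assert by_allele["DRB1*03:01:01"] == 4000


def _amp(locus, size):
    return Amplicon(locus, parse_allele_name(f"{locus}*01"), 0, size)


class TestVirtualGel:
    def test_close_sizes_merge(self):
        bands = virtual_gel([_amp("B", 4600), _amp("C", 4800)], 300)
        assert len(bands) == 1
        assert bands[0].loci == {"B", "C"}

    def test_distant_sizes_separate(self):
        bands = virtual_gel([_amp("B", 4600), _amp("DPB1", 7200)], 300)
        assert [b.loci for b in bands] == [{"DPB1"}, {"B"}]
        assert bands[0].size > bands[1].size  # sorted descending

    def test_empty_input(self):
        assert virtual_gel([], 300) == []

    def test_class_i_gel_pattern(self):
        """On the full-scale reference, B and C co-migrate while A stays a
        separate band at 300 bp resolution."""
        class_i = [a for a in toy_amplicons(1.0) if a.locus in ("A", "B", "C")]
        bands = virtual_gel(class_i, 300)
        assert [b.loci for b in bands] == [{"A"}, {"B", "C"}]


class TestReadLengthModel:
    def test_full_scale_mean_and_mode(self):
        lengths, probs = read_length_pmf(273.3, 358.6, 25, 400)
        assert np.dot(lengths, probs) == pytest.approx(273.3, abs=0.5)
        assert lengths[np.argmax(probs)] == pytest.approx(358.6, abs=2)

    def test_fast_profile(self):
        lengths, probs = read_length_pmf(72.0, 88.0, 30, 110)
        assert np.dot(lengths, probs) == pytest.approx(72.0, abs=0.5)
        assert lengths[np.argmax(probs)] == pytest.approx(88.0, abs=2)


def _one_locus_config(db, reads=1000, seed=5, **overrides):
    gt = {
        "S01": {
            "A": (parse_allele_name("A*01:01:01"), parse_allele_name("A*02:01:01"))
        }
    }
    kwargs = dict(FAST_READ_PROFILE)
    kwargs.update(overrides)
    return SimConfig(
        genotypes=gt, barcodes={"S01": make_barcodes(1)[0]},
        reads_per_sample=reads, seed=seed, **kwargs,
    )


class TestSimulateReads:
    def test_truth_row_count_equals_reads_per_sample(self, fast_ref):
        db, primers = fast_ref
        run = simulate_reads(_one_locus_config(db), db, primers)
        assert len(run.truth) == 1000
        assert len(run.reads) == 1000

    def test_balanced_skew_splits_alleles_binomially(self, fast_ref):
        db, primers = fast_ref
        run = simulate_reads(_one_locus_config(db, reads=1000), db, primers)
        counts = run.truth["allele"].value_counts()
        # 5 sigma band around the binomial expectation of 500
        assert abs(counts["A*01:01:01"] - 500) < 5 * np.sqrt(1000 * 0.25)

    def test_error_free_reads_are_exact_substrings(self, fast_ref):
        db, primers = fast_ref
        config = _one_locus_config(
            db, reads=300, substitution_rate=0.0, homopolymer_indel_rate=0.0
        )
        run = simulate_reads(config, db, primers)
        barcode = config.barcodes["S01"]
        for read, (_, row) in zip(run.reads, run.truth.iterrows()):
            frag = read.sequence[len(barcode):]
            source = db[row["allele"]].sequence
            assert frag in source or reverse_complement(frag) in source

    def test_same_seed_gives_identical_fastq(self, fast_ref, tmp_path):
        db, primers = fast_ref
        paths = []
        for i in (1, 2):
            run = simulate_reads(_one_locus_config(db, reads=200), db, primers)
            p = tmp_path / f"run{i}.fastq"
            run.write_fastq(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_locus_fractions_recover_configured_weights(self, fast_ref):
        """Empirical per-locus read fractions converge to the configured
        amplification weights (chi-square not rejected at n=1e5)."""
        db, primers = fast_ref
        config = panel_config(db, n_samples=1, seed=3, reads_per_sample=100000, skew=1.0)
        run = simulate_reads(config, db, primers)
        genotype = config.genotypes["S01"]
        weights = {
            l: DEFAULT_LOCUS_WEIGHTS[l] * (0.5 if len(genotype[l]) == 1 else 1.0)
            for l in genotype
        }
        total_w = sum(weights.values())
        counts = run.truth["locus"].value_counts()
        observed = [counts.get(l, 0) for l in sorted(genotype)]
        expected = [100000 * weights[l] / total_w for l in sorted(genotype)]
        assert sps.chisquare(observed, expected).pvalue > 0.01

    def test_unknown_genotype_allele_rejected(self, fast_ref):
        db, primers = fast_ref
        config = _one_locus_config(db)
        config.genotypes["S01"]["A"] = (parse_allele_name("A*99:99"),)
        with pytest.raises(Exception, match="A\\*99:99"):
            simulate_reads(config, db, primers)
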