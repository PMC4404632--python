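"""Allele nomenclature, database loading, and ambiguity grouping."""

import pytest
from hypothesis import given, settings, strategies as st

from multihla.allele_db import (
    AlleleDatabase,
    AlleleName,
    AlleleNameError,
    AlleleRecord,
    AnnotationError,
    DatabaseLoadError,
    Feature,
    SUPPORTED_LOCI,
    ambiguity_groups,
    genotyped_region,
    load_allele_fasta,
    parse_allele_name,
    parse_allele_set,
    render_allele_set,
    truncate_to_field,
    write_database,
)

allele_names = st.builds(
    AlleleName,
    locus=st.sampled_from(SUPPORTED_LOCI),
    fields=st.lists(
        st.integers(1, 999).map(lambda i: f"{i:02d}"), min_size=1, max_size=4
    ).map(tuple),
)


@pytest.mark.parametrize(
    "text, locus, fields",
    [
        ("DRB1*04:05:01", "DRB1", ("04", "05", "01")),
        ("A*01", "A", ("01",)),
        ("DPB1*107:01", "DPB1", ("107", "01")),
    ],
)
def test_parse_allele_name(text, locus, fields):
    name = parse_allele_name(text)
    assert name.locus == locus
    assert name.fields == fields
    assert str(name) == text


@pytest.mark.parametrize(
    "bad", ["DRB9-01", "", "A*", "A*01:", "ZZ*01:01", "A*01:02:03:04:05", "B*xx"]
)
def test_parse_allele_name_rejects_malformed(bad):
    with pytest.raises(AlleleNameError):
        parse_allele_name(bad)


@settings(derandomize=True, max_examples=200)
@given(allele_names)
def test_parse_render_roundtrip(name):
    assert parse_allele_name(str(name)) == name


def test_parse_allele_set_shorthand():
    names = parse_allele_set("DPB1*13:01/*107:01")
    assert [str(n) for n in names] == ["DPB1*13:01", "DPB1*107:01"]
    assert render_allele_set(names) == "DPB1*107:01/*13:01"


@pytest.mark.parametrize(
    "text, level, expected",
    [
        ("DPB1*05:01:01", 2, "DPB1*05:01"),
        ("B*39:01:01", 3, "B*39:01:01"),
        ("C*07:04", 3, "C*07:04"),
    ],
)
def test_truncate_to_field(text, level, expected):
    assert str(truncate_to_field(parse_allele_name(text), level)) == expected


def test_truncate_to_field_rejects_bad_level():
    with pytest.raises(ValueError):
        truncate_to_field(parse_allele_name("A*01"), 0)


def _record(name, seq, exons):
    feats = tuple(Feature("exon", i, s, e) for i, (s, e) in sorted(exons.items()))
    return AlleleRecord(parse_allele_name(name), seq, feats)


class TestGenotypedRegion:
    def test_class_i_uses_exons_2_and_3(self):
        rec = _record("A*01", "A" * 100, {1: (0, 10), 2: (20, 30), 3: (40, 50), 4: (60, 70)})
        assert genotyped_region(rec) == [(20, 30), (40, 50)]

    def test_class_ii_uses_exon_2_only(self):
        rec = _record("DQB1*03:01", "A" * 100, {1: (0, 10), 2: (20, 30), 3: (40, 50)})
        assert genotyped_region(rec) == [(20, 30)]

    def test_missing_exon_is_an_annotation_error(self):
        rec = _record("A*01", "A" * 100, {1: (0, 10), 2: (20, 30)})
        with pytest.raises(AnnotationError, match="A\\*01"):
            genotyped_region(rec)


class TestDatabaseLoad:
    def test_fasta_roundtrip(self, tmp_path, fast_ref):
        db, _ = fast_ref
        fasta, feats = tmp_path / "db.fasta", tmp_path / "db.tsv"
        write_database(db, fasta, feats)
        loaded = load_allele_fasta(fasta, feats)
        assert len(loaded) == len(db)
        for rec in db:
            assert loaded[rec.name].sequence == rec.sequence
            assert loaded[rec.name].features == rec.features

    def test_duplicate_name_rejected(self, tmp_path):
        fasta = tmp_path / "dup.fasta"
        fasta.write_text(">A*01\nACGT\n>A*01\nACGT\n")
        feats = tmp_path / "f.tsv"
        feats.write_text("allele\tkind\tindex\tstart\tend\n")
        with pytest.raises(DatabaseLoadError, match="duplicate"):
            load_allele_fasta(fasta, feats)

    def test_feature_out_of_bounds_rejected(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        fasta.write_text(">A*01\nACGTACGT\n")
        feats = tmp_path / "f.tsv"
        feats.write_text("allele\tkind\tindex\tstart\tend\nA*01\texon\t1\t0\t20\n")
        with pytest.raises(DatabaseLoadError, match="A\\*01"):
            load_allele_fasta(fasta, feats)


class TestAmbiguityGroups:
    def test_partition_covers_every_locus_allele(self, fast_ref):
        db, _ = fast_ref
        for locus in db.loci():
            for scope in ("genotyped_region", "amplicon"):
                groups = ambiguity_groups(db, locus, scope)
                flat = [str(n) for g in groups for n in g]
                assert sorted(flat) == db.locus_alleles(locus)  # disjoint + covering

    def test_difference_outside_amplicon_merges(self, fast_ref):
        db, _ = fast_ref
        groups = ambiguity_groups(db, "DPB1", "amplicon")
        merged = [g for g in groups if len(g) > 1]
        assert merged == [
            (parse_allele_name("DPB1*107:01"), parse_allele_name("DPB1*13:01"))
        ]

    def test_difference_inside_exon2_separates(self, fast_ref):
        db, _ = fast_ref
        # exon-2 SNP patterns distinguish every non-twin pair even under
        # the narrower genotyped-region scope
        groups = ambiguity_groups(db, "A", "genotyped_region")
        assert all(len(g) == 1 for g in groups)

    def test_intron_difference_ambiguous_only_in_exon_scope(self, fast_ref):
        db, _ = fast_ref
        exon_groups = ambiguity_groups(db, "B", "genotyped_region")
        pair = {parse_allele_name("B*40:02:01"), parse_allele_name("B*40:02:03")}
        assert any(set(g) == pair for g in exon_groups)
        amp_groups = ambiguity_groups(db, "B", "amplicon")
        assert all(len(g) == 1 for g in amp_groups)

    def test_single_allele_locus_is_one_singleton(self):
        rec = _record("DQB1*03:01", "ACGTACGTAC", {2: (2, 8)})
        db = AlleleDatabase([rec])
        assert ambiguity_groups(db, "DQB1", "genotyped_region") == [
            (parse_allele_name("DQB1*03:01"),)
        ]

    def test_unknown_locus_rejected(self, fast_ref):
        db, _ = fast_ref
        with pytest.raises(ValueError):
            ambiguity_groups(db, "DQA1")


def test_genotyped_region_within_exon_bounds(fast_ref):
    db, _ = fast_ref
    for rec in db:
        for start, end in genotyped_region(rec):
            exons = [f for f in rec.features if f.kind == "exon"]
            assert any(f.start <= start < end <= f.end for f in exons)
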