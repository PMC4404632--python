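"""HLA allele reference handling.

Models the slice of an IMGT/HLA-style allele database that amplicon
genotyping needs: colon-delimited allele nomenclature, per-allele
exon/intron annotation, and region-restricted ambiguity grouping
(alleles whose differences lie outside the sequenced region are
indistinguishable and must be reported together).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import total_ordering
from typing import Iterable, Iterator

from Bio import SeqIO

SUPPORTED_LOCI = ("A", "B", "C", "DRB1", "DRB3", "DRB4", "DRB5", "DQB1", "DPB1")
CLASS_I_LOCI = frozenset({"A", "B", "C"})
CLASS_II_LOCI = frozenset({"DRB1", "DRB3", "DRB4", "DRB5", "DQB1", "DPB1"})
DRB_PARALOG_LOCI = frozenset({"DRB3", "DRB4", "DRB5"})

#: loci fully evaluated at the two-allele level (the DRB paralogs are
#: hemizygous/absent depending on haplotype, so they are reported but not
#: counted among the per-sample diploid loci).
CORE_LOCI = ("A", "B", "C", "DRB1", "DQB1", "DPB1")

FEATURE_KINDS = ("promoter", "exon", "intron", "UTR3")


class AlleleNameError(ValueError):
    """Raised when an allele name string cannot be parsed."""


class DatabaseLoadError(ValueError):
    """Raised when a reference database violates its invariants on load."""


class AnnotationError(ValueError):
    """Raised when an allele lacks the feature annotation an operation needs."""


@total_ordering
@dataclass(frozen=True)
class AlleleName:
    """A structured HLA allele name, e.g. ``DRB1*04:05:01``.

    ``fields`` keeps the zero-padded numeric strings exactly as written
    ("04" is not "4"); comparison and rendering are therefore stable.
    """

    locus: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.locus not in SUPPORTED_LOCI:
            raise AlleleNameError(f"unsupported locus {self.locus!r}")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleNameError(
                f"allele name needs 1-4 fields, got {len(self.fields)}"
            )

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}"

    def __lt__(self, other: "AlleleName") -> bool:
        return (self.locus, self.fields) < (other.locus, other.fields)

    @property
    def first_field(self) -> str:
        return self.fields[0]


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``LOCUS*ff:ff[:ff[:ff]]`` into an :class:`AlleleName`.

    Rendering the result with ``str()`` reproduces the input exactly.
    """
    if not text:
        raise AlleleNameError("empty allele name")
    if "*" not in text:
        raise AlleleNameError(f"allele name {text!r} lacks '*' separator")
    locus, _, rest = text.partition("*")
    if locus not in SUPPORTED_LOCI:
        raise AlleleNameError(f"unsupported locus {locus!r} in {text!r}")
    fields = rest.split(":")
    for f in fields:
        if not f or not f.isdigit():
            raise AlleleNameError(f"bad field {f!r} in allele name {text!r}")
    if len(fields) > 4:
        raise AlleleNameError(f"too many fields in allele name {text!r}")
    return AlleleName(locus, tuple(fields))


def parse_allele_set(text: str) -> tuple[AlleleName, ...]:
    """Parse a slash-joined ambiguity string, e.g. ``DPB1*13:01/*107:01``.

    Later members may use the ``*fields`` shorthand inheriting the locus of
    the first member.
    """
    parts = text.split("/")
    first = parse_allele_name(parts[0])
    names = [first]
    for part in parts[1:]:
        if part.startswith("*"):
            part = first.locus + part
        names.append(parse_allele_name(part))
    return tuple(names)


def render_allele_set(names: Iterable[AlleleName]) -> str:
    """Render an ambiguity set slash-joined, lexicographic, shorthand after
    the first member (``DPB1*107:01/*13:01``)."""
    ordered = sorted(set(names))
    if not ordered:
        return ""
    out = [str(ordered[0])]
    out.extend("*" + ":".join(n.fields) for n in ordered[1:])
    return "/".join(out)


def truncate_to_field(name: AlleleName, level: int) -> AlleleName:
    """Truncate an allele name to at most ``level`` fields.

    A name with fewer fields than ``level`` is returned unchanged.
    """
    if level < 1:
        raise ValueError(f"field level must be >= 1, got {level}")
    if len(name.fields) <= level:
        return name
    return AlleleName(name.locus, name.fields[:level])


@dataclass(frozen=True)
class Feature:
    """One annotated region of an allele sequence (0-based half-open)."""

    kind: str
    index: int
    start: int
    end: int


@dataclass(frozen=True)
class AlleleRecord:
    """One named allele sequence with its exon/intron annotation."""

    name: AlleleName
    sequence: str
    features: tuple[Feature, ...]

    def feature(self, kind: str, index: int) -> Feature:
        for f in self.features:
            if f.kind == kind and f.index == index:
                return f
        raise AnnotationError(f"{self.name}: no {kind} {index} annotated")

    def exon(self, index: int) -> Feature:
        return self.feature("exon", index)


def validate_record(record: AlleleRecord) -> None:
    """Check feature invariants: sorted, non-overlapping, in-bounds,
    strictly increasing exon indices."""
    n = len(record.sequence)
    prev_end = 0
    prev_exon = 0
    for f in record.features:
        if f.kind not in FEATURE_KINDS:
            raise DatabaseLoadError(f"{record.name}: unknown feature kind {f.kind!r}")
        if not (0 <= f.start < f.end <= n):
            raise DatabaseLoadError(
                f"{record.name}: feature {f.kind} {f.index} [{f.start},{f.end}) "
                f"outside sequence of length {n}"
            )
        if f.start < prev_end:
            raise DatabaseLoadError(
                f"{record.name}: overlapping/unsorted feature {f.kind} {f.index}"
            )
        prev_end = f.end
        if f.kind == "exon":
            if f.index <= prev_exon:
                raise DatabaseLoadError(
                    f"{record.name}: exon indices not strictly increasing"
                )
            prev_exon = f.index


def genotyped_region(record: AlleleRecord) -> list[tuple[int, int]]:
    """Intervals genotyping is scored over: exons 2+3 for class I loci,
    exon 2 for class II loci."""
    locus = record.name.locus
    if locus in CLASS_I_LOCI:
        wanted = (2, 3)
    else:
        wanted = (2,)
    return [(record.exon(i).start, record.exon(i).end) for i in wanted]


class AlleleDatabase:
    """A collection of :class:`AlleleRecord` keyed by rendered name.

    Holds lazily-built k-mer indexes used by candidate selection and
    perfect-match mapping, and (once attached) the per-allele amplicon
    interval used for amplicon-scope ambiguity grouping.
    """

    def __init__(self, records: Iterable[AlleleRecord]):
        self.records: dict[str, AlleleRecord] = {}
        self.by_locus: dict[str, list[str]] = {}
        for rec in records:
            key = str(rec.name)
            if key in self.records:
                raise DatabaseLoadError(f"duplicate allele name {key}")
            validate_record(rec)
            self.records[key] = rec
            self.by_locus.setdefault(rec.name.locus, []).append(key)
        for names in self.by_locus.values():
            names.sort()
        self._amplicon_intervals: dict[str, tuple[int, int]] | None = None
        self._kmer_index: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self._kmer_sets: dict[int, dict[str, frozenset[str]]] = {}
        self._ambiguity_cache: dict[tuple[str, str], list[tuple[AlleleName, ...]]] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: object) -> bool:
        return str(name) in self.records

    def __getitem__(self, name: str | AlleleName) -> AlleleRecord:
        return self.records[str(name)]

    def __iter__(self) -> Iterator[AlleleRecord]:
        return iter(self.records.values())

    def loci(self) -> list[str]:
        return [l for l in SUPPORTED_LOCI if self.by_locus.get(l)]

    def locus_alleles(self, locus: str) -> list[str]:
        if locus not in SUPPORTED_LOCI:
            raise ValueError(f"unknown locus {locus!r}")
        return list(self.by_locus.get(locus, []))

    # -- amplicon attachment -------------------------------------------------

    def set_amplicon_intervals(self, intervals: dict[str, tuple[int, int]]) -> None:
        """Attach per-allele amplicon intervals (from predicted amplicons)."""
        for name in intervals:
            if name not in self.records:
                raise KeyError(f"amplicon interval for unknown allele {name}")
        self._amplicon_intervals = dict(intervals)
        self._ambiguity_cache.clear()

    def amplicon_interval(self, name: str | AlleleName) -> tuple[int, int]:
        if self._amplicon_intervals is None:
            raise AnnotationError("no amplicon intervals attached to database")
        return self._amplicon_intervals[str(name)]

    @property
    def has_amplicon_intervals(self) -> bool:
        return self._amplicon_intervals is not None

    # -- k-mer indexes -------------------------------------------------------

    def kmer_index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        """k-mer -> list of (allele name, position), over forward strands."""
        if k not in self._kmer_index:
            index: dict[str, list[tuple[str, int]]] = {}
            for key, rec in self.records.items():
                seq = rec.sequence
                for i in range(len(seq) - k + 1):
                    index.setdefault(seq[i : i + k], []).append((key, i))
            self._kmer_index[k] = index
        return self._kmer_index[k]

    def kmer_sets(self, k: int) -> dict[str, frozenset[str]]:
        """allele name -> set of distinct forward-strand k-mers."""
        if k not in self._kmer_sets:
            sets = {}
            for key, rec in self.records.items():
                seq = rec.sequence
                sets[key] = frozenset(
                    seq[i : i + k] for i in range(len(seq) - k + 1)
                )
            self._kmer_sets[k] = sets
        return self._kmer_sets[k]


def ambiguity_groups(
    db: AlleleDatabase, locus: str, region_scope: str = "genotyped_region"
) -> list[tuple[AlleleName, ...]]:
    """Partition a locus's alleles into sets identical over the chosen scope.

    ``region_scope`` is ``"genotyped_region"`` (the polymorphic exons) or
    ``"amplicon"`` (everything between the primers).  Two alleles land in the
    same set iff their sequences are equal over every interval of the scope;
    unambiguous alleles form singletons.  The result is a partition of the
    locus's alleles, each set sorted, sets ordered by first member.
    """
    if locus not in SUPPORTED_LOCI:
        raise ValueError(f"unknown locus {locus!r}")
    if region_scope not in ("genotyped_region", "amplicon"):
        raise ValueError(f"unknown region scope {region_scope!r}")
    cache_key = (locus, region_scope)
    if cache_key in db._ambiguity_cache:
        return db._ambiguity_cache[cache_key]
    buckets: dict[str, list[AlleleName]] = {}
    for name in db.locus_alleles(locus):
        rec = db[name]
        if region_scope == "genotyped_region":
            intervals = genotyped_region(rec)
        else:
            intervals = [db.amplicon_interval(name)]
        sig = "|".join(rec.sequence[s:e] for s, e in intervals)
        buckets.setdefault(sig, []).append(rec.name)
    groups = sorted(tuple(sorted(g)) for g in buckets.values())
    db._ambiguity_cache[cache_key] = groups
    return groups


def ambiguity_group_of(
    db: AlleleDatabase, name: AlleleName, region_scope: str = "amplicon"
) -> tuple[AlleleName, ...]:
    """The ambiguity set containing ``name`` under the given scope."""
    for group in ambiguity_groups(db, name.locus, region_scope):
        if name in group:
            return group
    raise KeyError(f"{name} not in database")


# -- file I/O ---------------------------------------------------------------

FEATURE_COLUMNS = ("allele", "kind", "index", "start", "end")


def load_allele_fasta(fasta_path, features_path) -> AlleleDatabase:
    """Load a reference database from FASTA + feature-annotation TSV.

    FASTA headers are ``>NAME optional description``; the feature table has
    columns ``allele, kind, index, start, end`` with 0-based half-open
    coordinates on the allele sequence.
    """
    sequences: dict[str, str] = {}
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        name = str(parse_allele_name(entry.id))
        if name in sequences:
            raise DatabaseLoadError(f"duplicate allele name {name} in FASTA")
        sequences[name] = str(entry.seq).upper()

    features: dict[str, list[Feature]] = {name: [] for name in sequences}
    with open(features_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(FEATURE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DatabaseLoadError(f"feature table lacks columns {sorted(missing)}")
        for row in reader:
            allele = row["allele"]
            if allele not in features:
                raise DatabaseLoadError(
                    f"feature table references unknown allele {allele}"
                )
            features[allele].append(
                Feature(row["kind"], int(row["index"]), int(row["start"]), int(row["end"]))
            )

    records = []
    for name, seq in sequences.items():
        feats = tuple(sorted(features[name], key=lambda f: f.start))
        records.append(AlleleRecord(parse_allele_name(name), seq, feats))
    return AlleleDatabase(records)


def write_database(db: AlleleDatabase, fasta_path, features_path) -> None:
    """Write a database back out as FASTA + feature TSV (inverse of load)."""
    with open(fasta_path, "w") as fh:
        for rec in db:
            fh.write(f">{rec.name}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(features_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(FEATURE_COLUMNS)
        for rec in db:
            for f in rec.features:
                writer.writerow([str(rec.name), f.kind, f.index, f.start, f.end])
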