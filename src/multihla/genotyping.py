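"""Allele assignment under the perfect-match condition.

The typing core works in four steps.  Candidate alleles are ranked per
locus by the number of distinct k-mers they share with the sample's read
set.  Reads are then placed on candidate alleles only where they match
exactly — zero mismatches, zero indels, either strand — which keeps reads
from straying between paralogous loci and silently absorbs PCR crossover
chimeras (a chimeric read matches neither parental allele exactly).  The
genotype is the allele pair that jointly explains the most mapped reads
over the genotyped exon region, and each called allele is widened to its
ambiguity set (alleles identical over the amplicon cannot be told apart).
Finally, reads left unmapped are re-examined allowing exactly one
substitution against the called alleles to surface novel single-nucleotide
variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Iterable

import edlib

from .allele_db import (
    AlleleDatabase,
    AlleleName,
    ambiguity_group_of,
    genotyped_region,
)
from .insilico_pcr import reverse_complement
from .metrics import depth_ratio, flag_imbalance, locus_depth, per_site_depth
from .readqc import Read, ReadBatch


@dataclass
class TypingParams:
    """Tunable typing parameters.

    k: k-mer size for candidate search and the mapping seed index.
    top_n: candidate alleles retained per locus.
    min_depth: minimum summed (pair) average depth for a call.
    low_depth_threshold: per-allele average depth below which the call is
        flagged low_depth (variant detection loses sensitivity below ~30x).
    hom_fraction: the call is homozygous when the minor allele's uniquely
        explained reads fall below this fraction of the major allele's.
    ambiguity_scope: region over which called alleles are widened to their
        ambiguity set ("amplicon" or "genotyped_region").
    """

    k: int = 15
    top_n: int = 10
    min_depth: float = 25.0
    low_depth_threshold: float = 30.0
    hom_fraction: float = 0.1
    ambiguity_scope: str = "amplicon"
    novel_min_fraction: float = 0.3
    novel_min_reads: int = 3
    candidate_max_reads: int | None = 4000


@dataclass(frozen=True)
class CandidateSet:
    """Alleles of one locus ranked by shared-k-mer evidence."""

    locus: str
    alleles: tuple[str, ...]
    scores: tuple[int, ...]


@dataclass(frozen=True)
class Placement:
    """One exact placement of a read on an allele (allele coordinates)."""

    read_id: str
    start: int
    end: int
    strand: str


@dataclass
class MappingResult:
    """Perfect-match placements of one sample's reads on candidate alleles.

    ``by_read`` maps read id -> tuple of (allele, start, strand);
    ``by_allele`` maps allele -> placements; ``cross_locus_reads`` are
    reads that placed on candidates at two or more loci (they support
    depth but not the pair-choice objective); ``unmapped`` keeps the
    reads with no placement for novel-variant re-examination.
    """

    by_read: dict[str, tuple[tuple[str, int, str], ...]]
    by_allele: dict[str, list[Placement]]
    cross_locus_reads: frozenset[str]
    unmapped: list[Read]


@dataclass
class CallDepth:
    """Depth metrics attached to a genotype call."""

    depth1: float
    depth2: float
    ratio: float | None
    locus_depth: float


@dataclass
class GenotypeCall:
    """Per-sample, per-locus genotype: two ambiguity sets of allele names
    (equal sets when homozygous), depth metrics, and QC flags."""

    sample: str
    locus: str
    allele1: tuple[AlleleName, ...] | None
    allele2: tuple[AlleleName, ...] | None
    primary_pair: tuple[AlleleName, AlleleName] | None
    metrics: CallDepth | None
    flags: set[str] = dataclass_field(default_factory=set)

    @property
    def is_no_call(self) -> bool:
        return self.allele1 is None


@dataclass(frozen=True)
class NovelVariant:
    """A candidate novel substitution on a called allele."""

    allele: str
    position: int
    ref: str
    alt: str
    support: int
    coverage: int

    @property
    def fraction(self) -> float:
        return self.support / self.coverage if self.coverage else 0.0


def select_candidates(
    batch: ReadBatch,
    db: AlleleDatabase,
    k: int = 15,
    top_n: int = 10,
    max_reads: int | None = None,
) -> dict[str, CandidateSet]:
    """Rank alleles per locus by distinct k-mers shared with the read set.

    Both read strands contribute; alleles sharing no k-mer are never
    candidates.  ``max_reads`` caps how many reads feed the k-mer pool
    (ranking stabilises long before the full batch is used).
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if not batch.reads:
        warnings.warn(f"sample {batch.sample}: empty read batch, no candidates")
    if max_reads is None or len(batch.reads) <= max_reads:
        reads = batch.reads
    else:  # stride-sample so every part of the batch contributes
        step = -(-len(batch.reads) // max_reads)
        reads = batch.reads[::step]
    read_kmers: set[str] = set()
    for read in reads:
        seq = read.seq
        for s in (seq, reverse_complement(seq)):
            read_kmers.update(s[i : i + k] for i in range(len(s) - k + 1))

    allele_kmers = db.kmer_sets(k)
    result: dict[str, CandidateSet] = {}
    for locus in db.loci():
        scored = []
        for name in db.locus_alleles(locus):
            score = len(allele_kmers[name] & read_kmers)
            if score > 0:
                scored.append((name, score))
        scored.sort(key=lambda t: (-t[1], t[0]))
        top = scored[:top_n]
        result[locus] = CandidateSet(
            locus, tuple(n for n, _ in top), tuple(s for _, s in top)
        )
    return result


def perfect_match_map(
    batch: ReadBatch,
    candidates: dict[str, CandidateSet] | Iterable[str],
    db: AlleleDatabase,
    k: int = 15,
) -> MappingResult:
    """Place each read on every candidate allele it matches exactly.

    A read is placed iff it equals a substring of the allele (or of its
    reverse complement); placements on several alleles are all retained.
    Uses the database k-mer index as a seed (every full match must match
    at its first k bases), so results are identical to brute-force
    substring comparison.
    """
    if isinstance(candidates, dict):
        cand_names = {a for cs in candidates.values() for a in cs.alleles}
    else:
        cand_names = {str(a) for a in candidates}
    for name in cand_names:
        if name not in db:
            raise KeyError(f"candidate allele {name} not in database")

    index = db.kmer_index(k)
    by_read: dict[str, tuple[tuple[str, int, str], ...]] = {}
    by_allele: dict[str, list[Placement]] = {n: [] for n in cand_names}
    unmapped: list[Read] = []
    read_loci: dict[str, set[str]] = {}

    for read in batch.reads:
        seq = read.seq
        L = len(seq)
        placements: list[tuple[str, int, str]] = []
        if L >= k:
            for oriented, strand in ((seq, "+"), (reverse_complement(seq), "-")):
                for name, pos in index.get(oriented[:k], ()):
                    if name not in cand_names:
                        continue
                    if db.records[name].sequence[pos : pos + L] == oriented:
                        placements.append((name, pos, strand))
        else:  # shorter than the seed: scan candidates directly
            for name in cand_names:
                target = db.records[name].sequence
                for oriented, strand in ((seq, "+"), (reverse_complement(seq), "-")):
                    pos = target.find(oriented)
                    while pos != -1:
                        placements.append((name, pos, strand))
                        pos = target.find(oriented, pos + 1)
        if not placements:
            unmapped.append(read)
            continue
        placements = sorted(set(placements))
        by_read[read.id] = tuple(placements)
        loci = {db.records[name].name.locus for name, _, _ in placements}
        read_loci[read.id] = loci
        for name, pos, strand in placements:
            by_allele[name].append(Placement(read.id, pos, pos + L, strand))

    cross = frozenset(rid for rid, loci in read_loci.items() if len(loci) > 1)
    return MappingResult(by_read, by_allele, cross, unmapped)


def _overlaps(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def call_genotype(
    sample: str,
    locus: str,
    mapping: MappingResult,
    db: AlleleDatabase,
    params: TypingParams | None = None,
) -> GenotypeCall:
    """Call the allele pair for one locus from a perfect-match mapping.

    The chosen pair (a, b), a == b allowed, maximises the number of reads
    placed on a or b over the genotyped region (cross-locus shared reads
    are excluded from this objective), tie-broken toward more even allele
    depths and then lexicographically.  The call is homozygous when the
    minor allele's uniquely explained reads fall below ``hom_fraction``
    of the major's, and becomes no_call when the summed pair depth falls
    below ``min_depth``.  Called alleles are widened to their ambiguity
    set over ``ambiguity_scope``.
    """
    params = params or TypingParams()

    locus_alleles = [
        name
        for name, places in mapping.by_allele.items()
        if places and db.records[name].name.locus == locus
    ]

    regions = {n: genotyped_region(db.records[n]) for n in locus_alleles}
    explained: dict[str, frozenset[str]] = {}
    for name in locus_alleles:
        rids = {
            p.read_id
            for p in mapping.by_allele[name]
            if p.read_id not in mapping.cross_locus_reads
            and _overlaps(p.start, p.end, regions[name])
        }
        explained[name] = frozenset(rids)
    locus_alleles = [n for n in locus_alleles if explained[n]]

    if not locus_alleles:
        return GenotypeCall(sample, locus, None, None, None, None, {"no_call"})

    avg_depth = {
        n: per_site_depth(db.records[n], mapping.by_allele[n], regions[n]).average
        for n in locus_alleles
    }

    # pairs are visited in lexicographic order and ties broken strictly,
    # so the winner is deterministic: objective, then evenness, then name
    best: tuple | None = None
    ordered = sorted(locus_alleles)
    for i, a in enumerate(ordered):
        for b in ordered[i:]:
            n_explained = len(explained[a] | explained[b])
            evenness = depth_ratio(avg_depth[a], avg_depth[b]) if a != b else 1.0
            key = (n_explained, evenness)
            if best is None or key > best[0]:
                best = (key, a, b)
    assert best is not None
    _, a, b = best

    if a != b:
        unique_a = len(explained[a] - explained[b])
        unique_b = len(explained[b] - explained[a])
        lo, hi = min(unique_a, unique_b), max(unique_a, unique_b)
        if hi == 0 or lo < params.hom_fraction * hi:
            a = b = a if unique_a >= unique_b else b

    flags: set[str] = set()
    if a == b:
        total = avg_depth[a]
        d1 = d2 = total / 2.0  # one template, two chromosomes
        ratio = 1.0
    else:
        d1, d2 = avg_depth[a], avg_depth[b]
        total = locus_depth(d1, d2)
        ratio = depth_ratio(d1, d2)
        if "excessive_imbalance" in flag_imbalance(ratio):
            flags.add("excessive_imbalance")

    if total < params.min_depth:
        return GenotypeCall(sample, locus, None, None, None, None, {"no_call"})
    if min(d1, d2) < params.low_depth_threshold:
        flags.add("low_depth")

    name_a, name_b = db.records[a].name, db.records[b].name
    set_a = ambiguity_group_of(db, name_a, params.ambiguity_scope)
    set_b = ambiguity_group_of(db, name_b, params.ambiguity_scope)
    if len(set_a) > 1 or len(set_b) > 1:
        flags.add("ambiguous")

    return GenotypeCall(
        sample,
        locus,
        set_a,
        set_b,
        (name_a, name_b),
        CallDepth(d1, d2, ratio, total),
        flags,
    )


def detect_novel_variant(
    call: GenotypeCall,
    mapping: MappingResult,
    db: AlleleDatabase,
    min_fraction: float = 0.3,
    min_reads: int = 3,
) -> list[NovelVariant]:
    """Re-examine unmapped reads for a single novel substitution.

    Unmapped reads are re-aligned against the called alleles allowing
    exactly one substitution (no indels, either strand).  A position is
    reported when at least ``min_fraction`` of all reads covering it
    (perfect placements plus re-aligned reads) agree on the same
    substitution, with at least ``min_reads`` supporting reads.  Sets the
    ``novel_variant_candidate`` flag on the call when anything is found.
    """
    if call.is_no_call:
        raise ValueError("cannot scan for novel variants on a no_call")
    assert call.primary_pair is not None
    targets = sorted({str(n) for n in call.primary_pair})

    support: dict[tuple[str, int, str], int] = {}
    remapped_spans: dict[str, list[tuple[int, int]]] = {t: [] for t in targets}
    for read in mapping.unmapped:
        hit = None
        for target_name in targets:
            target = db.records[target_name].sequence
            for oriented in (read.seq, reverse_complement(read.seq)):
                res = edlib.align(oriented, target, mode="HW", task="locations", k=1)
                if res["editDistance"] != 1:
                    continue
                s, e = res["locations"][0]
                if e - s + 1 != len(oriented):
                    continue  # the single edit is an indel, not a substitution
                window = target[s : e + 1]
                diff = [j for j in range(len(oriented)) if oriented[j] != window[j]]
                if len(diff) != 1:
                    continue
                j = diff[0]
                hit = (target_name, s + j, window[j], oriented[j], s, e + 1)
                break
            if hit:
                break
        if hit:
            name, pos, ref, alt, s, e = hit
            support[(name, pos, alt)] = support.get((name, pos, alt), 0) + 1
            remapped_spans[name].append((s, e))

    variants: list[NovelVariant] = []
    for (name, pos, alt), n_support in sorted(support.items()):
        if n_support < min_reads:
            continue
        perfect_cov = sum(
            1 for p in mapping.by_allele.get(name, ()) if p.start <= pos < p.end
        )
        remap_cov = sum(1 for s, e in remapped_spans[name] if s <= pos < e)
        coverage = perfect_cov + remap_cov
        if coverage and n_support / coverage >= min_fraction:
            ref = db.records[name].sequence[pos]
            variants.append(NovelVariant(name, pos, ref, alt, n_support, coverage))
    if variants:
        call.flags.add("novel_variant_candidate")
    return variants
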