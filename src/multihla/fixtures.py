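"""Synthetic reference fixtures: toy allele database, primer sets, panel.

The toy database is generated, not copied from IMGT/HLA: each locus gets
a random backbone laid out as promoter / exons / introns / 3'UTR, with
alleles derived by planting SNP patterns inside the polymorphic exons.
Primer sites are embedded so that predicted product sizes reproduce the
multiplex design at full scale — 5.5/4.6/4.8 kb for HLA-A/B/C
(promoter to 3'UTR), 4.0-5.2 kb for DRB1 (5.2 kb in the DR4 family),
4.1/4.5/4.1 kb for DRB3/4/5, 3.9-4.3 kb for DQB1 (intron 1 to exon 4),
and 7.2 kb for DPB1 (intron 1 to 3'UTR) — and a ``scale`` option shrinks
every segment proportionally for fast tests.  One shared DRB primer set
amplifies all four DRB paralogs.

Structural analogues of the published ambiguity cases are planted:
DPB1*13:01 / DPB1*107:01 and DRB1*09:01:02 / DRB1*09:21 differ only in
exon 1, upstream of the amplified region, so they are indistinguishable
from the amplicon; B*40:02:01 / B*40:02:03 differ in intron 2, inside
the amplicon but outside the genotyped exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .allele_db import (
    AlleleDatabase,
    AlleleName,
    AlleleRecord,
    Feature,
    parse_allele_name,
)
from .insilico_pcr import (
    Amplicon,
    Primer,
    SimConfig,
    predict_amplicons,
    reverse_complement,
)

_BUILDER_SEED = 101
PRIMER_LEN = 18

#: per-locus amplicon size classes, full-scale product sizes in bp
_SIZE_CLASSES: dict[str, dict[str, int]] = {
    "A": {"std": 5500},
    "B": {"std": 4600},
    "C": {"std": 4800},
    "DRB1": {"std": 4000, "alt": 4100, "dr4": 5200},
    "DRB3": {"std": 4100},
    "DRB4": {"std": 4500},
    "DRB5": {"std": 4100},
    "DQB1": {"std": 3900, "long": 4300},
    "DPB1": {"std": 7200},
}

#: primer groups: one shared set amplifies the four DRB paralogs
_PRIMER_GROUP = {
    "A": "A", "B": "B", "C": "C",
    "DRB1": "DRB", "DRB3": "DRB", "DRB4": "DRB", "DRB5": "DRB",
    "DQB1": "DQB1", "DPB1": "DPB1",
}


@dataclass(frozen=True)
class _AlleleSpec:
    name: str
    size: str = "std"
    pattern: int = 0  # SNP bit pattern id; twins share one
    extra_snp: str | None = None  # "exon1" (outside amplicon) | "intron2"


_ROSTER: dict[str, list[_AlleleSpec]] = {
    "A": [
        _AlleleSpec("A*01:01:01", pattern=1),
        _AlleleSpec("A*02:01:01", pattern=2),
        _AlleleSpec("A*02:06:01", pattern=3),
        _AlleleSpec("A*11:01:01", pattern=4),
        _AlleleSpec("A*24:02:01", pattern=5),
        _AlleleSpec("A*26:01:01", pattern=6),
        _AlleleSpec("A*31:01:02", pattern=7),
        _AlleleSpec("A*33:03:01", pattern=8),
    ],
    "B": [
        _AlleleSpec("B*07:02:01", pattern=1),
        _AlleleSpec("B*15:01:01", pattern=2),
        _AlleleSpec("B*35:01:01", pattern=3),
        _AlleleSpec("B*39:01:01", pattern=4),
        _AlleleSpec("B*40:01:02", pattern=5),
        _AlleleSpec("B*40:02:01", pattern=6),
        _AlleleSpec("B*40:02:03", pattern=6, extra_snp="intron2"),
        _AlleleSpec("B*44:03:01", pattern=7),
        _AlleleSpec("B*51:01:01", pattern=8),
        _AlleleSpec("B*52:01:01", pattern=9),
    ],
    "C": [
        _AlleleSpec("C*01:02:01", pattern=1),
        _AlleleSpec("C*03:03:01", pattern=2),
        _AlleleSpec("C*03:04:01", pattern=3),
        _AlleleSpec("C*04:01:01", pattern=4),
        _AlleleSpec("C*07:02:01", pattern=5),
        _AlleleSpec("C*07:04:01", pattern=6),
        _AlleleSpec("C*08:01:01", pattern=7),
        _AlleleSpec("C*12:02:01", pattern=8),
        _AlleleSpec("C*14:02:01", pattern=9),
    ],
    "DRB1": [
        _AlleleSpec("DRB1*01:01:01", pattern=1),
        _AlleleSpec("DRB1*03:01:01", pattern=2),
        _AlleleSpec("DRB1*04:05:01", size="dr4", pattern=3),
        _AlleleSpec("DRB1*04:06:01", size="dr4", pattern=4),
        _AlleleSpec("DRB1*07:01:01", pattern=5),
        _AlleleSpec("DRB1*08:03:02", pattern=6),
        _AlleleSpec("DRB1*09:01:02", pattern=7),
        _AlleleSpec("DRB1*09:21", pattern=7, extra_snp="exon1"),
        _AlleleSpec("DRB1*11:01:01", pattern=8),
        _AlleleSpec("DRB1*13:02:01", pattern=9),
        _AlleleSpec("DRB1*15:01:01", size="alt", pattern=10),
        _AlleleSpec("DRB1*15:02:01", size="alt", pattern=11),
        _AlleleSpec("DRB1*16:02:01", size="alt", pattern=12),
    ],
    "DRB3": [
        _AlleleSpec("DRB3*01:01:02", pattern=1),
        _AlleleSpec("DRB3*02:02:01", pattern=2),
        _AlleleSpec("DRB3*03:01:01", pattern=3),
    ],
    "DRB4": [
        _AlleleSpec("DRB4*01:03:01", pattern=1),
        _AlleleSpec("DRB4*01:03:02", pattern=2),
    ],
    "DRB5": [
        _AlleleSpec("DRB5*01:01:01", pattern=1),
        _AlleleSpec("DRB5*01:02", pattern=2),
        _AlleleSpec("DRB5*02:02", pattern=3),
    ],
    "DQB1": [
        _AlleleSpec("DQB1*03:01:01", pattern=1),
        _AlleleSpec("DQB1*03:02:01", pattern=2),
        _AlleleSpec("DQB1*03:03:02", pattern=3),
        _AlleleSpec("DQB1*04:01:01", pattern=4),
        _AlleleSpec("DQB1*05:01:01", pattern=5),
        _AlleleSpec("DQB1*06:01:01", size="long", pattern=6),
        _AlleleSpec("DQB1*06:02:01", size="long", pattern=7),
    ],
    "DPB1": [
        _AlleleSpec("DPB1*02:01:02", pattern=1),
        _AlleleSpec("DPB1*02:02", pattern=2),
        _AlleleSpec("DPB1*04:01:01", pattern=3),
        _AlleleSpec("DPB1*04:02:01", pattern=4),
        _AlleleSpec("DPB1*05:01:01", pattern=5),
        _AlleleSpec("DPB1*09:01", pattern=6),
        _AlleleSpec("DPB1*13:01", pattern=7),
        _AlleleSpec("DPB1*107:01", pattern=7, extra_snp="exon1"),
    ],
}

#: DRB1 allele -> DRB3/4/5 allele carried on the same toy haplotype
TOY_LINKAGE: dict[str, str | None] = {
    "DRB1*01:01:01": None,
    "DRB1*03:01:01": "DRB3*02:02:01",
    "DRB1*04:05:01": "DRB4*01:03:01",
    "DRB1*04:06:01": "DRB4*01:03:01",
    "DRB1*07:01:01": "DRB4*01:03:01",
    "DRB1*08:03:02": None,
    "DRB1*09:01:02": "DRB4*01:03:02",
    "DRB1*09:21": "DRB4*01:03:02",
    "DRB1*11:01:01": "DRB3*02:02:01",
    "DRB1*13:02:01": "DRB3*03:01:01",
    "DRB1*15:01:01": "DRB5*01:01:01",
    "DRB1*15:02:01": "DRB5*01:02",
    "DRB1*16:02:01": "DRB5*02:02",
}

#: relative per-locus amplification efficiencies; chosen so a pooled run
#: reproduces the depth hierarchy of a real multiplex run (highest at
#: DRB1 and DQB1, lowest at A and DPB1).  A hemizygous DRB3/4/5 locus
#: contributes half its weight.
DEFAULT_LOCUS_WEIGHTS: dict[str, float] = {
    "A": 1.00, "B": 1.24, "C": 1.45,
    "DRB1": 2.14, "DQB1": 1.86, "DPB1": 0.99,
    "DRB3": 1.0, "DRB4": 1.0, "DRB5": 1.0,
}

#: read-length parameters for the 1:10-scale test database (same
#: left-skewed shape as the full 400-bp chemistry profile)
FAST_READ_PROFILE: dict[str, float | int] = {
    "read_length_mean": 72.0,
    "read_length_mode": 88.0,
    "read_length_min": 30,
    "read_length_max": 110,
}


def _segments(locus: str, target: int, scale: float) -> list[tuple[str, int, int, bool]]:
    """Segment plan (kind, index, length, in_amplicon) hitting ``target``
    amplicon length exactly; introns inside the amplicon absorb the
    residual."""
    if locus in ("A", "B", "C"):
        fixed = [
            ("flank", 5, 60, False),
            ("promoter", 1, 300, True),
            ("exon", 1, 73, True),
            ("intron", 1, -1, True),
            ("exon", 2, 270, True),
            ("intron", 2, -1, True),
            ("exon", 3, 276, True),
            ("intron", 3, -1, True),
            ("exon", 4, 287, True),
            ("UTR3", 1, 300, True),
            ("flank", 3, 60, False),
        ]
    elif locus == "DPB1":
        fixed = [
            ("flank", 5, 60, False),
            ("promoter", 1, 200, False),
            ("exon", 1, 60, False),
            ("intron", 1, 150, False),  # intron 1 head, upstream of the primer
            ("intron", 1, -1, True),
            ("exon", 2, 264, True),
            ("intron", 2, -1, True),
            ("exon", 3, 282, True),
            ("intron", 3, -1, True),
            ("exon", 4, 96, True),
            ("UTR3", 1, 240, True),
            ("flank", 3, 60, False),
        ]
    else:  # DRB paralogs and DQB1: intron 1 to exon 4
        fixed = [
            ("flank", 5, 60, False),
            ("promoter", 1, 200, False),
            ("exon", 1, 60, False),
            ("intron", 1, 120, False),
            ("intron", 1, -1, True),
            ("exon", 2, 270, True),
            ("intron", 2, -1, True),
            ("exon", 3, 282, True),
            ("intron", 3, -1, True),
            ("exon", 4, 96, True),
            ("UTR3", 1, 150, False),
            ("flank", 3, 60, False),
        ]

    scaled = []
    for kind, index, length, inside in fixed:
        if length >= 0:
            scaled.append([kind, index, max(round(length * scale), 3), inside])
        else:
            scaled.append([kind, index, -1, inside])
    target_scaled = max(round(target * scale), 1)
    fixed_in = sum(s[2] for s in scaled if s[3] and s[2] >= 0)
    fillers = [s for s in scaled if s[2] < 0]
    residual = target_scaled - fixed_in
    if residual < 3 * len(fillers):
        raise ValueError(f"scale {scale} too small for locus {locus}")
    q, r = divmod(residual, len(fillers))
    for i, f in enumerate(fillers):
        f[2] = q + (1 if i < r else 0)
    return [tuple(s) for s in scaled]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


_ROTATE = {"A": "C", "C": "G", "G": "T", "T": "A"}
_DEGENERATE = {"A": "R", "G": "R", "C": "Y", "T": "Y"}


def _bounds(segments) -> tuple[dict[tuple[str, int], tuple[int, int]], tuple[int, int]]:
    """Positions of each (kind,index) plus the amplicon interval."""
    pos = 0
    spans: dict[tuple[str, int], tuple[int, int]] = {}
    amp_start = amp_end = None
    for kind, index, length, inside in segments:
        key = (kind, index)
        if key in spans:  # split intron: widen the span
            spans[key] = (spans[key][0], pos + length)
        else:
            spans[key] = (pos, pos + length)
        if inside:
            if amp_start is None:
                amp_start = pos
            amp_end = pos + length
        pos += length
    assert amp_start is not None and amp_end is not None
    return spans, (amp_start, amp_end)


@lru_cache(maxsize=4)
def toy_reference(scale: float = 0.1) -> tuple[AlleleDatabase, list[Primer]]:
    """Build the bundled synthetic reference at the given scale.

    Returns the database (with per-allele amplicon intervals attached)
    and the multiplex primer set.  ``scale=1.0`` reproduces the published
    product sizes exactly; ``scale=0.1`` is the fast test scale.
    """
    rng = np.random.default_rng(_BUILDER_SEED)

    # one primer-site pair per primer group, shared across its loci
    group_sites: dict[str, tuple[str, str]] = {}
    for group in dict.fromkeys(_PRIMER_GROUP.values()):
        group_sites[group] = (
            _random_bases(rng, PRIMER_LEN),
            _random_bases(rng, PRIMER_LEN),
        )

    records: list[AlleleRecord] = []
    for locus, specs in _ROSTER.items():
        classes = _SIZE_CLASSES[locus]
        largest = max(classes, key=classes.get)
        segs_large = _segments(locus, classes[largest], scale)
        # smaller size classes differ from the largest only in the first
        # in-amplicon intron (an indel polymorphism), so all alleles share
        # one backbone outside that block
        seg_by_class: dict[str, list[tuple[str, int, int, bool]]] = {largest: segs_large}
        i1_index = next(
            i for i, s in enumerate(segs_large) if s[0] == "intron" and s[3]
        )
        for cname, target in classes.items():
            if cname == largest:
                continue
            delta = round(classes[largest] * scale) - round(target * scale)
            segs = [list(s) for s in segs_large]
            segs[i1_index][2] -= delta
            if segs[i1_index][2] < 3:
                raise ValueError(f"scale {scale} too small for locus {locus}")
            seg_by_class[cname] = [tuple(s) for s in segs]
        spans_large, amp_large = _bounds(seg_by_class[largest])
        total_large = sum(s[2] for s in seg_by_class[largest])
        backbone = list(_random_bases(rng, total_large))

        # embed the group's primer sites at the amplicon boundaries
        fwd_site, rev_site = group_sites[_PRIMER_GROUP[locus]]
        a0, a1 = amp_large
        backbone[a0 : a0 + PRIMER_LEN] = fwd_site
        backbone[a1 - PRIMER_LEN : a1] = rev_site
        backbone_str = "".join(backbone)

        # derive smaller size classes by deleting a block from the middle
        # of the intra-amplicon part of intron 1
        class_seqs: dict[str, str] = {largest: backbone_str}
        class_spans = {largest: (spans_large, amp_large)}
        # the first in-amplicon intron absorbs class-size differences; for
        # the multi-class loci (DRB1, DQB1) it begins at the amplicon start
        i1_large = next(s[2] for s in seg_by_class[largest] if s[0] == "intron" and s[3])
        i1_start = amp_large[0]
        for cname, segs in seg_by_class.items():
            if cname == largest:
                continue
            delta = i1_large - [s for s in segs if s[0] == "intron" and s[3]][0][2]
            cut = i1_start + PRIMER_LEN + (i1_large - delta) // 2
            class_seqs[cname] = backbone_str[:cut] + backbone_str[cut + delta :]
            class_spans[cname] = _bounds(segs)

        # SNP offsets within the polymorphic exons (six pattern bits)
        for spec in specs:
            segs = seg_by_class[spec.size]
            spans, amp = class_spans[spec.size]
            seq = bytearray(class_seqs[spec.size].encode())

            def rotate(pos: int) -> None:
                seq[pos] = ord(_ROTATE[chr(seq[pos])])

            for exon_idx in (2, 3) if locus in ("A", "B", "C") else (2,):
                s, e = spans[("exon", exon_idx)]
                elen = e - s
                step = max((elen - 4) // 6, 1)
                for b in range(6):
                    if spec.pattern >> b & 1:
                        rotate(s + 2 + b * step)
            if spec.extra_snp == "exon1":
                s, e = spans[("exon", 1)]
                rotate(s + min(5, e - s - 1))
            elif spec.extra_snp == "intron2":
                s, e = spans[("intron", 2)]
                rotate((s + e) // 2)

            features = tuple(
                Feature(kind, index, a, b)
                for (kind, index), (a, b) in sorted(spans.items(), key=lambda kv: kv[1])
                if kind != "flank"
            )
            records.append(
                AlleleRecord(parse_allele_name(spec.name), seq.decode(), features)
            )

    db = AlleleDatabase(records)

    primers: list[Primer] = []
    for group, (fwd_site, rev_site) in group_sites.items():
        fwd = list(fwd_site)
        if group == "DRB":  # exercise a degenerate base in the shared set
            fwd[9] = _DEGENERATE[fwd[9]]
        primers.append(Primer(f"{group}-F", group, "forward", "".join(fwd)))
        primers.append(Primer(f"{group}-R", group, "reverse", reverse_complement(rev_site)))

    amplicons = predict_amplicons(primers, db)
    intervals: dict[str, tuple[int, int]] = {}
    for amp in amplicons:
        key = str(amp.allele)
        if key in intervals:
            raise AssertionError(f"multiple amplicons predicted for {key}")
        intervals[key] = (amp.start, amp.end)
    missing = set(db.records) - set(intervals)
    if missing:
        raise AssertionError(f"no amplicon predicted for {sorted(missing)}")
    db.set_amplicon_intervals(intervals)
    return db, primers


def toy_amplicons(scale: float = 0.1) -> list[Amplicon]:
    db, primers = toy_reference(scale)
    return predict_amplicons(primers, db)


def plant_substitution(
    db: AlleleDatabase,
    allele: str | AlleleName,
    kind: str = "exon",
    index: int = 4,
    offset: int | None = None,
) -> tuple[AlleleDatabase, int, str, str]:
    """Return a copy of the database where one allele carries a single
    substitution inside the named feature — a template for simulating a
    sample whose true allele is absent from the reference.

    Returns (mutated database, position, ref base, alt base).
    """
    rec = db[str(allele)]
    feat = rec.feature(kind, index)
    pos = feat.start + (offset if offset is not None else (feat.end - feat.start) // 2)
    if not feat.start <= pos < feat.end:
        raise ValueError("offset outside the feature")
    ref = rec.sequence[pos]
    alt = _ROTATE[ref]
    new_seq = rec.sequence[:pos] + alt + rec.sequence[pos + 1 :]
    new_records = [
        AlleleRecord(r.name, new_seq, r.features) if str(r.name) == str(allele) else r
        for r in db
    ]
    new_db = AlleleDatabase(new_records)
    if db.has_amplicon_intervals:
        new_db.set_amplicon_intervals(
            {name: db.amplicon_interval(name) for name in new_db.records}
        )
    return new_db, pos, ref, alt


# -- panel ------------------------------------------------------------------


def make_barcodes(n: int, length: int = 10, min_dist: int = 3, seed: int = 7) -> list[str]:
    """Deterministic barcode set with pairwise Hamming distance >= min_dist."""
    rng = np.random.default_rng(seed)
    barcodes: list[str] = []
    while len(barcodes) < n:
        cand = _random_bases(rng, length)
        if all(sum(a != b for a, b in zip(cand, bc)) >= min_dist for bc in barcodes):
            barcodes.append(cand)
    return barcodes


def panel_genotypes(
    db: AlleleDatabase, n_samples: int, rng: np.random.Generator
) -> dict[str, dict[str, tuple[AlleleName, ...]]]:
    """Draw a reference-panel genotype per sample: two alleles per diploid
    locus, DRB3/4/5 content derived from the DRB1 draw via the toy
    haplotype linkage."""
    genotypes: dict[str, dict[str, tuple[AlleleName, ...]]] = {}
    pools = {
        locus: sorted(db.locus_alleles(locus))
        for locus in ("A", "B", "C", "DRB1", "DQB1", "DPB1")
    }
    for i in range(n_samples):
        sample = f"S{i + 1:02d}"
        genotype: dict[str, tuple[AlleleName, ...]] = {}
        for locus in ("A", "B", "C", "DQB1", "DPB1"):
            pair = rng.choice(pools[locus], size=2, replace=True)
            genotype[locus] = tuple(parse_allele_name(a) for a in pair)
        drb1 = rng.choice(pools["DRB1"], size=2, replace=True)
        genotype["DRB1"] = tuple(parse_allele_name(a) for a in drb1)
        paralogs: dict[str, list[AlleleName]] = {}
        for a in drb1:
            linked = TOY_LINKAGE[str(a)]
            if linked is not None:
                name = parse_allele_name(linked)
                paralogs.setdefault(name.locus, []).append(name)
        for locus, alleles in paralogs.items():
            genotype[locus] = tuple(alleles)
        genotypes[sample] = genotype
    return genotypes


def panel_config(
    db: AlleleDatabase,
    n_samples: int = 46,
    seed: int = 0,
    reads_per_sample: int = 12000,
    skew: float | None = None,
    read_profile: Mapping[str, float | int] | None = None,
    locus_weights: Mapping[str, float] | None = None,
) -> SimConfig:
    """Assemble a multi-sample panel simulation configuration.

    With ``skew=None`` each sample-locus draws a realistic allelic-balance
    ratio near 0.9; passing a float forces that skew everywhere.  The
    default read profile is the fast-scale one; pass an empty mapping to
    use the full-length defaults.
    """
    rng = np.random.default_rng(seed)
    genotypes = panel_genotypes(db, n_samples, rng)
    barcodes = dict(zip(genotypes, make_barcodes(n_samples)))
    if skew is None:
        allelic_skew: float | dict[tuple[str, str], float] = {
            (sample, locus): float(np.clip(rng.normal(0.92, 0.08), 0.3, 1.0))
            for sample, genotype in genotypes.items()
            for locus in genotype
        }
    else:
        allelic_skew = float(skew)
    profile = FAST_READ_PROFILE if read_profile is None else read_profile
    return SimConfig(
        genotypes=genotypes,
        barcodes=barcodes,
        reads_per_sample=reads_per_sample,
        locus_weights=dict(locus_weights or DEFAULT_LOCUS_WEIGHTS),
        allelic_skew=allelic_skew,
        seed=int(rng.integers(0, 2**31 - 1)),
        **profile,
    )
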