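"""Demultiplexing, quality trimming, and run statistics.

Reads are binned by their per-read barcode tag, 3' ends are trimmed where
qualities fall below the QV threshold (the maximal all-low-quality
suffix is stripped), and per-sample / overall run statistics are computed
over the retained reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class Read(NamedTuple):
    """One read; quality is kept Sanger+33 encoded alongside the sequence."""

    id: str
    seq: str
    qual: str


@dataclass
class ReadBatch:
    """Demultiplexed reads for one sample."""

    sample: str
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class RunStats:
    """Run statistics over retained reads: read count, total bases, mean
    QV over all bases, mean read length, and the modal read length (None
    when there are no reads)."""

    n_reads: int
    total_bases: int
    mean_qv: float
    mean_length: float
    mode_length: int | None


def parse_fastq(path) -> list[Read]:
    with open(path) as fh:
        return [Read(rid.split()[0], seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[Read],
    barcode_map: Mapping[str, str],
    max_mismatches: int = 0,
) -> tuple[dict[str, ReadBatch], list[Read]]:
    """Bin reads by their leading barcode tag.

    Each read goes to the unique barcode within ``max_mismatches`` of its
    prefix (the tag is stripped from sequence and qualities); reads
    matching no barcode, or more than one, land in the unassigned bin.
    Assigned + unassigned always equals the input count.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode map")
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ValueError("barcodes must all have the same length")
    blen = lengths.pop() if lengths else 0

    exact = {b: s for s, b in barcode_map.items()}
    batches = {s: ReadBatch(s) for s in barcode_map}
    unassigned: list[Read] = []
    for read in reads:
        tag = read.seq[:blen]
        sample = exact.get(tag)
        if sample is None and max_mismatches > 0:
            hits = [s for s, b in barcode_map.items() if _hamming(tag, b) <= max_mismatches]
            sample = hits[0] if len(hits) == 1 else None
        if sample is None:
            unassigned.append(read)
        else:
            batches[sample].reads.append(
                Read(read.id, read.seq[blen:], read.qual[blen:])
            )
    return batches, unassigned


def quality_trim(
    read: Read,
    qv_threshold: int = 10,
    min_length: int = 50,
    trim_5prime: bool = False,
) -> Read | None:
    """Strip the maximal 3' suffix in which every base has QV below the
    threshold; return None (discard) if fewer than ``min_length`` bases
    remain.  Optionally apply the same rule to the 5' end."""
    if qv_threshold < 0:
        raise ValueError("qv_threshold must be >= 0")
    cutoff = chr(qv_threshold + 33)
    end = len(read.qual)
    while end > 0 and read.qual[end - 1] < cutoff:
        end -= 1
    start = 0
    if trim_5prime:
        while start < end and read.qual[start] < cutoff:
            start += 1
    if end - start < min_length:
        return None
    if start == 0 and end == len(read.qual):
        return read
    return Read(read.id, read.seq[start:end], read.qual[start:end])


def trim_batch(
    batch: ReadBatch, qv_threshold: int = 10, min_length: int = 50
) -> ReadBatch:
    kept = []
    for read in batch.reads:
        trimmed = quality_trim(read, qv_threshold, min_length)
        if trimmed is not None:
            kept.append(trimmed)
    return ReadBatch(batch.sample, kept)


def _stats_of(reads: list[Read]) -> RunStats:
    if not reads:
        return RunStats(0, 0, 0.0, 0.0, None)
    lengths = [len(r.seq) for r in reads]
    total = sum(lengths)
    quals = np.frombuffer("".join(r.qual for r in reads).encode(), dtype=np.uint8)
    mean_qv = float(quals.mean()) - 33.0
    counts = Counter(lengths)
    top = max(counts.values())
    # deterministic tie-break: the longest of the equally common lengths
    mode = max(l for l, c in counts.items() if c == top)
    return RunStats(len(reads), total, mean_qv, total / len(reads), mode)


def run_statistics(
    batches: Mapping[str, ReadBatch] | Iterable[ReadBatch],
) -> tuple[dict[str, RunStats], RunStats]:
    """Per-sample and overall run statistics over retained reads."""
    if isinstance(batches, Mapping):
        batch_list = list(batches.values())
    else:
        batch_list = list(batches)
    per_sample = {b.sample: _stats_of(b.reads) for b in batch_list}
    all_reads = [r for b in batch_list for r in b.reads]
    return per_sample, _stats_of(all_reads)
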