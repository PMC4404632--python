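"""Depth and uniformity statistics for amplicon genotyping QC.

Average depth is mean redundancy per nucleotide site over the genotyped
exon region; the allelic depth ratio is the smaller average depth over
the larger (1.0 by convention for homozygotes); locus depth is the sum
of the two allele depths.  Normalized variants rescale a sample's depth
to a reference draft-read count so samples with different read yields
are comparable.  A ratio below 0.2 is flagged as excessive allelic
imbalance; 0.2-0.5 as (tolerable) imbalance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_db import AlleleRecord

#: reference draft-read count used for depth normalization when none is
#: supplied (a typical per-sample yield of a pooled 46-sample run).
DEFAULT_REFERENCE_READS = 114882

EXCESSIVE_IMBALANCE_THRESHOLD = 0.2
IMBALANCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class DepthProfile:
    """Per-site read depth of one allele over a region (intervals are
    0-based half-open on the allele sequence, concatenated in order)."""

    allele: str
    region: tuple[tuple[int, int], ...]
    depths: np.ndarray

    @property
    def average(self) -> float:
        return float(self.depths.mean()) if self.depths.size else 0.0


def per_site_depth(
    record: AlleleRecord,
    placements: Iterable,
    region: Sequence[tuple[int, int]],
) -> DepthProfile:
    """Depth at every site of ``region`` from read placements on the allele.

    ``placements`` yields objects (or tuples) with ``start``/``end``
    attributes or ``[start, end]`` items, allele coordinates, half-open.
    """
    region = tuple((int(s), int(e)) for s, e in region)
    if not region or any(e <= s for s, e in region):
        raise ValueError("region must be non-empty intervals")
    n = len(record.sequence)
    for s, e in region:
        if not (0 <= s < e <= n):
            raise ValueError(f"region interval [{s},{e}) outside allele bounds")

    starts, ends = [], []
    for p in placements:
        if hasattr(p, "start"):
            starts.append(p.start)
            ends.append(p.end)
        else:
            starts.append(p[0])
            ends.append(p[1])
    starts_arr = np.asarray(starts, dtype=np.int64)
    ends_arr = np.asarray(ends, dtype=np.int64)

    chunks = []
    for s, e in region:
        diff = np.zeros(e - s + 1, dtype=np.int64)
        if starts_arr.size:
            lo = np.clip(starts_arr, s, e) - s
            hi = np.clip(ends_arr, s, e) - s
            keep = hi > lo
            np.add.at(diff, lo[keep], 1)
            np.add.at(diff, hi[keep], -1)
        chunks.append(np.cumsum(diff[:-1]))
    return DepthProfile(str(record.name), region, np.concatenate(chunks))


def depth_ratio(d1: float, d2: float) -> float:
    """Smaller average depth over the larger; raises if both are zero."""
    if d1 < 0 or d2 < 0:
        raise ValueError("depths must be non-negative")
    hi = max(d1, d2)
    if hi == 0:
        raise ValueError("depth ratio undefined when both depths are zero")
    return min(d1, d2) / hi


def locus_depth(d1: float, d2: float) -> float:
    """Sum of the average depths of both alleles."""
    return d1 + d2


def normalize_depth(
    observed: float, sample_draft_reads: int, reference_reads: int = DEFAULT_REFERENCE_READS
) -> float:
    """Rescale an observed depth to the reference draft-read count."""
    if sample_draft_reads <= 0:
        raise ValueError("sample_draft_reads must be positive")
    return observed * reference_reads / sample_draft_reads


def flag_imbalance(ratio: float) -> set[str]:
    """QC flags for an allelic depth ratio: <0.2 excessive, 0.2-0.5
    imbalanced, above 0.5 none."""
    if not 0 <= ratio <= 1:
        raise ValueError(f"ratio must be in [0,1], got {ratio}")
    if ratio < EXCESSIVE_IMBALANCE_THRESHOLD:
        return {"excessive_imbalance"}
    if ratio <= IMBALANCE_THRESHOLD:
        return {"imbalanced"}
    return set()


def run_capacity(total_reads: int, reads_per_sample: int) -> int:
    """How many samples a run's read yield could have served."""
    if total_reads <= 0 or reads_per_sample <= 0:
        raise ValueError("total_reads and reads_per_sample must be positive")
    return math.floor(total_reads / reads_per_sample)


def locus_balance_table(
    calls: Iterable,
    run_stats: Mapping[str, "RunStats"] | Mapping[str, int] | None = None,
    reference_reads: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample-locus depth table and per-locus summary.

    ``calls`` yields genotype calls carrying ``sample``, ``locus`` and a
    ``metrics`` record with the two allele depths.  ``run_stats`` maps
    sample -> RunStats (or draft read count) for normalization; the
    reference count defaults to the mean draft reads across samples.
    Returns (row table, per-locus summary with observed and normalized
    mean +/- SD columns); the row table doubles as plot data for a locus
    balance plot (sample, locus, normalized locus depth).
    """
    drafts: dict[str, int] = {}
    if run_stats:
        for sample, st in run_stats.items():
            drafts[sample] = int(getattr(st, "n_reads", st))
    if reference_reads is None:
        reference_reads = (
            int(round(np.mean(list(drafts.values())))) if drafts else DEFAULT_REFERENCE_READS
        )

    rows = []
    for call in calls:
        m = call.metrics
        if m is None:
            continue
        draft = drafts.get(call.sample)
        scale = reference_reads / draft if draft else np.nan
        rows.append(
            {
                "sample": call.sample,
                "locus": call.locus,
                "depth_allele1": m.depth1,
                "depth_allele2": m.depth2,
                "depth_ratio": m.ratio,
                "locus_depth": m.locus_depth,
                "norm_depth_allele1": m.depth1 * scale,
                "norm_depth_allele2": m.depth2 * scale,
                "norm_locus_depth": m.locus_depth * scale,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample",
            "locus",
            "depth_allele1",
            "depth_allele2",
            "depth_ratio",
            "locus_depth",
            "norm_depth_allele1",
            "norm_depth_allele2",
            "norm_locus_depth",
        ],
    )

    summaries = []
    for locus, grp in table.groupby("locus", sort=True):
        allele_depths = pd.concat([grp["depth_allele1"], grp["depth_allele2"]])
        norm_allele_depths = pd.concat(
            [grp["norm_depth_allele1"], grp["norm_depth_allele2"]]
        )
        summaries.append(
            {
                "locus": locus,
                "n": len(grp),
                "allele_depth_mean": allele_depths.mean(),
                "allele_depth_sd": allele_depths.std(ddof=1) if len(allele_depths) > 1 else 0.0,
                "norm_allele_depth_mean": norm_allele_depths.mean(),
                "norm_allele_depth_sd": norm_allele_depths.std(ddof=1) if len(norm_allele_depths) > 1 else 0.0,
                "ratio_mean": grp["depth_ratio"].mean(),
                "ratio_sd": grp["depth_ratio"].std(ddof=1) if len(grp) > 1 else 0.0,
                "locus_depth_mean": grp["locus_depth"].mean(),
                "locus_depth_sd": grp["locus_depth"].std(ddof=1) if len(grp) > 1 else 0.0,
                "norm_locus_depth_mean": grp["norm_locus_depth"].mean(),
                "norm_locus_depth_sd": grp["norm_locus_depth"].std(ddof=1) if len(grp) > 1 else 0.0,
            }
        )
    summary = pd.DataFrame(summaries)
    return table, summary
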