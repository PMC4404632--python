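"""End-to-end orchestration: demultiplex -> trim -> type -> validate.

Ties the modules together for a whole multi-sample run and collects the
per-sample-locus genotype rows, novel-variant findings, DRB linkage
findings, and run statistics into one result object that the CLI (and
the tests) render to tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .allele_db import AlleleDatabase, SUPPORTED_LOCI, render_allele_set
from .drb_haplotype import DRLinkageTable, Finding, validate_sample
from .genotyping import (
    GenotypeCall,
    NovelVariant,
    TypingParams,
    call_genotype,
    detect_novel_variant,
    perfect_match_map,
    select_candidates,
)
from .metrics import locus_balance_table
from .readqc import Read, ReadBatch, RunStats, demultiplex, run_statistics, trim_batch


@dataclass
class QCParams:
    qv_threshold: int = 10
    min_length: int = 50
    barcode_mismatches: int = 1


@dataclass
class PipelineResult:
    calls: list[GenotypeCall]
    novel_variants: list[tuple[str, NovelVariant]]
    findings: list[Finding]
    sample_stats: dict[str, RunStats]
    overall_stats: RunStats
    n_unassigned: int = 0

    @property
    def n_no_calls(self) -> int:
        return sum(1 for c in self.calls if c.is_no_call)

    def genotype_table(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "sample": c.sample,
                    "locus": c.locus,
                    "allele_1": render_allele_set(c.allele1) if c.allele1 else "",
                    "allele_2": render_allele_set(c.allele2) if c.allele2 else "",
                    "depth_allele1": c.metrics.depth1 if c.metrics else 0.0,
                    "depth_allele2": c.metrics.depth2 if c.metrics else 0.0,
                    "depth_ratio": c.metrics.ratio if c.metrics else "",
                    "locus_depth": c.metrics.locus_depth if c.metrics else 0.0,
                    "flags": ";".join(sorted(c.flags)),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sample",
                "locus",
                "allele_1",
                "allele_2",
                "depth_allele1",
                "depth_allele2",
                "depth_ratio",
                "locus_depth",
                "flags",
            ],
        )

    def metrics_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return locus_balance_table(
            [c for c in self.calls if not c.is_no_call], self.sample_stats
        )

    def findings_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sample": f.sample, "kind": f.kind, "severity": f.severity, "detail": f.message}
                for f in self.findings
            ],
            columns=["sample", "kind", "severity", "detail"],
        )

    def novel_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": s,
                    "allele": v.allele,
                    "position": v.position,
                    "ref": v.ref,
                    "alt": v.alt,
                    "support": v.support,
                    "coverage": v.coverage,
                }
                for s, v in self.novel_variants
            ],
            columns=["sample", "allele", "position", "ref", "alt", "support", "coverage"],
        )


def type_batches(
    batches: Mapping[str, ReadBatch],
    db: AlleleDatabase,
    params: TypingParams | None = None,
    linkage: DRLinkageTable | None = None,
    loci: Sequence[str] | None = None,
    trimmed: bool = True,
) -> PipelineResult:
    """Type already-demultiplexed (and optionally already-trimmed) batches.

    One genotype row is emitted per sample and reported locus, no_call
    rows included, so the report shape is independent of the genotypes.
    """
    params = params or TypingParams()
    report_loci = [l for l in (loci or SUPPORTED_LOCI) if db.by_locus.get(l)]

    calls: list[GenotypeCall] = []
    novel: list[tuple[str, NovelVariant]] = []
    findings: list[Finding] = []

    for sample in sorted(batches):
        batch = batches[sample]
        candidates = select_candidates(
            batch, db, k=params.k, top_n=params.top_n,
            max_reads=params.candidate_max_reads,
        )
        mapping = perfect_match_map(batch, candidates, db, k=params.k)
        sample_calls = []
        for locus in report_loci:
            call = call_genotype(sample, locus, mapping, db, params)
            sample_calls.append(call)
            if not call.is_no_call:
                for v in detect_novel_variant(
                    call, mapping, db, params.novel_min_fraction, params.novel_min_reads
                ):
                    novel.append((sample, v))
        drb1 = next(
            (c for c in sample_calls if c.locus == "DRB1" and not c.is_no_call), None
        )
        if drb1 is not None:
            sample_findings = validate_sample(sample_calls, linkage)
            if any(f.severity == "inconsistent" for f in sample_findings):
                drb1.flags.add("paralog_inconsistent")
            findings.extend(sample_findings)
        calls.extend(sample_calls)

    sample_stats, overall = run_statistics(batches)
    return PipelineResult(calls, novel, findings, sample_stats, overall)


def run_pipeline(
    reads: Iterable[Read],
    barcode_map: Mapping[str, str],
    db: AlleleDatabase,
    params: TypingParams | None = None,
    qc: QCParams | None = None,
    linkage: DRLinkageTable | None = None,
    loci: Sequence[str] | None = None,
) -> PipelineResult:
    """Full run from pooled barcoded reads to genotype calls."""
    qc = qc or QCParams()
    raw_batches, unassigned = demultiplex(reads, barcode_map, qc.barcode_mismatches)
    batches = {
        s: trim_batch(b, qc.qv_threshold, qc.min_length) for s, b in raw_batches.items()
    }
    result = type_batches(batches, db, params, linkage, loci)
    result.n_unassigned = len(unassigned)
    return result
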