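"""Truth-scoring helpers for simulated runs.

Scores pipeline calls against a simulation truth table at the field-3
level: a called ambiguity set matches when it contains the true allele
(alleles identical over the amplified region are legitimately
indistinguishable), and a hemizygous DRB3/4/5 locus matches when both
call slots carry its single allele.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .allele_db import AlleleDatabase, AlleleName, truncate_to_field
from .genotyping import GenotypeCall, TypingParams
from .insilico_pcr import Primer, SimConfig, simulate_reads
from .pipeline import PipelineResult, QCParams, run_pipeline
from .readqc import Read


def _set3(names) -> set[str]:
    return {str(truncate_to_field(n, 3)) for n in names}


def call_matches_truth(call: GenotypeCall, truth: Sequence[AlleleName] | None) -> bool:
    """Field-3 match of one call against the simulated truth genotype.

    ``truth`` is the tuple of 1-2 true alleles, or None for a locus absent
    from the sample (must be a no_call).
    """
    if truth is None:
        return call.is_no_call
    if call.is_no_call:
        return False
    assert call.allele1 is not None and call.allele2 is not None
    s1, s2 = _set3(call.allele1), _set3(call.allele2)
    t = [str(truncate_to_field(a, 3)) for a in truth]
    if len(t) == 1:
        return t[0] in s1 and t[0] in s2
    return (t[0] in s1 and t[1] in s2) or (t[0] in s2 and t[1] in s1)


def score_roundtrip(
    config: SimConfig,
    db: AlleleDatabase,
    primers: Sequence[Primer],
    params: TypingParams | None = None,
    qc: QCParams | None = None,
) -> tuple[int, int, PipelineResult]:
    """Simulate a run, type it, and score every simulated sample-locus.

    Returns (matching, total, pipeline result); only loci present in the
    simulated genotypes are scored.
    """
    run = simulate_reads(config, db, primers)
    reads = [Read(r.read_id, r.sequence, r.quality) for r in run.reads]
    result = run_pipeline(reads, config.barcodes, db, params, qc)
    by_key: Mapping[tuple[str, str], GenotypeCall] = {
        (c.sample, c.locus): c for c in result.calls
    }
    n_match = n_total = 0
    for sample, genotype in config.genotypes.items():
        for locus, truth in genotype.items():
            n_total += 1
            call = by_key.get((sample, locus))
            if call is not None and call_matches_truth(call, truth):
                n_match += 1
    return n_match, n_total, result
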