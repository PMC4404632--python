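"""DRB1-DRB3/4/5 haplotype linkage.

The DRB paralog genes segregate with DRB1 serogroups: DR52-group DRB1
alleles (DR3/5/6 families, first fields 03/11/12/13/14) carry a DRB3
gene on the same haplotype, DR53-group alleles (04/07/09) carry DRB4,
DR51-group alleles (15/16) carry DRB5, and DR1/DR8/DR10 haplotypes
(01/08/10) carry none.  This module encodes that structure, bundles an
observed haplotype reference table, and validates per-sample genotype
calls against it: a DRB1 call implies the presence (or absence) of the
matching paralog locus call.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple

from .allele_db import (
    AlleleName,
    DRB_PARALOG_LOCI,
    parse_allele_set,
    render_allele_set,
)

#: DRB1 first field -> serological DR group
SEROGROUP_OF_FAMILY = {
    "03": "DR52", "11": "DR52", "12": "DR52", "13": "DR52", "14": "DR52",
    "04": "DR53", "07": "DR53", "09": "DR53",
    "15": "DR51", "16": "DR51",
    "01": None, "08": None, "10": None,
}

#: DR group -> paralog locus carried on the haplotype
GROUP_PARALOG = {"DR52": "DRB3", "DR53": "DRB4", "DR51": "DRB5"}


class HaplotypeCounts(NamedTuple):
    n_drb3: int
    n_drb4: int
    n_drb5: int
    total: int


@dataclass(frozen=True)
class LinkageRow:
    """One observed DRB1 - DRB3/4/5 haplotype with its sample count."""

    dr_group: str
    drb1: tuple[AlleleName, ...]  # ambiguity set as observed
    paralog: AlleleName
    count: int

    @property
    def drb1_label(self) -> str:
        return render_allele_set(self.drb1)


@dataclass
class DRLinkageTable:
    rows: list[LinkageRow]

    def paralogs_for(self, drb1: AlleleName) -> list[AlleleName]:
        """Observed paralog alleles for a DRB1 allele (empty if absent)."""
        hits = []
        for row in self.rows:
            if drb1 in row.drb1:
                hits.append(row.paralog)
        return hits


def load_linkage_fixture(path=None) -> DRLinkageTable:
    """Load the bundled observed-haplotype reference table (or a user
    table with the same columns)."""
    if path is None:
        source = resources.files("multihla.data").joinpath("drb_linkage.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    required = {"dr_group", "drb1_allele", "paralog_allele", "observed_count"}
    if required - set(reader.fieldnames or ()):
        raise ValueError("linkage table missing required columns")
    rows = []
    for rec in reader:
        drb1 = parse_allele_set(rec["drb1_allele"])
        paralog = parse_allele_set(rec["paralog_allele"])[0]
        group = rec["dr_group"]
        if GROUP_PARALOG.get(group) != paralog.locus:
            raise ValueError(
                f"linkage table corrupted: {group} row carries {paralog.locus}"
            )
        rows.append(LinkageRow(group, drb1, paralog, int(rec["observed_count"])))
    return DRLinkageTable(rows)


def expected_paralog(drb1_allele: AlleleName) -> str | None:
    """The paralog locus a DRB1 allele's haplotype carries, or None.

    Resolved by the DRB1 first-field serogroup rule; a family outside the
    encoded table is treated as carrying no paralog.
    """
    if drb1_allele.locus != "DRB1":
        raise ValueError(f"expected a DRB1 allele, got {drb1_allele}")
    group = SEROGROUP_OF_FAMILY.get(drb1_allele.first_field)
    return GROUP_PARALOG[group] if group else None


@dataclass(frozen=True)
class Finding:
    sample: str
    kind: str  # "paralog_missing" | "unexpected_paralog" | "paralog_allele_info"
    severity: str  # "inconsistent" | "info"
    message: str


def validate_sample(
    calls: Iterable, linkage: DRLinkageTable | None = None
) -> list[Finding]:
    """Check one sample's DRB1 call against its DRB3/4/5 calls.

    Every DRB1 allele whose serogroup implies a paralog locus must have a
    call at that locus, and no paralog locus may carry a call that no
    DRB1 allele explains.  When a reference linkage table is given, the
    observed paralog allele identity is compared informationally (locus
    presence, not allele identity, is the consistency criterion).
    Ambiguity sets validate through their shared first-field family.
    """
    calls = list(calls)
    drb1_call = next(
        (c for c in calls if c.locus == "DRB1" and not c.is_no_call), None
    )
    if drb1_call is None:
        raise ValueError("sample has no DRB1 call to validate against")
    sample = drb1_call.sample

    paralog_calls = {
        c.locus: c
        for c in calls
        if c.locus in DRB_PARALOG_LOCI and not c.is_no_call
    }

    findings: list[Finding] = []
    expected_loci: set[str] = set()
    for allele_set in (drb1_call.allele1, drb1_call.allele2):
        rep = allele_set[0]  # members of a set share the first-field family
        locus = expected_paralog(rep)
        if locus is None:
            continue
        expected_loci.add(locus)
        if locus not in paralog_calls:
            findings.append(
                Finding(
                    sample,
                    "paralog_missing",
                    "inconsistent",
                    f"DRB1 allele {render_allele_set(allele_set)} implies a "
                    f"{locus} gene but no {locus} call is present",
                )
            )
            continue
        if linkage is not None:
            expected_alleles = {
                a for member in allele_set for a in linkage.paralogs_for(member)
            }
            observed = set(paralog_calls[locus].allele1) | set(
                paralog_calls[locus].allele2
            )
            if expected_alleles and not (expected_alleles & observed):
                findings.append(
                    Finding(
                        sample,
                        "paralog_allele_info",
                        "info",
                        f"{locus} call {render_allele_set(observed)} differs from "
                        f"the haplotypes reported for DRB1 "
                        f"{render_allele_set(allele_set)} "
                        f"({render_allele_set(expected_alleles)})",
                    )
                )

    for locus, call in sorted(paralog_calls.items()):
        if locus not in expected_loci:
            findings.append(
                Finding(
                    sample,
                    "unexpected_paralog",
                    "inconsistent",
                    f"{locus} call {render_allele_set(set(call.allele1) | set(call.allele2))} "
                    f"has no DRB1 haplotype that carries it",
                )
            )
    return findings


def count_haplotypes(table: DRLinkageTable) -> HaplotypeCounts:
    """Distinct (DRB1, paralog allele) pairs per paralog locus."""
    distinct: dict[str, set[tuple[str, str]]] = {l: set() for l in ("DRB3", "DRB4", "DRB5")}
    for row in table.rows:
        distinct[row.paralog.locus].add((row.drb1_label, str(row.paralog)))
    n3, n4, n5 = (len(distinct[l]) for l in ("DRB3", "DRB4", "DRB5"))
    return HaplotypeCounts(n3, n4, n5, n3 + n4 + n5)
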