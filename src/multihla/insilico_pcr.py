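"""In-silico multiplex PCR and amplicon read simulation.

Predicts primer-delimited amplicons from IUPAC primer sets, renders a
virtual gel (amplicons of similar size co-migrate into one band), and
simulates barcoded Ion-Torrent-like reads: fragments drawn uniformly from
each sample's amplicons with locus-level amplification skew and per-locus
allelic imbalance, substitution and homopolymer-length errors, a
left-skewed read-length distribution, and Sanger+33 qualities where
errored bases carry low QVs.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from Bio.Data.IUPACData import ambiguous_dna_values

from .allele_db import AlleleDatabase, AlleleName

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass(frozen=True)
class Primer:
    """One PCR primer: IUPAC sequence, owning primer group ("locus"), and
    orientation.  The DRB primer group is shared across DRB1/3/4/5."""

    name: str
    locus: str
    orientation: str  # "forward" | "reverse"
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"primer {self.name}: empty sequence")
        bad = set(self.sequence.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"primer {self.name}: non-IUPAC characters {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class Amplicon:
    """A primer-delimited subsequence of one allele (0-based half-open)."""

    locus: str
    allele: AlleleName
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GelBand:
    """One electrophoresis band: amplicons within the gel's resolution
    co-migrate and merge, pooling their loci."""

    lane: str
    size: int
    loci: frozenset[str]


def _iupac_pattern(seq: str) -> re.Pattern:
    parts = []
    for base in seq.upper():
        values = ambiguous_dna_values[base]
        parts.append(base if len(values) == 1 else "[" + values + "]")
    # lookahead so overlapping sites are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def find_primer_sites(primer: Primer, template: str) -> list[tuple[int, str]]:
    """All exact IUPAC-compatible matches of the primer on both strands.

    A ``+`` hit at position p means the primer sequence matches
    ``template[p:p+len]``; a ``-`` hit means its reverse complement does
    (i.e. the primer anneals to the plus strand pointing leftwards).
    """
    if not template:
        raise ValueError("empty template")
    template = template.upper()
    sites = [(m.start(), "+") for m in _iupac_pattern(primer.sequence).finditer(template)]
    sites += [
        (m.start(), "-")
        for m in _iupac_pattern(reverse_complement(primer.sequence)).finditer(template)
    ]
    return sorted(sites)


def predict_amplicons(
    primers: Sequence[Primer], db: AlleleDatabase, max_product: int | None = None
) -> list[Amplicon]:
    """Predict every convergent forward/reverse primer-pair product on every
    allele of the database.

    Each primer group ("locus" column) needs at least one forward and one
    reverse primer; a group that yields no product on any allele triggers a
    warning, not an error.  The amplicon locus is the template allele's
    locus (the DRB group amplifies all four DRB paralogs).
    """
    groups: dict[str, list[Primer]] = {}
    for p in primers:
        groups.setdefault(p.locus, []).append(p)
    for label, members in groups.items():
        orientations = {p.orientation for p in members}
        if orientations != {"forward", "reverse"}:
            raise ValueError(
                f"primer group {label!r} needs >=1 forward and >=1 reverse primer"
            )

    amplicons: list[Amplicon] = []
    productive: set[str] = set()
    for rec in db:
        template = rec.sequence
        for label, members in groups.items():
            fwd_sites: list[tuple[int, int]] = []  # (start, primer length)
            rev_sites: list[tuple[int, int]] = []  # (end, primer length)
            for p in members:
                for pos, strand in find_primer_sites(p, template):
                    if p.orientation == "forward" and strand == "+":
                        fwd_sites.append((pos, len(p.sequence)))
                    elif p.orientation == "reverse" and strand == "-":
                        rev_sites.append((pos + len(p.sequence), len(p.sequence)))
            seen: set[tuple[int, int]] = set()
            for fstart, flen in fwd_sites:
                for rend, rlen in rev_sites:
                    if rend - fstart < flen + rlen:
                        continue  # not convergent / primers overlap
                    if max_product is not None and rend - fstart > max_product:
                        continue
                    if (fstart, rend) in seen:
                        continue
                    seen.add((fstart, rend))
                    amplicons.append(
                        Amplicon(rec.name.locus, rec.name, fstart, rend)
                    )
                    productive.add(label)
    for label in sorted(set(groups) - productive):
        warnings.warn(f"primer group {label!r} produced no amplicon on any allele")
    return amplicons


def virtual_gel(amplicons: Iterable[Amplicon], resolution_bp: int, lane: str = "") -> list[GelBand]:
    """Merge amplicons whose sizes differ by <= resolution into bands.

    Single-linkage on sorted sizes, so a chain of close sizes forms one
    band, mirroring overlapping products on an agarose gel.  Bands are
    returned largest first; band size is the mean of its member sizes.
    """
    if resolution_bp <= 0:
        raise ValueError("resolution_bp must be positive")
    items = sorted(amplicons, key=lambda a: -a.length)
    bands: list[GelBand] = []
    cluster: list[Amplicon] = []
    for amp in items:
        if cluster and cluster[-1].length - amp.length > resolution_bp:
            bands.append(_band(lane, cluster))
            cluster = []
        cluster.append(amp)
    if cluster:
        bands.append(_band(lane, cluster))
    return bands


def _band(lane: str, members: list[Amplicon]) -> GelBand:
    size = int(round(sum(a.length for a in members) / len(members)))
    return GelBand(lane, size, frozenset(a.locus for a in members))


# -- read-length model ------------------------------------------------------


@lru_cache(maxsize=8)
def _standard_skewnorm_mode(shape: float) -> float:
    res = optimize.minimize_scalar(
        lambda x: -stats.skewnorm.pdf(x, shape), bounds=(-4, 4), method="bounded"
    )
    return float(res.x)


@lru_cache(maxsize=32)
def read_length_pmf(
    mean: float, mode: float, lmin: int, lmax: int, shape: float = -4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete truncated skew-normal read-length distribution.

    Calibrated so the truncated distribution has the requested mean and its
    peak sits at the requested mode — the left-skewed shape of Ion Torrent
    400-bp chemistry read lengths (long left tail of short reads, peak near
    the chemistry limit).  Requires lmin < mean < mode < lmax; if
    mean >= mode the model degrades to a truncated normal.
    """
    lengths = np.arange(lmin, lmax + 1)
    if mean >= mode:
        pdf = stats.norm.pdf(lengths, loc=mean, scale=(lmax - lmin) / 6)
        return lengths, pdf / pdf.sum()
    if not (lmin < mean < mode < lmax):
        raise ValueError("need lmin < mean < mode < lmax")
    m0 = _standard_skewnorm_mode(shape)

    def truncated_mean(scale: float) -> float:
        loc = mode - scale * m0
        pdf = stats.skewnorm.pdf(lengths, shape, loc=loc, scale=scale)
        pdf = pdf / pdf.sum()
        return float(np.dot(lengths, pdf))

    # small scale -> mean ~= mode (too high); large scale -> near-flat
    # over [lmin, lmax] (mean near the midpoint).  Bracket and solve.
    lo, hi = 1.0, 4.0 * (lmax - lmin)
    scale = optimize.brentq(lambda s: truncated_mean(s) - mean, lo, hi)
    loc = mode - scale * m0
    pdf = stats.skewnorm.pdf(lengths, shape, loc=loc, scale=scale)
    return lengths, pdf / pdf.sum()


# -- simulation -------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for one simulated multiplex run.

    ``genotypes`` maps sample -> locus -> tuple of 1 or 2 allele names
    (one allele for a hemizygous DRB3/4/5 locus).  ``locus_weights`` are
    relative amplification efficiencies; a hemizygous locus contributes
    half its weight (one template copy).  ``allelic_skew`` is the expected
    low/high depth ratio per sample-locus (1.0 = balanced); which allele is
    the major one is drawn at random.  Defaults emulate the Ion PGM 400-bp
    regime: mean read length ~273, mode ~359, substitution errors plus
    per-homopolymer-run +/-1 length errors.
    """

    genotypes: dict[str, dict[str, tuple[AlleleName, ...]]]
    barcodes: dict[str, str]
    reads_per_sample: int | Mapping[str, int] = 10000
    locus_weights: Mapping[str, float] = field(default_factory=dict)
    allelic_skew: float | Mapping[tuple[str, str], float] = 1.0
    read_length_mean: float = 273.3
    read_length_mode: float = 358.6
    read_length_min: int = 25
    read_length_max: int = 400
    substitution_rate: float = 0.002
    homopolymer_indel_rate: float = 0.005
    base_quality: int = 31
    error_quality: int = 8
    tail_prob: float = 0.12
    tail_quality: int = 6
    tail_mean: float = 8.0
    seed: int = 0

    def n_reads(self, sample: str) -> int:
        if isinstance(self.reads_per_sample, Mapping):
            n = int(self.reads_per_sample[sample])
        else:
            n = int(self.reads_per_sample)
        if n <= 0:
            raise SimulationConfigError(f"reads_per_sample must be > 0 for {sample}")
        return n

    def skew(self, sample: str, locus: str) -> float:
        if isinstance(self.allelic_skew, Mapping):
            s = float(self.allelic_skew.get((sample, locus), 1.0))
        else:
            s = float(self.allelic_skew)
        if not 0 < s <= 1:
            raise SimulationConfigError(f"allelic skew must be in (0,1], got {s}")
        return s


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str  # Sanger +33 encoded


@dataclass
class SimulatedRun:
    """Simulator output: pooled barcoded reads plus a per-read truth table
    (sample, locus, allele, fragment coordinates on the allele, strand)."""

    reads: list[SimulatedRead]
    truth: "pd.DataFrame"

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _homopolymer_run_starts(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    starts = np.flatnonzero(np.diff(arr) != 0) + 1
    return np.concatenate(([0], starts))


_ROTATE = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}


def simulate_reads(
    config: SimConfig, db: AlleleDatabase, primers: Sequence[Primer]
) -> SimulatedRun:
    """Simulate one pooled, barcoded multiplex sequencing run.

    Reads are drawn per sample from its predicted amplicons: locus chosen
    with probability proportional to locus weight, split between the two
    alleles by the configured skew, fragment start uniform over the
    amplicon with edge truncation, either strand.  Substitution and
    homopolymer-length errors are applied with low QVs at errored bases;
    an error-free run yields exact amplicon substrings.  Identical seeds
    give byte-identical output.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)

    # resolve one amplicon per genotype allele (the longest if several)
    all_amplicons = predict_amplicons(primers, db)
    by_allele: dict[str, Amplicon] = {}
    for amp in all_amplicons:
        key = str(amp.allele)
        if key not in by_allele or amp.length > by_allele[key].length:
            by_allele[key] = amp

    lengths, probs = read_length_pmf(
        config.read_length_mean,
        config.read_length_mode,
        config.read_length_min,
        config.read_length_max,
    )

    # per-amplicon homopolymer-run starts, for exact per-fragment run counts
    run_starts: dict[str, np.ndarray] = {}

    reads: list[SimulatedRead] = []
    truth_rows: list[tuple] = []

    for sample in config.genotypes:
        barcode = config.barcodes[sample]
        genotype = config.genotypes[sample]
        for locus, alleles in genotype.items():
            for a in alleles:
                if a not in db:
                    raise SimulationConfigError(
                        f"genotype allele {a} of sample {sample} not in database"
                    )
                if str(a) not in by_allele:
                    raise SimulationConfigError(
                        f"no amplicon predicted for genotype allele {a}"
                    )

        loci = sorted(genotype)
        weights = np.array(
            [
                float(config.locus_weights.get(l, 1.0))
                * (0.5 if len(genotype[l]) == 1 else 1.0)
                for l in loci
            ]
        )
        if np.any(weights <= 0):
            raise SimulationConfigError("locus weights must be positive")
        n_total = config.n_reads(sample)
        locus_counts = rng.multinomial(n_total, weights / weights.sum())

        serial = 0
        for locus, n_locus in zip(loci, locus_counts):
            alleles = genotype[locus]
            if len(alleles) == 1:
                allele_counts = [(alleles[0], n_locus)]
            else:
                skew = config.skew(sample, locus)
                p_major = 1.0 / (1.0 + skew)
                major = int(rng.integers(2))
                n_major = int(rng.binomial(n_locus, p_major))
                counts = [0, 0]
                counts[major] = n_major
                counts[1 - major] = n_locus - n_major
                allele_counts = list(zip(alleles, counts))

            for allele, n_allele in allele_counts:
                if n_allele == 0:
                    continue
                amp = by_allele[str(allele)]
                template = db[allele].sequence[amp.start : amp.end]
                L = len(template)
                key = str(allele)
                if key not in run_starts:
                    run_starts[key] = _homopolymer_run_starts(template)
                starts_arr = run_starts[key]

                max_start = max(1, L - config.read_length_min)
                frag_start = rng.integers(0, max_start, size=n_allele)
                frag_len = rng.choice(lengths, size=n_allele, p=probs)
                frag_end = np.minimum(frag_start + frag_len, L)
                strands = rng.integers(0, 2, size=n_allele)
                # exact homopolymer-run counts per fragment
                n_runs = (
                    np.searchsorted(starts_arr, frag_end, side="left")
                    - np.searchsorted(starts_arr, frag_start, side="right")
                    + 1
                )
                n_indels = rng.binomial(n_runs, config.homopolymer_indel_rate)
                n_subs = rng.binomial(frag_end - frag_start, config.substitution_rate)
                has_tail = rng.random(n_allele) < config.tail_prob
                tail_lens = rng.geometric(1.0 / config.tail_mean, size=n_allele)
                base_quals = rng.integers(
                    config.base_quality - 2, config.base_quality + 3, size=n_allele
                )

                for i in range(n_allele):
                    s, e = int(frag_start[i]), int(frag_end[i])
                    frag = template[s:e]
                    err_pos: set[int] = set()

                    if n_indels[i]:
                        frag, moved = _apply_homopolymer_indels(
                            frag, int(n_indels[i]), rng
                        )
                        err_pos.update(moved)
                    if n_subs[i]:
                        frag = _apply_substitutions(
                            frag, int(n_subs[i]), rng, err_pos
                        )

                    n = len(frag)
                    if strands[i]:
                        frag = reverse_complement(frag)
                        err_pos = {n - 1 - p for p in err_pos}
                        strand = "-"
                    else:
                        strand = "+"

                    qual = [int(base_quals[i])] * n
                    for p in err_pos:
                        if 0 <= p < n:
                            qual[p] = config.error_quality
                    if has_tail[i]:
                        t = min(int(tail_lens[i]), n // 3)
                        for p in range(n - t, n):
                            qual[p] = config.tail_quality
                    qual_str = "".join(chr(q + 33) for q in qual)

                    read_id = f"{sample}.{serial:06d}"
                    serial += 1
                    reads.append(
                        SimulatedRead(
                            read_id,
                            barcode + frag,
                            "I" * len(barcode) + qual_str,
                        )
                    )
                    truth_rows.append(
                        (
                            read_id,
                            sample,
                            locus,
                            str(allele),
                            amp.start + s,
                            amp.start + e,
                            strand,
                        )
                    )

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "locus", "allele", "start", "end", "strand"],
    )
    return SimulatedRun(reads, truth)


def _apply_substitutions(
    frag: str, k: int, rng: np.random.Generator, err_pos: set[int]
) -> str:
    arr = bytearray(frag.encode())
    for p in rng.integers(0, len(arr), size=k):
        p = int(p)
        arr[p] = ord(_ROTATE[chr(arr[p])])
        err_pos.add(p)
    return arr.decode()


def _apply_homopolymer_indels(
    frag: str, k: int, rng: np.random.Generator
) -> tuple[str, set[int]]:
    starts = _homopolymer_run_starts(frag)
    if len(starts) == 0:
        return frag, set()
    chosen = sorted(
        (int(starts[j]) for j in rng.choice(len(starts), size=min(k, len(starts)), replace=False)),
        reverse=True,
    )
    out = frag
    err_pos: set[int] = set()
    for pos in chosen:
        if rng.random() < 0.5 and len(out) > 1:
            out = out[:pos] + out[pos + 1 :]  # -1 contraction
        else:
            out = out[:pos] + out[pos] + out[pos:]  # +1 extension
        err_pos.add(pos)
    return out, err_pos


# -- primer table I/O -------------------------------------------------------

PRIMER_COLUMNS = ("name", "locus", "orientation", "sequence")


def load_primers(path) -> list[Primer]:
    primers = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(PRIMER_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"primer table lacks columns {sorted(missing)}")
        for row in reader:
            primers.append(
                Primer(row["name"], row["locus"], row["orientation"], row["sequence"].upper())
            )
    return primers


def write_primers(primers: Sequence[Primer], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(PRIMER_COLUMNS)
        for p in primers:
            writer.writerow([p.name, p.locus, p.orientation, p.sequence])
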