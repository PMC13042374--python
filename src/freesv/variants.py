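"""Candidate somatic-variant calling and the filter cascade.

Low-pass cfDNA lacks matched germline genotypes, so candidate somatic
variants are screened from pileup evidence alone and then pushed through
a cascade of structural and population filters: substitutions only, on
autosomes, single non-reference allele, detection quality >= 30, no
adjacent candidate, outside blacklisted regions, below the top coverage
quantile, and either rare in population databases (max allele frequency
<= 0.1%) or a known cancer hotspot.

The detection quality is a transparent consensus stand-in: the
phred-scaled binomial tail probability that the alt observations arise
from sequencing error alone at per-base error rate epsilon (each of the
three non-reference bases equally likely), capped at 255.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import BASES
from .io import logger

DEFAULT_ERROR_RATE = 1e-3
QUAL_CAP = 255.0
MIN_QUAL = 30.0
MAX_POP_AF = 0.001
ADJACENCY_WINDOW = 1  # bp; candidates this close are mutually discarded

HUMAN_AUTOSOMES = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
)
MOUSE_AUTOSOMES = frozenset(
    {f"chr{i}" for i in range(1, 20)} | {str(i) for i in range(1, 20)}
)
COVERAGE_QUANTILE_CUT = {"human": 0.01, "mouse": 0.10}


@dataclass
class PileupColumn:
    """Quality-filtered base counts at one 1-based position."""

    chrom: str
    pos: int
    ref_base: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}")
        for base in BASES:
            self.counts.setdefault(base, 0)

    @property
    def depth(self) -> int:
        return sum(self.counts[b] for b in BASES)


@dataclass
class VariantCall:
    """A candidate substitution with quality and filter provenance."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depth: int
    alt_count: int
    n_nonref_alleles: int = 1
    filter_flags: set[str] = field(default_factory=set)
    origin_class: Optional[str] = None  # candidate | CH_derived | tumor_derived | germline

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("alt must differ from ref")
        if self.alt_count > self.depth:
            raise ValueError("alt_count cannot exceed depth")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def passed(self) -> bool:
        return not self.filter_flags


@dataclass
class FilterResources:
    """Static inputs to the filter cascade."""

    blacklist: Sequence[tuple[str, int, int]] = ()  # 0-based half-open
    population_af: Mapping[tuple[str, int, str], float] = field(default_factory=dict)
    cosmic_set: frozenset = frozenset()  # {(chrom, pos1, alt)}
    coverage_quantile_cut: float = 0.01
    autosomes: frozenset = HUMAN_AUTOSOMES

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage_quantile_cut < 1.0:
            raise ValueError("coverage_quantile_cut must lie in (0, 1)")

    @classmethod
    def for_species(cls, species: str, **kwargs) -> "FilterResources":
        if species == "human":
            return cls(coverage_quantile_cut=COVERAGE_QUANTILE_CUT["human"],
                       autosomes=HUMAN_AUTOSOMES, **kwargs)
        if species == "mouse":
            return cls(coverage_quantile_cut=COVERAGE_QUANTILE_CUT["mouse"],
                       autosomes=MOUSE_AUTOSOMES, **kwargs)
        raise ValueError("species must be 'human' or 'mouse'")

    def in_blacklist(self, chrom: str, pos1: int) -> bool:
        pos0 = pos1 - 1
        return any(c == chrom and s <= pos0 < e for c, s, e in self.blacklist)

    def max_population_af(self, chrom: str, pos1: int, alt: str) -> float:
        return float(self.population_af.get((chrom, pos1, alt), 0.0))


def error_qual(alt_count: int, depth: int, error_rate: float = DEFAULT_ERROR_RATE) -> float:
    """Phred score of P(>= alt_count errors | depth, per-base error rate).

    Any specific miscalled base occurs at rate ``error_rate / 3``.
    """
    if alt_count <= 0:
        return 0.0
    tail = float(stats.binom.sf(alt_count - 1, depth, error_rate / 3.0))
    if tail <= 0.0:
        return QUAL_CAP
    return min(QUAL_CAP, -10.0 * np.log10(tail))


def _eligible_alts(column: PileupColumn, mode: str) -> list[str]:
    """Non-reference bases observable as alt alleles in this mode.

    In EM-seq data, unmethylated cytosines read as thymines, so T at a
    reference-C column is uninformative; the reverse-strand mirror (A at
    a reference-G column) is excluded symmetrically.
    """
    alts = [b for b in BASES if b != column.ref_base and column.counts[b] > 0]
    if mode == "emseq":
        if column.ref_base == "C":
            alts = [b for b in alts if b != "T"]
        elif column.ref_base == "G":
            alts = [b for b in alts if b != "A"]
    return alts


MIN_CALL_DEPTH = 4


def call_candidates(
    columns: Iterable[PileupColumn],
    mode: str = "wgs",
    error_rate: float = DEFAULT_ERROR_RATE,
    min_depth: int = MIN_CALL_DEPTH,
) -> list[VariantCall]:
    """Emit one candidate per column whose top non-reference allele has
    any support; the caller records how many distinct non-reference
    alleles were seen so the cascade can discard multi-allelic loci.

    Columns below ``min_depth`` are not called: the binomial error score
    degenerates at very small depth (a single mismatch over one or two
    observations is formally improbable as error), so a depth floor
    guards against promoting isolated errors at pile edges.  Columns
    must arrive sorted by (chrom, pos); zero-depth columns are skipped.
    """
    if mode not in {"wgs", "emseq"}:
        raise ValueError("mode must be 'wgs' or 'emseq'")
    calls: list[VariantCall] = []
    last: Optional[tuple[str, int]] = None
    seen_chroms: set[str] = set()
    for col in columns:
        key = (col.chrom, col.pos)
        if last is not None:
            if col.chrom == last[0] and col.pos <= last[1]:
                raise ValueError(f"pileup columns not sorted at {col.chrom}:{col.pos}")
            if col.chrom != last[0] and col.chrom in seen_chroms:
                raise ValueError(f"pileup columns not sorted at {col.chrom}:{col.pos}")
        seen_chroms.add(col.chrom)
        last = key
        if col.depth < max(min_depth, 1):
            continue
        alts = _eligible_alts(col, mode)
        if not alts:
            continue
        alt = max(alts, key=lambda b: (col.counts[b], b))
        calls.append(
            VariantCall(
                chrom=col.chrom,
                pos=col.pos,
                ref=col.ref_base,
                alt=alt,
                qual=error_qual(col.counts[alt], col.depth, error_rate),
                depth=col.depth,
                alt_count=col.counts[alt],
                n_nonref_alleles=len(alts),
                origin_class="candidate",
            )
        )
    return calls


def apply_filter_cascade(
    calls: Sequence[VariantCall],
    resources: FilterResources,
    coverage_by_locus: Mapping[tuple[str, int], int],
    adjacency_window: int = ADJACENCY_WINDOW,
    min_qual: float = MIN_QUAL,
    max_pop_af: float = MAX_POP_AF,
    cosmic_rescue: bool = True,
) -> list[VariantCall]:
    """Annotate every call with the filters it fails; returns all calls.

    Retained calls (empty ``filter_flags``) satisfy every filter.  Flags
    are computed independently per filter, so application order cannot
    change the outcome.  The coverage cut removes calls at loci whose
    coverage lies strictly above the (1 - coverage_quantile_cut) quantile
    of candidate-locus coverages.  COSMIC membership rescues a call from
    the population-AF filter only.
    """
    for call in calls:
        if (call.chrom, call.pos) not in coverage_by_locus:
            raise KeyError(f"no coverage for call locus {call.chrom}:{call.pos}")

    coverages = np.array(
        [coverage_by_locus[(c.chrom, c.pos)] for c in calls], dtype=float
    )
    cov_cut = (
        np.quantile(coverages, 1.0 - resources.coverage_quantile_cut)
        if len(coverages)
        else np.inf
    )

    positions_by_chrom: dict[str, list[int]] = {}
    for call in calls:
        positions_by_chrom.setdefault(call.chrom, []).append(call.pos)
    for chrom_positions in positions_by_chrom.values():
        chrom_positions.sort()

    out: list[VariantCall] = []
    for call in calls:
        flags: set[str] = set()
        if not call.is_snv:
            flags.add("indel")
        if call.chrom not in resources.autosomes:
            flags.add("non_autosome")
        if call.n_nonref_alleles > 1:
            flags.add("multiallelic")
        if call.qual < min_qual:
            flags.add("low_qual")
        if _has_neighbor(positions_by_chrom[call.chrom], call.pos, adjacency_window):
            flags.add("continuous")
        if resources.in_blacklist(call.chrom, call.pos):
            flags.add("blacklist")
        if coverage_by_locus[(call.chrom, call.pos)] > cov_cut:
            flags.add("high_coverage")
        af = resources.max_population_af(call.chrom, call.pos, call.alt)
        in_cosmic = (call.chrom, call.pos, call.alt) in resources.cosmic_set
        if af > max_pop_af and not (cosmic_rescue and in_cosmic):
            flags.add("common_polymorphism")
        annotated = VariantCall(
            chrom=call.chrom,
            pos=call.pos,
            ref=call.ref,
            alt=call.alt,
            qual=call.qual,
            depth=call.depth,
            alt_count=call.alt_count,
            n_nonref_alleles=call.n_nonref_alleles,
            filter_flags=flags,
            origin_class=call.origin_class,
        )
        out.append(annotated)
    return out


def retained(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Calls that passed every filter."""
    return [c for c in calls if c.passed]


def _has_neighbor(sorted_positions: list[int], pos: int, window: int) -> bool:
    idx = bisect_left(sorted_positions, pos)
    if idx > 0 and pos - sorted_positions[idx - 1] <= window:
        return True
    if idx + 1 < len(sorted_positions) and sorted_positions[idx + 1] - pos <= window:
        return True
    return False


# ---------------------------------------------------------------------------
# origin classification with paired genotypes
# ---------------------------------------------------------------------------

MIN_PAIRED_COVERAGE = 30
MIN_MINOR_READS = 3
MIN_PBMC_ONLY_COVERAGE = 300
PBMC_ONLY_MAF_RANGE = (0.02, 0.30)


def _major_minor(column: PileupColumn) -> tuple[str, str, int, int]:
    ranked = sorted(BASES, key=lambda b: (column.counts[b], b), reverse=True)
    major, minor = ranked[0], ranked[1]
    return major, minor, column.counts[major], column.counts[minor]


def classify_paired(
    pbmc: Mapping[tuple[str, int], PileupColumn],
    tumor: Mapping[tuple[str, int], PileupColumn],
    min_coverage: int = MIN_PAIRED_COVERAGE,
    min_minor_reads: int = MIN_MINOR_READS,
) -> list[VariantCall]:
    """Classify variant origin from paired PBMC and tumor pileups.

    Clonal-hematopoiesis-derived: PBMC heterozygous (minor allele
    supported by >= 3 reads) while the tumor is homozygous; the minor
    allele is the variant and the major allele germline.  Tumor-derived:
    the mirror case.  Loci present in only one map are skipped (counted
    in the log); loci heterozygous in both or homozygous in both are left
    unclassified.
    """
    out: list[VariantCall] = []
    skipped = 0
    for key in sorted(set(pbmc) | set(tumor)):
        if key not in pbmc or key not in tumor:
            skipped += 1
            continue
        p_col, t_col = pbmc[key], tumor[key]
        if p_col.depth < min_coverage or t_col.depth < min_coverage:
            continue
        p_major, p_minor, _, p_minor_n = _major_minor(p_col)
        t_major, t_minor, _, t_minor_n = _major_minor(t_col)
        p_het = p_minor_n >= min_minor_reads
        t_het = t_minor_n >= min_minor_reads
        chrom, pos = key
        if p_het and not t_het:
            out.append(VariantCall(chrom, pos, ref=p_major, alt=p_minor,
                                   qual=QUAL_CAP, depth=p_col.depth,
                                   alt_count=p_minor_n, origin_class="CH_derived"))
        elif t_het and not p_het:
            out.append(VariantCall(chrom, pos, ref=t_major, alt=t_minor,
                                   qual=QUAL_CAP, depth=t_col.depth,
                                   alt_count=t_minor_n, origin_class="tumor_derived"))
    if skipped:
        logger.warning("classify_paired: %d loci present in one sample only", skipped)
    return out


def classify_pbmc_only(
    pbmc: Mapping[tuple[str, int], PileupColumn],
    min_coverage: int = MIN_PBMC_ONLY_COVERAGE,
    maf_range: tuple[float, float] = PBMC_ONLY_MAF_RANGE,
) -> list[VariantCall]:
    """Classify clonal-hematopoiesis variants from deep PBMC pileups alone.

    At >= 300-fold coverage germline heterozygotes sit near 50% minor
    allele frequency; minor alleles in the 2-30% band are attributed to
    clonal hematopoiesis, with the major allele germline.
    """
    lo, hi = maf_range
    out: list[VariantCall] = []
    for key in sorted(pbmc):
        col = pbmc[key]
        if col.depth < min_coverage:
            continue
        major, minor, _, minor_n = _major_minor(col)
        if minor_n == 0:
            continue
        maf = minor_n / col.depth
        if lo <= maf <= hi:
            chrom, pos = key
            out.append(VariantCall(chrom, pos, ref=major, alt=minor,
                                   qual=QUAL_CAP, depth=col.depth,
                                   alt_count=minor_n, origin_class="CH_derived"))
    return out


# ---------------------------------------------------------------------------
# pileup construction from fragments
# ---------------------------------------------------------------------------

def pileup_from_fragments(
    fragments: Iterable,
    reference,
    min_baseq: int = 30,
    min_mapq: int = 60,
) -> tuple[list[PileupColumn], dict[tuple[str, int], int]]:
    """Tally fragment base observations into sorted pileup columns.

    Fragment records carry explicit base calls only where they differ
    from (or were genotyped against) the reference; every other
    overlapping fragment implicitly reports the reference base.  Column
    depth therefore equals fragment coverage: explicit observations plus
    implicit reference support.  Returns the columns (1-based positions,
    only positions with at least one explicit observation) together with
    fragment coverage at each column locus — the coverage input the
    filter cascade expects.
    """
    counts: dict[tuple[str, int], dict[str, int]] = {}
    explicit: dict[tuple[str, int], int] = {}
    frags = list(fragments)
    for frag in frags:
        if frag.mapq < min_mapq:
            continue
        for pos0, base, qual in frag.base_calls:
            key = (frag.chrom, pos0)
            explicit[key] = explicit.get(key, 0) + 1
            if qual < min_baseq or base == "N":
                continue
            counts.setdefault(key, {b: 0 for b in BASES})[base] += 1

    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {c for c, _ in counts}:
        s = sorted(f.interval.start for f in frags if f.chrom == chrom)
        e = sorted(f.interval.end for f in frags if f.chrom == chrom)
        starts[chrom] = np.array(s, dtype=np.int64)
        ends[chrom] = np.array(e, dtype=np.int64)

    columns: list[PileupColumn] = []
    coverage: dict[tuple[str, int], int] = {}
    for (chrom, pos0) in sorted(counts):
        ref_base = reference.base(chrom, pos0)
        if ref_base == "N":
            continue
        base_counts = dict(counts[(chrom, pos0)])
        n_started = int(np.searchsorted(starts[chrom], pos0, side="right"))
        n_ended = int(np.searchsorted(ends[chrom], pos0, side="right"))
        cov = n_started - n_ended
        implicit_ref = max(cov - explicit[(chrom, pos0)], 0)
        base_counts[ref_base] = base_counts.get(ref_base, 0) + implicit_ref
        columns.append(PileupColumn(chrom, pos0 + 1, ref_base, base_counts))
        coverage[(chrom, pos0 + 1)] = cov
    return columns, coverage
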