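"""Allele-aware fragmentomic statistics: Mut-DNA versus Wt-DNA.

Fragments overlapping retained variant loci are split by the allele they
carry — Mut-DNA (variant allele) versus Wt-DNA (reference allele) — and
each class is summarized by: the fraction of short fragments (<= 150
bp), 5'-end 4-mer motif usage (with the CCCA fraction singled out),
breakpoint 4-mer usage spanning the cut site (2 bases outside + 2
inside; CT-5'-CC singled out), normalized motif diversity (Shannon
entropy over the 256 motifs scaled to [0, 1]), the E-index (mean
occurrence of the sample's end positions in a healthy-control panel end
model), and the percentage of ends within ±50 bp of nucleosome centers.
Per-sample contrasts are always reported as Mut minus Wt.

Both fragment termini are treated orientation-aware: the upstream (U)
end is read on the forward strand and the downstream (D) end on the
reverse strand, so each fragment contributes two 5'->3' motifs.  Motifs
are looked up in the reference genome at the fragment coordinates
rather than taken from read bases, which keeps them immune to
sequencing errors and to enzymatic C-to-T conversion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import FragmentRecord, ReferenceGenome, revcomp
from .io import logger
from .variants import VariantCall

SHORT_FRAGMENT_MAX = 150  # bp, inclusive
NUCLEOSOME_HALF_WINDOW = 50  # bp, inclusive
MOTIF_K = 4

#: All 256 4-mers in lexicographic order.
MOTIFS_256: tuple[str, ...] = tuple(
    "".join(m) for m in product("ACGT", repeat=MOTIF_K)
)
_MOTIF_INDEX = {m: i for i, m in enumerate(MOTIFS_256)}


@dataclass
class AllelePartition:
    """Fragments split by carried allele at retained variant loci."""

    mut_fragments: list[FragmentRecord]
    wt_fragments: list[FragmentRecord]
    excluded_multi: int = 0
    excluded_other: int = 0  # no usable base call, or a third allele

    def __post_init__(self) -> None:
        mut_ids = {id(f) for f in self.mut_fragments}
        if any(id(f) in mut_ids for f in self.wt_fragments):
            raise ValueError("a fragment cannot be both Mut and Wt")


@dataclass
class EndModel:
    """Panel-derived counts of fragment end positions (E-index reference)."""

    u_counts: Mapping[tuple[str, int], int]
    d_counts: Mapping[tuple[str, int], int]

    @property
    def total_panel_ends(self) -> int:
        return sum(self.u_counts.values()) + sum(self.d_counts.values())

    @property
    def scale(self) -> float:
        """Ends-per-million normalizer."""
        total = self.total_panel_ends
        return 1e6 / total if total else 0.0

    def to_tsv(self, path) -> None:
        rows = []
        for (chrom, pos), n in self.u_counts.items():
            rows.append((chrom, pos, n, 0))
        for (chrom, pos), n in self.d_counts.items():
            rows.append((chrom, pos, 0, n))
        merged: dict[tuple[str, int], list[int]] = {}
        for chrom, pos, u, d in rows:
            entry = merged.setdefault((chrom, pos), [0, 0])
            entry[0] += u
            entry[1] += d
        with open(path, "w") as handle:
            handle.write("chrom\tpos0\tu_count\td_count\n")
            for (chrom, pos) in sorted(merged):
                u, d = merged[(chrom, pos)]
                handle.write(f"{chrom}\t{pos}\t{u}\t{d}\n")

    @classmethod
    def from_tsv(cls, path) -> "EndModel":
        u: dict[tuple[str, int], int] = {}
        d: dict[tuple[str, int], int] = {}
        with open(path) as handle:
            header = handle.readline()
            if not header.startswith("chrom"):
                raise ValueError(f"{path}: missing end-model header")
            for line in handle:
                chrom, pos, un, dn = line.rstrip("\n").split("\t")
                key = (chrom, int(pos))
                if int(un):
                    u[key] = u.get(key, 0) + int(un)
                if int(dn):
                    d[key] = d.get(key, 0) + int(dn)
        return cls(u, d)


@dataclass
class FragmentomicSummary:
    """Per-class (Mut or Wt) fragmentomic feature set for one sample."""

    n: int
    frac_short: Optional[float] = None
    end_motif_freqs: Optional[np.ndarray] = None
    frac_ccca: Optional[float] = None
    breakpoint_motif_freqs: Optional[np.ndarray] = None
    frac_ctcc: Optional[float] = None
    mds_end: Optional[float] = None
    mds_breakpoint: Optional[float] = None
    e_index: Optional[float] = None
    frac_ends_in_nucleosome: Optional[float] = None  # percentage 0-100


@dataclass
class DiffFeatures:
    """Mut-minus-Wt contrasts; None marks an undefined entry."""

    diff_size: Optional[float] = None
    diff_ccca: Optional[float] = None
    diff_ctcc: Optional[float] = None
    diff_nucleosome: Optional[float] = None
    diff_methylation: Optional[float] = None

    FIELDS = ("diff_size", "diff_ccca", "diff_ctcc", "diff_nucleosome",
              "diff_methylation")

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in self.FIELDS}


# ---------------------------------------------------------------------------
# allele partition
# ---------------------------------------------------------------------------

def partition_by_allele(
    fragments: Iterable[FragmentRecord],
    loci: Sequence[VariantCall],
) -> AllelePartition:
    """Split fragments into Mut-DNA / Wt-DNA at retained variant loci.

    A fragment overlapping two or more variant loci is excluded (counted
    in ``excluded_multi``); a fragment with no usable base observation at
    its locus, or carrying a third allele, is dropped (counted in
    ``excluded_other``).
    """
    by_locus = {(c.chrom, c.pos - 1): c for c in loci}
    positions: dict[str, np.ndarray] = {}
    for chrom in {c.chrom for c in loci}:
        positions[chrom] = np.array(
            sorted(c.pos - 1 for c in loci if c.chrom == chrom), dtype=np.int64
        )

    mut: list[FragmentRecord] = []
    wt: list[FragmentRecord] = []
    excluded_multi = 0
    excluded_other = 0
    for frag in fragments:
        pos_arr = positions.get(frag.chrom)
        if pos_arr is None:
            continue
        lo = int(np.searchsorted(pos_arr, frag.interval.start, side="left"))
        hi = int(np.searchsorted(pos_arr, frag.interval.end, side="left"))
        overlapped = pos_arr[lo:hi]
        if len(overlapped) == 0:
            continue
        if len(overlapped) > 1:
            excluded_multi += 1
            continue
        locus = by_locus[(frag.chrom, int(overlapped[0]))]
        observed = frag.base_at(int(overlapped[0]))
        if observed is None:
            excluded_other += 1
            continue
        base, _ = observed
        if base == locus.alt:
            mut.append(frag)
        elif base == locus.ref:
            wt.append(frag)
        else:
            excluded_other += 1
    if excluded_other:
        logger.debug("partition_by_allele: dropped %d fragments without a "
                     "usable ref/alt observation", excluded_other)
    return AllelePartition(mut, wt, excluded_multi, excluded_other)


# ---------------------------------------------------------------------------
# size
# ---------------------------------------------------------------------------

def frac_short(
    fragments: Sequence[FragmentRecord],
    max_length: int = SHORT_FRAGMENT_MAX,
) -> Optional[float]:
    """Fraction of fragments with length <= 150 bp; None on an empty set."""
    if not fragments:
        return None
    short = sum(1 for f in fragments if f.length <= max_length)
    return short / len(fragments)


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def _fragment_end_motifs(
    frag: FragmentRecord, reference: ReferenceGenome
) -> list[str]:
    """The two 5'-end 4-mers of a fragment (U forward, D reverse strand)."""
    motifs = []
    chrom_len = reference.chrom_length(frag.chrom)
    u = frag.u_end
    if u + MOTIF_K <= chrom_len:
        motifs.append(reference.fetch(frag.chrom, u, u + MOTIF_K))
    d = frag.d_end
    if d - MOTIF_K + 1 >= 0:
        motifs.append(revcomp(reference.fetch(frag.chrom, d - MOTIF_K + 1, d + 1)))
    return motifs


def _fragment_breakpoint_motifs(
    frag: FragmentRecord, reference: ReferenceGenome
) -> list[str]:
    """Breakpoint 4-mers: 2 reference bases outside + first 2 inside, per end."""
    motifs = []
    chrom_len = reference.chrom_length(frag.chrom)
    u = frag.u_end
    if u - 2 >= 0 and u + 2 <= chrom_len:
        motifs.append(reference.fetch(frag.chrom, u - 2, u + 2))
    d = frag.d_end
    if d - 1 >= 0 and d + 3 <= chrom_len:
        motifs.append(revcomp(reference.fetch(frag.chrom, d - 1, d + 3)))
    return motifs


def _normalize_motif_counts(counts: Counter) -> tuple[Optional[np.ndarray], int]:
    vec = np.zeros(256)
    total = 0
    for motif, n in counts.items():
        idx = _MOTIF_INDEX.get(motif)
        if idx is not None:  # motifs containing N are not representable
            vec[idx] += n
            total += n
    if total == 0:
        return None, 0
    return vec / total, total


def end_motifs(
    fragments: Sequence[FragmentRecord],
    reference: ReferenceGenome,
) -> tuple[Optional[np.ndarray], Optional[float]]:
    """5'-end 4-mer frequency vector (256) and the CCCA fraction.

    Each fragment contributes its U-end motif on the forward strand and
    its D-end motif on the reverse strand; termini too close to a contig
    edge are skipped.
    """
    counts: Counter = Counter()
    skipped = 0
    for frag in fragments:
        motifs = _fragment_end_motifs(frag, reference)
        skipped += 2 - len(motifs)
        counts.update(motifs)
    if skipped:
        logger.debug("end_motifs: skipped %d termini at contig edges", skipped)
    vec, total = _normalize_motif_counts(counts)
    if vec is None:
        return None, None
    return vec, float(vec[_MOTIF_INDEX["CCCA"]])


def breakpoint_motifs(
    fragments: Sequence[FragmentRecord],
    reference: ReferenceGenome,
) -> tuple[Optional[np.ndarray], Optional[float]]:
    """Breakpoint 4-mer frequency vector (256) and the CTCC fraction.

    The CTCC entry encodes the CT-5'-CC configuration: genomic CT just
    before the cut, fragment CC just after.
    """
    counts: Counter = Counter()
    skipped = 0
    for frag in fragments:
        motifs = _fragment_breakpoint_motifs(frag, reference)
        skipped += 2 - len(motifs)
        counts.update(motifs)
    if skipped:
        logger.debug("breakpoint_motifs: skipped %d termini at contig edges", skipped)
    vec, total = _normalize_motif_counts(counts)
    if vec is None:
        return None, None
    return vec, float(vec[_MOTIF_INDEX["CTCC"]])


def motif_diversity(motif_freqs: np.ndarray) -> float:
    """Normalized Shannon entropy of a 256-motif distribution.

    1 means maximal randomness (uniform usage), 0 means a single motif;
    0·ln 0 is taken as 0.
    """
    p = np.asarray(motif_freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("motif frequencies must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("motif frequencies must sum to 1")
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return entropy / np.log(256.0)


# ---------------------------------------------------------------------------
# end model and E-index
# ---------------------------------------------------------------------------

def build_end_model(panel_fragments: Iterable[FragmentRecord]) -> EndModel:
    """Tally U and D end positions of a healthy-control panel."""
    u: Counter = Counter()
    d: Counter = Counter()
    n = 0
    for frag in panel_fragments:
        u[(frag.chrom, frag.u_end)] += 1
        d[(frag.chrom, frag.d_end)] += 1
        n += 1
    if n == 0:
        raise ValueError("panel is empty")
    return EndModel(dict(u), dict(d))


def e_index(
    fragments: Sequence[FragmentRecord],
    model: EndModel,
    normalized: bool = True,
) -> Optional[float]:
    """Mean panel support of the sample's fragment end positions.

    For each fragment, look up how often its U end and its D end occur
    as U and D ends in the panel model and sum the two counts; the
    E-index is the mean over fragments.  With ``normalized`` (default)
    panel counts are scaled to ends-per-million so values are comparable
    across panels of different depth; the raw-count variant is the
    formula as printed in the field's literature.
    """
    if not fragments:
        return None
    scale = model.scale if normalized else 1.0
    total = 0.0
    for frag in fragments:
        mu = model.u_counts.get((frag.chrom, frag.u_end), 0)
        md = model.d_counts.get((frag.chrom, frag.d_end), 0)
        total += scale * (mu + md)
    return total / len(fragments)


# ---------------------------------------------------------------------------
# nucleosome context
# ---------------------------------------------------------------------------

def _nearest_center(centers: np.ndarray, pos: int) -> int:
    """Nearest nucleosome center; ties break toward the smaller coordinate."""
    idx = int(np.searchsorted(centers, pos))
    candidates = []
    if idx > 0:
        candidates.append(int(centers[idx - 1]))
    if idx < len(centers):
        candidates.append(int(centers[idx]))
    return min(candidates, key=lambda c: (abs(pos - c), c))


def nucleosome_end_fraction(
    fragments: Sequence[FragmentRecord],
    nucleosome_centers: Mapping[str, np.ndarray],
    half_window: int = NUCLEOSOME_HALF_WINDOW,
) -> tuple[Optional[float], np.ndarray]:
    """Percentage of fragment ends within ±50 bp of a nucleosome center.

    Each fragment contributes both its U and D end.  The distance to the
    nearest center is signed (negative when the end lies upstream of the
    center); the returned profile is the array of signed distances.
    Ends on chromosomes without annotated centers are excluded.
    """
    distances: list[int] = []
    excluded = 0
    for frag in fragments:
        centers = nucleosome_centers.get(frag.chrom)
        if centers is None or len(centers) == 0:
            excluded += 2
            continue
        for end in (frag.u_end, frag.d_end):
            center = _nearest_center(centers, end)
            distances.append(end - center)
    if excluded:
        logger.debug("nucleosome_end_fraction: %d ends on chromosomes "
                     "without centers", excluded)
    dist_arr = np.array(distances, dtype=np.int64)
    if len(dist_arr) == 0:
        return None, dist_arr
    inside = int((np.abs(dist_arr) <= half_window).sum())
    return 100.0 * inside / len(dist_arr), dist_arr


# ---------------------------------------------------------------------------
# contrasts and the per-class summary
# ---------------------------------------------------------------------------

def diff(metric_mut: Optional[float], metric_wt: Optional[float]) -> Optional[float]:
    """Mut minus Wt; None if either side is undefined."""
    if metric_mut is None or metric_wt is None:
        return None
    return metric_mut - metric_wt


def summarize(
    fragments: Sequence[FragmentRecord],
    reference: ReferenceGenome,
    end_model: Optional[EndModel] = None,
    nucleosome_centers: Optional[Mapping[str, np.ndarray]] = None,
) -> FragmentomicSummary:
    """Compute the full fragmentomic feature set for one fragment class."""
    summary = FragmentomicSummary(n=len(fragments))
    if not fragments:
        return summary
    summary.frac_short = frac_short(fragments)
    summary.end_motif_freqs, summary.frac_ccca = end_motifs(fragments, reference)
    summary.breakpoint_motif_freqs, summary.frac_ctcc = breakpoint_motifs(
        fragments, reference
    )
    if summary.end_motif_freqs is not None:
        summary.mds_end = motif_diversity(summary.end_motif_freqs)
    if summary.breakpoint_motif_freqs is not None:
        summary.mds_breakpoint = motif_diversity(summary.breakpoint_motif_freqs)
    if end_model is not None:
        summary.e_index = e_index(fragments, end_model)
    if nucleosome_centers is not None:
        summary.frac_ends_in_nucleosome, _ = nucleosome_end_fraction(
            fragments, nucleosome_centers
        )
    return summary


def diff_features(
    mut: FragmentomicSummary,
    wt: FragmentomicSummary,
    diff_methylation: Optional[float] = None,
) -> DiffFeatures:
    """Assemble the five Mut-minus-Wt contrasts for one sample."""
    return DiffFeatures(
        diff_size=diff(mut.frac_short, wt.frac_short),
        diff_ccca=diff(mut.frac_ccca, wt.frac_ccca),
        diff_ctcc=diff(mut.frac_ctcc, wt.frac_ctcc),
        diff_nucleosome=diff(mut.frac_ends_in_nucleosome, wt.frac_ends_in_nucleosome),
        diff_methylation=diff_methylation,
    )
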