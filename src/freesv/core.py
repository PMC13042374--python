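"""Core domain types shared across the package.

Coordinate conventions
----------------------
Fragment and interval coordinates are 0-based half-open throughout the
library (``start`` inclusive, ``end`` exclusive), matching BED.  The two
single-base fragment termini are exposed as inclusive positions:
``u_end = start`` (upstream end, lower coordinate) and ``d_end = end - 1``
(downstream end, last covered base).  Pileup columns and variant calls use
1-based positions, matching VCF and samtools pileup output; conversion
happens exactly once, at the boundary between the two worlds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N alphabet)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"require start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True if 0-based position ``pos`` lies inside the interval."""
        return self.start <= pos < self.end


@dataclass
class FragmentRecord:
    """One sequenced cfDNA fragment.

    ``base_calls`` holds allele observations as ``(pos0, base, baseq)``
    tuples (0-based genomic position); ``meth_calls`` holds per-CpG
    methylation observations as ``(cpg_pos0, methylated)`` tuples.
    """

    interval: GenomicInterval
    name: str = "."
    mapq: int = 60
    base_calls: list[tuple[int, str, int]] = field(default_factory=list)
    meth_calls: Optional[list[tuple[int, bool]]] = None

    def __post_init__(self) -> None:
        for _, base, qual in self.base_calls:
            if not 0 <= qual <= 60:
                raise ValueError(f"base quality {qual} outside [0, 60]")
            if base not in "ACGTN":
                raise ValueError(f"unexpected base {base!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def u_end(self) -> int:
        """Upstream end: the terminus with the lower genomic coordinate."""
        return self.interval.start

    @property
    def d_end(self) -> int:
        """Downstream end (inclusive): the last covered base."""
        return self.interval.end - 1

    @property
    def length(self) -> int:
        return len(self.interval)

    def base_at(self, pos0: int) -> Optional[tuple[str, int]]:
        """Observed (base, quality) at 0-based position, or None."""
        for pos, base, qual in self.base_calls:
            if pos == pos0:
                return base, qual
        return None


@dataclass
class Gene:
    """Minimal gene annotation: strand-aware TSS plus the gene span."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"
    name: str = "."

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class ReferenceGenome:
    """In-memory reference: per-chromosome sequence plus gene annotation.

    Sequences are plain uppercase strings; for the genome sizes this
    package targets (synthetic chromosomes, small references) this is the
    simplest correct container.  ``from_fasta`` loads an on-disk FASTA via
    pyfaidx.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        genes: Optional[list[Gene]] = None,
    ) -> None:
        self.sequences = {c: s.upper() for c, s in sequences.items()}
        for chrom, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{chrom}: non-ACGTN characters {bad}")
        self.genes = list(genes or [])
        for g in self.genes:
            n = len(self.sequences.get(g.chrom, ""))
            if not 0 <= g.tss < n:
                raise ValueError(f"TSS of {g.name} outside {g.chrom}")

    @classmethod
    def from_fasta(cls, path: str, genes: Optional[list[Gene]] = None):
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()}, genes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open subsequence; raises if out of bounds."""
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(
                f"{chrom}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]

    def base(self, chrom: str, pos0: int) -> str:
        return self.sequences[chrom][pos0]

    def cpg_positions(self, chrom: str) -> list[int]:
        """0-based positions of the C of every CpG dinucleotide."""
        seq = self.sequences[chrom]
        return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def iter_chroms(fragments: Iterable[FragmentRecord]):
    for frag in fragments:
        yield frag.chrom
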