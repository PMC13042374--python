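"""Readers and writers for the external formats the pipeline touches.

Fragments travel as 6-column BED (chrom, start, end, name, mapq, strand)
or as coordinate-sorted BAM/SAM; allele observations and methylation calls
attach to fragments through plain TSV sidecars keyed by fragment name.
Variant calls are emitted as minimal VCF 4.2 with filter labels in the
FILTER column.  All randomness is seeded explicitly.
"""

from __future__ import annotations

import logging
import sys
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .core import FragmentRecord, Gene, GenomicInterval

logger = logging.getLogger("freesv")


def configure_logging(level: int = logging.INFO) -> None:
    """Structured logging to stderr; idempotent."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# fragment I/O
# ---------------------------------------------------------------------------

def read_fragments(
    path: str | Path,
    min_mapq: int = 60,
    known_chroms: Optional[set[str]] = None,
    loci: Optional[Sequence[tuple[str, int]]] = None,
) -> Iterator[FragmentRecord]:
    """Stream fragments from a BED or BAM/SAM file.

    Only fragments with ``mapq >= min_mapq`` are yielded.  BED input is
    read as 0-based half-open.  For BAM/SAM input, proper pairs are
    collapsed to one fragment per template (leftmost mate defines the
    start, template length the size); when ``loci`` (chrom, 0-based pos)
    is given, per-fragment base observations at those positions are
    extracted from the alignments.

    Records on chromosomes absent from ``known_chroms`` (when provided)
    are skipped; the skip count is logged once at the end.
    """
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    path = Path(path)
    if path.suffix.lower() in {".bam", ".sam", ".cram"}:
        yield from _read_fragments_bam(path, min_mapq, known_chroms, loci)
    else:
        yield from _read_fragments_bed(path, min_mapq, known_chroms)


def _read_fragments_bed(
    path: Path, min_mapq: int, known_chroms: Optional[set[str]]
) -> Iterator[FragmentRecord]:
    skipped_chrom = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line {line!r}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if known_chroms is not None and chrom not in known_chroms:
                skipped_chrom += 1
                continue
            name = fields[3] if len(fields) > 3 else f"frag{lineno}"
            mapq = int(fields[4]) if len(fields) > 4 and fields[4] != "." else 60
            if mapq < min_mapq:
                continue
            yield FragmentRecord(GenomicInterval(chrom, start, end), name=name, mapq=mapq)
    if skipped_chrom:
        logger.warning("%s: skipped %d records on unknown chromosomes", path, skipped_chrom)


def _read_fragments_bam(
    path: Path,
    min_mapq: int,
    known_chroms: Optional[set[str]],
    loci: Optional[Sequence[tuple[str, int]]],
) -> Iterator[FragmentRecord]:
    import pysam

    loci_by_chrom: dict[str, set[int]] = {}
    for chrom, pos in loci or []:
        loci_by_chrom.setdefault(chrom, set()).add(pos)

    skipped_chrom = 0
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        # one fragment per template: keep the leftmost mate of each proper
        # pair; template length defines the fragment size (cfDNA convention)
        for read in bam:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
                or read.template_length <= 0
            ):
                continue
            if read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            if known_chroms is not None and chrom not in known_chroms:
                skipped_chrom += 1
                continue
            start = read.reference_start
            end = start + read.template_length
            base_calls: list[tuple[int, str, int]] = []
            wanted = loci_by_chrom.get(chrom)
            if wanted:
                seq = read.query_sequence
                quals = read.query_qualities
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if rpos in wanted:
                        base_calls.append((rpos, seq[qpos], int(quals[qpos])))
            yield FragmentRecord(
                GenomicInterval(chrom, start, end),
                name=read.query_name,
                mapq=read.mapping_quality,
                base_calls=base_calls,
            )
    if skipped_chrom:
        logger.warning("%s: skipped %d reads on unknown chromosomes", path, skipped_chrom)


def write_fragments(path: str | Path, fragments: Iterable[FragmentRecord]) -> int:
    """Write fragments as 6-column BED; returns the number written."""
    n = 0
    with open(path, "w") as handle:
        for frag in fragments:
            handle.write(
                f"{frag.chrom}\t{frag.interval.start}\t{frag.interval.end}"
                f"\t{frag.name}\t{frag.mapq}\t+\n"
            )
            n += 1
    return n


def write_base_call_sidecar(path: str | Path, fragments: Iterable[FragmentRecord]) -> int:
    """TSV sidecar of allele observations: fragment, pos0, base, baseq."""
    n = 0
    with open(path, "w") as handle:
        handle.write("fragment\tpos0\tbase\tbaseq\n")
        for frag in fragments:
            for pos, base, qual in frag.base_calls:
                handle.write(f"{frag.name}\t{pos}\t{base}\t{qual}\n")
                n += 1
    return n


def attach_base_calls(
    fragments: Sequence[FragmentRecord], path: str | Path
) -> int:
    """Attach allele observations from a sidecar TSV, in place.

    Returns the number of observations attached; observations naming an
    unknown fragment are an error (the sidecar must match the BED).
    """
    by_name = {frag.name: frag for frag in fragments}
    n = 0
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("fragment"):
            raise ValueError(f"{path}: missing sidecar header")
        for lineno, line in enumerate(handle, start=2):
            name, pos, base, qual = line.rstrip("\n").split("\t")
            frag = by_name.get(name)
            if frag is None:
                raise ValueError(f"{path}:{lineno}: unknown fragment {name!r}")
            frag.base_calls.append((int(pos), base, int(qual)))
            n += 1
    return n


def write_meth_sidecar(path: str | Path, fragments: Iterable[FragmentRecord]) -> int:
    """TSV sidecar of methylation calls: fragment, cpg_pos0, state (M/U)."""
    n = 0
    with open(path, "w") as handle:
        handle.write("fragment\tcpg_pos0\tstate\n")
        for frag in fragments:
            for pos, methylated in frag.meth_calls or []:
                handle.write(f"{frag.name}\t{pos}\t{'M' if methylated else 'U'}\n")
                n += 1
    return n


def attach_meth_calls(fragments: Sequence[FragmentRecord], path: str | Path) -> int:
    by_name = {frag.name: frag for frag in fragments}
    n = 0
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("fragment"):
            raise ValueError(f"{path}: missing sidecar header")
        for lineno, line in enumerate(handle, start=2):
            name, pos, state = line.rstrip("\n").split("\t")
            frag = by_name.get(name)
            if frag is None:
                raise ValueError(f"{path}:{lineno}: unknown fragment {name!r}")
            if state not in {"M", "U"}:
                raise ValueError(f"{path}:{lineno}: state must be M or U")
            if frag.meth_calls is None:
                frag.meth_calls = []
            frag.meth_calls.append((int(pos), state == "M"))
            n += 1
    return n


# ---------------------------------------------------------------------------
# down-sampling
# ---------------------------------------------------------------------------

def downsample(
    fragments: Sequence[FragmentRecord],
    threshold: int,
    target: int,
    seed: int,
) -> list[FragmentRecord]:
    """Cap library size: samples above ``threshold`` fragments are reduced
    to a uniform random subset of exactly ``target`` fragments (seeded,
    input order preserved); smaller samples pass through unchanged.
    """
    if target > threshold:
        raise ValueError("target must be <= threshold")
    fragments = list(fragments)
    if len(fragments) <= threshold:
        return fragments
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(fragments), size=target, replace=False)
    keep.sort()
    return [fragments[i] for i in keep]


def read_pileup_tsv(path: str | Path):
    """Pileup TSV (chrom, pos, ref, A, C, G, T; 1-based) -> PileupColumns."""
    from .variants import PileupColumn

    columns = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "chrom")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: need 7 columns")
            chrom, pos, ref = fields[0], int(fields[1]), fields[2]
            counts = dict(zip("ACGT", (int(x) for x in fields[3:7])))
            columns.append(PileupColumn(chrom, pos, ref, counts))
    return columns


# ---------------------------------------------------------------------------
# annotation, nucleosome track, VCF
# ---------------------------------------------------------------------------

def read_genes(path: str | Path) -> list[Gene]:
    """Gene annotation TSV: chrom, start, end, strand, name (0-based span)."""
    genes = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >=4 columns")
            name = fields[4] if len(fields) > 4 else f"gene{lineno}"
            genes.append(
                Gene(fields[0], int(fields[1]), int(fields[2]), fields[3], name)
            )
    return genes


def write_genes(path: str | Path, genes: Iterable[Gene]) -> None:
    with open(path, "w") as handle:
        for g in genes:
            handle.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.name}\n")


def read_nucleosome_centers(
    path: str | Path, dialect: str = "centers"
) -> dict[str, np.ndarray]:
    """Nucleosome track BED -> sorted center positions per chromosome.

    ``dialect='centers'`` takes the start column as the center position
    (single-base records); ``dialect='intervals'`` uses the interval
    midpoint, for tracks that store protected regions.
    """
    if dialect not in {"centers", "intervals"}:
        raise ValueError("dialect must be 'centers' or 'intervals'")
    centers: dict[str, list[int]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            pos = start if dialect == "centers" else (start + end) // 2
            centers.setdefault(chrom, []).append(pos)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in centers.items()}


def write_nucleosome_centers(path: str | Path, centers: dict[str, np.ndarray]) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(centers):
            for pos in centers[chrom]:
                handle.write(f"{chrom}\t{int(pos)}\t{int(pos) + 1}\n")


def write_vcf(path: str | Path, calls, reference_name: str = "synthetic") -> int:
    """Minimal VCF 4.2 with filter labels in FILTER; 1-based positions."""
    n = 0
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write(f"##reference={reference_name}\n")
        handle.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        handle.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt count">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            filt = ";".join(sorted(call.filter_flags)) if call.filter_flags else "PASS"
            handle.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}"
                f"\t{call.qual:.1f}\t{filt}\tDP={call.depth};AC={call.alt_count}\n"
            )
            n += 1
    return n
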