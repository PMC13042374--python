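"""Context-stratified CpG methylation density for Mut- versus Wt-DNA.

Enzymatic methyl sequencing reads unmethylated CpG cytosines as
thymines, so per-fragment methylation observations arrive as
(CpG position, methylated) pairs.  To compare Mut- and Wt-DNA on equal
footing, only CpG sites observed in at least one fragment of *each*
class are used, and densities are reported separately for promoters
(TSS ± 500 bp), gene bodies, and intergenic regions:

    density = 100 * C / (C + T)

where C counts methylated and T unmethylated CpG observations.  The
three region classes partition the genome with precedence promoter >
gene body > intergenic, so every CpG maps to exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import FragmentRecord, Gene, ReferenceGenome

PROMOTER_HALF_WINDOW = 500  # bp around the TSS
REGION_CLASSES = ("promoter", "gene_body", "intergenic")


@dataclass
class MethylationCounts:
    """Methylated / unmethylated observation counts in one region class."""

    region_class: str
    n_cytosine: int = 0  # methylated observations
    n_thymine: int = 0  # unmethylated observations

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.n_cytosine < 0 or self.n_thymine < 0:
            raise ValueError("counts must be non-negative")

    @property
    def density(self) -> Optional[float]:
        """Percent methylated; None when no observations (never silently 0)."""
        total = self.n_cytosine + self.n_thymine
        if total == 0:
            return None
        return 100.0 * self.n_cytosine / total


class RegionClassifier:
    """Assign genomic positions to promoter / gene body / intergenic.

    Promoter windows are TSS ± 500 bp; gene bodies are the annotated
    gene spans minus promoter windows; everything else is intergenic.
    Intervals are merged per chromosome and queried with searchsorted.
    """

    def __init__(
        self,
        genes: Sequence[Gene],
        promoter_half_window: int = PROMOTER_HALF_WINDOW,
    ) -> None:
        self.promoter_half_window = promoter_half_window
        promoters: dict[str, list[tuple[int, int]]] = {}
        bodies: dict[str, list[tuple[int, int]]] = {}
        for gene in genes:
            tss = gene.tss
            promoters.setdefault(gene.chrom, []).append(
                (tss - promoter_half_window, tss + promoter_half_window + 1)
            )
            bodies.setdefault(gene.chrom, []).append((gene.start, gene.end))
        self._promoters = {c: _merge(v) for c, v in promoters.items()}
        self._bodies = {c: _merge(v) for c, v in bodies.items()}

    def classify(self, chrom: str, pos0: int) -> str:
        if _covered(self._promoters.get(chrom), pos0):
            return "promoter"
        if _covered(self._bodies.get(chrom), pos0):
            return "gene_body"
        return "intergenic"


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    intervals = sorted(intervals)
    merged: list[list[int]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    starts = np.array([m[0] for m in merged], dtype=np.int64)
    ends = np.array([m[1] for m in merged], dtype=np.int64)
    return starts, ends


def _covered(merged: Optional[tuple[np.ndarray, np.ndarray]], pos: int) -> bool:
    if merged is None:
        return False
    starts, ends = merged
    idx = int(np.searchsorted(starts, pos, side="right")) - 1
    return idx >= 0 and pos < ends[idx]


# ---------------------------------------------------------------------------
# matched CpGs and density
# ---------------------------------------------------------------------------

def matched_cpgs(partition) -> set[tuple[str, int]]:
    """CpG sites observed in at least one Mut and one Wt fragment.

    Restricting both classes to this shared set keeps the density
    comparison on the same CpGs, immune to coverage imbalances.
    """
    def observed(fragments: Iterable[FragmentRecord]) -> set[tuple[str, int]]:
        sites: set[tuple[str, int]] = set()
        for frag in fragments:
            for pos, _ in frag.meth_calls or []:
                sites.add((frag.chrom, pos))
        return sites

    return observed(partition.mut_fragments) & observed(partition.wt_fragments)


def methylation_density(
    fragments: Sequence[FragmentRecord],
    cpg_set: set[tuple[str, int]],
    classifier: RegionClassifier,
    reference: Optional[ReferenceGenome] = None,
) -> dict[str, Optional[float]]:
    """Per-region-class methylation density over the matched CpG set.

    When a reference is supplied, every methylation call is checked to
    sit on a genomic CpG (corrupt sidecars fail loudly).  Classes with
    no observations report None.
    """
    counts = {cls: MethylationCounts(cls) for cls in REGION_CLASSES}
    for frag in fragments:
        for pos, methylated in frag.meth_calls or []:
            if reference is not None:
                if reference.fetch(frag.chrom, pos, min(pos + 2, reference.chrom_length(frag.chrom))) [:2] != "CG":
                    raise ValueError(
                        f"methylation call at {frag.chrom}:{pos} is not a CpG site"
                    )
            if (frag.chrom, pos) not in cpg_set:
                continue
            cls = classifier.classify(frag.chrom, pos)
            if methylated:
                counts[cls].n_cytosine += 1
            else:
                counts[cls].n_thymine += 1
    return {cls: counts[cls].density for cls in REGION_CLASSES}


def diff_methylation(
    mut_density: Mapping[str, Optional[float]],
    wt_density: Mapping[str, Optional[float]],
) -> dict[str, Optional[float]]:
    """Mut-minus-Wt methylation density per region class.

    Classes undefined on either side stay None.  The classifier features
    consume the gene-body entry.
    """
    out: dict[str, Optional[float]] = {}
    for cls in REGION_CLASSES:
        mut, wt = mut_density.get(cls), wt_density.get(cls)
        out[cls] = None if mut is None or wt is None else mut - wt
    return out
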