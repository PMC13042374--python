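"""End-to-end per-sample analysis and cohort feature assembly.

Glue that runs the full chain on one sample's fragments — pileup,
candidate calling, filter cascade, Mut/Wt partition, fragmentomic and
methylation summaries, Diff contrasts — and stacks the per-sample
results into the classifier's feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import FragmentRecord, ReferenceGenome
from .fragmentomics import (
    AllelePartition,
    DiffFeatures,
    EndModel,
    FragmentomicSummary,
    diff_features,
    partition_by_allele,
    summarize,
)
from .methylation import (
    RegionClassifier,
    diff_methylation,
    matched_cpgs,
    methylation_density,
)
from .model import assemble_features
from .signatures import MutationProfile, build_profile
from .variants import (
    FilterResources,
    VariantCall,
    apply_filter_cascade,
    call_candidates,
    pileup_from_fragments,
    retained,
)


@dataclass
class SampleResult:
    """Everything the pipeline derives from one sample."""

    sample_id: str
    calls: list[VariantCall]  # all candidates, filter flags attached
    retained_calls: list[VariantCall]
    profile: MutationProfile
    partition: AllelePartition
    mut_summary: FragmentomicSummary
    wt_summary: FragmentomicSummary
    mut_methylation: Optional[dict]
    wt_methylation: Optional[dict]
    diffs: DiffFeatures


def process_sample(
    sample_id: str,
    fragments: Sequence[FragmentRecord],
    reference: ReferenceGenome,
    resources: FilterResources,
    end_model: Optional[EndModel] = None,
    nucleosome_centers: Optional[Mapping] = None,
    classifier: Optional[RegionClassifier] = None,
    mode: str = "wgs",
    error_rate: float = 1e-3,
) -> SampleResult:
    """Run the full per-sample chain from fragments to Diff features.

    Methylation densities are computed only when fragments carry
    methylation calls and a region classifier is given.
    """
    columns, coverage = pileup_from_fragments(fragments, reference)
    candidates = call_candidates(columns, mode=mode, error_rate=error_rate)
    annotated = apply_filter_cascade(candidates, resources, coverage)
    kept = retained(annotated)
    profile = build_profile(kept, reference, sample_id=sample_id)
    partition = partition_by_allele(fragments, kept)
    mut_summary = summarize(partition.mut_fragments, reference, end_model,
                            nucleosome_centers)
    wt_summary = summarize(partition.wt_fragments, reference, end_model,
                           nucleosome_centers)

    mut_meth = wt_meth = None
    diff_meth_gene_body = None
    has_meth = any(f.meth_calls for f in fragments)
    if classifier is not None and has_meth:
        shared = matched_cpgs(partition)
        mut_meth = methylation_density(partition.mut_fragments, shared, classifier)
        wt_meth = methylation_density(partition.wt_fragments, shared, classifier)
        diff_meth_gene_body = diff_methylation(mut_meth, wt_meth)["gene_body"]

    diffs = diff_features(mut_summary, wt_summary, diff_meth_gene_body)
    return SampleResult(
        sample_id=sample_id,
        calls=annotated,
        retained_calls=kept,
        profile=profile,
        partition=partition,
        mut_summary=mut_summary,
        wt_summary=wt_summary,
        mut_methylation=mut_meth,
        wt_methylation=wt_meth,
        diffs=diffs,
    )


def cohort_features(
    results: Sequence[SampleResult],
    labels: Mapping[str, str],
    mode: str = "freesv",
    genomewide: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Stack per-sample results into the labelled feature matrix."""
    profiles = {r.sample_id: r.profile for r in results}
    diffs = {r.sample_id: r.diffs for r in results}
    return assemble_features(profiles, diffs, mode=mode, genomewide=genomewide,
                             labels=labels)
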