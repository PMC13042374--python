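"""Compare fragmentomic features of Mut-DNA versus Wt-DNA in one sample.

Fragments overlapping retained variant loci are partitioned by the
allele they carry; the two classes are then summarized (short-fragment
fraction, CCCA end motif, CTCC breakpoint motif, motif diversity,
E-index against a healthy panel, nucleosome-end fraction) and
contrasted as Mut minus Wt.
"""

from freesv.fragmentomics import build_end_model
from freesv.methylation import RegionClassifier
from freesv.pipeline import process_sample
from freesv.simulate import SimConfig, simulate_cohort, simulate_panel, simulate_reference
from freesv.variants import FilterResources

config = SimConfig(n_controls=1, n_cancers=1, master_seed=23)
reference, centers = simulate_reference(config)
samples, _ = simulate_cohort(config, reference, centers)
panel_model = build_end_model(simulate_panel(config, reference, centers))
resources = FilterResources(autosomes=frozenset(reference.sequences))
classifier = RegionClassifier(reference.genes)

for sample in samples:
    r = process_sample(sample.sample_id, sample.fragments, reference, resources,
                       end_model=panel_model, nucleosome_centers=centers,
                       classifier=classifier)
    mut, wt = r.mut_summary, r.wt_summary
    print(f"\n{sample.sample_id} ({sample.label}): "
          f"{len(r.retained_calls)} retained variants, "
          f"{mut.n} Mut / {wt.n} Wt fragments")
    print(f"  frac <=150bp    Mut {mut.frac_short:.3f}  Wt {wt.frac_short:.3f}  "
          f"Diff-size {r.diffs.diff_size:+.3f}")
    print(f"  CCCA end motif  Mut {mut.frac_ccca:.4f}  Wt {wt.frac_ccca:.4f}  "
          f"Diff-CCCA {r.diffs.diff_ccca:+.4f}")
    print(f"  E-index         Mut {mut.e_index:.2f}  Wt {wt.e_index:.2f}")
    print(f"  ends in nucl. % Mut {mut.frac_ends_in_nucleosome:.1f}  "
          f"Wt {wt.frac_ends_in_nucleosome:.1f}  "
          f"Diff-nucleosome {r.diffs.diff_nucleosome:+.1f}")
    if r.diffs.diff_methylation is not None:
        print(f"  gene-body methylation Diff {r.diffs.diff_methylation:+.2f} "
              f"percentage points")
print("\nMut-DNA runs shorter, avoids the CCCA end motif, sits more often")
print("inside nucleosomes, and is hypomethylated - by construction here,")
print("mirroring the behaviour of variant-carrying cfDNA.")
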