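"""Generate a small synthetic cfDNA cohort and inspect its ground truth.

Builds a toy genome with a nucleosome track, then emits control and
cancer samples whose fragments carry injected somatic variants:
controls draw variants from a background profile (platform noise plus
clonal hematopoiesis), cancers additionally from a mixture of peaked
signature columns at the configured tumor fraction.
"""

from collections import Counter

from freesv.simulate import SimConfig, simulate_cohort, simulate_reference

config = SimConfig(n_controls=2, n_cancers=2, master_seed=7)
reference, centers = simulate_reference(config)
samples, manifest = simulate_cohort(config, reference, centers)

print(f"genome: {config.n_chroms} chromosomes x {config.chrom_length:,} bp, "
      f"{len(reference.genes)} genes, "
      f"{sum(len(c) for c in centers.values()):,} nucleosome centers")
for sample in samples:
    origins = Counter(v["origin"] for v in sample.variants)
    print(f"{sample.sample_id:12s} label={sample.label:7s} "
          f"fragments={len(sample.fragments):5d} "
          f"variants={len(sample.variants):4d} (by origin: {dict(origins)})")
print("\nEach cancer sample injects ~tumor_fraction/(1-tumor_fraction) extra")
print("signature-drawn variants on top of the background rate; fragments")
print("carrying a variant allele are sampled with the configured Mut effects.")
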