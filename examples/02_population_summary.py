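"""Zygosity, allele frequencies and variability for a multi-species study.

Simulates a study-shaped dataset (8 species, mixed ploidy, Sanger-style
consensus sequences) and runs the full analysis. Prints the per-species
genotype/allele table, the frequency table of one species, and the intra-
vs interspecific variability comparison that justifies using the marker
for phylogenetics.
"""

from ctmarker.pipeline import analyze_samples
from ctmarker.simulate import SimulationConfig, make_dataset

dataset = make_dataset(SimulationConfig(seed=5))
print(
    f"{len(dataset.samples)} genotypes over "
    f"{dataset.config.n_species} species; "
    f"{len(dataset.unreadable)} unreadable (heterozygous indel, would be cloned)"
)

result = analyze_samples(dataset.samples, tree_method="nj")
print("\nper-species summary:")
print(result.report.to_string(index=False))

sp = result.report.species.iloc[0]
print(f"\nallele frequencies of {sp}:")
for allele_id, count, freq in result.frequencies[sp].entries:
    print(f"  {allele_id:<8s} count {count:>2d}  frequency {freq:.2f}")

v = result.variability
print(
    f"\nmean intraspecific p-distance {v.mean_intra:.4f} vs "
    f"interspecific {v.mean_inter:.4f} (ratio {v.ratio:.2f}): "
    "within-species alleles are far closer to each other than to other "
    "species, so species form coherent clades."
)
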