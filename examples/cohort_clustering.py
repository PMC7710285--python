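"""Cross-subject hierarchical clustering of paired tumor samples.

Each sample is represented by its MAF vector over the pooled locus union
(zero where a locus belongs to another subject); Euclidean distance with
complete linkage should pair every subject's pre and post samples as sister
leaves, because the truncal mutations a pair shares dwarf its private
differences.
"""

from pairedtumor import SimulationConfig, build_union_maf, cluster_samples, simulate_cohort

_, records = simulate_cohort(SimulationConfig(n_subjects=5, seed=7))
matrices = [build_union_maf(grp) for _, grp in records.groupby("subject_id")]
result = cluster_samples(matrices)

print(f"samples clustered: {len(result.sample_ids)}")
print(f"pairing score: {result.pairing_score:.2f}")
print(f"tree: {result.newick}")
# pairing score 1.00 = every subject's two samples merge with each other
# before merging with any other subject's sample.
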