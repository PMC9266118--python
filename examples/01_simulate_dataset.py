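"""Simulate a two-condition limbal label-retaining-cell study.

Builds a scaled-down copy of the default study (unwounded + wounded UMI
count matrices with planted clusters, pairings and maturation genes) and
prints what was planted.
"""

from collections import Counter

from limbtraj import default_config, generate_dataset

config = default_config(seed=42, n_scale=0.25)
unwounded, wounded, truth = generate_dataset(config)

print(f"unwounded: {unwounded.n_cells} cells x {unwounded.n_genes} genes")
print(f"wounded:   {wounded.n_cells} cells x {wounded.n_genes} genes")

sizes = Counter(truth.cell_to_cluster.values())
print("\nplanted clusters (cells):")
for name in sorted(sizes):
    lineage = truth.cluster_lineage[name]
    print(f"  {name:5s} {sizes[name]:5d}  {lineage:10s} {truth.cluster_branch[name]}")

print("\ncross-condition pairs:", sorted({tuple(sorted(p)) for p in truth.pairing.items()}))
print("planted maturation genes:", truth.planted_maturation_genes)
print(f"planted QC-failing cells: {len(truth.qc_fail_cells)}")
# Each pair above is one biological cell type observed in both conditions;
# the maturation genes rise geometrically along corneal stages 1 -> 2 -> 3.
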