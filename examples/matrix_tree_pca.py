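"""Build the missing-data-free bi-allelic matrix, then a p-distance
neighbour-joining tree and a PCA of the panel.

The two pure groups separate along PC1 and form two clades; the admixed
accession sits between them — the pattern expected when one
sub-population is a blend of the other two.
"""

import numpy as np

import popkit as pk

model = pk.PopulationModel(
    chromosome_lengths=(400_000,),
    n_sites=400,
    groups=(pk.GroupSpec("occ", 5, 0.3), pk.GroupSpec("ori", 5, 0.3)),
    admixed=(("mar_1", {"occ": 0.5, "ori": 0.5}),),
    seed=11,
)
truth = pk.simulate_populations(model)
outputs = pk.simulate_caller_outputs(truth, pk.DEFAULT_PROFILES, seed=12)

consensus, depths = {}, {}
for acc, (callers, track) in outputs.items():
    consensus[acc], _ = pk.consensus_for_accession(callers, track)
    depths[acc] = track

matrix = pk.build_biallelic_matrix(consensus, depths, reference_name="Morex")
print(f"bi-allelic matrix: {matrix.n_accessions} accessions x {matrix.n_sites} sites, no missing data")

dist = pk.p_distance(matrix)
tree = pk.neighbor_joining(dist)
print("\nneighbour-joining tree (p-distance):")
print(tree.newick())

pca = pk.run_pca(matrix, n_components=2)
print("\nPC1 / PC2 scores (Patterson-normalised):")
for name, (pc1, pc2) in zip(pca.accessions, pca.scores):
    print(f"  {name:10s} {pc1:8.3f} {pc2:8.3f}")
var1 = pca.eigenvalues[0] / pca.eigenvalues.sum()
print(f"\nPC1 carries {100 * var1:.1f}% of the variance — the occ/ori split.")
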