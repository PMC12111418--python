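"""Distance-based phylogeny of a simulated three-clade dataset.

Simulates six mitogenomes whose protein-coding genes diverged along a guide
tree with three clades, concatenates the 13 genes, and reconstructs the tree
with Jukes-Cantor distances and neighbor joining.
"""

import mitochar as mc
from mitochar.presets import PCG_NAMES

dataset = mc.simulate_clade_dataset(n_taxa=6, n_clades=3, seed=7)
print("true clades:", dataset.clades)

labels, supermatrix, partitions = mc.concatenate_pcgs(dataset.records, PCG_NAMES)
print(f"supermatrix: {len(labels)} taxa x {len(supermatrix[0])} bp, "
      f"{len(partitions)} gene partitions")

dm = mc.jc_distance_matrix(labels, supermatrix)
tree = mc.neighbor_joining(dm)
print("NJ tree:", tree.to_newick())
# Taxa from the same simulated clade join first; the three clades are
# recovered as monophyletic groups in the unrooted topology.
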