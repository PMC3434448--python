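"""Pool voxel correlations into an area proximity matrix and cluster it.

Shows the Fisher-z pooled 52 x 52 proximity matrix, the UPGMA dendrogram
(exported as Newick), and the seriated leaf order with its homotopic
left/right doublets.
"""

import warnings

warnings.filterwarnings("ignore")

import cortical_layout as cl

atlas = cl.load_reference_atlas()
raw = cl.simulate_dataset(atlas, cl.SynthConfig(n_subjects=2, voxels_per_area=3, seed=1))
innov = cl.prewhiten_dataset(raw, method="hannan_rissanen")

prox = cl.build_proximity(innov)
print(f"proximity matrix: {prox.values.shape[0]} x {prox.values.shape[1]}, "
      f"entries in ({prox.values.min():.2f}, {prox.values.max():.2f}) "
      "(mean voxel-pair correlation + 2)")

dist = cl.profile_distance_matrix(prox)
tree = cl.upgma(dist, labels=prox.labels)
print(f"UPGMA tree: {tree.n_leaves - 1} merges, "
      f"heights {tree.merges[0, 2]:.3f} .. {tree.merges[-1, 2]:.3f} (squared distance)")

nearest = tree.nearest_leaf()
hom = sum(atlas.stem(nearest[i]) == atlas.stem(l) for i, l in enumerate(atlas.labels))
print(f"homotopic partner is the nearest tree neighbor for {hom}/52 areas")

pa = atlas.frame["y"].to_numpy(dtype=float)
order = cl.leaf_order(tree, policy="seriate", dist=dist, orient_by=pa)
print("top of the tree (anterior end):", ", ".join(order.sequence[:4]))
print("bottom of the tree (posterior end):", ", ".join(order.sequence[-4:]))
print("newick prefix:", tree.to_newick()[:70], "...")
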