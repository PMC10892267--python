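"""PCA and hierarchical clustering of 59-dimensional RSCU vectors.

Each gene's relative synonymous codon usage is a point in 59 dimensions;
genes sharing planted subfamily preferences should cluster together
regardless of which synthetic species they were assigned to.
"""
import cubkit as ck

cfg = ck.GeneratorConfig(seed=4, n_genes=60, n_subfamilies=3, n_species=3,
                         subfamily_divergence=1.0, bias_strength_max=4.0)
ds = ck.generate_cds_set(cfg)
vectors = [ck.rscu(ck.count_codons(c)) for c in ds.cds]
matrix = ck.build_rscu_matrix(vectors, metadata=ds.metadata)

res = ck.pca(matrix, n_components=2)
print("explained variance:",
      ", ".join(f"PC{i+1} {v:.1%}" for i, v in enumerate(res.explained_variance_ratio)))

tree = ck.hierarchical_cluster(matrix)
first_a, first_b, h = tree.merges[0]
print(f"first merge at height {h:.3f}: {sorted(first_a)[0]} + {sorted(first_b)[0]}")

# species 'super-genes': pool each species' genes and cluster the pools
by_species = {}
for c in ds.cds:
    by_species.setdefault(c.species, []).append(c)
sp_tree = ck.species_supergene_cluster(by_species)
print("species tree:", sp_tree.to_newick())
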