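"""Cross-sample similarity: Spearman heatmap values, UPGMA tree, PCA.

Differentiated cell-line samples should correlate more strongly with the
primary-neutrophil template than undifferentiated ones, and hierarchical
clustering (distance = 1 - Spearman rho, average linkage) should group
samples by state.
"""

from neutromap.expression import log_transform
from neutromap.similarity import cluster_samples, pca_embed, spearman_matrix
from neutromap.simulate import ExpressionGenSpec, gen_expression

conditions = {"undiff": 0.0, "dmso": 0.6, "primary": 1.2}
samples = [
    ("human", "lab1", cond, r, 6) for cond in conditions for r in (1, 2)
]
gen = gen_expression(
    ExpressionGenSpec(
        n_genes=4000, samples=samples, differentiation_shift=conditions, seed=7
    )
)
logged = log_transform(gen.matrix)

corr = spearman_matrix(logged.values)
print("Spearman correlations with the primary-neutrophil template:")
template = [s for s in corr.index if "primary" in s][0]
print(corr[template].drop(index=[s for s in corr.index if "primary" in s])
      .round(3).to_string())
# differentiated (dmso) samples sit closer to the template than undiff ones

dend = cluster_samples(corr)
print("\nUPGMA leaf order:", " | ".join(dend.leaf_order))
print("merge heights:", [round(float(h), 3) for h in dend.heights])

emb = pca_embed(logged, floor=-2.0)
print("\nPC1/PC2 variance explained: "
      f"{emb.variance_ratio[0]:.2f}, {emb.variance_ratio[1]:.2f}")
print(emb.coordinates[["PC1", "PC2"]].round(2).to_string())
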