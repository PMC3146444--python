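"""PCA of population allele frequencies.

Runs the population-level PCA (populations weighted by gene counts) on a
synthetic two-species scenario and prints each axis's share of total
inertia, its apportioned FST and its randomization p-value.
"""

from introgress import survey_shape_scenario, pca_populations, pca_randomization_test

bundle = survey_shape_scenario(seed=0)
table = bundle.table

res = pca_populations(table, n_axes=4)
p = pca_randomization_test(table, n_rand=200, n_axes=4, seed=0)

print("axis  inertia%  axis_FST  P")
for j in range(4):
    print(f"PC{j + 1}   {100 * res.inertia_fraction[j]:7.1f}  "
          f"{res.axis_fst[j]:.4f}    {p[j]:.4f}")

scores = res.scores["PC1"]
g_pops = [s.population for s in table.samples if s.species == "graellsii"]
print("\nmean PC1 score, graellsii populations:",
      round(scores[scores.index.isin(g_pops)].mean(), 3))
print("mean PC1 score, elegans populations:  ",
      round(scores[~scores.index.isin(g_pops)].mean(), 3))
# The first axis separates the two species: graellsii and elegans
# populations sit on opposite sides of zero.
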