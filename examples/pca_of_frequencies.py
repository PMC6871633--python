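"""PCA of population allele frequencies with region-labeled scatter output.

Two regional clusters of populations are simulated; the first principal
component of the centered frequency matrix separates them.
"""

import popkit as pk
from popkit.synth import SynthConfig, simulate_frequencies

NEWICK = "((N1:0.03,N2:0.03,N3:0.03):0.08,(S1:0.03,S2:0.03,S3:0.03):0.08);"
tree = pk.drift_tree_from_newick(NEWICK)
table, _ = simulate_frequencies(tree, SynthConfig(seed=29))

res = pk.pca_populations(table, n_components=3)
regions = {p.abbrev: ("North" if p.pop_id.startswith("N") else "South")
           for p in table.populations}
print("variance explained (%):", [round(float(v), 1) for v in res.var_explained])
print(pk.pca_plot_table(res, table, regions).round(3).to_string())
print(
    "\nPC1 carries the deep split between the two regional clusters; the"
    " percentages say how much of the total frequency variance each"
    " component explains."
)
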