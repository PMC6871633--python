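"""Build population trees from drift-scale distances and diagnose gene flow.

Fits least-squares branch lengths on NJ topologies for two worlds: pure
drift (tree model true) and unequal admixture with a common pool (tree model
violated).  Negative fitted segments are the violation's signature.
"""

import popkit as pk
from popkit.synth import SynthConfig, simulate_frequencies

NEWICK = (
    "(((A:0.04,B:0.04):0.03,(C:0.04,D:0.04):0.03):0.01,"
    "((E:0.04,F:0.04):0.03,(G:0.04,H:0.04):0.03):0.01);"
)
tree = pk.drift_tree_from_newick(NEWICK)
rates = dict(zip("ABCDEFGH", (0.2, 0.6, 0.25, 0.5, 0.3, 0.55, 0.2, 0.45)))

for label, cfg in [
    ("pure drift", SynthConfig(seed=0)),
    ("unequal gene flow", SynthConfig(seed=0, gene_flow_m=rates)),
]:
    table, truth = simulate_frequencies(tree, cfg)
    dist = pk.tau_matrix(table)
    nj = pk.neighbor_joining(dist)
    nj_ls = pk.ls_fit(nj, dist)
    result = pk.search_topologies(dist, start=nj, max_structures=200)
    best = result.best
    rf = pk.robinson_foulds(truth.tree.nontrivial_splits(), best.topology)
    print(f"[{label}]")
    print(f"  LS fit of NJ structure: negative segments={nj_ls.fit.n_negative}")
    print(f"  structures evaluated: {result.n_structures_evaluated}")
    print(
        f"  best tree: ssq={best.fit.ssq:.4g}, total length={best.fit.total_length:.3f}, "
        f"negative segments={best.fit.n_negative} "
        f"({best.fit.n_negative_internal} internal / {best.fit.n_negative_terminal} terminal)"
    )
    print(f"  Robinson-Foulds distance to true topology: {rf}")
    print(f"  drawable as additive tree: {best.drawable_as_additive}")
print(
    "\nUnder pure drift the search recovers the generating topology with all"
    " positive segments; unequal admixture makes populations more similar"
    " than any tree allows, surfacing as negative segments that preclude an"
    " additive drawing."
)
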