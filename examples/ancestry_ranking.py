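"""Rank reference populations by the likelihood of one query genotype.

The likelihood of the query in each population is the product over loci of
the population-specific HWE genotype frequency; populations within one order
of magnitude of the best are not significantly different as origins.
"""

import popkit as pk
from popkit.synth import DriftNode, DriftTree, SynthConfig, sample_genotypes, simulate_frequencies

kids = [DriftNode(f"Pop{i}", 0.1) for i in range(8)]
table, _ = simulate_frequencies(DriftTree(DriftNode(None, 0.0, kids)), SynthConfig(seed=21))
genotypes = sample_genotypes(table, 5, seed=22)

query = genotypes.individual_ids[0]
true_pop = genotypes.individuals[0][1]
ranking = pk.rank_populations(genotypes.profile(query), table, query_id=query)
print(f"query {query} (truly from {true_pop}):")
print(pk.compare_top(ranking, k=8).round(2).to_string(index=False))
rmp = pk.individual_rmp(genotypes.profile(query), table, ranking.top.pop_id, floor="pseudo")
print(f"\nrank-1 likelihood = individual RMP = {rmp:.3e}")
print(
    "\nwithin_one_oom marks populations whose likelihood is within 10x of the"
    " best - candidate origins that cannot be distinguished; the top"
    " likelihood doubles as the query's forensic random match probability."
)
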