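"""Cluster a simulated clone-library survey into OTUs and summarize diversity.

Simulates 19 clone libraries (25-39 sequences each) over 59 planted OTUs,
clusters the sequence distance matrix with the furthest-neighbor criterion
at a 5% cutoff, and prints the per-library diversity table.
"""

from thaumflow import (
    SimConfig,
    build_otu_table,
    cluster_furthest_neighbor,
    library_summary,
    simulate_libraries,
)

sim = simulate_libraries(SimConfig(seed=42))
assignment = cluster_furthest_neighbor(sim.distances, cutoff=0.05)
table = build_otu_table(assignment, sim.membership)

print(f"recovered {assignment.n_otus} OTUs from {len(sim.membership)} sequences\n")
print(library_summary(table).round({"shannon": 2, "chao1": 1}))

# Columns: n = library size, otus = observed richness, coverage_pct = Good's
# coverage (100% means no singleton OTUs, i.e. the library depth captured the
# local diversity), shannon = H' in nats, chao1 = estimated true richness
# including unseen OTUs. Because distances are planted, the clustering
# recovers all 59 OTUs exactly.
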