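"""Score a marker panel and build a bootstrapped NJ dendrogram.

Simulates 12 diploid individuals at 8 SSR loci under Hardy-Weinberg
equilibrium, prints per-locus diversity statistics (allele count Na,
observed and unbiased expected heterozygosity, PIC), and builds a
neighbor-joining tree from the shared-allele distance Dps = -ln(ps)
with 100 locus-resampling bootstrap replicates.
"""

from ssrmine.marker_diversity import (
    bootstrap_nj,
    dps_matrix,
    locus_stats,
    write_newick,
    write_phylip,
)
from ssrmine.simulate import GenoSimSpec, generate_genotypes

spec = GenoSimSpec(
    n_individuals=12,
    locus_alleles={
        f"EsSSR{i+1:02d}": {100 + 2 * j: 0.25 for j in range(4)}
        for i in range(8)
    },
    missing_rate=0.05,
    seed=7,
)
table = generate_genotypes(spec)

print(f"{'locus':<10}{'n':>4}{'Na':>4}{'Ho':>8}{'He':>8}{'PIC':>8}")
for locus in table.loci:
    s = locus_stats(table, locus)
    print(f"{s.locus:<10}{s.n_typed:>4}{s.na:>4}{s.ho:>8.3f}{s.he:>8.3f}{s.pic:>8.3f}")

tree = bootstrap_nj(table, n_replicates=100, seed=1)
print("\nNJ tree (supports = % of 100 locus-bootstrap replicates):")
print(write_newick(tree, min_support=30))
# Ho near He indicates genotype frequencies consistent with random
# mating; PIC ~0.6-0.7 marks these equifrequent 4-allele loci as
# informative markers.
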