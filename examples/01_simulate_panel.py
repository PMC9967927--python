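"""Simulate a mixed SNP/SSR genotype panel with known truth.

The default configuration mirrors a 12-population x 15-individual survey
typed at 220 bi-allelic SNPs and 8 multi-allelic SSRs, under a
Balding-Nichols island model with Fst = 0.05 and no inbreeding.
"""

from weevilpop.synthetic_data import SimulationConfig, simulate_panel

config = SimulationConfig(fst=0.05, seed=1)
matrix, popmap, truth = simulate_panel(config)

print(f"individuals : {matrix.n_individuals}")
print(f"loci        : {matrix.n_loci} "
      f"({sum(l.kind.value == 'SNP' for l in matrix.loci)} SNP, "
      f"{sum(l.kind.value == 'SSR' for l in matrix.loci)} SSR)")
print(f"populations : {', '.join(popmap.populations)}")

ssr = next(l for l in matrix.loci if l.kind.value == "SSR")
print(f"\nexample SSR locus {ssr.name}: motif ({ssr.motif}), "
      f"size range {ssr.size_range[0]}-{ssr.size_range[1]} bp, "
      f"{len(ssr.alleles)} alleles")
print(f"first genotype: {matrix.genotype(matrix.individuals[0], ssr.name)}")

# The truth object records the generative allele frequencies per population,
# which is what estimator-recovery checks compare against.
anc = truth.ancestral_frequencies[ssr.name]
print(f"ancestral frequencies at {ssr.name}: "
      + ", ".join(f"{p:.3f}" for p in anc))
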