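"""Hard-filter a SNP panel: depth gating, minor-allele frequency, call rate.

Mimics a RAD-seq discovery screen: calls under 8 reads are blanked, loci
need a minor-allele frequency strictly above 5% and at least 32/48 called
genotypes, and a validation stage keeps only loci with call rate > 95%.
"""

import numpy as np

from weevilpop.geno_io import GenotypeMatrix
from weevilpop.marker_discovery import check_flanks, filter_call_rate, filter_variants
from weevilpop.synthetic_data import SimulationConfig, apply_missingness, simulate_panel

cfg = SimulationConfig(n_populations=1, n_per_population=48, n_snp=60,
                       n_ssr=0, fst=0.0, seed=2)
matrix, _, _ = simulate_panel(cfg)
matrix = apply_missingness(matrix, rate=0.02, seed=3)

# attach synthetic read depths so the depth gate has something to do:
# mostly well-covered calls with a 2% sprinkle of shallow ones
rng = np.random.default_rng(4)
depths = rng.integers(8, 40, size=(matrix.n_individuals, matrix.n_loci)).astype(np.int32)
depths[rng.random(depths.shape) < 0.02] = 5
depths[~matrix.called_mask()] = -1
matrix = GenotypeMatrix(matrix.individuals, matrix.loci, matrix.codes, depths)

step1, report1 = filter_variants(matrix, min_depth=8, min_maf=0.05,
                                 min_called=32, total=48)
print(f"{report1.stage}: {report1.n_in} -> {report1.n_out} loci")
for locus, reason in list(report1.removed.items())[:3]:
    print(f"  removed {locus}: {reason}")

step2, report2 = filter_call_rate(step1, threshold=0.95)
print(f"{report2.stage}: {report2.n_in} -> {report2.n_out} loci")

# flank check used when selecting SNPs for probe design on short RAD tags
print("\nSNP at position 76 of a 151 bp tag has 75/75 bp flanks:",
      check_flanks(tag_length=151, snp_position=76, min_flank=75))
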