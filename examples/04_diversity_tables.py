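"""Per-marker and per-population diversity tables (MAF, N_A, He, Ho, PIC, Fis).

Statistics are computed over called genotypes only; the population Fis is
the unweighted mean of defined per-locus Fis values. A positive Fis means a
heterozygote deficit (possible inbreeding — or null alleles, see example 05);
a negative Fis means heterozygote excess.
"""

from weevilpop.cli_report import render_marker_table, render_population_table
from weevilpop.diversity_stats import hwe_test, ld_r2, locus_summary, population_summary_table
from weevilpop.geno_io import MarkerKind
from weevilpop.synthetic_data import SimulationConfig, simulate_panel

cfg = SimulationConfig(n_populations=4, n_per_population=15, n_snp=12,
                       n_ssr=4, fst=0.1, seed=6)
matrix, popmap, _ = simulate_panel(cfg)

ssr_names = [l.name for l in matrix.loci if l.kind is MarkerKind.SSR]
summaries = [locus_summary(matrix, n) for n in ssr_names]
print(render_marker_table(summaries))

rows = population_summary_table(matrix, popmap)
print(render_population_table(rows))

a, b = ssr_names[:2]
print(f"HWE p-value at {a}: {hwe_test(matrix, a, seed=1):.4f} "
      "(small = departs from random-mating proportions)")
print(f"LD r^2 between {a} and {b}: {ld_r2(matrix, a, b):.4f} "
      "(< 0.5 = no strong linkage)")
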