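"""Null-allele bias: raw SSR Fis is inflated; Brookfield-1 correction shrinks it.

The panel is simulated with NO inbreeding but with null alleles at 20% on
every SSR locus. Raw Fis comes out strongly positive (heterozygotes carrying
one null look homozygous); after estimating the null frequency from the
heterozygote deficit and correcting, the adjusted Fis falls back toward 0.
"""

import numpy as np

from weevilpop.diversity_stats import locus_summary
from weevilpop.null_alleles import estimate_locus
from weevilpop.synthetic_data import SimulationConfig, simulate_panel

cfg = SimulationConfig(
    n_populations=1, n_per_population=400, n_snp=0, n_ssr=8,
    ssr_allele_counts=(5,) * 8, fst=0.0,
    naf_per_ssr_locus=(0.2,) * 8, seed=8,
)
matrix, _, _ = simulate_panel(cfg)

print(f"{'marker':8s} {'NAF_hat':>8s} {'class':>10s} {'Fis_raw':>8s} {'Fis_adj':>8s}")
raw, adj = [], []
for locus in matrix.loci:
    s = locus_summary(matrix, locus.name)
    est = estimate_locus(matrix, locus.name)
    raw.append(s.fis)
    adj.append(est.fis_adj)
    print(f"{locus.name:8s} {est.naf:8.4f} {est.naf_class.value:>10s} "
          f"{s.fis:8.4f} {est.fis_adj:8.4f}")

print(f"\ntrue null frequency 0.2, true inbreeding f = 0")
print(f"median raw Fis      {np.median(raw):.4f}  (upward-biased by nulls)")
print(f"median adjusted Fis {np.median(adj):.4f}  (bias largely removed)")
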