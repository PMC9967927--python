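"""Population structure: Nei distances, UPGMA phenogram and allele-dosage PCA.

Simulates two divergent 'native' lineages and a cluster of introduced
populations derived from one of them, then shows that the phenogram attaches
the introduced cluster to its true source and that PCA separates the groups.
"""

import numpy as np

from weevilpop.geno_io import GenotypeMatrix, Locus, MarkerKind, PopulationMap, newick_string
from weevilpop.structure import distance_matrix, pca, upgma
from weevilpop.synthetic_data import _draw_population_frequencies, _sample_genotypes

rng = np.random.default_rng(9)
n_loci, n_per = 100, 15
codes = ["CAM", "GHN"] + [f"INT{k:02d}" for k in range(1, 6)]
individuals = [f"{c}_{i}" for c in codes for i in range(n_per)]
popmap = PopulationMap({i: i.rsplit("_", 1)[0] for i in individuals}, codes)

loci = []
calls = np.zeros((len(individuals), n_loci, 2), dtype=np.int16)
for j in range(n_loci):
    p = rng.uniform(0.1, 0.9)
    natives = _draw_population_frequencies(np.array([p, 1 - p]), 0.4, 2, rng)
    derived = _draw_population_frequencies(natives[0], 0.02, len(codes) - 2, rng)
    freqs = np.vstack([natives, derived])
    loci.append(Locus(f"s{j}", MarkerKind.SNP, ("A", "T")))
    for k in range(len(codes)):
        calls[k * n_per:(k + 1) * n_per, j, :] = _sample_genotypes(freqs[k], 0.0, n_per, rng)
matrix = GenotypeMatrix(individuals, loci, calls)

dm = distance_matrix(matrix, popmap)
print(f"mean pairwise Nei D: {dm.mean_off_diagonal():.4f}")
print(f"D(CAM, GHN) = {dm.get('CAM', 'GHN'):.4f}   (the two natives, most distant)")
print(f"D(CAM, INT01) = {dm.get('CAM', 'INT01'):.4f} (source vs derived, close)")

tree = upgma(dm)
print("\nUPGMA phenogram (Newick):")
print(newick_string(tree))

res = pca(matrix, n_components=2)
print(f"\nPCA: PC1 explains {res.explained_variance[0]:.1%}, "
      f"PC2 {res.explained_variance[1]:.1%} of dosage variance")
for code in ("CAM", "GHN", "INT01"):
    members = [i for i, ind in enumerate(res.individuals) if ind.startswith(code + "_")]
    centroid = res.coordinates[members].mean(axis=0)
    print(f"  {code} centroid on PC1/PC2: ({centroid[0]:+.2f}, {centroid[1]:+.2f})")
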