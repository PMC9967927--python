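import numpy as np
import pytest

from weevilpop.geno_io import (
    MISSING,
    GenotypeMatrix,
    Locus,
    MarkerKind,
    PopulationMap,
)
from weevilpop.synthetic_data import SimulationConfig, simulate_panel


def build_matrix(genotypes, kind=MarkerKind.SNP, depths=None, individuals=None,
                 locus_names=None):
    """Small-matrix builder: genotypes[i][j] is an allele-label pair or None."""
    n = len(genotypes)
    m = len(genotypes[0])
    individuals = individuals or [f"ind{i+1}" for i in range(n)]
    locus_names = locus_names or [f"loc{j+1}" for j in range(m)]
    loci = []
    codes = np.full((n, m, 2), MISSING, dtype=np.int16)
    for j in range(m):
        observed = []
        for i in range(n):
            pair = genotypes[i][j]
            if pair is not None:
                for a in pair:
                    if a not in observed:
                        observed.append(a)
        if kind is MarkerKind.SSR:
            observed = sorted(observed, key=int)
        loci.append(Locus(locus_names[j], kind, tuple(observed)))
        index = {a: k for k, a in enumerate(observed)}
        for i in range(n):
            pair = genotypes[i][j]
            if pair is not None:
                codes[i, j] = sorted((index[pair[0]], index[pair[1]]))
    d = None
    if depths is not None:
        d = np.array(depths, dtype=np.int32)
    return GenotypeMatrix(individuals, loci, codes, d)


@pytest.fixture(scope="session")
def demo_panel():
    """12 populations x 15 individuals, 30 SNP + 4 SSR, mild differentiation."""
    cfg = SimulationConfig(n_snp=30, n_ssr=4, fst=0.05, seed=42)
    return simulate_panel(cfg)


@pytest.fixture
def two_pop_map():
    return PopulationMap(
        assignment={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        populations=["A", "B"],
    )
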