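"""Per-locus and per-population genetic-diversity statistics.

Conventions (each a deliberate, documented choice):

* MAF here is the *major* allele frequency (the most common allele), the
  convention of the marker-characterisation tables this module emulates.
* He is the plain expected heterozygosity 1 - sum(p_i^2); an optional
  small-sample (2n/(2n-1)) correction is available but off by default.
* PIC is Botstein's measure 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2
  (biallelic maximum 0.375 at p = 0.5).
* Fis is Wright's 1 - Ho/He, undefined (None) at monomorphic loci; undefined
  values are excluded from aggregation, never coerced to zero.
* The population-level Fis is the unweighted mean of defined per-locus Fis
  values, not a ratio of mean heterozygosities.
* The HWE screen is a Monte-Carlo exact test on the heterozygote count under
  random re-pairing of the pooled alleles; LD is the squared Pearson
  correlation of major-allele dosages.

All statistics are computed over called genotypes only; missing calls are
excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geno_io import MISSING, GenotypeMatrix, PopulationMap

GLOBAL = "GLOBAL"


@dataclass(frozen=True)
class AlleleFrequencies:
    locus: str
    scope: str
    frequencies: dict[str, float]
    n_called: int

    def vector(self, registry: tuple[str, ...]) -> np.ndarray:
        """Frequencies ordered by a registry (zeros for unobserved alleles)."""
        return np.array([self.frequencies.get(a, 0.0) for a in registry])


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    scope: str
    maf: float | None
    n_alleles: int
    n_genotypes: int
    he: float | None
    ho: float | None
    pic: float | None
    fis: float | None
    n_called: int


@dataclass(frozen=True)
class PopulationSummary:
    """Per-population means over loci of the marker statistics."""

    population: str
    n: int
    maf: float | None
    n_alleles: float | None
    he: float | None
    ho: float | None
    pic: float | None
    fis: float | None
    fis_adjusted: float | None = None


def _scope_rows(
    matrix: GenotypeMatrix, scope: str, popmap: PopulationMap | None
) -> np.ndarray:
    if scope == GLOBAL:
        return np.arange(matrix.n_individuals)
    if popmap is None:
        raise ValueError("population scope requires a population map")
    if scope not in popmap.populations:
        raise ValueError(f"unknown population {scope!r}")
    members = set(popmap.members(scope))
    return np.array(
        [i for i, ind in enumerate(matrix.individuals) if ind in members],
        dtype=int,
    )


def allele_frequencies(
    matrix: GenotypeMatrix,
    locus: str,
    scope: str = GLOBAL,
    popmap: PopulationMap | None = None,
) -> AlleleFrequencies:
    """Allele frequencies over called genotypes within a scope."""
    j = matrix.locus_index(locus)
    rows = _scope_rows(matrix, scope, popmap)
    codes = matrix.codes[rows, j, :]
    called = codes[codes[:, 0] != MISSING]
    registry = matrix.loci[j].alleles
    if len(called) == 0:
        return AlleleFrequencies(locus, scope, {}, 0)
    counts = np.bincount(called.ravel(), minlength=len(registry))
    freqs = {
        registry[a]: counts[a] / (2 * len(called))
        for a in range(len(registry))
        if counts[a] > 0
    }
    return AlleleFrequencies(locus, scope, freqs, int(len(called)))


def expected_heterozygosity(
    frequencies: np.ndarray | dict[str, float] | AlleleFrequencies,
    n_called: int | None = None,
    unbiased: bool = False,
) -> float:
    """He = 1 - sum(p_i^2); ``unbiased`` applies the 2n/(2n-1) correction."""
    p = _as_vector(frequencies)
    he = 1.0 - float(np.sum(p**2))
    if unbiased:
        if not n_called:
            raise ValueError("unbiased He needs the number of called genotypes")
        he *= 2 * n_called / (2 * n_called - 1)
    return he


def pic(frequencies: np.ndarray | dict[str, float] | AlleleFrequencies) -> float:
    """Botstein's polymorphism information content."""
    p = _as_vector(frequencies)
    sq = p**2
    cross = float(np.sum(np.outer(sq, sq))) - float(np.sum(sq**2))
    return 1.0 - float(np.sum(sq)) - cross


def _as_vector(
    frequencies: np.ndarray | dict[str, float] | AlleleFrequencies,
) -> np.ndarray:
    if isinstance(frequencies, AlleleFrequencies):
        p = np.array(list(frequencies.frequencies.values()))
    elif isinstance(frequencies, dict):
        p = np.array(list(frequencies.values()))
    else:
        p = np.asarray(frequencies, dtype=float)
    if p.size and abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, expected 1")
    return p


def observed_heterozygosity(
    matrix: GenotypeMatrix,
    locus: str,
    scope: str = GLOBAL,
    popmap: PopulationMap | None = None,
) -> float | None:
    """Fraction of called genotypes that are heterozygous (None if none called)."""
    j = matrix.locus_index(locus)
    rows = _scope_rows(matrix, scope, popmap)
    codes = matrix.codes[rows, j, :]
    called = codes[codes[:, 0] != MISSING]
    if len(called) == 0:
        return None
    return float(np.mean(called[:, 0] != called[:, 1]))


def fis(he: float | None, ho: float | None) -> float | None:
    """Wright's inbreeding coefficient 1 - Ho/He; None when He is 0/undefined."""
    if he is None or ho is None or he == 0.0:
        return None
    return 1.0 - ho / he


def locus_summary(
    matrix: GenotypeMatrix,
    locus: str,
    scope: str = GLOBAL,
    popmap: PopulationMap | None = None,
    unbiased_he: bool = False,
) -> LocusSummary:
    """Assemble MAF, N_A, N_G, He, Ho, PIC and Fis for one locus and scope."""
    j = matrix.locus_index(locus)
    rows = _scope_rows(matrix, scope, popmap)
    codes = matrix.codes[rows, j, :]
    called = codes[codes[:, 0] != MISSING]
    if len(called) == 0:
        return LocusSummary(locus, scope, None, 0, 0, None, None, None, None, 0)
    af = allele_frequencies(matrix, locus, scope, popmap)
    p = np.array(list(af.frequencies.values()))
    he = expected_heterozygosity(p, n_called=af.n_called, unbiased=unbiased_he)
    ho = observed_heterozygosity(matrix, locus, scope, popmap)
    n_geno = len({(int(a), int(b)) for a, b in called})
    return LocusSummary(
        locus=locus,
        scope=scope,
        maf=float(p.max()),
        n_alleles=int(len(p)),
        n_genotypes=n_geno,
        he=he,
        ho=ho,
        pic=pic(p),
        fis=fis(he, ho),
        n_called=af.n_called,
    )


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def population_summary_table(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    loci: list[str] | None = None,
    unbiased_he: bool = False,
    include_mean_row: bool = True,
) -> list[PopulationSummary]:
    """Per-population means over loci of MAF, N_A, He, Ho, PIC and Fis.

    Means are taken over loci with at least one called genotype in the
    population; the population Fis is the unweighted mean of defined
    per-locus Fis values. When ``include_mean_row`` is set, a final row
    labelled ``Mean`` holds the unweighted arithmetic mean of the population
    values (each column over the populations where it is defined).
    """
    names = loci if loci is not None else [l.name for l in matrix.loci]
    rows: list[PopulationSummary] = []
    for code in popmap.populations:
        summaries = [
            locus_summary(matrix, n, code, popmap, unbiased_he=unbiased_he)
            for n in names
        ]
        informative = [s for s in summaries if s.n_called > 0]
        rows.append(
            PopulationSummary(
                population=code,
                n=len(popmap.members(code)),
                maf=_mean_defined([s.maf for s in informative]),
                n_alleles=_mean_defined([float(s.n_alleles) for s in informative]),
                he=_mean_defined([s.he for s in informative]),
                ho=_mean_defined([s.ho for s in informative]),
                pic=_mean_defined([s.pic for s in informative]),
                fis=_mean_defined([s.fis for s in informative]),
            )
        )
    if include_mean_row:
        rows.append(
            PopulationSummary(
                population="Mean",
                n=sum(r.n for r in rows),
                maf=_mean_defined([r.maf for r in rows]),
                n_alleles=_mean_defined([r.n_alleles for r in rows]),
                he=_mean_defined([r.he for r in rows]),
                ho=_mean_defined([r.ho for r in rows]),
                pic=_mean_defined([r.pic for r in rows]),
                fis=_mean_defined([r.fis for r in rows]),
            )
        )
    return rows


def hwe_test(
    matrix: GenotypeMatrix,
    locus: str,
    scope: str = GLOBAL,
    popmap: PopulationMap | None = None,
    n_permutations: int = 10000,
    seed: int = 0,
) -> float | None:
    """Monte-Carlo exact test for Hardy-Weinberg equilibrium.

    The 2n called alleles are pooled and re-paired uniformly at random; the
    statistic is the heterozygote count. Two-sided p-value = 2 * min(tail
    fractions), capped at 1, with the observed panel counted in its own tail
    (add-one smoothing). None when fewer than 2 genotypes are called or the
    locus is monomorphic.
    """
    j = matrix.locus_index(locus)
    rows = _scope_rows(matrix, scope, popmap)
    codes = matrix.codes[rows, j, :]
    called = codes[codes[:, 0] != MISSING]
    n = len(called)
    if n < 2 or len(np.unique(called)) < 2:
        return None
    obs_het = int(np.sum(called[:, 0] != called[:, 1]))
    pool = called.ravel()
    rng = np.random.default_rng(seed)
    # shuffle whole pools row-wise, then pair consecutive alleles
    tiled = np.tile(pool, (n_permutations, 1))
    shuffled = rng.permuted(tiled, axis=1).reshape(n_permutations, n, 2)
    het_counts = (shuffled[:, :, 0] != shuffled[:, :, 1]).sum(axis=1)
    lower = (np.sum(het_counts <= obs_het) + 1) / (n_permutations + 1)
    upper = (np.sum(het_counts >= obs_het) + 1) / (n_permutations + 1)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _major_dosage(
    matrix: GenotypeMatrix, locus: str, rows: np.ndarray
) -> np.ndarray:
    """Copies of the scope-major allele per individual; -1 where missing."""
    j = matrix.locus_index(locus)
    codes = matrix.codes[rows, j, :]
    called = codes[codes[:, 0] != MISSING]
    if len(called) == 0:
        return np.full(len(rows), -1)
    counts = np.bincount(called.ravel())
    major = int(np.argmax(counts))
    dosage = (codes == major).sum(axis=1)
    dosage[codes[:, 0] == MISSING] = -1
    return dosage


def ld_r2(
    matrix: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    scope: str = GLOBAL,
    popmap: PopulationMap | None = None,
) -> float | None:
    """Squared Pearson correlation of major-allele dosages (0/1/2).

    Computed over individuals called at both loci; None when either dosage is
    constant (no correlation defined).
    """
    rows = _scope_rows(matrix, scope, popmap)
    da = _major_dosage(matrix, locus_a, rows)
    db = _major_dosage(matrix, locus_b, rows)
    ok = (da >= 0) & (db >= 0)
    if ok.sum() < 2:
        return None
    x, y = da[ok].astype(float), db[ok].astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)
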