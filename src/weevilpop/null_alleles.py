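"""Null-allele frequency estimation (Brookfield-1) and Fis bias correction.

A null allele is a PCR-invisible allele: heterozygotes carrying one null are
scored as homozygotes for the visible allele and null homozygotes drop out as
missing calls. The resulting heterozygote deficit inflates Wright's Fis, so a
positive SSR-based Fis need not indicate inbreeding.

Brookfield's first estimator infers the null frequency from the deficit:

    r = (He - Ho) / (1 + He)        (clamped at 0 when Ho >= He)

Estimates are classified as negligible (r < 0.05), moderate (0.05 <= r <
0.20) or large (r >= 0.20). Correction rescales every visible allele
frequency by (1 - r) and adds a NULL pseudo-allele at r; heterozygosities are
then re-expressed on the all-individuals scale:

    He_adj = 1 - (1-r)^2 (1 - He_obs) - r^2
    Ho_adj = Ho_obs (1 - r^2) + 2 r (1 - r)

(Ho_obs is measured among called genotypes, a fraction (1 - r^2) of
individuals; the 2r(1-r) term restores the visible x null heterozygotes that
were mis-scored as homozygotes.) When the true r is supplied these formulas
cancel exactly — a panel simulated with null alleles and no inbreeding has
adjusted Fis identically 0 — while under the Brookfield-1 estimate the
correction is approximate and should be read as bias reduction, not exact
recovery.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geno_io import GenotypeMatrix, PopulationMap
from .diversity_stats import (
    GLOBAL,
    allele_frequencies,
    expected_heterozygosity,
    fis as wright_fis,
    observed_heterozygosity,
)

NULL_LABEL = "NULL"


class NafClass(enum.Enum):
    NEGLIGIBLE = "negligible"
    MODERATE = "moderate"
    LARGE = "large"


@dataclass(frozen=True)
class NullAlleleEstimate:
    locus: str
    scope: str
    naf: float
    naf_class: NafClass
    he_obs: float
    ho_obs: float
    adjusted_frequencies: dict[str, float]
    he_adj: float
    ho_adj: float
    fis_adj: float | None


def brookfield1(he_obs: float, ho_obs: float) -> float:
    """Brookfield-1 null-allele frequency r = (He - Ho)/(1 + He), floored at 0."""
    if not (0.0 <= he_obs <= 1.0 and 0.0 <= ho_obs <= 1.0):
        raise ValueError("heterozygosities must lie in [0, 1]")
    return max(0.0, (he_obs - ho_obs) / (1.0 + he_obs))


def classify_naf(naf: float) -> NafClass:
    """Negligible (< 0.05), moderate (0.05 <= r < 0.20) or large (>= 0.20)."""
    if naf < 0.05:
        return NafClass.NEGLIGIBLE
    if naf < 0.20:
        return NafClass.MODERATE
    return NafClass.LARGE


def adjust_frequencies(
    frequencies: dict[str, float], naf: float
) -> dict[str, float]:
    """Rescale visible frequencies by (1 - r) and add a NULL allele at r."""
    if not 0.0 <= naf < 1.0:
        raise ValueError("null-allele frequency must be in [0, 1)")
    adjusted = {a: p * (1.0 - naf) for a, p in frequencies.items()}
    adjusted[NULL_LABEL] = naf
    return adjusted


def adjusted_fis(
    he_obs: float, ho_obs: float, naf: float | None = None
) -> tuple[float, float, float, float | None]:
    """Null-corrected (naf, He_adj, Ho_adj, Fis_adj) from observed He/Ho.

    ``naf`` overrides the Brookfield-1 estimate when the true null frequency
    is known (the exact-recovery case); otherwise r is estimated first.
    """
    r = brookfield1(he_obs, ho_obs) if naf is None else float(naf)
    if not 0.0 <= r < 1.0:
        raise ValueError("null-allele frequency must be in [0, 1)")
    he_adj = 1.0 - (1.0 - r) ** 2 * (1.0 - he_obs) - r**2
    ho_adj = ho_obs * (1.0 - r**2) + 2.0 * r * (1.0 - r)
    return r, he_adj, ho_adj, wright_fis(he_adj, ho_adj)


def estimate_locus(
    matrix: GenotypeMatrix,
    locus: str,
    scope: str = GLOBAL,
    popmap: PopulationMap | None = None,
) -> NullAlleleEstimate | None:
    """Full Brookfield-1 chain for one locus and scope.

    He/Ho are computed over called genotypes only (missing excluded). Returns
    None when no genotypes are called in the scope.
    """
    af = allele_frequencies(matrix, locus, scope, popmap)
    if af.n_called == 0:
        return None
    he_obs = expected_heterozygosity(af)
    ho_obs = observed_heterozygosity(matrix, locus, scope, popmap)
    r, he_adj, ho_adj, f_adj = adjusted_fis(he_obs, ho_obs)
    return NullAlleleEstimate(
        locus=locus,
        scope=scope,
        naf=r,
        naf_class=classify_naf(r),
        he_obs=he_obs,
        ho_obs=ho_obs,
        adjusted_frequencies=adjust_frequencies(af.frequencies, r),
        he_adj=he_adj,
        ho_adj=ho_adj,
        fis_adj=f_adj,
    )


def population_adjusted_fis(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    loci: list[str] | None = None,
) -> dict[str, float | None]:
    """Per-population adjusted Fis: unweighted mean of per-locus adjusted Fis.

    Mirrors the raw population Fis aggregation (mean of defined per-locus
    values) so raw and adjusted columns are directly comparable.
    """
    names = loci if loci is not None else [l.name for l in matrix.loci]
    out: dict[str, float | None] = {}
    for code in popmap.populations:
        vals: list[float] = []
        for name in names:
            est = estimate_locus(matrix, name, code, popmap)
            if est is not None and est.fis_adj is not None:
                vals.append(est.fis_adj)
        out[code] = float(np.mean(vals)) if vals else None
    return out
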