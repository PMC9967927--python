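"""Synthetic genotype panels with known truth, for testing every pipeline stage.

The generative model is the Balding–Nichols island model: each locus has an
ancestral allele-frequency vector p drawn uniformly on the simplex, and each
population draws its own frequency vector from Dirichlet(p * (1 - Fst) / Fst).
Fst = 0 means every population uses the ancestral frequencies exactly.
Within a population, genotypes follow the inbreeding model

    P(hom i)  = p_i^2 + f * p_i * (1 - p_i)
    P(het ij) = 2 * p_i * p_j * (1 - f)

so f is exactly the quantity the Fis estimator should recover. Loci are
independent (no linkage).

Null alleles are overlaid at the generative-frequency level: a null allele at
frequency r joins the locus, visible frequencies are rescaled by (1 - r), and
genotypes are re-drawn — visible/visible keeps its coding, visible/null is
scored as a homozygote for the visible allele, null/null becomes MISSING.
This matches the PCR mechanism (null alleles fail to amplify, so true
heterozygotes carrying one null look homozygous) and gives closed-form
expectations: apparent visible frequencies q_i / (1 - r) and called-genotype
heterozygosity ((1 - r)^2 - sum q_i^2) / (1 - r^2).

SSR allele labels are arithmetic progressions of fragment lengths (step =
motif length), echoing real electropherogram size ranges; SNP alleles are
bases. The default panel dimensions (12 populations x 15 individuals,
220 SNP + 8 SSR) mirror the weevil survey design the pipeline targets.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict

import numpy as np

from .geno_io import (
    MISSING,
    GenotypeMatrix,
    Locus,
    MarkerKind,
    PopulationMap,
)

_DEFAULT_POP_CODES = (
    "CAM", "GHN", "SR", "NR", "CWK", "SK", "NPM", "CPM", "SPM", "SS", "NS", "SBH",
)

_SSR_MOTIFS = ("AAC", "AG", "CTGCA", "T", "AT", "ATG", "AC", "CT")


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic panel.

    Defaults reproduce the survey design the analysis assumes: 12 populations
    of 15 individuals typed at 220 bi-allelic SNPs and 8 multi-allelic SSRs,
    with mild differentiation and no inbreeding, null alleles or missingness
    unless requested.
    """

    n_populations: int = 12
    n_per_population: int = 15
    n_snp: int = 220
    n_ssr: int = 8
    fst: float = 0.05
    inbreeding_f: float = 0.0
    naf_per_ssr_locus: tuple[float, ...] | None = None
    missing_rate: float = 0.0
    ssr_allele_counts: tuple[int, ...] | None = None
    seed: int = 0
    population_codes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_populations, self.n_per_population) <= 0:
            raise ValueError("population counts must be positive")
        if self.n_snp < 0 or self.n_ssr < 0:
            raise ValueError("negative locus counts")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not -1.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must be in [-1, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ssr_allele_counts is None:
            # 4-13 visible alleles, the range seen in real SSR panels
            self.ssr_allele_counts = tuple(
                4 + (i * 3) % 10 for i in range(self.n_ssr)
            )
        if len(self.ssr_allele_counts) != self.n_ssr:
            raise ValueError("ssr_allele_counts length must equal n_ssr")
        if self.naf_per_ssr_locus is None:
            self.naf_per_ssr_locus = tuple(0.0 for _ in range(self.n_ssr))
        self.naf_per_ssr_locus = tuple(float(r) for r in self.naf_per_ssr_locus)
        if len(self.naf_per_ssr_locus) != self.n_ssr:
            raise ValueError("naf_per_ssr_locus length must equal n_ssr")
        if any(not 0.0 <= r < 1.0 for r in self.naf_per_ssr_locus):
            raise ValueError("null-allele frequencies must be in [0, 1)")
        if self.population_codes is None:
            if self.n_populations <= len(_DEFAULT_POP_CODES):
                self.population_codes = _DEFAULT_POP_CODES[: self.n_populations]
            else:
                self.population_codes = tuple(
                    f"P{i + 1:02d}" for i in range(self.n_populations)
                )
        if len(self.population_codes) != self.n_populations:
            raise ValueError("population_codes length must equal n_populations")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated panel, for estimator-recovery tests.

    ``ancestral_frequencies`` and ``population_frequencies`` map locus name to
    frequency vectors over the locus registry (population frequencies keyed by
    population code). Frequencies refer to *visible* alleles only until a
    null-allele overlay rescales them (the overlay records per-locus null
    frequencies in ``null_allele_frequencies``).
    """

    config: SimulationConfig
    ancestral_frequencies: dict[str, np.ndarray]
    population_frequencies: dict[str, dict[str, np.ndarray]]
    null_allele_frequencies: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name, p in self.ancestral_frequencies.items():
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"ancestral frequencies at {name} do not sum to 1")
        for pops in self.population_frequencies.values():
            for p in pops.values():
                if abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError("population frequencies do not sum to 1")

    def to_json(self, path: str) -> None:
        payload = {
            "config": asdict(self.config),
            "null_allele_frequencies": self.null_allele_frequencies,
            "ancestral_frequencies": {
                k: v.tolist() for k, v in self.ancestral_frequencies.items()
            },
            "population_frequencies": {
                k: {pk: pv.tolist() for pk, pv in pops.items()}
                for k, pops in self.population_frequencies.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _draw_population_frequencies(
    ancestral: np.ndarray, fst: float, n_populations: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding–Nichols draw: Dirichlet(p (1-Fst)/Fst) per population."""
    if fst == 0.0:
        return np.tile(ancestral, (n_populations, 1))
    conc = ancestral * (1.0 - fst) / fst
    # Dirichlet with tiny concentrations can underflow to exact zeros; a
    # floor keeps every registry allele drawable without shifting Fst.
    draws = rng.dirichlet(np.maximum(conc, 1e-6), size=n_populations)
    return draws / draws.sum(axis=1, keepdims=True)


def _genotype_probabilities(p: np.ndarray, f: float) -> tuple[np.ndarray, np.ndarray]:
    """All unordered genotype probabilities under the inbreeding model.

    Returns (pairs, probs): pairs is (G, 2) sorted allele-index pairs.
    """
    k = len(p)
    iu = np.triu_indices(k)
    pairs = np.stack(iu, axis=1)
    probs = np.empty(len(pairs))
    hom = pairs[:, 0] == pairs[:, 1]
    pi = p[pairs[:, 0]]
    pj = p[pairs[:, 1]]
    probs[hom] = pi[hom] ** 2 + f * pi[hom] * (1.0 - pi[hom])
    probs[~hom] = 2.0 * pi[~hom] * pj[~hom] * (1.0 - f)
    if (probs < -1e-12).any():
        raise ValueError(
            f"inbreeding f={f} yields negative genotype probabilities for "
            "these allele frequencies"
        )
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate genotype distribution")
    return pairs, probs / total


def _sample_genotypes(
    p: np.ndarray, f: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n unordered genotypes (n, 2) of allele indices."""
    pairs, probs = _genotype_probabilities(p, f)
    idx = rng.choice(len(pairs), size=n, p=probs)
    return pairs[idx].astype(np.int16)


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SimulationTruth]:
    """Simulate a full mixed SNP/SSR panel under the configured model.

    Null-allele overlays (``naf_per_ssr_locus``) and random missingness
    (``missing_rate``) from the config are applied on top of the clean draw,
    using sub-seeds derived from ``config.seed``; the returned truth records
    the generative frequencies and the per-locus null frequencies.
    Deterministic under a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    n_pop = config.n_populations
    n_ind = n_pop * config.n_per_population
    codes_list = config.population_codes

    individuals = [
        f"{code}_{i + 1:02d}"
        for code in codes_list
        for i in range(config.n_per_population)
    ]
    assignment = {
        ind: code
        for code, block in zip(
            codes_list,
            [
                individuals[k * config.n_per_population : (k + 1) * config.n_per_population]
                for k in range(n_pop)
            ],
        )
        for ind in block
    }
    popmap = PopulationMap(assignment=assignment, populations=list(codes_list))

    loci: list[Locus] = []
    ancestral: dict[str, np.ndarray] = {}
    popfreqs: dict[str, dict[str, np.ndarray]] = {}
    calls = np.full((n_ind, config.n_snp + config.n_ssr, 2), MISSING, dtype=np.int16)

    pop_slices = {
        code: slice(k * config.n_per_population, (k + 1) * config.n_per_population)
        for k, code in enumerate(codes_list)
    }

    def simulate_locus(locus: Locus, anc: np.ndarray, j: int) -> None:
        freqs = _draw_population_frequencies(anc, config.fst, n_pop, rng)
        ancestral[locus.name] = anc
        popfreqs[locus.name] = {
            code: freqs[k] for k, code in enumerate(codes_list)
        }
        for k, code in enumerate(codes_list):
            calls[pop_slices[code], j, :] = _sample_genotypes(
                freqs[k], config.inbreeding_f, config.n_per_population, rng
            )

    bases = np.array(list("ACGT"))
    for s in range(config.n_snp):
        ref, alt = rng.choice(4, size=2, replace=False)
        locus = Locus(
            name=f"snp{s + 1:04d}",
            kind=MarkerKind.SNP,
            alleles=(str(bases[ref]), str(bases[alt])),
        )
        loci.append(locus)
        p_ref = rng.uniform()  # uniform on the 2-simplex
        simulate_locus(locus, np.array([p_ref, 1.0 - p_ref]), s)

    for t in range(config.n_ssr):
        k_alleles = config.ssr_allele_counts[t]
        motif = _SSR_MOTIFS[t % len(_SSR_MOTIFS)]
        base_len = int(rng.integers(100, 200))
        step = len(motif)
        registry = tuple(str(base_len + step * a) for a in range(k_alleles))
        locus = Locus(
            name=f"ssr{t + 1:02d}",
            kind=MarkerKind.SSR,
            alleles=registry,
            motif=motif,
            size_range=(base_len, base_len + step * (k_alleles - 1)),
        )
        loci.append(locus)
        anc = rng.dirichlet(np.ones(k_alleles))
        simulate_locus(locus, anc, config.n_snp + t)

    matrix = GenotypeMatrix(individuals, loci, calls)
    truth = SimulationTruth(
        config=config, ancestral_frequencies=ancestral, population_frequencies=popfreqs
    )
    truth.validate()

    if any(r > 0 for r in config.naf_per_ssr_locus):
        ssr_names = [l.name for l in loci if l.kind is MarkerKind.SSR]
        naf = dict(zip(ssr_names, config.naf_per_ssr_locus))
        matrix = apply_null_alleles(
            matrix, truth, naf, popmap=popmap, seed=config.seed + 1
        )
    if config.missing_rate > 0:
        matrix = apply_missingness(matrix, config.missing_rate, seed=config.seed + 2)
    return matrix, popmap, truth


def apply_null_alleles(
    matrix: GenotypeMatrix,
    truth: SimulationTruth,
    naf: dict[str, float],
    popmap: PopulationMap | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Overlay null alleles on SSR loci at the generative-frequency level.

    For each target locus with null frequency r, visible generative
    frequencies are rescaled by (1 - r) and each individual's genotype is
    re-drawn under the same inbreeding model with the null as an extra
    allele: visible/visible keeps normal coding, visible/null is scored as a
    homozygote for the visible allele, null/null becomes MISSING. The truth
    object is updated in place with the applied null frequencies.
    """
    out = matrix.copy()
    f = truth.config.inbreeding_f
    rng = np.random.default_rng(seed)
    by_name = {l.name: l for l in matrix.loci}
    for lname, r in naf.items():
        locus = by_name.get(lname)
        if locus is None:
            raise KeyError(f"locus {lname!r} not in matrix")
        if locus.kind is not MarkerKind.SSR:
            raise ValueError(f"null-allele overlay targets SSR loci, {lname} is SNP")
        if not 0.0 <= r < 1.0:
            raise ValueError("null-allele frequency must be in [0, 1)")
        if r == 0.0:
            continue
        j = matrix.locus_index(lname)
        null_idx = len(locus.alleles)  # pseudo-allele appended past the registry
        pops = truth.population_frequencies[lname]
        ind_pos = {ind: i for i, ind in enumerate(matrix.individuals)}
        if popmap is not None:
            groups = {code: popmap.members(code) for code in popmap.populations}
        elif len(pops) == 1:
            groups = {next(iter(pops)): list(matrix.individuals)}
        else:
            raise ValueError(
                "popmap required: truth holds frequencies for multiple populations"
            )
        for code, members in groups.items():
            q = pops[code]
            aug = np.append(q * (1.0 - r), r)
            draws = _sample_genotypes(aug, f, len(members), rng)
            for ind, (a, b) in zip(members, draws):
                i = ind_pos[ind]
                if a == null_idx and b == null_idx:
                    out.codes[i, j] = (MISSING, MISSING)
                elif b == null_idx:  # pairs are sorted, so null is second
                    out.codes[i, j] = (a, a)
                else:
                    out.codes[i, j] = (a, b)
        # truth keeps the visible-allele frequencies; r is recorded beside them
        truth.null_allele_frequencies[lname] = r
    return out


def apply_missingness(
    matrix: GenotypeMatrix, rate: float, seed: int = 0
) -> GenotypeMatrix:
    """Set each called genotype to MISSING independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must be in [0, 1)")
    out = matrix.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    drop = rng.random(out.codes.shape[:2]) < rate
    out.codes[drop] = MISSING
    if out.depths is not None:
        out.depths[drop] = -1
    return out


# ---------------------------------------------------------------------------
# Sequence fixtures with planted SSR motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRepeat:
    """Truth record for one planted perfect repeat (1-based inclusive span)."""

    contig: str
    motif: str
    repeats: int
    start: int
    end: int


_DEFAULT_MIN_REPEATS = {1: 10, 2: 5, 3: 5, 4: 4, 5: 4, 6: 4}


def _qualifying_spans(
    seq: str, min_repeats: dict[int, int] | None = None
) -> list[tuple[int, int, int]]:
    """Brute-force regex scan for qualifying perfect repeats.

    Returns (start0, end0_exclusive, unit) for every maximal qualifying run;
    used by the fixture generator for rejection sampling (kept independent of
    the production scanner, which it also cross-checks in tests).
    """
    mins = dict(_DEFAULT_MIN_REPEATS if min_repeats is None else min_repeats)
    found: list[tuple[int, int, int]] = []
    for unit, min_rep in mins.items():
        pattern = re.compile(r"([ACGT]{%d})\1{%d,}" % (unit, min_rep - 1))
        for m in pattern.finditer(seq):
            found.append((m.start(), m.end(), unit))
    # a run reported under a longer unit inside a shorter-unit run (e.g. (TT)5
    # inside (T)10) is the same tract, not an extra repeat
    found = [
        (s, e, u)
        for (s, e, u) in found
        if not any(
            u2 < u and s2 <= s and e <= e2 for (s2, e2, u2) in found if (s2, e2, u2) != (s, e, u)
        )
    ]
    return sorted(set(found))


def make_contig_fixtures(
    n: int,
    planted: list[tuple[str, int, tuple[int, int]]],
    seed: int = 0,
    length_range: tuple[int, int] = (150, 320),
    max_tries: int = 200,
) -> tuple[list[tuple[str, str]], list[PlantedRepeat]]:
    """Build random contigs, the first ``len(planted)`` carrying a planted repeat.

    ``planted`` entries are (motif, repeats, (left_flank, right_flank)).
    Returns (records, truth): records as (name, sequence) pairs ready for
    FASTA, truth as 1-based repeat positions. Backgrounds are rejection-
    sampled so that NO qualifying repeat other than the planted one occurs
    (the planted repeat set is exactly the scanner's expected output).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if len(planted) > n:
        raise ValueError("more planted repeats than contigs")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records: list[tuple[str, str]] = []
    truth: list[PlantedRepeat] = []

    def random_seq(length: int) -> str:
        return "".join(bases[rng.integers(0, 4, size=length)])

    for idx in range(n):
        name = f"contig{idx + 1:04d}"
        if idx < len(planted):
            motif, repeats, (left, right) = planted[idx]
            motif = motif.upper()
            if not (1 <= len(motif) <= 6) or set(motif) - set("ACGT"):
                raise ValueError(f"motif {motif!r} must be 1-6 nt over ACGT")
            if left < 0 or right < 0:
                raise ValueError("flank lengths must be non-negative")
            tract = motif * repeats
            for _ in range(max_tries):
                seq = random_seq(left) + tract + random_seq(right)
                spans = _qualifying_spans(seq)
                expected = (left, left + len(tract), len(motif))
                if spans == [expected] or (not spans and repeats * len(motif) == 0):
                    break
            else:
                raise RuntimeError(
                    f"could not build a clean background for {motif}x{repeats}"
                )
            records.append((name, seq))
            truth.append(
                PlantedRepeat(
                    contig=name,
                    motif=motif,
                    repeats=repeats,
                    start=left + 1,
                    end=left + len(tract),
                )
            )
        else:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            for _ in range(max_tries):
                seq = random_seq(length)
                if not _qualifying_spans(seq):
                    break
            else:
                raise RuntimeError("could not build a repeat-free background")
            records.append((name, seq))
    return records, truth


def write_fasta(records: list[tuple[str, str]], path: str) -> None:
    """Write (name, sequence) records as FASTA via Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(s), id=n, description="") for n, s in records],
        path,
        "fasta",
    )
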