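"""Marker-panel construction: variant hard filters, flank checks, SSR scanning
and primer constraint screening.

The SNP filters mirror a standard RAD-seq panel workflow: per-call read-depth
gating (calls under the minimum depth become MISSING), then locus-level
removal on minor-allele frequency (strict >, so a MAF exactly at the
threshold is dropped) and on the number of called genotypes; a later
validation stage retains only loci whose call rate strictly exceeds a
threshold. The SSR scanner reports maximal perfect tandem repeats of unit
length 1-6 with per-unit minimum repeat counts, and the primer screen applies
fixed length/product/melting-temperature windows with a simple GC-fraction
Tm approximation (Tm = 64.9 + 41*(GC - 16.4)/length). The Tm model is a
documented, swappable strategy: commercial design tools use proprietary
nearest-neighbour parameters and will not agree numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geno_io import MISSING, GenotypeMatrix

DEFAULT_MIN_REPEATS = {1: 10, 2: 5, 3: 5, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class SSRMotifHit:
    """One maximal perfect tandem repeat, 1-based inclusive coordinates."""

    contig: str
    motif: str
    repeats: int
    start: int
    end: int
    left_flank: int
    right_flank: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.repeats:
            raise ValueError("span does not equal motif length x repeats")


@dataclass(frozen=True)
class PrimerAssessment:
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    tm_delta: float
    product_length: int
    violations: tuple[str, ...]

    @property
    def verdict(self) -> str:
        return "fail" if self.violations else "pass"


@dataclass
class FilterReport:
    """Accounting for one filter stage: every input locus is retained or has
    a removal reason; counts always reconcile."""

    stage: str
    n_in: int
    n_out: int
    removed: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in or self.n_in - self.n_out != len(self.removed):
            raise ValueError("filter report counts do not reconcile")


def _minor_allele_frequency(codes_j: np.ndarray) -> float | None:
    """Frequency of the second most common allele (None if no calls)."""
    alleles = codes_j[codes_j[:, 0] != MISSING]
    if alleles.size == 0:
        return None
    counts = np.bincount(alleles.ravel())
    if (counts > 0).sum() < 2:
        return 0.0
    top2 = np.sort(counts)[-2]
    return float(top2) / float(alleles.size)


def filter_variants(
    matrix: GenotypeMatrix,
    min_depth: int = 8,
    min_maf: float = 0.05,
    min_called: int | None = None,
    total: int | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Two-stage discovery filter: depth-gate calls, then drop loci.

    Calls with depth below ``min_depth`` are set MISSING first (skipped with a
    warning when the matrix carries no depths). A locus is then removed if its
    minor-allele frequency is <= ``min_maf`` (strictly greater is retained) or
    if fewer than ``min_called`` genotypes remain called out of ``total``
    individuals (defaults: 2/3 of the panel, the discovery rule's ratio).
    """
    total = matrix.n_individuals if total is None else total
    if min_called is None:
        min_called = int(np.ceil(total * 2 / 3))
    if min_called > total:
        raise ValueError(f"min_called={min_called} exceeds total={total}")
    work = matrix.copy()
    if work.depths is None:
        if min_depth > 0:
            warnings.warn(
                "matrix carries no per-call depths; depth criterion skipped",
                stacklevel=2,
            )
    else:
        low = (work.depths >= 0) & (work.depths < min_depth)
        work.codes[low] = MISSING
        work.depths[low] = -1
    keep: list[str] = []
    removed: dict[str, str] = {}
    called = work.called_mask().sum(axis=0)
    for j, locus in enumerate(work.loci):
        if called[j] < min_called:
            removed[locus.name] = (
                f"called in {called[j]}/{total} samples (< {min_called})"
            )
            continue
        maf = _minor_allele_frequency(work.codes[:, j, :])
        if maf is None or maf <= min_maf:
            removed[locus.name] = f"minor allele frequency {maf} <= {min_maf}"
            continue
        keep.append(locus.name)
    out = work.subset_loci(keep)
    report = FilterReport(
        stage="variant-hard-filter",
        n_in=matrix.n_loci,
        n_out=out.n_loci,
        removed=removed,
    )
    return out, report


def filter_call_rate(
    matrix: GenotypeMatrix, threshold: float
) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain loci whose call rate strictly exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    rates = matrix.call_rate()
    keep = [l.name for j, l in enumerate(matrix.loci) if rates[j] > threshold]
    removed = {
        l.name: f"call rate {rates[j]:.4f} <= {threshold}"
        for j, l in enumerate(matrix.loci)
        if rates[j] <= threshold
    }
    out = matrix.subset_loci(keep)
    return out, FilterReport(
        stage=f"call-rate>{threshold}",
        n_in=matrix.n_loci,
        n_out=out.n_loci,
        removed=removed,
    )


def check_flanks(tag_length: int, snp_position: int, min_flank: int = 75) -> bool:
    """True iff the SNP has at least ``min_flank`` bases on both sides.

    ``snp_position`` is 1-based within a tag of ``tag_length`` bases.
    """
    if not 1 <= snp_position <= tag_length:
        raise ValueError("snp_position must lie within the tag")
    return (snp_position - 1) >= min_flank and (tag_length - snp_position) >= min_flank


# ---------------------------------------------------------------------------
# SSR motif scanning
# ---------------------------------------------------------------------------

def scan_ssr_motifs(
    sequence: str,
    contig: str = "seq",
    min_repeats_by_unit_len: dict[int, int] | None = None,
) -> list[SSRMotifHit]:
    """Find all maximal perfect tandem repeats of unit length 1-6.

    A repeat is reported under its leftmost phase with 1-based inclusive
    coordinates. Runs wholly contained in a longer reported run with a
    shorter unit are suppressed (a (T)12 tract is not also a (TT)6 hit).
    ``N`` never occurs inside a reported repeat.
    """
    mins = dict(DEFAULT_MIN_REPEATS if min_repeats_by_unit_len is None else
                min_repeats_by_unit_len)
    seq = sequence.upper()
    n = len(seq)
    raw: list[tuple[int, int, int]] = []  # (start0, end0_exclusive, unit)
    for unit, min_rep in sorted(mins.items()):
        if unit < 1:
            raise ValueError("unit length must be >= 1")
        i = 0
        while i + unit * 2 <= n:
            if seq[i] == "N" or seq[i] != seq[i + unit]:
                i += 1
                continue
            # extend the match run s[j] == s[j-unit]
            j = i + unit
            while j < n and seq[j] != "N" and seq[j] == seq[j - unit]:
                j += 1
            run_len = j - i  # total tract length (>= unit+1 matched chars)
            repeats = run_len // unit
            if repeats >= min_rep and "N" not in seq[i : i + repeats * unit]:
                raw.append((i, i + repeats * unit, unit))
            i = j - unit + 1  # next possible distinct run start
    kept: list[tuple[int, int, int]] = []
    for s, e, u in sorted(raw, key=lambda t: (t[2], t[0])):
        contained = any(
            u2 < u and s2 <= s and e <= e2 for s2, e2, u2 in raw if u2 < u
        )
        if not contained:
            kept.append((s, e, u))
    hits = [
        SSRMotifHit(
            contig=contig,
            motif=seq[s : s + u],
            repeats=(e - s) // u,
            start=s + 1,
            end=e,
            left_flank=s,
            right_flank=n - e,
        )
        for s, e, u in sorted(kept)
    ]
    return hits


def scan_fasta(
    path: str, min_repeats_by_unit_len: dict[int, int] | None = None
) -> list[SSRMotifHit]:
    """Scan every record of a FASTA file for SSR motifs."""
    from Bio import SeqIO

    hits: list[SSRMotifHit] = []
    for rec in SeqIO.parse(path, "fasta"):
        hits.extend(
            scan_ssr_motifs(str(rec.seq), contig=rec.id,
                            min_repeats_by_unit_len=min_repeats_by_unit_len)
        )
    return hits


# ---------------------------------------------------------------------------
# Primer screening
# ---------------------------------------------------------------------------

def gc_fraction_tm(primer: str) -> float:
    """Quick-reference melting temperature: 64.9 + 41*(GC - 16.4)/length."""
    primer = primer.upper()
    if set(primer) - set("ACGT") or not primer:
        raise ValueError("primer must be non-empty over ACGT")
    gc = primer.count("G") + primer.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


@dataclass(frozen=True)
class PrimerConstraints:
    """Inclusive design windows for an SSR genotyping assay."""

    min_length: int = 18
    max_length: int = 23
    min_product: int = 100
    max_product: int = 280
    min_tm: float = 54.0
    max_tm: float = 60.0
    max_tm_delta: float = 0.5


def evaluate_primer_pair(
    forward: str,
    reverse: str,
    product_length: int,
    constraints: PrimerConstraints = PrimerConstraints(),
    tm_model: Callable[[str], float] = gc_fraction_tm,
) -> PrimerAssessment:
    """Check a primer pair against the design constraints.

    Each constraint is evaluated independently and every violation is listed;
    all ranges are inclusive. ``tm_model`` is swappable (default: GC-fraction
    approximation) — violations are relative to the chosen model.
    """
    tm_f = tm_model(forward)
    tm_r = tm_model(reverse)
    delta = abs(tm_f - tm_r)
    c = constraints
    violations: list[str] = []
    for label, seq in (("forward", forward), ("reverse", reverse)):
        if not c.min_length <= len(seq) <= c.max_length:
            violations.append(
                f"{label} length {len(seq)} outside [{c.min_length}, {c.max_length}]"
            )
    for label, tm in (("forward", tm_f), ("reverse", tm_r)):
        if not c.min_tm <= tm <= c.max_tm:
            violations.append(
                f"{label} Tm {tm:.2f} C outside [{c.min_tm}, {c.max_tm}]"
            )
    if not c.min_product <= product_length <= c.max_product:
        violations.append(
            f"product {product_length} bp outside [{c.min_product}, {c.max_product}]"
        )
    if delta > c.max_tm_delta:
        violations.append(f"Tm difference {delta:.2f} C exceeds {c.max_tm_delta}")
    return PrimerAssessment(
        forward=forward,
        reverse=reverse,
        tm_forward=tm_f,
        tm_reverse=tm_r,
        tm_delta=delta,
        product_length=product_length,
        violations=tuple(violations),
    )
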