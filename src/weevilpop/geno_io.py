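"""Domain model and file I/O for co-dominant genotype panels.

A panel is a rectangular grid of diploid genotype calls: individuals x loci,
where a locus is either a bi-allelic SNP (alleles are single bases) or a
microsatellite/SSR (alleles are PCR fragment lengths in base pairs). Missing
calls are atomic — a genotype is either a full unordered allele pair or
MISSING, never a half call. Optional per-call read depths are carried for
depth-gated filtering.

Supported formats: VCF 4.2 (SNPs, GT + optional DP), GenePop 3-digit and a
simple CSV table (SSRs), a TSV population map, and Newick output for
phenograms. Internally genotypes are stored as a dense integer array of
allele-registry indices (-1 = missing), the canonical form being the sorted
pair, which makes the diversity statistics vectorisable.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

MISSING = -1

SNP_BASES = frozenset("ACGT")


class MarkerKind(enum.Enum):
    SNP = "SNP"
    SSR = "SSR"


class GenotypeParseError(ValueError):
    """Raised when an input file violates the format contract."""


def _validate_allele(label: str, kind: MarkerKind) -> str:
    if not label:
        raise ValueError("empty allele label")
    if kind is MarkerKind.SNP:
        if label not in SNP_BASES:
            raise ValueError(
                f"SNP allele must be one of A/C/G/T, got {label!r}"
            )
    else:
        if not label.isdigit() or int(label) <= 0:
            raise ValueError(
                f"SSR allele must be a positive integer fragment length, got {label!r}"
            )
    return label


@dataclass(frozen=True)
class Locus:
    """A marker locus with its ordered allele registry.

    ``alleles`` lists every allele label that genotypes at this locus may
    reference, in registry order (for SNPs: REF first, then ALTs). SSR
    metadata columns (repeat motif, observed size range, annealing
    temperature) are optional carriers for report output.
    """

    name: str
    kind: MarkerKind
    alleles: tuple[str, ...]
    motif: str | None = None
    size_range: tuple[int, int] | None = None
    annealing_temp: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate alleles in registry of {self.name}")
        for a in self.alleles:
            _validate_allele(a, self.kind)
        if self.kind is MarkerKind.SNP and len(self.alleles) > 2:
            warnings.warn(
                f"SNP locus {self.name} has {len(self.alleles)} registry alleles "
                "(panel is expected to be bi-allelic)",
                stacklevel=2,
            )


class GenotypeMatrix:
    """Individuals x loci grid of unordered diploid genotype calls.

    Parameters
    ----------
    individuals : ordered unique individual IDs.
    loci : ordered :class:`Locus` objects with unique names.
    codes : int array (n_individuals, n_loci, 2) of allele-registry indices;
        both entries are -1 for a MISSING call. Pairs are stored sorted so
        the unordered genotype has one canonical encoding.
    depths : optional int array (n_individuals, n_loci); -1 where no depth
        is known. Depth may only be present on called genotypes.
    """

    def __init__(
        self,
        individuals: list[str],
        loci: list[Locus],
        codes: np.ndarray,
        depths: np.ndarray | None = None,
    ) -> None:
        individuals = list(individuals)
        loci = list(loci)
        if len(set(individuals)) != len(individuals):
            raise ValueError("individual IDs must be unique")
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        codes = np.asarray(codes, dtype=np.int16)
        if codes.shape != (len(individuals), len(loci), 2):
            raise ValueError(
                f"codes shape {codes.shape} != ({len(individuals)}, {len(loci)}, 2)"
            )
        half = (codes == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half calls are not allowed: both alleles or MISSING")
        for j, locus in enumerate(loci):
            top = codes[:, :, :][:, j, :].max(initial=MISSING)
            if top >= len(locus.alleles):
                raise ValueError(
                    f"genotype at locus {locus.name} references allele index {top} "
                    f"outside registry of size {len(locus.alleles)}"
                )
        # canonical: sorted pair (missing pairs are (-1,-1), already sorted)
        codes = np.sort(codes, axis=2)
        if depths is not None:
            depths = np.asarray(depths, dtype=np.int32)
            if depths.shape != (len(individuals), len(loci)):
                raise ValueError("depths shape mismatch")
            if ((depths >= 0) & (codes[:, :, 0] == MISSING)).any():
                raise ValueError("depth present on a MISSING call")
        self.individuals = individuals
        self.loci = loci
        self.codes = codes
        self.depths = depths
        self._locus_idx = {l.name: j for j, l in enumerate(loci)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, name: str) -> int:
        return self._locus_idx[name]

    def genotype(self, individual: str, locus: str) -> tuple[str, str] | None:
        """Return the unordered allele-label pair, or None when MISSING."""
        i = self.individuals.index(individual)
        j = self._locus_idx[locus]
        a, b = self.codes[i, j]
        if a == MISSING:
            return None
        reg = self.loci[j].alleles
        return (reg[a], reg[b])

    def depth(self, individual: str, locus: str) -> int | None:
        if self.depths is None:
            return None
        d = self.depths[self.individuals.index(individual), self._locus_idx[locus]]
        return None if d < 0 else int(d)

    def called_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is not MISSING."""
        return self.codes[:, :, 0] != MISSING

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of individuals with a called genotype."""
        return self.called_mask().mean(axis=0)

    # -- subsetting ------------------------------------------------------

    def subset_loci(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self._locus_idx[n] for n in names]
        return GenotypeMatrix(
            self.individuals,
            [self.loci[j] for j in idx],
            self.codes[:, idx, :],
            None if self.depths is None else self.depths[:, idx],
        )

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(
            [self.individuals[i] for i in idx],
            self.loci,
            self.codes[idx],
            None if self.depths is None else self.depths[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individuals),
            list(self.loci),
            self.codes.copy(),
            None if self.depths is None else self.depths.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_depth = (
            (self.depths is None and other.depths is None)
            or (
                self.depths is not None
                and other.depths is not None
                and np.array_equal(self.depths, other.depths)
            )
        )
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.codes, other.codes)
            and same_depth
        )


@dataclass
class PopulationMap:
    """Assignment of individuals to population codes, in file order."""

    assignment: dict[str, str]
    populations: list[str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population codes")
        missing = set(self.assignment.values()) - set(self.populations)
        if missing:
            raise ValueError(f"assignment references unlisted populations: {missing}")

    def members(self, code: str) -> list[str]:
        return [i for i, c in self.assignment.items() if c == code]

    @property
    def n_individuals(self) -> int:
        return len(self.assignment)


# ---------------------------------------------------------------------------
# VCF (SNPs)
# ---------------------------------------------------------------------------

def read_snp_vcf(path: str) -> GenotypeMatrix:
    """Read diploid SNP genotypes (GT, optional DP) from a VCF 4.x file.

    One :class:`Locus` per record; the allele registry is REF followed by the
    ALTs. ``./.`` and ``.|.`` become MISSING. Multi-allelic records are
    accepted with a warning; non-diploid GT is an error.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise GenotypeParseError(f"cannot parse VCF {path}: {exc}") from exc
    individuals = list(vf.header.samples)
    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    any_depth = False
    for rec in vf:
        alts = tuple(rec.alts or ())
        alleles = (rec.ref,) + alts
        if len(alleles) > 2:
            warnings.warn(
                f"multi-allelic record {rec.chrom}:{rec.pos} accepted "
                f"({len(alleles)} alleles)",
                stacklevel=2,
            )
        name = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        loci.append(Locus(name=name, kind=MarkerKind.SNP, alleles=alleles))
        col = np.full((len(individuals), 2), MISSING, dtype=np.int16)
        dcol = np.full(len(individuals), -1, dtype=np.int32)
        for i, sample in enumerate(individuals):
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            if len(gt) != 2 or any(a is None for a in gt):
                raise GenotypeParseError(
                    f"non-diploid GT {gt} for sample {sample} at {name}"
                )
            col[i] = sorted(gt)
            dp = call.get("DP")
            if dp is not None:
                dcol[i] = dp
                any_depth = True
        cols.append(col)
        depth_cols.append(dcol)
    vf.close()
    if not loci:
        return GenotypeMatrix(individuals, [], np.empty((len(individuals), 0, 2), np.int16))
    codes = np.stack(cols, axis=1)
    depths = np.stack(depth_cols, axis=1) if any_depth else None
    return GenotypeMatrix(individuals, loci, codes, depths)


def write_snp_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a SNP matrix as a minimal VCF 4.2 file (GT, DP when present).

    Locus names of the form ``chrom:pos`` are split back into coordinates;
    any other name becomes the record ID on a synthetic contig.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        contigs = []
        for locus in matrix.loci:
            chrom, _, pos = locus.name.partition(":")
            if not (pos and pos.isdigit()):
                chrom = "panel"
            if chrom not in contigs:
                contigs.append(chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        fmt = "GT:DP" if matrix.depths is not None else "GT"
        for j, locus in enumerate(matrix.loci):
            if locus.kind is not MarkerKind.SNP:
                raise ValueError(f"locus {locus.name} is not a SNP")
            chrom, _, pos = locus.name.partition(":")
            ident = "."
            if not (pos and pos.isdigit()):
                chrom, pos, ident = "panel", str(j + 1), locus.name
            ref = locus.alleles[0]
            alt = ",".join(locus.alleles[1:]) or "."
            fields = [chrom, pos, ident, ref, alt, ".", "PASS", ".", fmt]
            for i in range(matrix.n_individuals):
                a, b = matrix.codes[i, j]
                if a == MISSING:
                    gt = "./."
                    cell = gt if matrix.depths is None else gt + ":."
                else:
                    gt = f"{a}/{b}"
                    if matrix.depths is None:
                        cell = gt
                    else:
                        d = matrix.depths[i, j]
                        cell = gt + (":." if d < 0 else f":{d}")
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# SSR tables (GenePop / CSV)
# ---------------------------------------------------------------------------

def _decode_genepop_cell(cell: str, line_no: int) -> tuple[int, int] | None:
    if len(cell) == 4:
        raise GenotypeParseError(
            f"line {line_no}: 2-digit GenePop coding ({cell!r}) is not supported; "
            "re-export with 3-digit allele codes"
        )
    if len(cell) != 6 or not cell.isdigit():
        raise GenotypeParseError(
            f"line {line_no}: malformed GenePop genotype {cell!r} "
            "(expected six digits)"
        )
    a, b = int(cell[:3]), int(cell[3:])
    if a == 0 and b == 0:
        return None
    if a == 0 or b == 0:
        raise GenotypeParseError(
            f"line {line_no}: half call {cell!r} (one allele 000)"
        )
    return (a, b)


def read_ssr_table(
    path: str, dialect: str = "genepop"
) -> tuple[GenotypeMatrix, PopulationMap | None]:
    """Read SSR genotypes (fragment-length alleles).

    ``genepop`` dialect: standard GenePop with 3-digit allele coding;
    ``000000`` is MISSING, and the POP block structure yields a
    :class:`PopulationMap` as a side product (population code = first
    individual's ID prefix up to the last digit run, or ``POP<k>``).
    ``csv`` dialect: header row of locus names, one row per individual,
    cells ``a/b`` or ``-``; no population map (second return is None).
    """
    if dialect == "genepop":
        return _read_genepop(path)
    if dialect == "csv":
        return _read_ssr_csv(path), None
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_genepop(path: str) -> tuple[GenotypeMatrix, PopulationMap]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise GenotypeParseError("GenePop file too short")
    locus_names: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for name in lines[i].replace(",", " ").split():
            locus_names.append(name)
        i += 1
    if i == len(lines):
        raise GenotypeParseError("no POP line found")
    individuals: list[str] = []
    rows: list[list[tuple[int, int] | None]] = []
    assignment: dict[str, str] = {}
    pop_codes: list[str] = []
    pop_no = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_no += 1
            code = f"POP{pop_no}"
            pop_codes.append(code)
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise GenotypeParseError(f"line {i}: expected 'name , genotypes'")
        name, _, rest = line.partition(",")
        name = name.strip()
        cells = rest.split()
        if len(cells) != len(locus_names):
            raise GenotypeParseError(
                f"line {i}: {len(cells)} genotypes for {len(locus_names)} loci"
            )
        rows.append([_decode_genepop_cell(c, i) for c in cells])
        individuals.append(name)
        assignment[name] = pop_codes[-1]
    matrix = _ssr_matrix_from_pairs(individuals, locus_names, rows)
    popmap = PopulationMap(assignment=assignment, populations=pop_codes)
    return matrix, popmap


def _read_ssr_csv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeParseError("empty CSV genotype table")
    header = [c.strip() for c in lines[0].split(",")]
    locus_names = header[1:]
    individuals: list[str] = []
    rows: list[list[tuple[int, int] | None]] = []
    for ln_no, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != len(header):
            raise GenotypeParseError(f"line {ln_no}: wrong number of columns")
        individuals.append(cells[0])
        row: list[tuple[int, int] | None] = []
        for cell in cells[1:]:
            if cell == "-":
                row.append(None)
            else:
                a, _, b = cell.partition("/")
                if not (a.isdigit() and b.isdigit()):
                    raise GenotypeParseError(
                        f"line {ln_no}: malformed genotype cell {cell!r}"
                    )
                row.append((int(a), int(b)))
        rows.append(row)
    return _ssr_matrix_from_pairs(individuals, locus_names, rows)


def _ssr_matrix_from_pairs(
    individuals: list[str],
    locus_names: list[str],
    rows: list[list[tuple[int, int] | None]],
) -> GenotypeMatrix:
    loci: list[Locus] = []
    codes = np.full((len(individuals), len(locus_names), 2), MISSING, dtype=np.int16)
    for j, lname in enumerate(locus_names):
        observed = sorted(
            {a for row in rows for pair in [row[j]] if pair for a in pair}
        )
        registry = tuple(str(a) for a in observed)
        loci.append(Locus(name=lname, kind=MarkerKind.SSR, alleles=registry))
        index = {a: k for k, a in enumerate(observed)}
        for i, row in enumerate(rows):
            pair = row[j]
            if pair is not None:
                codes[i, j] = sorted((index[pair[0]], index[pair[1]]))
    return GenotypeMatrix(individuals, loci, codes)


def write_ssr_table(
    matrix: GenotypeMatrix,
    path: str,
    dialect: str = "genepop",
    popmap: PopulationMap | None = None,
) -> None:
    """Write an SSR matrix as GenePop (3-digit) or CSV."""
    for locus in matrix.loci:
        if locus.kind is not MarkerKind.SSR:
            raise ValueError(f"locus {locus.name} is not an SSR")
        if any(int(a) > 999 for a in locus.alleles):
            raise ValueError(
                f"locus {locus.name}: fragment length > 999 bp cannot use 3-digit coding"
            )
    if dialect == "genepop":
        groups: list[list[str]]
        if popmap is None:
            groups = [list(matrix.individuals)]
        else:
            groups = [
                [i for i in matrix.individuals if popmap.assignment.get(i) == code]
                for code in popmap.populations
            ]
            groups = [g for g in groups if g]
        with open(path, "w") as fh:
            fh.write("weevilpop SSR export\n")
            for locus in matrix.loci:
                fh.write(locus.name + "\n")
            for group in groups:
                fh.write("POP\n")
                for ind in group:
                    i = matrix.individuals.index(ind)
                    cells = []
                    for j, locus in enumerate(matrix.loci):
                        a, b = matrix.codes[i, j]
                        if a == MISSING:
                            cells.append("000000")
                        else:
                            cells.append(
                                f"{int(locus.alleles[a]):03d}{int(locus.alleles[b]):03d}"
                            )
                    fh.write(f"{ind} , " + " ".join(cells) + "\n")
    elif dialect == "csv":
        with open(path, "w") as fh:
            fh.write("individual," + ",".join(l.name for l in matrix.loci) + "\n")
            for i, ind in enumerate(matrix.individuals):
                cells = []
                for j, locus in enumerate(matrix.loci):
                    a, b = matrix.codes[i, j]
                    if a == MISSING:
                        cells.append("-")
                    else:
                        cells.append(f"{locus.alleles[a]}/{locus.alleles[b]}")
                fh.write(ind + "," + ",".join(cells) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Population map (TSV)
# ---------------------------------------------------------------------------

def read_population_map(path: str) -> PopulationMap:
    """Read a whitespace/TSV map: individual, population[, latitude, longitude]."""
    assignment: dict[str, str] = {}
    populations: list[str] = []
    coordinates: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if ln_no == 1 and parts[0].lower() == "individual":
                continue
            if len(parts) < 2:
                raise GenotypeParseError(f"line {ln_no}: expected at least 2 columns")
            ind, pop = parts[0], parts[1]
            if ind in assignment:
                raise GenotypeParseError(
                    f"line {ln_no}: individual {ind!r} assigned twice"
                )
            assignment[ind] = pop
            if pop not in populations:
                populations.append(pop)
            if len(parts) >= 4:
                coordinates[pop] = (float(parts[2]), float(parts[3]))
    if not assignment:
        raise GenotypeParseError(f"population map {path} is empty")
    return PopulationMap(assignment, populations, coordinates)


def write_population_map(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\n")
        for ind, pop in popmap.assignment.items():
            fh.write(f"{ind}\t{pop}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def newick_string(tree) -> str:
    """Serialise a phenogram (rooted, node heights) to Newick.

    ``tree`` is any node object exposing ``label`` (leaf name or None),
    ``children`` (list of nodes) and ``height`` (ultrametric node height);
    branch lengths are parent height minus child height.
    """
    if tree is None:
        raise ValueError("empty tree")

    def render(node) -> str:
        if not node.children:
            if not node.label:
                raise ValueError("unnamed leaf in phenogram")
            return node.label
        inner = ",".join(
            f"{render(child)}:{node.height - child.height:.8g}"
            for child in node.children
        )
        return f"({inner})"

    return render(tree) + ";"


def write_newick(tree, path: str) -> None:
    """Write a phenogram as a Newick file (see :func:`newick_string`)."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")
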