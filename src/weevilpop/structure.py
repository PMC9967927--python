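"""Between-population distance, UPGMA phenograms and individual ordination.

Nei's standard genetic distance (1972) between populations X and Y over L
shared loci:

    Jx = mean_l sum_i x_li^2,  Jy likewise,  Jxy = mean_l sum_i x_li y_li
    I = Jxy / sqrt(Jx Jy),     D = -ln I

(the classical ratio-of-locus-averaged-J form, not a per-locus average of
identities). D is non-negative up to floating error but not a metric; a pair
sharing no alleles at any locus has I = 0 and infinite D, carried as inf and
substituted by (1 + max finite D) before clustering, which preserves the
"farthest" rank.

UPGMA merges the closest pair, with cluster-to-cluster distance the
size-weighted arithmetic average of member distances and merge height half
the merge distance; ties break on the smallest (row, column) label order, so
trees are deterministic. The result is ultrametric by construction.

PCA runs on an individuals x allele-dosage design (one column per registry
allele minus one per locus, counts 0/1/2), with per-column mean imputation of
missing cells and centering (no unit-variance scaling), via SVD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geno_io import MISSING, GenotypeMatrix, PopulationMap
from .diversity_stats import allele_frequencies


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Nei D among populations (inf = no shared alleles)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T]
        ):
            raise ValueError("distance matrix must be symmetric")
        if (v[finite] < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    def mean_off_diagonal(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.values[iu]
        return float(np.mean(vals[np.isfinite(vals)]))

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class PhenogramNode:
    """Node of an ultrametric phenogram (leaf when ``children`` is empty)."""

    label: str | None
    height: float
    children: list["PhenogramNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label else []
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every node (internal and leaf), root included."""
        own = frozenset(self.leaves())
        out = [own]
        for c in self.children:
            out.extend(c.clades())
        return out


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    explained_variance: np.ndarray
    individuals: list[str]
    column_labels: list[str]
    degenerate: bool = False


def nei_distance(
    freqs_a: dict[str, dict[str, float]],
    freqs_b: dict[str, dict[str, float]],
) -> float:
    """Nei's standard genetic distance from per-locus allele frequencies.

    Arguments map locus name -> {allele label -> frequency} for each
    population. Loci absent (or empty) in either population are dropped
    pairwise; D = inf when the normalised identity is 0.
    """
    shared = [
        l
        for l in freqs_a
        if l in freqs_b and freqs_a[l] and freqs_b[l]
    ]
    if not shared:
        raise ValueError("no loci with data in both populations")
    jx = jy = jxy = 0.0
    for l in shared:
        fa, fb = freqs_a[l], freqs_b[l]
        alleles = set(fa) | set(fb)
        xa = np.array([fa.get(a, 0.0) for a in sorted(alleles)])
        xb = np.array([fb.get(a, 0.0) for a in sorted(alleles)])
        jx += float(np.sum(xa**2))
        jy += float(np.sum(xb**2))
        jxy += float(np.sum(xa * xb))
    jx /= len(shared)
    jy /= len(shared)
    jxy /= len(shared)
    identity = jxy / np.sqrt(jx * jy)
    if identity <= 0.0:
        return float("inf")
    return float(max(0.0, -np.log(identity)))


def population_frequencies(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> dict[str, dict[str, dict[str, float]]]:
    """population code -> locus -> allele -> frequency (called genotypes only)."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for code in popmap.populations:
        per_locus: dict[str, dict[str, float]] = {}
        for locus in matrix.loci:
            af = allele_frequencies(matrix, locus.name, code, popmap)
            per_locus[locus.name] = dict(af.frequencies)
        out[code] = per_locus
    return out


def distance_matrix(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> DistanceMatrix:
    """All-pairs Nei D among the mapped populations."""
    freqs = population_frequencies(matrix, popmap)
    labels = list(popmap.populations)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nei_distance(freqs[labels[i]], freqs[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def upgma(distances: DistanceMatrix) -> PhenogramNode:
    """Average-linkage (UPGMA) phenogram from a distance matrix.

    Infinite entries are replaced by 1 + the largest finite distance (with a
    warning) so every pair is mergeable. Ties break on the smallest (row,
    column) pair in label order. Leaf heights are 0; merge height is half the
    merge distance, so the tree is ultrametric.
    """
    labels = list(distances.labels)
    if len(labels) == 0:
        raise ValueError("empty distance matrix")
    d = distances.values.astype(float).copy()
    if not np.isfinite(d).all():
        finite_max = np.max(d[np.isfinite(d)]) if np.isfinite(d).any() else 1.0
        warnings.warn(
            f"infinite distances replaced by {finite_max + 1.0} for UPGMA",
            stacklevel=2,
        )
        d[~np.isfinite(d)] = finite_max + 1.0
    nodes: list[PhenogramNode] = [PhenogramNode(l, 0.0) for l in labels]
    sizes = [1] * len(labels)
    # "smallest label order": order of first appearance in the input labels
    ranks = list(range(len(labels)))
    while len(nodes) > 1:
        best: tuple[int, int] | None = None
        best_key: tuple[float, int, int] | None = None
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                a, b = sorted((ranks[i], ranks[j]))
                key = (float(d[i, j]), a, b)
                if best_key is None or key < best_key:
                    best_key, best = key, (i, j)
        i, j = best  # type: ignore[misc]
        height = d[i, j] / 2.0
        merged = PhenogramNode(None, height, [nodes[i], nodes[j]])
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * d[i, :] + nj * d[j, :]) / (ni + nj)
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = new_row[keep]
        nodes = [nodes[k] for k in keep] + [merged]
        sizes = [sizes[k] for k in keep] + [ni + nj]
        ranks = [ranks[k] for k in keep] + [min(ranks[i], ranks[j])]
    return nodes[0]


def cophenetic_distance(tree: PhenogramNode, a: str, b: str) -> float:
    """Tree distance between two leaves (2 x height of their join node)."""

    def smallest_containing(node: PhenogramNode) -> PhenogramNode | None:
        leaves = set(node.leaves())
        if not {a, b} <= leaves:
            return None
        for child in node.children:
            found = smallest_containing(child)
            if found is not None:
                return found
        return node

    join = smallest_containing(tree)
    if join is None:
        raise KeyError(f"leaves {a!r}, {b!r} not in tree")
    return 2.0 * join.height


def pca(
    matrix: GenotypeMatrix,
    n_components: int | None = None,
    scale: bool = False,
) -> OrdinationResult:
    """Principal components of the individuals x allele-dosage design.

    One column per registry allele minus one per locus (dosage 0/1/2 of each
    non-reference allele); missing calls are mean-imputed per column, columns
    are centred (and optionally unit-variance scaled), then decomposed by
    SVD. A panel with no genotype variance is returned flagged degenerate.
    """
    if matrix.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for j, locus in enumerate(matrix.loci):
        codes = matrix.codes[:, j, :]
        missing = codes[:, 0] == MISSING
        for a in range(1, len(locus.alleles)):
            dosage = (codes == a).sum(axis=1).astype(float)
            dosage[missing] = np.nan
            cols.append(dosage)
            labels.append(f"{locus.name}:{locus.alleles[a]}")
    design = np.column_stack(cols) if cols else np.empty((matrix.n_individuals, 0))
    col_mean = np.nanmean(np.where(np.isnan(design), np.nan, design), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(design), col_mean[None, :], design)
    centred = filled - filled.mean(axis=0)
    if scale:
        sd = centred.std(axis=0)
        centred = centred / np.where(sd == 0, 1.0, sd)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    total = float(np.sum(s**2))
    degenerate = total <= 1e-12
    explained = (s**2 / total) if not degenerate else np.zeros_like(s)
    coords = u * s
    if n_components is not None:
        coords = coords[:, :n_components]
        explained = explained[:n_components]
    return OrdinationResult(
        coordinates=coords,
        explained_variance=explained,
        individuals=list(matrix.individuals),
        column_labels=labels,
        degenerate=degenerate,
    )
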