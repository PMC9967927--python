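"""Nei distance, UPGMA phenograms and PCA ordination."""

import numpy as np
import pytest

from weevilpop.structure import (
    DistanceMatrix,
    PhenogramNode,
    cophenetic_distance,
    distance_matrix,
    nei_distance,
    pca,
    upgma,
)
from weevilpop.synthetic_data import SimulationConfig, simulate_panel


class TestNeiDistance:
    def test_identical_populations_zero(self):
        f = {"l1": {"A": 0.8, "T": 0.2}, "l2": {"124": 0.5, "130": 0.5}}
        assert nei_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_infinite(self):
        a = {"l1": {"A": 1.0}}
        b = {"l1": {"T": 1.0}}
        assert nei_distance(a, b) == float("inf")

    def test_hand_worked_single_locus(self):
        a = {"l1": {"A": 0.8, "T": 0.2}}
        b = {"l1": {"A": 0.2, "T": 0.8}}
        # Jx = Jy = 0.68, Jxy = 0.32, I = 0.470588, D = 0.75377
        assert nei_distance(a, b) == pytest.approx(0.75377, abs=1e-5)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a = {f"l{i}": dict(zip("ACGT", rng.dirichlet(np.ones(4)))) for i in range(5)}
        b = {f"l{i}": dict(zip("ACGT", rng.dirichlet(np.ones(4)))) for i in range(5)}
        assert nei_distance(a, b) == pytest.approx(nei_distance(b, a))

    def test_loci_without_shared_data_dropped_pairwise(self):
        a = {"l1": {"A": 1.0}, "l2": {}}
        b = {"l1": {"A": 0.5, "T": 0.5}, "l2": {"A": 1.0}}
        # l2 has no data in population a -> only l1 contributes
        d = nei_distance(a, b)
        assert np.isfinite(d)


class TestDistanceMatrix:
    def test_shape_and_symmetry(self, demo_panel):
        matrix, popmap, _ = demo_panel
        dm = distance_matrix(matrix, popmap)
        assert dm.labels == popmap.populations
        assert dm.values.shape == (12, 12)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_same_frequencies_give_near_zero_distance(self):
        # fst=0 -> both populations draw from identical frequencies
        cfg = SimulationConfig(
            n_populations=2, n_per_population=200, n_snp=100, n_ssr=0,
            fst=0.0, seed=12,
        )
        matrix, popmap, _ = simulate_panel(cfg)
        dm = distance_matrix(matrix, popmap)
        assert dm.values[0, 1] < 0.01

    def test_mean_d_increases_with_fst(self):
        means = []
        for fst in (0.01, 0.05, 0.2):
            cfg = SimulationConfig(
                n_populations=4, n_per_population=50, n_snp=60, n_ssr=0,
                fst=fst, seed=9,
            )
            matrix, popmap, _ = simulate_panel(cfg)
            means.append(distance_matrix(matrix, popmap).mean_off_diagonal())
        assert means[0] < means[1] < means[2]


class TestUpgma:
    def test_hand_executed_three_taxa(self):
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = upgma(dm)
        # ((A:1,B:1):1,C:2) — join heights 1 then 2
        assert tree.height == pytest.approx(2.0)
        assert sorted(tree.leaves()) == ["A", "B", "C"]
        assert cophenetic_distance(tree, "A", "B") == pytest.approx(2.0)
        assert cophenetic_distance(tree, "A", "C") == pytest.approx(4.0)
        assert frozenset({"A", "B"}) in tree.clades()

    def test_two_taxa_cherry(self):
        dm = DistanceMatrix(["X", "Y"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = upgma(dm)
        assert tree.height == pytest.approx(1.5)
        assert sorted(tree.leaves()) == ["X", "Y"]

    def test_ultrametric_input_reconstructed_exactly(self):
        # build a random ultrametric matrix from a random tree, then check
        # UPGMA returns exactly those cophenetic distances
        rng = np.random.default_rng(5)
        labels = list("ABCDEF")
        # random agglomeration with increasing heights
        clusters = [{l} for l in labels]
        heights = sorted(rng.uniform(0.5, 10.0, size=len(labels) - 1))
        join_height = {}
        for h in heights:
            i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
            for a in clusters[i]:
                for b in clusters[j]:
                    join_height[frozenset((a, b))] = h
            clusters[i] = clusters[i] | clusters[j]
            del clusters[j]
        values = np.zeros((6, 6))
        for x in range(6):
            for y in range(x + 1, 6):
                d = 2 * join_height[frozenset((labels[x], labels[y]))]
                values[x, y] = values[y, x] = d
        tree = upgma(DistanceMatrix(labels, values))
        for x in range(6):
            for y in range(x + 1, 6):
                assert cophenetic_distance(tree, labels[x], labels[y]) == pytest.approx(
                    values[x, y]
                )

    def test_ultrametric_output_property(self, demo_panel):
        matrix, popmap, _ = demo_panel
        tree = upgma(distance_matrix(matrix, popmap))
        assert sorted(tree.leaves()) == sorted(popmap.populations)

        def leaf_depths(node, acc):
            if not node.children:
                return [acc]
            out = []
            for c in node.children:
                out.extend(leaf_depths(c, acc + (node.height - c.height)))
            return out

        depths = leaf_depths(tree, 0.0)
        assert np.allclose(depths, depths[0])

    def test_tie_break_deterministic(self):
        values = np.array(
            [[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        t1 = upgma(DistanceMatrix(["A", "B", "C"], values.copy()))
        t2 = upgma(DistanceMatrix(["A", "B", "C"], values.copy()))
        # smallest (row, column) pair merges first: (A, B)
        assert frozenset({"A", "B"}) in t1.clades()
        assert t1.clades() == t2.clades()

    def test_infinite_distance_substituted_with_warning(self):
        values = np.array(
            [[0.0, np.inf, 1.0], [np.inf, 0.0, 2.0], [1.0, 2.0, 0.0]]
        )
        with pytest.warns(UserWarning, match="infinite"):
            tree = upgma(DistanceMatrix(["A", "B", "C"], values))
        assert sorted(tree.leaves()) == ["A", "B", "C"]
        # A-B were farthest; they must not form the first cherry
        assert frozenset({"A", "B"}) not in tree.clades()


class TestIntroductionScenario:
    def test_derived_populations_cluster_with_their_source(self):
        # two natives diverged at high Fst; ten introduced populations
        # resampled around the first native's frequencies at low Fst
        from weevilpop.synthetic_data import (
            _draw_population_frequencies,
            _sample_genotypes,
        )
        from weevilpop.geno_io import GenotypeMatrix, Locus, MarkerKind, PopulationMap
        import numpy as np

        rng = np.random.default_rng(99)
        n_loci, n_per = 80, 15
        codes = ["CAM", "GHN"] + [f"INT{k:02d}" for k in range(1, 11)]
        n_pop = len(codes)
        individuals = [f"{c}_{i}" for c in codes for i in range(n_per)]
        popmap = PopulationMap(
            {ind: ind.rsplit("_", 1)[0] for ind in individuals}, codes
        )
        loci = []
        calls = np.zeros((len(individuals), n_loci, 2), dtype=np.int16)
        for j in range(n_loci):
            p = rng.uniform(0.1, 0.9)
            anc = np.array([p, 1 - p])
            natives = _draw_population_frequencies(anc, 0.4, 2, rng)
            derived = _draw_population_frequencies(natives[0], 0.02, 10, rng)
            freqs = np.vstack([natives, derived])
            loci.append(Locus(f"s{j}", MarkerKind.SNP, ("A", "T")))
            for k in range(n_pop):
                calls[k * n_per : (k + 1) * n_per, j, :] = _sample_genotypes(
                    freqs[k], 0.0, n_per, rng
                )
        matrix = GenotypeMatrix(individuals, loci, calls)
        tree = upgma(distance_matrix(matrix, popmap))
        clades = tree.clades()
        derived_set = frozenset(codes[2:])

        smallest_derived = min(
            (c for c in clades if derived_set <= c), key=len
        )
        assert "GHN" not in smallest_derived
        smallest_with_source = min(
            (c for c in clades if derived_set | {"CAM"} <= c), key=len
        )
        assert "GHN" not in smallest_with_source


class TestPca:
    def test_identical_individuals_degenerate(self):
        from conftest import build_matrix

        m = build_matrix([[("A", "A")], [("A", "A")]])
        res = pca(m)
        assert res.degenerate

    def test_fewer_than_two_individuals_rejected(self):
        from conftest import build_matrix

        m = build_matrix([[("A", "T")]])
        with pytest.raises(ValueError):
            pca(m)

    def test_explained_variance_properties(self, demo_panel):
        matrix, _, _ = demo_panel
        res = pca(matrix)
        ev = res.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1.0 + 1e-9

    def test_three_cluster_separation_nearest_centroid(self):
        cfg = SimulationConfig(
            n_populations=3, n_per_population=15, n_snp=200, n_ssr=0,
            fst=0.3, seed=17,
        )
        matrix, popmap, _ = simulate_panel(cfg)
        res = pca(matrix, n_components=2)
        labels = np.array(
            [popmap.assignment[i] for i in res.individuals]
        )
        coords = res.coordinates
        centroids = {
            c: coords[labels == c].mean(axis=0) for c in popmap.populations
        }
        assigned = [
            min(centroids, key=lambda c: np.linalg.norm(x - centroids[c]))
            for x in coords
        ]
        accuracy = np.mean([a == t for a, t in zip(assigned, labels)])
        assert accuracy >= 0.95

    def test_missing_cells_mean_imputed(self):
        from conftest import build_matrix

        m = build_matrix(
            [[("A", "T")], [None], [("T", "T")], [("A", "A")]]
        )
        res = pca(m)
        assert np.isfinite(res.coordinates).all()
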