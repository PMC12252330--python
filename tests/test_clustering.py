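"""Distances, Ward.D2 merges, tree cuts, and group summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phenotax import (
    GermplasmRecord,
    GermplasmRegister,
    QualitativeTraitSpec,
    QuantitativeTraitSpec,
    SimulationConfig,
    aggregate,
    cut,
    euclidean_distances,
    generate_population,
    gower_distances,
    species_proportions,
    species_share,
    standardize,
    summarize_groups,
    ward_d2,
)

from conftest import make_matrix


def ward_oracle(points: np.ndarray) -> list[frozenset]:
    """Exhaustive agglomeration: at each step merge the pair of clusters
    whose union gives the minimal increase in total within-cluster sum of
    squares (ties: smallest indices). Returns the merged sets in order."""

    def ess(idx):
        pts = points[sorted(idx)]
        return ((pts - pts.mean(axis=0)) ** 2).sum()

    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            inc = ess(clusters[i] | clusters[j]) - ess(clusters[i]) - ess(clusters[j])
            if best is None or inc < best[0] - 1e-12:
                best = (inc, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return merges


def linkage_merge_sets(dendro) -> list[frozenset]:
    n = dendro.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(dendro.linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


def matrix_from_points(points: np.ndarray):
    return make_matrix({f"d{j}": points[:, j].tolist()
                        for j in range(points.shape[1])})


class TestDistances:
    def test_three_four_five(self):
        m = make_matrix({"x": [0.0, 3.0], "y": [0.0, 4.0]})
        d = euclidean_distances(m)
        assert d.iloc[0, 1] == pytest.approx(5.0)
        assert d.iloc[1, 0] == pytest.approx(5.0)
        assert np.diag(d).tolist() == [0.0, 0.0]

    def test_identical_rows_zero(self):
        m = make_matrix({"x": [1.0, 1.0], "y": [2.0, 2.0]})
        assert euclidean_distances(m).iloc[0, 1] == 0.0

    def test_triangle_inequality(self):
        rng = np.random.default_rng(0)
        m = matrix_from_points(rng.normal(size=(6, 3)))
        d = euclidean_distances(m).to_numpy()
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_gower_bounded_and_symmetric(self):
        m = make_matrix({"q": [0, 1, 2, 1], "v": [1.0, 5.0, 3.0, 2.0]},
                        kinds={"q": "qualitative"})
        d = gower_distances(m).to_numpy()
        assert np.allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1


class TestWard:
    def test_two_points_merge_at_their_distance(self):
        m = make_matrix({"x": [0.0, 3.0], "y": [0.0, 4.0]})
        dendro = ward_d2(euclidean_distances(m))
        assert dendro.heights.tolist() == pytest.approx([5.0])

    def test_close_pair_merges_first(self):
        m = make_matrix({"x": [0.0, 0.1, 10.0]})
        dendro = ward_d2(euclidean_distances(m))
        assert linkage_merge_sets(dendro)[0] == frozenset({0, 1})

    def test_single_point_rejected(self):
        m = make_matrix({"x": [1.0]})
        with pytest.raises(ValueError):
            ward_d2(euclidean_distances(m))

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(1)
        m = matrix_from_points(rng.normal(size=(12, 4)))
        dendro = ward_d2(euclidean_distances(m))
        assert np.all(np.diff(dendro.heights) >= -1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_sequence_matches_ess_oracle(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(7, 3))
        dendro = ward_d2(euclidean_distances(matrix_from_points(points)))
        assert linkage_merge_sets(dendro) == ward_oracle(points)

    def test_height_is_sqrt_twice_ess_increase(self):
        # distance-scale convention: h^2 / 2 equals the ESS increase
        rng = np.random.default_rng(2)
        points = rng.normal(size=(6, 2))
        dendro = ward_d2(euclidean_distances(matrix_from_points(points)))

        def ess(idx):
            pts = points[sorted(idx)]
            return ((pts - pts.mean(axis=0)) ** 2).sum()

        n = len(points)
        members = {i: frozenset([i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(dendro.linkage):
            left, right = members[int(a)], members[int(b)]
            merged = left | right
            members[n + step] = merged
            inc = ess(merged) - ess(left) - ess(right)
            assert h == pytest.approx(np.sqrt(2 * inc))


class TestCut:
    def make_dendro(self, n=8, seed=3):
        rng = np.random.default_rng(seed)
        return ward_d2(euclidean_distances(
            matrix_from_points(rng.normal(size=(n, 2)))))

    def test_extremes(self):
        d = self.make_dendro()
        assert len(set(cut(d, 8).assignments.values())) == 8
        assert set(cut(d, 1).assignments.values()) == {1}

    def test_out_of_range_rejected(self):
        d = self.make_dendro()
        for k in (0, 9):
            with pytest.raises(ValueError):
                cut(d, k)

    def test_labels_numbered_by_first_occurrence(self):
        d = self.make_dendro()
        part = cut(d, 3)
        seen = []
        for g in d.labels:
            c = part.assignments[g]
            if c not in seen:
                seen.append(c)
        assert seen == [1, 2, 3]

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(4)
        points = np.vstack([rng.normal(0, 0.3, size=(10, 2)),
                            rng.normal(8, 0.3, size=(10, 2))])
        truth = [0] * 10 + [1] * 10
        part = cut(ward_d2(euclidean_distances(matrix_from_points(points))), 2)
        labels = [part.assignments[f"g{i + 1}"] for i in range(20)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(10, 3))
        m = matrix_from_points(points)
        part1 = cut(ward_d2(euclidean_distances(m)), 3)
        perm = rng.permutation(10)
        m2 = matrix_from_points(points[perm])
        ids2 = [f"g{i + 1}" for i in perm]
        m2.data.index = pd.Index(ids2, name="germplasm_id")
        part2 = cut(ward_d2(euclidean_distances(m2)), 3)
        a = [part1.assignments[f"g{i + 1}"] for i in range(10)]
        b = [part2.assignments[f"g{i + 1}"] for i in range(10)]
        assert adjusted_rand_score(a, b) == 1.0


def blob_population(seed=0, fidelity=1.0):
    """5 widely separated groups, tight replicates."""
    n_groups = 5
    quant = tuple(
        QuantitativeTraitSpec(
            f"v{j}", tuple(10.0 + 30.0 * ((g + j) % n_groups) for g in range(n_groups)),
            germplasm_sd=0.5, within_cv=1.0)
        for j in range(4)
    )
    cfg = SimulationConfig(
        n_species=20, n_cultivars=10, n_groups=n_groups,
        qualitative=(), quantitative=quant,
        inheritance_fidelity=fidelity, replicates_per_germplasm=5, seed=seed)
    return generate_population(cfg)


class TestRecovery:
    def test_five_separated_groups_ari_one(self):
        reg, cb, obs, truth = blob_population(seed=7)
        m = aggregate(obs, cb)
        part = cut(ward_d2(euclidean_distances(standardize(m))), 5)
        ids = list(part.assignments)
        ari = adjusted_rand_score([truth.group[g] for g in ids],
                                  [part.assignments[g] for g in ids])
        assert ari == 1.0


class TestSummaries:
    def test_single_cluster_whole_sample_means(self, register):
        m = make_matrix({"v": [2.0, 4.0, 6.0]}, ids=["g1", "g2", "g3"])
        from phenotax import Partition
        part = Partition({"g1": 1, "g2": 1, "g3": 1})
        s = summarize_groups(part, m, register)
        assert s.counts.at[1, "n"] == 3
        assert s.counts.at[1, "n_species"] == 2
        assert s.quantitative.at[(1, "v"), "mean"] == pytest.approx(4.0)

    def test_singleton_cluster_sd_zero_flagged(self, register):
        m = make_matrix({"v": [2.0, 4.0, 6.0]}, ids=["g1", "g2", "g3"])
        from phenotax import Partition
        part = Partition({"g1": 1, "g2": 2, "g3": 2})
        s = summarize_groups(part, m, register)
        assert s.quantitative.at[(1, "v"), "sd"] == 0.0
        assert bool(s.quantitative.at[(1, "v"), "singleton"])

    def test_group_mean_recovery_on_synthetic_blobs(self):
        reg, cb, obs, truth = blob_population(seed=8)
        m = aggregate(obs, cb)
        part = cut(ward_d2(euclidean_distances(standardize(m))), 5)
        s = summarize_groups(part, m, reg)
        # each cluster's mean of v0 must sit near one configured group mean
        cfg_means = set(truth.config.quantitative[0].group_means)
        for c in part.clusters():
            mean = s.quantitative.at[(c, "v0"), "mean"]
            assert min(abs(mean - gm) for gm in cfg_means) < 2.0


def partition_of(sizes_species: dict[int, tuple[int, int]]):
    """Build (Partition, Register) with given (n_species, n_cultivars) per
    cluster."""
    from phenotax import Partition
    records, assignments = [], {}
    i = 0
    for c, (n_sp, n_cv) in sizes_species.items():
        for _ in range(n_sp):
            gid = f"S{i}"
            records.append(GermplasmRecord(gid, "species", section="X"))
            assignments[gid] = c
            i += 1
        for _ in range(n_cv):
            gid = f"C{i}"
            records.append(GermplasmRecord(gid, "cultivar"))
            assignments[gid] = c
            i += 1
    return Partition(assignments), GermplasmRegister(tuple(records))


class TestSpeciesProportions:
    def test_printed_subgroup_compositions(self):
        part, reg = partition_of({1: (12, 1), 2: (6, 16)})
        props = species_proportions(part, reg)
        assert props[1] == 92.3
        assert props[2] == 27.3

    def test_all_cultivar_cluster_zero(self):
        part, reg = partition_of({1: (0, 5), 2: (3, 0)})
        assert species_proportions(part, reg)[1] == 0.0

    def test_size_weighted_proportions_reproduce_global_fraction(self):
        part, reg = partition_of({1: (6, 16), 2: (2, 8), 3: (11, 10),
                                  4: (3, 4), 5: (12, 1)})
        props = species_proportions(part, reg)
        sizes = part.sizes()
        total = sum(sizes.values())
        weighted = sum(props[c] * sizes[c] for c in sizes) / total
        global_frac = 100 * len(reg.species_ids()) / total
        assert weighted == pytest.approx(global_frac, abs=0.05)

    def test_species_share_sums_to_hundred(self):
        part, reg = partition_of({1: (6, 16), 2: (2, 8), 3: (11, 10),
                                  4: (3, 4), 5: (12, 1)})
        share = species_share(part, reg)
        assert sum(share.values()) == pytest.approx(100.0, abs=0.3)


class TestNewick:
    def test_round_trip_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        m = matrix_from_points(rng.normal(size=(8, 3)))
        dendro = ward_d2(euclidean_distances(m))
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        assert leaves == set(dendro.labels)
        # root-to-leaf path length equals the root merge height for every leaf
        root_h = dendro.heights[-1]
        for leaf in tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_h, abs=1e-4)
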