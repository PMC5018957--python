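"""p-distance, neighbour joining (additive-exactness), PCA conventions."""

import itertools

import numpy as np
import pytest

from popkit import (
    DistanceMatrix,
    GroupSpec,
    PopulationModel,
    neighbor_joining,
    p_distance,
    run_pca,
    simulate_populations,
)
from popkit.core import BiallelicMatrix

from conftest import make_matrix


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns the exact
    leaf-to-leaf path-distance matrix (the additive oracle)."""
    names = [f"t{i}" for i in range(n_taxa)]
    # start from a star over 3 leaves, attach remaining leaves to random edges
    # represented as a distance matrix built by explicit path bookkeeping:
    # simplest exact construction: random topology via random joins.
    nodes = {i: [n] for i, n in enumerate(names)}
    D = np.zeros((n_taxa, n_taxa))
    # build a random tree by sequential joining, tracking leaf distances
    active = list(range(n_taxa))
    dist_to_leaves = {i: {names[i]: 0.0} for i in range(n_taxa)}
    next_id = n_taxa
    while len(active) > 2:
        i, j = rng.choice(active, size=2, replace=False)
        li = rng.uniform(0.5, 3.0)
        lj = rng.uniform(0.5, 3.0)
        for a, da in dist_to_leaves[i].items():
            for b, db in dist_to_leaves[j].items():
                ia, ib = names.index(a), names.index(b)
                D[ia, ib] = D[ib, ia] = da + li + db + lj
        merged = {a: d + li for a, d in dist_to_leaves[i].items()}
        merged.update({b: d + lj for b, d in dist_to_leaves[j].items()})
        dist_to_leaves[next_id] = merged
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    i, j = active
    l = rng.uniform(0.5, 3.0)
    for a, da in dist_to_leaves[i].items():
        for b, db in dist_to_leaves[j].items():
            ia, ib = names.index(a), names.index(b)
            D[ia, ib] = D[ib, ia] = da + db + l
    return names, D


class TestPDistance:
    def test_extremes(self):
        m = make_matrix([[0] * 50, [0] * 50, [1] * 50])
        D = p_distance(m).values
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0

    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="non-negative"):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # three-point formulas: la = (dab + dac - dbc)/2 etc.
        D = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = neighbor_joining(D)
        got = tree.leaf_distances()
        assert np.allclose(got.values, D.to_frame().values)

    def test_four_taxon_additive_case(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): split AB|CD, exact path lengths
        names = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            float,
        )
        tree = neighbor_joining(DistanceMatrix(names, D))
        assert frozenset({"A", "B"}) in tree.splits()
        got = tree.leaf_distances().loc[names, names].values
        assert np.allclose(got, D, atol=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7])
    def test_recovers_random_additive_trees_exactly(self, n_taxa):
        """NJ is consistent on additive input: recovered path distances
        reproduce the generating matrix to machine precision, which pins
        both the topology and every branch length."""
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(5):
            names, D = random_additive_tree(rng, n_taxa)
            tree = neighbor_joining(DistanceMatrix(names, D))
            got = tree.leaf_distances().loc[names, names].values
            assert np.allclose(got, D, atol=1e-8)

    def test_matches_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbour joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        names, D = random_additive_tree(rng, 6)
        noisy = D + rng.uniform(0, 0.05, D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        mine = neighbor_joining(DistanceMatrix(names, noisy))
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        sk_tree = sk_nj(SkDM(noisy, ids=names))
        sk_splits = set()
        all_names = frozenset(names)
        for node in sk_tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(names) - 1:
                sk_splits.add(min(below, all_names - below, key=lambda s: (len(s), sorted(s))))
        assert mine.splits() == sk_splits

    def test_newick_is_deterministic_and_parseable(self):
        rng = np.random.default_rng(7)
        names, D = random_additive_tree(rng, 5)
        t1 = neighbor_joining(DistanceMatrix(names, D)).newick()
        t2 = neighbor_joining(DistanceMatrix(names, D)).newick()
        assert t1 == t2 and t1.endswith(";")
        import dendropy

        tree = dendropy.Tree.get(data=t1, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(names)

    def test_two_groups_form_two_clades(self):
        hits = 0
        for seed in range(10):
            model = PopulationModel(
                chromosome_lengths=(100_000,),
                n_sites=300,
                groups=(GroupSpec("a", 5, 0.3), GroupSpec("b", 5, 0.3)),
                admixed=(),
                seed=seed,
            )
            t = simulate_populations(model)
            m = BiallelicMatrix(t.accessions, t.sites, t.genotypes)
            tree = neighbor_joining(p_distance(m))
            split_a = frozenset(f"a_{i}" for i in range(1, 6))
            split_b = frozenset(f"b_{i}" for i in range(1, 6))
            canon = min(split_a, split_b, key=lambda s: (len(s), sorted(s)))
            if canon in tree.splits():
                hits += 1
        assert hits >= 9


class TestPCA:
    def test_two_clusters_concentrate_on_pc1(self):
        G = np.array([[0] * 40] * 5 + [[1] * 40] * 5)
        m = make_matrix(G)
        res = run_pca(m)
        pc1 = res.scores[:, 0]
        assert len(np.unique(np.round(pc1, 9))) == 2
        assert np.sign(pc1[0]) != np.sign(pc1[-1])
        assert res.eigenvalues[0] / res.eigenvalues.sum() > 0.99

    def test_duplicated_rows_share_scores(self):
        rng = np.random.default_rng(5)
        G = rng.integers(0, 2, size=(6, 30))
        G = np.vstack([G, G[2]])
        res = run_pca(make_matrix(G))
        keep = res.eigenvalues[: res.scores.shape[1]] > 1e-9  # ignore null space
        assert np.allclose(res.scores[2, keep], res.scores[-1, keep], atol=1e-9)

    def test_eigenvalue_bookkeeping(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.integers(0, 2, size=(10, 80)))
        res = run_pca(m)
        assert np.all(res.eigenvalues >= 0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        # eigenvalues sum to the total variance (trace of the covariance)
        G = m.genotypes.astype(float)
        poly = G.min(axis=0) != G.max(axis=0)
        G = G[:, poly]
        X = G - G.mean(axis=0)
        p_hat = (1.0 + G.sum(axis=0)) / (2.0 + G.shape[0])
        X = X / np.sqrt(p_hat * (1 - p_hat))
        total = np.trace(X @ X.T) / X.shape[1]
        assert res.eigenvalues.sum() == pytest.approx(total, abs=1e-8)
        # scores along distinct PCs are orthogonal
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            run_pca(make_matrix(np.zeros((4, 10), dtype=np.int8)))

    def test_admixed_accessions_fall_between_groups_on_pc1(self):
        hits = 0
        for seed in range(10):
            model = PopulationModel(
                chromosome_lengths=(200_000,),
                n_sites=400,
                groups=(GroupSpec("occ", 6, 0.3), GroupSpec("ori", 6, 0.3)),
                admixed=(
                    ("mar_1", {"occ": 0.5, "ori": 0.5}),
                    ("mar_2", {"occ": 0.5, "ori": 0.5}),
                ),
                seed=seed,
            )
            t = simulate_populations(model)
            res = run_pca(BiallelicMatrix(t.accessions, t.sites, t.genotypes))
            pc1 = dict(zip(t.accessions, res.scores[:, 0]))
            occ = [pc1[f"occ_{i}"] for i in range(1, 7)]
            ori = [pc1[f"ori_{i}"] for i in range(1, 7)]
            lo, hi = sorted([np.mean(occ), np.mean(ori)])
            if all(lo < pc1[f"mar_{j}"] < hi for j in (1, 2)):
                hits += 1
        assert hits >= 9
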