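"""Recoding, distances, neighbor joining, PCA and admixture EM."""

import numpy as np
import pytest

from cnvpop.cnvr import Cnvr, CnvrGenotypes
from cnvpop.simdata import SimConfig, simulate_freqs, simulate_genotypes
from cnvpop.structure import (
    AdmixtureEM,
    BiallelicMatrix,
    align_q,
    distance_matrix,
    nj_tree,
    pca,
    recode_biallelic,
    to_newick,
    tree_distances,
)

from conftest import truth_dosages


def _geno(states, types):
    states = np.asarray(states)
    cnvrs = [
        Cnvr(id=f"c{j}", chrom="chr1", start=1000 * j, end=1000 * j + 500,
             type=t, carriers={"b": {"s0"}})
        for j, t in enumerate(types)
    ]
    n = states.shape[0]
    return CnvrGenotypes(
        sample_ids=[f"s{i}" for i in range(n)],
        breed_labels=["b1"] * (n // 2) + ["b2"] * (n - n // 2),
        cnvrs=cnvrs,
        states=states,
    )


def _mat(dosages, breeds=None):
    dosages = np.asarray(dosages)
    return BiallelicMatrix(
        sample_ids=[f"s{i}" for i in range(dosages.shape[0])],
        dosages=dosages,
        loci=None,
        breed_labels=breeds,
    )


class TestRecode:
    def test_loss_gain_and_mixed_recoding(self):
        geno = _geno([[0, 3, 2], [1, 2, 4]], ["loss", "gain", "mixed"])
        mat = recode_biallelic(geno)
        # mixed region yields two pseudo-loci -> 4 columns
        assert mat.dosages.shape == (2, 4)
        assert list(mat.loci["allele"]) == ["loss", "gain", "loss", "gain"]
        np.testing.assert_array_equal(mat.dosages[0], [2, 1, 0, 0])  # copy 0,3,2
        np.testing.assert_array_equal(mat.dosages[1], [1, 0, 0, 2])  # copy 1,2,4

    def test_frequencies_and_monomorphic_flag(self):
        mat = _mat([[0, 2], [0, 2]])
        np.testing.assert_allclose(mat.freqs, [0.0, 1.0])
        assert mat.monomorphic.all()


class TestDistances:
    def test_identical_rows_zero_distance(self):
        labels, D = distance_matrix(_mat([[1, 1, 0], [1, 1, 0]]))
        assert D[0, 1] == 0.0

    def test_opposite_rows_max_distance(self):
        labels, D = distance_matrix(_mat([[0, 0, 0], [2, 2, 2]]))
        assert D[0, 1] == 1.0

    def test_symmetry_zero_diagonal_bounds(self):
        rng = np.random.default_rng(0)
        labels, D = distance_matrix(_mat(rng.integers(0, 3, size=(6, 40))))
        np.testing.assert_allclose(D, D.T)
        assert np.diagonal(D).sum() == 0.0
        assert ((D >= 0) & (D <= 1)).all()

    def test_fst_population_distance_tracks_drift(self):
        cfg = SimConfig(
            seed=4, n_loci=2000, F_bg=0.2, frac_selected=0.0, pop_sizes=(30, 30),
            chrom_lengths={f"chr{i}": 5_000_000 for i in range(1, 11)},
            min_locus_len=1_000, max_locus_len=2_000,
        )
        rng = np.random.default_rng(cfg.seed)
        truth = simulate_genotypes(simulate_freqs(cfg, rng), cfg, rng)
        mat = _mat(truth_dosages(truth), breeds=truth.breed_labels)
        labels, D = distance_matrix(mat, mode="fst_population")
        assert labels == ["pop1", "pop2"]
        assert 0.16 <= D[0, 1] <= 0.24


WORKED_4TAXON = np.array(
    [
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ],
    dtype=float,
)  # additive: ((A:1,B:2):1,(C:3,D:4))


def random_additive_matrix(rng, n_taxa):
    """Random binary tree with positive lengths -> its tip-tip metric."""
    from skbio import TreeNode

    tips = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 2))) for i in range(n_taxa)]
    nodes = list(tips)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]], length=float(rng.uniform(0.1, 2)))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    labels = [f"t{i}" for i in range(n_taxa)]
    dm = root.tip_tip_distances()
    ids = list(dm.ids)
    D = np.array([[dm[ids.index(a), ids.index(b)] if a != b else 0.0 for b in labels] for a in labels])
    return labels, D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_tree(labels, D)
        got = tree_distances(tree, labels)
        np.testing.assert_allclose(got, D, atol=1e-9)

    def test_worked_four_taxon_example(self):
        labels = ["A", "B", "C", "D"]
        tree = nj_tree(labels, WORKED_4TAXON)
        got = tree_distances(tree, labels)
        np.testing.assert_allclose(got, WORKED_4TAXON, atol=1e-9)
        # topology AB|CD: A and B share a parent apart from C, D
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].parent is tips["B"].parent or tips["C"].parent is tips["D"].parent

    def test_random_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            labels, D = random_additive_matrix(rng, n)
            got = tree_distances(nj_tree(labels, D), labels)
            np.testing.assert_allclose(got, D, atol=1e-9)

    def test_agrees_with_reference_nj_implementation(self):
        """Independent cross-check against scikit-bio's neighbor joining."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(2)
        labels, D = random_additive_matrix(rng, 6)
        ours = tree_distances(nj_tree(labels, D), labels)
        ref_tree = skbio_nj(DistanceMatrix(D, ids=labels))
        dm = ref_tree.tip_tip_distances()
        ids = list(dm.ids)
        ref = np.array(
            [[dm[ids.index(a), ids.index(b)] if a != b else 0.0 for b in labels] for a in labels]
        )
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_newick_roundtrip_six_decimals(self):
        import io as _io

        from skbio import TreeNode

        labels = ["A", "B", "C", "D"]
        nwk = to_newick(nj_tree(labels, WORKED_4TAXON))
        reread = TreeNode.read(_io.StringIO(nwk))
        assert sorted(t.name for t in reread.tips()) == labels

    def test_asymmetric_matrix_rejected(self):
        D = WORKED_4TAXON.copy()
        D[0, 1] = 99
        with pytest.raises(ValueError):
            nj_tree(["A", "B", "C", "D"], D)


class TestPca:
    def test_two_identical_blocks_give_rank_one(self):
        G = np.array([[0, 0, 2, 2]] * 4 + [[2, 2, 0, 0]] * 4)
        res = pca(_mat(G))
        assert res.pct_variance[0] == pytest.approx(100.0)
        assert np.sign(res.coords[:4, 0]).std() == 0  # block-constant PC1
        assert res.coords[0, 0] * res.coords[-1, 0] < 0

    def test_pct_variance_sums_to_100(self):
        rng = np.random.default_rng(3)
        res = pca(_mat(rng.integers(0, 3, size=(10, 50))))
        assert res.pct_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert (res.eigenvalues >= 0).all()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            pca(_mat(np.zeros((4, 5), dtype=int)))

    def test_two_populations_separate_on_pc1(self):
        cfg = SimConfig(
            seed=6, n_loci=1000, F_bg=0.2, frac_selected=0.0, pop_sizes=(30, 30),
            chrom_lengths={f"chr{i}": 3_000_000 for i in range(1, 11)},
            min_locus_len=1_000, max_locus_len=2_000,
        )
        rng = np.random.default_rng(cfg.seed)
        truth = simulate_genotypes(simulate_freqs(cfg, rng), cfg, rng)
        res = pca(_mat(truth_dosages(truth)))
        pc1 = res.coords[:, 0]
        assert max(pc1[:30].min(), pc1[30:].min()) > min(pc1[:30].max(), pc1[30:].max()) or (
            pc1[:30].max() < pc1[30:].min() or pc1[30:].max() < pc1[:30].min()
        )
        assert res.pct_variance[0] > res.pct_variance[1]


class TestAdmixture:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(12, 40)).astype(float)
        fit = AdmixtureEM(n_components=1, n_init=1, max_iter=5, random_state=0).fit(G)
        np.testing.assert_allclose(fit.Q_, 1.0)
        phat = np.clip(G.mean(axis=0) / 2, 1e-6, 1 - 1e-6)
        np.testing.assert_allclose(fit.F_[0], phat, atol=1e-6)

    def test_loglik_monotone_on_random_data(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(20, 60)).astype(float)
        fit = AdmixtureEM(n_components=3, n_init=2, max_iter=300, random_state=1).fit(G)
        assert (np.diff(fit.loglik_trace_) >= -1e-8).all()

    def test_component_permutation_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, size=(10, 30)).astype(float)
        fit = AdmixtureEM(n_components=2, n_init=1, max_iter=50, random_state=2).fit(G)
        model = AdmixtureEM(n_components=2)
        ll = model._loglik(G, fit.Q_ @ fit.F_)
        ll_perm = model._loglik(G, fit.Q_[:, ::-1] @ fit.F_[::-1])
        assert ll == pytest.approx(ll_perm, abs=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            AdmixtureEM(n_components=5).fit(np.zeros((3, 10)))

    def test_two_population_ancestry_recovered(self):
        cfg = SimConfig(
            seed=11, n_loci=1000, F_bg=0.3, frac_selected=0.0, pop_sizes=(20, 20),
            chrom_lengths={f"chr{i}": 3_000_000 for i in range(1, 11)},
            min_locus_len=1_000, max_locus_len=2_000,
        )
        rng = np.random.default_rng(cfg.seed)
        truth = simulate_genotypes(simulate_freqs(cfg, rng), cfg, rng)
        fit = AdmixtureEM(n_components=2, n_init=3, random_state=5).fit(
            truth_dosages(truth).astype(float)
        )
        Qa = align_q(fit.Q_, truth.Q_true)
        rmse = float(np.sqrt(((Qa - truth.Q_true) ** 2).mean()))
        assert rmse < 0.05
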