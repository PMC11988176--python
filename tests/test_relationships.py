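"""G, A, A-inverse and single-step H-inverse construction."""

import numpy as np
import pytest

from gpcomp import (
    Pedigree,
    assemble_H_inverse,
    blend_G,
    compute_A,
    compute_A22,
    compute_A_inverse,
    compute_G,
    invert_psd,
)
from gpcomp.relationships import SingularKinshipError

from conftest import make_geno


class TestG:
    def test_all_heterozygous_gives_zero_matrix(self):
        geno = make_geno(np.ones((4, 6)))
        G = compute_G(geno)
        assert np.allclose(G.values, 0.0)

    def test_hand_worked_example(self):
        # dosages [[0,2],[1,1],[2,0]], p=(0.5,0.5): denom = 2*(0.25+0.25) = 1
        # M = [[-1,1],[0,0],[1,-1]]; MM' = [[2,0,-2],[0,0,0],[-2,0,2]]
        geno = make_geno([[0, 2], [1, 1], [2, 0]])
        G = compute_G(geno)
        assert G.denominator == pytest.approx(1.0)
        assert np.allclose(G.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])

    def test_duplicated_individuals_share_relationship(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, (3, 50)).astype(float)
        dos = np.vstack([dos, dos[0]])  # duplicate individual 0
        G = compute_G(make_geno(dos))
        assert G.values[0, 3] == pytest.approx(G.values[0, 0])
        assert G.values[3, 3] == pytest.approx(G.values[0, 0])

    def test_all_monomorphic_raises(self):
        with pytest.raises(ZeroDivisionError):
            compute_G(make_geno(np.zeros((3, 4))))

    def test_monomorphic_markers_excluded(self):
        geno_poly = make_geno([[0, 2], [1, 1], [2, 0]])
        with_mono = make_geno([[0, 2, 0], [1, 1, 0], [2, 0, 0]])
        assert np.allclose(compute_G(with_mono).values, compute_G(geno_poly).values)

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, (5, 40)).astype(float)
        perm = rng.permutation(40)
        a = compute_G(make_geno(dos))
        b = compute_G(make_geno(dos[:, perm]))
        assert np.allclose(a.values, b.values)

    def test_mean_diagonal_near_one_on_simulated_panel(self, small_population):
        _, _, geno, _, _ = small_population
        G = compute_G(geno)
        assert abs(np.diag(G.values).mean() - 1.0) < 0.1

    def test_missing_requires_imputation_flag(self):
        dos = np.array([[0.0, np.nan], [1, 1], [2, 0]])
        with pytest.raises(ValueError, match="missing"):
            compute_G(make_geno(dos))
        G = compute_G(make_geno(dos), impute_missing=True)
        assert np.isfinite(G.values).all()


def trio() -> Pedigree:
    return Pedigree(ids=[1, 2, 3], sire=[0, 0, 1], dam=[0, 0, 2])


class TestA:
    def test_founders_only_identity(self):
        ped = Pedigree(ids=[1, 2, 3], sire=[0, 0, 0], dam=[0, 0, 0])
        assert np.allclose(compute_A(ped).values, np.eye(3))

    def test_parent_offspring_half(self):
        A = compute_A(trio()).values
        assert A[2, 0] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)

    def test_full_sibs_and_inbred_diagonal(self):
        # 1x2 -> 3,4 full sibs; 3x4 mating -> 5 with F = 0.25 -> diag 1.25
        # offspring of half sibs: 1x2 -> 3; 1x4 -> 5; 3x5 -> 6, F=0.125
        ped = Pedigree(
            ids=[1, 2, 3, 4, 5, 6],
            sire=[0, 0, 1, 1, 3, 0],
            dam=[0, 0, 2, 2, 4, 0],
        )
        A = compute_A(ped).values
        assert A[2, 3] == pytest.approx(0.5)  # full sibs
        assert A[4, 4] == pytest.approx(1.25)  # full-sib mating
        ped2 = Pedigree(
            ids=[1, 2, 3, 4, 5, 6],
            sire=[0, 0, 1, 0, 1, 3],
            dam=[0, 0, 2, 0, 4, 5],
        )
        A2 = compute_A(ped2).values
        # 3 and 5 are half sibs (common sire 1): a(3,5)=0.25 -> F6 = 0.125
        assert A2[5, 5] == pytest.approx(1.125)

    def test_relabel_permutation_invariance(self):
        ped = Pedigree(ids=[1, 2, 3], sire=[0, 0, 1], dam=[0, 0, 2])
        ped_relab = Pedigree(ids=[10, 20, 30], sire=[0, 0, 10], dam=[0, 0, 20])
        assert np.allclose(compute_A(ped).values, compute_A(ped_relab).values)


class TestAInverse:
    def test_founders_identity(self):
        ped = Pedigree(ids=[1, 2], sire=[0, 0], dam=[0, 0])
        assert np.allclose(compute_A_inverse(ped).values, np.eye(2))

    def test_trio_matches_dense_inverse(self):
        ped = trio()
        Ainv = compute_A_inverse(ped).values
        dense = np.linalg.inv(compute_A(ped).values)
        assert np.allclose(Ainv, dense, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_pedigrees_invert_A(self, seed):
        # oracle: dense inversion of the tabular A, incl. inbred pedigrees
        rng = np.random.default_rng(seed)
        n = 50
        ids, sire, dam = [1, 2], [0, 0], [0, 0]
        for i in range(3, n + 1):
            if rng.random() < 0.3:
                s = d = 0
            else:
                s, d = rng.choice(np.arange(1, i), size=2, replace=False)
            ids.append(i)
            sire.append(int(s))
            dam.append(int(d))
        ped = Pedigree(ids=ids, sire=sire, dam=dam)
        Ainv = compute_A_inverse(ped).values
        A = compute_A(ped).values
        assert np.abs(Ainv @ A - np.eye(n)).max() < 1e-8


class TestHInverse:
    @staticmethod
    def random_ped(seed, n=30):
        rng = np.random.default_rng(seed)
        ids, sire, dam = [1, 2, 3, 4], [0] * 4, [0] * 4
        for i in range(5, n + 1):
            s, d = rng.choice(np.arange(1, i), size=2, replace=False)
            ids.append(i)
            sire.append(int(s))
            dam.append(int(d))
        return Pedigree(ids=ids, sire=sire, dam=dam)

    def test_all_genotyped_G_equals_A_gives_Ginv(self):
        ped = self.random_ped(0, 20)
        A = compute_A(ped)
        Ainv = compute_A_inverse(ped)
        A22 = compute_A22(ped, ped.ids)  # all genotyped, G = A
        Ginv = invert_psd(A22)
        H = assemble_H_inverse(Ainv, invert_psd(A22), Ginv)
        assert np.allclose(H.values, Ginv.values, atol=1e-8)

    def test_no_genotyped_gives_Ainv(self):
        ped = self.random_ped(1, 15)
        Ainv = compute_A_inverse(ped)
        empty = compute_A22(ped, np.array([], dtype=int))
        H = assemble_H_inverse(Ainv, invert_psd(empty), invert_psd(empty),
                               genotyped_ids=np.array([], dtype=int))
        assert np.allclose(H.values, Ainv.values)

    def test_matches_dense_block_arithmetic(self, small_population):
        # oracle: H^-1 assembled by explicit dense block arithmetic
        _, ped_big, geno_big, _, _ = small_population
        ped = self.random_ped(2, 30)
        rng = np.random.default_rng(3)
        gen_ids = np.sort(rng.choice(ped.ids, 20, replace=False))
        dos = rng.integers(0, 3, (20, 80)).astype(float)
        geno = make_geno(dos, ids=gen_ids)
        A = compute_A(ped)
        A22 = compute_A22(ped, gen_ids, A=A)
        G = blend_G(compute_G(geno), A22, 0.2)
        Ainv = compute_A_inverse(ped)
        H = assemble_H_inverse(Ainv, invert_psd(A22), invert_psd(G))
        assert np.allclose(H.values, H.values.T)
        # brute force
        pos = {int(i): k for k, i in enumerate(ped.ids)}
        idx = np.array([pos[int(i)] for i in gen_ids])
        expected = np.linalg.inv(A.values).copy()
        expected[np.ix_(idx, idx)] += np.linalg.inv(G.values) - np.linalg.inv(A22.values)
        assert np.abs(H.values - expected).max() < 1e-6

    def test_singular_G_advises_blending(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, (5, 30)).astype(float)
        G = compute_G(make_geno(dos))  # observed-frequency centring: singular
        with pytest.raises(SingularKinshipError, match="blend"):
            invert_psd(G)
        Gb = blend_G(G, None, 0.05)
        assert np.all(np.linalg.eigvalsh(Gb.values) > 0)
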