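"""QNA atom descriptors and Chebyshev feature expansion."""

import numpy as np
import pytest

from qsarcons.chem import MoleculeGraph, from_smiles
from qsarcons.qna import (
    QnaFeaturizer,
    chebyshev_basis_indices,
    chebyshev_features,
    electronic_ab,
    matrix_exponential_half,
    qna_atom_values,
)


def expm_taylor(M, terms=60):
    """Independent series-summation oracle for the matrix exponential."""
    out = np.eye(len(M))
    term = np.eye(len(M))
    for k in range(1, terms):
        term = term @ M / k
        out = out + term
    return out


def single_atom(element="C"):
    return MoleculeGraph(
        id=element,
        elements=[element],
        charges=np.zeros(1, dtype=int),
        in_ring=np.zeros(1, dtype=bool),
        aromatic=np.zeros(1, dtype=bool),
        adjacency=np.zeros((1, 1), dtype=np.int8),
        mol_weight=12.0,
        logp=0.0,
    )


def bonded_pair(element="C"):
    return MoleculeGraph(
        id=element + "2",
        elements=[element, element],
        charges=np.zeros(2, dtype=int),
        in_ring=np.zeros(2, dtype=bool),
        aromatic=np.zeros(2, dtype=bool),
        adjacency=np.array([[0, 1], [1, 0]], dtype=np.int8),
        mol_weight=24.0,
        logp=0.0,
    )


class TestMatrixExponential:
    def test_identity_for_single_atom(self):
        assert matrix_exponential_half(np.zeros((1, 1)))[0, 0] == pytest.approx(1.0)

    def test_two_atom_closed_form(self):
        # exp(-C/2) for an involution C equals cosh(1/2) I - sinh(1/2) C
        E = matrix_exponential_half(np.array([[0, 1], [1, 0]]))
        c, s = np.cosh(0.5), np.sinh(0.5)
        assert E == pytest.approx(np.array([[c, -s], [-s, c]]), abs=1e-12)
        assert E[0, 0] == pytest.approx(1.12763, abs=1e-5)
        assert E[0, 1] == pytest.approx(-0.52110, abs=1e-5)

    def test_inverse_identity(self, fixture_mols):
        C = fixture_mols["benzene"].adjacency.astype(float)
        E = matrix_exponential_half(C)
        w, V = np.linalg.eigh(0.5 * C)
        Einv = (V * np.exp(w)) @ V.T
        assert E @ Einv == pytest.approx(np.eye(len(C)), abs=1e-10)

    def test_matches_taylor_oracle_on_fixtures(self, fixture_mols):
        for m in fixture_mols.values():
            E = matrix_exponential_half(m.adjacency)
            assert E == pytest.approx(expm_taylor(-0.5 * m.adjacency.astype(float)), abs=1e-9)

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            matrix_exponential_half(np.array([[0, 1], [0, 0]]))

    def test_chain_locality_decay(self):
        # influence of a chain end decays monotonically with distance
        for L in range(3, 11):
            C = np.diag(np.ones(L - 1), 1) + np.diag(np.ones(L - 1), -1)
            row = np.abs(matrix_exponential_half(C)[0])
            assert (np.diff(row) < 0).all()


class TestQnaValues:
    def test_isolated_atom_closed_form(self):
        A, B = electronic_ab("C")
        P, Q = qna_atom_values(single_atom("C"))
        assert P[0] == pytest.approx(B**2, rel=1e-12)
        assert Q[0] == pytest.approx(B**2 * A, rel=1e-12)

    def test_homonuclear_pair_closed_form(self):
        A, B = electronic_ab("N")
        P, Q = qna_atom_values(bonded_pair("N"))
        expected_p = B**2 * np.exp(-0.5)
        assert P == pytest.approx([expected_p, expected_p], rel=1e-12)
        assert Q == pytest.approx(A * P, rel=1e-12)

    def test_benzene_symmetry_classes(self, fixture_mols):
        P, Q = qna_atom_values(fixture_mols["benzene"])
        assert np.ptp(P[:6]) < 1e-9 and np.ptp(Q[:6]) < 1e-9
        assert np.ptp(P[6:]) < 1e-9 and np.ptp(Q[6:]) < 1e-9

    @pytest.mark.parametrize("name", ["ethane", "benzene", "cyclopropane"])
    def test_automorphism_equivalence(self, fixture_mols, name):
        # neopentane: all four methyl carbons equivalent, all 12 H equivalent
        neo = from_smiles("CC(C)(C)C", "neopentane")
        mol = neo if name == "neopentane" else fixture_mols[name]
        P, Q = qna_atom_values(mol)
        groups = {}
        for i, el in enumerate(mol.elements):
            groups.setdefault((el, int(mol.adjacency[i].sum()), bool(mol.in_ring[i])), []).append(i)
        # atoms in the same (element, degree, ring) orbit of these molecules
        # are related by an automorphism and must share P and Q
        for idx in groups.values():
            assert np.ptp(P[idx]) < 1e-9 and np.ptp(Q[idx]) < 1e-9

    def test_unknown_element_names_culprit(self):
        mol = single_atom("C")
        mol.elements = ["Xx"]
        with pytest.raises(KeyError, match="Xx"):
            qna_atom_values(mol)


class TestChebyshevFeatures:
    def test_constant_term_is_one(self, fixture_mols):
        for m in fixture_mols.values():
            P, Q = qna_atom_values(m)
            f = chebyshev_features(P, Q, degree=4, scale_p=1.0, scale_q=10.0)
            assert f[0] == pytest.approx(1.0)
            assert (np.abs(f) <= 1 + 1e-12).all()

    def test_single_atom_features_are_pointwise_products(self):
        from numpy.polynomial import chebyshev as cheb

        mol = single_atom("O")
        P, Q = qna_atom_values(mol)
        f = chebyshev_features(P, Q, degree=2, scale_p=1.0, scale_q=10.0)
        phat = P[0] / (1.0 + abs(P[0]))
        qhat = Q[0] / (10.0 + abs(Q[0]))
        expected = [
            cheb.chebval(phat, [0] * m + [1]) * cheb.chebval(qhat, [0] * n + [1])
            for m, n in chebyshev_basis_indices(2)
        ]
        assert f == pytest.approx(expected, rel=1e-12)

    def test_basis_size(self):
        assert len(chebyshev_basis_indices(6)) == 28

    def test_permutation_invariance(self, fixture_mols):
        feat = QnaFeaturizer(degree=4).fit(list(fixture_mols.values()))
        rng = np.random.default_rng(0)
        for m in (fixture_mols["ethanol"], fixture_mols["benzene"]):
            ref = feat.transform([m])[0]
            for _ in range(20):
                perm = rng.permutation(m.n_atoms)
                assert feat.transform([m.permuted(perm)])[0] == pytest.approx(ref, abs=1e-10)

    def test_isomorphic_molecules_identical_vectors(self):
        a = from_smiles("OCC", "a")  # atom order differs from CCO
        b = from_smiles("CCO", "b")
        feat = QnaFeaturizer(degree=5).fit([a, b])
        fa, fb = feat.transform([a, b])
        assert fa == pytest.approx(fb, abs=1e-10)

    def test_featurizer_scales_frozen_at_fit(self, fixture_mols):
        mols = list(fixture_mols.values())
        feat = QnaFeaturizer(degree=3).fit(mols)
        allP = np.concatenate([np.abs(qna_atom_values(m)[0]) for m in mols])
        assert feat.scale_p_ == pytest.approx(np.median(allP))

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            chebyshev_features(np.array([]), np.array([]), 3, 1.0, 1.0)
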