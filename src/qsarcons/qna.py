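"""Quantitative neighborhoods of atoms (QNA) descriptors.

Each atom i of a hydrogen-complete molecular graph receives two values

    P_i = B_i * sum_k E_ik * B_k
    Q_i = B_i * sum_k E_ik * B_k * A_k,      E = exp(-C/2)

where C is the binary connectivity matrix, A_k = (IP_k + EA_k)/2 and
B_k = (IP_k - EA_k)^(-1/2) are built from the tabulated atomic ionization
potential and electron affinity (eV). The matrix exponential spreads each
atom's electronic character over the whole graph with weights that decay
with topological distance, so P and Q are per-atom quantities that depend
on the entire molecule.

For regression the per-atom (P, Q) cloud is summarized by averages of
two-dimensional Chebyshev polynomials T_m(P^)T_n(Q^) over all atoms, after
a bounded squashing map into [-1, 1].
"""

from __future__ import annotations

from importlib import resources
from itertools import combinations_with_replacement

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import MoleculeGraph, whole_molecule_descriptors, WHOLE_MOLECULE_NAMES

#: shift (eV) applied to both IP and EA per unit of formal charge; keeps
#: IP - EA (hence B) unchanged while moving the electronegativity midpoint A
CHARGE_SHIFT_EV = 3.0


def load_electronic_params() -> dict[str, tuple[float, float]]:
    """Tabulated neutral-atom ionization potential and electron affinity (eV)."""
    text = resources.files("qsarcons").joinpath("data/atomic_electronic.tsv").read_text()
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        el, ip, ea = line.split("\t")
        table[el] = (float(ip), float(ea))
    return table


_PARAMS = load_electronic_params()


def electronic_ab(element: str, charge: int = 0) -> tuple[float, float]:
    """(A, B) for an element in a formal charge state.

    A = (IP+EA)/2 shifted by CHARGE_SHIFT_EV per unit charge; B = (IP-EA)^(-1/2)
    is charge-independent under this shift.
    """
    if element not in _PARAMS:
        raise KeyError(f"no ionization potential / electron affinity tabulated for element {element!r}")
    ip, ea = _PARAMS[element]
    ip += CHARGE_SHIFT_EV * charge
    ea += CHARGE_SHIFT_EV * charge
    return 0.5 * (ip + ea), (ip - ea) ** -0.5


def matrix_exponential_half(adjacency: np.ndarray) -> np.ndarray:
    """exp(-C/2) of a symmetric binary connectivity matrix, via eigh.

    Exact (to floating point) for symmetric C; raises on asymmetric input.
    """
    C = np.asarray(adjacency, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.array_equal(C, C.T):
        raise ValueError("connectivity matrix must be square and symmetric")
    w, V = eigh(-0.5 * C)
    return (V * np.exp(w)) @ V.T


def qna_atom_values(mol: MoleculeGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom (P, Q) for a molecule; sums run over all atoms including i."""
    ab = np.array([electronic_ab(el, int(q)) for el, q in zip(mol.elements, mol.charges)])
    A, B = ab[:, 0], ab[:, 1]
    E = matrix_exponential_half(mol.adjacency)
    EB = E @ B
    EBA = E @ (B * A)
    return B * EB, B * EBA


def squash(x: np.ndarray, scale: float) -> np.ndarray:
    """Bounded map x -> x/(scale + |x|) onto (-1, 1)."""
    return x / (scale + np.abs(x))


def chebyshev_basis_indices(degree: int) -> list[tuple[int, int]]:
    """All (m, n) with m + n <= degree, in graded lexicographic order."""
    return [(m, n) for s in range(degree + 1) for m in range(s + 1) for n in [s - m]]


def chebyshev_features(P: np.ndarray, Q: np.ndarray, degree: int, scale_p: float, scale_q: float) -> np.ndarray:
    """Mean over atoms of T_m(P^)T_n(Q^) for all m + n <= degree."""
    if P.size == 0:
        raise ValueError("empty molecule has no QNA features")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    phat, qhat = squash(P, scale_p), squash(Q, scale_q)
    Tp = _cheb.chebvander(phat, degree)  # (n_atoms, degree+1)
    Tq = _cheb.chebvander(qhat, degree)
    feats = [np.mean(Tp[:, m] * Tq[:, n]) for m, n in chebyshev_basis_indices(degree)]
    return np.array(feats)


class QnaFeaturizer(BaseEstimator, TransformerMixin):
    """Molecule -> QNA-Chebyshev feature vector (+ whole-molecule block).

    Parameters
    ----------
    degree : maximum total Chebyshev degree D; all T_m(P^)T_n(Q^) with
        m + n <= D are emitted (28 terms at the default D = 6)
    include_whole_molecule : append the nine whole-molecule descriptors
    scale : fixed squashing scale; if None, fit() freezes the median |P| and
        |Q| over all training atoms as the per-channel scales

    Fitted attributes: ``scale_p_``, ``scale_q_``, ``feature_names_``.
    """

    def __init__(self, degree: int = 6, include_whole_molecule: bool = True, scale: float | None = None):
        self.degree = degree
        self.include_whole_molecule = include_whole_molecule
        self.scale = scale

    def fit(self, mols: list[MoleculeGraph], y=None):
        if self.scale is not None:
            self.scale_p_ = self.scale_q_ = float(self.scale)
        else:
            allP, allQ = [], []
            for m in mols:
                P, Q = qna_atom_values(m)
                allP.append(np.abs(P))
                allQ.append(np.abs(Q))
            self.scale_p_ = float(np.median(np.concatenate(allP)))
            self.scale_q_ = float(np.median(np.concatenate(allQ)))
        names = [f"T{m}{n}" for m, n in chebyshev_basis_indices(self.degree)]
        if self.include_whole_molecule:
            names += list(WHOLE_MOLECULE_NAMES)
        self.feature_names_ = names
        return self

    def transform(self, mols: list[MoleculeGraph]) -> np.ndarray:
        rows = []
        for m in mols:
            P, Q = qna_atom_values(m)
            f = chebyshev_features(P, Q, self.degree, self.scale_p_, self.scale_q_)
            if self.include_whole_molecule:
                f = np.concatenate([f, whole_molecule_descriptors(m)])
            rows.append(f)
        return np.array(rows)

    @property
    def n_chebyshev_(self) -> int:
        return len(chebyshev_basis_indices(self.degree))
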