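"""Multilevel neighborhoods of atoms (MNA) descriptors.

MNA descriptors are canonical strings describing each atom's environment on
the hydrogen-complete graph, ignoring bond types:

* level 0: the atom mark — element symbol, prefixed with "-" when the atom
  is not in a ring, with an explicit "+"/"--" charge suffix when the formal
  charge is nonzero;
* level k+1 for atom a: ``mark(a)(D1 D2 ...)`` where the D_i are the level-k
  descriptors of a's immediate neighbors, concatenated in lexicographic
  order so the notation is canonical.

Two atoms whose neighborhoods up to the given level are isomorphic produce
identical strings, which makes the per-molecule descriptor multiset
invariant under atom relabeling.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .chem import MoleculeGraph


def atom_mark(mol: MoleculeGraph, i: int) -> str:
    mark = ("" if mol.in_ring[i] else "-") + mol.elements[i]
    q = int(mol.charges[i])
    if q > 0:
        mark += "+" * q
    elif q < 0:
        mark += "--" * (-q)  # "--" so the charge suffix cannot be read as a ring prefix
    return mark


def mna_atom_descriptors(mol: MoleculeGraph, level: int) -> list[list[str]]:
    """Per-level, per-atom MNA notation strings: result[k][i] is atom i at level k."""
    if level < 0:
        raise ValueError("MNA level must be >= 0")
    neighbors = [np.flatnonzero(mol.adjacency[i]) for i in range(mol.n_atoms)]
    levels = [[atom_mark(mol, i) for i in range(mol.n_atoms)]]
    for _ in range(level):
        prev = levels[-1]
        levels.append(
            [
                levels[0][i] + "(" + "".join(sorted(prev[j] for j in neighbors[i])) + ")"
                for i in range(mol.n_atoms)
            ]
        )
    return levels


def mna_descriptors(mol: MoleculeGraph, level: int = 2) -> Counter:
    """Multiset of MNA descriptors of all levels 0..level for a molecule."""
    counts: Counter = Counter()
    for lvl in mna_atom_descriptors(mol, level):
        counts.update(lvl)
    return counts


def descriptor_sets(mols: list[MoleculeGraph], level: int = 2) -> list[set[str]]:
    """Per-molecule set of distinct MNA descriptors (presence, not counts)."""
    return [set(mna_descriptors(m, level)) for m in mols]
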