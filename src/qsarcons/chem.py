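"""Molecule graph model, structure ingestion and whole-molecule descriptors.

Molecules are handled as hydrogen-complete colored graphs: every atom
(including explicit hydrogens) is a node carrying an element symbol, a formal
charge and an in-ring flag; edges record connectivity only, never bond order.
This is the substrate shared by the atom-neighborhood descriptor generators.

Parsing, aromaticity perception, ring perception, molecular weight and the
additive Crippen logP estimate are delegated to RDKit; the graph itself is
extracted into plain numpy arrays so that everything downstream is
independent of the toolkit object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

#: names of the nine whole-molecule descriptors, in output order
WHOLE_MOLECULE_NAMES = (
    "topological_length",
    "topological_volume",
    "lipophilicity",
    "n_positive_charges",
    "n_negative_charges",
    "n_hbond_acceptors",
    "n_aromatic_atoms",
    "molecular_weight",
    "n_halogen_atoms",
)


class RejectReason(str, Enum):
    """Machine-readable reasons a structure fails curation."""

    PARSE_ERROR = "parse_error"
    MULTI_COMPONENT = "multi_component"
    NET_CHARGE = "net_charge"
    MW_BELOW_50 = "MW_below_50"
    MW_ABOVE_1250 = "MW_above_1250"
    NO_CARBON = "no_carbon"


@dataclass(frozen=True)
class Rejection:
    """A structure-level rejection: which record, which compound, why."""

    index: int
    compound_id: str
    reason: RejectReason


@dataclass
class MoleculeGraph:
    """Hydrogen-complete molecular graph with element/charge/ring coloring.

    Attributes
    ----------
    id : compound identifier
    elements : element symbol per atom (hydrogens explicit)
    charges : formal charge per atom
    in_ring : True iff the atom lies on a cycle of the graph
    aromatic : True iff the parser's Hueckel perception marks the atom aromatic
    adjacency : symmetric 0/1 matrix, zero diagonal; bond orders not recorded
    mol_weight : molecular weight in Da (all atoms, standard atomic masses)
    logp : additive Crippen logP estimate
    """

    id: str
    elements: list[str]
    charges: np.ndarray
    in_ring: np.ndarray
    aromatic: np.ndarray
    adjacency: np.ndarray
    mol_weight: float
    logp: float
    smiles: str = field(default="", repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def permuted(self, order: Sequence[int]) -> "MoleculeGraph":
        """Return the same molecule with atoms relabeled by `order`."""
        order = np.asarray(order)
        return MoleculeGraph(
            id=self.id,
            elements=[self.elements[i] for i in order],
            charges=self.charges[order],
            in_ring=self.in_ring[order],
            aromatic=self.aromatic[order],
            adjacency=self.adjacency[np.ix_(order, order)],
            mol_weight=self.mol_weight,
            logp=self.logp,
            smiles=self.smiles,
        )


def from_rdkit(mol: "Chem.Mol", compound_id: str = "") -> MoleculeGraph:
    """Extract a MoleculeGraph from an RDKit Mol, completing hydrogens.

    Hydrogens are added according to valence and formal charge; ring flags
    come from RDKit's ring perception on the hydrogen-complete graph.
    """
    molH = Chem.AddHs(mol)
    Chem.GetSymmSSSR(molH)
    n = molH.GetNumAtoms()
    adjacency = Chem.GetAdjacencyMatrix(molH).astype(np.int8)
    return MoleculeGraph(
        id=compound_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
        elements=[a.GetSymbol() for a in molH.GetAtoms()],
        charges=np.array([a.GetFormalCharge() for a in molH.GetAtoms()], dtype=int),
        in_ring=np.array([a.IsInRing() for a in molH.GetAtoms()], dtype=bool),
        aromatic=np.array([a.GetIsAromatic() for a in molH.GetAtoms()], dtype=bool),
        adjacency=adjacency,
        mol_weight=float(Descriptors.MolWt(molH)),
        logp=float(Crippen.MolLogP(molH)),
        smiles=Chem.MolToSmiles(mol),
    )


def from_smiles(smiles: str, compound_id: str = "") -> MoleculeGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return from_rdkit(mol, compound_id)


def read_structures(
    path: str | Path, fmt: str | None = None
) -> tuple[list[MoleculeGraph], list[Rejection]]:
    """Read an SDF (V2000) or SMILES file into MoleculeGraphs.

    SMILES files hold one record per line, optionally ``SMILES<TAB>id``.
    The format is inferred from the suffix when `fmt` is None. Unparseable
    records are reported as Rejections, never silently dropped; record order
    is preserved among the parsed molecules.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smiles"
    if fmt not in {"sdf", "smiles"}:
        raise ValueError(f"unknown format {fmt!r}")

    mols: list[MoleculeGraph] = []
    rejections: list[Rejection] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
        for idx, mol in enumerate(supplier):
            if mol is None:
                rejections.append(Rejection(idx, "", RejectReason.PARSE_ERROR))
                continue
            mols.append(from_rdkit(mol, mol.GetProp("_Name") if mol.HasProp("_Name") else f"rec{idx}"))
    else:
        with open(path) as fh:
            for idx, line in enumerate(l for l in fh if l.strip()):
                parts = line.split()
                smi = parts[0]
                cid = parts[1] if len(parts) > 1 else f"rec{idx}"
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    rejections.append(Rejection(idx, cid, RejectReason.PARSE_ERROR))
                    continue
                mols.append(from_rdkit(mol, cid))
    return mols, rejections


def standardize(
    mol: MoleculeGraph, strip_salts: bool = False
) -> tuple[MoleculeGraph | None, RejectReason | None]:
    """Apply the curation inclusion rules for model-ready structures.

    A structure is accepted iff it is a single connected component, net
    electroneutral, contains carbon, and has molecular weight in [50, 1250]
    Da. Multi-component records are rejected by default; with
    ``strip_salts=True`` the largest organic fragment is kept instead and the
    rules re-applied to it.

    Returns ``(molecule, None)`` on acceptance, ``(None, reason)`` otherwise.
    Idempotent: an accepted molecule is returned unchanged.
    """
    import scipy.sparse.csgraph as csgraph

    n_comp, labels = csgraph.connected_components(mol.adjacency, directed=False)
    if n_comp > 1:
        if not strip_salts:
            return None, RejectReason.MULTI_COMPONENT
        # keep the largest fragment that contains carbon, re-standardize it
        sizes = np.bincount(labels)
        order = np.argsort(-sizes)
        for comp in order:
            keep = np.flatnonzero(labels == comp)
            if any(mol.elements[i] == "C" for i in keep):
                frag = _subgraph(mol, keep)
                return standardize(frag, strip_salts=False)
        return None, RejectReason.NO_CARBON
    if int(mol.charges.sum()) != 0:
        return None, RejectReason.NET_CHARGE
    if "C" not in mol.elements:
        return None, RejectReason.NO_CARBON
    if mol.mol_weight < 50.0:
        return None, RejectReason.MW_BELOW_50
    if mol.mol_weight > 1250.0:
        return None, RejectReason.MW_ABOVE_1250
    return mol, None


def _subgraph(mol: MoleculeGraph, keep: np.ndarray) -> MoleculeGraph:
    sub = from_smiles(_fragment_smiles(mol, keep), mol.id) if mol.smiles else None
    if sub is not None:
        return sub
    return MoleculeGraph(
        id=mol.id,
        elements=[mol.elements[i] for i in keep],
        charges=mol.charges[keep],
        in_ring=mol.in_ring[keep],
        aromatic=mol.aromatic[keep],
        adjacency=mol.adjacency[np.ix_(keep, keep)],
        mol_weight=float("nan"),
        logp=mol.logp,
    )


def _fragment_smiles(mol: MoleculeGraph, keep: np.ndarray) -> str:
    frags = mol.smiles.split(".")
    best = max(frags, key=lambda s: (sum(c.upper() == "C" for c in s), len(s)))
    return best


def topological_length(mol: MoleculeGraph) -> int:
    """Graph diameter in bonds, hydrogens included."""
    from scipy.sparse.csgraph import shortest_path

    d = shortest_path(mol.adjacency, method="D", unweighted=True)
    finite = d[np.isfinite(d)]
    return int(finite.max()) if finite.size else 0


def whole_molecule_descriptors(mol: MoleculeGraph) -> np.ndarray:
    """The nine whole-molecule descriptors, ordered as WHOLE_MOLECULE_NAMES.

    Topological length is the graph diameter in bonds and topological volume
    the total atom count, both over the hydrogen-complete graph; lipophilicity
    is the additive Crippen logP; hydrogen-bond acceptors are N/O atoms that
    are not positively charged.
    """
    elements = np.array(mol.elements)
    return np.array(
        [
            topological_length(mol),
            mol.n_atoms,
            mol.logp,
            int((mol.charges > 0).sum()),
            int((mol.charges < 0).sum()),
            int((np.isin(elements, ["N", "O"]) & (mol.charges <= 0)).sum()),
            int(mol.aromatic.sum()),
            mol.mol_weight,
            int(np.isin(elements, list(HALOGENS)).sum()),
        ],
        dtype=float,
    )


def whole_molecule_matrix(mols: Iterable[MoleculeGraph]) -> np.ndarray:
    return np.array([whole_molecule_descriptors(m) for m in mols])


def write_rejection_report(rejections: Sequence[Rejection], path: str | Path) -> None:
    """Write rejections as a TSV: record index, compound id, reason code."""
    with open(path, "w") as fh:
        fh.write("index\tcompound_id\treason\n")
        for r in rejections:
            fh.write(f"{r.index}\t{r.compound_id}\t{r.reason.value}\n")
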