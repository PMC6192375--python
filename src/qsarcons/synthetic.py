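"""Synthetic study generator: valence-correct random molecules, replicate
activity tables with a planted structure-activity relationship, and a
labeled corpus for the activity-spectrum engine.

The generator emulates the shape of a curated bioactivity extraction so the
whole pipeline is testable offline: a few hundred small organic molecules
(connected, electroneutral, MW within the 50-1250 Da inclusion window),
per-compound Ki/IC50 values in nM spanning roughly four log units with 1-5
replicate measurements and lognormal replicate scatter, and a configurable
fraction of junk rows (wrong unit or relation) to exercise the filters.

The planted relationship makes the true p-value an affine function of
substructure counts (heavy atoms, halogens, H-bond acceptors by default)
plus Gaussian noise, so a working pipeline must recover it and a null
configuration (zero coefficients) must not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import HALOGENS, MoleculeGraph, from_rdkit
from .mna import descriptor_sets

VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1}
ELEMENT_PROBS = {
    "C": 0.62, "N": 0.12, "O": 0.12, "S": 0.04,
    "F": 0.04, "Cl": 0.04, "Br": 0.015, "I": 0.005,
}

DEFAULT_PLANTED = (("n_heavy", 0.12), ("n_halogen", 0.45), ("n_hba", 0.30))


@dataclass
class SyntheticConfig:
    """Conditions of one synthetic study."""

    n_compounds: int = 300
    heavy_range: tuple[int, int] = (8, 24)
    ring_rate: float = 1.5                 # mean ring closures per molecule
    planted_effect: tuple = DEFAULT_PLANTED
    noise_sd: float = 0.2                  # p-units
    fraction_active: float | None = 0.4    # sets the intercept; None -> intercept 2.2
    replicate_range: tuple[int, int] = (1, 5)
    replicate_sigma: float = 0.3           # lognormal scatter, log10 units
    fraction_junk: float = 0.1             # extra rows with bad unit/relation
    endpoint: str = "Ki"
    # PASS corpus
    n_corpus: int = 150
    n_activities: int = 200
    label_noise: float = 0.0
    min_actives: int = 5
    seed: int = 0


# -- molecules -------------------------------------------------------------

def _random_molecule(rng: np.random.Generator, heavy_range: tuple[int, int], ring_rate: float) -> str:
    """One valence-correct connected molecule as SMILES (single bonds only)."""
    n_heavy = int(rng.integers(heavy_range[0], heavy_range[1] + 1))
    symbols = list(ELEMENT_PROBS)
    probs = np.array(list(ELEMENT_PROBS.values()))
    probs /= probs.sum()
    for _ in range(50):  # bounded retries if growth gets stuck
        elements = ["C"]
        free = [VALENCE["C"]]
        edges = []
        ok = True
        while len(elements) < n_heavy:
            open_atoms = [i for i, f in enumerate(free) if f > 0]
            if not open_atoms:
                ok = False
                break
            el = symbols[rng.choice(len(symbols), p=probs)]
            parent = open_atoms[rng.integers(len(open_atoms))]
            elements.append(el)
            free[parent] -= 1
            free.append(VALENCE[el] - 1)
            edges.append((parent, len(elements) - 1))
        if not ok:
            continue
        # ring closures between non-adjacent atoms with free valence
        n_rings = rng.poisson(ring_rate)
        if n_rings:
            import networkx as nx

            g = nx.Graph(edges)
            g.add_nodes_from(range(len(elements)))
            for _ in range(n_rings):
                open_atoms = [i for i, f in enumerate(free) if f > 0]
                rng.shuffle(open_atoms)
                done = False
                for a in open_atoms:
                    dist = nx.single_source_shortest_path_length(g, a)
                    partners = [b for b in open_atoms if b != a and dist.get(b, 99) >= 3]
                    if partners:
                        b = partners[rng.integers(len(partners))]
                        edges.append((a, b))
                        g.add_edge(a, b)
                        free[a] -= 1
                        free[b] -= 1
                        done = True
                        break
                if not done:
                    break
        mol = Chem.RWMol()
        for el in elements:
            mol.AddAtom(Chem.Atom(el))
        for a, b in edges:
            mol.AddBond(int(a), int(b), Chem.BondType.SINGLE)
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return Chem.MolToSmiles(m)
    raise RuntimeError("molecule growth failed repeatedly; constraints infeasible")


def generate_molecules(config: SyntheticConfig, seed: int | None = None) -> list[MoleculeGraph]:
    """Deterministic list of valence-correct, connected, neutral molecules."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mols = []
    for i in range(config.n_compounds):
        smi = _random_molecule(rng, config.heavy_range, config.ring_rate)
        mol = from_rdkit(Chem.MolFromSmiles(smi), f"SYN{i:05d}")
        mols.append(mol)
    return mols


# -- planted features ------------------------------------------------------

def substructure_counts(mol: MoleculeGraph) -> dict[str, float]:
    elements = np.array(mol.elements)
    heavy = elements != "H"
    return {
        "n_heavy": float(heavy.sum()),
        "n_halogen": float(np.isin(elements, list(HALOGENS)).sum()),
        "n_hba": float(np.isin(elements, ["N", "O"]).sum()),
        "n_ring_atoms": float((mol.in_ring & heavy).sum()),
    }


def planted_p_values(
    mols: list[MoleculeGraph], config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(true p-values without noise, observed p-values with noise)."""
    raw = np.array(
        [sum(c * substructure_counts(m)[name] for name, c in config.planted_effect) for m in mols]
    )
    if config.fraction_active is not None:
        # intercept placed so the target fraction of compounds sits at or
        # above the 1 uM activity threshold (p = 6)
        intercept = 6.0 - float(np.quantile(raw, 1.0 - config.fraction_active))
    else:
        intercept = 2.2
    p_true = intercept + raw
    p_obs = p_true + rng.normal(0.0, config.noise_sd, size=len(mols)) if config.noise_sd > 0 else p_true.copy()
    return p_true, p_obs


def generate_activities(
    mols: list[MoleculeGraph], config: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """Raw replicate activity table (compound_id, endpoint, relation, value, unit).

    Replicate values scatter lognormally around the compound's observed
    p-value; junk rows (unit uM or relation ">") are appended for a
    configurable fraction of compounds.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    _, p_obs = planted_p_values(mols, config, rng)
    rows = []
    lo, hi = config.replicate_range
    for mol, p in zip(mols, p_obs):
        n_rep = int(rng.integers(lo, hi + 1))
        for _ in range(n_rep):
            p_rep = p + (rng.normal(0.0, config.replicate_sigma) if config.replicate_sigma > 0 else 0.0)
            rows.append((mol.id, config.endpoint, "=", 10.0 ** (9.0 - p_rep), "nM"))
        if rng.random() < config.fraction_junk:
            if rng.random() < 0.5:
                rows.append((mol.id, config.endpoint, ">", 10.0 ** (9.0 - p), "nM"))
            else:
                rows.append((mol.id, config.endpoint, "=", 10.0 ** (6.0 - p), "uM"))
    return pd.DataFrame(rows, columns=["compound_id", "endpoint", "relation", "value", "unit"])


# -- PASS corpus -----------------------------------------------------------

def generate_pass_corpus(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[list[MoleculeGraph], np.ndarray, list[str], list[str]]:
    """Labeled (molecule, activity) corpus with planted descriptor rules.

    Each activity is defined by one MNA descriptor: a compound is active iff
    it contains the rule descriptor, with optional label-flip noise. Rule
    descriptors are drawn among those present in 20-80% of the corpus so
    every activity has both actives and inactives (at least `min_actives`
    of each).

    Returns (molecules, label matrix, activity names, rule descriptors).
    """
    base_seed = config.seed if seed is None else seed
    corpus_cfg = SyntheticConfig(
        n_compounds=config.n_corpus,
        heavy_range=config.heavy_range,
        ring_rate=config.ring_rate,
        seed=base_seed + 10_000,
    )
    mols = generate_molecules(corpus_cfg)
    rng = np.random.default_rng(base_seed + 20_000)
    dsets = descriptor_sets(mols, level=2)
    n = len(mols)
    counts: dict[str, int] = {}
    for ds in dsets:
        for d in ds:
            counts[d] = counts.get(d, 0) + 1
    eligible = sorted(
        d
        for d, c in counts.items()
        if max(config.min_actives, int(0.2 * n)) <= c <= n - max(config.min_actives, int(0.2 * n))
    )
    if not eligible:
        raise RuntimeError("no descriptor occurs at an intermediate frequency; enlarge the corpus")
    Y = np.zeros((n, config.n_activities), dtype=bool)
    rules = []
    for j in range(config.n_activities):
        d = eligible[rng.integers(len(eligible))]
        rules.append(d)
        labels = np.array([d in ds for ds in dsets])
        if config.label_noise > 0:
            flip = rng.random(n) < config.label_noise
            labels = labels ^ flip
            # keep the activity trainable after noise
            if labels.sum() < config.min_actives or (~labels).sum() < config.min_actives:
                labels = np.array([d in ds for ds in dsets])
        Y[:, j] = labels
    names = [f"activity_{j:03d}" for j in range(config.n_activities)]
    return mols, Y, names, rules


# -- file output -----------------------------------------------------------

def write_smiles(mols: list[MoleculeGraph], path) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.smiles}\t{m.id}\n")


def write_sdf(mols: list[MoleculeGraph], path) -> None:
    with open(path, "w") as fh:
        for m in mols:
            rd = Chem.MolFromSmiles(m.smiles)
            rd.SetProp("_Name", m.id)
            fh.write(Chem.MolToMolBlock(rd))
            fh.write("$$$$\n")
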