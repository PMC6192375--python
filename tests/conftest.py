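import numpy as np
import pytest

from qsarcons.chem import from_smiles
from qsarcons.curation import curate
from qsarcons.pass_spectra import PassActivitySpectra
from qsarcons.synthetic import (
    SyntheticConfig,
    generate_activities,
    generate_molecules,
    generate_pass_corpus,
)
from qsarcons.validate import DescriptorTables

# small molecules (all <= 12 atoms with hydrogens) used across descriptor tests
FIXTURE_SMILES = {
    "methane": "C",
    "ethane": "CC",
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "chloroform": "C(Cl)(Cl)Cl",
    "methylamine": "CN",
    "cyclopropane": "C1CC1",
    "dimethyl_ether": "COC",
}


@pytest.fixture(scope="session")
def fixture_mols():
    return {name: from_smiles(smi, name) for name, smi in FIXTURE_SMILES.items()}


def make_study(seed: int, n: int = 300, null: bool = False, with_pass: bool = True,
               n_models: int = 32):
    """One synthetic study: aligned (curated table, descriptor tables).

    The default conditions are the benchmark ones: 300 compounds, planted
    substructure-count signal, observation noise 0.2 p-units, 1-5 replicates
    with lognormal scatter.
    """
    cfg = SyntheticConfig(n_compounds=n, seed=seed)
    if null:
        cfg.planted_effect = tuple((name, 0.0) for name, _ in cfg.planted_effect)
    mols = generate_molecules(cfg)
    table = generate_activities(mols, cfg)
    curated, _ = curate(table)
    by_id = {m.id: m for m in mols}
    mols = [by_id[c] for c in curated["compound_id"]]
    pass_model = None
    if with_pass:
        corpus, Y, names, _ = generate_pass_corpus(cfg)
        pass_model = PassActivitySpectra(level=2).fit(corpus, Y, names)
    tables = DescriptorTables(mols, pass_model=pass_model, degree=6)
    return curated, tables


@pytest.fixture(scope="session")
def signal_study():
    """Planted-signal benchmark study shared by the slower tests."""
    return make_study(seed=1)


@pytest.fixture(scope="session")
def signal_features(signal_study):
    curated, tables = signal_study
    X, blocks = tables.features_for(np.arange(len(curated)))
    return curated, X, blocks
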