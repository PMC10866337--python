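import numpy as np
import pytest

from kinsolv.featurize import FeatureSchema
from kinsolv.pairtable import PairRecord
from kinsolv.reactions import parse_mapped_reaction
from kinsolv.synthetic import SurrogateParams, fixture_dataset

# toy bimolecular H-abstraction: methane + hydroxyl -> methyl + water
H_ABSTRACTION = "[CH3:1][H:2].[O:3][H:4]>>[CH3:1].[H:2][O:3][H:4]"
# unimolecular 1,2-H shift: 2-hydroxyethyl radical -> ethoxy radical
H_MIGRATION = "[CH2:1][CH2:2][O:3][H:4]>>[CH2:1]([H:4])[CH2:2][O:3]"
# methyl radical addition to ethylene
R_ADDITION = "[CH3:1].[CH2:2]=[CH2:3]>>[CH3:1][CH2:2][CH2:3]"
IDENTITY = "[CH4:1]>>[CH4:1]"


@pytest.fixture(scope="session")
def schema():
    return FeatureSchema()


@pytest.fixture
def h_abstraction():
    return parse_mapped_reaction(H_ABSTRACTION)


@pytest.fixture
def identity_reaction():
    return parse_mapped_reaction(IDENTITY)


@pytest.fixture(scope="session")
def small_dataset():
    """20 reactions x 5 solvents, both directions: 200 records."""
    return fixture_dataset(20, 5, SurrogateParams(noise_sd=0.1, seed=0), seed=0)


def make_record(rxn_smiles, solvent, ddg=0.0, ddh=0.0, **kw):
    return PairRecord(
        reaction=parse_mapped_reaction(rxn_smiles),
        solvent=solvent,
        ddG298=ddg,
        ddH298=ddh,
        **kw,
    )


def renumber_maps(reaction, permutation):
    """Rewrite a reaction's atom-map numbers through a permutation dict."""
    from rdkit import Chem

    from kinsolv.reactions import MappedReaction

    def remap(mol):
        work = Chem.RWMol(mol)
        for atom in work.GetAtoms():
            atom.SetAtomMapNum(permutation[atom.GetAtomMapNum()])
        return work.GetMol()

    r = remap(reaction.reactant_graph)
    p = remap(reaction.product_graph)
    return parse_mapped_reaction(Chem.MolToSmiles(r) + ">>" + Chem.MolToSmiles(p))
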