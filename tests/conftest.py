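import numpy as np
import pytest
from rdkit import Chem

from hydrolyze.io import FixtureSpec, generate_fixtures
from hydrolyze.molgraph import Featurizer
from hydrolyze.reaction_graph import build_reaction_graph
from hydrolyze.templates import catalog_fg_ids, load_template_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_template_catalog()


@pytest.fixture(scope="session")
def featurizer(catalog):
    return Featurizer([t.fg_id for t in catalog])


@pytest.fixture(scope="session")
def mixed_fixture_reactions():
    """~300 labeled fixture reactions across all three conditions."""
    spec = FixtureSpec(
        n=300, seed=11, noise_sd=0.5,
        condition_mix={"neutral": 1 / 3, "acidic": 1 / 3, "basic": 1 / 3})
    records, reactions = generate_fixtures(spec)
    return records, reactions


@pytest.fixture(scope="session")
def mixed_fixture_graphs(mixed_fixture_reactions, featurizer):
    _, reactions = mixed_fixture_reactions
    return [build_reaction_graph(r, featurizer) for r in reactions]


def relabel_reaction(rxn, perm_seed: int):
    """Consistently permute the atom-map numbers of a reaction (both sides)
    and shuffle species order; the chemistry is unchanged."""
    from hydrolyze.molgraph import record_from_rdmol
    from hydrolyze.templates import HydrolysisReaction

    rng = np.random.default_rng(perm_seed)
    all_maps = sorted(
        a.map_idx for m in rxn.reactants for a in m.atoms)
    new_maps = dict(zip(all_maps, rng.permutation(all_maps)))

    def remap(mols):
        out = []
        for m in mols:
            mol = Chem.Mol(m.rdmol)
            for a in mol.GetAtoms():
                a.SetAtomMapNum(int(new_maps[a.GetAtomMapNum()]))
            out.append(record_from_rdmol(mol))
        order = rng.permutation(len(out))
        return [out[i] for i in order]

    return HydrolysisReaction(
        condition=rxn.condition, reactants=remap(rxn.reactants),
        products=remap(rxn.products), fg_id=rxn.fg_id,
        n_water=rxn.n_water, dG_label=rxn.dG_label)
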