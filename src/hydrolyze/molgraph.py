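"""Molecular data model and featurization.

Every molecule is handled as an explicit-hydrogen graph: hydrolysis
bookkeeping deletes a water O-H bond and forms a new O-H bond on a product
fragment, so hydrogens must be first-class graph nodes. Molecules are
restricted to the element vocabulary {H, C, N, O, F, S, Cl}; anything else
is rejected rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

SCHEMA_VERSION = "hydrolyze-features-1"

#: Allowed elements (QM9 + Alchemy chemistry) in one-hot order.
ELEMENTS = ("H", "C", "N", "O", "F", "S", "Cl")

#: Standard IUPAC atomic weights, 3 decimals, amu.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "S": 32.060,
    "Cl": 35.450,
}

HYBRIDIZATIONS = ("S", "SP", "SP2", "SP3", "OTHER")

BOND_ORDERS = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")

_BOND_TYPE_TAG = {
    Chem.BondType.SINGLE: "SINGLE",
    Chem.BondType.DOUBLE: "DOUBLE",
    Chem.BondType.TRIPLE: "TRIPLE",
    Chem.BondType.AROMATIC: "AROMATIC",
}

ATOM_FEATURE_DIM = len(ELEMENTS) + 1 + 1 + 1 + len(HYBRIDIZATIONS) + 1
BOND_FEATURE_DIM = len(BOND_ORDERS) + 1 + 1


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


class FeatureSchemaError(ValueError):
    """Raised when an atom/bond/label falls outside the feature schema."""


@dataclasses.dataclass
class AtomInfo:
    element: str
    formal_charge: int
    hybridization: str
    in_ring: bool
    degree: int  # heavy + hydrogen neighbors
    map_idx: int  # 0 = unassigned


@dataclasses.dataclass
class BondInfo:
    atoms: tuple[int, int]
    order: str
    in_ring: bool
    conjugated: bool


@dataclasses.dataclass
class MoleculeRecord:
    """Explicit-hydrogen molecular graph with per-atom/per-bond attributes.

    ``rdmol`` is the authoritative RDKit object (explicit Hs); the flat
    ``atoms``/``bonds`` lists are derived views kept for convenience and
    serialization.
    """

    atoms: list[AtomInfo]
    bonds: list[BondInfo]
    total_charge: int
    smiles: str
    rdmol: Chem.Mol = dataclasses.field(repr=False, compare=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def molecular_weight(self) -> float:
        return float(sum(ATOMIC_WEIGHTS[a.element] for a in self.atoms))

    def element_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.atoms:
            out[a.element] = out.get(a.element, 0) + 1
        return out

    def map_numbers(self) -> list[int]:
        return [a.map_idx for a in self.atoms]


def _hyb_tag(atom: Chem.Atom) -> str:
    name = str(atom.GetHybridization())
    return name if name in HYBRIDIZATIONS else "OTHER"


def _check_vocabulary(mol: Chem.Mol, source: str) -> None:
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ELEMENTS:
            raise FeatureSchemaError(
                f"element {atom.GetSymbol()!r} in {source!r} is outside the "
                f"supported vocabulary {ELEMENTS}"
            )


def record_from_rdmol(mol: Chem.Mol) -> MoleculeRecord:
    """Build a :class:`MoleculeRecord` from an explicit-H RDKit mol."""
    _check_vocabulary(mol, Chem.MolToSmiles(mol))
    atoms = [
        AtomInfo(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            hybridization=_hyb_tag(a),
            in_ring=a.IsInRing(),
            degree=a.GetDegree(),
            map_idx=a.GetAtomMapNum(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        BondInfo(
            atoms=(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            order=_BOND_TYPE_TAG.get(b.GetBondType(), "SINGLE"),
            in_ring=b.IsInRing(),
            conjugated=b.GetIsConjugated(),
        )
        for b in mol.GetBonds()
    ]
    total = sum(a.formal_charge for a in atoms)
    # canonical map-free SMILES of the heavy-atom form; the graph keeps Hs
    # and the atom maps live on rdmol
    noh = Chem.Mol(mol)
    for a in noh.GetAtoms():
        a.SetAtomMapNum(0)
    noh = Chem.RemoveHs(noh)
    smiles = Chem.MolToSmiles(noh)
    return MoleculeRecord(atoms=atoms, bonds=bonds, total_charge=total,
                          smiles=smiles, rdmol=mol)


def parse_molecule(smiles: str) -> MoleculeRecord:
    """Parse a SMILES string into an explicit-hydrogen molecule record.

    Raises
    ------
    MoleculeParseError
        If the SMILES cannot be parsed or sanitized, naming the input.
    FeatureSchemaError
        If the molecule contains an element outside {H,C,N,O,F,S,Cl}.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    Chem.SanitizeMol(mol)
    return record_from_rdmol(mol)


def write_molecule(record: MoleculeRecord) -> str:
    """Canonical SMILES round-trip partner of :func:`parse_molecule`."""
    return record.smiles


def sanitize_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Sanitize a post-edit fragment, falling back to kekulized aromatic
    perception when the default pipeline fails."""
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        Chem.Kekulize(mol, clearAromaticFlags=True)
        Chem.SanitizeMol(mol)
    return mol


class Featurizer:
    """Deterministic atom/bond/global featurization with a fixed schema.

    Parameters
    ----------
    fg_catalog : sequence of str
        Ordered functional-group labels defining the fg one-hot block.
    """

    schema_version = SCHEMA_VERSION

    def __init__(self, fg_catalog: Sequence[str]):
        self.fg_catalog = tuple(fg_catalog)
        self.atom_dim = ATOM_FEATURE_DIM
        self.bond_dim = BOND_FEATURE_DIM
        self.global_static_dim = 4 + len(self.fg_catalog)
        self.global_diff_dim = 2

    # -- atoms ------------------------------------------------------------
    def featurize_atom(self, atom: AtomInfo) -> np.ndarray:
        if atom.element not in ELEMENTS:
            raise FeatureSchemaError(
                f"element {atom.element!r} outside vocabulary {ELEMENTS}")
        v = np.zeros(self.atom_dim)
        v[ELEMENTS.index(atom.element)] = 1.0
        i = len(ELEMENTS)
        v[i] = float(atom.degree)
        v[i + 1] = ATOMIC_WEIGHTS[atom.element]
        v[i + 2] = 1.0 if atom.in_ring else 0.0
        j = i + 3
        v[j + HYBRIDIZATIONS.index(atom.hybridization)] = 1.0
        v[j + len(HYBRIDIZATIONS)] = float(atom.formal_charge)
        return v

    # -- bonds ------------------------------------------------------------
    def featurize_bond(self, bond: BondInfo) -> np.ndarray:
        v = np.zeros(self.bond_dim)
        v[BOND_ORDERS.index(bond.order)] = 1.0
        v[len(BOND_ORDERS)] = 1.0 if bond.in_ring else 0.0
        v[len(BOND_ORDERS) + 1] = 1.0 if bond.conjugated else 0.0
        return v

    # -- side / reaction level --------------------------------------------
    def featurize_global(self, species: Iterable[MoleculeRecord],
                         fg_label: str, total_charge: int) -> np.ndarray:
        """Side-level aggregate: [atom count, bond count, MW, charge, fg 1-hot]."""
        if fg_label not in self.fg_catalog:
            raise FeatureSchemaError(
                f"unknown functional-group label {fg_label!r}; "
                f"catalog: {sorted(self.fg_catalog)}")
        species = list(species)
        v = np.zeros(self.global_static_dim)
        v[0] = sum(m.n_atoms for m in species)
        v[1] = sum(m.n_bonds for m in species)
        v[2] = sum(m.molecular_weight for m in species)
        v[3] = float(total_charge)
        v[4 + self.fg_catalog.index(fg_label)] = 1.0
        return v

    def atom_matrix(self, record: MoleculeRecord) -> np.ndarray:
        return np.stack([self.featurize_atom(a) for a in record.atoms]) \
            if record.atoms else np.zeros((0, self.atom_dim))
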