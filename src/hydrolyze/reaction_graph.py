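"""Union reaction graphs with product-minus-reactant difference features.

A reaction is represented as a single heterograph: one node per mapped atom
(the atom map is total, so the count is equal on both sides), one node per
bond in the union of the reactant and product bond sets (bonds are keyed by
their unordered mapped atom-index pair), and one global node. Node features
are the difference of the product-side and reactant-side featurizations;
the side on which a bond does not exist contributes a zero vector. This
lets a single fixed-size scheme express any number of simultaneous bond
cleavages and formations.

Bonds whose order changes between sides (e.g. a carbonyl reduced to a
single bond) are present on both sides and carry a nonzero difference; they
are not treated as a break plus a formation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Iterable, Optional, Sequence

import numpy as np

from .molgraph import Featurizer, MoleculeRecord
from .templates import HydrolysisReaction

SCHEMA_VERSION = "hydrolyze-rxngraph-1"

#: bond presence classes, in one-hot order
BOND_PRESENCE = ("both", "reactant_only", "product_only")


class AtomMappingError(ValueError):
    pass


class GraphStoreError(RuntimeError):
    pass


@dataclasses.dataclass
class ReactionGraph:
    """Global union reaction graph for one hydrolysis reaction.

    Attributes
    ----------
    atom_diff : (n_atoms, A) product-minus-reactant atom features, rows
        ordered by ascending atom-map number.
    bond_diff : (n_bonds, B) difference features over the bond union.
    bond_flag : (n_bonds,) int index into :data:`BOND_PRESENCE`.
    bond_atoms : (n_bonds, 2) atom-node indices of each bond's endpoints.
    global_static : side-independent reaction descriptors
        [atom count, union bond count, reactant MW, total charge, fg 1-hot].
    global_diff : antisymmetric global part [bond count delta,
        conjugated-bond count delta].
    """

    atom_diff: np.ndarray
    bond_diff: np.ndarray
    bond_flag: np.ndarray
    bond_atoms: np.ndarray
    global_static: np.ndarray
    global_diff: np.ndarray
    fg_id: str
    condition: str
    schema_version: str = SCHEMA_VERSION
    dG_label: Optional[float] = None

    @property
    def n_atoms(self) -> int:
        return self.atom_diff.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_diff.shape[0]

    def bond_flag_onehot(self) -> np.ndarray:
        out = np.zeros((self.n_bonds, len(BOND_PRESENCE)))
        if self.n_bonds:
            out[np.arange(self.n_bonds), self.bond_flag] = 1.0
        return out

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "atom_diff": self.atom_diff,
            "bond_diff": self.bond_diff,
            "bond_flag": self.bond_flag,
            "bond_atoms": self.bond_atoms,
            "global_static": self.global_static,
            "global_diff": self.global_diff,
        }


def map_reaction_atoms(rxn: HydrolysisReaction) -> dict[int, tuple[tuple[int, int], tuple[int, int]]]:
    """Total atom bijection keyed by map number.

    Returns ``{map_num: ((r_species, r_atom), (p_species, p_atom))}``. The
    result is independent of species ordering within each side.
    """

    def index_side(mols: Sequence[MoleculeRecord], label: str):
        out: dict[int, tuple[int, int]] = {}
        for si, mol in enumerate(mols):
            for ai, atom in enumerate(mol.atoms):
                n = atom.map_idx
                if n <= 0:
                    raise AtomMappingError(
                        f"unmapped atom {ai} ({atom.element}) in {label} "
                        f"species {mol.smiles!r}")
                if n in out:
                    raise AtomMappingError(
                        f"duplicate map index {n} on {label} side")
                out[n] = (si, ai)
        return out

    r = index_side(rxn.reactants, "reactant")
    p = index_side(rxn.products, "product")
    if set(r) != set(p):
        missing = set(r) ^ set(p)
        raise AtomMappingError(
            f"atom map is not a bijection; unmatched map indices {sorted(missing)}")
    return {n: (r[n], p[n]) for n in sorted(r)}


def _side_features(mols: Sequence[MoleculeRecord], featurizer: Featurizer):
    """Per-side feature lookup: atom features keyed by map number, bond
    features keyed by unordered map pair, plus conjugated-bond count."""
    atom_feats: dict[int, np.ndarray] = {}
    bond_feats: dict[frozenset, np.ndarray] = {}
    n_conj = 0
    for mol in mols:
        for atom in mol.atoms:
            atom_feats[atom.map_idx] = featurizer.featurize_atom(atom)
        for bond in mol.bonds:
            i, j = bond.atoms
            key = frozenset((mol.atoms[i].map_idx, mol.atoms[j].map_idx))
            bond_feats[key] = featurizer.featurize_bond(bond)
            n_conj += int(bond.conjugated)
    return atom_feats, bond_feats, n_conj


def build_reaction_graph(rxn: HydrolysisReaction,
                         featurizer: Featurizer) -> ReactionGraph:
    """Build the union reaction graph with difference features."""
    mapping = map_reaction_atoms(rxn)
    map_order = sorted(mapping)
    atom_index = {n: i for i, n in enumerate(map_order)}

    r_atoms, r_bonds, r_conj = _side_features(rxn.reactants, featurizer)
    p_atoms, p_bonds, p_conj = _side_features(rxn.products, featurizer)

    atom_diff = np.stack([p_atoms[n] - r_atoms[n] for n in map_order])

    union = sorted({*r_bonds, *p_bonds}, key=lambda k: tuple(sorted(k)))
    zero = np.zeros(featurizer.bond_dim)
    bond_diff = np.zeros((len(union), featurizer.bond_dim))
    bond_flag = np.zeros(len(union), dtype=np.int64)
    bond_atoms = np.zeros((len(union), 2), dtype=np.int64)
    for bi, key in enumerate(union):
        rf = r_bonds.get(key)
        pf = p_bonds.get(key)
        bond_diff[bi] = (pf if pf is not None else zero) - \
                        (rf if rf is not None else zero)
        bond_flag[bi] = 0 if (rf is not None and pf is not None) else \
            (1 if pf is None else 2)
        i, j = sorted(key)
        bond_atoms[bi] = (atom_index[i], atom_index[j])

    total_charge = sum(m.total_charge for m in rxn.reactants)
    gstat = featurizer.featurize_global(rxn.reactants, rxn.fg_id, total_charge)
    # replace the per-side bond count with the union count; keep reactant MW
    gstat = gstat.copy()
    gstat[1] = len(union)
    n_rb = sum(m.n_bonds for m in rxn.reactants)
    n_pb = sum(m.n_bonds for m in rxn.products)
    gdiff = np.array([float(n_pb - n_rb), float(p_conj - r_conj)])

    return ReactionGraph(
        atom_diff=atom_diff, bond_diff=bond_diff, bond_flag=bond_flag,
        bond_atoms=bond_atoms, global_static=gstat, global_diff=gdiff,
        fg_id=rxn.fg_id, condition=rxn.condition,
        dG_label=rxn.dG_label)


# --------------------------------------------------------------------------
# serialized graph store
# --------------------------------------------------------------------------

def _graph_checksum(graphs: Iterable[ReactionGraph]) -> str:
    h = hashlib.sha256()
    for g in graphs:
        for name, arr in sorted(g.arrays().items()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(g.fg_id.encode())
        h.update(g.condition.encode())
        h.update(repr(g.dG_label).encode())
    return h.hexdigest()


def precompute_graphs(reactions: Sequence[HydrolysisReaction],
                      featurizer: Featurizer,
                      path: str | pathlib.Path) -> list[ReactionGraph]:
    """Build and serialize reaction graphs for offline preprocessing.

    Writes ``graphs.npz`` plus a JSON manifest carrying the schema version,
    feature dimensions, per-record failures and a content checksum. Returns
    the successfully built graphs. Failures are recorded per input index,
    never raised collectively.
    """
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    graphs: list[ReactionGraph] = []
    meta: list[dict] = []
    failures: list[dict] = []
    arrays: dict[str, np.ndarray] = {}
    for idx, rxn in enumerate(reactions):
        try:
            g = build_reaction_graph(rxn, featurizer)
        except Exception as exc:  # logged per record, enumeration continues
            failures.append({"index": idx, "error": str(exc)})
            continue
        for name, arr in g.arrays().items():
            arrays[f"g{len(graphs)}_{name}"] = arr
        meta.append({"fg_id": g.fg_id, "condition": g.condition,
                     "dG_label": g.dG_label})
        graphs.append(g)
    np.savez(path / "graphs.npz", **arrays)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "feature_schema": featurizer.schema_version,
        "fg_catalog": list(featurizer.fg_catalog),
        "n_graphs": len(graphs),
        "atom_dim": featurizer.atom_dim,
        "bond_dim": featurizer.bond_dim,
        "records": meta,
        "failures": failures,
        "checksum": _graph_checksum(graphs),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return graphs


def load_graph_store(path: str | pathlib.Path) -> tuple[list[ReactionGraph], dict]:
    """Reload a serialized graph store; bit-identical to the build."""
    path = pathlib.Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
        data = np.load(path / "graphs.npz")
    except Exception as exc:
        raise GraphStoreError(f"cannot read graph store at {path}") from exc
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise GraphStoreError(
            f"schema mismatch: store {manifest.get('schema_version')!r}, "
            f"library {SCHEMA_VERSION!r}")
    graphs = []
    for i, rec in enumerate(manifest["records"]):
        try:
            graphs.append(ReactionGraph(
                atom_diff=data[f"g{i}_atom_diff"],
                bond_diff=data[f"g{i}_bond_diff"],
                bond_flag=data[f"g{i}_bond_flag"],
                bond_atoms=data[f"g{i}_bond_atoms"],
                global_static=data[f"g{i}_global_static"],
                global_diff=data[f"g{i}_global_diff"],
                fg_id=rec["fg_id"], condition=rec["condition"],
                dG_label=rec["dG_label"]))
        except KeyError as exc:
            raise GraphStoreError(f"corrupt graph store: record {i}") from exc
    if _graph_checksum(graphs) != manifest["checksum"]:
        raise GraphStoreError("graph store checksum mismatch")
    return graphs, manifest
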