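"""Functional-group detection and pH-aware hydrolysis product generation.

Each hydrolyzable functional group is a template: a SMARTS pattern, the
scissile bond within the match, the atoms that receive the two water
fragments, and per-condition site rules. The neutral scheme follows the
classic four-edit picture: the scissile bond 'a' and one water O-H bond 'b'
are deleted, and bonds 'c' (substrate atom R1 to the water oxygen) and 'd'
(substrate atom R2 to the transferred hydrogen) are formed. Groups whose
hydrolysis is not a single-bond cleavage (nitriles, carbamates, ureas,
cyclic carbonates, enamines) carry custom edit scripts.

Extreme-pH surrogates: under acid the substrate is protonated at its most
electron-rich site and reacts with two waters, returning the neutral
products plus hydronium; under base the substrate is hydroxylated at its
electrophilic site and, with one balancing water, returns the neutral
products plus hydroxide.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import yaml
from rdkit import Chem

from .molgraph import (
    MoleculeRecord,
    parse_molecule,
    record_from_rdmol,
    sanitize_fragment,
)

logger = logging.getLogger(__name__)

CONDITIONS = ("neutral", "acidic", "basic")


class TemplateError(ValueError):
    pass


class GenerationError(RuntimeError):
    """Raised when a template edit yields an unsanitizable product."""


class UnsupportedConditionError(ValueError):
    """Functional group has no protonation/hydroxylation site rule."""


class ConservationError(AssertionError):
    """Internal bug guard: an emitted reaction failed mass/charge balance."""


@dataclasses.dataclass(frozen=True)
class FunctionalGroupTemplate:
    fg_id: str
    smarts: str
    #: indices (into the SMARTS match tuple) of the scissile bond 'a';
    #: None for custom edit scripts.
    scissile: Optional[tuple[int, int]]
    #: match index receiving the water OH (R1) / the water H (R2).
    r1: Optional[int]
    r2: Optional[int]
    #: match index of the protonation site (most electron-rich atom).
    protonation_site: Optional[int]
    #: match index of the hydroxylation site (electrophilic atom).
    hydroxylation_site: Optional[int]
    #: how the hydroxyl is attached while keeping valence legal.
    hydroxylation_mode: Optional[str]
    expected_products: int
    edit: str = "generic"

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise TemplateError(f"SMARTS for {self.fg_id!r} does not compile")
        return patt


@dataclasses.dataclass(frozen=True)
class FunctionalGroupMatch:
    fg_id: str
    atoms: tuple[int, ...]
    scissile: Optional[tuple[int, int]]  # host-molecule atom indices


@dataclasses.dataclass
class HydrolysisReaction:
    condition: str
    reactants: list[MoleculeRecord]
    products: list[MoleculeRecord]
    fg_id: str
    n_water: int
    dG_label: Optional[float] = None

    def reaction_smiles(self) -> str:
        """Atom-mapped reaction SMILES, reactants>>products."""
        r = ".".join(Chem.MolToSmiles(m.rdmol) for m in self.reactants)
        p = ".".join(Chem.MolToSmiles(m.rdmol) for m in self.products)
        return f"{r}>>{p}"

    def canonical_key(self) -> str:
        """Canonical string used for deduplication. Atom maps are retained
        so that distinct occurrences of the same group (which the catalog
        treats as separate reaction entries) are not merged; only
        genuinely identical reactions collapse."""
        return f"{self.condition}|{self.fg_id}|{self.reaction_smiles()}"


# --------------------------------------------------------------------------
# catalog
# --------------------------------------------------------------------------

_AMIDE_N = ("[NX3;!$([NX3]([CX3]=[OX1])[CX3]=[OX1]);"
            "!$([NX3][SX2,SX3,SX4])]")

_CATALOG_SPECS = [
    dict(fg_id="carboxylic acid ester",
         smarts=f"[CX3;!R](=[OX1])([#6,#1])[OX2;!R][#6]",
         scissile=(0, 3), r1=0, r2=3,
         protonation_site=1, hydroxylation_site=0,
         hydroxylation_mode="carbonyl", expected_products=2),
    dict(fg_id="lactone",
         smarts="[CX3;R](=[OX1])([#6,#1])[OX2;R][#6;R]",
         scissile=(0, 3), r1=0, r2=3,
         protonation_site=1, hydroxylation_site=0,
         hydroxylation_mode="carbonyl", expected_products=1),
    dict(fg_id="amide",
         smarts=f"[CX3;!R](=[OX1])([#6,#1]){_AMIDE_N.replace('[NX3;', '[NX3;!R;')}",
         scissile=(0, 3), r1=0, r2=3,
         protonation_site=1, hydroxylation_site=0,
         hydroxylation_mode="carbonyl", expected_products=2),
    dict(fg_id="lactam",
         smarts=f"[CX3;R](=[OX1])([#6,#1]){_AMIDE_N.replace('[NX3;', '[NX3;R;')}",
         scissile=(0, 3), r1=0, r2=3,
         protonation_site=1, hydroxylation_site=0,
         hydroxylation_mode="carbonyl", expected_products=1),
    dict(fg_id="imide",
         smarts="[CX3](=[OX1])([#6,#1])[NX3]([CX3]=[OX1])",
         scissile=(0, 3), r1=0, r2=3,
         protonation_site=1, hydroxylation_site=0,
         hydroxylation_mode="carbonyl", expected_products=2),
    dict(fg_id="nitrile",
         smarts="[CX2]#[NX1]",
         scissile=None, r1=None, r2=None,
         protonation_site=1, hydroxylation_site=0,
         hydroxylation_mode="nitrile", expected_products=1,
         edit="nitrile"),
    dict(fg_id="epoxide",
         smarts="[CX4;r3][OX2;r3][CX4;r3]",
         scissile=(0, 1), r1=0, r2=1,
         protonation_site=1, hydroxylation_site=0,
         hydroxylation_mode="epoxide", expected_products=1),
    dict(fg_id="cyclic carbonate",
         smarts="[CX3;R](=[OX1])([OX2;R][#6])[OX2;R][#6]",
         scissile=None, r1=None, r2=None,
         protonation_site=1, hydroxylation_site=0,
         hydroxylation_mode="carbonyl", expected_products=2,
         edit="carbonate"),
    dict(fg_id="carbamate",
         smarts="[NX3][CX3](=[OX1])[OX2][#6]",
         scissile=None, r1=None, r2=None,
         protonation_site=2, hydroxylation_site=1,
         hydroxylation_mode="carbonyl", expected_products=3,
         edit="carbamate"),
    dict(fg_id="urea",
         smarts="[NX3][CX3](=[OX1])[NX3]",
         scissile=None, r1=None, r2=None,
         protonation_site=2, hydroxylation_site=1,
         hydroxylation_mode="carbonyl", expected_products=3,
         edit="urea"),
    dict(fg_id="aliphatic fluoride",
         smarts="[CX4][F]",
         scissile=(0, 1), r1=0, r2=1,
         protonation_site=1, hydroxylation_site=None,
         hydroxylation_mode=None, expected_products=2),
    dict(fg_id="nitrogen–sulfur cleavage",
         smarts="[NX3][SX2,SX3,SX4]",
         scissile=(0, 1), r1=1, r2=0,
         protonation_site=0, hydroxylation_site=None,
         hydroxylation_mode=None, expected_products=2),
    dict(fg_id="enamine",
         smarts="[NX3]([#6,#1])([#6,#1])[CX3]=[CX3]",
         scissile=None, r1=None, r2=None,
         protonation_site=0, hydroxylation_site=3,
         hydroxylation_mode="vinyl", expected_products=2,
         edit="enamine"),
]


def load_template_catalog(path: Optional[str] = None) -> list[FunctionalGroupTemplate]:
    """Load the functional-group template catalog (stable order).

    With no argument the built-in 13-group catalog is returned. ``path``
    may point to a YAML file of additional/overriding template entries
    using the same keys as the built-in specs.
    """
    specs = [dict(s) for s in _CATALOG_SPECS]
    if path is not None:
        with open(path) as fh:
            extra = yaml.safe_load(fh) or []
        by_id = {s["fg_id"]: i for i, s in enumerate(specs)}
        for entry in extra:
            entry = dict(entry)
            for key in ("scissile",):
                if entry.get(key) is not None:
                    entry[key] = tuple(entry[key])
            if entry["fg_id"] in by_id:
                specs[by_id[entry["fg_id"]]] = entry
            else:
                specs.append(entry)
    templates = [FunctionalGroupTemplate(**s) for s in specs]
    for t in templates:
        t.pattern()  # compiles or raises
    return templates


def catalog_fg_ids(templates: Optional[list[FunctionalGroupTemplate]] = None) -> list[str]:
    return [t.fg_id for t in (templates or load_template_catalog())]


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def detect_functional_groups(
    mol: MoleculeRecord,
    templates: Optional[list[FunctionalGroupTemplate]] = None,
) -> list[FunctionalGroupMatch]:
    """One match per distinct substructure occurrence, symmetric duplicates
    (same atom set, same scissile bond) removed."""
    templates = templates or load_template_catalog()
    out: list[FunctionalGroupMatch] = []
    seen: set[tuple] = set()
    for tpl in templates:
        patt = tpl.pattern()
        for match in mol.rdmol.GetSubstructMatches(patt, uniquify=True):
            if tpl.scissile is not None:
                sc = (match[tpl.scissile[0]], match[tpl.scissile[1]])
                key = (tpl.fg_id, frozenset(match), frozenset(sc))
            else:
                sc = None
                key = (tpl.fg_id, frozenset(match), None)
            if key in seen:
                continue
            seen.add(key)
            out.append(FunctionalGroupMatch(fg_id=tpl.fg_id,
                                            atoms=tuple(match), scissile=sc))
    return out


def _template_by_id(fg_id: str,
                    templates: Optional[list[FunctionalGroupTemplate]] = None
                    ) -> FunctionalGroupTemplate:
    for t in templates or load_template_catalog():
        if t.fg_id == fg_id:
            return t
    raise TemplateError(f"no template with fg_id {fg_id!r}")


# --------------------------------------------------------------------------
# edits
# --------------------------------------------------------------------------

def _assign_maps(mol: Chem.Mol, start: int) -> int:
    """Assign consecutive atom-map numbers starting at ``start``; returns
    the next free number."""
    n = start
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(n)
        n += 1
    return n


def _water(o_map: int, h1_map: int, h2_map: int) -> Chem.Mol:
    m = Chem.RWMol()
    o = m.AddAtom(Chem.Atom(8))
    h1 = m.AddAtom(Chem.Atom(1))
    h2 = m.AddAtom(Chem.Atom(1))
    m.AddBond(o, h1, Chem.BondType.SINGLE)
    m.AddBond(o, h2, Chem.BondType.SINGLE)
    m.GetAtomWithIdx(o).SetAtomMapNum(o_map)
    m.GetAtomWithIdx(h1).SetAtomMapNum(h1_map)
    m.GetAtomWithIdx(h2).SetAtomMapNum(h2_map)
    mol = m.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _ion(symbol: str, charge: int, n_h: int, maps: list[int]) -> Chem.Mol:
    """Build hydronium/hydroxide with explicit map numbers [heavy, H...]."""
    m = Chem.RWMol()
    a = m.AddAtom(Chem.Atom(symbol))
    m.GetAtomWithIdx(a).SetFormalCharge(charge)
    m.GetAtomWithIdx(a).SetNoImplicit(True)
    m.GetAtomWithIdx(a).SetAtomMapNum(maps[0])
    for k in range(n_h):
        h = m.AddAtom(Chem.Atom(1))
        m.AddBond(a, h, Chem.BondType.SINGLE)
        m.GetAtomWithIdx(h).SetAtomMapNum(maps[1 + k])
    mol = m.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _neutral_edit(tpl: FunctionalGroupTemplate, sub: Chem.Mol,
                  match: FunctionalGroupMatch, water: Chem.Mol) -> list[Chem.Mol]:
    """Apply the template's bond edits to substrate + one water; return the
    sanitized product fragments (atom maps preserved through the edit)."""
    combo = Chem.RWMol(Chem.CombineMols(sub, water))
    off = sub.GetNumAtoms()
    o_w, h1, h2 = off, off + 1, off + 2
    a = match.atoms

    def rm(i, j):
        combo.RemoveBond(i, j)

    def add(i, j, order=Chem.BondType.SINGLE):
        combo.AddBond(i, j, order)

    def setorder(i, j, order):
        combo.GetBondBetweenAtoms(i, j).SetBondType(order)

    if tpl.edit == "generic":
        i, j = match.scissile
        rm(i, j)
        rm(o_w, h1)
        add(a[tpl.r1], o_w)
        add(a[tpl.r2], h1)
    elif tpl.edit == "nitrile":
        c, n = a[0], a[1]
        rm(o_w, h1)
        rm(o_w, h2)
        setorder(c, n, Chem.BondType.SINGLE)
        add(c, o_w, Chem.BondType.DOUBLE)
        add(n, h1)
        add(n, h2)
    elif tpl.edit == "enamine":
        n, c3, c4 = a[0], a[3], a[4]
        rm(n, c3)
        rm(o_w, h1)
        rm(o_w, h2)
        setorder(c3, c4, Chem.BondType.SINGLE)
        add(c3, o_w, Chem.BondType.DOUBLE)
        add(n, h1)
        add(c4, h2)
    elif tpl.edit == "carbamate":
        n, c, o_est = a[0], a[1], a[3]
        rm(n, c)
        rm(c, o_est)
        rm(o_w, h1)
        rm(o_w, h2)
        add(c, o_w, Chem.BondType.DOUBLE)
        add(n, h1)
        add(o_est, h2)
    elif tpl.edit == "urea":
        n1, c, n2 = a[0], a[1], a[3]
        rm(n1, c)
        rm(c, n2)
        rm(o_w, h1)
        rm(o_w, h2)
        add(c, o_w, Chem.BondType.DOUBLE)
        add(n1, h1)
        add(n2, h2)
    elif tpl.edit == "carbonate":
        c, o1, o2 = a[0], a[2], a[4]
        rm(c, o1)
        rm(c, o2)
        rm(o_w, h1)
        rm(o_w, h2)
        add(c, o_w, Chem.BondType.DOUBLE)
        add(o1, h1)
        add(o2, h2)
    else:  # pragma: no cover
        raise TemplateError(f"unknown edit script {tpl.edit!r}")

    merged = combo.GetMol()
    frags = Chem.GetMolFrags(merged, asMols=True, sanitizeFrags=False)
    out = []
    for frag in frags:
        try:
            out.append(sanitize_fragment(frag))
        except Exception as exc:
            raise GenerationError(
                f"unsanitizable product {Chem.MolToSmiles(frag)!r} from "
                f"{tpl.fg_id!r} on {Chem.MolToSmiles(sub)!r}") from exc
    return out


# --------------------------------------------------------------------------
# protonation / hydroxylation
# --------------------------------------------------------------------------

def protonate(mol: MoleculeRecord, match: FunctionalGroupMatch,
              templates: Optional[list[FunctionalGroupTemplate]] = None,
              proton_map: int = 0) -> MoleculeRecord:
    """Add H+ at the template's most electron-rich site (charge +1)."""
    tpl = _template_by_id(match.fg_id, templates)
    if tpl.protonation_site is None:
        raise UnsupportedConditionError(
            f"{match.fg_id!r} has no protonation site rule")
    site = match.atoms[tpl.protonation_site]
    rw = Chem.RWMol(Chem.Mol(mol.rdmol))
    h = rw.AddAtom(Chem.Atom(1))
    rw.AddBond(site, h, Chem.BondType.SINGLE)
    rw.GetAtomWithIdx(h).SetAtomMapNum(proton_map)
    at = rw.GetAtomWithIdx(site)
    at.SetFormalCharge(at.GetFormalCharge() + 1)
    at.SetNoImplicit(True)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise GenerationError(
            f"protonation of {mol.smiles!r} at atom {site} failed") from exc
    return record_from_rdmol(out)


def hydroxylate(mol: MoleculeRecord, match: FunctionalGroupMatch,
                templates: Optional[list[FunctionalGroupTemplate]] = None,
                o_map: int = 0, h_map: int = 0) -> MoleculeRecord:
    """Add OH- at the template's electrophilic site (charge -1).

    The attachment keeps valence legal: a carbonyl pi bond is reduced to a
    single bond with the oxygen carrying the negative charge (tetrahedral
    alkoxide); an epoxide ring-opens onto an alkoxide; a nitrile becomes an
    amide anion precursor; an enamine gives a beta-carbanion.
    """
    tpl = _template_by_id(match.fg_id, templates)
    if tpl.hydroxylation_site is None:
        raise UnsupportedConditionError(
            f"{match.fg_id!r} has no hydroxylation site rule")
    site = match.atoms[tpl.hydroxylation_site]
    a = match.atoms
    rw = Chem.RWMol(Chem.Mol(mol.rdmol))

    o = rw.AddAtom(Chem.Atom(8))
    h = rw.AddAtom(Chem.Atom(1))
    rw.AddBond(o, h, Chem.BondType.SINGLE)
    rw.AddBond(site, o, Chem.BondType.SINGLE)
    rw.GetAtomWithIdx(o).SetAtomMapNum(o_map)
    rw.GetAtomWithIdx(h).SetAtomMapNum(h_map)

    mode = tpl.hydroxylation_mode
    if mode == "carbonyl":
        # site is the carbonyl carbon; its =O becomes an alkoxide
        carbonyl_o = None
        for nb in mol.rdmol.GetAtomWithIdx(site).GetNeighbors():
            b = mol.rdmol.GetBondBetweenAtoms(site, nb.GetIdx())
            if nb.GetSymbol() == "O" and b.GetBondType() == Chem.BondType.DOUBLE:
                carbonyl_o = nb.GetIdx()
                break
        if carbonyl_o is None:
            raise GenerationError(
                f"no carbonyl oxygen at atom {site} of {mol.smiles!r}")
        rw.GetBondBetweenAtoms(site, carbonyl_o).SetBondType(Chem.BondType.SINGLE)
        ox = rw.GetAtomWithIdx(carbonyl_o)
        ox.SetFormalCharge(-1)
        ox.SetNoImplicit(True)
    elif mode == "epoxide":
        ring_o = a[1]
        rw.RemoveBond(site, ring_o)
        ox = rw.GetAtomWithIdx(ring_o)
        ox.SetFormalCharge(-1)
        ox.SetNoImplicit(True)
    elif mode == "nitrile":
        c, n = a[0], a[1]
        rw.GetBondBetweenAtoms(c, n).SetBondType(Chem.BondType.DOUBLE)
        nat = rw.GetAtomWithIdx(n)
        nat.SetFormalCharge(-1)
        nat.SetNoImplicit(True)
    elif mode == "vinyl":
        c3, c4 = a[3], a[4]
        rw.GetBondBetweenAtoms(c3, c4).SetBondType(Chem.BondType.SINGLE)
        cat = rw.GetAtomWithIdx(c4)
        cat.SetFormalCharge(-1)
        cat.SetNoImplicit(True)
    else:  # pragma: no cover
        raise TemplateError(f"unknown hydroxylation mode {mode!r}")

    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise GenerationError(
            f"hydroxylation of {mol.smiles!r} at atom {site} failed") from exc
    return record_from_rdmol(out)


# --------------------------------------------------------------------------
# reaction assembly
# --------------------------------------------------------------------------

def _validate(rxn: HydrolysisReaction) -> None:
    def side(mols):
        counts: dict[str, int] = {}
        charge = 0
        maps: list[int] = []
        for m in mols:
            for el, n in m.element_counts().items():
                counts[el] = counts.get(el, 0) + n
            charge += m.total_charge
            maps.extend(m.map_numbers())
        return counts, charge, maps

    rc, rq, rmaps = side(rxn.reactants)
    pc, pq, pmaps = side(rxn.products)
    if rc != pc:
        raise ConservationError(
            f"element multiset not conserved: {rc} vs {pc} in "
            f"{rxn.reaction_smiles()}")
    if rq != pq:
        raise ConservationError(
            f"charge not conserved: {rq} vs {pq} in {rxn.reaction_smiles()}")
    if sorted(rmaps) != sorted(pmaps) or len(set(rmaps)) != len(rmaps) \
            or 0 in rmaps:
        raise ConservationError(
            f"atom map is not a bijection in {rxn.reaction_smiles()}")


def apply_hydrolysis_template(
    mol: MoleculeRecord, match: FunctionalGroupMatch,
    templates: Optional[list[FunctionalGroupTemplate]] = None,
) -> HydrolysisReaction:
    """Neutral-scheme hydrolysis of ``mol`` at ``match``."""
    return assemble_reaction(mol, match, "neutral", templates)


def assemble_reaction(
    substrate: MoleculeRecord, match: FunctionalGroupMatch, condition: str,
    templates: Optional[list[FunctionalGroupTemplate]] = None,
) -> HydrolysisReaction:
    """Build the fully atom-mapped reaction for one match and condition.

    ``substrate`` is the neutral molecule; protonation/hydroxylation for
    the acidic/basic schemes is applied internally so that the atom map is
    total by construction.

    Stoichiometry:

    * neutral:  X + H2O -> products
    * acidic:   X.H+ + 2 H2O -> products + H3O+
    * basic:    X.OH- + H2O -> products + OH-
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    templates = templates or load_template_catalog()
    tpl = _template_by_id(match.fg_id, templates)

    # condition-specific site rules are checked before any heavy work so an
    # unsupported condition surfaces as the right error type
    if condition == "acidic" and tpl.protonation_site is None:
        raise UnsupportedConditionError(
            f"{match.fg_id!r} has no protonation site rule")
    if condition == "basic" and tpl.hydroxylation_site is None:
        raise UnsupportedConditionError(
            f"{match.fg_id!r} has no hydroxylation site rule")

    sub = Chem.Mol(substrate.rdmol)
    n = _assign_maps(sub, 1) - 1  # substrate maps 1..n
    sub_rec = record_from_rdmol(sub)
    # incorporated water: O=n+1, transferred H=n+2, retained H=n+3
    w1 = _water(n + 1, n + 2, n + 3)
    product_mols = _neutral_edit(tpl, sub, match, w1)
    products = [record_from_rdmol(m) for m in product_mols]

    if condition == "neutral":
        rxn = HydrolysisReaction("neutral", [sub_rec, record_from_rdmol(w1)],
                                 products, match.fg_id, n_water=1)
    elif condition == "acidic":
        psub = protonate(sub_rec, match, templates, proton_map=n + 7)
        w2 = _water(n + 4, n + 5, n + 6)
        hydronium = record_from_rdmol(
            _ion("O", +1, 3, [n + 4, n + 5, n + 6, n + 7]))
        rxn = HydrolysisReaction(
            "acidic",
            [psub, record_from_rdmol(w1), record_from_rdmol(w2)],
            products + [hydronium], match.fg_id, n_water=2)
    else:  # basic
        hsub = hydroxylate(sub_rec, match, templates,
                           o_map=n + 1, h_map=n + 3)
        w2 = _water(n + 4, n + 2, n + 5)
        hydroxide = record_from_rdmol(_ion("O", -1, 1, [n + 4, n + 5]))
        rxn = HydrolysisReaction(
            "basic", [hsub, record_from_rdmol(w2)],
            products + [hydroxide], match.fg_id, n_water=1)

    _validate(rxn)
    return rxn


def enumerate_hydrolysis(
    mol: MoleculeRecord, condition: str = "neutral",
    templates: Optional[list[FunctionalGroupTemplate]] = None,
) -> list[HydrolysisReaction]:
    """All hydrolysis reactions of ``mol`` under ``condition``.

    Each functional-group occurrence yields an independent reaction.
    Nitrile matches additionally emit the one-step cascade reaction whose
    reactant is the intermediate amide. Failures are logged per reaction
    and do not affect the remaining matches; duplicates (identical
    canonical reaction strings) are removed with stable ordering.
    """
    templates = templates or load_template_catalog()
    out: list[HydrolysisReaction] = []
    seen: set[str] = set()

    def emit(rxn: HydrolysisReaction) -> None:
        key = rxn.canonical_key()
        if key not in seen:
            seen.add(key)
            out.append(rxn)

    for match in detect_functional_groups(mol, templates):
        try:
            rxn = assemble_reaction(mol, match, condition, templates)
        except (GenerationError, UnsupportedConditionError) as exc:
            logger.info("dropping %s reaction for %s on %s: %s",
                        condition, match.fg_id, mol.smiles, exc)
            continue
        emit(rxn)
        if match.fg_id == "nitrile":
            # cascade depth exactly 1: the amide intermediate reacts on
            neutral = rxn if condition == "neutral" else \
                assemble_reaction(mol, match, "neutral", templates)
            for prod in neutral.products:
                inter = parse_molecule(prod.smiles)
                for m2 in detect_functional_groups(inter, templates):
                    if m2.fg_id != "amide":
                        continue
                    try:
                        emit(assemble_reaction(inter, m2, condition, templates))
                    except (GenerationError, UnsupportedConditionError) as exc:
                        logger.info("dropping cascade reaction on %s: %s",
                                    inter.smiles, exc)
    return out
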