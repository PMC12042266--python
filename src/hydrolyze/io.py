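"""Reaction dataset readers/writers and the synthetic fixture generator.

Two on-disk dialects are supported: ``jsonl`` (one JSON object per line,
the package's native format) and ``deposit`` (CSV with auto-detected column
names, matching the published hydrolysis free-energy deposit whose exact
schema is not documented; the alias table below is config-overridable).

The fixture generator is a synthetic stand-in for the DFT-labeled data: it
runs the real template engine on small randomly decorated scaffolds and
labels each reaction with an additive bond-increment surrogate energy

    dG = sum(increments over broken bonds) - sum(over formed bonds)
         + functional-group offset + Gaussian noise.

The increment table uses bond-energy-flavored magnitudes (tens of
kcal/mol) so labels span roughly -40..40 kcal/mol like the neutral data;
the labels are synthetic, not physical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .molgraph import MoleculeRecord, parse_molecule
from .templates import (
    ConservationError,
    HydrolysisReaction,
    enumerate_hydrolysis,
    load_template_catalog,
    _validate,
)
from rdkit import Chem

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    pass


@dataclasses.dataclass
class ReactionRecord:
    reactant_smiles: str            # atom-mapped, dot-joined reactant side
    product_smiles: list[str]       # atom-mapped product species
    condition: str
    fg_id: str
    dG_label: Optional[float] = None
    source: str = "fixture"

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "ReactionRecord":
        return cls(**d)


class ReactionDataset(list):
    """List of validated :class:`ReactionRecord` with rejection accounting."""

    def __init__(self, records=(), n_rejected: int = 0,
                 diagnostics: Optional[list[str]] = None):
        super().__init__(records)
        self.n_rejected = n_rejected
        self.diagnostics = diagnostics or []


def _mapped_mol(smiles: str) -> MoleculeRecord:
    from .molgraph import record_from_rdmol
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise DatasetError(f"unparsable SMILES {smiles!r}")
    Chem.SanitizeMol(mol)
    mol = Chem.AddHs(mol)
    Chem.SanitizeMol(mol)
    return record_from_rdmol(mol)


def record_to_reaction(rec: ReactionRecord) -> HydrolysisReaction:
    """Parse and validate a record into a fully mapped reaction."""
    reactants = [_mapped_mol(s) for s in rec.reactant_smiles.split(".")]
    # regroup fragments written as one mapped SMILES into connected species
    products = [_mapped_mol(s) for p in rec.product_smiles
                for s in p.split(".")]
    rxn = HydrolysisReaction(
        condition=rec.condition, reactants=reactants, products=products,
        fg_id=rec.fg_id,
        n_water=2 if rec.condition == "acidic" else 1,
        dG_label=rec.dG_label)
    _validate(rxn)
    return rxn


def reaction_to_record(rxn: HydrolysisReaction,
                       source: str = "fixture") -> ReactionRecord:
    return ReactionRecord(
        reactant_smiles=".".join(Chem.MolToSmiles(m.rdmol)
                                 for m in rxn.reactants),
        product_smiles=[Chem.MolToSmiles(m.rdmol) for m in rxn.products],
        condition=rxn.condition, fg_id=rxn.fg_id,
        dG_label=rxn.dG_label, source=source)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

#: documented alias table for the deposit dialect; keys are record fields,
#: values are candidate column names checked in order (case-insensitive).
DEPOSIT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "reactant_smiles": ("reactant_smiles", "reactant", "reactants",
                        "reactant_molecule_graph", "rxn_reactants"),
    "product_smiles": ("product_smiles", "products", "product",
                       "rxn_products"),
    "condition": ("condition", "ph_condition", "medium", "state"),
    "fg_id": ("fg_id", "functional_group", "fg", "reaction_type"),
    "dG_label": ("dg_label", "dg", "dg_r", "delta_g", "free_energy",
                 "dg_rxn", "target"),
    "source": ("source", "dataset", "origin"),
}


def _detect_columns(columns, aliases) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    out = {}
    for field, cands in aliases.items():
        for cand in cands:
            if cand in lower:
                out[field] = lower[cand]
                break
    missing = {"reactant_smiles", "product_smiles"} - set(out)
    if missing:
        raise DatasetError(
            f"deposit dialect: cannot locate columns for {sorted(missing)}; "
            f"available: {list(columns)}")
    return out


def _validate_record(rec: ReactionRecord) -> None:
    if rec.dG_label is not None and not np.isfinite(rec.dG_label):
        raise DatasetError("non-finite free-energy label")
    record_to_reaction(rec)


def read_reaction_dataset(path: str | pathlib.Path, dialect: str = "jsonl",
                          column_aliases: Optional[dict] = None,
                          validate: bool = True) -> ReactionDataset:
    """Read and validate reaction records.

    Invalid records (unparsable species, broken conservation, bad atom
    maps) are rejected with per-record diagnostics and counted on the
    returned dataset; they never raise.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw: list[dict] = []
    if dialect == "jsonl":
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            try:
                raw.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raw.append({"__error__": f"line {i}: {exc}"})
    elif dialect == "deposit":
        df = pd.read_csv(path, float_precision="round_trip")
        cols = _detect_columns(df.columns,
                               column_aliases or DEPOSIT_COLUMN_ALIASES)
        for _, row in df.iterrows():
            d = {field: row[col] for field, col in cols.items()}
            prods = d.get("product_smiles")
            if isinstance(prods, str):
                try:
                    d["product_smiles"] = json.loads(prods)
                except json.JSONDecodeError:
                    d["product_smiles"] = prods.split(".")
            if "dG_label" in d and d["dG_label"] is not None:
                d["dG_label"] = float(d["dG_label"])
            d.setdefault("condition", "neutral")
            d.setdefault("fg_id", "carboxylic acid ester")
            d.setdefault("source", "deposit")
            raw.append(d)
    else:
        raise DatasetError(f"unknown dialect {dialect!r}")

    records, diags = [], []
    for i, d in enumerate(raw):
        if "__error__" in d:
            diags.append(d["__error__"])
            continue
        try:
            rec = ReactionRecord.from_json(d)
            if validate:
                _validate_record(rec)
            records.append(rec)
        except Exception as exc:
            diags.append(f"record {i}: {exc}")
    ds = ReactionDataset(records, n_rejected=len(diags), diagnostics=diags)
    if diags:
        logger.warning("rejected %d/%d records from %s",
                       len(diags), len(raw), path)
        for msg in diags[:20]:
            logger.debug("  %s", msg)
    return ds


def write_reaction_dataset(records: Sequence[ReactionRecord],
                           path: str | pathlib.Path,
                           dialect: str = "jsonl") -> None:
    path = pathlib.Path(path)
    if dialect == "jsonl":
        path.write_text(
            "".join(json.dumps(r.to_json()) + "\n" for r in records))
    elif dialect == "deposit":
        df = pd.DataFrame([{
            "reactant_smiles": r.reactant_smiles,
            "product_smiles": json.dumps(r.product_smiles),
            "condition": r.condition,
            "fg_id": r.fg_id,
            "dg_label": None if r.dG_label is None else repr(r.dG_label),
            "source": r.source,
        } for r in records])
        df.to_csv(path, index=False)
    else:
        raise DatasetError(f"unknown dialect {dialect!r}")


def summarize_deposit(paths: dict[str, str | pathlib.Path],
                      dialect: str = "deposit") -> dict[str, dict]:
    """Record counts and endergonic counts per deposit file.

    Intended for checking a downloaded copy of the published dataset
    (neutral/protonated/hydroxylated folds); returns
    ``{name: {"n": ..., "n_endergonic": ...}}``.
    """
    out = {}
    for name, p in paths.items():
        ds = read_reaction_dataset(p, dialect=dialect, validate=False)
        labels = np.array([r.dG_label for r in ds if r.dG_label is not None])
        out[name] = {"n": len(ds),
                     "n_endergonic": int(np.sum(labels > 0))}
    return out


# --------------------------------------------------------------------------
# synthetic fixtures
# --------------------------------------------------------------------------

#: surrogate energy increments per bond class, kcal/mol. Keys are
#: (sorted element pair, order tag). Values are bond-energy-flavored but
#: deliberately detuned so hydrolysis labels land in roughly -40..40.
DEFAULT_BOND_INCREMENTS: dict[tuple[tuple[str, str], str], float] = {
    (("C", "O"), "SINGLE"): 85.0,
    (("C", "O"), "DOUBLE"): 177.0,
    (("H", "O"), "SINGLE"): 111.0,
    (("C", "N"), "SINGLE"): 73.0,
    (("C", "N"), "DOUBLE"): 147.0,
    (("C", "N"), "TRIPLE"): 213.0,
    (("H", "N"), "SINGLE"): 93.0,
    (("C", "C"), "SINGLE"): 83.0,
    (("C", "C"), "DOUBLE"): 146.0,
    (("C", "F"), "SINGLE"): 116.0,
    (("F", "H"), "SINGLE"): 135.0,
    (("N", "S"), "SINGLE"): 58.0,
    (("O", "S"), "SINGLE"): 87.0,
    (("C", "H"), "SINGLE"): 99.0,
}

#: synthetic per-group offsets (kcal/mol), spreading the label distribution.
DEFAULT_FG_OFFSETS: dict[str, float] = {
    "carboxylic acid ester": -6.0,
    "lactone": -18.0,
    "amide": 14.0,
    "lactam": 22.0,
    "imide": 8.0,
    "nitrile": -10.0,
    "epoxide": -24.0,
    "cyclic carbonate": -12.0,
    "carbamate": 4.0,
    "urea": 10.0,
    "aliphatic fluoride": -4.0,
    "nitrogen–sulfur cleavage": -8.0,
    "enamine": 6.0,
}

#: small decorated scaffolds containing each catalog group.
FIXTURE_SCAFFOLDS: dict[str, tuple[str, ...]] = {
    "carboxylic acid ester": ("CC(=O)OC", "CCC(=O)OC", "CC(=O)OCC",
                              "O=COC", "CC(C)C(=O)OC", "COC(=O)CO"),
    "lactone": ("O=C1CCO1", "O=C1CCCO1", "O=C1CCCCO1", "CC1CC(=O)O1"),
    "amide": ("CC(=O)N", "CC(=O)NC", "CCC(=O)NC", "CC(=O)N(C)C", "O=CNC"),
    "lactam": ("O=C1CCN1", "O=C1CCCN1", "O=C1CCCN1C", "O=C1CCCCN1"),
    "imide": ("CC(=O)NC(C)=O", "O=C1CCC(=O)N1", "O=C1CCC(=O)N1C"),
    "nitrile": ("CC#N", "CCC#N", "N#CCO", "CC(C)C#N"),
    "epoxide": ("C1CO1", "CC1CO1", "CC1OC1C", "OCC1CO1"),
    "cyclic carbonate": ("O=C1OCCO1", "CC1COC(=O)O1"),
    "carbamate": ("CNC(=O)OC", "NC(=O)OC", "CCNC(=O)OC", "CNC(=O)OCC"),
    "urea": ("NC(N)=O", "CNC(N)=O", "CNC(=O)NC", "CN(C)C(N)=O"),
    "aliphatic fluoride": ("CF", "CCF", "CC(F)C", "OCCF"),
    "nitrogen–sulfur cleavage": ("CS(=O)(=O)NC", "CNSC", "CS(=O)(=O)N"),
    "enamine": ("C=CN(C)C", "CC=CN(C)C", "C=CNC", "CC(=CC)N(C)C"),
}


@dataclasses.dataclass
class FixtureSpec:
    n: int = 100
    seed: int = 0
    fg_mix: Optional[dict[str, float]] = None       # None = uniform
    condition_mix: Optional[dict[str, float]] = None  # None = neutral only
    noise_sd: float = 0.5
    bond_increments: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BOND_INCREMENTS))
    fg_offsets: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FG_OFFSETS))

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for mix in (self.fg_mix, self.condition_mix):
            if mix is not None and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("mix proportions must sum to 1")


def _bond_multiset(mols: Sequence[MoleculeRecord]) -> dict:
    """Map-pair keyed bond orders over a reaction side."""
    out = {}
    for m in mols:
        for b in m.bonds:
            i, j = b.atoms
            key = frozenset((m.atoms[i].map_idx, m.atoms[j].map_idx))
            out[key] = (b, m)
    return out


def _bond_class(mols_entry) -> tuple[tuple[str, str], str]:
    b, m = mols_entry
    i, j = b.atoms
    pair = tuple(sorted((m.atoms[i].element, m.atoms[j].element)))
    return (pair, b.order)


def surrogate_label(rxn: HydrolysisReaction, increments: dict,
                    fg_offsets: dict) -> float:
    """Noiseless additive bond-increment energy of a reaction."""
    r = _bond_multiset(rxn.reactants)
    p = _bond_multiset(rxn.products)
    broken = [k for k in r if k not in p or
              _bond_class(r[k]) != _bond_class(p[k])]
    formed = [k for k in p if k not in r or
              _bond_class(p[k]) != _bond_class(r[k])]
    total = 0.0
    for k in broken:
        total += increments.get(_bond_class(r[k]), 80.0)
    for k in formed:
        total -= increments.get(_bond_class(p[k]), 80.0)
    return total + fg_offsets.get(rxn.fg_id, 0.0)


class FixtureGenerationError(RuntimeError):
    pass


def generate_fixtures(spec: FixtureSpec
                      ) -> tuple[list[ReactionRecord], list[HydrolysisReaction]]:
    """Labeled synthetic reactions produced by the real template engine.

    Deterministic under ``spec.seed``. Returns both the serializable
    records and the in-memory reactions (same order).
    """
    rng = np.random.default_rng(spec.seed)
    templates = load_template_catalog()
    fg_ids = list(FIXTURE_SCAFFOLDS)
    fg_mix = spec.fg_mix or {fg: 1.0 / len(fg_ids) for fg in fg_ids}
    for fg in fg_mix:
        if fg not in FIXTURE_SCAFFOLDS:
            raise FixtureGenerationError(f"no scaffolds for fg {fg!r}")
    cond_mix = spec.condition_mix or {"neutral": 1.0}
    fg_names = list(fg_mix)
    fg_p = np.array([fg_mix[k] for k in fg_names])
    cond_names = list(cond_mix)
    cond_p = np.array([cond_mix[k] for k in cond_names])

    records, reactions = [], []
    attempts = 0
    while len(records) < spec.n:
        attempts += 1
        if attempts > 50 * spec.n:
            raise FixtureGenerationError(
                "unsatisfiable fixture mix: too many failed draws")
        fg = fg_names[rng.choice(len(fg_names), p=fg_p)]
        cond = cond_names[rng.choice(len(cond_names), p=cond_p)]
        scaffolds = FIXTURE_SCAFFOLDS[fg]
        smi = scaffolds[rng.integers(len(scaffolds))]
        mol = parse_molecule(smi)
        rxns = [r for r in enumerate_hydrolysis(mol, cond, templates)
                if r.fg_id == fg]
        if not rxns:
            continue
        rxn = rxns[rng.integers(len(rxns))]
        label = surrogate_label(rxn, spec.bond_increments, spec.fg_offsets)
        if spec.noise_sd > 0:
            label += rng.normal(0.0, spec.noise_sd)
        rxn.dG_label = float(label)
        reactions.append(rxn)
        records.append(reaction_to_record(rxn, source="fixture"))
    return records, reactions
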