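# hydrolyze

Template-driven enumeration of hydrolysis reactions and graph-neural-network
prediction of their free energies, for screening the hydrolytic stability of
small organic molecules under neutral, acidic and basic conditions.

## The problem

Hydrolysis — bond cleavage in which water is both reactant and solvent —
controls the fate of esters, amides, nitriles, epoxides and many other
functional groups in biological, environmental and polymer chemistry. Its
thermodynamic feasibility is quantified by the reaction free energy
ΔG_r (kcal/mol): negative = exergonic (favorable), positive = endergonic.
Within a reaction family the Bell–Evans–Polanyi relation links ΔG_r to the
activation barrier, so ranking pathways by ΔG_r is a useful screening proxy.
Computing ΔG_r with DFT takes hours per reaction; this package couples

1. a **template engine** that detects 13 hydrolyzable functional groups
   (SMARTS substructure matching on explicit-hydrogen graphs), applies the
   bond-edit scheme — delete the scissile bond *a* and a water O–H bond *b*,
   form bonds *c* (substrate→water O) and *d* (substrate→water H) — and
   emits fully atom-mapped, mass- and charge-balanced reactions.
   Extreme-pH surrogates: under acid the substrate is protonated at its most
   electron-rich site and reacts with two waters, yielding the products plus
   hydronium (X·H⁺ + 2 H₂O → products + H₃O⁺); under base the substrate is
   hydroxylated at its electrophilic site (X·OH⁻ + H₂O → products + OH⁻).
   Nitriles cascade: nitrile → amide, then amide → acid + amine, two
   reaction entries per nitrile.

2. a **reaction-graph GNN** that regresses ΔG_r from a single *union
   reaction graph*: one node per mapped atom, one node per bond in the
   union of reactant and product bond sets, plus a global node. Node
   features are product-minus-reactant differences; a bond absent on one
   side contributes a zero vector, so any number of simultaneous bond
   cleavages/formations is representable. Gated graph convolutions pass
   messages bond → atom → global with sigmoid gating and residual updates;
   readout is one of {set2set, weighted mean, self-attention, mean} pooling
   over atom+bond nodes concatenated with the global embedding, followed by
   a dense head.

The GNN runs on a small NumPy reverse-mode autodiff engine included in the
package (`hydrolyze.autograd`) — no deep-learning framework is required.

## Worked example

```python
from hydrolyze import parse_molecule, enumerate_hydrolysis

mol = parse_molecule("CC(=O)OC")            # methyl acetate
for rxn in enumerate_hydrolysis(mol, "acidic"):
    print(rxn.fg_id, "->", [p.smiles for p in rxn.products])
# carboxylic acid ester -> ['CC(=O)O', 'CO', '[OH3+]']
```

Methyl acetate under acid gives acetic acid, methanol and hydronium — the
protonated substrate plus two waters on the reactant side keep the +1
charge and the atom balance exact.

Train and use a model on synthetic fixtures from the command line:

```bash
hydrolyze --seed 3 fixtures --n 400 --noise-sd 0 --output fix.jsonl
hydrolyze preprocess --input fix.jsonl --store store/
hydrolyze --seed 1 train --store store/ --model-out model.npz
hydrolyze predict --smiles "N#CCC(=O)OC" --model model.npz
```

`predict` enumerates every hydrolysis pathway of the molecule and prints
one line per pathway, sorted ascending by predicted ΔG_r (most favorable
first), e.g.

```
    -5.451 kcal/mol  carboxylic acid ester        -> N#CCC(=O)O + CO
    -2.522 kcal/mol  nitrile                      -> COC(=O)CC(N)=O
    26.011 kcal/mol  amide                        -> COC(=O)CC(=O)O + N
```

Methyl cyanoacetate carries two hydrolyzable groups; the third row is the
one-step cascade of the nitrile's amide intermediate. Labels here are the
fixture generator's synthetic bond-increment energies, not DFT, so the
numbers rank pathways on the surrogate scale only.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch: enumerates reactions for a set
of canonical substrates under all three conditions, generates 1200 labeled
fixture reactions with the template engine, precomputes and reloads the
serialized graph store, trains the GNN and reports held-out regression
metrics to stderr (~1 min on one CPU).

## Package layout

| module | contents |
| --- | --- |
| `hydrolyze.molgraph` | explicit-H molecule records, atom/bond/global featurization |
| `hydrolyze.templates` | functional-group catalog, detection, bond edits, pH schemes |
| `hydrolyze.reaction_graph` | atom mapping, union difference graphs, graph store |
| `hydrolyze.autograd` | minimal reverse-mode autodiff (dense + segment ops) |
| `hydrolyze.model` | gated graph conv, pooling menu, training, evaluation |
| `hydrolyze.io` | JSONL/CSV readers and writers, synthetic fixture generator |
| `hydrolyze.cli` | `hydrolyze` command: enumerate/fixtures/preprocess/train/evaluate/predict |

See `docs/methods.md` for the model equations, parameter defaults and the
limits of what the synthetic fixtures can establish.
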