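# Methods

## Molecular representation

Every molecule is an explicit-hydrogen graph. This is not cosmetic: the
neutral hydrolysis edit deletes a water O–H bond and forms a new O–H bond
on a product fragment, so hydrogens must be bookkept as first-class nodes,
and every atom (hydrogens included) carries an atom-map index that is
unique across a reaction's species. The element vocabulary is
{H, C, N, O, F, S, Cl}; molecules containing anything else are rejected
with a schema error rather than silently truncated. Atomic weights are
standard IUPAC values to three decimals.

Feature schema (version `hydrolyze-features-1`):

- **atom** (16 dims): element one-hot (7), degree (heavy+H neighbors),
  atomic weight (amu), in-ring flag, hybridization one-hot
  (S/SP/SP2/SP3/other), formal charge.
- **bond** (6 dims): order one-hot (single/double/triple/aromatic),
  in-ring flag, conjugation flag. The bond feature set is a documented
  design choice — only the atom and molecule-level descriptors of this
  architecture family are standardized, so the bond block was chosen as
  the minimal set that distinguishes the edits the templates perform.
- **global/side** (4 + 13 dims): atom count, bond count, molecular weight,
  total charge, functional-group one-hot over the 13-group catalog.

## Template engine

A functional-group template is a SMARTS pattern plus: the scissile bond
within the match, the two attachment atoms that receive the water
fragments, a protonation-site rule, a hydroxylation-site rule, and an
expected product count. The built-in catalog covers 13 groups: lactone,
nitrile, lactam, imide, nitrogen–sulfur cleavage, enamine, amide, cyclic
carbonate, aliphatic fluoride, carboxylic acid ester, carbamate, urea and
epoxide. The catalog is extensible/overridable through a YAML file with
the same keys.

**Neutral scheme.** Substrate and one water are combined into a single
editable graph with maps preassigned; the scissile bond and the first
water O–H are deleted; new bonds substrate→O_w and substrate→H are added;
connected components are split and sanitized individually. A sanitization
failure raises a generation error carrying the offending fragment — the
reaction is dropped and logged, never emitted silently.

Groups whose hydrolysis is not a single-bond cleavage use custom edit
scripts over the same machinery:

- *nitrile*: C≡N reduced to C–N, water O double-bonded to carbon, both
  water hydrogens to nitrogen — the amide is produced directly rather than
  its imidic-acid tautomer. The amide intermediate is then itself
  hydrolyzed (cascade depth exactly 1), so each nitrile yields two
  reaction entries.
- *carbamate*: N–C and C–O(ester) cleaved; amine + alcohol + CO₂
  (3 products). *urea*: both C–N cleaved; two amines + CO₂.
- *cyclic carbonate*: both ring ester bonds cleaved; diol + CO₂.
- *enamine*: N–C(sp2) cleaved and the C=C reduced; amine + carbonyl
  compound.

**Acidic scheme.** The substrate is protonated at the template's most
electron-rich site (carbonyl O for acyl groups, nitrile N, epoxide O,
amine N of enamines and N–S groups, F of alkyl fluorides) and reacts with
two waters; the extra water absorbs the proton so the products are the
neutral products plus hydronium. Charge +1 on both sides by construction.

**Basic scheme.** The substrate is hydroxylated at the electrophilic site.
Valence is kept legal per group: carbonyl groups form the tetrahedral
alkoxide (π bond reduced, O⁻), epoxides ring-open onto an alkoxide,
nitriles form the C=N⁻ adduct, enamines a β-carbanion. The literal
reading "X·OH⁻ → products + OH⁻" cannot conserve atoms, so the engine
uses the minimal balanced form X·OH⁻ + H₂O → neutral products + OH⁻; the
balancing water supplies the hydrogen the leaving group needs and exits
as hydroxide. Aliphatic fluoride and N–S cleavage have no hydroxylation
rule (the adduct is not representable as a closed-shell molecule /
sanitizable hypervalent sulfur) and raise an unsupported-condition error
under base; all other groups support all three conditions.

Atom maps are assigned on the reactant union before any edit and carried
through, so the map is total and bijective by construction; every emitted
reaction passes an internal element-multiset/charge/bijection check that
raises (bug guard) rather than producing bad data. Each occurrence of a
group in a molecule is an independent reaction entry; deduplication only
collapses literally identical atom-mapped reaction strings.

## Union reaction graph

Atom nodes are ordered by map number (stable under species reordering);
bond nodes are the union of the reactant and product bond sets keyed by
unordered map pairs; one global node completes the heterograph. Node
features are product − reactant differences, with a zero vector standing
in for the side on which a bond does not exist; each bond node also
carries a presence flag (both / reactant-only = broken / product-only =
formed). A bond whose order changes counts as "both" with a nonzero
difference, not as break+form. Formed bonds are treated symmetrically to
broken ones (zero reactant-side vector).

The difference direction is frozen as product − reactant and versioned
(`hydrolyze-rxngraph-1`); reversing a reaction negates every atom/bond
difference exactly. The global node splits into a static part (atom
count, union bond count, reactant molecular weight, total charge — which
encodes the condition: 0/+1/−1 — and the fg one-hot) and an antisymmetric
part (bond-count and conjugated-bond-count deltas), so the negation
property holds for everything that is a difference while reaction-level
context stays intact.

Graph stores serialize all arrays to `graphs.npz` with a JSON manifest
holding the schema version, per-record failures and a SHA-256 content
checksum; rebuild determinism is defined (and tested) as checksum
equality, and reload verifies the checksum.

## Network

Embeddings of size d (default 64) for atom, bond and global nodes are
obtained by linear projection of the (scaled) input features. Each of the
stacked layers (default 3, valid 2–4) applies, in order:

    bond b=(u,v):  z_b = [h_u + h_v, h_b, h_g]
                   h_b ← h_b + σ(z_b W_b^g) ⊙ tanh(z_b W_b^m)
    atom a:        z_a = [mean of incident h_b, h_a, h_g]
                   h_a ← h_a + σ(z_a W_a^g) ⊙ tanh(z_a W_a^m)
    global:        z_g = [mean_a h_a, mean_b h_b, h_g]
                   h_g ← h_g + σ(z_g W_g^g) ⊙ tanh(z_g W_g^m)

The exact gated-update equations of the predecessor architecture are not
published; these are this package's own frozen equations satisfying the
same contract (bond updates from incident atoms + global, atoms from
incident bonds + global, global from aggregates, sigmoid gating,
residual identity at zero weights, permutation equivariance).

Readout pools the atom+bond node set with one of: **mean**,
**weighted mean** (σ-gated weights, normalized — equal weights reduce
exactly to mean), **self-attention** (softmax over tanh scores), or
**set2set** (default; LSTM-driven iterative attention, 3 steps, output
2d). The pooled vector concatenated with the global embedding feeds a
dense head (default one hidden layer of 64, ReLU) ending in a scalar.

All tensors run on the package's reverse-mode autodiff engine
(`hydrolyze.autograd`): dense ops plus gather/segment-sum/segment-mean/
segment-softmax for batching variable-size graphs. Every op's gradient is
verified against central finite differences in the test suite. No GPU or
framework dependency; determinism is bitwise given config seed and data.

## Training

- Loss: MSE on standardized labels (MAE available by config); MAE is the
  reported metric.
- Input scaling: per-dimension scales from the training set; difference
  features are scaled but not centered so zero keeps meaning
  "no change"; the global block is centered too. Stored on the model.
- Optimizer Adam, lr 1e-3 (default), batch 128, early stopping on a
  seeded 9:1 train/validation split with patience 30; the
  best-validation parameters are restored. Defaults follow the upstream
  architecture family where published; the exact hyperparameters of the
  reference models are not available, so all are surfaced in
  `ModelConfig` and none are hard-coded.
- One unified model covers all three conditions: the condition enters
  through the total charge in the global features; per-condition training
  is just filtering the input dataset.
- Checkpoints embed parameters, config, feature-schema version, input
  scales and label statistics; prediction refuses graphs whose feature
  dimensions mismatch the stored schema.

Evaluation reports MAE, RMSE, R², endergonic/exergonic sign accuracy
(percent of reactions with correct sign of ΔG_r), absolute-error bins
(<2, 2–5, 5–10, >10 kcal/mol) and a per-functional-group MAE table.

## Synthetic fixtures: what they are and are not

The fixture generator runs the *real* template engine on small decorated
scaffolds (2–6 heavy-atom neighborhoods around each catalog group) and
labels each reaction with an additive surrogate:

    ΔG = Σ increments(broken bonds) − Σ increments(formed bonds)
         + fg offset + N(0, noise_sd)

The increment table uses bond-energy-flavored magnitudes (tens of
kcal/mol, e.g. O–H 111, C=O 177, C≡N 213) and the offsets spread the
groups so labels span roughly −40..40 kcal/mol, mirroring the neutral
free-energy range of real hydrolysis datasets; default noise_sd is
0.5 kcal/mol. The labels are synthetic, not physical.

Because the surrogate is an additive function of exactly the broken/formed
bond classes that the difference features encode, a green recovery test
establishes that the architecture, mapping, batching and optimization are
correct — it does **not** establish chemical accuracy. Real DFT labels
depend on ring strain, conjugation across the molecule and solvation in
ways the surrogate omits; reproducing the published accuracy
(MAE ≈ 1.7 kcal/mol neutral, ≈ 3–7 kcal/mol charged, 97% sign accuracy)
requires the deposited DFT dataset and long training runs, which are out
of desk scale by design.

## Numerical choices and degenerate inputs

- Which water O–H breaks is deterministic (the first hydrogen); waters
  are symmetric so the choice is a tie-break, not chemistry.
- Segment softmax subtracts per-segment maxima for stability; segment
  means clip empty-segment counts to 1 (an isolated node contributes a
  zero aggregate).
- y standardization guards σ=0 with σ←1; feature scales are clipped at
  1e-3.
- Training on a single labeled graph skips validation (no split
  possible); empty datasets raise, as does a non-finite loss (with the
  epoch index).
- Deposit CSV floats are written via `repr` and read with
  `float_precision="round_trip"` so read∘write is exact.

## Known limitations

- 13 of the "20 standard" hydrolyzable groups are shipped; the remaining
  templates can be supplied via the YAML catalog but are not built in.
- Site selection under acid/base is rule-based (one site per template);
  pKa-based site prediction is explicitly out of scope.
- The basic-scheme balancing water is a modeling decision (see above);
  datasets generated under a different convention will fail conservation
  validation at read time unless remapped.
- Pure-NumPy training is single-CPU; it is comfortable at 10³–10⁴
  reactions but not engineered for the full 68k-reaction scale.
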