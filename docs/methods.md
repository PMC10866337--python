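# Methods

## Targets and thermodynamic conventions

The two regression targets are the solvation free energy and solvation
enthalpy of activation at 298 K, in kcal/mol, for a reaction in a solvent:

    ΔΔG‡_solv = ΔG_solv(TS) − Σ_i ΔG_solv(reactant_i)
    ΔΔH‡_solv = ΔH_solv(TS) − Σ_i ΔH_solv(reactant_i)

with a 1 M ideal-gas / 1 M solution standard state. For bimolecular
reactions the reactant terms are summed. Sign convention: positive
ΔΔG‡_solv means the solvent destabilizes the transition state relative to
the reactants and the liquid-phase reaction is slower;
`log10(k_liq/k_gas) = −ΔΔG‡_solv/(R·T·ln 10)`. At 298 K one log10 unit is
R·T·ln 10 = 1.3636 kcal/mol, so magnitudes of 40 and 10 kcal/mol correspond
to about 29 and 7 orders of magnitude in the rate ratio — the scales at
which the curation cutoffs below operate. The gas constant is carried as
1.98720425864083e-3 kcal/(mol·K).

Temperature dependence uses the constant-enthalpy linear form

    ΔΔG‡(T) = ΔΔH‡₂₉₈ − T·(ΔΔH‡₂₉₈ − ΔΔG‡₂₉₈)/298,

treated as valid for 250–400 K (a warning, not an error, outside). Its
inverse, the central finite difference
`ΔΔH = ΔΔG(T) − T·(ΔΔG(T+1) − ΔΔG(T−1))/2` over 297/298/299 K, is exact for
any ΔΔG linear in T; the two functions round-trip to 1e-9 and the test suite
asserts this as an identity. Relative-rate errors convert to the
free-energy scale by `−R·T·(ln k_rel,expt − ln k_rel,calc)`.

## Input representation

Reactions arrive as atom-mapped reaction SMILES. Every explicit atom on
both sides must be mapped and the maps must form a bijection; the element
multisets (including implicit hydrogens) must balance. Spectator hydrogens
stay implicit; a hydrogen that changes bonding must be written explicitly
(`[H:n]`) so the transfer is visible in the graph. Parsing is strict by
default — bad rows are rejected, never repaired — with a permissive mode
that skips and reports offending lines.

The condensed graph of reaction (CGR) has one node per atom-map number with
features `[reactant atom features | product − reactant]`, and one edge per
atom pair bonded on either side with `[reactant bond features | product −
reactant]`, where a bond missing from one side contributes a null-bond
vector (zeros plus a null flag). Consequences used as test invariants: an
identity reaction has all-zero difference blocks, and reversing a reaction
negates every difference block.

Atom features are the standard D-MPNN set: element one-hot over
{H, C, N, O, S, other}, degree 0–5, formal charge −2…+2, hybridization,
aromaticity, total hydrogen count 0–4, and scaled atomic mass; every
categorical block has an "other" fallback so one-hot blocks always sum to 1.
Bond features are order one-hot {single, double, triple, aromatic},
conjugation, ring membership, and the null flag. Chirality and a
six-feature RDKit atom block (radical electrons, smallest ring size, lone
pairs, H-bond donor/acceptor flags, electronegativity) exist in the
vocabulary but default off — the targets derive from 2D structure.
Molecular-level extras (e.g. the four reactant/product solvation values) are
carried per record and concatenated with the embeddings at the regression
head; per-atom/per-bond extras are concatenated before encoding.

## Encoder and head

Both encoders are directed bond-level message-passing networks. Messages
live on directed arcs; arc v→w is initialized from `[atom_v | bond_vw]`
through a shared input projection, and each of `depth` update rounds
aggregates the messages incoming to v *excluding the reverse arc w→v* —
the defining property of the directed formulation, which stops messages
from echoing straight back. Final atom states combine each atom's own
features with its incident messages; the graph embedding is the mean over
atoms (sum available by config; mean is the default because the data mix
uni- and bimolecular reactions of different sizes). `depth = 0`
deliberately builds no messages at all, so the output depends only on atom
features. The reaction and solvent encoders never share parameters.

The head is a ReLU feed-forward network on `[reaction embedding | solvent
embedding | molecular extras]` with exactly two outputs. Targets are
standardized per target with training-split statistics only; the statistics
live in the model bundle and predictions are de-normalized on the way out.

Defaults (all config-overridable): hidden width 300, depth 3, head 2×300,
dropout 0.05. The whole network and its backpropagation are written in
NumPy; gradients are exact (finite-difference checked) and a dense
arc-by-arc reference implementation pins the batched forward pass to 1e-6 in
the tests. Checkpoints store every weight block as little-endian 32-bit
floats plus a JSON manifest (architecture, schema version, fingerprint,
target statistics) in one `.npz` archive; loading verifies fingerprint and
schema compatibility.

## Curation and splits

Cleaning mirrors the provenance of quantum-chemistry solvation tables:

1. keep only reaction–solvent pairs present in both the forward and reverse
   direction for the *same* solvent (palindromic reactions count as their
   own reverse);
2. drop pairs with |ΔΔG‡| > 40 or |ΔΔH‡| > 56 kcal/mol for the broad
   pre-training table — both cutoffs sit about 14 standard deviations
   (2.76/3.92 kcal/mol) from the mean — and the stricter 10/18 kcal/mol for
   the fine-tuning table. The inequality is strict: the boundary value is
   kept. Filtering is idempotent and reports counts per rule.

Subsampling offers a coverage sampler (every reaction and solvent at least
once when the budget allows, else plain uniform) and a weighted
per-reaction solvent sampler (~25 solvents per reaction, probability
proportional to a polarity weight, with a post-pass swap guaranteeing every
solvent appears). The default weight, `1 + 2·(heteroatoms/heavy atoms)`, is
a deliberately simple monotone polarity proxy and can be overridden by a
user weight table.

Splits group by a direction-agnostic reaction key — the lexicographically
sorted pair of canonical unmapped side SMILES — or by canonical solvent.
All records of a selected group (both directions, every solvent) go to
test; the remainder splits 80/20 into train/validation at the record level.
Group counts round half-up with at least one group selected. k folds are k
independent redraws with seeds `seed..seed+k−1`, not a partition; each
fold's invariants hold separately. All sampling and splitting is a pure
function of (input, parameters, seed).

## Training protocol

Loss is the mean squared error summed over the two normalized targets,
optimized by Adam under a Noam-style schedule (linear warmup over ~2 epochs
from 1e-4 to the peak, then exponential decay). Early stopping is pure
best-epoch selection on total validation loss: training always runs to
`max_epochs` (80 for pre-training, 10 for fine-tuning by convention) and
the returned bundle is the snapshot from the best validation epoch. The
exact peak learning rate and batch size were not fixed by any external
constraint; defaults are peak 1e-3 and batch 50, and the parameter-recovery
experiments use batch 16 with peak 2e-3, which converges measurably better
at that problem size.

Fine-tuning initializes every weight from a pre-trained bundle and keeps
its target normalization, so the initialized function is exactly the
pre-trained one; an empty fine-tuning set is an error, never a silent
pass-through. Ensembles train `folds × ensemble_size` members (5 × 5 = 25
in the reference protocol); member (f, i) derives its seed by stable
hashing of (base seed, f, i), so runs reproduce bit-for-bit. The epoch
sweep utility re-runs fine-tuning at each maximum-epoch value, with epoch 0
reporting the untouched pre-trained model, to locate the plateau where
fine-tuning gains level off.

## Synthetic data

The fixture generator emulates the *structure* of the real tables, not
their physics. Reactions come from templates of the three radical families
— bimolecular hydrogen abstraction (14 donors × 6 radical acceptors),
unimolecular 1,n-hydrogen migration, and radical addition to alkenes and
carbonyls (5 radicals × 5 acceptors) — over H/C/O fragments of at most 10
heavy atoms, each emitted in both directions (102 distinct reactions). The
solvent pool enumerates 60 molecules from alkanes to water, characterized
by a polarity proxy (heteroatoms/heavy atoms) and H-bond-donor count.

Targets come from a closed-form surrogate built only from information the
model can see:

    ΔΔG = polarity · Σ_c w_c·n_c + 0.8 · hbd · n_{O−H} + ε,
    ΔΔH = 1.4 · ΔΔG_noiseless + ε′,

where n_c are signed (formed − broken) bond-change counts per element pair,
split into σ and π channels so that a reverse reaction gets the exact
negation of the structural term — mirroring the approximate thermodynamic
antisymmetry of real forward/reverse data. The enthalpy scale 1.4 mirrors
the |ΔΔH|/|ΔΔG| magnitude ratio of real solvation tables; the default
weights put |ΔΔG| mostly within ±8 kcal/mol, comfortably inside the
fine-tuning cutoffs; noise defaults to σ = 0.3 kcal/mol. Per-record noise
seeds derive from a stable hash of (directed reaction key, solvent, global
seed), so tables are reproducible and reverse directions get fresh noise.

What passing on this surrogate shows: the pipeline is leakage-safe, the
encoder respects the CGR symmetries, and the trainer can recover a target
that is genuinely a function of the CGR and solvent graph, down to the
noise floor on unseen reactions. What it does not show: accuracy on real
solvation physics — the surrogate has no conformers, no specific
solute–solvent interactions beyond the H-bond count term, and its
functional form (a polarity-scaled linear form in bond changes) is far
simpler than COSMO-RS-derived targets.

## Experiment sizes

The desk-scale experiments are sized to run on one CPU in minutes: the
parameter-recovery runs train a depth-3/hidden-64 single model on ~1960
training pairs (55 reactions × 25 solvents, reaction split) for 50 epochs,
reaching unseen-reaction ΔΔG MAE ≈ 0.25 kcal/mol at σ = 0.3 and ≈ 0.03 in
the noiseless limit; the transfer experiment pre-trains 30 epochs on one
surrogate parameterization (50 × 20) and fine-tunes 10 epochs on a shifted
one, improving the shifted-holdout MAE by ~0.15 kcal/mol over the
pre-trained baseline. The split-safety audit uses a 10 000-record table
(100 reactions × 50 solvents × 2 directions) across 5 folds in both modes.

## Numerical and degenerate-input choices

- Target standardization guards a zero variance with 1e-8.
- Canonicalization ties in the reaction key break by plain string order.
- Reaction-key and solvent canonicalization are cached per object/string;
  featurization is cached per unique reaction and solvent within a fit.
- Group-count rounding is half-up with a minimum of one group; selecting
  every group (degenerate split) is a usage error.
- An ensemble of one reports spread 0 (sample standard deviation needs two).
- Temperatures ≤ 0 K are usage errors; 250–400 K extrapolation bounds only
  warn.
- Checkpoint weights are stored as 32-bit floats; reloaded predictions agree
  with the in-memory model to ~1e-4 kcal/mol, far below model error.

## Known limitations

- The noiseless parameter-recovery error on unseen reactions varies with
  the random reaction split (≈0.03–0.2 kcal/mol): the concatenate-then-FFN
  head has to approximate a product of solvent polarity and reaction
  structure, and extrapolating that product to unseen bond-change
  combinations is the binding constraint, not optimization.
- The surrogate's reverse-direction antisymmetry is exact, which real
  solvation data only approximately obey.
- No 3D information, conformer effects, solvent friction or diffusion
  limits; predictions are relative rate effects only, never absolute rate
  constants.
- Atom mapping is consumed, not produced; incorrect maps upstream yield
  well-formed but wrong CGRs, which no internal check can detect beyond
  balance and bijection validation.
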