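# Methods

## Problem and model

`eluent` models the choice of normal-phase (silica) column-chromatography
conditions for the purification step of an organic synthesis.  The input
is the reaction itself — reactants and products as a dot-separated
multi-molecule SMILES string — and the output is a *solvent system*: one
or two of ten canonical solvents (acetone, ethanol, hexane, toluene,
petroleum ether, methanol, chloroform, ethyl acetate, dichloromethane,
diethyl ether) and, for two-solvent systems, the volume fraction γ ∈ (0, 1)
of the first solvent.

Prediction is hierarchical, with two separately trained networks used in
sequence:

1. a **multilabel classifier** η₁: X → {0,1}¹⁰ with ten sigmoid outputs
   trained under binary cross-entropy; a decision rule turns the ten
   scores into 1–2 labels (threshold 0.5, clipped to the top two by
   score, arg-max fallback when nothing passes, ties broken by the
   canonical solvent order);
2. a **ratio regressor** η₂: X → γ with a single linear output trained
   under mean squared error, consulted only when the classifier predicts
   two solvents.  The complement 1 − γ is reported for the second
   solvent, so the pair always sums to one.

Binary systems are always stored in a fixed canonical order (descending
overall frequency: ethyl acetate, hexane, dichloromethane, methanol,
chloroform, petroleum ether, diethyl ether, toluene, acetone, ethanol),
and γ always refers to the first label.  This orientation convention is
what makes the single-number ratio well defined.

## Dataset machinery

**Text mining.** Purification paragraphs are matched against a solvent
lexicon (canonical names plus common synonyms such as DCM, EtOAc,
ethylacetate, pet ether).  Matching is case-insensitive, longest-match
first, and bounded by non-letter characters so that e.g. "ethanol" never
fires inside "methanol".  The first integer `a:b` pattern supplies the
raw ratio, read in the textual order of the two solvent mentions and
re-oriented when canonical ordering swaps the labels.  Records with no
known solvent, three or more solvents, degenerate ratios (0:1, 0:0), or
percentage/gradient programs are rejected with a recorded reason; a
rejected ratio removes the record entirely rather than admitting a
mislabeled instance.

**Normalization.** A raw ratio a:b becomes γ = a/(a+b); γ and its
complement sum to exactly 1.

**DS1/DS2.** DS1 pairs every accepted reaction with its label set
(classification); DS2 keeps the two-solvent subset with a valid γ
(regression).  The train/test split holds out round(0.10·n) instances,
stratified by label set (DS1) or ratio decile (DS2) under a
largest-remainder apportionment, so the held-out set preserves the class
distribution; the assignment is deterministic given the seed.

**Augmentation.** Molecule order within a reaction string is arbitrary,
so each *training* instance is augmented with min(cap, m!−1) distinct
non-identity permutations of its m molecules (default cap 5, the value
retained after exploring 2–7).  Sampling is uniform without replacement
from a per-instance seeded stream that does not depend on the cap, which
gives a prefix property: a larger cap yields a superset of a smaller
one.  Augmentation runs strictly after the split and only on the
training side, so no permuted twin of a test reaction is ever trained
on.  The test of this choice is leak-freedom, not accuracy.

**Baselines.** Classification: random baseline Σᵢ P(Yᵢ)² and majority
baseline max P(Yᵢ), both over the empirical distribution of label
*sets* (up to 52 combinations), computed on the full dataset.
Regression: the MSE of the constant mean and constant median predictors,
evaluated on the test subset — the same instances on which models are
scored.  A trained model is only meaningful if it beats these floors.

## Vectorization

* **Learned embedding (LE).**  Character-level tokenization of the
  reaction string against a vocabulary built from the training corpus
  (PAD and UNK reserved), padded/truncated to length 200.  Each symbol
  is embedded in 12 dimensions; the table is trained jointly with the
  network, producing a 200×12 input matrix.
* **ECFP.**  Each molecule is hashed to a binary 512-bit Morgan
  (extended-connectivity) fingerprint of radius 2 — the common default,
  exposed as configuration since only the width is fixed by the design.
  Up to 8 molecules stack into an 8×512 matrix (zero rows pad), with a
  row-major 4096-bit flattened view.  Fingerprints are invariant to atom
  renumbering, so equal molecular graphs give equal rows.
* **ECFP+E.**  The 8×512 matrix compressed to 512 reals by a trained
  fingerprint auto-encoder (below); an 8× compression of the flattened
  input.
* **Products-only variant.**  A reduced input using only the product
  molecules' fingerprint union (1×512), available as a config switch.

## Auto-encoders

Three reconstruction architectures, all trained with binary
cross-entropy and a latent width from the grid {32, 64, 128, 256, 512}
(default 512):

* *ffnn*: flatten → dense latent → dense 4096 + sigmoid;
* *cnn1d*: convolutions along the 512-bit axis with the 8 molecule rows
  as channels (the printed kernel widths 12, 10, 10 exceed 8, so the
  molecule axis cannot be the convolved one) — filters 256/128/64,
  pool 2 after each; dense latent; the decoder mirrors with four
  kernel-1 convolutions and nearest-neighbour ×2 upsampling;
* *lstm*: one LSTM layer over the 8 fingerprint rows whose final hidden
  state is the latent code; the decoder repeats it 8 times through a
  second LSTM with a time-distributed sigmoid dense layer.

Average pooling is used in the pooling stages (the pooling operator is
otherwise unspecified).  AE training defaults to the downstream settings
(Adam, batch 256, 40 epochs) with a seeded 10% held-out slice for the
reported reconstruction BCE.  After training the encoder is frozen —
its parameters are flagged untrainable and skipped by the optimizer —
and a SHA-256 digest of its weights makes any later mutation detectable.
Head training over latents provably leaves the digest unchanged.

## Networks and training

Heads for both tasks share the hyperparameters: ReLU hidden activations,
Adam (learning rate 10⁻³), batch 256, 40 epochs, and a seeded 90/10
train/validation split inside the training subset.  Architectures per
vectorization:

* FFNN: three fully connected layers, default widths 256→128→64 on the
  flattened 4096-bit ECFP input (widths from the explored grid
  {16 … 512}), exposed in config;
* 1D CNN: three 64-filter convolutions with kernels 12, 12, 5 and
  average pooling 3 after each, a 64-unit dense layer, then the output;
* LSTM: one 512-unit layer over the 8 fingerprint rows (ECFP) or the
  200×12 embedded sequence (LE);
* ECFP+E: always the FFNN head on the 512-real latent; the AE family is
  chosen by `encoder_flavour`.

The whole stack — layers, losses, Adam, and the training loop — is a
small NumPy implementation inside the package (`eluent.nn`) with
explicit reverse-mode gradients; every layer's backward pass is tested
against central-difference numerical gradients at tolerance 10⁻⁷.
Training is single-threaded deterministic for a fixed seed on one
platform; cross-platform bit-identity is not promised.  Non-finite loss
aborts training with a diagnostic rather than silently continuing.

## Synthetic data: what it emulates, and what it does not

The generator builds reactions from a pool of ~215 distinct molecules
(18 scaffold templates × 12 decorating groups, singly decorated,
canonicalized and de-duplicated).  A prioritized list of planted rules maps functional
groups to solvent systems:

| rule | trigger (SMARTS) | system | ratio law |
|---|---|---|---|
| acid | `[CX3](=O)[OX2H1]` | methanol | — |
| amine | `[NX3;H2]` | dichloromethane/methanol | 0.60 + 0.05·count |
| hydroxyl | `[OX2H]` | ethyl acetate/hexane | 0.30 + 0.10·count |
| halogen | `[F,Cl,Br]` | hexane/dichloromethane | 0.45 + 0.05·count |
| default | (any) | dichloromethane | — |

Each reaction samples 2–8 molecules (weighted toward 3–5) such that the
intended rule is the highest-priority one triggered; the ratio is the
law value (clipped to (0.05, 0.95)) plus Gaussian noise of σ = 0.02,
clipped to (0.001, 0.998).  Rule weights default to one dominant pair
system (hydroxyl → ethyl acetate/hexane at 50%), mimicking the skew of
real purification data.  Every record also renders a purification
paragraph from templates modeled on patent phrasing — including synonym
surface forms, swapped mention order, and "parts by volume" wording —
whose extraction round-trips to the generated system and raw ratio by
construction.

This emulates the *structure* of the real problem (functional groups
determine the eluent; ratio laws with noise; class imbalance; free-text
provenance) but not its hard parts: real reactions have by-products and
label noise (an estimated few percent of patent-mined labels are wrong),
real text is far messier than three templates, and the 10-label space
with 52 observed combinations is richer than the five planted systems.
Passing the desk-scale tests therefore demonstrates that the machinery
is correct and that the models can recover planted structure — not that
the headline accuracies on the patent corpus are reproduced, which
requires the full ~450k-instance corpus and far longer training.

## Desk-scale problem sizes

The test suite and reproduction script use sizes chosen to exercise
every pipeline stage on one CPU: 300–1000 reactions for extraction and
distribution checks, 5000 reactions (≈4100 binary) for the recovery
experiments, 40 epochs for recovery, 2–20 epochs for smoke tests.  The
recovery experiment trains the classifier on the un-augmented training
split and the regressor on the augmented one: label recovery is an
easier function (presence of a group anywhere) while the ratio law's
count structure benefits measurably from the permutation augmentation.

## Numerical choices and degenerate inputs

* Sigmoid/BCE are clipped at 10⁻⁷ to avoid log(0); LSTM/sigmoid
  arguments are clipped at ±500 against overflow.
* Regressor outputs are clipped into (ε, 1−ε), ε = 10⁻³, with a logged
  warning — γ is a fraction by definition.
* Dense/conv/LSTM weights use Glorot-uniform initialization (the common
  framework default); the LSTM forget-gate bias starts at 1.
* Zero-variance truth makes Pearson r (and, unless exact, R²) undefined:
  reported as NaN with a warning, never silently zero.
* Nearest-integer rounding fixes the 10% holdout size; n < 10 refuses to
  split.
* Ties in the label decision rule break by canonical solvent priority,
  making predictions deterministic.
* Confidence intervals over repeated runs use Student's t with n−1
  degrees of freedom at the stated confidence level (default 95%).

## Known limitations

* The NumPy training loop is CPU-bound; corpus-scale training is out of
  scope by design.
* Desk-scale recovery is asymmetric between the tasks.  At 5000
  reactions and 40 epochs the fingerprint classifier recovers the
  planted label rules almost perfectly (subset accuracy ≈ 0.95), but
  the ratio regressor reaches R² ≈ 0.83 — well above its baselines yet
  short of the noise ceiling (σ = 0.02 implies an irreducible MSE of
  only 4·10⁻⁴).  The residual error concentrates in 6–8-molecule
  reactions and the rarest rule: with a position-sensitive flattened
  input, a corpus of this size thinly covers (molecule, position)
  combinations for large reactions even after cap-5 permutation
  augmentation.  Closing the gap needs more data, not more epochs.
* Ratio extraction handles single isocratic `a:b` pairs only; gradient
  programs are rejected, not modeled.
* The multilabel decision rule (0.5 threshold, top-2 clip) is a
  reasonable convention, not a calibrated operating point.
* Both the per-label accuracy (over all instance×label binary decisions)
  and the stricter subset accuracy are reported side by side, since
  headline "accuracy" figures for multilabel classifiers are ambiguous
  between the two.
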