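# Methods

## The problem and the modeling strategy

Carcinogenicity data exist almost exclusively for single chemicals
(regulatory group labels from agency classifications; TD50 potencies from
rodent bioassay compilations), while exposure happens to mixtures. The
package therefore *constructs* mixture training data from single-chemical
libraries under explicit assumptions, then learns to predict mixture
carcinogenicity (binary), category (three-class), and potency (regression)
from mixture-level features.

### Assumption cases for binary labels

A virtual binary mixture of two labeled chemicals receives its label from
one of five rules: Case 1, carcinogen + carcinogen → carcinogen (1+1=1);
Case 2, noncarcinogen + noncarcinogen → noncarcinogen (0+0=0); Case 3,
noncarcinogen + noncarcinogen → carcinogen (0+0=1, modeling sensitization /
synergy); Cases 4 and 5, one carcinogen in either position → carcinogen.
The labeler is total on the documented patterns and rejects a label pattern
inconsistent with the requested case. The default pipeline builds Case 1
and Case 2 sets (the configurations with real-world support in the curated
libraries); Cases 3–5 are available to callers. Multiclass mixtures are
intraclass only — two chemicals of the same class yield a mixture of that
class; interclass pairing raises an error rather than silently guessing.

### Group-label harmonization

Source group labels map onto a three-class scheme: class 0 noncarcinogens
(e.g. MEG Group E, CPDB noncarcinogenic), class 1 possible/not-classifiable
carcinogens (MEG C/D, IARC 2B/3, JSOH 2B), class 2 known/probable
carcinogens (MEG A/B, both NTP categories, IARC 1/2A, JSOH 1/2A, CPDB
TD50-annotated). The binary map uses MEG A/B/C → 1, E → 0 and excludes
Group D entirely. Unknown (source, group) combinations raise a mapping
error listing the valid labels; nothing is coerced.

Duplicates are detected on canonical SMILES, not raw strings, because
sources spell the same structure differently. When duplicate records agree,
the first occurrence is kept and unset optional fields are filled from
later ones; when records *disagree* on a binary or class label, every
record of that structure is dropped and logged — voting would manufacture
certainty the sources do not contain.

## Concentration addition

The CA model predicts mixture potency from component potencies assuming
components act as dilutions of one another. Toxic units TU_i = C_i/TD50_i;
TU_A + TU_B = 1 is simple addition. At the equitoxic ratio
(TU_A : TU_B = 0.5 : 0.5) the component concentrations are C_i = 0.5·TD50_i
and the mixture TD50 is the arithmetic mean of the component TD50s.
Concentration fractions p_i = C_i/C_M follow from TD50 weights
(p_A = TD50_A/(TD50_A+TD50_B)) and invert back to component concentrations
via C_i = p_i·TD50_mix. The chain is closed: for any positive TD50 pair the
recovered toxic units sum to 1 within 1e-9 relative, and this identity is
both property-tested and recomputed by `scripts/acceptance.py`.

The regression target is −log10 of TD50_mix in its native mg/kg/day units
by default. A molar conversion hook (supply a mixture molecular weight;
dose is converted to mol/kg/day before the log) exists because potency
modeling conventions differ; the chosen convention must be identical at
train and predict time, so fitted models record their feature manifest.
Neither convention is asserted to be the one used for any published error
figure — reported regression errors in this domain are convention-dependent.

## Mixture featurization

Per-chemical 2D descriptors come from RDKit's descriptor set (~210
descriptors). Columns containing any missing or non-finite value across the
library are dropped wholesale; the retained *count* is engine- and
dataset-dependent and is deliberately not part of any contract — the
completeness rule is. Mixture descriptors combine component vectors
weighted by concentration fractions: `sum` (x1·d1 + x2·d2, the default and
the method used throughout), `difference` (|x1·d1 − x2·d2|), and `norm`
(sqrt((x1·d1)² + (x2·d2)²)). The norm's final exponent is taken as 2 (the
Euclidean combination consistent with the prior mixture-descriptor
literature); all three are invariant to swapping the two components.
Classification pairs use exposure-concentration weights when both
components carry a concentration and 0.5/0.5 otherwise; regression pairs
always use the CA-derived TD50 weights.

Mixture SMILES are the period-joined concatenation `S1.S2` (a valid
multi-component SMILES). Tokenization maps the 94 printable ASCII
characters (codes 33–126) to indices 1–94 (index = code − 32; '!'→1,
'C'→35, '~'→94), with 0 reserved for padding. Vectors are post-padded and
tail-truncated to a uniform length L (default 400 for mixture SMILES; two
drug-like SMILES plus separator rarely exceed it). Head-vs-tail truncation
and the value of L are configuration, recorded in the model manifest.

## The hybrid network

Architecture (defaults in parentheses): token indices → embedding (100) →
1-D convolution (64 filters, kernel 5) → ReLU → global max pooling;
descriptor vector → dense ReLU stack (512 → 128) with inverted dropout
(0.2); the pooled CNN output is concatenated with the descriptor branch's
last layer, passed through one merged dense ReLU layer (128, dropout), and
the head is one sigmoid unit (binary), K softmax units (multiclass), or
one linear unit (regression). Only the embedding size, the two-branch
structure, the merge point and the head activations are anchored by the
method description this package implements; filter counts, depths and
pooling kind are this package's own defaults and are recorded per fit.

Training is minibatch Adam (lr 1e-3, batch 64, 50 epochs by default) with
manual backpropagation in NumPy. Descriptor columns are standardized with
training-set statistics only (zero-variance columns get unit scale);
regression targets are internally centered/scaled and mapped back at
prediction. Losses are numerically stable (softplus-form BCE on logits,
log-sum-exp softmax CE). A non-finite epoch loss raises a divergence error
carrying the epoch index rather than training on. Determinism contract:
bitwise reproducibility for a fixed seed under single-threaded execution;
statistical reproducibility otherwise. Decision rules: 0.5 threshold
(binary), argmax (multiclass).

Either branch can be dropped: `smiles_length=0` is the descriptor-only
FFNN — also serving as the "NN" regression baseline — and descriptor-free
input gives a SMILES-only CNN. Ablation tests verify that descriptor-borne
signal is learned equally well without the CNN, and that token-motif signal
is learnable only with it.

Baselines use scikit-learn defaults with fixed seeds: RF / bagging /
AdaBoost for classification; RF, SVR, gradient boosting, kernel ridge,
AdaBoost-boosted trees, k-nearest neighbours and the descriptor-only FFNN
for regression. The consensus regressor is the elementwise mean of exactly
seven method predictions.

## Evaluation

Binary metrics derive from confusion counts; AUC uses the Mann–Whitney
rank statistic with mid-ranked ties (verified against trapezoidal ROC
integration). Multiclass metrics are micro-averaged: each sample
contributes K one-vs-rest decisions, counts are pooled, ratios computed on
the pool. For single-label data this yields exact identities —
micro-sensitivity = micro-precision = overall accuracy a,
micro-accuracy = 1 − 2(1−a)/K, micro-specificity = 1 − (1−a)/(K−1) —
which the tests verify against brute-force pooling and which reproduce the
standard printed triples (e.g. a = 96.03% at K = 3 pools to 97.35% and
98.015%). Micro-AUC pools the one-vs-rest score columns before ranking.
Regression reports MSE, MAE and R². Undefined metrics (zero denominators,
constant truth for R²) are reported as missing and excluded from
aggregates — coercing them to 0 would silently bias a 30-iteration mean.

`repeated_holdout` shuffles and splits 80/20 at the mixture level per
iteration (iteration seed = base seed + index), fits, scores, and averages
over 30 iterations by default; optional fivefold CV on the training
portion is reported separately. Degenerate iterations (single-class test
split) are flagged and excluded, not silently resampled. `disjoint_eval`
scores a fixed compound-disjoint test set, *verifying* chemical-level
disjointness first and raising a leakage error naming the offending
chemicals; repetition varies only the learner seed.

The compound split assigns ceil(n · test_fraction) chemicals to the test
side by default. Published partitions in this literature do not follow a
single rounding rule, so `split_then_pair` accepts an explicit test-side
count to reproduce any printed partition (e.g. 106 → 84/22, 555 → 443/112,
561 → 449/112); the printed sizes are treated as inputs.

## The synthetic library generator

Real curated libraries (agency classifications, TD50 compilations, drug
combination databases) cannot be redistributed here, so a seeded generator
emulates their statistical shape: unique valid structures drawn from a
deterministic pool of ~370 small molecules (branched alkanes, alcohols,
amines, halides, nitriles, acids, substituted benzenes), three-class labels
with consistent binary labels, TD50 sampled log-uniformly on
[1e-3, 1e3] mg/kg/day for every class-2 record (spanning typical rodent
carcinogenic potencies without extreme magnitudes), and exposure
concentrations log-uniform on [0.01, 100] mg/L. What it does *not* emulate:
any real structure–activity relationship (labels are assigned to structures
at random), the heavy-tailed size/heteroatom distribution of real
carcinogens, or inter-source label noise. Passing tests on synthetic data
therefore demonstrate pipeline correctness, seeded reproducibility and
learnability of planted signal — not real-world predictive accuracy, which
depends on the curated libraries the CSV ingestion format accepts.

## Problem sizes and numerical choices

Test and example runs use reduced configurations chosen as sensible desk
scale for the synthetic data: libraries of 14–200 chemicals, ~50–2000
mixtures, SMILES length 40–120, embedding 16, 8–16 filters, hidden sizes
(32, 16), 4–80 epochs, and 1–5 harness iterations (30 for the null
simulation, where each iteration re-permutes the labels so the draws are
independent). Tolerances: fraction/toxic-unit identities 1e-9 relative;
descriptor-formula equivalence 1e-12; softmax row sums 1e-6. Tie-breaks:
argmax takes the first maximal class; Tanimoto similarity of two empty
fingerprints is defined as 0; zero-variance descriptor columns standardize
to zero rather than dividing by zero.

## Known limitations

- The assumption cases are labeling conventions, not biology; Case 3's
  mechanistic justification in particular is outside this package's scope.
- CA with simple addition ignores synergy and antagonism by construction;
  no independent-action or dose-response-curve machinery is included.
- The descriptor engine is RDKit's 2D set; other engines produce different
  column sets, and only the completeness-filtering rule transfers.
- The hybrid network's unanchored hyperparameters are pragmatic defaults,
  not a reconstruction of any particular published fit; headline accuracy
  figures from curated-library studies are not reproducible from synthetic
  data and are not claimed.
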