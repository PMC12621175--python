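# Methods

This note documents the models, algorithms, numerical choices, and design
decisions behind `clmdesign`, and what the synthetic-data-based tests do and
do not demonstrate about behavior on real corpora.

## Corpus preparation

SMILES standardization clears isotopic labels, strips stereochemistry,
keeps the largest organic fragment, and emits RDKit canonical SMILES.
"Largest organic fragment" means: most heavy atoms, preferring fragments
that contain carbon, with ties broken by lexicographically smallest
canonical SMILES — a deterministic rule chosen because plain "salt
removal" underdetermines multi-fragment records. Charges are not
neutralized and protonation states are not enumerated. Corpora are
deduplicated on the canonical form (first occurrence wins, preserving input
order) and capped at 140 characters, measured on the canonical string after
standardization. In bulk loading, unparseable records are flagged and
skipped with a logged count; in single-molecule use they raise. Cross-set
deduplication (pretraining vs fine-tuning sets) is not applied by default —
each corpus is deduplicated independently, matching how the sets are used
at different training stages.

Similarity is Morgan/Tanimoto: radius-2 fingerprints hashed to 2048 bits.
A Tanimoto between two all-zero fingerprints is undefined and raises rather
than silently returning 0 or 1.

## Tokenization

Greedy longest-match character tokenization with two-character element
symbols (Cl, Br) and bracket atoms `[...]` kept atomic. Three specials are
reserved: PAD (always index 0), START (`^`), END (`$`). The vocabulary is
the sorted distinct token set of the fitted corpus plus specials, making
refits deterministic; it is serialized as JSON and referenced by a content
hash in every checkpoint so decoding always uses the training vocabulary.
Drug-like corpora of this kind produce vocabularies of a few dozen symbols;
the production configuration's 71-wide output corresponds to 68 corpus
tokens plus the three specials. Sequences are encoded as
`START tokens END PAD…`, right-padded to max_len + 2 for batching.

## Network and training

Layer plan: BatchNorm → LSTM(1024) → LSTM(512) → LSTM(256) → BatchNorm →
Dense(vocab), one-hot input of width vocab. Parameter count for the
71-token configuration is 8,444,003, which matches the closed forms
4u(d+u+1) per LSTM, 4f per BatchNorm (γ, β, and the two moving statistics —
so the count is total parameters, not trainable-only), and (u+1)v for the
dense layer. The test suite checks closed form against instantiation for
arbitrary toy shapes.

The network is implemented in NumPy:

- LSTM gates in input/forget/cell/output order; Glorot-uniform input
  weights, orthogonal recurrent weights, forget-gate bias 1.
- Dropout (default 0.4) is applied to each LSTM layer's inputs as inverted
  dropout with one mask per sequence shared across timesteps; disabled at
  inference.
- BatchNorm statistics are computed over valid (non-PAD) positions only and
  tracked with momentum 0.99 for inference; ε = 10⁻³.
- Loss is next-token cross-entropy with teacher forcing, masked on PAD.
  Because padding is always trailing and recurrence is causal, padded
  positions contribute exactly zero gradient; the gradient-check test
  verifies backpropagation against central differences through the whole
  stack.
- Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁷). Frozen layers are excluded from the
  update entirely, so their weights stay bit-identical.

Pretraining uses learning rate 10⁻³; fine-tuning 10⁻⁴ for 20 epochs
(configurable) with reduce-on-plateau: factor 0.5, patience 3, floor
5·10⁻⁵, monitored on training loss since no validation split is defined
at these corpus sizes. The first call establishes the baseline, so on a
flat loss curve the rate halves after patience stagnant epochs following
the last improvement. Stage 1 freezes the first recurrent layer, stage 2
the first and second ("the LSTM layer" of a stacked network is read as the
first recurrent layer, consistent with the stage-2 rule). Checkpoints are
captured every epoch — epoch selection needs all of them — as one `.npz`
weights file plus JSON metadata (epoch, loss, vocabulary hash).

SMILES augmentation produces up to `fold` (default 10) distinct spellings
per molecule via seeded random atom renumbering, always including the
canonical spelling; every variant canonicalizes back to the input. Variants
stay in the same epoch stream and shuffling is seeded. One practical
consequence, visible in the desk-scale experiments: if pretraining sees
only canonical spellings, fine-tuning on augmented spellings pushes the
model into unfamiliar syntax and degrades sample validity, so the pipeline
pretrains with a small augmentation fold as well (default 3).

## Decoding

**Beam search** keeps the top-k partial sequences by cumulative
log-probability, no length normalization. Ties at equal score break
lexicographically on token indices, making decoding fully deterministic.
PAD and START are never emitted. A hypothesis completes at END or at
max_len = 140 tokens (truncated hypotheses keep their accumulated score).
Correctness is checked against exhaustive enumeration on probability-table
models small enough to enumerate; with a beam at least as wide as the
number of complete sequences the two rankings must be identical.

**Temperature sampling** draws each position from softmax(z/T), T = 0.2 by
default. Dividing log-probabilities by T and renormalizing is identical to
dividing logits, since the log-partition constant cancels. END is excluded
at the first position (no empty molecules). Invalid strings are kept in
the raw multiset — sampling frequency semantics stay faithful — and are
filtered during prioritization. Sampling is seeded and reproducible; the
same seed yields the identical multiset.

**Epoch selection** runs a k = 50 beam per fine-tuning checkpoint,
deduplicates and standardizes the valid designs, and aggregates each
design's nearest-neighbor Tanimoto to the template set by the mean (the
comparison statistic is a design choice; the mean is the least surprising
aggregate). Epochs whose aggregate falls inside a configured acceptance
band are selected; the band has no canonical published value, so it is a
configuration parameter (default 0.3–0.8, i.e. clearly template-like but
not memorized). An epoch with zero valid beam designs scores 0 and is
logged. Samples from multiple selected epochs are pooled before ranking by
default.

## Prioritization

Frequency ranking canonicalizes valid samples, merges spelling variants,
and ranks by descending frequency with lexicographic tie-breaks; the
invalid count is reported, and designs present in any training corpus are
flagged non-novel. Similarity prioritization annotates nearest-neighbor
Tanimoto to the template set and retains the top 1000 (configurable).

Docking is an adapter around the external smina engine — the scoring
function is not re-implemented. Grid: autobox around the cocrystallized
ligand plus 8 Å, exhaustiveness 16. Ligands are prepared as a single
ETKDG-embedded, MMFF-optimized conformer with hydrogens. The two subtype
affinities (negative, kcal/mol-scale) aggregate as the negated geometric
mean of magnitudes, −√(|a|·|b|); mixed-sign pairs have no defined
aggregate and raise. Redocking mode re-docks each receptor's own crystal
ligand (5 repeats) and reports mean ± sd of score and of symmetry-aware
heavy-atom RMSD to the crystal pose. When the engine or receptor files are
absent, docking columns are NaN, a diagnostic is logged, and every other
ranking is unaffected; per-molecule engine failures exclude only that
molecule from the docking rank.

## Chemical space

Fingerprints are reduced to 50 dimensions by truncated SVD and projected
to 2D by t-SNE (perplexity 30, seeded). The Jaccard metric is applied to
the sign-binarized SVD coordinates by default — Jaccard over a continuous
SVD output is otherwise ill-defined — and a mode applying Jaccard to the
raw 2048-bit fingerprints is provided as the alternative reading. The
distance matrix is precomputed on boolean vectors.

The virtual screen ranks library + spiked designs by Tanimoto to each
query, keeps the top 1000 per query (ties broken by library insertion
order), and forms a consensus by ascending mean rank. Members outside a
query's top list are imputed rank retained_n + 1, keeping the mean defined
for every member without unbounded penalties.

## Synthetic study

Families are combinatorial: a drug-like core with numbered attachment
points crossed against substituent pools, assembled with RDKit molzip,
canonicalized, and deduplicated. The default study draws the pretraining
corpus from ten diverse chemotypes (anilides, indoles, benzimidazoles,
quinolines, sulfonamides, ureas, …) and the fine-tuning corpora from three
target-focused chemotypes echoing nuclear-receptor ligand series: aryl
amides, biaryl methylsulfones, arylpiperazines. The template set is a
stratified subset of set I spanning at least two families and is excluded
from the pretraining corpus. All randomness derives from the single study
seed; regeneration is byte-identical.

What the generator emulates: corpus-size hierarchy, scaffold-family
clustering (within-family nearest-neighbor similarity strictly exceeds
between-family similarity — asserted on every generated study), shared
drug-like token statistics, and template/set-I scaffold sharing. What it
does not: the breadth of a multi-hundred-thousand-molecule pretraining
corpus, bioactivity structure, stereochemistry and charge diversity, and
string lengths approaching the 140-character cap (synthetic molecules are
30–80 characters). Passing tests therefore demonstrate the pipeline's
mechanics and its relative behaviors (e.g. fine-tuning shifts samples
toward the templates); they do not calibrate absolute validity rates or
similarity levels for production corpora.

## Problem sizes in the test suite

The suite trains a (96, 64, 48)-unit model on a 200-molecule synthetic
corpus (16 epochs, 3-fold augmentation), fine-tunes it in two stages on 60
and 8 molecules, and runs the full pipeline once at comparable scale —
the package's chosen desk-scale configuration, keeping the whole suite in
the minutes range on a single CPU while still exercising real convergence
(final pretraining loss ≈ 0.5, sample validity ≈ 85% at T = 0.2). The
pipeline's default `RunConfig` is a larger desk-scale setting
((128, 96, 64) units, 1000 pretraining molecules); production-scale corpora
are a matter of configuration, not code.

## Known limitations

- The NumPy implementation is single-threaded apart from BLAS matmuls;
  production-scale pretraining (10⁵–10⁶ molecules, 1024/512/256 units) is
  out of desk-scale reach, though the architecture instantiates and counts
  correctly at that size.
- Beam search is exact top-k per step but, like all beam decoding, is not
  guaranteed globally optimal for narrow beams; the enumeration equality
  holds for beams at least as wide as the sequence space.
- The docking adapter requires externally prepared receptor structures;
  it does not fetch or protonate receptors itself.
- The final selection of synthesis candidates from frequency and docking
  ranks is intentionally not formalized: both ranks are reported and the
  trade-off is left to the user.
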