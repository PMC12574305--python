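# Methods

## The retrieval task

Given originals X = (x_1, …, x_n) and their augmentations
X′ = (x_1′, …, x_n′), the encoder under test maps both sets to
embedding matrices (row i ↔ molecule i). For each query e(x_i) the
candidate pool is the *augmented set only*; the rank of e(x_i′) is the
competition rank

rank_i = 1 + #{ j : d(i, j) < d(i, i) } + #{ j < i : d(i, j) = d(i, i) },

i.e. exact distance ties are broken by ascending candidate index — a
deterministic total rule. (Ties have probability zero for real-valued
model embeddings but occur systematically for the built-in toy
encoders, e.g. unchanged strings under a no-op augmentation.) All
metrics derive from the rank vector: Acc@k = P(rank ≤ k),
MRR = E[1/rank], Recall@K ≡ Acc@K because each query has exactly one
relevant item. An option to pool originals together with augmentations
exists but is off by default.

Distances: Euclidean L2 (default), cosine (1 − cos similarity), and
the *unnormalized* negated inner product; similarities are negated so
one ranking code path serves all kinds. On unit-normalized rows all
three induce the same ordering (‖a−b‖² = 2 − 2·a·b), which the tests
assert. Two exact code paths — a dense distance matrix and a
brute-force flat nearest-neighbour index — must agree rank-for-rank
and are cross-checked on random instances. An approximate backend
(NN-descent graph index) is available for large pools; it is labelled
approximate, never used as ground truth, and a true partner missing
from the returned neighbour list is assigned rank k+1 (a lower bound).
All distance computation is float64.

## Augmentations and the identity constraint

Each transformation rewrites the string, never the molecule, and every
output is verified with the package-wide identity oracle: canonical
SMILES equality of the parsed molecules (chosen over InChI to keep a
single toolkit dependency; the oracle and toolkit version are recorded
in report metadata, since canonical output is version-sensitive).

- **canonical** — the toolkit's default aromatic canonical form;
  idempotent.
- **explicit_hydrogen** — all atoms written in bracket form with
  explicit H counts (`C` → `[CH4]`), not appended `[H]` atoms: the
  heavy-atom order is preserved while the syntax inflates.
- **kekulized** — the toolkit's canonical Kekulé form. Note the
  kekulé writer re-canonicalizes, so against a randomized-order
  original this rewrite carries the canonicalization reordering *plus*
  the notation change; its surface perturbation is therefore
  comparable to canonicalization, not to the tiny cycle relabeling.
- **cycle_renumbered** — a string-level pass with a
  ring-closure-aware scanner: bracket-atom contents `[...]` are opaque
  (digits there are isotopes/charges/H-counts), `%nn` labels are
  supported, and a label is "open" at first occurrence, "closed" at
  second, then reusable — the remapper tracks pairing, not digits.
  Each pair receives a fresh label by a seeded injective assignment
  into 1..99 that exhausts the single-digit namespace 1..9 first (the
  conventional rendering; labels ≥ 10 are written `%nn`), so
  concurrently open labels can never collide and the edit cost stays
  bounded by the ring-label character count. Rings are relabelled on
  aliphatic and aromatic systems alike. Molecules without ring
  closures pass through unchanged.
- **random_order** — the molecule is re-written from a seeded random
  atom permutation; a pure function of (string, seed).

Dataset-level policy: output is row-aligned with input and n is never
silently reduced. Inapplicable rewrites (no rings, no aromatics) are
retained with `changed=false` so retrieval pool sizes stay fixed;
reports carry changed-only metric blocks alongside the all-pairs ones.
Failures (e.g. an unkekulizable aromatic system) mark the pair
`valid=false` and appear in a skip report instead of crashing.
Per-record seeds are stable hashes of (master seed, record id), making
results independent of dataset ordering.

## Built-in encoders

All built-ins are deterministic given their configuration (hashing is
process-stable), return L2-normalized rows, and expose the same
`encode(strings) → LayerEmbeddings` contract as external adapters.
`mean_pool` implements the pooling rule for token-level models: the
arithmetic mean over non-padding positions, *including* begin/end
special tokens by default (the simplest inclusive rule; configurable
via the mask).

- **InvariantToyEncoder** (positive control) hashes character n-grams
  (n = 1..3) of the *canonical* form, so all synonyms of a molecule
  collapse to one vector; retrieval is perfect by construction.
- **SurfaceToyEncoder** (non-robust baseline) hashes n-grams of a
  notation-folded copy of the raw string: letter case is folded, bond
  marks `= # :` dropped, and aromatic-hydrogen brackets (`[nH]` → `n`)
  unwrapped. The folding removes exactly the aromatic-vs-Kekulé
  notational axis — a purely syntactic choice two writings of the same
  ring — while keeping full sensitivity to atom order, branching, ring
  labels and explicit-hydrogen bracketing. This makes the baseline's
  difficulty profile interpretable: perturbation of the *layout* of
  the string, not its notation dialect, drives the score.
- **NoisySyntheticEncoder** (parameter-recovery fixture) returns
  ρ·invariant(molecule) + (1−ρ)·noise, with unit-Gaussian noise drawn
  deterministically from (seed, salt, string). ρ=1 reproduces the
  invariant encoder; ρ=0 is pure noise. The `salt` distinguishes
  encoding passes: control experiments encode originals and
  augmentations with different salts, emulating a model whose
  idiosyncratic component is not shared between runs, so at ρ=0 every
  query's rank is exactly uniform on 1..n (even for pairs whose strings
  coincide).

## Control experiments and expected values

The standard study set is the synthetic fixture n = 100, seed = 1
(below). Under uniform ranks the chance baselines are
Acc@1 = 1/n = 0.01 and MRR = H_n/n ≈ 0.0519 for n = 100; the chance
control averages 50 encoder seeds (5 000 Bernoulli trials) and is
checked against the exact binomial 99% interval for Acc@1 and ±3
analytic standard errors for MRR (uniformity of the rank distribution
was additionally verified by χ² on independent seeds). The robustness
sweep averages 10 seeds per ρ ∈ {0, .25, .5, .75, 1} and must be
non-decreasing. The surface baseline must order the augmentations
cycle > kekulized ≥ canonical > explicit-hydrogen in Acc@1, with the
Levenshtein-ratio profile ordered hydrogen > canonical ≈ kekulized >
cycles; "≈" is asserted as a ratio below 1.5 between the pair while
hydrogen exceeds both at least twofold and cycles sits at least
twofold below. These sizes keep the full suite under a minute while
leaving the binomial and SE bands far wider than the effects tested.

## Synthetic molecule sets

`generate_smiles_set` draws from a small structural grammar — benzene
and heteroaromatic scaffolds (~40%), aliphatic mono-/fused/bridged
rings (~35%), random acyclic C/N/O skeletons (~25%), each optionally
decorated with 0–3 substituents at hydrogen-bearing positions — then
enforces pairwise distinctness by canonical-form dedup and checks
composition targets (defaults: ≥30% aromatic, ≥50% ring-bearing,
≥40% heteroatom-bearing). Originals are emitted in randomized atom
order, so canonicalization is a non-trivial rewrite for essentially
every record. Generation is a pure function of the spec.

`isomer_like_set` emulates pools where molecular composition alone
cannot separate molecules: it builds random spanning trees over the
heavy atoms of a target formula, spends each degree of unsaturation on
a random ring closure or bond-order increment, keeps exact-formula
matches, and dedups canonically; requesting more isomers than
reachable raises with the achievable count.

What these sets do *not* emulate: realistic drug-likeness, natural
ring-system frequencies, stereochemistry, charged species, or the
length distribution of curated corpora (grammar molecules average ~17
characters vs. ~79 in real collections — Levenshtein *ratios* for the
label-local cycle rewrite are therefore somewhat larger here, though
the ordering across augmentations is preserved). Passing controls on
these sets validates the measurement machinery, not any claim about a
particular real corpus.

## Copeland ranking

Models are compared pairwise: per contest, the model better on
strictly more tasks wins (per-task direction flags handle error
metrics; tied tasks count for neither). The classical Copeland score
is wins − losses (a wins-only variant is available behind a flag; the
variant used is recorded in the output). Ranking is by descending
score; ties — absent for real benchmark tables but possible (e.g.
preference cycles) — break by mean per-task rank then lexicographic
name, with tie groups reported explicitly.

## Statistics

Levenshtein distance is the unit-cost insert/delete/substitute edit
distance, computed by a numpy row-recurrence DP (the insertion chain
folded in via a running minimum); it accepts token sequences as well
as strings, so the same routine serves the character-level analysis
and the optional token-level variant behind a caller-supplied
tokenizer. The per-pair Levenshtein ratio divides by the original
string length. Report standard deviations are population (÷n) by
default with a sample (÷(n−1)) switch. Spearman correlation uses
average ranks for ties; the two-sided p-value is computed by full
permutation enumeration for n ≤ 10 (vectorized in chunks) and by the
large-sample approximation otherwise, with the method recorded —
relevant because the intended use correlates per-augmentation metric
deltas, where n is the number of augmentation types.

## Known limitations

- Canonical-form identity does not unify tautomers; distinctness and
  identity are defined at the canonical-SMILES level.
- The approximate backend's ranks beyond its query depth are lower
  bounds; only exact kinds carry exactness guarantees.
- The kekulé writer's traversal may differ from the aromatic writer's,
  so the kekulized and canonical rewrites are comparable but not
  identical surface perturbations; their baseline accuracies may swap
  within sampling noise on sets other than the standard fixture.
- Encoder-side evaluation of real transformer checkpoints is out of
  scope for the test suite; external models enter via the encoder
  contract or precomputed embedding matrices.
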