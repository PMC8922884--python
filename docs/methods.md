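# Methods

## Problem and model

One-step retrosynthesis proposers (template-based or template-free) return,
for a target product `P`, a ranked list of candidate reactant-sets
`{R_k}_{k=1..K}`. Their top-1 accuracy against the published reaction is
far below their top-50 accuracy, which means the right answer is usually
*in* the list but not *first*. `retrorank` trains an energy-based model
(EBM) to re-rank that list.

The EBM is a neural network `E_θ(P, R)` returning one scalar per
(product, reactant-set) pair — an inverse feasibility score, lower is
better. Candidates are sorted ascending by energy. The intractable
partition function of the EBM's probability model is approximated by the
candidate pool itself: for each product, the non-published candidates act
as hard negatives and training minimizes the listwise contrastive loss

    L = -log( exp(-E(P, R_true)) / Σ_k exp(-E(P, R_k)) )
      = logsumexp_k( E(P, R_true) - E(P, R_k) ),

i.e. softmax cross-entropy over negated energies with the published
reactant-set as the positive class. The second (energy-gap) form is the
one implemented: it is algebraically identical, max-shifted for overflow
safety, and invariant under a common shift of all energies to rounding
level. The gradient is the closed form `softmax(-E) - onehot(pos)` and is
seeded directly into the reverse-mode graph.

At train time, when the proposer's top-K misses the truth, the truth is
appended to the list (size K+1) so every item has exactly one positive —
appending rather than displacing keeps all K hard negatives. At
evaluation time nothing is injected: a product whose pool lacks the truth
is unrankable, stays in every denominator, and bounds re-ranked accuracy
by the proposer's top-K recall.

## Architectures

**FF-EBM.** Each molecule is a Morgan count fingerprint (default length
16384, radius 3, chirality on). The reactant fingerprint `R_in` is the
elementwise sum over reactants; the signed difference `D_in = P_in − R_in`
encodes fragments lost and gained. Three separate input networks embed
`P_in`, `R_in`, `D_in` to a common width d; the output network reads

    [P ‖ R ‖ D ‖ P*R ‖ R*D ‖ P*D ‖ cos(P, R)]   (width 6d+1),

where `*` is elementwise and the cosine is guarded to exactly 0 when
either embedding is the zero vector (the dot product is exactly 0 and the
denominator is kept positive by a 1e-24 additive term inside the square
root), so degenerate embeddings cannot produce NaN.

**Graph-EBM.** Molecules are attributed graphs: per-atom one-hots for
element (configurable vocabulary, out-of-vocabulary → "other"), degree,
formal charge, aromaticity, H-count and chirality tag; per-bond one-hots
for bond order plus conjugation and ring flags. Two message-passing
encoders with fully separate parameters handle the product and the
reactants. One round of message passing sends
`relu(W_msg [h_v ‖ x_uv])` along each directed bond, aggregates by
scatter-sum, and updates `h_u ← relu(W_self h_u + W_agg m_u)`; T rounds
(default 4). With T = 0 an atom's representation depends on its own
features alone, and messages travel only along bonds, so batch
composition can never leak between molecules. Per-molecule embeddings are
attention-pooled: a feedforward network scores each atom, a per-graph
softmax normalizes the scores (nonnegative, summing to 1), and atoms are
summed with those weights. Reactant embeddings are summed into one vector
and projected to `R_G`; the product embedding is projected to `P_G`; the
output network reads `[P_G ‖ R_G ‖ P_G−R_G ‖ P_G*R_G]`.

Both models are *exactly* (bitwise) invariant to reactant-list
permutations because reactant lists are canonically sorted (by canonical
SMILES) before any floating-point summation; the candidate-matching key —
dot-join of canonical, atom-map-stripped SMILES, lexicographically
sorted — fixes that order globally.

## Numerical core

The models run on a small reverse-mode automatic-differentiation engine
over NumPy arrays (`retrorank.autodiff`): broadcast arithmetic, matmul,
ReLU, concatenation, axis sums, row gather and segment sum. Its gradients
are verified against central finite differences in the test suite.
Training uses Adam (default lr 1e-3, β = 0.9/0.999). Energies are finite
by construction for finite parameters; a non-finite activation raises
immediately with layer context, and a NaN loss aborts with epoch/step
context. Model selection keeps the epoch with the best validation top-1.
All randomness flows through `numpy.random.default_rng` seeded from the
run seed, so identical (seed, config, data) reproduce identical histories
and checkpoints reload bit-identical parameters.

## Synthetic planted task

Real benchmarks require the original reaction corpus plus four retrained
proposer models, so the package ships a generator that plants a
re-ranking task with known structure:

* **Fragments** — an enumerated core × substituent grammar (alkyl/cyclic/
  aryl/heteroaryl cores; halide, hydroxyl, amine, ester, nitrile, amide,
  thiol substituents) canonicalized and deduplicated; a seeded permutation
  picks the library (default 150 fragments).
* **Reactions** — two fragments joined at random open-valence carbons;
  the true reactants are the fragments with a bromide on the bond-forming
  atom of one, so the difference fingerprint has the lost-halide /
  formed-bond structure of real couplings.
* **Proposals** — per product, K = 10 candidates. The truth sits at
  rank 1 with probability p1 = 0.30, is absent with probability 0.05
  (recall ceiling 0.95), and otherwise lands on ranks 2..K with
  geometrically decaying mass (factor 0.6) — the qualitative shape of
  real proposer rank profiles. Decoys mix three kinds (weights
  0.4/0.4/0.2): leaving-group swaps of the true reactants (hardest),
  one-fragment replacements, and random halogenated pairs.
* The true leaving group is fixed (Br) while swap decoys draw from
  {F, Cl, I}. This is deliberate: without a consistent signature on the
  positives, leaving-group decoys would be information-theoretically
  indistinguishable from the truth and no re-ranker could separate them.
  A planted-separability oracle (shared folded fingerprint positions with
  the product, ties counting for the truth) certifies learnability.

One global seed derives independent per-product streams, so datasets are
reproducible and extensible. The generator emulates rank profiles and
near-miss negatives; it does **not** emulate chemical balance, reagents,
stereo-selectivity, proposer score calibration, or the train/test
distribution shift of real template-free proposers — passing on it shows
the re-ranking machinery works, not that any particular chemistry is
learned.

## Problem sizes and defaults

Library defaults are full scale (fingerprint 16384, d = 300, K_train = 50,
K_eval = 200, T = 4). The shipped study runs at desk scale, chosen as the
smallest sizes at which the planted effects are unambiguous: FF-EBM on
2000 training products (fingerprint 2048, d = 64, K = 10, 5 epochs,
batch 16), Graph-EBM on 500 products (hidden 64, T = 2, 35 epochs, lr
5e-4, batch 8 — the graph model must learn the product↔reactant
correspondence rather than read it off a difference vector, so it needs
more passes over less data), evaluation on 400 held-out products, and a
two-proposer pooling study (600/300 products) where each proposer puts
the truth at rank 1 on half the products and misses it on the other half.
Optimizer settings were tuned on validation top-1 only, mirroring
standard practice.

## Conventions and edge cases

* Ranks are 1-based everywhere. Proposal pooling truncates each
  proposer's list to per-model K, merges duplicates (concatenating
  provenance), and orders by best original rank with proposer-name
  tie-break.
* Re-ranking ties on exact energy equality fall back to the proposer's
  original order (deterministic; favors the proposer's prior).
* Top-N AUC is the mean of acc(N) over N = 1..N_max (normalized
  step-function area); the convention is fixed here and documented rather
  than inherited.
* Invalid candidate SMILES in proposal files are dropped with a logged
  count, not errors — template-free proposers emit them routinely.
  Malformed reaction rows are skipped and counted. Reagents (the middle
  field of the reaction SMILES) are discarded.
* Duplicate-reaction cleaning of a real corpus is corpus-specific; the
  reader takes the dataset as given rather than guessing a dedup rule.
* Morgan count totals are *not* (radius+1) × heavy atoms on small
  molecules: the toolkit deduplicates environments that stop growing
  (benzene at radius 3 totals 19, not 24). Folding conserves totals
  exactly; tests pin both facts.

## Known limitations

* The loss treats each product as one listwise batch and averages over
  products within an optimizer minibatch; per-product candidate counts
  vary freely (no padding is needed in this implementation).
* Proposer scores are carried through the I/O layer but not used as model
  input.
* CPU-only by design; the graph model at full scale (T = 4, d = 300) is
  not tuned for speed.
* The leaving-group signature makes the planted task learnable by
  construction; real tasks have no such guarantee, and real re-ranking
  gains will be smaller than the planted recovery measured here.
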