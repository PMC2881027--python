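# Methods

## Classification protocol

The core statistical problem is two-class discrimination (organellar set A vs
cell-envelope set P) from noisy compositional features with a roughly 1:2
class imbalance and very few samples. The protocol:

1. **Features.** Word frequencies $f_w = c_w / L$ for words of length 1
   (20 features) or 2 (400 features), where $L$ is the length of the chosen
   region (full-length, signal peptide, or mature chain). The denominator is
   the region length in both orders, so order-2 vectors sum to $(L-1)/L$
   rather than 1; this per-sequence monotone rescaling is fixed globally
   (counts divided by $L-1$ would be the common alternative). Two exclusion
   variants address the worry that the heme c attachment motif CxxCH could
   dominate cytochrome-rich training sets: `drop_CH` removes every feature
   containing C or H from the feature *space* (18 / 324 features, counts of
   the remaining words unchanged), `mask_CxxCH` zeroes residues covered by
   CxxCH matches before counting. The default is no exclusion (400 features).
2. **Randomization rounds.** Round $i$ (seeded `base_seed + i`, so every
   round is independently reproducible) splits P uniformly at random into
   halves P1/P2 differing by at most one member, trains a three-class random
   forest (scikit-learn backend, `n_trees` trees, bootstrap with out-of-bag
   scoring, other hyperparameters at backend defaults since only the tree
   count is part of the protocol), and reads per-sample OOB vote fractions
   from the forest. Samples that were in every bootstrap (possible only for
   very small forests) receive zero votes and fall to the conservative side.
3. **Pooling and metrics.** Pooled P vote $= v_{P1} + v_{P2}$; predicted
   class is A iff $v_A > v_P$ (ties → P, conservative against organellar
   calls). Recorded per round: the 2×2 pooled confusion, pooled accuracy
   $(\mathrm{TP}_A + \mathrm{TN}) / (n_A + n_P)$, set-A recall, and the
   three-class OOB error (argmax over the three vote columns). Evaluation
   uses OOB votes only — no held-out split; with ~90 samples OOB is the
   least wasteful unbiased estimate.
4. **Selection.** Best round = max accuracy, ties by set-A recall, then the
   earliest round (stable). The winning round's forest is refit from its
   seed and used for downstream prediction; its impurity-based feature
   importances are reported.

The three-class OOB error is expected to hover near 1/3 even for perfectly
separable classes, because P1 and P2 are exchangeable draws from one
distribution; only the pooled two-class metrics measure the biological
contrast. Because pooling sums votes rather than merging argmax labels, a
weakly recognised A protein (plurality A but $v_A < 0.5$) can be pooled-wrong
while three-class-correct; under the exchangeable-halves design the
three-class error still dominates the pooled error by a wide margin in
practice, and the test suite checks this at protocol conditions rather than
asserting it as a theorem.

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes, not
any real genome. Defaults are the study conditions: $n_A = 30$, $n_P = 59$
(the training-set sizes of the design), mature lengths uniform in 100–300
residues, divergence δ = 1.

**Mature chains.** First-order Markov chains over the 20 residues: class
matrix $T_c = (1-w)\,T_0 + w\,B_c$ with $w(\delta) = \delta/(\delta + 1/2)$,
where $T_0$ is an i.i.d. background (Swiss-Prot-like frequencies) and $B_c$ a
class-biased matrix (A tilted hydrophobic/aliphatic, P tilted polar/charged)
with a same-category transition boost of 0.6 so that dipeptide features carry
signal beyond monomer frequencies. Consequences, by construction: δ = 0 is an
exact null (identical distributions); class contrast grows monotonically in
δ; mean GRAVY(A) > mean GRAVY(P) for δ > 0. The saturation constant 1/2 was
fixed so that δ ≥ 3 puts the classes at near-complete separation (downstream
best-run accuracy 1.0), the generator's stated extreme-separation regime;
δ = 1 is a moderate, realistic contrast. Soluble mature chains are
rejection-sampled until they contain no membrane-like hydrophobic window — a
contract of being soluble, not a statistical nicety.

**Signal peptides** are drawn from one model shared by both classes (so the
discriminative signal lives in the mature chain): n-region Met + K/R (2–6
residues), h-region from {L,A,V,I,F} (7–17), c-region from small/polar
residues (3–6) with Ala forced at −3 and −1 — the SPase I A-x-A consensus.
Membrane proteins alternate hydrophilic linkers (10–40 residues) with 1–6
hydrophobic helices of 18–25 residues; every other membrane protein also
carries a signal peptide so both membrane sets are populated. Cytoplasmic
proteins are background chains rejection-sampled to be helix-free.

**What the generator does not emulate:** real cytochrome sequences or heme
motifs, domain structure, length/composition covariation, homology between
proteins (the redundancy filter therefore removes nothing at default
settings), or predictor-specific error profiles (vote noise is i.i.d. flips
plus uniform cleavage jitter). Passing tests show the pipeline's logic is
correct and calibrated under these conditions; they do not certify accuracy
on real proteomes, where the compositional contrast and the external
predictors' error structure are unknown.

## Signal-peptide heuristics

The n/h/c delineation replaces an expert's manual call with an explicit
rule: the h-region is the window of length ≥ 6 inside residues 1..k
maximising mean Kyte–Doolittle hydropathy, subject to mean ≥ 1.0; ties prefer
the longer, then the leftmost window (window means are compared as exact
rationals over the 0.1-grid scale values, so ties are genuine, not
floating-point accidents). n is everything before the window, c everything
after, up to k. A peptide with no qualifying window raises a "no h-region"
error rather than guessing.

Segmental alignments use four anchors. Since three regions cannot tile four
anchors, the cleavage-site segment is defined as the final three residues of
the signal peptide (the −3..−1 motif window, right-justified at k) and the
other three regions are truncated at its start; the four ungapped,
sentinel-padded alignments then join row-wise to reproduce each signal
peptide exactly. Position frequency matrices use gap-excluded denominators.

Surrogate scanners (used only where external calls are absent): the TMH scan
reports greedy left-to-right non-overlapping windows of 18–25 residues with
mean hydropathy ≥ 1.6 (the 25-cap matches the physical helix length and
prevents two helices separated by a short loop from merging); the Tat scan
requires an RR pair starting in positions 2–35, a polar residue before it,
and a ≥ 10-residue window of mean hydropathy ≥ 1.0 beginning within 6
residues downstream. Majority voting over external predictors is strict
(> n/2; even-count ties negative); the consensus cleavage site is the floored
median over positive callers, robust to single outliers.

## Partition and prediction

SP+/TMH− → set 1, SP+/TMH+ → set 2, SP−/TMH+ → set 3, SP−/TMH− → set 4.
For SP-positive proteins the helix scan runs on the mature region only
(mirroring a constrained prediction with the N-terminus fixed as signal
peptide) — otherwise the hydrophobic h-region itself would masquerade as a
helix. Tat status is an annotation, not a partition axis. Type-IV substrate
exclusion applies at the organellar-prediction step, not at partition.

## Digestion and cleavage validation

Trypsin rule: cut after K/R except before P (the community default). Peptide
masses are monoisotopic (pyteomics), water included. The detectability window
for the "first detectable peptide" criterion defaults to 600–4000 Da and is
configurable, as is the maximum plausible cleavage depth (50 residues).
Validation is deliberately strict: all three criteria must hold.

## Numerical and design choices

- Redundancy filtering: global alignment with match 1 / mismatch 0 / gap −1
  (Needleman–Wunsch via Biopython), identity = matches ÷ alignment columns;
  the shorter member of an offending pair is removed (equal lengths: the
  later one), scanning pairs in input order until no pair exceeds the
  threshold — deterministic for a given input order.
- All coordinates in files and APIs are 1-based inclusive; the cleavage
  convention is SP = 1..k, mature = k+1..end, everywhere.
- Pipeline seeding: one base seed; per-stage seeds derived as
  `(base·1000003 + stage·7919) mod (2^31−1)`.
- Test and acceptance problem sizes (50 randomizations × 200 trees for the
  null calibration; 10 × 100 over five seeds per divergence level for the
  recovery curve; proteomes of ~20–180 proteins) were chosen as the smallest
  sizes at which the Monte-Carlo error of each check is comfortably below
  its assertion margin.

## Known limitations

- The forest backend's per-sample OOB votes are a hard dependency; swapping
  in a backend without `oob_decision_function_` would silently change the
  evaluation semantics.
- The h-region heuristic prefers the most hydrophobic window and can
  therefore report shorter h-regions than an expert would on mixed-residue
  peptides; downstream statistics (e.g. h-region phenylalanine counts) are
  defined relative to this rule.
- `compare_input_types` at full protocol scale (6 × 500 rounds × 1000 trees)
  is minutes-to-hours of compute; the defaults in tests use reduced rounds.
- Real-data use requires externally computed predictor calls in the vote-TSV
  format; the surrogates are calibrated for the synthetic sequences only.
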