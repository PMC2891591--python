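# Methods

## Model

The package treats an RNA alignment as a set of columns evolving
independently along a fixed rooted binary tree (τ, b) under one of two
reversible continuous-time Markov chains:

* **Unpaired model** — states Σ = {A, C, G, U}, rate matrix Q_u,
  equilibrium π_u.  Applied to single columns.
* **Paired model** — the 16 ordered dinucleotides AA…UU, rate matrix Q_p,
  equilibrium π_p.  Applied jointly to a pair of columns hypothesized to be
  base-paired; the two bases of a pair evolve as one state, so compensatory
  double substitutions (AU↔GC etc.) are single events with their own rate.

A candidate helix h — an ordered list of L(h) column pairs — is scored by
the length-normalized log-likelihood ratio of the paired hypothesis
(product of paired-model likelihoods over its column pairs) against the
unpaired hypothesis (product of unpaired-model likelihoods over the same
2·L(h) columns), both computed with Felsenstein pruning on the input tree.
Natural logarithms are used throughout; p-values are invariant to the log
base.  The division by L(h) makes helices of different lengths comparable.

Assumptions worth stating: columns are independent given the structure
hypothesis; the tree (with branch lengths) is known and shared by all
columns; there is no rate heterogeneity across sites; base-pair geometry
beyond the six consensus pairs is not modelled.

### Gap semantics

* Unpaired column: gap and `N` are missing information (all-ones leaf
  vector).
* Paired columns, two-sided gap: missing information over all 16 states —
  helices gain and lose whole pairs over time, so a doubly-gapped row is
  uninformative.
* Paired columns, one-sided gap: an indicator over the 3 dinucleotide
  states that retain the observed base but cannot form a consensus pair.
  A nucleotide aligned against a gap is evidence *against* pairing, not
  absence of evidence; treating it as missing would let the likelihood be
  dominated by the consensus completions.  The uniform unit-weight
  indicator is the minimal implementation of "counts as a non-consensus
  pair".

### Default rate matrices

The packaged matrices are **synthetic**: they are not transcribed from any
published table (none was available to transcribe exactly), and the data
files say so.  Construction, frozen in `src/transat/data/*.dat`:

* Unpaired: GTR form Q[a,b] = s[a,b]·π_b with transition/transversion
  exchangeability ratio 4:1 and π_u = (A 0.35, C 0.17, G 0.20, U 0.28), an
  A-rich loop-like composition; scaled to 1 expected substitution per site
  per unit branch length.
* Paired: π_p puts 92 % of the mass on the six consensus pairs
  (GC = CG = 0.24, AU = UA = 0.17, GU = UG = 0.05) and 0.008 on each of the
  ten non-consensus states.  Single-base changes inherit the 4-state
  exchangeabilities; double changes have exchangeability 1.5 between
  consensus pairs (compensatory) and 0.02 otherwise; scaled to 1 expected
  event per pair per unit branch length.

Both files store Q to full float precision so the loader's reversibility
check (detailed balance to 1e-9) passes by construction.  Every
downstream validation is property-based (reversibility, pruning oracles,
null calibration, recovery trends) and holds for any valid reversible
pair of models; users with a preferred published model drop two files of
the same layout into a directory and pass `--model-dir`.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `min_helix_len` | 4 | minimum consecutive consensus pairs per helix (bp) |
| `min_loop` | 3 | minimum unpaired nt enclosed by the innermost pair |
| `shuffles` | 500 | shuffled alignments pooled into the null |
| `conservation_bins` | 10 | conservation discretization for column binning |
| `p̂` (evaluation only) | user choice | significance threshold; predictions always carry all p-values |

`min_helix_len = 4` is the method's defining constant; `min_loop = 3` is
the conventional minimal hairpin loop (the method description is silent on
it, so it is exposed as a flag).  500 shuffles resolve p-values down to
roughly 1/(pooled scores + 1); increase for smaller p-values.

## Null distribution and p-values

Columns are binned by the key (gap count, ⌊conservation · bins⌋) where
conservation is the frequency of the most common non-gap character among
non-gap rows.  Gap *count* rather than the exact gap pattern is used
because exact-pattern bins degenerate into singletons on deep alignments
and freeze the shuffle.  Within each bin, columns are permuted uniformly
(one seeded generator; per-shuffle substreams derived by counter, so the
result is independent of evaluation order).  Helices are detected and
scored in every shuffled alignment exactly as for the input, and all
scores pool into one empirical null.  The p-value is the add-one right
tail (#{null ≥ S} + 1)/(N + 1): monotone in the score, never 0, and
conservative — preferred over a binned histogram, which is a lossy version
of the same tail.

The original protocol realigns the sequences on primary-sequence identity
(T-Coffee) before shuffling, to strip alignment patterns that exist only
because of structure conservation.  Realignment is an external-tool hook
here (`--realign-cmd 'cmd {in} {out}'`); the default is the identity, and
the deviation is logged whenever the null is built without a realigner.

## Synthetic benchmark generator

`simulate` draws a root state for every site from the equilibrium
distribution (jointly over dinucleotides for paired sites), then walks the
tree root-to-leaves sampling children from P(b) = exp(Qb).  Trees are
maximally balanced rooted binary trees with all 2n−2 edges equal, so the
total tree length is an exact input.  Reference structures are either
user-supplied dot-bracket strings or random non-overlapping helices (≥ 4
pairs, ≥ 3 nt loops, target pair fraction 0.5, crossing placements
allowed) standing in for a curated structure database so that nothing need
be downloaded.  The benchmark designs are 9 sequence-length bins
(100–199 … 900–999) × 10 structures × tree lengths {0.5, 1, 2, 4, 8, 16}
(540 alignments) and 9 bins × 50 structures at tree length 4 (450
alignments), 10 sequences each.

What the generator does *not* emulate: indels (simulated alignments are
gapless and error-free), structural variation between sequences,
non-stationary composition, and rate variation across sites.  Passing
recovery tests on this data therefore demonstrates the machinery under the
model's own assumptions — an idealized upper bound, not field performance
on curated alignments, where alignment errors and incomplete annotation
depress measured PPV.

## Evaluation protocol

Base-pair level: a predicted pair inherits the minimum p-value over all
predicted helices containing it; at threshold p̂ the confusion counts are
TP (known, min-p ≤ p̂), FP (unknown, min-p ≤ p̂), FN (known but
insignificant or never predicted), TN (predicted, unknown, insignificant).
The TN universe is deliberately the set of *predicted* pairs, not all
O(n²) column pairs — the reported FPR depends on this choice.  Helix
level: a prediction matches when ≥ 70 % of its pairs are identical to
reference pairs (ties at 0.7 match; identity, not one-sided overlap).
Metrics: Sens = TP/(TP+FN), FPR = FP/(FP+TN), PPV = TP/(TP+FP), F the
harmonic mean of Sens and PPV, and MCC; any 0/0 is reported as undefined
and excluded from macro-averages (with the contributing count reported).
The dataset-quality utilities (canonical-pair fraction and covariation
fraction) implement the compensatory-pair-type count; their filter cutoffs
are configuration with no claimed defaults, since no authoritative values
were available.

## Numerical choices

* Transition matrices by symmetrized eigendecomposition
  (diag(√π) Q diag(1/√π) is symmetric for reversible Q, guaranteeing a
  real spectrum); results cached per distinct branch length.  Entries are
  clipped at 0 and rows renormalized to absorb rounding.
* Pruning uses per-node rescaling with an accumulated log-scale, so
  log-likelihoods are exact to ~1e-10 regardless of tree depth (verified
  against exhaustive state summation at 1e-12 on small trees).
* An unrooted Newick tree (trifurcating root) is rooted on its first child
  edge with a zero-length edge; for reversible models the likelihood is
  root-invariant (tested on random rerootings at 1e-10).
* Ties in the predictions TSV sort by descending score, then
  lexicographically by column pairs, making output byte-stable.
* Helices broken by `N` split into their flanking runs; `N` never pairs.
* IUPAC ambiguity codes are normalized to `N` on input and treated as
  missing information in likelihoods.

## Design decisions

* **Maximal-only enumeration.**  Only maximal consensus runs are emitted
  per sequence; sub-helices would add a quadratic number of near-duplicate
  candidates with interpolated scores.  Staggered variants proposed by
  different sequences are kept as distinct conserved helices and are not
  merged on partial overlap.
* **Mapping, not realignment.**  Helices are found on ungapped sequences
  and mapped through each row's gap structure, which bounds the damage an
  alignment error can do to any single helix.
* **p-values always reported.**  Thresholding is a post-hoc user decision
  applied only in evaluation and plots.

## Problem sizes used in validation

The shipped validation suite runs the recovery experiment at 10 replicates
per condition (10 sequences, alignment lengths 100–200, 100 shuffles,
p̂ = 0.05) and the calibration check on 3 structure-free alignments of
length 120 with 100 shuffles; the full benchmark designs are exercised for
their counts (540/450/990).  These sizes were chosen so the whole suite
completes in minutes while every check retains clear statistical
resolution.

## Known limitations

* Helices are strictly consecutive stacks: bulges and internal loops are
  not bridged, so an interrupted biological helix appears as two
  predictions.
* No multiple-testing correction across helices; ranking is by raw
  p-value, and p-values of overlapping helices are dependent.
* Analytic p-values are not available; resolution is limited by the pooled
  null size.
* Tree inference is out of scope — the tree is an input.
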