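# Methods

## Problem setting and assumptions

`pairface` models inter-protein residue contacts from sequence alone. A
complex has a ligand side and a receptor side, each one or more chains;
only cross-side residue pairs are considered, and a pair is binding when
the minimum any-atom distance is ≤ 6.0 Å (boundary inclusive). The model
assumes bound-state geometry when deriving labels, treats chains as
independent sequences (no inter-chain features beyond the pairing itself),
and sees evolutionary context only through per-chain PSSMs supplied by the
user. Observed residues are treated as sequence-adjacent: chain breaks in
crystal structures are logged but do not interrupt window arithmetic,
because windows need gap-free indices and the parser renumbers residues
1..L per chain (a mapping to author numbering is available via
`structure.residue_index_map`).

Structure parsing keeps all atoms present in the coordinate records (no
heavy-atom filtering beyond what the file provides), keeps the first
alternate location, folds insertion codes into the sequential index, maps
unambiguous modified residues (MSE, SEP, PTR, …) to their parents and
drops everything else with a logged warning.

## Propensity statistics

Pair counts accumulate per complex: with side-specific type counts
N_i(ligand), N_j(receptor), the unordered type pair (i, j) receives
N_i^L·N_j^R + N_j^L·N_i^R for i ≠ j and N_i^L·N_i^R for i = j, so the
unordered counts sum exactly to (Σm)(Σn) per complex. Expected contacts
are pair_count/total_pairs × total_contacts, which conserves the contact
total exactly (Σ E_ij = N_o); the propensity is observed/expected and the
significance statistic is (O − E)²/E against the 1-df chi-squared
distribution. Dividing by E (not O) is the standard goodness-of-fit form
and is the form that published interface censuses actually tabulate.
Propensities are reported as raw ratios; a log transform is presentation
only.

## Feature encoding

- One-hot residue identity windows and PSSM windows of sizes
  {0, 1, 3, 5, 7} (0 = block absent), centred on the residue.
- PSSM log-odds are squashed through 1/(1+e^−x) before entering the
  network. Raw log-odds are configurable, but bounded inputs keep the
  small networks in their responsive range.
- A 20-dim normalised amino-acid composition of the whole chain is
  appended per residue (on by default). This is a per-chain quantity —
  the minimal reading of "global composition"; per-complex pooling is a
  plausible alternative that was not adopted.
- Training excludes positions whose largest window would overrun a
  terminus; prediction zero-pads the missing neighbour slots instead, so
  every pair in a complex receives a score and the downstream conversions
  see complete matrices.
- The alphabet order is fixed to ARNDCQEGHILKMFPSTWYV everywhere,
  matching the column order of PSI-BLAST ASCII matrices.

## The two-stage ensemble

Stage 1 is one network per cell of the window grid {0,1,3,5,7}² minus
(0,0): 24 members. Residue-pair patterns are the two order-concatenations
(i,j) and (j,i) with identical targets, so the network population sees the
pair symmetrically; at prediction time the two order scores are averaged,
making the final score exactly order-invariant. Each member keeps all
positive pairs and draws an independent uniform sample of negatives —
min(round(0.02·N), 1000) in pair mode, fraction √0.02 in single-residue
mode — seeded as base_seed + member index. Stage 2 is the unweighted mean
of the 24 member scores; independent negative samples are what make the
averaging cancel sampling noise.

The stage-1 learner is a one-hidden-layer network: logistic hidden units
(default 5), logistic scalar output, 0/1 targets, squared-error loss by
default (cross-entropy selectable), trained by mini-batch SGD (batch 32)
for a fixed cycle count (default 100) with per-epoch reshuffling. All
randomness (init, shuffling) flows from one seed, so training is
bit-reproducible.

### Numerical choices

- **Learning rate 1.0.** Gradients are averaged over the batch, so the
  effective per-sample step is ≈ lr/32. With the logistic-output ×
  squared-error gradient (which carries an extra σ′ ≤ 0.25 factor), rates
  near 0.01 leave the network at chance after the fixed 100 cycles;
  lr = 1.0 reaches held-out AUC ≈ 0.86 on planted-signal data where 0.01
  reaches ≈ 0.40. The rate, like all other hyper-parameters, is exposed
  in `NetworkParams`.
- Weight init: Gaussian, scale 1/√fan-in, from the member's seed.
- Class predictions use score ≥ threshold (fixed convention).
- AUC is tie-aware (ties count ½), so a constant predictor scores exactly
  0.5; it equals the normalised Mann–Whitney statistic and is computed via
  the standard rank-based routine, cross-checked in tests against an
  O(n²) enumeration oracle.
- Best-F1 search sweeps all distinct score values; F1 ties resolve to the
  lowest threshold; F1 is defined 0 when precision and recall are both 0.
- Complexes whose held-out labels are single-class are excluded from
  leave-one-out averaging with a logged warning (their AUC is undefined).
- Degenerate paired t-tests (zero-variance differences) are flagged
  rather than given a fabricated p-value.

## Leave-one-out protocol

Cycle c trains a full 24-member ensemble on all complexes except c (cycle
seed = base_seed + 100·c) and evaluates on complex c only. Pair-task
scores come directly from the pair-trained ensemble, or from averaging the
two residue scores of the single-trained ensemble; single-task scores come
from row/column maxima of the pair matrix, or directly from the
single-trained ensemble. Per-complex AUCs are averaged unweighted, and the
two training modes are compared with a two-sided paired t-test over the
per-complex values.

## Synthetic data

The generator emulates the statistical structure of a docking benchmark,
not protein geometry:

- Chains are sequences drawn from a background composition (uniform by
  default). A planted interface is a matching of k ligand residues to k
  receptor residues; each contacting pair's types are drawn with
  probability ∝ f_i f_j m_ij, where m is a configurable symmetric
  enrichment-multiplier map. The induced theoretical propensity is
  m_ij / (f·M·f), exposed as `expected_pair_propensity` for recovery
  tests.
- Geometry is stylised: one dummy atom per residue (a few, jittered
  < 0.4 Å, when multi-atom residues are requested); each contact pair sits
  4 Å apart at a site ≥ 25 Å from other sites, and non-interface residues
  sit hundreds of Å away. This guarantees the 6.0-Å extractor recovers
  the planted table *exactly*, which is what makes the labelling pipeline
  testable end-to-end.
- PSSMs are integer log-odds peaked (strength `signal`, default 5) at the
  true residue plus Gaussian noise (default sd 1), written and re-read in
  the PSI-BLAST ASCII dialect bit-identically.
- Decoy sets contain ≥ 1 near-native pose (true contact set, RMSD drawn
  below 2.5 Å) and shuffled decoys (same contact count placed uniformly at
  random, RMSD 5–20 Å); external ranks order poses by RMSD perturbed with
  Gaussian noise, emulating an imperfect external scoring function.

The default enrichment map plants the strongest enriched and depleted
type pairs observed in real interfaces at their observed magnitudes
(D-R 2.9, R-Y 3.0, N-Y 3.0, R-W 3.6, E-K 1.9; A-V 0.3, A-L 0.5, L-V 0.5).
At these realistic magnitudes only a small minority of contacts carry
type-pair information, so the Bayes-optimal pair AUC is only ≈ 0.55: this
regime is used for propensity-recovery tests, where it is informative,
but not for model benchmarking, where it is not.

**What passing tests do and do not show.** Fixtures carry signal only in
residue identities (and the PSSM echo of them); there is no structural
neighbourhood, no co-evolution, no composition bias between surface and
core, and interfaces are matchings rather than patches. Tests therefore
demonstrate that the machinery learns and evaluates what was planted —
they do not certify real-data performance, which depends on biological
signal the generator does not emulate.

## Benchmark conditions

The frozen pair-vs-single benchmark (`experiments.headline_comparison`)
uses 20 complexes, one 30-residue chain per side, 12 planted contacts per
complex, and a *strong* pair-specific map: the five enriched pairs above
at multiplier 400, under which contacts are drawn almost exclusively from
those five type pairs. Concentrating the signal keeps the partner-aware vs
partner-unaware comparison identifiable at a 20-complex problem size while
leaving the single-trained baseline genuinely competitive (the marginal
type enrichments remain strong). Networks run at the package defaults
(5 hidden units, 100 cycles). These problem sizes are the package's own
choice of a small, fully reproducible benchmark; larger fixture sets
simply sharpen the same comparison.

## Known limitations

- Absolute AUCs on synthetic data are not comparable to real-benchmark
  numbers; only the ordering of models within one synthetic condition is
  meaningful.
- The stage-1 learner is deliberately minimal; no early stopping,
  validation splits, regularisation or GPU path.
- Propensities condition on all residues, not surface residues, so they
  fold surface propensity into the ratio.
- The partner-specific site report masks "common" residues by top-k
  intersection across partners (k = 30 by default); threshold-based
  masking is a reasonable alternative the package does not implement.
- Decoy scoring consumes pose contact sets (or pose coordinates through
  the same 6.0-Å extractor); it does not generate poses and has no
  energetic or repulsive terms.
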