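# pairface

Partner-aware, sequence-based prediction of interacting residue pairs in
protein–protein complexes.

Most sequence-based interface predictors score each residue of a single
protein for its propensity to bind *any* partner. `pairface` instead asks a
sharper question: given the sequences of two specific proteins, **which
residue pairs across the two are in contact?** Training directly on residue
pairs lets the model exploit complementarity — an Asp scores highly only
when the candidate partner residue is a plausible counterpart such as Arg —
and the pair scores convert naturally back to per-protein binding-site
predictions and forward to a docking-decoy scoring function.

The package is aimed at structural bioinformaticians who work with docking
benchmarks: it reads bound complexes in PDB format, FASTA sequences and
PSI-BLAST ASCII profile matrices, and ships a synthetic-fixture generator
so the entire pipeline runs and is tested without any external download.

## The model

**Contact definition.** With ligand chains of *m₁, m₂, …* residues and
receptor chains of *n₁, n₂, …* residues, all (Σmᵢ)×(Σnⱼ) cross-side residue
pairs are labelled; a pair is *binding* when any atom of one residue is
within 6.0 Å of any atom of the other. Intra-side contacts are ignored.

**Pair propensities.** For residue types *i, j*, with pair count
Nᵢ·Nⱼ accumulated per complex and observed contact count *O*ᵢⱼ,

    E_ij = (N_i N_j) / Σ(N_i N_j) · N_o        (expected contacts)
    P_ij = O_ij / E_ij                          (propensity)
    χ²   = (O_ij − E_ij)² / E_ij                (1 df)

`P_ij > 1` marks pairs enriched at interfaces (e.g. Asp–Arg, Arg–Tyr);
`P_ij < 1` marks depleted ones (e.g. Ala–Val).

**Two-stage ensemble.** Each residue is encoded by a sliding window of
one-hot residue identities and/or a window of logistic-squashed PSSM
columns, plus the chain's global amino-acid composition; window sizes come
from the grid {0, 1, 3, 5, 7}² minus the featureless (0, 0) cell, giving 24
feature specs. A residue pair is the concatenation of its two residue
vectors in both orders, with identical 0/1 targets. Stage 1 trains one
small logistic network per spec, keeping all binding pairs and subsampling
non-binding pairs (2% or 1000, whichever is smaller — they outnumber
positives by orders of magnitude) independently per member. Stage 2 simply
averages the 24 order-averaged member scores; the final pair score is
exactly symmetric in the two residues. A partner-unaware baseline trains
the same machinery on single residues (negative fraction √0.02) for
comparison.

**Conversions and evaluation.** Pair → single: a residue inherits the
highest score of any pair it joins. Single → pair: a pair scores the mean
of its two residue scores. Evaluation is leave-one-complex-out: recall,
precision, specificity, F1, best-F1 operating point and tie-aware ROC AUC
are computed per held-out complex and averaged unweighted; model pairs are
compared with a two-sided paired t-test over per-complex AUCs.

**Decoy rescoring.** For each rigid-body docking pose, the AUC of the
predicted pair scores against the pose's own contact set is the pose score;
poses are ranked by it, optionally blended 3:1 with an external ranking,
and judged by native-like hits (RMSD < 2.5 Å) in the top 2000.

## Worked example

Generate synthetic complexes with strongly pair-specific planted contacts,
inspect propensities, fit the ensemble and score a held-out complex:

```python
from pairface import PropensityModel, PairInterfaceModel, roc_auc
from pairface.experiments import STRONG_PAIR_PREFERENCES
from pairface.simulate import FixtureConfig, generate_fixture_set

config = FixtureConfig(seed=42, n_complexes=21, interface_size=(12, 12),
                       pair_preferences=dict(STRONG_PAIR_PREFERENCES))
structures, tables, pssms = generate_fixture_set(config)

stats = PropensityModel(tables).fit()
print(stats.summary(top=5))

results = PairInterfaceModel(tables[:20], pssms=pssms).fit(seed=0)
heldout = tables[20]
auc = roc_auc(results.predict_complex(heldout).ravel(),
              heldout.labels.ravel()).auc
print(f"held-out complex {heldout.complex_id}: pair AUC = {auc:.3f}")
```

Output:

```
Contact propensity summary
  complexes:      21
  residue pairs:  18900
  contacts:       252

Top 5 type pairs by p-value:
pair  pair_count propensity  observed expected  chi2   p_value
 E-K         192      16.41        42      2.6 607.6 3.68e-134
 N-Y         255      12.06        41      3.4 415.8  1.99e-92
 R-W         364       9.27        45      4.9 332.1  3.37e-74
 R-D         435       8.28        48      5.8 307.0  9.63e-69
 R-Y         558       6.32        47      7.4 210.3  1.15e-47

held-out complex synth021: pair AUC = 0.789
```

The propensity table recovers the planted Glu–Lys / Asn–Tyr / Arg–Trp /
Arg–Asp / Arg–Tyr enrichments with large χ² values, and the ensemble
ranks the planted contacts of an unseen complex well above non-contacts
(AUC 0.79 from a single fit; the leave-one-out benchmark below averages
over 20 held-out complexes).

The same workflows are available from the shell via the `pairface`
executable (`simulate`, `extract-contacts`, `propensity`, `train`,
`predict`, `loo-evaluate`, `convert-scores`, `score-decoys`).

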