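# Methods

## Scope and data flow

The package scores single amino-acid substitutions for disease association.
Inputs are plain-text files: an aligned FASTA of homologs per protein (query
first), a PDB file whose Cα ATOM records define the structure model, a TSV of
domain segments and a TSV of variants. Homology search, structure prediction
and domain parsing are upstream of the package; it consumes their outputs.
Positions are 1-based everywhere, and every per-position array lives in the
query's coordinate system (alignment columns where the query is gapped are
dropped on read).

## Sequence profile and entropy

Identity between two aligned rows is the fraction of matching letters over
columns where both are non-gap (0 when no such column exists) — a standard,
symmetric convention. The 35–90 filter scans non-query rows in input order
and keeps a row iff its identity to the query lies in [0.35, 0.90] and its
identity to every previously kept row is ≤ 0.90. The greedy scan is
deterministic and O(n²); tests verify its output is always a maximal valid
subset by exhaustive enumeration on small alignments.

Profiles count the 20 standard types per column, query included, and
normalize by the number of contributing sequences at that column; gaps and
nonstandard letters are excluded from numerator and denominator. Entropy is
in nats (the 0 – ln 20 ≈ 2.996 range is the fixed convention), with
0·ln 0 := 0 and an all-zero (no-coverage) column mapped to S = 0 — the same
degenerate behaviour as a query-only profile, where every position is one-hot
and carries zero information. Counting the query is a deliberate choice: it
forces exactly that query-only limit. The relative entropy RS = S − ⟨S⟩ uses
the unweighted mean over all positions, so Σ RS = 0 per protein by
construction.

## Structure features

Contacting composition takes all residues of the supplied model whose Cα is
within the cutoff (≤, boundary inclusive; default 12 Å, 8 Å in the CUT8
variant) of the mutated residue's Cα, excluding the residue itself, and
normalizes their type counts. No neighbors yields an all-zero sentinel,
which is distinct from "position absent from the model" (an error). Wild-type
coordinates serve for both wild and mutant — no mutant remodeling. Domain
composition is computed over the query-sequence letters of the covering
segment; a position covered by no segment falls back to the whole sequence
[1, L]. Both vectors are rotation/translation invariant by construction
(distances only), which tests assert to 1e-9.

## Feature vector

Fixed block order: [RS | wild one-hot | mutant one-hot | domain composition |
contact composition], alphabetical amino-acid indexing (A…Y) throughout,
disabled blocks omitted. The order is frozen in serialized models via the
configuration tag so a model file is self-describing. Assembly checks the
variant's stated wild type against the query sequence letter and refuses on
mismatch — silently scoring the wrong residue is the worst failure mode of a
variant annotator. Variants whose protein lacks structural coverage default
to being dropped (configurable: zero-sentinel scoring or an error instead).

## Boosted trees

Least-squares boosting: F0 = 0, and at every stage a regression tree with
maximal depth 8 is fit to the current residuals y − f(X); leaf values are
residual means and the stage update is ε·T. The squared-error loss is the
canonical reading for 0/1 regression targets and keeps scores interpretable
against probability-like cutoffs. Split candidates are midpoints between
consecutive distinct sorted feature values, found by a vectorized
prefix-sum scan over all features at once; ties between equal-gain splits
break to the lowest feature index, then the lowest threshold, so refits are
bit-identical. Routing is left iff feature ≤ threshold. There is no row or
feature subsampling and no early stopping: the configured N_tree (default
2000) always runs, with ε = 0.005 — empirical values, not optimized here.
min_leaf defaults to 5 because depth-8 trees with single-sample leaves
overfit pathologically on small synthetic sets; the tiny hand-checked
examples in the tests pass min_leaf = 1 explicitly. Training MSE is provably
non-increasing for ε ∈ (0, 2) with leaf-mean trees, and the tests assert it.

The test suite checks the implementation two ways: against
scikit-learn trees on continuous targets (where tie-breaking is immaterial),
and exactly against a brute-force exhaustive-split reference written
independently in the tests. Exact agreement requires that mathematically
tied split gains also compare identically in floating point, so the
reference accumulates its left-hand sums sequentially in sorted order — the
natural way to write the scan — which reproduces the prefix-sum arithmetic.

Models serialize to a structured JSON document (nodes, shrinkage, feature
configuration, version tag). JSON doubles round-trip exactly in Python, so
reloaded models predict bit-identically; a wrong version tag is an error.

## Dataset protocol and evaluation

A protein is balanced when it has ≥ 1 disease variation and a
neutral/disease ratio within [0.3, 3.0] (bounds inclusive, following the
tabulated definition; the alternative strict-boundary reading appears once in
prose and is not adopted). Over-sampling replicates balanced-protein
variations to six copies, computed on — and applied to — the training side
only, after the seeded variation-level split. The grouped k-fold splitter
shuffles groups by seed and assigns them largest-first to the smallest test
fold; group leakage across folds is zero by construction. The exome
pre-filter drops variants with allele frequency ≥ 0.17 (kept when the
frequency is unknown).

MCC/ACC/Sen/Spe/PPV/NPV come straight from the confusion table with disease
as the positive class. A zero factor in the MCC denominator maps MCC to 0;
an undefined ratio (e.g. PPV with no positive calls) is reported as missing,
never as 0. AUC uses the tie-aware rank (Mann–Whitney) formulation —
exactly the probability a random disease score exceeds a random neutral
score with ties at ½ — which equals the trapezoidal ROC area and is verified
against both pair enumeration and scikit-learn. The cross-dataset FPR fit is
ordinary least squares of one set's per-method FPR on the other's (matching
the one-directional form of the published equation), with Pearson r; its
intercept extrapolates the contamination of the putatively neutral set.

## Hot spots

The saturation scan scores all 19 substitutions at every position whose
features are computable; a position is hot iff the minimum of its 19 scores
is strictly above the cutoff. Hot fractions use covered positions as the
denominator — uncovered positions appear in neither numerator nor
denominator — and isoform profiles sharing a protein id are averaged
unweighted. The threshold curve reports, for each threshold t, the mean
attribute over proteins with hot fraction ≥ t (for a 0/1 attribute this is a
cumulative fraction), omitting and logging empty thresholds, plus the
Pearson correlation between the threshold grid and the curve.

## Synthetic data

The generator emulates exactly the statistics the predictor relies on:
alignments with a controllable fraction of conserved columns (variable
columns resample uniform letters at a set rate, placing homolog identities
around 1 − v·rate·19/20 so the 35–90 window can be straddled); idealized
extended (collinear, 3.8 Å spacing — interior residues have exactly 6
neighbors at 12 Å and 4 at 8 Å) or α-helical (rise 1.5 Å, 100°/residue,
radius 2.3 Å) Cα chains whose letters match the query sequence; and variant
tables whose labels are Bernoulli draws from
P(disease) = logistic(−slope·(RS − rs0)), with rs0 solved by bisection so the
per-protein neutral/disease ratio hits its target in expectation. Slope 0 is
the no-signal null. Everything derives from one integer seed and is
byte-reproducible.

Defaults — 20 proteins × 100 residues, 50 homologs, half the columns
conserved, substitution rate 0.5, 100 variants per protein, slope 4, target
ratio 1 — give a clearly bimodal RS distribution and near-deterministic
labels, and keep a full featurize/train/evaluate round with a 200-tree model
in the low tens of seconds on one CPU.

What passing on this generator shows — and does not show: the pipeline
recovers a planted conservation signal through the full feature encoding and
training protocol (held-out AUC ≈ 0.93 at the default conditions), stays at
chance when no signal exists, and degrades when the signal-carrying block is
ablated. Real proteins are harder: profile depth varies wildly, structures
are imperfect predictions, labels are noisy and biased per protein, and
signal is spread across blocks rather than concentrated in entropy. Synthetic
results therefore validate the machinery, not clinical accuracy. One known
artefact: contact compositions on random-letter chains nearly fingerprint
positions, so a variation-level split lets tree ensembles partially memorize
per-position label propensities; the NOENT ablation lands above 0.5 (≈ 0.6)
for this reason, which mimics the position-memorization channel real
predictors also exhibit.

## Known limitations

- Solvent accessibility, secondary structure, all-atom contacts and
  substitution-matrix features are out of scope by design.
- The identity filter is order-dependent (greedy); a different input order
  can keep a different — equally valid — maximal subset.
- Profile columns do not weight sequences beyond the identity window.
- The boosted trees are exact and deterministic but not as fast as
  histogram-based libraries; they are intended for the data sizes of the
  training protocol, not for millions of rows.
- Whether published hot-spot fractions use total or covered residues as the
  denominator is unstated; this package uses covered residues and records
  the coverage alongside.
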