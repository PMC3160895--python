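# Methods

This note records the modelling choices, defaults and numerical
conventions of `epireact`, and what the synthetic study conditions do
and do not establish.

## Peptide featurization

**Residue counts.** The 24 occurrence counts cover the 20 standard
amino acids plus the ambiguity codes B (N/D), X (any), Z (Q/E) and J
(L/I), which occur in real array data and are counted as themselves.

**Isoelectric point.** Net charge at a given pH is the
Henderson–Hasselbalch sum over the free termini and the ionizable side
chains D, E, C, Y (acidic) and H, K, R (basic), with an EMBOSS-style
pKa table (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, Y 10.1, H 6.5,
K 10.8, R 12.5). The charge is strictly decreasing in pH, so the pI is
the unique root in [0, 14]; it is bracketed by bisection on the *sign*
of the charge down to a pH interval of 1e-4. Stopping on a charge
tolerance instead would be ill-conditioned for peptides without
ionizable side chains (e.g. poly-G), whose charge curve is nearly flat
over a wide pH plateau. Ambiguity codes are treated as non-ionizable.

**Scale-window features.** Each of the five propensity scales
(antigenicity, accessibility, hydrophilicity, flexibility, beta-turn)
yields one feature: the maximum over all sliding windows of 9 residues
of the within-window *mean* scale value. The within-window statistic is
the package's choice — the mean is the standard aggregation for
propensity profiles, and for homopolymers (where the window feature
equals the plain scale entry) the mean and max readings coincide; a
`statistic="max"` variant is available. Sequences shorter than the
window use one window spanning the whole sequence. Ambiguity codes take
the mean of their referent residues (B = (N+D)/2, Z = (Q+E)/2,
J = (L+I)/2) and X the grand mean of all 20 — a documented convention,
configurable by supplying a custom scale.

**Normalization.** Min–max per feature, learned on the training table
only; constant columns map to 0; test/query features are normalized
with the training (min, max) and clipped into [0, 1]. Whether scale
features should be normalized before or after windowing is genuinely
open; raw-then-table-level min–max is used.

## Alignment features

Pairwise scoring is exact affine-gap dynamic programming (BLOSUM50,
gap open 10, gap extend 1: a gap of length L costs 10 + (L−1)); global
mode penalizes terminal gaps. The matrix and penalties are the
package's defaults (BLOSUM50 keeps the alignment scoring consistent
with the BLOSUM50-derived residue groups used in motif extraction) and
are configurable. The stock BLOSUM tables lack the J code; the matrix
is extended so J scores through the X row, the table's own catch-all.
Scores enter the feature table raw (not length-normalized);
normalization happens at the table level.

The six features of peptide *i* are the maxima of its alignment scores
against the negative and positive references excluding itself, per
mode, plus their differences. An empty reference class makes the
feature undefined and raises.

## Leakage-aware leave-one-out cross-validation

The alignment features of *every* peptide depend on the labels of the
others, so the held-out peptide must not contribute to any reference
maximum in its fold. `loocv` masks the held-out index out of the
precomputed score matrices (no re-alignment is needed), recomputes the
remaining n−1 peptides' alignment features, re-learns normalization
(and the feature subset, unless the fast mode is chosen), refits, and
scores the held-out peptide against the n−1 references. Metrics are
computed over the n held-out probabilities at threshold 0.5 (the
package's choice of operating point).

A known small-sample artifact is worth stating: at small n with many
features, LOOCV is *pessimistically* biased — leaving out a positive
shifts the class prior of the fold and an overfit model anti-correlates
with the held-out label — so label-free data can score visibly below
AUROC 0.5 at n below roughly 100. The null-fixture calibration (below)
therefore uses a set large enough for the bias to be small against the
±0.05 band.

## Model fitting and selection

* **SRC.** The univariate slope of the 0/1 class on each standardized
  feature (= corr × sd(class)); a sign/importance check on the
  multivariate fit. Constant features get 0 with a warning.
* **Collinearity filter.** Greedy: while any kept pair has |r| > 0.95,
  drop the member with the smaller |SRC| (ties: the lexicographically
  later name).
* **M5 (subset B).** Backward elimination on the linear fit of the 0/1
  class: repeatedly drop the feature with the smallest |standardized
  coefficient| while Gaussian AIC (n·ln(RSS/n) + 2k) does not worsen;
  ties drop the lexicographically first name. Deterministic. Note that
  AIC is a mild filter: a pure-noise regressor survives one elimination
  step with probability P(χ²₁ > 2) ≈ 0.16.
* **LASSO (subset C).** L1-penalized logistic regression, penalty
  chosen on a 13-point log grid by 5-fold cross-validated deviance;
  zero-coefficient features are removed.
* **Logistic fit.** Unpenalized maximum likelihood (checked to gradient
  norm < 1e-6); under (quasi-)perfect separation the likelihood has no
  maximizer and the fit falls back to a tiny L2 ridge (1e-6) with a
  warning. Coefficients outside the selected subset are exact zeros.
* **Comparators.** Cross-validation can swap the logistic model for
  off-the-shelf alternatives (`linear`: least squares on the 0/1
  outcome, clipped to [0, 1]; `naive_bayes`: Gaussian; `tree`: CART
  with a 1%-of-n minimum leaf). They exist for comparison only; the
  trained, persisted, and generation-facing model is always logistic.
* **Metrics.** Confusion metrics at 0.5; F-measure = harmonic mean of
  sensitivity and precision; Brier = mean squared (p − y); AUROC by
  trapezoid; AUPR by precision-recall step interpolation (average
  precision). Single-class label vectors leave AUROC/AUPR undefined
  (reported as missing).

## De-novo generation

**Distance and clustering.** The local score matrix is normalized by
geometric self-score, d(i,j) = 1 − s(i,j)/√(s(i,i)·s(j,j)) — symmetric
and in [0, 1] for non-negative local scores (the exact normalization is
the package's choice). Complete-linkage clustering cut at 0.7 bounds
every cluster's diameter by the cutoff, which is asserted in tests.

**Cluster selection.** H: all members positive, size ≥ 5. L: all
negative, size ≥ 8. M: size ≥ 5 and positive fraction within ±5
percentage points (configurable) of the training class balance.

**Multiple alignment.** Star-progressive around the medoid (maximal
summed local score): members are globally aligned to the medoid and
merged once-a-gap-always-a-gap. Chosen for determinism and desk-scale
cost; any MSA could be substituted. Column conservation is sequence-
logo information, log2(20) − H(column) bits over non-gap symbols, with
no small-sample correction; all-gap columns carry 0 bits.

**Motif extraction.** For each 15-mer cluster member, positions are
visited in decreasing column information (ties: ascending position) and
fixed greedily. Fixing is refused when it would (i) complete a run of
four consecutive fixed residues whose concatenation occurs in the 4-mer
index of the training∪test sequences, or (ii) — in the generation
pipeline — place more than 5 fixed residues into an 11-position window.
Budget (ii) is implied rather than stated by the identity constraint:
fixed residues are guaranteed identities against the source training
peptide, so a motif violating it can never yield a candidate that
survives filtering; without the budget the filter rejects 100% of
enumerated candidates once conservation is high. Variable positions
may take any residue of the source residue's amino-acid group (the
union of group and column variation) observed in the alignment column;
choices that would re-create an indexed 4-mer together with flanking
fixed residues are pruned. When that pruning empties a position —
common when the index saturates the motif's variant neighbourhood —
the least-conserved fixed neighbour within 4-mer reach is released and
the sets recomputed, so every returned allowed set is non-empty and the
procedure always terminates.

**Residue groups.** Complete-linkage clustering of the 20 residues on
1 − s/√(s_ii·s_jj) from BLOSUM50, cut at 8 groups:
`AG, C, DN, EHKQR, FWY, ILMV, P, ST`. Printed here because ties in the
dendrogram make the exact partition depend on residue ordering; the
shipped partition is fixed and overridable.

**Novelty constraints.** Constraint 1: no 4-mer of a candidate may
occur in any training *or* test sequence. Constraint 2: against any
*training* sequence, over every ungapped relative offset, at most 5
positional identities within any 11-position stretch (gapped comparison
is not used; the constraint text reads as positional identity).
Overlaps shorter than 11 count their total matches. Both constraints
are enforced at emission and re-checked in tests by an independent
brute-force scan.

**Enumeration and ranking.** Motifs expand by Cartesian product up to a
cap (default 1e5; a seeded uniform sample beyond it). The final lists
take the top-ranked predicted reactivities from positive-cluster
candidates (H), the bottom-ranked from negative clusters (L) and a
seeded uniform draw from mixed clusters (M); ties break by sequence.
The pipeline can cap per-class candidate pools (subsampling before the
scoring step) to bound the quadratic alignment cost of featurizing
candidates against the training set.

## Synthetic study conditions

The generator emulates the assay's statistical structure: ~25%
positives; lengths 85% 15-mers, 10% 13-mers, 5% from {9, 16, 18, 20,
21}; positives carry one mutated copy (default per-position mutation
rate 0.1, replacements drawn from all 20 residues) of one of 3 family
motifs of length 8–10 implanted at a random offset; 10% of negatives
carry decoy motifs so length or composition alone cannot separate the
classes; reactivities are uniform in the positive/negative bands;
ambiguity codes are injected at 0.1% per residue to exercise those code
paths; record order is shuffled so it carries no label information.
Everything is reproducible from one seed.

Named fixtures pin the study conditions used by the tests:

* `tiny` (n=30) for oracle-style checks,
* `medium` (n=300) for cross-validation properties (planted-signal
  LOOCV AUROC is expected above 0.85),
* `separable` (n=40, verbatim 10-mer motifs, no decoys) where LOOCV
  accuracy 1.0 is expected by construction,
* `null` (n=200, labels independent of sequence: the implant is fully
  randomized) for the no-leakage calibration over 20 seeds; at this
  size the pessimistic LOOCV bias noted above stays well inside the
  ±0.05 band,
* `clustered` (n=200, strong families, heavy decoy use, one
  mixed-membership family at the training balance with deterministic
  per-family label counts) so that H, L and M clusters all occur at
  desk scale; end-to-end generation runs use 25–30 candidates per class
  with per-class pool caps of 200–300.

What passing these tests shows: the pipeline's contracts hold (no
leakage, constraint conservation, separation of H from L) under data
whose only signal is shared local motifs. What they do not show:
performance on real IVIg array data, whose motif structure, residue
composition and label noise are richer than the generator's; the
absolute metric values on synthetic fixtures should not be read as
expected real-data performance.

## Known limitations

* Exact O(n²) alignment makes the score matrix the dominant cost;
  no heuristic seeding is provided (desk-scale n only).
* The M5 and collinearity procedures are operational reconstructions
  (the classical references underdetermine the details); both are
  deterministic and documented above.
* Star-progressive MSA is order-independent but seed-dependent through
  the medoid; star alignments can be suboptimal for highly gapped
  clusters.
* Reactivity is modelled only through P(positive); no regression on the
  raw [1, 65536] signal is attempted.
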