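# Methods

## Problem setting

An extract library with a crossed design — nine individual trees, two
collection sites (mountain, littoral), three organs (leaf, stem bark, fruit),
54 extracts in all — is profiled by LC-MS in negative and positive
electrospray modes and assayed for α-glucosidase inhibition in a 96-well
plate at 405 nm. The analysis asks two questions: how does inhibition vary
with organ and provenance, and which ions' peak areas track it. Raw data of
this kind are rarely deposited, so the package ships a synthetic generator
that emulates the design with known ground truth; all quantitative claims in
the test suite refer to that generator, not to any real extract set.

## Assay model

Inhibition is `(A_ctrl − A_sample)/A_ctrl × 100` against the mean
negative-control absorbance. Replicates are summarized per extract at the
10 µg/mL reference dose (mean, SD with n−1 denominator). Negative
inhibition values are retained — an extract absorbing more than the control
is informative for the multivariate response; clipping happens only inside
the generator, where latent activity is a percentage by construction.

IC50 is estimated two ways, both labelled in the output, because plate-based
reports rarely state the model used:

* **monotone interpolation** (default): isotonic regression of inhibition on
  dose followed by linear interpolation on the bracketing dose pair. It is
  assumption-free; it returns "undefined, with reason" when the smoothed
  curve never crosses 50%, which is the honest answer for weak extracts.
* **four-parameter logistic**: least-squares 4PL fit inverted at 50%, for
  users who want a parametric summary. On noise-free logistic data it
  recovers the generating IC50 to ~1e-6 (self-inversion, tested).

## Feature filtering

Applied per ionization block, in this order:

1. **Retention-time window**, closed interval, default 0.5–5.0 min.
2. **Intensity filter**: an ion is kept iff its mean peak area within at
   least one organ group (pooling sites) is strictly greater than 2000.
   "Condition" is read as the organ; organ×site grouping and a max
   aggregator are available in `FilterConfig` for stricter or looser
   readings.
3. **Correlation pruning**: ions are linked when they co-elute
   (|Δrt| ≤ 0.02 min by default — a typical UHPLC alignment width; the
   tolerance is configurable) *and* correlate at r ≥ 0.80 (inclusive) across
   samples on raw peak areas (signed coefficient; absolute-value and
   log-scale options exist). Within each connected component exactly one ion
   is retained — the highest median peak area, ties broken by smallest ion
   id — so the rule is deterministic. Constant ions correlate with nothing
   and are noted rather than erroring.

The chain is idempotent, and both the intensity filter and the pruning are
tested for exact agreement with brute-force enumeration on small instances.

## Consensus multiblock OPLS

Each column-scaled block X_b yields a linear kernel K_b = X_bX_bᵀ,
Frobenius-normalized; the consensus kernel is K = Σ w_b K_b. One
y-predictive component plus `n_ortho` y-orthogonal components are extracted,
and block weights are iterated: w_b ∝ squared Frobenius congruence between
K_b and the predictive-score outer product (an RV-type measure in [0, 1]),
renormalized, until the largest weight change is below 1e-6 (at most 100
rounds; the fixed point is reached in a handful of iterations in practice).

Since all kernels here are linear, the decomposition is computed in the
mathematically identical primal form: Trygg–Wold OPLS (NIPALS) on the
concatenation of the scaled blocks, each multiplied by √(w_b/‖K_b‖_F). Every
score and fit metric depends on the data only through K, so this changes
nothing, and it makes new-sample projection transparent: held-out samples are
centered/scaled with the *training* column parameters and block factors, then
passed through the stored orthogonal deflations. Orthogonal scores are
exactly orthogonal to the final predictive score (a property of the
deflation algebra, asserted to 1e-6 in correlation throughout the tests).

Defaults and why:

* **Scaling: unit variance.** Peak areas are log-normal-ish with wildly
  different magnitudes; uv puts all ions on one footing and is the common
  default for consensus OPLS. Pareto and centering-only are exposed.
* **n_ortho = 1.** One predictive + one orthogonal axis is the canonical
  OPLS geometry for a single response with one dominant confounding
  structure (here, organ/site variation unrelated to activity).
* **Cross-validation: 7 folds, stratified by organ×site cell, seeded.**
  Sevenfold is the conventional chemometrics default; stratification keeps
  every fold's training set representative of the design. Each fold refits
  the full iterative model, including scaling and kernel norms, on the
  training samples only. Q² = 1 − PRESS/SS_tot.
* **Permutation test**: y is permuted, the whole CV-Q² is recomputed, and
  p = (1 + #{null ≥ observed})/(1 + n_perm) — the add-one form is valid
  (never anti-conservative) for any number of permutations.
* **Orientation**: the predictive score is flipped if needed so that
  corr(t_p, y) > 0. NIPALS leaves the component's sign arbitrary; the rule
  pins it, making "high score = high inhibition" and one-sided selection
  deterministic.

Loading coordinates are x_jᵀt_p/‖t_p‖ on the column-scaled (unweighted)
block — the summed covariance with the unit-norm predictive score. Under uv
scaling this equals √(n−1)·corr(x_j, t_p), so with n = 54 a coordinate of 5
corresponds to |corr| ≈ 0.69: a natural cutoff between ions that genuinely
track activity and organ-structured bystanders. Both predictive and
orthogonal coordinates are emitted.

## Selection and enrichment

Selection is one-sided — coordinate strictly greater than the threshold
(default 5; a percentile-based alternative is available) — with dense ranks
descending in the coordinate and ties broken by ion id. Raising the threshold
can only shrink the set. Negating the response mirrors every coordinate
exactly, so the orientation rule makes the procedure sign-stable; the
mirrored set reappears at the mirrored threshold (tested). Enrichment tables
report each selected ion's mean peak area per organ×site cell and the argmax
cell.

## Univariate statistics

Global Kruskal–Wallis with mid-ranks and tie correction (complete ties give
H = 0, p = 1 by convention). Pairwise post hocs are literal two-group
Kruskal–Wallis tests (equivalent to rank-sum) with one-step Bonferroni over
the k(k−1)/2 comparisons, capped at 1; Dunn's many-to-one test compares each
group to a named control on joint ranks with tie-corrected variance and
Bonferroni over k−1 comparisons. The two procedures are kept separate
because they answer different questions (all-pairs structure vs
control-anchored screening).

The compact letter display is computed as an **exact minimum clique cover**
of the non-significance graph (enumeration over maximal cliques), so two
groups share a letter exactly when their adjusted p ≥ α and the number of
letters is provably minimal — heuristic insert-and-absorb displays can use
one letter too many on adversarial patterns. Letters are assigned in
first-use order over groups sorted by descending median. Exhaustive search
is exponential in the number of groups, which is immaterial for designed
experiments (≤ ~12 groups). Note the monotonicity direction: *raising* α
makes more pairs significant and never merges a separated pair; lowering α
can merge pairs, which is the expected behaviour of any display driven by a
significance threshold.

## Synthetic generator

What it emulates, per the crossed design above, all driven by one master
seed with per-stage substreams (design; latent activity; blocks; plates):

* **Latent activity**: organ×site cell means (stem bark 84.7/69.9%, leaf
  49% both sites, fruit 13.6% both sites — the leaf and fruit values are
  site-invariant because no per-site figure is available for them) plus
  tree-level Gaussian noise (SD 6 percentage points), clipped to [0, 100].
* **Active ions** (10 by default, split across modes): log peak area =
  baseline + effect × activity/100 + noise, effect sizes U(2.0, 3.5) in log
  units, noise SD 0.35. Their retention times are spread evenly inside the
  analytical window so that co-elution pruning cannot silently delete a
  planted signal.
* **Inactive ions**: log-normal baselines with organ×site cell offsets that
  are *orthogonalized against the realized activity cell-mean vector* — they
  vary by organ and site but carry no linear information about inhibition.
  This is what gives the model a genuine orthogonal component to absorb.
* **Redundant clones**: copies of in-window inactive parents at the parent's
  exact retention time, ×0.97 × (1 + ε) with ε ~ N(0, 0.01) — correlation
  > 0.99 and a slightly lower median, so the pruning rule deterministically
  retains the parent.
* **Sub-threshold ions**: low-abundance ions rescaled if necessary so every
  organ-mean peak area stays below the 2000 intensity cutoff.
* **Assay plates**: triplicate absorbances A = A_ctrl(1 − inh/100)(1 + CV·z)
  with CV 5%; the extract dose–response is linear in concentration with the
  latent activity reached at the top dose (10 µg/mL) — the simplest monotone
  shape consistent with a single reference concentration, and it makes the
  assay arithmetic exactly invertible in the noise-free limit (closure
  tested). Acarbose (positive control, 0.2–1 mg/mL) follows a saturating
  Hill-2 curve that is ≈100% inhibitory at the top dose.

Pre-filter ion counts (230 negative / 190 positive), clone counts (8/6) and
sub-threshold counts (12/10) were calibrated once so that the standard filter
chain lands near 198/160 retained ions, and then frozen.

**What the generator does not emulate**, hence what green tests do *not*
show about real data: chromatographic peak shapes, m/z accuracy, adducts and
isotopes, missing values, batch and injection-order drift, nonlinear
dose–response of real extracts, and matrix effects on ionization. Passing
recovery tests demonstrate that the pipeline's logic is sound under its own
stated noise model, not that any particular real extract set will yield a
Q² of similar size.

### A geometric subtlety of the synthetic null

With no planted actives, the inactive ions' organ structure is exactly
orthogonal to the activity pattern. That makes the observed response
*non-exchangeable* with its permutations: a permuted y presents the model
with spurious, generalization-free correlation against the structured X and
earns a far worse Q² than the observed y does, so permutation p-values pile
up near the floor even though nothing is planted. This is a property of the
synthetic construction, not of the method. Calibration checks of the
permutation test therefore use a fully signal-free configuration
(`organ_structure_sd = 0`, predictors independent of the response), where
exchangeability — the actual premise of a permutation test — holds. The
alternative (organ offsets independent of, rather than orthogonal to, the
activity contrast) would be worse: organ-structured predictors genuinely
predict an organ-driven response even with zero active ions.

## Numerical choices and degenerate inputs

* Zero-variance ion columns are centered only and flagged; zero-variance
  response is an error (nothing to model).
* Constant ions in pruning: correlation treated as 0, logged, never fatal.
* NIPALS orthogonal extraction stops early if no orthogonal variation
  remains (‖w_o‖ < 1e-12).
* Fold assignment: seeded permutation, round-robin within strata; leave-one-
  out is the k = n boundary and is supported.
* All randomness flows from explicit seeds; identical (config, seed) runs
  are byte-identical on serialization, which the manifest checksums make
  checkable end to end.

## Problem sizes in the test suite

The default scenario (54 samples, 230+190 pre-filter ions) is used where the
full design matters: recovery over 20 seeds, the end-to-end qualitative
pattern, the acceptance script. Null calibrations use 100 seeds at ~30+25
ions and 50 permutation runs at 39 permutations each; the statistics
calibration uses 1000 null replicates of 6 groups × 9 samples. These sizes
give stable Monte-Carlo estimates while keeping the whole suite under a
minute on one CPU.

## Known limitations

* One predictive component and a single response only; no OPLS-DA, no
  multi-Y, no VIP statistics.
* The loading-coordinate threshold of 5 is scaling-dependent; it is a
  calibrated default for uv-scaled data at n ≈ 54, not a universal constant.
* The exact letter display is exponential in the number of groups; beyond
  ~12 groups a heuristic display would be needed.
* IC50 interpolation cannot extrapolate: extracts that never cross 50%
  inhibition in the tested range are reported as undefined rather than
  guessed.
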