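# Methods

This note documents the models, numerical choices and limitations behind
`coralmet`. Everything stated here is computed by the package's tests or
the acceptance script; nothing is asserted beyond what the code produces.

## Data model and preprocessing

A study is an MGF of consensus MS/MS spectra plus a feature × sample
intensity matrix with groups A, B, QC (pooled quality-control injections)
and blank. Intensities are arbitrary detector counts, non-negative; m/z is
in Thomson; retention times in minutes (stored as `RTINSECONDS` in MGF,
kept to 1e-6 min so the unit conversion round-trips exactly).

**Internal-standard normalization** divides each sample's column by the
spike-in's intensity in that sample, making the standard exactly 1
everywhere (hence idempotent). It removes per-sample injection/extraction
scale; it cannot remove per-feature technical noise.

**QC CV filter** keeps a feature when sd/mean over the QC injections is
below `cv_max` (default 0.30). The standard deviation uses the n−1
denominator: QC counts are small (5 by default) and the n−1 form is the
unbiased-variance convention. The filter runs after normalization by
default (configurable); the kept set grows monotonically with the
threshold.

**Scaling.** Unit-variance (autoscaling) divides centered columns by their
SD; Pareto by √SD. Constant columns are centered to zero and flagged
rather than divided. Scaling statistics are computed on the analysis
samples only (A and B), never on QC or blank columns, because the models
compare the two groups.

**Log transformation.** Untargeted intensities are multiplicative and span
orders of magnitude. The pipeline log-transforms (natural log, offset =
half the smallest positive value so zeros stay finite) before both the
univariate tests and the multivariate models, then applies the scaling
schemes above. Two concrete reasons, both visible in the test suite:
multiplicative noise is normal on the log scale, so the Shapiro–Wilk gate
routes features to the t-test instead of the low-powered rank test (at
n = 8 vs 4, a Mann–Whitney p can never pass Benjamini–Hochberg over
hundreds of features — its smallest achievable two-sided value is
2/C(12,4) ≈ 0.004); and on the raw scale Pareto-scaled OPLS-DA weights are
dominated by high-abundance features, which halves VIP sensitivity for
low-abundance planted signals. Both transforms can be disabled in the
pipeline config (`log_transform_tests`, `log_transform_multivariate`).

## Modified cosine and networking

Peaks below `min_intensity` (default 20 000 counts) are removed first.
For spectra a, b with precursor difference Δp = prec_b − prec_a,
candidate pairs are (i, j) with |mz_i − mz_j| ≤ 0.02 Da (direct) or
|mz_j − mz_i − Δp| ≤ 0.02 Da (shifted). Intensities are square-rooted and
each spectrum's √-intensity vector normalized to unit Euclidean norm; a
pair contributes the product of its normalized weights. A one-to-one
matching is chosen greedily by descending pair score, ties broken by
smaller |mass error| then lower peak indices, making the result
deterministic and symmetric. By the rearrangement/Cauchy–Schwarz bound the
score lies in [0, 1] and self-similarity is exactly 1.

Greedy matching is not optimal in the worst case (two peaks inside one
tolerance window can force a suboptimal assignment), but on random and
analog-structured spectra with ≤ 8 peaks it reproduces the exhaustive
maximum-weight matching in 1000/1000 cases (acceptance suite, exhaustive
branch-and-bound oracle).

Network edges require score ≥ 0.7 and ≥ 2 matched peaks; an edge survives
only if it is within the top-10 edges of both endpoints, and components
larger than 100 nodes are pruned lowest-score-edge-first. The 0.7/2/0.02
Da/20 000 values are the workflow defaults of the emulated study; top-k
and the component cap are the usual FBMN defaults, exposed in the config.

## Analog annotation

Given an annotated spectrum, an unknown neighbor, and the diagnostic
head-group fragment series of the annotated compound's class (the
glycerophosphocholine series 86.0968 / 104.1072 / 184.0730 / 240.0991 is
packaged), every unknown peak within a ±25 Da search window of a
diagnostic fragment proposes a shift. The shift supported by the most
fragments (ties → smallest magnitude) is taken as the dissociation-pattern
displacement; each fragment then contributes its nearest candidate, and
the median is the consistent shift. A plain nearest-peak rule is not
enough: a 12 Da head-group shift is smaller than the spacing of the
diagnostic series, so the nearest unknown peak to one fragment can be
another fragment's shifted image.

Classification (all deltas signed unknown − known):

* dispersion (max |shift − median|) > 0.01 Da, or fewer than two
  fragments recovered → `unclassified` with a reason;
* |shift| ≤ 0.005 Da and |parent Δm| within 0.02 Da of k·14.01565 (k =
  1…10) → `chain_homolog`;
* |parent Δm − shift| ≤ 0.005 Da → `head_group_substitution`;
* otherwise, both components non-negligible → `mixed`.

The 0.005/0.01 Da tolerances correspond to ~5 ppm accuracy over the
relevant m/z range; 14.01565 Da is the exact CH₂ unit. The packaged
worked-example MGF contains the annotated lyso PC P-18:0 spectrum
(m/z 508.3752) and its two analogs at 507.3549 and 522.3905; the
507.3549 fragment list is the published one, while the 522.3905 fragment
list is constructed from the published 11.9997 Da shift (only the shift,
not the list, is printed) and its intensities are representative
stand-ins — shift inference does not use intensities.

The unsaturation index UI_x = Σ_y(%lipid_y · db_y)/100 is linear in
double-bond counts and order-invariant. Because the percentage basis is a
modelling choice, `abundance_percentages` supports percent-of-total-signal
and percent-within-class bases explicitly rather than fixing one.

## Statistics

**Gated univariate test.** Shapiro–Wilk on each group (≥ 3 values
required); both p ≥ 0.05 → two-sided t-test, else Mann–Whitney U. Welch's
unequal-variance t is the default because the group sizes are unequal
(8 vs 4); a flag restores the pooled form. A constant group cannot be
called normal and routes to the rank test; input constant across both
groups returns p = 1 with a flag. Correction is Benjamini–Hochberg
step-up ("corrected p" without a named procedure is interpreted as BH; the
method string is configurable).

**PCA/Hotelling.** SVD-based PCA of the unit-variance-scaled matrix;
T²ᵢ = Σₐ t²ᵢₐ/λₐ over the retained components with the 95% bound
k(n²−1)/(n(n−k))·F₀.₉₅(k, n−k).

**OPLS-DA.** Single-response O-PLS: w ∝ X'y normalized; the loading of the
X-score is split into its component along w and an orthogonal remainder
w_o; t_o = X·w_o is deflated from X; repeat; finally one predictive
component t = X·w, q = y't/t't. R²X sums the variance captured by all
components over ‖X‖²; R²Y = 1 − ‖y − tq‖²/‖y‖² (y centered 0/1). The
orthogonal-component count is chosen by cross-validated Q², stopping at
the first decrease (up to 5); only cumulative metrics are reported, so a
parsimony-based stopping rule is the natural choice.

**Cross-validation.** Q² = 1 − PRESS/SSY over stratified k-folds (default
7). Folds are dealt round-robin within class from a seeded permutation —
a hand-rolled scheme because standard stratified splitters refuse more
folds than the minority class count (7 > 4); any training fold losing a
class entirely raises. k = n reduces to leave-one-out. Scaling is refit
on each training split, so no statistics leak from held-out samples.

**VIP.** With one predictive component and unit-norm w,
VIP_j = √p·|w_j|, so mean(VIP²) = 1 exactly (asserted to 1e−10 on every
fit). A SIMCA-style "total" variant additionally weighting orthogonal
components by explained X-variance is provided behind a flag;
predictive-only is the default since the orthogonal part is by
construction unrelated to class separation.

**Permutation test.** The observed model fixes the component count; y is
randomly permuted `n_perm` = 200 times, each refit yields R²Y and Q², and
the empirical p is the add-one estimator (1 + #{Q²_perm ≥ Q²_obs})/201
(avoids p = 0 at finite n_perm). A drawn permutation that reproduces the
original partition is redrawn — it re-indexes the same split rather than
providing a null relabeling, and with n = 12 (8/4) such draws occur in a
non-negligible ~1/495 of permutations. R²/Q² intercepts are reported from
the regression of each statistic on |corr(y_perm, y)|.

**Screening** declares a feature differential iff VIP > 1 and adjusted
p < 0.05; direction comes from the group means. Significance is monotone
in both thresholds. **Shannon diversity** H = −Σ Pᵢ log₂ Pᵢ over detected
features (0·log 0 = 0; probabilities that underflow to zero are dropped).
**Venn counts** call a feature detected in a group if any sample exceeds
the detection floor (default 0). **Pathway ORA** is the one-sided
hypergeometric tail on the background-intersected pathway, BH-corrected
across tested pathways; pathways empty after intersection are skipped
with a note.

## Synthetic generator

The generator plants exactly the structure the pipeline is meant to
detect; defaults mirror the emulated design.

* Samples: 8 group A, 4 group B, 5 pooled QC, 1 blank.
* Abundances: per-feature log-normal baselines (σ_log uniform in
  [0.5, 1.5] around a 2·10⁵-count scale). Differential features (10% by
  default) have group-B means multiplied by 2^(±2) with random sign.
* Noise: measured = base · effect · s_j · ε_ij with a per-sample
  injection-scale factor s_j (log-normal, CV 0.10) shared by all features
  and per-cell technical noise ε (log-normal, CV 0.20). The internal
  standard is spiked at a constant amount and carries only s_j, so raw QC
  CVs exceed the technical CV while IS-normalized QC CVs converge to it —
  this is what makes normalization demonstrably useful and the QC filter
  interpretable.
* QC samples measure the pooled mean of the analysis groups; blanks are
  zero (background-free idealization).
* Group-exclusive features (3 unique-to-A, 10 unique-to-B by default —
  the published Venn is likewise asymmetric) are zeroed in the other
  group, emulating dropout below the detection floor. They are genuine
  differential signal and the ground truth records them as such.
* Analog families: each family is a distinct compound class — its head
  fragment series is the glycerophosphocholine series offset by
  53.71 Da·family and its seed parent offset by 91.37 Da·family. The two
  offsets are deliberately unequal: if they matched, the precursor delta
  between two families would re-align their head series and the modified
  cosine would (correctly) link them, merging planted families. Members:
  the seed, one head-group analog (fragments shifted by the family's head
  delta — 1.0204, 11.9997 or 19.9684 Da — and parent by 0.0001 Da less,
  as the published analog pair shows), and one CH₂ chain homolog (head
  fragments unchanged, chain fragments and parent shifted by 14.0157 Da).
  Peak intensities are jittered ±10% per member.
* Determinism: a single `numpy` Generator seeded from the config; the
  same config yields byte-identical MGF/CSV/TSV output (floats written
  via shortest-round-trip repr).

What the generator does **not** emulate: chromatographic peak shapes, RT
drift, isotope patterns, adducts, correlated biological variation beyond
the group effect, batch structure, or real blank contamination. Passing
tests therefore demonstrate the correctness and statistical behavior of
the algorithms under the stated noise model, not performance on raw
instrument data.

## Problem sizes and acceptance quantities

The reference evaluation uses the default design (500 features, 8 vs 4
samples) — large enough for BH correction and VIP normalization to be
meaningful, small enough that a full 20-seed recovery sweep plus a
200-permutation test completes in tens of seconds. `scripts/acceptance.py`
recomputes, per run seed: the worked-example shifts (1.0204 Da fragment
shift; 14.0153 Da parent delta), summary percentage arithmetic
(2044/3815 → 53.6, 1771/3815 → 46.4, 160+190 → 350), 1000-case
greedy-vs-exhaustive matching agreement, analog-family recovery,
OPLS-DA R²Y/Q²/mean VIP², the permutation p, and 20-seed screening
sensitivity and false-discovery proportion.

## Known limitations

* The OPLS-DA VIP is predictive-only by default; SIMCA's total-VIP
  variant can rank differently on models with strong orthogonal
  structure.
* Greedy peak matching can be suboptimal when several peaks crowd one
  tolerance window (not observed on the tested spectrum classes).
* The analog classifier assumes the diagnostic series is supplied per
  compound class; it does not discover diagnostic ions de novo.
* Blank samples are read and carried but not subtracted — background
  handling beyond QC filtering is out of scope.
* Pathway ORA requires a user-supplied pathway→metabolite map; no pathway
  database ships with the package.
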