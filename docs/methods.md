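# Methods

## Signal-to-graph model

`ergraph` analyses short transient single-channel recordings — in the
motivating application, light-adapted (photopic) electroretinograms of
roughly 200–300 ms sampled at 2 kHz (N ≈ 400–600 samples). Each recording
is treated as one complete physiological response and mapped to one graph
in three stages:

1. **Normalization.** Min-max scaling per waveform,
   x(t) = (x̃(t) − min x̃)/(max x̃ − min x̃) ∈ [0, 1]. Topology thus
   reflects relative amplitude dynamics, independent of electrode gain or
   impedance. A flat signal leaves the map undefined; it is sent to the
   all-0.5 constant and flagged degenerate rather than raising, so batch
   pipelines stay total (downstream it yields the single-node self-loop
   graph).
2. **Quantization.** q(t) = round(x(t)·(Q−1))/(Q−1) with Q ≥ 2 levels.
   The tie rule is round-half-away-from-zero on x·(Q−1) (0.5 rounds up),
   fixed explicitly because the platform default banker's rounding would
   make outputs platform-dependent. The level spacing ε = 1/(Q−1) is also
   the resolution bound: |x(t) − q(t)| ≤ 1/(2(Q−1)).
3. **Graph construction.** Nodes are the *visited* levels; every
   consecutive sample pair contributes an undirected edge between its two
   levels with inverse-distance weight w(v_i, v_j) = 1/(|l_i − l_j| + ε).
   ε prevents division by zero on self-loops (weight Q−1), which arise
   when the signal dwells at one level.

The printed weight is a function of the two levels alone, while repeated
transitions are described as accumulating strength; we store both — a
level-determined `weight` and an integer `count` of transitions — and use
`weight` in the adjacency/Laplacian by default, with
`use_count_weight=True` multiplying the two for sensitivity analysis.
Self-loops are kept on the graph but excluded from the adjacency,
Laplacian, degree, density and clustering views: L = D − A is invariant
to self-loops under the standard convention and the density denominator
V(V−1) presumes a simple graph.

Five comparison constructions are provided: natural visibility graph
(O(N²) running-max-slope sweep), recurrence network (|x_i − x_j| < ε_r,
embedding dimension 1, delay 1, default ε_r = 0.1), k-nearest-neighbour
graph in amplitude space (k = 3, ties to the earlier time index,
symmetrized union), ε-ball graph on visited levels (default
ε_b = 2/(Q−1), connecting adjacent and next-adjacent levels), and ordinal
partition network (patterns of dimension m = 3, delay 1, ties resolved
earlier-index-smaller).

## Features

Nine per-graph descriptors: total load centrality (the unnormalized
betweenness-style sum over unordered pairs of σ_st(v)/σ_st — note the
field's "load centrality" sometimes denotes a path-splitting variant that
differs on some graphs; we implement the summed-fraction form), total
harmonic centrality Σ_v Σ_{u≠v} 1/d(v,u), number of maximal cliques
(Bron–Kerbosch), diameter, radius, average clustering coefficient (c_v = 0
for degree < 2), average path length over ordered pairs, algebraic
connectivity λ₂ of the weighted combinatorial Laplacian, and density
2E/(V(V−1)).

Distances default to hop counts on the self-loop-free graph: the weighted
graph admits several distance conventions, hop counts avoid an arbitrary
weight→length mapping, and they are consistent with diameters of order
5–20 on ≤ Q-node graphs. A weighted mode (length = |l_i − l_j| + ε) is
available behind `weighted_paths=True` for the level-based constructions.
Whether λ₂ should come from the weighted or an unweighted/normalized
Laplacian is genuinely open; weighted combinatorial is the default and
the unweighted value is obtainable by passing an unweighted graph.

Disconnected graphs (possible for recurrence/ε-ball constructions at
small thresholds) follow a giant-component policy: diameter, radius, APL
and λ₂ are computed on the largest connected component with a logged
warning; `strict=True` raises instead. TLC, THC, GNC, CC and density are
well defined without connectivity and always use the full graph.

Standard graph algorithms are delegated to networkx and the dense
symmetric eigensolver to scipy (node counts are ≤ Q ≈ 50–100, so no
iterative solver is needed); the test suite validates every feature
against independent brute-force oracles (Floyd–Warshall, exhaustive
clique subset enumeration, A³ triangle counts, dense eigendecomposition)
on 200 seeded random graphs at 1e−9 relative tolerance, plus closed forms
for complete, path, cycle and star graphs.

## Synthetic cohorts

Clinical recordings for this problem are not public, so the `synth`
module generates photopic-ERG-like waveforms: a sum of unit-height
Gaussian bumps (negative a-wave at 15 ms, dominant positive b-wave at
32 ms, late photopic negative response at 55 ms), a Gaussian-windowed
120 Hz sinusoid on the b-wave rising limb (oscillatory potentials), and
Gaussian noise low-passed at 300 Hz to match the acquisition band —
250 ms at 2 kHz by default (N = 500). Amplitudes are in microvolts at
skin-electrode scale (b-wave ≈ 10–40 µV).

Cohorts draw per-subject log-normal multipliers (σ = 0.15) on the four
component amplitudes and smaller within-subject repeat jitter (σ = 0.05),
so repeats of a subject resemble each other more than other subjects —
exactly the dependence structure subject-wise cross-validation must
respect. Subjects contribute 1–4 recordings per eye × flash combination;
the stronger flash (446 Td.s) scales amplitudes ×1.5 against a fixed
noise floor. `default_study_cohort()` mirrors the study population shape
(77/43/21/137 subjects across the four groups, with the co-occurring
group's morphology a convex blend of the two disorder styles).

Two style presets encode the group contrast the graphs must recover.
After per-waveform normalization, two mechanisms control topology:
the *relative noise floor* (noise sd ÷ component amplitudes) sets the
width of the local level flicker, raising density, clustering and λ₂ and
shrinking diameter/APL; *transient sharpness* sets how many levels the
a/b sweep skips per sample, lowering the visited-node count and with it
THC and the clique count. The COMPACT preset (reduced, sharpened
components against an unchanged noise floor) therefore yields dense,
clustered, small-diameter graphs and the EXPANSIVE preset (large smooth
b-wave, strong OPs) sparse, chain-like, large-diameter graphs — the
compact/expansive contrast reported for the clinical groups. The preset
constants were tuned once against this directionality property (all nine
feature signs, |Cliff's δ| ≥ 0.43 for diameter/APL/CC) and then frozen.
The directionality check uses the presets' base morphology (the 113 Td.s
condition): under the ×1.5 flash scaling the relative noise floor
shrinks and the clustering-coefficient contrast washes toward zero while
all other signs persist.

What the generator does *not* emulate: mechanistic retinal physiology,
realistic age/sex effects, artifacts, inter-site device differences, or
the actual effect sizes of the clinical data. Passing tests demonstrate
that the pipeline recovers a known planted contrast under realistic
acquisition parameters — not that the clinical findings replicate.

## Statistics

Group differences use the Kruskal–Wallis H test (tie-corrected, χ²
reference, via scipy), Dunn's post hoc z-tests on pooled tie-corrected
ranks with Bonferroni correction (implemented in-package; default post hoc
α = 0.017 = 0.05/3, surfaced as a parameter), and Cliff's delta with the
conventional bins — |δ| < 0.15 negligible, [0.15, 0.28) small,
[0.28, 0.43) medium, ≥ 0.43 large; bins are lower-closed/upper-open
except the closed "large" bound, resolving the prose ranges' boundary
ambiguity. A Shapiro–Wilk p-value per feature × group is recorded as
metadata only. Statistics pool recordings by default (samples, not
subjects); `per_subject_mean=True` averages within subject first.

## Classification pipeline

Scenario label maps: ASD-vs-control merges the co-occurring group into
the positive class (as does ADHD-vs-control); three-group drops it;
four-group keeps all labels. Right+left concatenation pairs rows on
(subject, flash, recording index) — the pairing key is our rule, since
only the combination itself is specified — and drops unpaired recordings
with a logged count.

Folds partition subjects, stratified by class via least-filled-fold
assignment after a seeded within-class shuffle. Stage 1 ranks features by
random-forest impurity importance (500 trees, fixed seed, stable sort on
ties); `top_k="auto"` picks k over the grid {3, 5, 7, 9, all} by inner-CV
balanced accuracy (grid bounds chosen to bracket typical selected-feature
counts of 5–20 in this problem family). Stage 2 runs 3-fold subject-wise
inner CV over the candidate classifiers with SMOTE applied to the
inner-training portion only; ties in mean inner balanced accuracy go to
the earlier registry entry (reproducibility over optimism). Stage 3
refits the winner on the full outer-train split (with SMOTE) and scores
the held-out fold.

SMOTE is implemented in-package as minority-class k-NN interpolation
(k = 5, parity target, k reduced to n−1 for tiny classes, skipped for
singletons); original rows always precede synthetic rows, and synthetic
rows never reach validation or test partitions — asserted by tests.

The registry holds exactly seven candidates with the named settings
(RF 500 trees; AdaBoost 200; GradientBoosting 200; XGBoost depth 6; RBF
SVM; 5-NN; MLP 128×64) and pins every remaining hyperparameter in
`CLASSIFIER_DEFAULTS`; scale-sensitive models are wrapped with
standardization. Metrics are balanced accuracy (mean per-class recall,
computed over classes present in the fold) and macro-F1.

An optional attribution hook reports mean-|SHAP| rankings when the
`shap` package is installed and falls back to scikit-learn permutation
importance otherwise.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use cohorts of 12–60 subjects
per group with N = 500 waveforms at Q = 50 (N = 160 for the
construction-comparison harness, where the time-sample constructions make
feature extraction quadratic in N), 10 outer folds, and cheap classifiers
(k-NN) wherever the property under test does not depend on the model; the
full seven-model registry is exercised on small tables. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
identical seeds give byte-identical cohorts, folds and serialized CV
results. Eigendecompositions use the dense symmetric solver; Laplacian
row sums are zero to 1e−9 and the multiplicity of the zero eigenvalue
equals the component count on every tested graph.

## Known limitations

- The generator is a phenomenological emulator; its effect sizes are
  planted, not estimated, so classification numbers on synthetic cohorts
  are not comparable to clinical results.
- Hop-count distances discard the edge-weight information for the path
  features; the weighted mode exists but has no external reference values.
- The recurrence-network and ε-ball constructions can disconnect at small
  thresholds; the giant-component policy then changes the meaning of the
  path features (logged).
- Per-signal monotone refinement of distinct-level counts in Q can fail
  for close value pairs (two values distinct at Q may merge at a larger
  Q); only the mean over signals is monotone, and the test asserts that.
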