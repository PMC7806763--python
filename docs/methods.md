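# Methods

## Scope and data model

The package analyzes per-subject regional time series (nodes × timepoints
at a fixed sampling interval) together with an atlas node table (node id,
label, lobe, hemisphere) and a subject table (group, age, sex, motion,
hallucination-modality flags, symptom score). All stages operate on a
canonical edge enumeration — the upper triangle of the node adjacency in
`numpy.triu_indices` order — so edge vectors, F-statistic arrays and
feature matrices are always column-aligned.

Real imaging data cannot be redistributed with the package, so a
synthetic cohort generator provides study-shaped inputs; the pipeline
itself is agnostic to whether time series were simulated or loaded from
files.

## Synthetic cohort generator

**Subjects.** Five groups (HC, NC-H, SCZ-H, BD-H, BD) with default sizes
228/40/99/74/42 (483 subjects). Per-group covariate distributions mimic
the reference cohort: age is normal (e.g. HC 40.7 ± 14.6 years, SCZ-H
32.3 ± 10.9, clipped to 18–90), sex a Bernoulli draw at the group's male
fraction, motion (relative mean displacement) normal with group means
0.08–0.10 mm truncated at a small positive floor. Modality flags are
drawn at the group's lifetime-auditory/visual rates; HC and BD always
carry `false/false`, and hallucination-group subjects endorse at least
one modality. Symptom scores (a gamma(4, 2) stand-in for a severity
scale) exist only for groups in which severity was assessed (NC-H,
SCZ-H); elsewhere the score is missing and written as an explicit `NA`
sentinel, never dropped.

**Signals.** Baseline node signals are white Gaussian noise band-passed
to 0.01–0.15 Hz (4th-order Butterworth, zero-phase, padded by 64 samples
on each side before the kept window) and standardized to unit variance.
The default sampling interval is 0.625 s (fs = 1.6 Hz) so the level-4
wavelet scale spans exactly 0.05–0.10 Hz; both are configurable.
Default length is 256 timepoints.

**Planted effects.** An effect is (target group, edge set, direction,
shared variance s). Each effect owns one latent source z(t), band-limited
to 0.05–0.10 Hz and drawn fresh per subject; for subjects the effect
applies to, every node touched by the edge set receives `√s·z`, and the
node's baseline noise is scaled by `√(1−S)` with S the node's total
shared variance (an error is raised if S ≥ 1). Consequences worth
knowing:

- all node pairs inside one effect's node set gain coherence, the listed
  edges among them — a connected planted component is representable at
  any s < 1;
- `increase` mixes the source into the target group only; `decrease`
  mixes it into everyone *except* the target group, so the target sits
  below the cohort baseline (the paper-facing notion of reduced
  connectivity) — both directions are detected by the same unsigned F;
- an effect with `visual_only=true` applies only to target-group
  subjects with visual hallucinations, giving the modality classifier a
  recoverable signal.

Optional knobs: a broadband common source scaled by the subject's motion
value (`motion_nuisance`) and a global band-limited source whose shared
variance rises with standardized age and male sex
(`age_sex_coherence`), used to exercise covariate adjustment. Both
default to 0.

**What the generator does not emulate:** hemodynamics, spatial structure
or realistic motion artifacts, autocorrelated scanner noise,
heavy-tailed weight distributions, or site effects. Passing tests
therefore demonstrate the statistical machinery is correct and
calibrated under exchangeable band-limited Gaussian signals, not that
any particular clinical finding generalizes.

## Connectome construction

The MODWT is implemented as the standard non-decimated pyramid with
filters rescaled by 1/√2 per level, computed by circular convolution
with upsampled filters via the FFT. The default filter is the
least-asymmetric length-8 wavelet (`sym4`); the default boundary rule
("reflection") extends the series with its time-reverse before the
circular transform, and boundary coefficients are retained. The level-j
detail isolates [fs/2^(j+1), fs/2^j]; the per-scale coefficient
variances sum to the signal variance (verified to 5% on white noise).

Edge weights are Welch magnitude-squared coherence between level-4
detail series: segment length timepoints/8 rounded down to a power of
two (minimum 16), 50% overlap, Hann window, per-segment constant
detrend, averaged over the frequency bins inside the scale band. The
all-pairs implementation computes each node's windowed segment FFTs once
and forms the cross-spectral array by einsum; it matches
`scipy.signal.coherence` on every pair to rounding error (tested).
Zero-variance signals make coherence undefined and raise with subject
and node context. Whether to compute coherence on detail coefficients
(done here) or on band-passed raw series is a genuine ambiguity of the
method; coefficients were chosen because the transform is the stated
filtering step, and the band/estimator settings are exposed for the
alternative.

## Global graph metrics

- **Weighted global efficiency**: mean over ordered pairs of 1/d(i,j)
  with Dijkstra shortest paths on edge lengths 1/w; unreachable pairs
  contribute 0, so the metric is defined on disconnected graphs.
- **Weighted clustering**: Onnela geometric-mean triangle intensity with
  weights used as-is (they are already in [0, 1]); nodes of degree < 2
  contribute 0.
- **Spanning tree**: maximum spanning tree on the coherence weights
  (equivalently minimum on 1−w), the convention of the brain-MST
  literature; Kruskal with a deterministic scan order (weight
  descending, then node-pair lexicographic) so ties never make results
  run-dependent. Reported: leaf fraction `leaves/(N−1)`, hop diameter
  (double-BFS, exact on trees) and the normalized diameter
  `diameter/(N−1)`.
- **Group comparison**: per metric, the partial F for the group factor
  in `metric ~ group + covariates` (age, sex by default), the same
  linear-model machinery the NBS uses, so a single code path is tested
  against the normal-equations oracle.

## Network-Based Statistics

Design matrices use treatment-coded group dummies plus covariates
(numeric as-is, categorical as dummies). The per-edge partial F is
computed for all edges simultaneously from QR decompositions of the full
and reduced designs. Edges constant across subjects have an undefined F
(0/0) and are reported as F = 0 with a degeneracy flag.

Suprathreshold edges (F ≥ T, default T = 8.0 for every contrast — the
one threshold printed for the omnibus contrast, configurable per run)
form a graph whose connected components are scored by extent (edge
count). The null distribution of the maximum extent is built by
Freedman–Lane permutation: residuals of the covariates-only model are
permuted, the reduced fit added back, and the full-model F recomputed,
keeping covariates attached to subjects. Plain label permutation is
available as an option. One permutation stream (seeded) is shared across
edges within a test, preserving edge exchangeability. The FWE p-value is
`(1 + #{max_perm ≥ extent})/(1 + n_perm)`, bounded below by
1/(n_perm+1) and never zero.

Direction labels are assigned post hoc: for each suprathreshold edge the
sign of the covariate-adjusted mean difference (non-reference groups
minus the reference group, the contrast's first group) labels the edge
`increase` or `decrease`. The unsigned-F-plus-post-hoc-sign reading was
chosen over paired directional tests because a single F per edge with
two-sided sensitivity matches the reported analysis structure; adjusted
means come from a cell-means model with centered covariates.

Subjects are internally sorted by id before testing, making results
invariant to input order. Default 10,000 permutations; the simulation
studies use 500, which bounds the attainable p at 1/501 ≈ 0.002 — ample
for an alpha of 0.05.

## Component characterization

Lobe-pair proportions divide the count of altered edges joining each
unordered lobe pair by the total altered-edge count (entries over
unordered pairs sum to 1; presented symmetrically). Degree rankings sort
nodes by within-component degree, ties broken by label. Conjunction is
strict intersection of unordered edge sets, no spatial tolerance.
Symptom correlations are Spearman rho (tie-corrected, pairwise deletion
of missing scores, minimum 4 pairs) with Benjamini–Hochberg adjustment
across the tested family. The demographics summary reports per-group
mean (SD) with one-way ANOVA for continuous variables and counts with
percentages on the full group denominator plus Pearson chi-square
(no continuity correction, df = (groups−1)(levels−1)) for dichotomous
ones; a chi-square over non-missing denominators is available by flag.

## Edge clustering

Profiles are covariate-adjusted group means per component edge (the same
cell-means model as NBS direction labeling). K-means uses k-means++
seeding, Lloyd iterations and 50 restarts; k defaults to 6, mirroring
the six connection sets the reference analysis reports, with an optional
silhouette-based selector (off by default, since how k was originally
chosen is unknown). Profiles are not z-scored per edge by default —
standardization would erase the increased-versus-decreased level
information the clusters are meant to express. Cluster ids are
canonicalized by (size descending, first-group centroid value), so
labelings are reproducible and invariant to row order.

## Modality random forest

The ensemble is built in-package from scikit-learn CART trees because
out-of-bag bookkeeping per tree (needed for OOB permutation importance)
requires owning the bootstrap: 500 trees by default, each grown on an
n-out-of-n bootstrap with `m_try = round(√p)` candidate features per
split, Gini criterion, leaves down to size 1. OOB predictions are
majority votes of the trees not trained on a subject (with 500 trees
every subject receives votes). VIMP is the mean over trees of the OOB
accuracy drop when one feature is permuted among that tree's OOB rows,
min–max scaled to [0, 1]. Metrics: sensitivity and specificity are class
recalls; weighted accuracy is the prevalence-weighted recall average,
which reproduces the reference triple (0.175×0.0 + 0.825×93.9 = 77.5)
where a balanced average would not. Class convention: "visual" marks
subjects with visual hallucinations (possibly plus auditory); "auditory"
means auditory-only. Features are the edge weights of the subject's
group-specific NBS component.

## Pipeline

`run_pipeline` executes simulate/ingest → connectomes → global metrics →
NBS contrasts (defaults: each group versus HC, plus the three-group
omnibus) → characterization → k-means on the omnibus component → random
forest per hallucination group, writing a results bundle of TSV tables
and JSON files plus a run manifest (version, seed, config digest). Stage
seeds are spawned from the global seed via `numpy.random.SeedSequence`,
so a config + seed pair reproduces the bundle byte-for-byte, and
stand-alone CLI stage commands share the orchestrated code path so their
numbers cannot drift from `run-all`.

## Numerical and testing choices

- Validation thresholds: degenerate-edge detection uses a relative
  1e-12 tolerance; connectivity matrices are validated symmetric within
  1e-10 and clipped to [0, 1] after validation.
- Simulation studies (also used by `scripts/acceptance.py`) run at desk
  scale — 30 nodes, 256 timepoints, 500 permutations: null calibration
  over 200 replicate cohorts (15/group), planted 10-edge recovery at
  shared variance 0.5 over 25 replicates (25/group), and
  concordant/inverted recovery over 20 replicates (20/group, two 5-edge
  paths sharing a node so the planted sets form one component). These
  sizes give stable rates in about a minute of compute.
- Oracles in the test suite are independent of the implementation:
  exhaustive path/spanning-tree/partition enumeration for the graph
  metrics and k-means objective, t²-identity and normal equations for
  the edge GLM, `networkx` connected components for the union-find,
  rank-then-Pearson for Spearman.

## Known limitations

- The generator's Gaussianity means coherence estimates are better
  behaved than in real fMRI; permutation calibration under realistic
  noise must be established on real data.
- Freedman–Lane assumes the reduced-model errors are exchangeable;
  strong heteroscedasticity across groups would require a different
  scheme.
- Direction labels for omnibus (≥3 group) contrasts compress a
  multi-group pattern into one sign versus the reference group; the edge
  profiles from the clustering module are the faithful representation.
- The packaged 90-region lobe table follows the common lobar convention
  (hippocampus/amygdala temporal; caudate/putamen/pallidum, thalamus and
  peri-rolandic cortex central); alternative conventions can be supplied
  as custom node tables.
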