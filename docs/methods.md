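# Methods

`perfnet` implements group-level cerebral blood flow (CBF) covariance
network analysis for 3D pseudo-continuous arterial spin labeling (PCASL)
data, from voxelwise quantification through graph-theoretic group
comparison. This note records the models, the parameters that matter, the
numerical conventions, and the design choices made where the procedure is
genuinely under-determined.

## CBF quantification

Voxelwise CBF is computed with the single-compartment PCASL model

    CBF = 6000 · λ · (SI_control − SI_label) · e^(PLD/T1b)
          ─────────────────────────────────────────────────
          2 · α · T1b · SI_PD · (1 − e^(−τ/T1b))

in ml/100 g/min, where `SI_PD` is the proton-density-weighted calibration
image. Defaults: T1b (blood T1) = 1.4 s, τ (label duration) = 1.5 s,
λ (partition coefficient) = 0.9 ml/g, PLD (post-labeling delay) = 2.025 s,
α (labeling efficiency) = 0.8. Two caveats are deliberate:

* A PLD of 2.025 s is used for quantification even though such protocols
  are usually described with a nominal PLD of 2,000 ms; the value is
  configurable and the discrepancy between nominal and effective delay is
  surfaced here rather than silently resolved.
* T1b = 1.4 s is low for 3 T (1.6–1.65 s is more common); it is kept as the
  default for consistency with the GE product quantification it mirrors,
  and is configurable.

The factor 6000 is a pure unit conversion (ml/g/s → ml/100 g/min) and is
not exposed. Voxels with SI_PD ≤ 0 or outside the brain mask carry NaN, not
±inf, so invalidity cannot leak into correlations; negative CBF values are
retained (clipping would bias regional means). If a 4D series of
control/label pairs is supplied, pair differences are averaged after
subtraction, the standard product behavior. Motion correction, brain
extraction and registration are out of scope: the package consumes
co-registered volumes.

## Parcellation

An integer label volume on the CBF grid (246 positive labels for the
bundled whole-brain atlas convention) reduces each map to regional means
over valid voxels — i.e., voxels under the label that survive the brain
mask and quantification validity. A region with no valid voxel is missing
(NaN) for that subject, and any region missing in any subject of a group is
excluded from that group's network with a warning, because Pearson
correlation needs complete columns. Region order is ascending label id
everywhere, and all outputs carry region ids explicitly.

## Network construction

For each group the network is the R × R matrix of Pearson correlations of
regional CBF **across subjects** (structural/perfusion covariance). Two
under-determined conventions are explicit configuration:

* **Normalization** (default `global-mean`): each subject's row is divided
  by its own mean before correlation, removing between-subject global
  perfusion offsets that would otherwise inflate every correlation. `none`
  preserves the literal raw-correlation reading.
* **Sparsity** (default: fraction of possible edges *removed*): thresholding
  at sparsity s keeps exactly `round((1−s)·R(R−1)/2)` edges with the largest
  signed correlation, giving 17–35% density over the default grid
  0.65–0.83 (step 0.02) — the density range typical of this literature.
  Ranking by |r| is available (`use_absolute`); at these densities negative
  correlations are never selected under the signed ranking.

Ties at the cutoff break by ascending (i, j) region-id order, so thresholded
graphs are bit-reproducible, and edge sets are nested across the grid.
Graphs are binary and undirected; the metric definitions used are the
binary-graph forms.

## Graph metrics

* **Global efficiency**: mean inverse shortest-path length over ordered
  pairs, with 1/∞ = 0 for disconnected pairs.
* **Clustering coefficient**: per node, the fraction of closed triangles
  `2tᵢ/(kᵢ(kᵢ−1))` (0 when kᵢ < 2), averaged over all nodes.
* **Characteristic path length**: mean distance over ordered pairs within
  the largest connected component (the standard toolbox convention for
  possibly-disconnected thresholded graphs).
* **Betweenness centrality (BC)**: exact unnormalized Brandes betweenness
  with fractional counting of shortest-path multiplicity. Normalization is
  irrelevant to the hub rule, which is scale-invariant.
* **Small-world coefficient**: σ = (C/C_rand)/(L/L_rand) with C_rand and
  L_rand averaged over 100 degree-preserving random references (Maslov–
  Sneppen double edge swaps, 10·|E| swap attempts per reference, seeded).
  σ > 1 is read as small-world organization. The reference ensemble and its
  size are configurable; degree-preserving nulls are the field default.
  The swap kernel is JIT-compiled when numba is importable, with a
  bit-identical pure-Python fallback.
* **Hub rule**: a region is a hub when its BC strictly exceeds twice the
  mean BC over all regions ("two times higher" read literally as `>`). Hub
  sets detected in a reference group can be looked up by region id in the
  other groups' nodal tables.

All shortest paths are breadth-first (unweighted); distances come from
scipy's compiled BFS, triangles from a dense matrix product — both are
exact, and every metric is checked against exhaustive pure-Python
enumeration on small graphs in the test suite.

## Group statistics

All p-values are two-sided; the analysis reports both decreases and
increases.

* **Permutation tests** (global metrics over the grid; per-region BC at
  sparsity 0.83): subjects are pooled and reassigned to pseudo-groups of
  the original sizes; each pseudo-group's correlation network is rebuilt
  and thresholded inside every permutation — necessary because each group
  yields a single graph, so the graph statistic has no subject-level
  distribution. The permutation p uses the add-one estimator
  `(1 + #{|null| ≥ |obs|})/(1 + n_perm)` (never 0; 1,000 permutations by
  default). Pseudo-groups of 3 subjects are permitted inside the
  permutation machinery (the mathematical minimum for a sample
  correlation), while observed group networks require ≥ 4 subjects, the
  minimum for the Fisher-z variance 1/(n−3).
* **Edge comparison**: per edge, Z = (atanh r_A − atanh r_B) /
  √(1/(n_A−3) + 1/(n_B−3)) with a standard-normal two-sided p, then
  Benjamini–Hochberg FDR (default q = 0.001). The tested family defaults to
  the union of both groups' retained edges at sparsity 0.83; `family="all"`
  tests every pair. **Caveat**: the union family is selected by the same
  sample correlations being tested, so BH's FDR guarantee holds exactly
  only for the fixed all-pairs family; the union family inherits a mild
  selection-driven inflation (measured ≈ 8× the nominal 0.001 in
  simulation, still below 1%). Correlations at |r| = 1 are clamped to
  1 − 10⁻¹⁵ with a warning.
* **Regional t-tests**: per-region two-sample Welch t (pooled-variance
  Student's t available) with BH FDR at q = 0.05. Regions with zero
  variance in both groups are excluded from the family with a warning.
* The α conventions (0.05 for metrics/regions/nodes, 0.001 for edges) are
  defaults, not constants.

## Synthetic study design

Real 3D PCASL cohorts of this design are restricted-access, so the
generator produces the statistical structure the analysis assumes, with
recorded ground truth:

* Three groups, CN/MCI/AD-like, n = 53/43/30; 246 regions in 8 contiguous
  anatomically named blocks (frontal, temporal/parahippocampal,
  hippocampus, precuneus, parietal, occipital, cingulate, subcortical).
* Regional means drawn once from U(40, 80) ml/100 g/min (plausible
  gray-matter perfusion) and shared across groups, so every between-group
  mean difference is planted. Regional SD = 15% of the mean, a plausible
  between-subject variability for resting CBF.
* Correlation structure from an explicit factor model: a global factor
  (loading √0.1 everywhere → background r = 0.1) plus block factors
  (within-block r = 0.6). This modular structure makes the thresholded
  group networks small-world across the whole sparsity grid.
* **Planted hypoperfusion**: the temporal/parahippocampal block is reduced
  10% in MCI; in AD the reduction is 20% and extends into the hippocampus
  block (62 regions total at R = 246).
* **Planted decoupling**: 12 region pairs inside/between the hippocampus
  and precuneus blocks carry a private pair factor giving population
  r = 0.95 in CN and MCI — the scale seen for strongly coupled (e.g.,
  homotopic) pairs in covariance networks — which is removed in AD,
  returning the pair to the background r = 0.1. Pair members couple to the
  rest of the matrix only through the global factor, so both covariance
  matrices are positive-definite *by construction* and the CN−AD population
  difference is confined exactly to the planted pairs (an earlier
  set-and-project construction smeared the difference over the whole
  matrix and was abandoned; eigenvalue clipping is retained only as a
  safety net). The effect size follows a pre-hoc power calculation: at
  n = 53 vs 30 and BH q = 0.001 over a ~5,000-edge family, detection needs
  |Z| ≈ 4.7, and r = 0.95 → 0.1 gives an expected |Z| ≈ 6.5 (per-edge power
  ≈ 0.95 after the small attenuation from global-mean normalization).
* Rows are multivariate normal (Cholesky, seeded generator), truncated at
  zero (configurable off); at the default means truncation is negligible.

What the generator does **not** emulate: MR physics (coil sensitivity,
motion, background suppression), anatomy, spatial autocorrelation within
regions, non-Gaussian between-subject variation, and site/scanner effects.
Passing tests therefore demonstrate that the pipeline's inference machinery
is correct and calibrated under the assumed covariance model — not that the
effects would be recoverable at these rates in real cohorts.

A small voxel-level generator inverts the quantification equation on a
16×16×8 grid with angular-sector label volumes; it exists to test
quantification + parcellation end to end (exact round trip at zero noise),
not for realism.

## Problem sizes used in the test suite

The suite exercises the full 246-region, 53/43/30-subject design for
network construction, σ across the whole grid (100 references per graph),
and planted-effect recovery (20 seeds). Permutation-test calibration runs
at 40 regions with 200 replicates × 200 permutations, and metric-oracle
checks enumerate 500 random graphs of ≤ 8 nodes — sizes at which the
independent brute-force oracles are exact and the null calibration has
useful resolution.

## Known limitations

* Group-level covariance networks yield one graph per group; nothing here
  supports individual-level inference.
* The union-family edge test has the selection caveat described above.
* Permutation tests rebuild ~2·n_perm networks per sparsity and metric;
  with 1,000 permutations at 246 regions this is minutes of compute per
  pair, scaling linearly in n_perm and grid size.
* The hub rule (BC > 2× mean) is a convention, not an inferential
  statement; hub-set differences carry no p-value.
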