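# Methods

`popmanifold` re-implements, as a tested library, an unsupervised pipeline for
characterizing the population-activity manifold of two-photon calcium-imaging
sessions recorded during a go/no-go discrimination task: intrinsic-dimension
estimation, spectral embedding, topological shape comparison, central-cloud
clustering, behavioral parameterization, and cross-session trial-outcome
decoding.  Real sessions of this kind are not redistributable, so the package
ships a synthetic-session generator with full ground truth; every stage is
validated against that ground truth or against independent mathematical
oracles.

## Preprocessing

ΔF/F traces (nominally 31 Hz) are down-sampled by averaging every 15
consecutive frames (~0.5 s bins; the exact bin width is
`frames_per_bin / frame_hz`, and event bins are `floor(t / bin_s)` so frame
and time indexing agree exactly).  A trailing partial bin is dropped.  Neurons
whose maximum ΔF/F exceeds a per-microscope threshold (2000% or 5000%) are
excluded before binning — the outlier statistic is the session-wide maximum,
and exclusion operates on raw frames because the artifacts it targets are
single-frame transients that binning would dilute.  Each remaining neuron is
z-scored with the population-SD convention (divisor *n*), either over the
whole session or per acquisition run (`per_run_zscore`) when runs are not
directly comparable.

## Intrinsic dimension

The two-nearest-neighbor estimator: for each time bin (a point in neuron
space) the ratio μ = r₂/r₁ of second-nearest to nearest Euclidean neighbor
distance follows, on a locally uniform d-dimensional manifold, a Pareto(d)
law.  The empirical CDF is F(μ) = rank/(n+1) (avoiding log 0), the top 4% of
ratios are discarded (boundary effects corrupt the tail), and d̂ is the slope
of the origin-constrained regression of −log(1−F) on log μ.  Some
presentations print the inverted ratio r₁/r₂; the r₂/r₁ orientation is used
here so the slope is directly the dimension — the two differ only in sign
conventions.  Duplicate points are an error at the API surface (r₁ = 0 makes
the ratio undefined); the iterative wrapper merges bins that collapse to one
point during reduction (rounding at 1e-9, far below coordinate scale) before
estimating.

Because the estimate should be invariant to the embedding dimension, the
iterative procedure re-estimates after spectral reductions to each requested
intermediate dimension and reports the value at the plateau — the smallest
intermediate dimension whose estimate lies within 1 of the previous stage.
The plateau rule is a package decision (the idea of iterating across
reductions fixes no explicit stopping rule); it is monotone, deterministic,
and validated on sessions with a known 6-dimensional latent space
(recovered within ±1.5).  A neuron-subsampling control (`subsample_control`)
repeatedly estimates on random fixed-size neuron subsets so sessions with
different neuron counts can be compared fairly.

## Spectral embedding

Two rounds of Laplacian eigenmaps on the binned matrix, time bins as points.
The graph is *mutual* kNN — an edge requires each point to be within the
other's K nearest neighbors — binarized, symmetric, zero diagonal.  Round 1
reduces neuron space to 20 dimensions with K = round(0.075·T); round 2
reduces those 20 to 6 with K = round(0.025·T) (K floored at 2).  The
generalized problem L f = λ D f (L = D − W) is solved through the symmetric
normalization; eigenvectors are D-orthonormal, ordered by ascending
eigenvalue, the constant leading one dropped, and each column's sign is fixed
by making its largest-magnitude entry positive so the embedding is
deterministic.  Mutual kNN at these K values is virtually always connected;
if not, the minimum-spanning-tree edges of the Euclidean distance matrix are
added (minimal, deterministic repair, flagged in the graph summary) and a
still-disconnected graph is an error listing component sizes.

## Topology

Manifold shape is summarized by persistent homology of the embedded cloud,
condensed to 80 K-means landmarks; because K-means is stochastic the
condensation is repeated 20 times.  Vietoris–Rips persistence is computed in
degrees 0 (components) and 1 (loops), in-package: degree 0 by Kruskal
union-find (component death radii are the merge weights — identical to
single-linkage heights, which the test suite uses as an independent oracle),
degree 1 by GF(2) reduction of the triangle boundary matrix with the clearing
shortcut.  The filtration is capped at the landmark diameter, where the
2-skeleton is complete and contractible, so every loop dies; the one
infinite component is excluded (it exists for every dataset and carries no
comparative information).  Zero-lifespan pairs are dropped.

Two datasets are compared by the mean order-1 Wasserstein distance between
their per-repetition lifespan distributions across all 20 × 20 pairings
(lifespans are compared as 1-D distributions, not as persistence diagrams).
The permutation test pools the two lifespan lists of matched repetitions,
re-splits at the original sizes 200 times, and reports the mean over
repetitions of the fraction of permuted distances *strictly below* the
observed distance.  Note the direction: a small p says the observed distance
is smaller than expected under exchange — evidence of topological
*similarity*.  That printed convention is implemented as stated rather than
"corrected"; under the null the p-value is approximately uniform, which the
calibration tests verify (mean p ≈ 0.5 over 50 seeds).

## Central-cloud clustering

Time points nearest the embedding centroid (ascending Euclidean distance,
ties by bin index) form the central point cloud.  The configuration —
central-cloud size n_exc and K-means K — is chosen on a grid: n_exc runs in a
12-step geometric progression from 40 toward T (cells keep at least 40
points), K from 2 to 20.  Each cell holds the mean over 20 seeded K-means
repetitions of the within-cluster summed squared error (inertia).  The sum —
not a per-point mean — is essential: excluding central points removes the
cheapest points first, so a per-point mean is nearly flat along the exclusion
axis and the optimization would always prefer minimal exclusion.  Both grid
axes and the error are min–max scaled to [0, 1] and the cell nearest the
origin of the scaled 3-D system wins: few exclusions, few clusters, low
error.  On long sessions (T > 3000) the scan uses mini-batch K-means for
tractability; the consensus stage always uses full Lloyd iterations.

Final labels are consensus-based: 500 seeded K-means runs at K\* on the
non-central points, a co-association matrix (fraction of runs grouping two
points together — invariant to per-run label permutations), and hierarchical
clustering of 1 − co-association cut at K\* groups.  Ward linkage is the
default with complete linkage as an option (the two names are given jointly
in the method's source description, which is self-contradictory; Ward is
named first and behaves better on co-association matrices).  Central points
get the sentinel label −1; clusters are 1..K\*.

## Behavioral parameterization

Each of the six trial-outcome classes (reward hit/miss, aversive and neutral
false-alarm/correct-rejection) yields a binary per-bin vector marking the
3–6 s window after that class's cue onsets — late enough to exclude
cue-driven visual transients.  Pupil size and cumulative consumed rewards are
split into eight equal-count bins (equal-count rather than equal-width so no
level is empty), evaluated only on the final 3 s of inter-trial intervals
following correct rejections, where no task event or consummatory behavior is
in progress.  Association with the cluster labels (sentinel included as a
level, since the central cloud is itself informative) is the mutual
information of the joint contingency table in nats.  The shuffle null
circularly shifts the behavior labels within the valid mask, preserving their
autocorrelation; p is the fraction of null MI values at or above the
observed.

## Trial dynamics and decoding

Each trial becomes the sequence of 20 cluster labels covering 10 s from cue
onset (trials too close to the session end are dropped).  Trial similarity is
the cosine between label sequences treated as numeric vectors — the sentinel
−1 makes central-cloud bins agree with each other and disagree with cluster
bins.  For cross-session decoding, cluster indices (arbitrary per session)
are aligned via transition-probability matrices: the 8 × 8 row-stochastic
matrix over {sentinel, clusters} (self-transitions included — dwell
probabilities are a cluster's most stable signature; transitions across run
boundaries excluded), Ward-clustered on its rows.  A session in which any of
the 8 labels never occurs cannot be aligned and is rejected.

The leaf order of a dendrogram as returned by the linkage solver depends on
internal cluster ids and is therefore *not* equivariant under relabeling of
the rows — two sessions identical up to a label permutation could produce
differently-oriented subtrees.  Subtrees are therefore oriented canonically:
at every internal node the child whose member labels have the smaller mean
self-transition probability comes first (the diagonal is invariant under
conjugation by a permutation), with label index as the final tie-break.
Matching leaf-order positions then defines the label translation, and on
paired synthetic sessions with distinct per-state dwell probabilities the
true permutation is recovered exactly.

Decoding assigns each test trial the class whose (translated) training trials
maximize the summed cosine similarity.  The null shuffles trial classes in
both sessions 200 times; p is the fraction of null accuracies at or above
the observed (≥ rather than >, the conservative choice).  Two baselines
replace the label sequences with per-bin mean population activity, or with
the projection onto the thirsty–quenched axis x̄_T − x̄_Q scaled so the anchor
patterns map to 1 and 0.

## Lick analysis

The anticipatory-lick threshold is 1/(μ + C·σ) seconds, where μ and σ are the
mean and SD across trials of the per-trial lick rate (licks/s) over the first
15 frames (0.5 s) of cue presentation, and C is 0.1 for water sessions and
0.35 for food sessions.  This is read dimensionally: μ and σ are rates, so
their combination inverts to a time threshold.  The onset is the first lick
of the first post-cue pair whose inter-lick interval falls below the
threshold, required to lie in the response window.  Cluster-sequence onsets
on rewarded trials: the two clusters with highest occupancy in the response
window (bins 4–8 after cue onset, i.e. the 2 s after cue offset —
configurable, since the exact occupancy window is a free choice) are
candidates; per candidate, each trial's onset is the first sentinel→candidate
transition (reported at the bin *center*, the unbiased time estimate for an
event inside a bin); the candidate whose onsets correlate best with the lick
onsets is chosen.

Lick patterns are smoothed with a forward 100-frame mean (~3.3 s), fixed
1/100 divisor, window truncated at the trial end; similarity is
1/(ε + ‖SL_i − SL_j‖₂) with ε = 1e-6 regularizing the identical-pattern case.
Free-consumption pseudo-trials are anchored at the second lick of pairs
separated by more than 1 s (0.5 s fallback when fewer than 5 result), span
[−2 s, +4 s), and overlapping windows are removed greedily in time order; an
optional rate-matching filter keeps pseudo-trials whose first-2 s lick rate
lies within μ ± σ of the task trials'.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, not
calcium biophysics.  A discrete latent state (0 = central cloud, 1..7 =
clusters) evolves per 0.5-s bin: background excursions from the central state
start with probability 0.18 per bin, visit a peripheral state with
pupil-modulated preference, and dwell geometrically with state-specific
continuation probability 0.30 + 0.07·(state−1) — the distinct dwell
probabilities give every cluster a unique transition signature, which the
alignment procedure requires.  Rewarded trials overwrite the background with
a stereotyped back-and-forth sequence over states (3, 5, 2), whose onset lags
the anticipatory-lick onset by N(1.0, 0.15) s (truncated to [0.4, 1.6]);
other classes have no stereotyped dynamics, so only rewarded trials are
decodable — matching the design goal that the decoder's signal is sequence
stereotypy, not amplitude.  Emission adds the state's loading column
(N(0, 1) per neuron, zero for the central state), a slow drift tracking
cumulative rewards, and white noise (σ = 1); lick trains are inhomogeneous
Bernoulli (0.2 Hz baseline, 8 Hz bursts from the anticipatory onset); a
free-consumption epoch appends lick bouts with distinct latent dynamics
(states 6, 4).  Defaults (200 neurons, 50 trials per class × 6 classes × 24
bins ≈ 7,400 bins) give a session the size of a typical imaging day.  With
noise, drift and couplings disabled the emitted bins equal the loading
columns exactly, which anchors the emission tests.

Paired sessions share one latent trajectory and behavior; the second relabels
state ids by a caller-given permutation (0 fixed), permutes the loading
columns consistently, and redraws observation noise — the ground truth for
translation and decoding tests.

What the generator does **not** emulate: calcium-indicator kinetics
(rise/decay asymmetry), correlated noise across neurons, continuous latent
drift within states, session-to-session neuron identity changes, or
behavior-dependent movement artifacts.  Tests passing on these synthetics
show the pipeline recovers the structure it assumes when that structure is
present; they do not certify performance on real data whose violations of
these assumptions are material.

The geometric fixtures carry analytically known answers: uniform d-cubes
(dimension), a noisy ring (one dominant loop), and "blobs+cloud" — seven
Gaussian blobs at the vertices of a regular 6-simplex around a compact
central Gaussian core (6% of points).  The simplex arrangement makes all
blob pairs equidistant, so K-means has no arbitrarily cheap merge and the
grid optimum is stable; a compact core matches the clustering procedure's
premise that the excluded centroid-distance prefix is the cloud.  On this
fixture the grid selects the true cloud size to within one grid step and
K\* = 7, and consensus labels reach ARI > 0.94 against ground truth.

## Numerical choices and limitations

- Eigen-decomposition is dense (`scipy.linalg.eigh`, index subset); at
  T ≈ 7,400 one decomposition takes ~45 s on one core and the full session
  pipeline ~4 minutes.
- K-means uses k-means++ with per-repetition seeds spawned from the master
  seed; all stochastic stages are reproducible byte-for-byte under a fixed
  seed.
- The Rips reduction is pure Python; it is intended for ≤ ~100 landmarks
  (3,160 edges / 82,160 triangles at n = 80), not raw sessions.
- On synthetic sessions whose central state holds ~half the bins, the grid
  optimization retains a small sentinel set rather than the full latent
  cloud: a compact dense core is cheap for K-means to absorb as its own
  cluster, so the error axis rewards exclusion only weakly.  The partition
  itself still tracks the latent states (ARI ≈ 0.88 end-to-end), but
  sentinel-dependent statistics (e.g. cluster-onset detection, which needs
  sentinel→cluster transitions) degrade under the end-to-end labels; the
  behavior analyses are therefore validated on ground-truth labels, and this
  is the main known gap between the pipeline's behavior on synthetics and
  the idealized description.
- MI uses natural log; only relative comparisons matter.
- The trial-outcome window (3–6 s post-cue), the eight-level continuous
  binning, K = 80 landmarks, 20/500 repetition counts, 200 permutations, and
  the K grid 2..20 are the method's standard constants and are exposed as
  parameters.
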