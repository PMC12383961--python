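# Methods

`wvgerp` implements a network-biomarker pipeline for two-group
discrimination from epoched, stimulus-locked EEG: event-related series
are mapped to weighted visibility graphs (WVGs), graph-topological
features feed a leakage-safe selection/reduction stage, and six
classifier families are evaluated over repeated matched splits, with an
optional trial-subgroup majority-vote ensemble.  A synthetic ERP cohort
generator supplies data with the statistical structure the pipeline
assumes, so that every stage is testable without clinical recordings.

## Synthetic cohort model

Each trial is the sum of a deterministic event-related signal and
stochastic background noise, in microvolts, on a 4 s epoch (−2..+2 s
around word onset) sampled at 250 Hz.

**Signal.**  Two Gabor-like atoms (Gaussian-windowed cosines, phase 0 at
the envelope centre):

* a negative component peaking 400 ms post-onset (σ = 120 ms, 1.2 Hz
  carrier, default amplitude −4 µV) standing in for the semantic N400;
* a positive late component peaking 600 ms post-onset (σ = 150 ms,
  0.8 Hz carrier, default amplitude +5 µV) standing in for the
  P600/late positive component tied to verbal memory.

Condition gains emulate a word-repetition/congruity design over six
conditions (NA, NC, NI, OA, OC, OI): incongruous new words maximise the
negative component, repeated (old) words maximise the late positivity.
A fixed topography vector per component puts the maxima on the midline
(Cz for the early component, Pz for the late one), with the 12
off-midline sites at 0.3–0.55 relative gain, mirroring the
centro-parietal dominance of word-repetition effects.

**Group structure** enters in exactly one place: the late component of
the `preAD` group is multiplied by `1 − effect_size`.  `effect_size = 0`
therefore yields two literally identical generating distributions (the
null used for calibration tests); `effect_size = 1` removes the late
component entirely in the patient group.  This mimics the reported
attenuation of the late repetition effect in preclinical Alzheimer's
disease while keeping the null exactly exchangeable.

**Variability.**  Per-trial latency jitter ~ N(0, 20 ms) shifts both
components of an event coherently across channels; a per-subject
amplitude factor ~ N(1, 0.15), floored at 0.1 to preserve polarity,
makes subjects exchangeable draws rather than clones.  Background noise
is spectrally shaped Gaussian noise with 1/f power (amplitude
1/sqrt(f), flattened below 1 Hz to bound drift), normalised to unit
variance per trial and scaled by `noise_sd` (default 10 µV, a realistic
single-trial EEG noise floor against 4–5 µV components).

**What the generator does not model:** ocular/muscle artifacts,
channel-specific noise correlation, volume-conduction covariance between
sites, non-stationarity across a session, behavioural responses.
Passing tests on this generator therefore demonstrate that the pipeline
recovers group structure expressed as ERP amplitude differences under
realistic noise — not that it would survive artifact-laden clinical
recordings; artifact rejection would be a preprocessing hook upstream of
the filter bank.

## Preprocessing

Per (channel, condition): trials are averaged pointwise; the 4 s average
is mirror-padded by 2 s at each end (reflection without repeating the
boundary sample); band-pass filtered; cropped to −1..+2 s (750 samples);
and block-averaged over non-overlapping 80 ms (20-sample) windows.

The filter bank holds five bands (δ 1–4, θ 4–8, α 8–13, β 13–30,
γ 30–45 Hz) plus the unfiltered "raw" series.  Each band is realised as
a high-pass followed by a low-pass Hamming windowed-sinc FIR kernel.
Transition bandwidth per passband edge: 25% of the edge, at least 2 Hz,
but never more than the edge itself (so 1 Hz for the 1 Hz edge and 2 Hz
for the 4 Hz edge).  Kernel length is `ceil(3.3 · fs / transition_bw)`,
forced odd; cutoffs sit at the transition-band centres, giving −6 dB
exactly there.  Kernels are symmetric (linear phase) and applied in a
single delay-compensated pass, so the output is zero-phase; padding is
done before filtering so edge transients fall outside the analysis
window.  "Raw" is the recorded epoch without filtering or detrending.

750 samples / 20 per block = 37.5 blocks; the trailing half block is
dropped, fixing the series length at 37 points (the block size and crop
window are configuration knobs; every graph feature depends on N, so
the default is pinned).

## Weighted visibility graphs

Each 37-point series becomes a graph with one node per time point.
Nodes i < j connect when the chord between them passes strictly above
every intermediate sample — equivalently when the slope from i to j
strictly exceeds the slope from i to every intermediate k (collinear
intermediates block visibility).  Edge weights are
`|arctan((x_i − x_j)/(t_i − t_j))|` with time in node-index units, i.e.
the slope-angle magnitude per 80 ms block, dimensionless and in
[0, π/2).  Consecutive points are always mutually visible, so the graph
is connected and contains the Hamiltonian path 1–2–…–N.  Flat segments
keep their adjacency edge with weight 0: binary features see the edge,
strength-based features ignore it.  Construction is O(N²) via a running
slope maximum per source node, validated against an O(N³) brute-force
check of the inequality.

## Features

Sixteen per-graph features and one cross-channel feature per (band,
condition).  The average weighted degree and modularity are weighted
(they are defined on edge weights); the rest are computed on the binary
visibility adjacency.  Definitions of the features named only by
convention in the source literature are pinned as follows and frozen
here for reproducibility:

* **CC** mean local clustering (triangles over connected triples;
  degree < 2 contributes 0).
* **GIC** graph index complexity `4c(1−c)` with
  `c = (λ_max − 2cos(π/(N+1))) / (N − 1 − 2cos(π/(N+1)))`, λ_max the
  largest adjacency eigenvalue.
* **LE** mean over nodes of the global efficiency of the
  neighbour-induced subgraph.
* **GE** mean of 1/l_ij over ordered pairs (hop counts).
* **SW** `(C/C_rand)/(L/L_rand)` with the analytic Erdős–Rényi
  reference `C_rand = density`, `L_rand = ln N / ln(mean degree)`; the
  analytic reference avoids the nondeterminism of rewired null models.
* **SMaC / IN** exact maximum clique / independence number via a
  bitmask branch-and-bound with a greedy-coloring bound (independence =
  clique of the complement); exact up to 64 nodes.
* **VCN** chromatic number: clique lower bound, DSATUR-greedy upper
  bound, and — only when they disagree — an exact backtracking search
  with maximum-clique pre-coloring and bitmask domain propagation,
  capped at a deterministic node budget; if the budget is exhausted the
  greedy bound is returned (logged).  On block-averaged visibility
  graphs the bounds almost always coincide.
* **SMiC** global minimum cut with unit capacities (exact).
* **CTSP** closed-tour cost on hop-count distances from a deterministic
  heuristic: nearest-neighbour construction from node 0 plus
  best-improvement 2-opt to a local optimum.  On graphs of ≤ 7 nodes
  this matches exhaustive search in all randomized tests; at N = 37 it
  is a pinned deterministic surrogate for the (intractable-by-design)
  exact tour.
* **DD** Poisson rate fitted to the binary degree distribution; the
  maximum-likelihood fit (λ = mean degree) is the default because it is
  closed-form and deterministic; a least-squares histogram fit is
  available by option.
* **NE** Shannon entropy, natural log, of the empirical degree
  distribution (`0·log 0 := 0`).
* **M** modularity Q of the Louvain partition of the weighted graph;
  the partition comes from the standard two-phase local-moving +
  aggregation algorithm (igraph backend, deterministic for a fixed
  graph), and Q is recomputed from its definition on the final
  partition rather than taken from incremental gains.  Total edge
  weight m = 0 (an exactly flat series) leaves Q undefined and raises.
* **APL** mean shortest-path hop count over ordered pairs.
* **CCSS** mean pairwise Pearson correlation between the node-wise
  clustering-coefficient sequences of all channels in the active
  montage, one value per (band, condition).  The aggregation functional
  is not fixed by the source literature; mean pairwise correlation is
  the pinned choice.  Pairs involving a constant sequence contribute 0
  and are logged.

At the standard configuration (15 channels × 6 bands × 6 conditions ×
16 features + 6 × 6 CCSS) the feature vector has exactly 8676 named
entries; reduced configurations follow the same counting formula
(5 channels → 2916; 3 bands → 4338).  Missing or non-finite cells are
an error, never imputed.

Note on invariances: all graph-level features are invariant to
consistent node relabelling except CTSP (fixed start node and
order-dependent tie-breaks) and the Louvain partition (order-dependent
local moving).  Since WVG nodes are time points with a canonical order,
this is a documented property rather than a defect.

## Selection, reduction, classification

Per split, 85% of subjects train and 15% test, with the test set holding
equally many subjects of each group (3 + 3 at the 40-subject default).
Feature selection is a per-feature two-sample two-tailed Student
(pooled-variance) t-test on training subjects only, threshold p < 0.01
(Welch variant by option); features constant across training subjects
get p = 1.  Selected columns are centred (scaling to unit variance by
option) and projected by PCA to 11 components.  If fewer than 11
features survive, all surviving directions are used; if none survive,
the 11 smallest-p features are taken — both fallbacks are logged, and
exist so that 100-round evaluations do not abort on unlucky splits.
Test rows never enter any fit; this is asserted bit-exactly in tests.

Classifiers (pinned hyperparameters, chosen as library-typical defaults
since the method description leaves them open): L2 logistic regression
(C = 1), linear hinge-loss SVM (C = 1), LDA (SVD solver), 3-NN
(Euclidean), random forest (100 trees, seeded), and a fully connected
network 11→32→output with ReLU, trained full-batch by L-BFGS with a
200-iteration budget (seeded).
The positive class is `preAD`; reported metrics are accuracy, precision,
recall and AUROC per split, aggregated as mean ± sd over rounds.

## Ensemble

The trials of each condition are partitioned into 31 non-overlapping
subgroups (72 trials → twenty-one groups of 2 and ten of 3), contiguous
by trial order by default (interleaved by option).  Each subgroup is
averaged into its own band-series grid and feature table, and the
complete selection → PCA → classifier pipeline is re-fitted
independently per subgroup within the training subjects — the only
reading of "independently trained" that preserves the leakage
guarantee member-wise.  Test predictions aggregate by majority vote
(31 members ⇒ no ties; even member counts break ties toward the
positive class, configurable).  The ensemble AUROC uses the mean member
score rather than the vote fraction, which would offer at most 31
distinct thresholds.  Sessions with fewer trials than subgroups fall
back to the largest odd subgroup count the trial budget supports
(e.g. 30 trials → 29 subgroups), keeping votes tie-free.

## Reduced configurations

`channels5` restricts the montage to Fz, Pz, Cz, Wl, Wr (2916
features); `trials30` keeps the first 30 trials per condition (8676
features, shorter-session emulation); `bands3` keeps raw, δ, γ (4338
features).  Arbitrary channel/band/condition subsets are supported
through the same configuration object.

## Numerical and reproducibility choices

* All randomness flows from explicit integer seeds: cohort generation
  uses per-subject child seeds spawned from the cohort seed; splits,
  subgroup shuffling (interleaved scheme) and seeded classifiers take
  their own seeds.  Fixed seeds give bit-identical cohorts, feature
  tables and split reports.
* Selection/PCA inputs are copied to fresh contiguous arrays so that
  fitted objects are bit-reproducible regardless of the parent table's
  memory layout.
* Hop distances use Floyd–Warshall on the dense 37-node adjacency;
  dense matrices are used throughout (simplicity wins at N = 37).
* Degenerate inputs: empty trial lists, ragged trials, pads longer than
  the series, blocks longer than the series, empty crop windows,
  non-finite series and single-class training labels all raise with
  explicit messages.

## Problem sizes used in the validation suite

The statistical validation runs at sizes chosen to make the checks
sharp while keeping the whole suite desk-scale: null calibration uses
the full 20 + 20-subject cohort and 8676-feature configuration for the
selection-rate check and the single-model chance check (50 splits), and
a midline 3-channel × 2-band grid (588 features) for the ensemble
chance check; signal recovery uses a 10 + 10 cohort at effect size 0.9,
noise 1 µV, on the same reduced grid (20 splits, random forest).
Chance level and ensemble-vs-single comparisons do not depend on the
grid size, so the reduced grids change runtime, not the hypotheses
being tested.

Because the repeated splits of one cohort share subjects, the
across-split standard error understates the variability of the cohort
mean; chance-level assertions therefore use subject-level
(cluster-robust) standard errors computed from each subject's mean
correctness across the rounds that tested it.  On a fixed finite null
cohort the conditional expected accuracy legitimately deviates from 0.5
(features that separate the cohort's forty subjects by chance are
selected repeatedly and generalise within that cohort); the
subject-level SE is the scale of exactly that fluctuation.

## Known limitations

* The chromatic-number search is exact up to its node budget; on hard
  instances (rare sparse graphs where the clique and greedy bounds
  disagree) it may return the greedy upper bound instead.  It is not a
  general-purpose coloring solver.
* CTSP is a deterministic local optimum, not the exact tour cost, for
  N beyond exhaustive reach.
* The t-test treats the discrete integer features (SMaC, IN, SMiC,
  VCN) as continuous; near-constant columns are handled by the p = 1
  convention rather than an exact test.
* The synthetic generator's group effect is a pure late-component
  amplitude scaling; real cohorts presumably differ in latency,
  topography and spectral content as well.
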