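# wvgerp

Weighted visibility graph (WVG) analysis and ensemble classification of
event-related EEG cohorts.

## The problem

Event-related potentials (ERPs) from word-repetition paradigms carry
early markers of preclinical Alzheimer's disease: cognitively normal
individuals with abnormal amyloid PET show attenuated late
(P600/LPC-like) repetition effects over midline channels.  Classical
ERP analysis inspects predefined windows, sites and bands; this package
instead maps each (channel, frequency-band, condition) series to a
graph and classifies subjects from the graph's topology, so the whole
shape of the response contributes.

## The method

For a series x(t_1..t_N), nodes i < j of the *visibility graph* connect
when the chord between (t_i, x_i) and (t_j, x_j) clears every
intermediate sample:

    (x_i − x_k)/(t_k − t_i) > (x_i − x_j)/(t_j − t_i)   for all t_i < t_k < t_j

and each edge carries the slope-angle weight
w_ij = |arctan((x_i − x_j)/(t_i − t_j))| ∈ [0, π/2).

The pipeline: epoched EEG → per-condition trial averaging → zero-phase
windowed-sinc filter bank (raw, δ, θ, α, β, γ) → 80 ms block averaging
(37 points over −1..+2 s) → WVG per (channel, band, condition) → 16
graph features per WVG (average weighted degree, Poisson
degree-distribution index, network entropy, Louvain modularity Q,
average path length, clustering coefficient, graph index complexity,
local/global efficiency, small-worldness, max clique, TSP tour cost,
density, independence number, min cut, chromatic number) plus one
cross-channel clustering-sequence similarity (CCSS) per (band,
condition) — 8676 features per subject at the standard 15-channel
configuration.  Per split (85/15, group-matched test sets), features
are selected by a two-tailed t-test (p < 0.01) on training subjects
only, PCA-reduced to 11 components, and classified by six families
(logistic regression, linear SVM, LDA, 3-NN, random forest, MLP).  The
ensemble partitions each condition's 72 trials into 31 non-overlapping
subgroups, re-runs the whole pipeline per subgroup, and majority-votes.

Because the clinical recordings that motivated the design are
restricted, the package ships a synthetic two-group ERP cohort
generator (N400/P600-like Gabor atoms with midline topography, 1/f
noise, per-trial latency jitter, per-subject amplitude variation) whose
`effect_size` parameter scales the group difference in the late
component — 0 gives exactly exchangeable groups.

## Worked example

```python
import numpy as np
from wvgerp import (ClassifierSpec, CohortSpec, PipelineConfig,
                    evaluate_cohort, generate_cohort, make_splits,
                    subject_features)

spec = CohortSpec(n_per_group=10, effect_size=0.9, noise_sd=1.0, seed=42)
cohort, labels = generate_cohort(spec)

vec = subject_features(cohort[0], PipelineConfig())
print(len(vec))                      # 8676
print(round(vec["Pz|raw|OC|CC"], 3)) # 0.768

config = PipelineConfig(channels=("Fz", "Pz", "Cz", "Wl", "Wr"),
                        bands=("raw", "delta", "gamma"))
plans = make_splits(labels, n_rounds=10, seed=0)
report = evaluate_cohort(cohort, labels,
                         [ClassifierSpec("random_forest", seed=0)],
                         plans, mode="ensemble", config=config, seed=0)
print(report.formatted())
```

which prints

```
                 accuracy    precision       recall        auroc
random_forest  100.00~0.00  100.00~0.00  100.00~0.00  100.00~0.00
```

i.e. on a strong-effect, low-noise cohort the 31-member majority-vote
random forest separates the groups perfectly in every split;
`mean~std` values are percentages over the 10 splits.  The clustering
coefficient 0.768 says that in this subject's raw-band WVG at Pz
(repeated congruous words), neighbouring time points are themselves
mutually visible three times out of four — a smooth, strongly
structured evoked response.  At `effect_size=0` the same
pipeline hovers at chance, and the t-test selects ≈1% of features —
the calibration checks in `tests/test_acceptance.py` assert exactly
this.

The command-line interface mirrors the library:

```sh
wvgerp simulate --n-per-group 10 --effect-size 0.9 --noise-sd 1 --seed 42 --out cohort/
wvgerp features --manifest cohort/manifest.tsv --config channels5 --out features.csv
wvgerp evaluate --manifest cohort/manifest.tsv --mode ensemble --config bands3 --rounds 20 --seed 0
```

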