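# pdkin

Classification of Parkinson's disease (PD) motor subtypes — **Tremor-Dominant
(TD)** versus **Postural Instability and Gait Difficulty (PIGD)** — from
full-body 3D marker kinematics recorded during standardized walking tasks.

PD presents with at least two partially overlapping motor phenotypes. PIGD
patients progress faster, fall more, freeze more and respond less well to
levodopa, so recognizing the subtype matters for prognosis and care — but the
conventional route is an MDS-UPDRS-III motor exam scored by a movement
disorders specialist. `pdkin` implements the alternative: a machine-learning
pipeline that reads 11-marker motion-capture trajectories (head, chest,
sacrum, wrists, thighs, shanks, heels at 120 frames/s) from straight-walk,
360°-turn and timed-up-and-go (TUG) sessions and predicts the subtype label
from windowed kinematic features. Since clinical recordings of this kind are
not publicly available, the package includes a first-class synthetic-cohort
generator that reproduces the phenotype signatures the features measure, so
every stage is testable end to end.

## The analysis

**Subtype ground truth (MDS-UPDRS ratio rule).** With tremor score
$T = \tfrac15\sum(\text{items } 2.10, 3.15, 3.16, 3.17, 3.18)$ and gait score
$G = \tfrac15\sum(\text{items } 2.12, 2.13, 3.10, 3.11, 3.12)$, the ratio
$R = T/G$ labels a patient PIGD when $R \le 0.90$, TD when $R \ge 1.15$, and
Indeterminate otherwise (Indeterminate cases are excluded from
classification).

**Features.** Recordings are gap-filled, projected to a hip-centered frame,
Z-normalized and cut into 4-s windows with 1 s of overlap. Each of the 33
channels yields mean, minimum, maximum, variance, freezing index
$\mathrm{fi} = \int_{3}^{8} P(f)\,df \,/\, \int_{0.5}^{3} P(f)\,df$
(freeze-band over locomotor-band power), spectral centroid, dominant
frequency, and the mean absolute detail coefficient of a 4-level db4 wavelet
transform — 264 named features per window
(`fi-L.Thigh_Z` = freezing index of the left-thigh anterior channel).
A parallel gait-feature baseline summarizes spatiotemporal parameters (step
and stride length, cadence, forward velocity, support/swing phases, step
width, sagittal knee/ankle angle proxies) per walking session, detected from
heel anterior excursions relative to the sacrum.

**Evaluation.** Random forest, RBF-kernel SVM and MLP classifiers are scored
by binary F1 under repeated (50×) 5-fold cross-validation with 50/20/30
train/validation/test fractions and Wilson 95% score intervals at N = 250, in
two schemes: *user-independent* (participants partitioned across sets) and
*user-dependent* (windows partitioned within participants, with windows that
overlap or neighbor a training window excluded from evaluation). Feature
standardization always uses training-fold statistics only. Feature relevance
is read out by mean-decrease-in-impurity (Gini) importance and Pearson
correlation of top features with the UPDRS component scores, plus restricted
feature- and marker-set reruns.

## Worked example

```python
from pdkin.benchmark import standard_benchmark
from pdkin.classify import SplitSpec, run_experiment

kin, gait, cohort = standard_benchmark(n_participants=20, seed=2,
                                       tug_duration=30.0)
for scheme in ("user_independent", "user_dependent"):
    spec = SplitSpec(scheme=scheme, n_folds=5, n_repeats=2, seed=2)
    res = run_experiment(kin, spec, "rf", tuned_params={"n_estimators": 200})
    print(scheme, round(res.mean_f1, 3), [round(v, 3) for v in res.wilson])
```

prints

```
user_independent 1.0 [0.722, 1.0]
user_dependent 1.0 [0.722, 1.0]
```

while the same experiment on the summarized gait parameters reaches a mean
F1 of 0.844: the injected subtype discriminators are spectral (4–6 Hz wrist
and leg tremor for TD, 3–8 Hz freeze-band trembling for PIGD freezers), so
windowed kinematic features separate the classes where session-level gait
summaries — whose stride distributions overlap between subtypes — do not.
The Wilson interval is wide because the smoke configuration uses only 10
folds. `examples/` walks through each capability (cohort simulation, feature
extraction, gait parameters, classification, feature importance); each
script runs in seconds and prints what its numbers mean. The `pdkin` console
command wires the same steps for shell use
(`pdkin simulate|features|subtype|classify|analyze|report`).

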