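# emokinetics

Encoding, decoding and clustering of dynamic emotion ratings against
ROI-level BOLD time series from naturalistic movie viewing.

## The problem

When people watch emotional movies, they continuously *perceive* emotions in
the characters and *feel* emotions themselves. Given (a) continuous
intensity ratings of many emotion categories collected from a rater panel in
short movie segments, and (b) fMRI time series averaged within brain regions
of interest (ROIs) from an independent participant sample watching the same
movies, this package answers: which emotions are rated reliably enough to
model, where in the brain does each emotion's time course leave a consistent
trace, how well do emotion models generalise across stimuli (runs) and
across people, do felt and perceived emotion models explain different
regions, and how do emotions group by the similarity of their brain
response patterns?

It is written for cognitive-neuroimaging researchers who have ROI-level,
preprocessed BOLD data and segment-level ratings, and for methodologists who
want a tested, self-contained reference implementation of this analysis
family. Everything runs on plain TSV inputs; a bundled synthetic-data
generator with known ground truth makes every stage testable without any
scanner data.

## The model

Segment ratings are linearly interpolated within each movie clip (anchored
at zero at every scene start), sampled on the TR grid (TR = 2.4 s), and
convolved with a single-gamma haemodynamic response function h(t) (shape 6,
scale 1 s, no undershoot, unit sum) to give design matrices
X ∈ R^(T×E) per run and task.

An emotion enters the models only if its combined reliability
(a·b·c)^(1/3) — a = fraction of raters ever reporting it, b = fraction of
timepoints with a non-zero rating, c = mean pairwise inter-rater
correlation, each averaged over runs — exceeds the 95th percentile of the
same statistic after shuffling each component independently across emotions.

ROI series are conditioned (percent signal change; regression of WM/CSF,
six motion parameters, their squares, and a linear trend; zero-phase
equiripple FIR bandpass 0.005–0.05 Hz, ≥40 dB upper-stopband attenuation,
<1 dB passband ripple), then fit by ordinary least squares after demeaning:

    encoding   Y ≈ X B      (BOLD from emotion regressors)
    decoding   X ≈ Y W      (emotion regressors from BOLD)

Generalisation is cross-validated between runs (fit on the
across-participant mean of standardized activity in 3 of 5 runs, test on
individual participants in the held-out runs, all C(5,3)=10 combinations)
and within runs (10-fold cross-validation across participants). Inference
uses max-statistic permutation tests: per-participant felt/perceived
swapping for the task contrast, and circular-shift + label-permutation
nulls (two-tailed, 97.5th percentile of the maximum |t| over ROIs, emotions
and runs) for single-emotion maps. Emotion response patterns are compared
across non-overlapping run sets (Pearson across ROIs, or generalized
two-sided Dice on thresholded maps) and clustered by average linkage
(UPGMA) with optimal leaf ordering and a 70%-of-maximum-linkage cutoff.

## Worked example

```python
import emokinetics as ek
from emokinetics.simulate import SimulationSpec, simulate_study

spec = SimulationSpec(n_raters=8, n_emotions=12, n_reliable=4, n_runs=3,
                      n_timepoints_per_run=380, n_participants=6, n_rois=12,
                      snr=5.0, rng_seed=42, occurrence_rate=0.25)
study = simulate_study(spec)

rel = ek.compute_reliability(study.panel, study.manifests, spec.tr,
                             n_perm=500, seed=42)
print(f"reliability threshold: {rel.threshold:.3f}")
print(f"reliable emotions: {rel.reliable_emotions}")

conditioned = ek.condition_dataset(study.dataset)
designs = {r: study.designs[(r, "perceived")].subset(rel.reliable_emotions)
           for r in conditioned.runs}
fit = ek.between_run_cv(conditioned, designs, n_train=2, seed=42)
print(f"mean between-run encoding fit: {fit.test_fit.to_numpy().mean():.3f}")

dec = ek.between_run_cv(conditioned, designs, direction="decode",
                        n_null=200, seed=42)
print(f"shuffled-label null maximum: {dec.threshold:.3f}")
print(f"decoded above chance: {sorted(dec.significant[dec.significant].index)}")
```

Output:

```
reliability threshold: 0.625
reliable emotions: ['emotion01', 'emotion02', 'emotion03', 'emotion04']
mean between-run encoding fit: 0.532
shuffled-label null maximum: 0.310
decoded above chance: ['emotion01', 'emotion02', 'emotion03', 'emotion04']
```

The four emotions planted with shared rating profiles pass the permutation
threshold (the eight idiosyncratic ones do not). The encoding model
predicts held-out-run activity of individual participants at a mean Pearson
r of 0.53 at this noise level, and all four reliable emotions are decoded
from brain activity above the maximum correlation achieved by models
trained with deranged emotion labels.

The full pipeline (reliability → conditioning → encoding fits →
felt-vs-perceived contrast → per-emotion significance maps → similarity
clustering) runs from a YAML config:

```bash
emokinetics run --config cfg.yaml --out results/
emokinetics simulate --config cfg.yaml --out study/   # TSV inputs + ground truth
```

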