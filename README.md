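# blockmvpa

Whole-brain single-scan decoding of block-design fMRI.

`blockmvpa` asks whether one 2-second BOLD volume is enough to tell which
of two self-driven mental tasks (counting down numbers vs. recalling
negative or positive autobiographical memories) a person is performing,
and where in the brain the discriminating information lives. It
implements the complete analysis chain for a 12-session, 32-s-block
paradigm:

- **Preprocessing** — nuisance regression (6 motion parameters,
  white-matter and CSF sphere means, global signal, session constants),
  0.008-Hz DCT high-pass, grand-mean-100 session scaling, and per-voxel
  z-scoring over the whole experiment.
- **Scan datasets** — behavioral screening (start cue acknowledged
  within 2000 ms), strict block-level class balancing, 2-TR onset shift,
  voxel-based and 116-region encodings.
- **Decoding** — linear SVM (C = 1) with per-feature training-min/max
  scaling to [−1, 1], under leave-one-session-out, adjacent-session-pair
  and leave-one-subject-out cross-validation; accuracy is the pooled
  proportion c/(c+e) of correctly classified test scans.
- **Inference** — balanced-block permutation test (labels shuffled at
  the block level under class-balance constraints, the full CV rerun per
  draw, p = (1 + #{null ≥ obs})/(1 + n_perm)) and Beta(c+1, e+1)
  confidence intervals.
- **Maps** — discriminating volumes (SVM weights re-projected to the
  grid, unit-variance standardized, 8-mm-FWHM smoothed, averaged), GLM
  boxcar⊗HRF contrast T-maps with optional AR(1) prewhitening, group
  one-sample t, and the voxelwise Pearson correlation between the two.
- **Synthetic data** — a generator producing multi-subject, multi-session
  block-design BOLD with known activation patterns plus drift,
  physiological oscillations, global fluctuations, motion-coupled
  artifact, session offsets and white noise, so every stage is testable
  without scanner data.

The decoding core is sklearn-style: `SymmetricMinMaxScaler` is a
transformer and `LinearScanClassifier` a classifier, so both compose
with scikit-learn pipelines and model selection.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

## Worked example

```python
from blockmvpa import DesignSpec, simulate_subject, run_cv
from blockmvpa.simdata import default_ground_truth
from blockmvpa.preprocess import preprocess_subject
from blockmvpa.features import build_dataset, make_folds
from blockmvpa.inference import accuracy_ci, permutation_test

design = DesignSpec()                      # 12 sessions, 144 scans each
truth = default_ground_truth(seed=1)       # planted patterns, RMS 0.08
subject = simulate_subject(design, truth, seed=42)

subject.runs, report = preprocess_subject(subject.runs, subject.nuisance,
                                          truth.mask)
print(report.stages)

dataset = build_dataset(subject, pair="cd-nam", encoding="voxel",
                        mask=truth.mask)
folds = make_folds(dataset, "loso-session")
result = run_cv(dataset, folds)
ci = accuracy_ci(result.c, result.e)
perm = permutation_test(dataset, folds, n_perm=99, seed=7,
                        observed=result)
print(f"accuracy {result.accuracy:.3f} ({result.c}/{result.n}), "
      f"95% CI [{ci.lower:.3f}, {ci.upper:.3f}], p = {perm.p_value:.3f}")
```

Output:

```
['regress_nuisance', 'highpass', 'grand_mean_scale', 'standardize_experiment']
accuracy 0.863 (497/576), 95% CI [0.832, 0.889], p = 0.010
```

The subject's six Type A sessions yield 576 balanced scans
(288 Countdown, 288 negative-memory). Decoding single scans at 86.3%
accuracy, the classifier is far above the chance level of 50%; the
Beta-interval reflects the pooled counts, and p = 0.010 is the smallest
value attainable with 99 permutations — no balanced block relabeling
decoded as well as the true labels.

The same flow scales to a full study via one config:

```python
from blockmvpa.pipeline import RunConfig, run_all
report = run_all(RunConfig(n_subjects=11, seed=0))
```

which adds region encodings, the across-subject scheme, confusion
matrices, encoding comparisons (Mann-Whitney), discriminating volumes,
GLM T-maps and their correlation to the JSON report. A thin CLI wraps
the same calls: `blockmvpa simulate --seed 0 --subjects 2 --out data/`
and `blockmvpa run --seed 0 --out results/`.

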