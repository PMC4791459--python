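# motorimagery

Classification of imagined arm movements (rest vs. grasp vs. elbow flexion)
from multichannel EEG, built around cheap time-domain features and a tuned
RBF-kernel SVM, with the three standard motor-imagery pipelines — CSP,
filter-bank CSP and logarithmic band power — as comparison methods.  It is
aimed at BCI researchers who want a tested, deterministic reference
implementation of this scheme that runs end to end on synthetic EEG, with no
recordings required.

## The method

Each 3 s trial (sampled at 1000 Hz on 20 scalp electrodes) is cut into
twelve 250 ms windows.  Per window and channel the features are

* the four prediction coefficients of an AR(4) model
  x[n] = Σᵢ aᵢ x[n−i] + e[n] (Burg's method),
* the RMS amplitude √(Σᵢ xᵢ²/n),
* the waveform length Σᵢ |xᵢ₊₁ − xᵢ|,

giving 20 × 6 = 120 features per window.  The classifier is the soft-margin
SVM min ½‖a‖² + c Σᵢ ξᵢ under the RBF kernel k(u,v) = exp(−γ‖u−v‖²); the
penalty c ∈ (0, 100] and kernel width γ ∈ (0, 3] are selected by exhaustive
grid search scored by stratified tenfold cross-validation, with folds drawn
at the trial level so correlated windows never straddle a split.  The
comparison pipelines band-pass 6–40 Hz and feed a shrinkage LDA; a
synthetic-EEG generator provides subjects whose mu/beta rhythm power drops
over C3/C4 during imagined movement (event-related desynchronization).

## Worked example

Tune and validate the proposed pipeline on one synthetic subject
(`examples/03_grid_search_svm.py`):

```python
from motorimagery import (GridSpec, SimSpec, extract_epochs, extract_features,
                          grid_search, segment, simulate_recording)

rec = simulate_recording(SimSpec(n_trials=15, seed=3))
segs = segment(extract_epochs(rec, ("rest", "grasp"), 3.0), 0.25)
F = extract_features(segs)
report = grid_search(F, GridSpec(c_values=(1, 10, 100),
                                 gamma_values=(0.1, 0.5, 1.0, 2.0, 3.0), seed=0))
```

prints

```
best parameters: c=1, gamma=0.1
tenfold CV accuracy: 97.7 +/- 2.9 %
confusion counts (rows true, cols predicted):
[[174   6]
 [  3 177]]
```

97.7 % is the mean over the ten test folds of the grid cell with the highest
cross-validated accuracy; the confusion counts cover all 360 windows (30
trials × 12 windows), each predicted by a model that never saw its parent
trial.  `examples/04_compare_methods.py` runs all four methods on a
two-subject cohort and prints the comparison table; on strong-contrast
synthetic subjects the proposed pipeline leads (95.7 % aggregate vs. 93.5 %
CSP, 89.3 % band power, 86.5 % FBCSP, one-way ANOVA p = 0.014).

The other examples show simulation + EDF round-trip + per-channel contrast
localization (`01`), and the feature set itself (`02`).  A thin CLI mirrors
the library: `motorimagery simulate|gridsearch|baseline|train|evaluate|compare`
(see `--help`).

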