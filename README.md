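# vsabci — gaze-independent visual oddball BCI simulation and decoding

`vsabci` is a research toolkit for studying **gaze-independent decoding of
visual oddball brain–computer interfaces (BCIs)**. It targets the question
faced by BCI users with speech, physical and gaze impairment: a classical
Hex-o-Spell-style visual speller works well when the user can fixate the
attended target (*overt* visuospatial attention, VSA), but what happens when
gaze is pinned to the screen center (*covert* VSA) or left uninstructed
(*free* VSA)?

The package provides, end to end:

1. **A synthetic session generator** for the 6-target hexagonal oddball
   paradigm (100 ms flashes, 200 ± 50 ms stimulus-onset asynchrony, 10–15
   intensifications per target, 6 targets × 3 VSA conditions = 18 blocks),
   producing 1000 Hz multichannel EEG with a component-sum ERP model
   (P1/N1/P3), spatially correlated colored noise, binocular gaze traces
   with per-eye dropout, and complete ground truth (per-trial P3 latency
   shifts, effective amplitudes, gaze strategy).
2. **Preprocessing**: zero-phase 0.5–16 Hz Butterworth band-pass, RANSAC
   bad-channel detection, mastoid (TP9/TP10) re-referencing, optional EOG
   regression, stimulus-locked epochs (−0.1…0.9 s, no baseline correction),
   and repetition truncation (first 10 intensifications per target).
3. **Three decoders**:
   - `tlda` — block-Toeplitz LDA: shrinkage LDA whose spatiotemporal
     covariance is constrained so the channels × channels cross-covariance
     between feature time points depends only on their lag,
   - `xdawn_ts` — xDAWN spatial filtering → prototype-augmented epoch
     covariances → tangent-space projection at the affine-invariant
     Riemannian mean → shrinkage LDA,
   - `wcble` — Woody-iteration classifier-based latency estimation: slide
     the trained classifier over a wide (−0.1…0.9 s) epoch, realign target
     epochs at their score maxima, retrain, and score test epochs by the
     (regularized) maximum sliding score. Corrects the P3 latency jitter
     that grows under covert VSA.
4. **Evaluation machinery**: 6-fold block-wise cross-validation,
   single-trial and k-averaged target selections, percentile-bootstrap 95%
   confidence intervals (10,000 resamples), cross-condition train/test
   grids, and repetitions-to-80%-accuracy summaries.
5. **Gaze analysis**: binocular fusion (mean / adopt / never interpolate),
   affine mapping into stimulus space, per-block dwell fractions and gaze
   strategy labels, heatmaps.

## Worked example

```python
from vsabci import simulate_session
from vsabci.preprocess import standard_chain
from vsabci.decoders import ToeplitzLDA, WCBLE
from vsabci.evaluate import blockwise_cv

session = simulate_session(seed=3)          # 18 blocks, 3 VSA conditions
epochs = standard_chain(session)            # filter, re-reference, epoch, truncate

for cond in ("overt", "covert", "free"):
    cv = blockwise_cv(epochs, ToeplitzLDA, condition=cond)
    print(cond, cv.estimate)

cv_w = blockwise_cv(epochs, WCBLE, condition="covert")
print("covert/wcble", cv_w.estimate)
```

Output (accuracy with bootstrap 95% CI over n single-trial selections):

```
overt 0.867 [0.783, 0.950] (n=60)
covert 0.250 [0.150, 0.367] (n=60)
free 0.650 [0.533, 0.767] (n=60)
covert/wcble 0.333 [0.217, 0.450] (n=60)
```

Overt attention decodes well above the 1/6 chance level, covert attention is
markedly harder — its P3 is weaker and jittered in latency — and the
jitter-correcting WCBLE decoder recovers part of that loss. Accuracies vary
between simulated sessions; the pipeline quantifies that with bootstrap CIs.

The same pipeline runs from the shell:

```bash
vsabci simulate -c examples/scenario.yaml -o session/
vsabci decode -s session/ --decoder wcble --plan cross_condition -o out/
vsabci report out/report.json -o summary.md
```

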