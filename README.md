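# stainqa

Reference-free quality and hallucination assessment for virtual tissue
staining.

## The problem

Virtual staining uses a generative network to turn a label-free
autofluorescence (AF) image of an unstained tissue section into an image that
emulates the chemically stained (H&E) slide. Adversarially trained
generators hallucinate: undertrained or overfitted models produce blur,
aberrant colour, or — worse — plausible-looking content such as missing or
invented nuclei. At deployment the chemical ground truth does not exist, so
supervised image-quality metrics cannot be computed, and hallucinated images
can reach a pathologist undetected.

`stainqa` implements an autonomous assessment framework that works from the
virtual stain alone:

1. **Cycle inference.** A fixed, trusted pair of transforms — the best
   forward model `G_vs : AF → stain` and backward model `G_vaf : stain → AF`
   — is iterated from the image under test:
   `x_{t+1} = G_vaf(y_t)`, `y_t = G_vs(x_t)`, producing an alternating
   sequence of `2T` frames. Errors in the input perturb the cycle away from
   the transforms' fixed point and accumulate along the sequence.
2. **Temporal ensemble classifier.** A frozen convolutional backbone embeds
   each frame; `C` independently seeded temporal heads score the sequence
   and soft voting averages them: `s_(C) = (1/C) Σ s_(i)`, with `s ∈ [0,1]`
   higher for hallucinated inputs. The decision threshold `α` is the largest
   threshold with validation sensitivity 1.0 (reject iff `s ≥ α`).
3. **Model-level gate.** A whole staining model is accepted or rejected from
   the voted scores of `N` of its images: class-conditional Gaussians are
   fitted to the score logits, the threshold `β` is their equal-density
   point, and the model is rejected iff the mean score `s̄ ≥ β`.
4. **Metrics and nuclei QC.** The full supporting metric suite (m.s.e., PCC,
   PSNR, global SSIM, pooled t, binned KL divergence, Hellinger distance,
   G-tests, ROC/PR curves) and a hand-crafted stain QC pipeline
   (stain-vector colour deconvolution, Otsu segmentation, nuclei count and
   area features).

A seeded synthetic generator renders paired AF/H&E-like patches with planted
nuclei and controllable degradations (nuclei dropout, blur, colour shift,
noise), so the entire pipeline trains and evaluates in minutes on one CPU —
no data downloads, no GPU. All networks run on a small numpy
autodifferentiation engine bundled with the package.

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Train the desk-scale study end to end (synthetic data, transform training,
cycle inference, ensemble training) and inspect the result:

```python
from stainqa.experiments import StudyConfig, run_study, model_level_assessment

study = run_study(StudyConfig(seed=0))     # ~5 min on one CPU core
print("alpha =", round(study.alpha, 4))
for k in ("accuracy", "sensitivity", "specificity", "roc_auc"):
    print(k, "=", round(study.test_metrics[k], 4))

gate = model_level_assessment(study)
print("beta =", round(gate["lda"].beta, 4))
print(gate["table"][gate["table"].N == 20][
    ["model_id", "label", "mean_sbar", "decision_accuracy"]])
```

prints

```
alpha = 0.697
accuracy = 0.99
sensitivity = 0.98
specificity = 1.0
roc_auc = 1.0
beta = 0.3878
       model_id label  mean_sbar  decision_accuracy
3        good_0  good   0.042729                1.0
7        good_1  good   0.028714                1.0
11       good_2  good   0.020389                1.0
15       good_3  good   0.025459                1.0
19       good_4  good   0.043759                1.0
23   poor_early  poor   1.000000                1.0
27  poor_drop_a  poor   0.802443                1.0
31  poor_drop_b  poor   0.956806                1.0
35    poor_blur  poor   0.999011                1.0
39  poor_drop_c  poor   0.997435                1.0
```

Read: on 100 held-out synthetic fields of view the `T = 5`, `C = 3` ensemble
rejects 98% of hallucinated images while passing every clean one at the
100%-validation-sensitivity threshold `α`; and averaging the scores of
`N = 20` images per staining model, every good model falls below the LDA
threshold `β` (accepted) and every degraded model above it (rejected).
Absolute scores and thresholds are fixture-specific; see `docs/methods.md`
for what the synthetic study does and does not demonstrate.

The same stages are scriptable from the shell — `stainqa simulate`,
`train-staining`, `label-checkpoints`, `cycle`, `train-classifier`, `score`,
`assess-model`, `qc-hs`, `metrics`; run `stainqa --help`.

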