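# mindwander

Detection of mind wandering from EEG event-related potentials, within and
across individuals.

During sustained tasks, attention drifts from the external world to
internal, self-generated thought ("mind wandering"), and the brain's
stimulus-evoked responses shrink: the early auditory **N1** (a negative
deflection ~100 ms after a tone, maximal fronto-centrally) and the later
**P3** (a positive deflection ~400–600 ms, maximal parietally) are both
attenuated.  `mindwander` implements the full analysis pipeline that turns
this observation into a decoder of attentional state:

1. **Simulation** — synthetic auditory-oddball sessions: 14 subjects,
   25 blocks of 45–75 s, 1500 tones (1200 standard at 800 Hz / 300 target
   at 1000 Hz, p = 0.8/0.2), 800–1200 ms inter-trial jitter, epochs of
   −1000…+2000 ms at 512 Hz on six analysis electrodes (FC1, FCz, FC2,
   P1, Pz, P2).  Each block ends in a thought probe labelling it
   *on task* (0) or *mind wandering* (1); N1/P3 amplitudes are attenuated
   during mind wandering and buried in 1/f + white sensor noise.
2. **ERP features** — per block, the last ≤10 artifact-free pre-probe
   trials (standard tones only) are band-passed 1–15 Hz (zero-phase),
   baselined to −200…0 ms, and reduced to four features: mean and sample
   SD of the per-trial N1 minimum (80–120 ms) and P3 maximum (400–600 ms).
   Features are centred per subject on the on-task mean.
3. **Balancing** — SMOTE oversampling of the minority attention state
   (each synthetic row is `x + γ·(z − x)` for a real minority row `x`,
   a k-nearest minority neighbour `z`, and `γ ~ U[0,1]`), plus exclusion
   of subjects with fewer than 5 minority blocks.
4. **Classification & evaluation** — an RBF-kernel SVM and an L2
   logistic regression, evaluated person-dependently (stratified 5-fold
   CV over one subject's 25 blocks) and person-independently
   (leave-one-subject-out), scored by accuracy, AUC, MCC and
   per-actual-class-normalized confusion matrices.
5. **Univariate statistics** — 2×2 attention × tone ANOVA on per-subject
   cell means of the peak amplitudes, post-hoc paired t-tests, and the
   behavioural reaction-time contrast.

It is aimed at cognitive-neurophysiology researchers who want a tested,
reproducible reference implementation of this detection protocol — either
to benchmark on simulated data or to run on their own pre-extracted
feature tables (a documented CSV schema).

## Worked example

```python
import mindwander as mw

cfg = mw.GeneratorConfig(seed=3).short_blocks()   # quick preset, ~13-trial blocks
model = mw.MindWanderingModel.from_simulation(cfg, seed=3)
print(model.fit(mode="across", seed=3).summary())
```

```
Mind-wandering detection results
==============================================
mode:              person-independent (LOSO)
model family:      rbf_svm
subjects:          9  (excluded: sub-05, sub-06, sub-08, sub-11, sub-13)
----------------------------------------------
metric          mean        SD
accuracy       0.858     0.151
auc            0.958     0.062
mcc            0.759     0.193
----------------------------------------------
confusion (columns: actual MW, actual not-MW)
  pred MW      0.835    0.109
  pred not-MW  0.165    0.891
```

Five subjects drew extreme mind-wandering rates and reported fewer than
five minority-class blocks, so the N < 5 rule removed them before the
leave-one-subject-out loop.  For the nine retained subjects the SVM
detects the simulated attentional attenuation (default 30 % amplitude
reduction during mind wandering) well above chance: mean AUC 0.958
(chance 0.5), mean MCC 0.759 (chance 0).  The confusion matrix is
column-normalized: 83.5 % of truly mind-wandering blocks are flagged as
such.  Single-feature models (`model.ablate(seed=3)`) rank the component
means (`n1_mean` AUC 0.879, `p3_mean` 0.857) above the variability
features (`n1_sd` 0.610, `p3_sd` 0.676), as expected when the injected
effect is a mean shift.

A command-line interface covers the same stages
(`mindwander simulate|features|evaluate|ablate|stats|run`), e.g.:

```bash
mindwander run --seed 3 --out my_run     # all stages, artifacts under my_run/
```

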