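# entrocsp

Entropy-based EEG channel selection with filter-bank common-spatial-pattern
(CSP) features for two-class motor-imagery (MI) classification.

Motor imagery modulates sensorimotor rhythms (mu, ~8–13 Hz; beta, ~13–35 Hz)
through event-related desynchronization: imagining a movement *reduces*
band-limited power over the corresponding cortical area. Modern recordings use
dozens to hundreds of electrodes, but most channels carry little
task-relevant signal, inflating computation and hurting accuracy. This
package implements a selection-first pipeline for brain–computer-interface
researchers:

1. **Channel scoring.** Each channel *l* of each trial *m* is scored by the
   Shannon entropy of its amplitude histogram,
   `h_l = (1/M) Σ_m [ −Σ_b p_b ln p_b ]`,
   with equal-width bins over that trial's amplitude range. Channels are
   ranked by mean entropy and the top *k* retained (high entropy ≈ richer,
   less predictable signal).
2. **Sub-band decomposition.** Selected channels are split into mu (8–13 Hz),
   low beta (13–22 Hz), high beta (22–35 Hz) and full band (8–35 Hz) with
   zero-phase 5th-order Butterworth filters.
3. **CSP features.** Per band, spatial filters solve
   `w = argmax (wᵀB₁w)/(wᵀB₂w)` via the generalized eigenproblem
   `B₁w = λ(B₁+B₂)w`, where `B_c` are trace-normalized class covariances.
   The V=2 filters from each spectral end give per-trial log-variance
   features `f_v = ln var(w_vᵀx)`, concatenated over bands into a
   16-dimensional vector.
4. **Classification.** SVM (RBF kernel), LDA, or a small neural network,
   evaluated with stratified 5-fold cross-validation in which channel
   ranking, CSP and the classifier are all refit inside each training fold
   (no information leak), reporting accuracy, precision, recall and F1.

A seeded generator of synthetic two-class MI-EEG (band-limited sources with
class-dependent amplitude on known channels, broadband noise elsewhere)
provides ground truth for every stage, so the whole pipeline is testable
without downloading recordings. Readers for the MATLAB files distributed by
the BCI Competition III-IVa / IV-I organisers are included for users who have
those datasets.

## Worked example

```python
import entrocsp as ec

# 120 synthetic trials: 4 of 16 channels carry a mu-band source whose
# amplitude drops to 40% in class 2 (strong ERD contrast)
epoched, truth = ec.simulate_mi_eeg(
    ec.SimConfig(trials_per_class=60, erd_ratio=0.4, seed=1))

report = ec.cross_validate(epoched, ec.PipelineConfig(n_select=4),
                           n_folds=5, seed=1)
print("mean accuracy:", report.mean["accuracy"])
print("fold-0 channels:", report.selected_channels[0])
print("planted channels:", truth.informative_channels)
```

prints

```
mean accuracy: 1.0
fold-0 channels: ['ch05', 'ch11', 'ch08', 'ch02']
planted channels: (2, 5, 8, 11)
```

The entropy ranking recovered exactly the four channels carrying the source
(in its own order), and the fold-wise pipeline separates the two classes
perfectly at this contrast. Shuffling the labels of the same data drops the
mean accuracy to ≈ 0.5, confirming the protocol does not leak.

The same pipeline from a shell:

```sh
entrocsp simulate --out data/sim --trials-per-class 60 --erd-ratio 0.4 --seed 1
entrocsp run-pipeline data/sim --out results/
entrocsp sweep data/sim --ks 2,4,8,16
```

`run-pipeline` writes `ranking.csv`, `features.csv`, `model.json` and
`report.json`; `show-config` prints every default; a YAML file passed with
`--config` overrides any of them.

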