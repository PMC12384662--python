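# microcaps

Automated detection of epileptic seizure states in **single-channel EEG**
with a compact **capsule network**. The package targets the small-sample
regime of the public Bonn EEG corpus (five sets A–E of 100 single-channel
files, 4096 points at 173.61 Hz): short 1 s windows are expanded into small
2-D matrices and classified by a micro capsule network trained with a
margin loss, separating normal, interictal and ictal states.

It is aimed at researchers who want a fully reproducible, dependency-light
reference implementation of capsule routing for biomedical time series:
the network — including backpropagation — runs on a small reverse-mode
autodiff core over numpy, with no deep-learning framework required.

## Model

A window of `L` amplitudes is written row-major into an `h x w` matrix
(`h/w <= 2`, zero-padded tail) and passed through

```
(h, w, 1) ── 8 x 4x4 conv, same, ReLU ──> (h, w, 8)
          ── two 4x4 valid convs, ReLU ──> (h-6, w-6, 8)
          ── reshape + squash          ──> n_primary capsules u_i ∈ R^4
          ── û_{j|i} = W_ij u_i        ──> predictions per class capsule
          ── routing-by-agreement (r=3)──> label capsules v_j ∈ R^16
          ── ‖v_j‖                     ──> class presence probabilities
```

with `squash(s) = (‖s‖²/(1+‖s‖²)) s/‖s‖` and coupling coefficients
`c_ij = softmax_j(b_ij)` updated by the agreement `û_{j|i}·v_j`. Training
minimises the margin loss

```
L_k = p_k max(0, m⁺-‖v_k‖)² + λ(1-p_k) max(0, ‖v_k‖-m⁻)²,
m⁺ = 0.9,  m⁻ = 0.1,  λ = 0.5
```

with Adam (lr 5e-4, batch 32). For the 342-point window preset the input
is (19, 18, 1), the feature map (13, 12, 8), and there are 312 primary
capsules — see `docs/methods.md` for every architectural and protocol
decision.

## Worked example

The library is sklearn-style; the snippet below generates a small
synthetic corpus (the generator emulates background, interictal spiking
and ictal spike-wave EEG at the Bonn dimensions), runs the full protocol —
sliding-window segmentation, 7:3 stratified split, 3-fold cross-validation,
one model per fold, shared test set — and prints the cross-validated
metrics:

```python
from microcaps import (DatasetCase, SegmentationConfig, SynthConfig,
                       TrainConfig, run_case)
from microcaps.synth import gen_class_recordings

cfg = SynthConfig(seed=7, classes=("background", "ictal"))
recordings = {c: gen_class_recordings(cfg, c) for c in cfg.classes}
case = DatasetCase("background_vs_ictal", {"background": 0, "ictal": 1})
report = run_case(recordings, case, SegmentationConfig(),
                  TrainConfig(epochs=8, seed=1))
print(report)
```

```
background_vs_ictal: acc 100.00±0.00% sens 100.00±0.00% spec 100.00±0.00%
```

Accuracy, sensitivity (ictal detection rate) and specificity are mean ± sd
over the three fold-models, in percent; the synthetic regime is easy by
design, so near-ceiling numbers here validate the pipeline, not clinical
performance. The same protocol is exposed on the command line:

```bash
microcaps synth --config run.yaml --out data/synthetic
microcaps train --config run.yaml --data data/synthetic \
    --case background_vs_ictal --out runs/bg_vs_ictal
microcaps sweep --config run.yaml --data data/synthetic \
    --case background_vs_ictal --out runs/sweep      # 0.6–1.4 s windows
microcaps eval --checkpoint runs/bg_vs_ictal/fold0_model.npz \
    --data data/synthetic --config run.yaml --case background_vs_ictal
```

## Using the Bonn corpus

The package never downloads data. Place the five sets as plain ASCII files
under `data/bonn/A/ … data/bonn/E/` (one amplitude per line, 4096 lines per
file) and the standard cases `AB_vs_E`, `C_vs_E`, `D_vs_E` and
`A_vs_C_vs_E` become runnable through `microcaps train` or
`microcaps.run_case`; the corpus-dependent tests in
`tests/test_acceptance.py` activate automatically when the directory is
present.

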