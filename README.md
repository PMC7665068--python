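# dgntrace

Unsupervised analysis of single-molecule fluorescence intensity traces
with a discriminator–generator biLSTM network (DGN): photobleaching step
counting for subunit stoichiometry, and dynamic finding — state
occupancies, transition rates and dwell times of protein aggregation —
from the same per-frame hidden state paths.

## Who this is for

Single-molecule biophysicists with TIRF-derived intensity traces (one
intensity per frame after spot detection/tracking) who want the hidden
fluorophore-count path behind each trace without hand-tuned step filters,
a predefined state number, or manual labeling.

## The method

A trace x = (x_1…x_T) is modeled as a noisy rendering of a hidden
fluorophore-count path h. A **discriminator** (biLSTM, 32 units per
direction, per-frame softmax) maps x to a posterior over states 0…s_max;
a **generator** (biLSTM, 16 units per direction, linear head) reconstructs
x̂_t from the posterior h_t and the previous value x̂_{t−1}. Both are
trained jointly to minimize the quadratic reconstruction loss
L = (1/2T)Σ(x̂_t−x_t)², so the posterior must explain the trace — no labels
needed. Synthetic traces with known ground truth add an annealed
cross-entropy: with α = 0.5·e^(−2k/K) over epochs k, labeled batches
minimize (1−α)L + αL_h. After training, the discriminator alone decodes
the state path (per-frame argmax); blinking dips are rejected by the
temporal context the bidirectional LSTM carries, and no Markov assumption
is imposed on the hidden process.

A from-scratch Gaussian-emission HMM (Baum–Welch + Viterbi) provides the
classical baseline, and a calibrated simulator generates training and
benchmark data at target adjusted signal-to-noise ratios
(aSNR = mean over adjacent states of 2Δμ/(σ_i+σ_{i+1})).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from dgntrace import synthesize_dataset, DGNModel, TrainConfig
from dgntrace.analyze import confusion_and_accuracy, population_distribution

# 300 photobleaching traces, up to 10 fluorophores, calibrated to aSNR 4.74
ds = synthesize_dataset("photobleach", s_max=10, n_traces=300,
                        n_frames=200, target_asnr=4.74, seed=42)
print(f"achieved aSNR: {ds.achieved_asnr:.2f}")

res = DGNModel(ds).fit(TrainConfig(epochs=15, seed=7))
print(res.summary())

test = ds.subset("test")
pred = res.predict_paths(test.traces())
rep = confusion_and_accuracy(pred, [r.path for r in test.records])
print(f"min per-state accuracy: {rep.min_state_accuracy:.3f}")
print("step-count fractions:", np.round(population_distribution(pred), 3))
```

prints (exact numbers from this seed):

```
achieved aSNR: 4.72
Discriminator-Generator Network Results
===========================================
states (s_max + background): 10 + 1
unit intensity (normalization): 100
parameters: 13164
epochs: 15
final train loss: 0.0538
final val loss:   0.0344
final alpha:      0.0773
min per-state accuracy: 0.521
step-count fractions: [0.    0.    0.089 0.022 0.133 0.133 0.111 0.133 0.044 0.156 0.178]
```

The minimum per-state accuracy (the smallest diagonal of the
row-normalized confusion matrix) is the headline score, and it is the
quantity that needs training scale: this demonstration corpus is an
order of magnitude below the benchmark protocols (300 × 200-frame traces,
15 epochs, versus a pooled multi-aSNR corpus trained for 60 epochs —
see `docs/methods.md`), so the rarest states drag the minimum to ~0.5
here while the benchmark models reach 0.79–0.92 bootstrap means. The
step-count fractions estimate the population stoichiometry distribution
of the 45-trace test split.

The same objects handle dynamic (state-switching) data with
`mode="dynamic"`, and `dgntrace.analyze` turns decoded paths into
occupancies, transition-rate matrices (s⁻¹) and exponential dwell-time
constants. A CLI mirrors the pipeline:

```bash
dgntrace simulate --mode photobleach --asnr 2.98 --n 100 --seed 7 --out ds/
dgntrace train --data ds/manifest.yaml --out model.npz --epochs 30
dgntrace predict --data ds/manifest.yaml --model model.npz --out paths.csv
dgntrace evaluate --data ds/manifest.yaml --model model.npz --out report/
```

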