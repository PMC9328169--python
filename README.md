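# qrstangle

Estimation of the **spatial QRS-T angle** from reduced-lead ECGs.

The spatial QRS-T angle α is the 3-D angle between the dominant
depolarization (QRS) and repolarization (T) vectors of a heartbeat; wide
angles (≥ ~110°) are an established marker of elevated sudden-cardiac-death
risk. Conventionally α is computed from the vectorcardiogram (VCG) — leads
X, Y, Z — which requires a full 12-lead recording and is therefore
impractical for ambulatory monitoring with patch- or textile-based devices
that record only a handful of leads.

This package implements both routes and the machinery connecting them:

- **Conventional computation** (`core_geometry`): for a signal-averaged VCG
  beat v(t), the loop origin v₀ is the componentwise median over the 25 ms
  before QRS onset; each loop is summarized by the dominant vector

  u = mean{ v(t) − v₀ : ‖v(t) − v₀‖ ≥ 0.7 · maxₜ ‖v(t) − v₀‖ },

  and α = atan2(‖u_QRS × u_T‖, u_QRS · u_T).
- **Kors transform** (`kors_vcg`): [X;Y;Z] = M·[I;II;V1…V6] with the 3×8
  regression matrix shipped as an auditable text table.
- **Preprocessing** (`preprocessing`): zero-phase Butterworth band limiting
  (0.5–45 Hz), R-peak detection, template-correlation beat quality,
  record-eligibility rules, R-aligned signal averaging, and model-input
  formatting (250 Hz, zero-padded to 550 samples, sex/age scaled).
- **Labeling and splitting** (`labeling_split`): per-record targets
  (u_QRS, u_T, α, metadata, morphological class incl. LOWM for
  ‖u_T‖/‖u_QRS‖ < 0.1) and a class × sex × 5°-bin stratified 80:20 split
  (50:50 for LOWM).
- **CNN regressor + composite loss** (`model_loss`): a compact 1-D CNN
  (depthwise first block, residual blocks with channel doubling, global
  average pooling, metadata-aware dense head) maps reduced-lead averaged
  beats to the six coordinates of (û_QRS, û_T); α̂ is the angle between
  them. Training minimizes

  L = w₁·(L_d(u_QRS, û_QRS) + L_d(u_T, û_T)) + w₂·L_α(α, α̂),

  where L_d is the Euclidean distance between unit-normalized vectors
  (∈ [0, 2], = 2 at antiparallel directions) and L_α the mean absolute
  angle error in radians. Default weights (w₁, w₂) = (0.8, 0.2). The
  network and its backpropagation are implemented in NumPy.
- **Evaluation** (`evaluation`): RMSE / mean / median absolute error,
  bias-corrected percentile bootstrap CIs (5000 resamples), Spearman ρ,
  Bland-Altman agreement with limits at median bias ± 1.45·iqr, and
  per-5°-bin error profiles.
- **Synthetic generator** (`synthetic_data`): two-dipole beats with exactly
  known u_QRS, u_T, α, projected to 12 leads through the Kors
  pseudo-inverse and written as WFDB records, so the whole pipeline runs —
  and is testable against closed-form ground truth — without any download.

## Worked example

```bash
qrstangle synth --n 200 --seed 7 --out data/
qrstangle label --data data/ --out labels.csv
qrstangle split --labels labels.csv --seed 7 --out split.csv --min-class-count 1
qrstangle train --data data/ --labels split.csv --leads I,II,aVF,V2 \
    --depth 3 --kernels 16 --epochs 30 --seed 0 --out model
qrstangle evaluate --model model --data data/ --labels split.csv --out report.json
```

On a 1000-record synthetic training set (angles uniform on 10–150°, leads
{I, II, aVF, V2}, D = 3, k = 16, 30 epochs) the same pipeline, run through
the library API, printed:

```
 epoch  train_loss  val_loss  val_median_abs_err_deg
     1       2.045     1.875                  33.255
    15       1.109     0.946                  19.694
    30       0.822     0.763                  16.647
rho 0.719
```

i.e. the validation median absolute angle error fell from ~30° (an
untrained network, or always predicting the training median) to ~16°, with
Spearman ρ = 0.72 between α̂ and α. The composite loss starts near
w₁·2·√2 ≈ 2.26 (random directions) and decreases as both predicted
directions converge toward their targets.

The same library API is shown in miniature below:

```python
from qrstangle import SyntheticBeatSpec, generate_record, label_record

rec = generate_record(SyntheticBeatSpec(alpha_true=60.0, noise_sd=0.0,
                                        loop_spread=0.0, seed=7))
label = label_record(rec.record, r_peaks=rec.r_peaks)
print(round(label.alpha, 2))   # 59.99 — the pipeline recovers the true angle
```

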