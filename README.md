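# nirs-vispercept

Quantifying visual perception from two-wavelength functional near-infrared
spectroscopy (fNIRS) recordings.

In a block-design driving-simulator task, participants judge four kinds of
interface questions (layout, design, color, information) under two picture
saturations while a 15-channel fNIRS montage (5 optode sites × 3
sub-channels) records light intensities at 760 and 850 nm. This package
implements the complete analysis chain from those raw intensities to task
classification and questionnaire-score comparison:

1. **Modified Beer–Lambert inversion** — per channel and sample,
   ΔOD(λ) = log₁₀(I_b(λ)/I_t(λ)) = [ε_HbO₂(λ)·ΔHbO₂ + ε_Hb(λ)·ΔHb]·d·DPF;
   the two-wavelength 2×2 system is solved in closed form and
   ΔHbt = ΔHbO₂ + ΔHb.
2. **Signal preparation** — zero-phase second-order Butterworth band-pass
   (0.01–0.5 Hz default), min–max normalization
   x′ = (x − min x)/(max x − min x), and protocol-driven windowing
   (per-trial task/baseline windows, or one window per stage).
3. **Channel screening** — plug-in mutual information
   I(X;Y) = Σ p(x,y) log₂ [p(x,y)/(p(x)p(y))] between all channel pairs;
   the 7 channels with the highest mean off-diagonal MI are retained per
   question and signal.
4. **Features** — nine per (window, channel, signal): duration, mean,
   median, variance, range, kurtosis, skewness, Shannon entropy, and
   approximate entropy ApEn(m, r) = Φᵐ(r) − Φᵐ⁺¹(r).
5. **Classification** — recursive feature elimination to 30 features, then
   KNN with K chosen by inner cross-validation, evaluated out-of-fold under
   stratified 5-fold CV; accuracy/precision/recall/F1 are reported one-vs-rest
   per class with a mean ± SD summary.
6. **Score comparison** — questionnaire scores split at the mean into
   high/low groups; Welch tests per channel and signal on fixation-referenced
   participant-level task means.

Because no public recording of this protocol exists, the package ships a
first-class forward simulator (`simulate_study`) that reproduces the
experiment's statistical structure — 16-trial sessions (2 × 4 × 2 design),
stage durations 4/6/6/8 s, double-gamma hemodynamic responses with
anticorrelated Hb, physiological noise, and scores coupled to response
gain — so every stage is testable end to end.

## Worked example

```python
import nirs_vispercept as nv
from nirs_vispercept.channel_screen import mi_matrix, pooled_retention

cfg = nv.SimulationConfig(n_participants=6, seed=11)
study = nv.simulate_study(cfg, optics=nv.MBLLConfig())

optics = nv.MBLLConfig()
sets = []
for p in study.participants:
    hemo = nv.invert_mbll(p.recording, optics)          # intensities -> ΔHbO₂/ΔHb/ΔHbt
    filt = nv.bandpass(hemo)                            # 0.01–0.5 Hz, zero phase
    sets.append(nv.segment_windows(nv.normalize_series(filt), p.schedule,
                                   mode="per_stage", participant=p.participant))
windows = nv.concat_window_sets(sets)                   # 384 windows (6 x 64)

selection = nv.select_channels(windows, n_bins=10, k=7)
print(selection.retained[("layout", "hbo2")])
# ['1c', '2b', '3c', '4b', '4c', '5a', '5c']

mats = [mi_matrix(windows, q, s) for q in nv.QUESTIONS for s in windows.signals]
chans = pooled_retention(mats, k=7)
table = nv.feature_table(windows, channels=chans, classes=16)
X, y, _ = nv.feature_matrix(table)                      # (384, 189): 7 ch x 3 signals x 9
result = nv.knn_crossval(X, y, seed=42)
print(nv.build_report(y, result.predictions).to_table().loc[["layout/diagram", "Average"]])
#                     accuracy    precision       recall           f1
# layout/diagram         100.0        100.0        100.0        100.0
# Average          99.7 ± 0.41  97.7 ± 3.46  97.7 ± 4.56  97.6 ± 3.39
```

Each report row is the one-vs-rest confusion of one of the 16
stage × question classes, in percent; the `Average` row is the unweighted
mean ± SD across classes. On this simulated cohort the stage × question
structure is recovered almost perfectly because each class carries a
distinct per-channel response pattern well above the noise floor.

The same chain is scriptable from the shell:

```bash
nirs-vispercept simulate --out data/ --seed 11 --participants 6
nirs-vispercept run --out results/ --seed 11
```

`RfeKnnClassifier` is a scikit-learn estimator (fit/predict,
`get_params`/`set_params`) and composes with sklearn model selection.

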