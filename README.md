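# ovotrace

A visible/near-infrared (Vis/NIR) spectroscopy toolkit for **food origin
authentication**, built around the pipeline used for geographic origin
classification of intact duck eggs from their 400–1100 nm transmission
spectra. It is aimed at chemometricians and food-quality engineers who need
a reproducible, scriptable implementation of the full chain:

1. **Preprocessing** — multiplicative scatter correction (MSC), standard
   normal variate (SNV), or Savitzky–Golay (SG) smoothing;
2. **Wavelength selection** — the successive projections algorithm (SPA)
   and competitive adaptive reweighted sampling (CARS) over a partial least
   squares (PLS) engine;
3. **Classification** — random forest, RBF-kernel SVM, and a convolutional
   neural network whose 2-D input is the outer-product matrix
   `S = x xᵀ` of each sample's selected-wavelength vector;
4. **Evaluation** — per-class precision `P = TP/(TP+FP)`, recall
   `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`, classification error `E = 1 − R`,
   and overall (micro) accuracy.

Because no public duck-egg spectra exist, the package ships a synthetic
generator that reproduces the reported class structure — band-mean ordering
Jiangsu > Henan > Sichuan over 550–900 nm and a class-ordered 700:800 nm
absorption-peak depth ratio, with per-sample multiplicative scatter and
noise — so every stage is testable end-to-end. See `docs/methods.md` for
the models and all numerical choices.

## Worked example

```python
import numpy as np
import ovotrace as ot
from ovotrace.metrics import format_report
from ovotrace.cnn import TrainConfig

train, test, _ = ot.make_benchmark()          # 182 / 79 / 90 samples
tr, te = ot.snv(train), ot.snv(test)          # scatter correction
sel = ot.spa_select(tr, max_vars=12)          # wavelength selection
print("selected wavelengths (nm):", np.round(sel.selected_wavelengths_nm, 1))

trs = tr.subset_columns(sel.selected_indices)
tes = te.subset_columns(sel.selected_indices)
clf = ot.train_cnn(trs, cfg=TrainConfig(max_epochs=50, seed=0))
report = ot.class_report(ot.confusion(te.y, ot.predict(clf, tes)))
print(format_report(report))
```

prints (about a minute on one CPU):

```
selected wavelengths (nm): [1091.5  800.  1096.   801.   792.5 1094.   795.   443.   688.5 1084.
 1089.5  929.5]
Category     Number      P/%      R/%     F1/%      E/%    Acc/%
0 (Sichuan)      24   100.00   100.00   100.00     0.00   100.00
1 (Jiangsu)      30   100.00   100.00   100.00     0.00
2 (Henan)        25   100.00   100.00   100.00     0.00
```

SPA settles on 12 wavelengths: a cluster on the 800 nm absorption band and
around the 700 nm band shoulder (688.5 nm), plus band-level and edge
wavelengths that track the class-dependent mean level — both structures the
generator plants. The CNN (trained 50 epochs here) separates the three
origins perfectly on this benchmark; so do the RF and SVM models. At the
moderate-noise preset the benchmark is separable by construction, so these
100.00 values demonstrate the machinery, not field performance on real
eggs.

## Command line

The same stages are available as subcommands:

```sh
ovotrace simulate --seed 1 --out spectra.csv
ovotrace preprocess --method snv --inp spectra.csv --out snv.csv
ovotrace select --method spa --max-vars 12 --inp snv.csv --out selection.json
ovotrace train --model cnn --selection selection.json --inp snv.csv --out model.pkl
ovotrace predict --model-file model.pkl --inp snv.csv --out predictions.csv
ovotrace evaluate --truth snv.csv --predictions predictions.csv
ovotrace run --config pipeline.yaml      # full pipeline, one config file
```

Spectra tables are delimited text (header: `sample_id, origin,
<wavelength nm>, ...`, one sample per row); selection reports and metrics
are JSON; every `run` writes a manifest with the config hash and seed that
reproduce it.

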