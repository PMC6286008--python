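# regpoincare

Lagged Poincaré-plot analysis of rheoencephalographic (REG) cerebral
blood-flow signals.

REG measures electrical impedance through the scalp: each heartbeat pushes
blood into the head, impedance drops, and the recorded trace is a pulsatile
waveform (~1 s period, ~0.1 Ω pulse amplitude at 250 Hz). Breath holding
(apnea) raises cerebral blood flow and changes the beat-to-beat regularity
of this waveform. This package implements the full nonlinear analysis chain
that detects that change, for researchers working on impedance-based brain
monitoring or on lagged Poincaré methods for other pulsatile biosignals.

## What it computes

A Poincaré plot is the two-dimensional delay embedding of a signal `x`:
the point cloud (x(t), x(t+τ)) for a lag of τ samples. From each plot the
package extracts

- **SD1, SD2** — standard deviations across and along the identity line:
  `SD1 = std((x − y)/√2)`, `SD2 = std((x + y)/√2)`;
- **SDarea** = π·SD1·SD2, the fitted-ellipse area;
- **SDratio** = SD1/SD2, a dimensionless regularity index;
- **R** — Pearson correlation of the signal with its lagged copy;
- **CCM** — the Complex Correlation Measure: the mean unsigned area of the
  triangles formed by consecutive point triplets, normalised by the ellipse
  area, which captures temporal ordering that variance descriptors ignore.

Around this core sit: a synthetic REG generator with distinct apnea and
baseline regimes (no public REG recordings exist), Chebyshev-II band
limiting (0.1 Hz high-pass, 20 Hz low-pass, zero phase) with automatic
artifact screening, classical pulse-wave geometry features, eight
literature criteria for choosing the embedding lag plus a CCM-inflection
criterion, normality-gated group statistics with ROC analysis, and
Relief-weighted leave-one-out classification (logistic regression, Gaussian
naive Bayes, linear SVM, CART).

## Worked example

```python
import numpy as np
from regpoincare import generate_dataset, poincare, tau_selection, group_stats

segments = generate_dataset(n_apnea=29, n_baseline=24, seed=7)
table = poincare.feature_sweep(segments, range(1, 71))
print(f"{len(table)} descriptor rows from {len(segments)} segments")

stats = group_stats.group_comparison_sweep(table, features=("SDratio", "R", "CCM"))
best = stats.loc[stats.groupby("feature")["p"].idxmin()]
print(best[["feature", "tau", "p", "auc"]].to_string(index=False))

knee = tau_selection.ccm_inflection(table.groupby("tau")["CCM"].median().to_numpy())
print(f"CCM inflection (knee) at tau = {knee} samples")
```

prints

```
3710 descriptor rows from 53 segments
feature  tau        p      auc
    CCM   52 0.000007 0.862069
      R    2 0.000007 0.862069
SDratio    2 0.000007 0.862069
CCM inflection (knee) at tau = 27 samples
```

Reading: 53 segments swept over lags 1–70 give 3710 descriptor rows.
SDratio and R separate apnea from baseline best at very small lags (τ = 2
samples, 8 ms), while CCM stays discriminative across the whole lag range —
the regularity change shows up in short-range temporal structure. The CCM
curve falls with τ and flattens near τ ≈ 27; that knee marks where the
signal and its delayed copy lose correlation and is itself a usable upper
bound for the lag sweep.

The same pipeline is scriptable from a shell:

```bash
regpoincare simulate --n-apnea 29 --n-baseline 24 --seconds 16 --seed 7 --out data/
regpoincare features --in data/ --tau-min 1 --tau-max 70 --out features.csv
regpoincare stats --features features.csv --out stats/
regpoincare classify --features features.csv --tau-max 13 --out models/ --seed 0
```

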