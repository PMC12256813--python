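# sinkindex

Dynamic-network **sink-index** markers from multichannel scalp EEG.

Neurodegenerative syndromes such as frontotemporal dementia (FTD) and
Alzheimer's disease (AD) disrupt how brain regions drive one another.
`sinkindex` quantifies that disruption directly from resting-state scalp
EEG: it fits a subject-specific *linear time-varying dynamic network
model* — a sequence of state-transition matrices, one per short time
window — and summarizes each channel's role in the network as a **sink
index**: high for channels that are strongly driven by the network while
driving little themselves ("sinks"), low for the converse ("sources").
Regions affected by focal pathology tend to behave as sinks, so the ratio
of sink indices between the frontal–temporal (FT) and
central–parietal–occipital (CPO) electrode groups becomes a scalar
per-subject marker that separates FTD-like, AD-like and healthy dynamics.

The package is aimed at EEG methods researchers: it covers ingest
(EDF / EEGLAB `.set` / CSV, BIDS-style participants tables),
preprocessing, model fitting, sink-map construction, conventional
spectral / time-frequency baseline features, one-vs-rest LOOCV
classification, nonparametric group statistics, a synthetic-cohort
generator with planted ground truth, figures, and a CLI.

## The model and the marker

Within each non-overlapping window of duration T = 125 ms the multichannel
signal x(t) ∈ R^N follows a one-step linear model

```
x(t+1) = A x(t) + e(t)
```

with A ∈ R^(N×N) estimated by least squares (30 regression pairs per
window at 250 Hz) and e(t) white Gaussian noise. Entry A_ij measures how
channel j's activity drives channel i at the next step. For each window
the row and column 2-norms of A are ranked across channels and normalized
to {1/N, …, 1}; channel i's coordinates (rr_i, cr_i) are compared with the
ideal sink corner (rr = 1: most driven; cr = 1/N: least driving):

```
SI_i = √2 − ‖(rr_i, cr_i) − (1, 1/N)‖₂
```

so SI ∈ [√2/N, √2] ≈ [0.074, 1.414] for N = 19. Sink indices are averaged
over all windows, then over the FT group {Fp1, Fp2, F3, F4, F7, F8, T3,
T4} and the CPO group {O1, T5, O2, T6, Cz, Pz, P3, Fz, P4, C3, C4}; the
subject marker is `SI_FT / SI_CPO`.

## Worked example

```python
import numpy as np
from sinkindex import (SyntheticCohortConfig, generate_cohort,
                       fit_dnm, sink_map, subject_marker)
from sinkindex.classify import evaluate_ovr

cfg = SyntheticCohortConfig(duration_s=60.0, seed=7)   # 10 FTD / 10 AD / 10 HC
recordings, cohort = generate_cohort(cfg)

ratios, labels = [], []
for rec, (_, row) in zip(recordings, cohort.iterrows()):
    marker = subject_marker(sink_map(fit_dnm(rec)), subject_id=rec.subject_id)
    ratios.append(marker.si_ratio)
    labels.append(row["group"])

for g in ("FTD", "HC", "AD"):
    med = np.median([r for r, l in zip(ratios, labels) if l == g])
    print(f"{g}: median SI ratio {med:.3f}")

report = evaluate_ovr(np.asarray(ratios)[:, None], np.asarray(labels),
                      "random_forest", seed=7)
print(f"micro AUC {report.micro_auc:.3f}")
```

Output:

```
FTD: median SI ratio 1.419
HC: median SI ratio 0.987
AD: median SI ratio 0.693
micro AUC 1.000
```

FTD-like subjects (sinks planted at FT electrodes) sit well above 1,
AD-like (sinks at CPO electrodes) well below, healthy-like near 1 — and
the scalar ratio alone separates the three synthetic cohorts perfectly
under LOOCV.

The same analysis runs from the shell:

```
sinkindex simulate --output cohort/ --n-per-group 10 --duration 60 --seed 7
sinkindex run --input cohort/ --output run/ --seed 7
sinkindex render --input run/
```

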