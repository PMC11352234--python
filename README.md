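# datbio

Quantitative EEG biomarkers for animal-assisted therapy, built around
single-channel recordings taken before, during, and after a therapy
session. The package targets the protocol used in dolphin-assisted
therapy (DAT) studies of children with spastic cerebral palsy: one
frontopolar (fp1) channel from a consumer biosensor at 512 samples/s,
with a 0–255 poor-signal quality flag (≤ 51 = stabilized), recorded for
about 60 s at rest, 5 min of therapy, and 60 s of rest again.

It provides, end to end on synthetic cohorts:

- **Descriptive analyses** — Welch power spectral density with
  decomposition into the canonical rhythms δ (0.5–4 Hz), θ (4–8),
  α (8–12), β (12–30), γ (30–60); event-related-potential averaging; and
  a self-affine fluctuation analysis whose log–log curve crossovers are
  summarized per phase as C_B, C_D, C_A with the similarity statistics

  S_BA = |C_A − C_B|,  S_DR = (|C_A − C_D| + |C_D − C_B|) / 2.

- **Siamese metric learning** — a shared-weight 1-D convolutional
  encoder Net(·) trained with the contrastive loss
  L = ½·Y·D² + ½·(1−Y)·max(0, m−D)² or the triplet loss
  Σᵢ [‖Net(xᵢᵃ)−Net(xᵢᵖ)‖² − ‖Net(xᵢᵃ)−Net(xᵢⁿ)‖² + α]₊,
  where D = ‖Net(x₁)−Net(x₂)‖₂. The network is plain numpy with manual
  backpropagation (verified against finite differences); only the
  synaptic weights are persisted, never feature descriptors.

- **The biomarker** — retrieval distance D between unit-normalized
  embeddings maps to a similarity index S = clamp(1 − D/2, 10⁻⁶, 1),
  and the therapy biomarker is

  QB_DAT = 10·log₁₀(1/S) dB,

  0 dB when activity during therapy is indistinguishable from rest,
  growing as they diverge.

Because no recordings from the protocol are publicly deposited, a
first-class synthetic-EEG module generates cohorts with the same
structure (1/f background, band-limited rhythms, additive noise,
stabilization flag), with distinct rest and therapy band profiles.

## Worked example

Train a triplet encoder on three synthetic subjects and score the
held-out fourth subject's resting epochs against the training database:

```python
import pandas as pd
from datbio import (CohortSpec, SiameseModel, TrainConfig, bandpass,
                    epoch_signal, generate_cohort, permutation_pvalue)
from datbio.biomarker import cohort_report, score_pairs

spec = CohortSpec(n_subjects=4, seed=7)   # 60 s rest, 300 s therapy, 60 s rest
epochs = []
for rec in generate_cohort(spec):
    epochs += epoch_signal(bandpass(rec.stabilized()), window_s=2.0)

train_epochs = [e for e in epochs if e.subject_id != "S04"]
held = [e for e in epochs if e.subject_id == "S04" and e.phase != "during"]

results = SiameseModel.from_epochs(
    train_epochs, config=TrainConfig(epochs=10, seed=11)).fit(mode="triplet")

db_rest = [e for e in train_epochs if e.phase != "during"]
db_during = [e for e in train_epochs if e.phase == "during"]
pairs = pd.concat([
    score_pairs(results, held, db_rest, group="rest_vs_rest"),
    score_pairs(results, held, db_during, group="rest_vs_DAT"),
])
print(cohort_report(pairs).aggregates.round(4).to_string(index=False))
```

prints

```
       group  n_pairs  mean_S  mean_qb_dB  qb_of_mean_dB
 rest_vs_DAT    25926  0.3309      4.8547         4.8028
rest_vs_rest    10092  0.9566      0.1934         0.1929
```

Resting queries are highly similar to the resting database
(S ≈ 0.96, QB ≈ 0.19 dB ≈ no deviation) but dissimilar to the
during-therapy database (S ≈ 0.33, QB ≈ 4.9 dB), i.e. the therapy phase
carries a distinct EEG signature; a 1000-draw permutation test on the
similarity gap gives p ≈ 0.001. Both aggregation orders (mean of
per-pair dB, and dB of the mean similarity) are always reported.

The same flow is available from the shell:

```sh
datbio simulate --subjects 4 --seed 7 --out cohort/
datbio train --data cohort/ --mode triplet --out model/
datbio score --model model/ --query queries/ --db cohort/ --out report.tsv
datbio run --out artifacts/          # full pipeline with a manifest
```

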