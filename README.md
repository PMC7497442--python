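# actispoof

Black-box impersonation attacks against biometric actigraphy
user-identification models.

Wrist actigraphy records human movement as per-minute activity counts.
Summarized as 24 hourly means per day, those counts form a behavioural
signature good enough for a classifier to tell users apart — and
therefore good enough to *steal*. `actispoof` implements and evaluates a
query-based attack for security researchers and digital-health teams who
want to assess this exposure: given only an identification model's
confidence score `f(x, t) ∈ [0,1]` that profile `x` belongs to user `t`,
a real-coded genetic algorithm searches

    x* = argmax_{x ∈ [0,1]^24} f(x, t)

and produces an *impersonator example* — a synthetic daily profile the
model accepts as the target user, which also mirrors the target's real
circadian profile closely enough to reveal when they wake and sleep.

The package provides:

- **`actispoof.features`** — DEPRESJON-dialect CSV reading, per-day
  24-hour mean profiles (missing-hour sentinel −1, first-day exclusion),
  min–max normalization, inter-user correlation.
- **`actispoof.simulate`** — a synthetic cohort generator with per-user
  circadian structure (logistic day/night ramps, negative-binomial count
  noise, missing minutes), so everything runs without any download.
- **`actispoof.oracle`** — the 500-tree random-forest target model,
  transfer models (naive Bayes, kNN k=1/3/5, SVM, MLP, LDA), per-user
  split evaluation, and the query-counting confidence/binary oracle.
- **`actispoof.ga`** — the attack: rank selection, blend crossover,
  uniform-reset mutation, elitism, patience-based early stopping, and
  weak/medium/strong/escalated presets (population 10/20/50/100).
- **`actispoof.evaluation`** — success criterion (top-1 and confidence
  ≥ 0.20), success rates, transferability with/without threshold, the
  confidence-omission countermeasure, profile comparison and wake/sleep
  estimation.
- **`actispoof` CLI** — `simulate`, `extract`, `run-all`.

## Worked example

```python
from actispoof import evaluation, ga, oracle, pipeline, simulate

result = pipeline.run_pipeline(
    cohort=simulate.CohortConfig(seed=1),  # 20 users x 15 days
    preset="strong",                       # GA population 50
    seed=1,
)

r = result.attack_report
print(f"strong attack SR {r.success_rate}% "
      f"({sum(r.successes.values())}/{len(r.successes)} users), "
      f"mean generations {r.mean_generations:.1f}")
print(f"binary-oracle countermeasure SR "
      f"{result.countermeasure_report.success_rate}%")
print(f"SVM transfer SR (with threshold) "
      f"{result.transfer_report.rows['svm']['with_threshold']}%")
```

prints

```
strong attack SR 100.0% (20/20 users), mean generations 427.9
binary-oracle countermeasure SR 15.0%
SVM transfer SR (with threshold) 90.0%
```

Every one of the 20 users is impersonated at confidence ≥ 0.20 by
querying only the model's scores (about 21 000 queries per user here).
When the model returns only a binary decision, the success rate
collapses to the neighbourhood of the 1/20 random-guess level — the
confidence score is what powers the attack. The examples also transfer:
profiles crafted against the forest fool an SVM trained on the same data
for 18 of the 20 targets.

The same pipeline runs on real per-user CSVs
(`timestamp,date,activity`, one file per user, file stem = user id):

```sh
actispoof run-all --recordings data/ --preset strong --seed 1 --out results/
```

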