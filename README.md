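# cellcognize

Supervised classification of individual flow-cytometry (FCM) events
against a library of predefined cell and bead standards, with downstream
quantification of microbial community composition, probability-based
similarity scoring, ecological diversity summaries and biomass/yield
estimation.

**Who it is for.** Microbial ecologists who measure community samples on
a flow cytometer alongside a panel of pure standards (strains, growth
states, beads) and want per-cell class attributions — a cheap,
cultivation-free fingerprint of "cell type" diversity that complements
16S amplicon sequencing and supports absolute counts and biomass
estimates, thanks to volumetric counting hardware.

## The model

Each event is a vector of seven optical parameters (FITC-A, FITC-H,
FSC-A, FSC-H, SSC-A, SSC-H, Width). After window filtering (default
[100, 10⁷] per parameter) and log₁₀ transformation, events are classified
by a feed-forward network

    p(class k | x) = softmax(W₂ · σ(W₁ x + b₁) + b₂)ₖ

with 7 inputs, 20 logistic-sigmoid hidden nodes and K softmax outputs
(one per standard). Training minimizes categorical cross-entropy by
full-batch scaled conjugate gradient on a 50/25/25
train/validation/test split, stopping at 1000 cycles, gradient norm
< 10⁻⁶, or 6 consecutive validation failures (best-validation weights
kept). Two synthetic *anchor* events at the log filter bounds pin the
[-1, 1] min-max scaling to the filter configuration. The whole procedure
runs five times with independent seeds, and all downstream metrics are
mean ± SD over the five replicate classifiers.

Downstream, per-event probability vectors become class-count profiles,
and:

* **CPC** (correct predicted classification) — events attributed to a
  target class as % of the number spiked in (can exceed 100%);
* **classification similarity** — 100 × mean winning probability of
  query cells / mean winning probability of the standard's own cells;
* **diversity** — richness (classes > 0.05% abundance), Shannon index
  (nats), Bray–Curtis dissimilarities on counts;
* **biomass** — per-cell dry weight m_b = 435 · V^0.86 fg from biovolume
  V (µm³), carbon = m_b / 2, summed over classes; yields as g biomass-C
  per g substrate-C.

## Worked example

Train a five-replicate ensemble on the built-in synthetic five-standard
fixture (five well-separated log-normal clusters, two with bimodal
subpopulations), then evaluate held-out events:

```python
import numpy as np, pandas as pd
import cellcognize as cc

spec = cc.FilterSpec()                        # raw window [100, 1e7] per parameter
standards = [cc.generate_standard(s, seed=i)
             for i, s in enumerate(cc.paperlike_standards(n_events=12_000))]

ensemble = cc.train_ensemble(standards, 10_000, spec,
                             cc.TrainingConfig(seed=1), n_replicates=5)

held_out = [cc.generate_standard(s, seed=900 + i)
            for i, s in enumerate(cc.paperlike_standards(n_events=5_000))]
recall = np.array([[100 * (cc.forward_pass(m, ds.events).assigned_class
                           == ds.standard_name).mean()
                    for ds in held_out] for m in ensemble.models])
for name, mu, sd in zip(ensemble.class_labels,
                        recall.mean(axis=0), recall.std(axis=0, ddof=1)):
    print(f"{name}: recall {mu:.1f} +/- {sd:.2f} %")

result = cc.forward_pass(ensemble.models[0], held_out[0].events)
profile = cc.attribution_profile(result)
own_p = profile.mean_probability["STD1"]
print(f"STD1 mean winning probability: {own_p:.3f}")
print(f"chance accuracy, 5 classes: {cc.chance_accuracy(5):.0f} %")

table = cc.BiomassStandardTable(pd.DataFrame(
    {"standard": ensemble.class_labels, "v_mean": 0.5, "v_sd": 0.1}))
est = cc.community_biomass(result.class_counts, table)
print(f"community biomass: {est.total_fg_c:.3g} fg C "
      f"[{est.lower_fg_c:.3g}, {est.upper_fg_c:.3g}]")
```

Output:

```
STD1: recall 100.0 +/- 0.00 %
STD2: recall 100.0 +/- 0.00 %
STD3: recall 100.0 +/- 0.00 %
STD4: recall 100.0 +/- 0.00 %
STD5: recall 100.0 +/- 0.00 %
STD1 mean winning probability: 1.000
chance accuracy, 5 classes: 20 %
community biomass: 5.99e+05 fg C [4.95e+05, 7.01e+05]
```

At ~9 pooled-SD separation every replicate recovers every class
perfectly — far above the 20% chance level — and the 5,000 held-out STD1
cells (biovolume 0.5 ± 0.1 µm³ each, i.e. ~120 fg C per cell) sum to
about 6 × 10⁵ fg of community carbon, with bounds from the biovolume SD.
Real standards overlap more; the `separability_sweep` utility quantifies
how recall degrades as clusters approach.

A command-line interface wraps the same functions:

```sh
cellcognize simulate --seed 1 --out sim/          # synthetic standards
cellcognize preprocess --input raw.csv --out out/ # filter + log10 (+ gates)
cellcognize train --standards manifest.yaml --out models/
cellcognize classify --model models/ --input sample.csv --out counts.csv
cellcognize diversity --profiles counts.csv --out report/
cellcognize biomass --profile counts.csv --table biovolumes.csv --out biomass.json
```

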