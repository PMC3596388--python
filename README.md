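# tsnet

Network-integrated classification of clinical time-series gene
expression.

## The problem

Short expression time courses are increasingly collected in clinical
studies — for example to predict, from a handful of measurements, which
multiple-sclerosis patients will respond to interferon-beta treatment.
Such data are awkward for standard classifiers: very few samples
(tens of patients), many noisy features (tens of genes × a few time
points), patient-specific response dynamics, and markers that are
functionally redundant.  `tsnet` addresses this by (i) denoising each
gene's trajectory into a handful of qualitative states, (ii) grouping
genes that move together over contiguous time windows, (iii) asking a
protein-interaction network which of those groups look like functional
modules rather than coincidences, and (iv) classifying patients by a
similarity measure over these weighted modules.

## The method

1. **Gene states.**  A hidden Markov model with Gaussian-mixture
   emissions (one component per gene, `n` components per state) is
   fitted to all (patient, gene) series pooled, by EM; Viterbi decoding
   turns every trajectory into a path over `Q` qualitative states.
   Baseline threshold discretizers (average, mid-range, max-X%max,
   top-X%, equal-frequency) are included for comparison.
2. **Temporal biclusters.**  Per patient, all *maximal* biclusters
   `B(G, J(T, S))` — gene sets `G` sharing the exact state profile `S`
   over a contiguous time window `T` — are extracted by time-stamping
   states into tokens `(t, s)`, MSD-radix-sorting all suffixes of the
   token sequences, and reading maximal runs off the
   longest-common-prefix array.
3. **Network weight.**  Each bicluster is scored by how surprisingly
   interconnected its genes are in an interaction network: per member
   gene, the upper tail `P(X ≥ k)` with
   `X ~ Hypergeometric(N−1, m, d_i)`; the score averages `1 − p` over
   members, and scores are normalized per patient (PPIScore).
4. **Classification.**  Patient similarity (PPISim) is the symmetrized
   best-match of bicluster Jaccard similarities weighted by the
   normalized scores; it satisfies `PPISim(A,A)=1` and symmetry.  A
   test patient's `K` nearest training patients vote; if they disagree,
   a soft-margin linear SVM trained on the neighborhood with PPISim as
   kernel decides.  Evaluation is 10 repetitions of stratified 4-fold
   cross-validation, with the model, biclusters, scores and kernel all
   refitted inside each training fold.

A synthetic-cohort generator with planted discriminative modules,
patient-specific decoy modules and a stochastic-block interaction
network makes every stage testable without external data.

See `docs/methods.md` for assumptions, parameter defaults and design
decisions.

## Worked example

```python
from tsnet import (PipelineConfig, cross_validate, generate_benchmark,
                   similarity_matrix, class_distance_ratio)
from tsnet.pipeline import preprocess_dataset, fit_discretizer, build_profiles

dataset, network, truth = generate_benchmark(
    seed=7, n_pos=10, n_neg=8, n_genes=24, T=6, noise_sd=0.2,
    missing_rate=0.05, n_disc_modules=2, decoy_modules=1, module_size=4,
    disc_window=(2, 5))
config = PipelineConfig(seed=7, reps=3, folds=4, K=3)

processed = preprocess_dataset(dataset, config)
profiles = build_profiles(processed, network, config,
                          model=fit_discretizer(processed, config))
print("biclusters for", profiles[0].patient_id, "->", profiles[0].n_biclusters)

kernel = similarity_matrix(profiles)
print("D =", round(class_distance_ratio(kernel, dataset.labels), 3))

report = cross_validate(dataset, network, config)
for k in report.mean:
    print(f"{k}: {report.mean[k]:.3f} +/- {report.sd[k]:.3f}")
```

prints

```
biclusters for P001 -> 41
D = 3.387
accuracy: 1.000 +/- 0.000
precision: 1.000 +/- 0.000
recall: 1.000 +/- 0.000
f_measure: 1.000 +/- 0.000
```

Patient `P001` carries 41 maximal biclusters.  `D` is the
class-distance ratio — mean within-class over mean between-class
patient similarity — so `D = 3.4` means same-class patients sit three
times closer in bicluster space than opposite-class patients, and the
cross-validated classifier separates this (deliberately easy) cohort
perfectly.  On harder cohorts raise `noise_sd` or remove the planted
signal (`identical_classes=True`) to watch the metrics fall to chance.

The same pipeline is available from the shell:

```sh
tsnet simulate --seed 7 --out sim/
tsnet classify --expression sim/expression.tsv --labels sim/labels.tsv \
      --network sim/network.tsv --out results/
```

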