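# aclspeech

Articulation-constrained sparse models for speech emotion recognition.

## The problem

Emotion leaves traces in both the speech signal and the motion of the
articulators (jaw opening widens in anger, lips protrude differently across
emotions).  Classifiers that use articulatory measurements outperform
acoustic-only ones — but electromagnetic articulography and motion-capture
recordings are invasive and expensive, so requiring them at recognition time
kills most applications.  `aclspeech` implements *articulation-constrained
learning* (ACL): articulatory data shapes the classifier **during training
only**, and recognition needs acoustics alone.

## The model

A sparse logistic regression over supra-segmental acoustic features
x ∈ R^150 (five statistics of 30 frame-level descriptors per vowel segment or
utterance) is trained per articulatory target k by minimizing the convex
objective

    f(w_k) = −(1/N) Σ_i [ y_i log σ(w_kᵀx_i) + (1−y_i) log(1−σ(w_kᵀx_i)) ]
             + λ₁ ‖w_k‖₁  +  (λ₂/M) Σ_j (a_j^k − w_kᵀx_j)²

where a_j^k is the mean of articulatory channel k over segment j.  The N
labeled rows and the M articulatory rows are independent — different
speakers, or even a different corpus.  Columns are stacked into
W = [w₁ … w_K]; the recognition posterior is p(y=1|x) = (1/K) Σ_k σ(w_kᵀx),
binary decisions threshold at 0.5, and categorical emotion (neutral / angry /
sad / happy) uses one-vs-rest models with an argmax decision.  Setting λ₂ = 0
gives the acoustic-only baseline (ACO); least squares on the targets alone is
the articulation-only criterion (AR).  A FISTA proximal-gradient solver with
exact soft-thresholding does the optimization (tolerance 1e−5).

Model selection follows two cross-validation protocols (repeated random
halves of a designated speaker, or leave-one-speaker-out) with an exhaustive
search over λ₁ ∈ {0.1, 0.5, 1.0}, λ₂ ∈ {0.001, …, 0.1}.  Metrics: unweighted
average recall (UAR), its permutation chance level (BCUAR), per-target
reconstruction correlation, and a difference-of-proportions significance
test.  Because the real corpora this method targets are licensed, the package
ships a synthetic two-corpus generator that reproduces the statistical
structure the method assumes (sparse shared supports between label and target
weights, speaker and corpus effects); see `docs/methods.md`.

## Worked example

Simulate a small corpus, fit the constrained model, predict from acoustics
alone, and score:

```sh
aclspeech -q simulate --seed 3 --out sim --n-segments 120 --n-speakers 3 --n-features 12
aclspeech -q fit --features sim/features.csv --targets sim/targets.csv \
          --criterion ACL --task arousal --lambda1 0.1 --lambda2 0.1 --out fitdir
aclspeech -q predict --model fitdir/model.json --features sim/features.csv --out preddir
aclspeech -q evaluate --predictions preddir/predictions.csv \
          --features sim/features.csv --task arousal --n-permutations 200 --out evaldir
```

The last command prints

```
{"uar": 0.8762320473106167, "bcuar": 0.5012954097437341}
```

a UAR of 87.6% on the (training) corpus against a permutation chance level of
50.1% — the labels here sit on the arousal axis of a two-class synthetic
corpus, so chance is 50%.  `evaldir/` also holds the confusion matrix as
counts and row percentages, and `preddir/predictions.csv` lists the averaged
posterior, the thresholded decision and the contributing articulatory targets
per segment.  Every command writes a manifest with the resolved
configuration, its hash, and library versions; equal-hash reruns produce
byte-identical artifacts.

The same functionality is available as a library (`aclspeech.fit_multi_target`,
`aclspeech.grid_search`, `aclspeech.generate_paired_corpora`, …).

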