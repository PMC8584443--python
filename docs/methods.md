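# Methods

This note documents the models, numerical conventions and design choices in
`pepcaps`, in the spirit of a package's own methods appendix. Nothing here
states an empirical result the test suite or `scripts/acceptance.py` does
not itself compute.

## 1. Feature pipeline

### Residue conical coordinates (RCC)

The RCC feature embeds a peptide's residues as points on four cones — one
per polarity class (1 non-polar A,V,L,I,P,F,W,M; 2 polar G,S,T,C,Y,N,Q;
3 basic K,R,H; 4 acidic D,E) — so that residues of a class share a polar
angle while their azimuths separate them by physicochemical deviation from
the class mean, and the radius (the free amino acid's molecular weight, Da)
separates residues by size.

For one group of 10 standardized properties, with `S_j` the property sum of
residue `j` and `d̄_i` the mean of `S_j` over residues of class `i` present
in the peptide:

* `φ_i = π · |sin((d̄_i − μ)/σ)|`, where `μ` and `σ` are the mean and
  population standard deviation of the `d̄_i` over the classes present.
  The source formula is typographically corrupted; this reading uses
  exactly its printed ingredients, mirrors the azimuth's standardized-
  deviate structure, and keeps `φ ∈ [0, π]`. It is isolated in
  `conical_params` so an alternative reading is a one-line change.
  `σ = 0` (e.g. a single-class peptide) falls back to `φ = π/2`.
* `θ_ij = π + 2·atan((S_j − d̄_i) / RMS_i)` with `RMS_i` the within-class
  root-mean-square deviation; a zero denominator (all class members
  identical) maps to `θ = π`. This keeps `θ ∈ (0, 2π)` and makes the
  argument dimensionless.
* The printed four-class averages use a literal 1/4; when a class is absent
  from a peptide the averages here run over the classes present, and the
  absent class's geometric center is set to the overall center so it
  contributes zero deviation to every moment while the 24-value group block
  stays fixed-length.

Per group the feature block is `[u̅₁ u̅₂ u̅₃ u̅₄ | u̅ | σ² g h]` (12 + 3 + 9
values): class centers, overall center, and per-axis variance, skewness and
kurtosis of the four class centers. Kurtosis uses the conventional `σ⁴`
denominator; the source prints `σ²`, available via `kurtosis_sigma2=True`.
Ten groups give the 240-value RCC vector.

### Composition and sequence code

AAC is the 20-vector of residue frequencies; DPC the 400-vector of ordered
adjacent-pair frequencies normalized by the `L−1` observed positions (so it
is a probability distribution). Residue order is alphabetical by one-letter
code everywhere (AAC, DPC rows/columns, sequence-code indices 1–20, pad 0);
the source states no order, and alphabetical is reproducible. All features
are computed on the chain truncated at 50 residues — the same cap as the
sequence input — so every view of a long peptide describes the same prefix.

### Property table

The source names a 100-property table without accessions. The bundled
stand-in (`pepcaps/data/aa_properties.csv`) holds 100 RDKit molecular
descriptors of the 20 free amino acids — genuine physicochemical and
topological quantities, regenerable with `scripts/make_property_table.py`.
Any 20 × ≥100 numeric table can be supplied instead; columns are z-scored
across the 20 residues (population SD), zero-variance columns rejected by
name, and grouping defaults to consecutive blocks of 10. The tested
invariants and dimensions are independent of which properties are used.

Non-canonical residues (B, J, O, U, X, Z) reject the record with a logged
warning by default; `non_canonical="drop_residue"` strips them instead.
Silent coercion would corrupt the composition features.

## 2. Network

Two branches (biological 33 × 20, embedded sequence 50 × 20) each pass
through: 9 × 9 convolution (256 filters; padding 1 biological / 0 sequence),
ReLU, CBAM, and a stride-2 convolution (kernel 7 biological / 9 sequence)
reshaped into 16-dim primary capsules. The printed 7 × 7 kernel for the
sequence branch's first convolution cannot produce the printed 42 × 12
output under any symmetric stride-1 padding, so the output shapes — which
chain consistently into the published capsule counts 544/704/1248 — are
treated as ground truth and both first-layer kernels are 9 × 9.

* Capsule reshape: the 256 channels are read as (16 capsule groups × 16
  dimensions); capsules are formed per group and spatial position. This
  grouping reproduces the published counts exactly (bio 16·11·4 = 704,
  seq 16·17·2 = 544) and is fixed for reproducibility.
* Routing: a single dynamic-routing pass over the concatenated 1248
  capsules (one weight tensor over all of them), logits initialized to
  zero, couplings softmaxed over the two output capsules each of three
  iterations, agreement `û·v` added to the logits. Logits are per batch
  item and the whole loop is differentiated.
* Squash: `v = s·‖s‖/(1 + ‖s‖²)` (canonical; the printed `1 + ‖s‖`
  denominator does not bound the norm below 1 and is treated as a typo,
  available via `squash_norm_squared=False`). A small `ε = 1e-8` inside the
  norm keeps the zero vector an exact fixed point with finite gradients.
* Primary capsules are **not** squashed by default: the published routing
  diagram applies the squash only at the output capsules, and at desk scale
  the un-squashed variant trains more stably within the mandated six
  epochs. `primary_squash=True` restores the common CapsNet convention.
* Class capsules: index 0 = detectable, 1 = undetectable; the continuous
  score is the detectable capsule's norm; hard decisions compare the two
  norms with ties resolved to undetectable (deterministic, conservative).
* CBAM: channel attention = sigmoid of the summed shared-bottleneck MLP
  (reduction 16) over global average- and max-pooled descriptors; spatial
  attention = sigmoid of a 7 × 7 convolution (padding 3) over the stacked
  channel-mean/max maps; both gates multiply elementwise, preserving shape.
* Margin loss with m⁺ = 0.9, m⁻ = 0.1, λ = 0.5, summed over the two
  capsules and averaged over the batch. Adam, lr 1e-3, ε 1e-8, batch 32,
  6 epochs.

### Feature scaling

The raw biological feature mixes molecular-weight-scale coordinates (and
their higher moments, up to ~10⁴) with frequencies of order 0.01; fed raw,
the first convolution saturates both output-capsule norms near 1 at
initialization. A standardizer fit on the training set z-scores the RCC and
AAC columns and leaves the DPC block raw (z-scoring 400 sparse dipeptide
frequencies amplifies rare-event noise). The scaler is part of the model
and is stored in its checkpoint.

### Autodiff engine

No deep-learning framework is assumed. `pepcaps.autograd` implements
reverse-mode differentiation over numpy arrays for exactly the operations
the model needs (broadcast arithmetic, batched matmul, im2col convolution,
pooling reductions, sigmoid/ReLU/softmax, embedding lookup) plus Adam.
Gradients of every operation and of the assembled network are verified
against central finite differences in the test suite. Tensors are float32.
Max-pool gradients split equally among tied maxima. Weight init: He-normal
for convolutions and MLPs, `N(0, 0.1)` for the embedding (pad row zero and
masked), `N(0, √(2/(d_in+d_out)))` for routing weights; all draws come from
one generator seeded by `NetworkConfig.seed`, which with the shuffling seed
makes training runs bit-reproducible on fixed hardware.

## 3. Synthetic data

`generate_synthetic` stands in for mass-spectrometry corpora. Each peptide
draws a hydrophobic propensity from Beta(2, 2), samples residues class-
biased by it (length uniform on 7–50), and receives a latent score
`logistic(w·[f_hydro − 0.4, n_KR − 2, L/50 − 0.57] + b)` with the intercept
`b` bisected so the mean score matches the class-balance target. Labels are
Bernoulli draws from the score, then flipped at the `noise` rate.

Default weights are deliberately large (64, 4, 10): real detectability
sets are built from *extreme* groups (most- vs least-observed peptides), so
the emulated latent rule is near-deterministic, and the flip rate is then
the single interpretable difficulty knob. With weights at this scale the
label-noise ceiling on ROC-AUC at `noise = 0.1` is ≈ 0.90 (flip algebra:
(1−ε)² + ε(1−ε)); weak weights would add Bernoulli ambiguity on top and
push the ceiling below what any correct pipeline could reach. The
generator emulates composition- and length-dependent detectability only; it
does not emulate missed cleavages, modification states, charge/mass
effects, protein context, or the selection bias of real corpora — a green
learnability test establishes that the pipeline can extract a planted
composition/length signal at a stated noise level, not field performance.

## 4. Evaluation

Scores are detectable-capsule norms; counts use the norm-comparison rule.
ROC points come from sklearn's threshold enumeration (no intermediate-point
dropping) and AUC is the trapezoid over them — verified in tests against
the Mann–Whitney U statistic. The printed definition "accuracy = TP/(TP+FP)"
is the textbook precision; reports carry it as `precision` alongside the
conventional `accuracy` = (TP+TN)/N. Single-class evaluation sets get
`auc = NaN` with a warning. Cross-validation is stratified (fold label
proportions within ±2 % of global for n ≥ 1000), seed-deterministic, trains
a fresh model per fold (seed = config seed + fold index), and reports
per-fold metrics, their mean ± SD, and fold-averaged ROC/PR curves
interpolated on a common 101-point grid.

## 5. Desk-scale preset and limitations

`small_config()` keeps the full architecture (two branches, CBAM, capsules,
routing) at reduced width — 16 conv filters, 8-dim primary capsules, 16-dim
outputs — so that 2000 peptides train in well under a minute on one CPU.
The published width (256 filters, 544/704/1248 capsules, 32-dim outputs) is
built and shape-verified exactly in the tests, but full-width training at
corpus scale (100k peptides) is out of desk scope. Known limitations: no
GPU path; checkpoint format is a single `.npz` tied to the package's
parameter ordering; the conical-angle formula follows a documented reading
of a corrupted source equation rather than a confirmed original.
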