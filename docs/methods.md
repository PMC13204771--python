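# Methods

## Model

### Per-slice encoder

ViT-Base/16: 224 × 224 × 3 inputs, 16 × 16 patches (196 per slice), width
D = 768, 12 pre-norm blocks with 12 attention heads (head width 64) and 4×
GELU MLPs, learnable positional embeddings over the 197 tokens (CLS + 196
patches), and a final LayerNorm.  The final LayerNorm is included because
the component's parameter total (85,798,656) requires it and it is the
standard ViT-Base composition.  QKV/O projections carry biases; the
attention, MLP and residual dropouts default to 0.1.  Initialization is
truncated normal (σ = 0.02) for weights, zeros for biases; a hook for
loading published ViT weights from a local checkpoint exists but nothing
in the package requires a download.

### Learnable query attention pooling

The five per-slice sequences concatenate along the token axis (985
tokens).  Each pooling stage holds a bank of trainable queries
(Xavier-uniform; 197 for the latent stage, 1 for the patient stage) and
computes

    Z' = MHA(LN_q(Q), LN_k(X), LN_v(X)) + Q
    Z  = MLP(LN(Z')) + Z'

Three design points are deliberate and parameter-count-verified:

* **independent LayerNorms** on the query, key and value inputs (even
  though K and V receive the same tensor);
* the residual adds the **raw** (pre-norm) queries;
* attention projections carry **biases** (the printed totals 7.24 M /
  7.09 M only match with biases included).

Because attention is a weighted sum over the key set, the pooled output is
invariant to permuting the five slice blocks; the suite asserts this at
1e-5.  Output length always equals the query count, independent of how
many slice blocks are fed — the architectural reason the decoder can rely
on a fixed 197-token context.

The classification head is LN → Linear(768→256) → GELU → Linear(256→3).
The hidden width 256 is a free design choice (kept ≪ 1 M parameters and
out of the published component totals).  Class order is (Normal, SCLC,
NSCLC) everywhere.

Baseline pools for the ablation: mean and max over the 985 tokens, and a
single-head attention pool in which one learnable query scores tokens
through a key projection and the output is the probability-weighted mean
of the *raw* tokens.  That last design makes the degenerate case exact:
zeroing the query reproduces mean pooling, which the suite uses as an
oracle.  All three produce a single vector and therefore cannot feed the
cross-attention decoder.

### Decoder

12 blocks of masked self-attention → cross-attention → 4× MLP, all
pre-norm with residuals; token embedding 50,257 × 768, learned positional
embeddings over 1024 positions; LM head weight-tied to the token
embedding (object identity, not a copy).  Cross-attention applies
LayerNorm to the **text query path only**; the LQAP context enters as raw
keys/values — again pinned by the component total (152,806,656).  GPT-2's
single special token (id 50,256) serves as both BOS and EOS.  Generation
is greedy by default (temperature/top-k sampling is config-exposed);
teacher-forced training computes the next-token cross-entropy as a
**token mean** over non-padding positions.

A loader can transfer shape-matching tensors from a local NPZ checkpoint
into the decoder, always leaving cross-attention sublayers (absent from a
plain language model) freshly initialized, and reports which tensors were
copied.

### Tokenizer

A byte-level BPE implemented in-package: ids 0–255 are raw bytes, merges
learned greedily by pair frequency (deterministic tie-break), one special
token at the top of the configured vocabulary.  In this repository the
merge table is trained on the synthetic report corpus at run time; the
decoder's embedding table is always sized by the configured vocabulary
(50,257 at full size), so parameter accounting does not depend on how
many merges exist.

## Training

Joint loss `L_total = L_cls + λ·L_report`, λ = 0.3.  Adam (β = 0.9/0.999,
ε = 1e-8, no weight decay) with a one-cycle schedule: linear warmup over
the first 30 % of steps to the max learning rate (1e-4 at full scale),
then cosine annealing.  Batch size 16, up to 100 epochs, early stopping
after 5 non-improving validation epochs, best-validation checkpointing.
All randomness (cohort generation, splits, initialization, shuffling,
dropout) flows from explicit seeds; two runs with one seed produce
identical logs.  The `amp` flag is accepted for config compatibility but
the engine always computes in full precision.

Splitting is stratified at the patient level: per class,
test = round(n·0.10) and val = round(n·0.20) with round-half-up, the
remainder train.  At the emulated cohort size (256/248/263) this yields
exactly the 77-patient test set with per-class sizes 26/25/26.  All five
slices of a patient share one partition by construction.

## Grad-CAM

For a target class c, the gradient of the logit y_c is taken with respect
to each head's attention-probability map in the **final** encoder block of
each slice; the head weight is the spatial mean of that gradient and heads
combine as ReLU(Σ_k α_k A_k).  The CLS-query row of the combined map
(one value per patch) is reshaped row-major to the patch grid (14 × 14 at
224 px), bilinearly upsampled and min-max normalized per slice.  Dropout
is disabled during the gradient pass.  Spatializing via the CLS
attention row is a modeling choice: attention maps live in token-token
space and the CLS row is the one consistent with using the CLS summary
for classification-adjacent pooling.  A constant-logit head has zero
gradient and yields an all-zero, explicitly flagged map.

Saliency validation binarizes the top 20 % of map activation.  The
threshold is the k-th largest value with k = round(0.2·N), ties included
— an order-statistic definition chosen over interpolated quantiles
because it behaves correctly on heavily tied maps (an 80/20 two-valued
map binarizes to exactly the top fifth).  Scores: IoU, Dice (the identity
Dice = 2·IoU/(1+IoU) is property-tested), and the Pointing Game (first
row-major maximal pixel; boxes rescaled from volume to display
coordinates with floor/ceil so coverage never shrinks).

## Metrics

Classification metrics derive one-vs-rest from the 3 × 3 confusion
matrix; specificity is TN/(TN+FP) and macro means are unweighted.
Undefined ratios surface as NaN rather than 0.  ROC-AUC is one-vs-rest
per class (scikit-learn).  Reported percentages round to 2 decimals,
caption scores to 3.

Caption metrics are computed on lowercase punctuation-stripped word
tokens, independent of the model's BPE: corpus BLEU-n (uniform 1/n
weights, standard brevity penalty), ROUGE-L as the LCS F-measure with
β = 1, METEOR with exact-match unigram alignment (α = 0.9, fragmentation
penalty γ = 0.5 with exponent 3; chunk counting uses a greedy in-order
alignment that extends the previous match when possible), and plain
CIDEr (tf-idf n-gram cosine, n = 1..4, uniform weights, ×10, idf from the
reference corpus).  ROUGE-L's β and the METEOR constants are standard
defaults adopted because the quantities are otherwise under-specified;
they are config-visible in the code.

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes,
not CT physics.  Lung parenchyma is a −800 HU background with Gaussian
noise (σ = 25 HU default).  Lesions are Gaussian-smoothed ellipsoids
thresholded at half-maximum: SCLC-like lesions are compact, smooth and
placed near the volume center (a central/hilar analogue); NSCLC-like
lesions are unions of 3–5 offset ellipsoids in the lateral peripheral
third with ±120 HU internal texture (irregular margin and heterogeneity
analogues).  Lesion plateau intensity is drawn from 10–60 HU, the
soft-tissue range of solid tumors.  Volumes clamp to the 12-bit CT range
[−1024, 3071].  Five slice levels bracket the lesion's maximal-area slice
± 2 for malignant patients; Normal patients get five evenly spaced
depths — a stand-in for the anatomy-defined landmark levels used on real
data, not a claim of equivalence.  Reports are eight fixed-order tagged
sentences per language; sentence 6 ("Lung Parenchyma" / "Akciğer
Parankimi") carries the lesion description with location, long-axis size
(box extent × 3 mm/px default spacing) and margin-descriptor slots that
match the rendered blob.  Everything is a pure function of
(seed, label, index).

What the generator does **not** emulate: real anatomy (airways, vessels,
chest wall), scanner noise spectra, lesion growth patterns, free-text
report variability, or inter-annotator disagreement.  Tests passing on
this cohort demonstrate that the pipeline is mechanically and
statistically sound (signal present → learnable; structure preserved
end-to-end), not that the published clinical performance is reproduced —
that would require the original dataset.

## Problem sizes and numerics

The default test cohort uses 64 × 64 × 24 volumes and the tiny model
profile (width 64, 2 layers, 2 heads, 32 px inputs, 512-token
vocabulary) so the whole suite runs in about a minute on one CPU core;
full-size components are instantiated once, sequentially, for the
structural checks.  Learning smoke tests use a max learning rate of 3e-3
(appropriate for the tiny width) rather than the full-scale 1e-4.  The
engine computes in float64; windowing rounds half-to-even; the bilinear
resize dialect (scikit-image, no corner alignment, no antialiasing) is
pinned so cached fixtures are bit-stable.  Degenerate inputs are explicit
errors or flags rather than silent defaults: empty lesion boxes, constant
saliency maps, missing report sections, non-finite pooling inputs.

## Limitations

* The NumPy engine is single-threaded per op and unsuited to full-scale
  training; the full-size profile exists for structural verification and
  small-batch inference experiments.
* METEOR omits stemming/synonym matching (exact matches only), so its
  absolute values sit below implementations with linguistic resources.
* The synthetic Turkish reports exercise the UTF-8/BPE path but are
  templated; no morphological variability is modeled.
* Real-data slice selection is consumed as an input (the tool never
  detects lesions), so DICOM/NIfTI pipelines must supply the five level
  indices.
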