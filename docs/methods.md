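# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests demonstrate.

## Pipeline

Every experiment arm follows the same chain:

1. **Background masking.**  A foreground mask is the thresholded
   difference of a high- and a low-reflectance band
   (`R(high) − R(low) > t`).  Presets: sweets 957/1496 nm at 0.22 on a
   bright tile; salmon 944/1450 nm at 0.2 on a dark stage.  The difference
   image cancels band-independent offsets, which is why the rule is stated
   on the difference rather than on raw reflectance.
2. **Unfolding.**  Foreground pixels are rearranged into a
   `(pixels × bands)` matrix in row-major scan order with their
   coordinates recorded; refolding places per-pixel results back to image
   space with a fill value (0) elsewhere.  Fixing the scan order makes
   training order, and hence every seeded fit, reproducible.
3. **Pre-treatment chains.**  Ordered, serializable step lists over
   {SNV, SG first derivative, EPO}.  SNV centers each spectrum and scales
   it to unit *sample* (n−1) standard deviation — the dominant
   chemometric convention; rows with sd < 1e−12 are rejected rather than
   silently passed.  The SG derivative (default window 11, polynomial
   order 3) is taken with respect to band index; the 7 nm grid spacing is
   a constant factor that no downstream classifier can see.  Its edge
   policy drops the (window−1)/2 unsupported bands per side
   (101 → 91 bands) instead of padding, because padded values would be
   fabricated spectra.  Both step orders, "SG then SNV" and "SNV then
   SG", are expressible; the chain is explicit configuration.
4. **Models** (below), each consuming either the flat matrix or per-pixel
   patches.
5. **Evaluation.**  Confusion counts over pixels with ground truth > 0;
   per-class one-vs-rest TPR/FNR/PPV/FDR and CCR = trace/total.  A pixel
   the background mask dropped counts against the classifier — it was a
   labelled pixel that received no label.  FDR is reported in two forms:
   the conventional FP/(FP+TP) = 1 − PPV, and a legacy form FP/(FP+TN)
   (actually a false-positive rate) that some published confusion tables
   print; both live in every report so the divergence is never silent.

## EPO (external parameter orthogonalization)

Interference spectra `D` (here: the mean foreground spectrum of every
cube) are column-centered and decomposed by SVD; the first `c` right
singular vectors `V` span the parasitic subspace, and spectra are
corrected as `X ← X(I − VVᵀ)`.  The projector is symmetric and idempotent
and annihilates `span(V)` exactly — these algebraic contracts are tested
to 1e−8 or better.  Centering isolates the *variation* of the external
effect rather than the shared mean spectrum.

Two deliberate choices:

* **The interference matrix uses all cubes, not just training cubes.**
  Cube means require no labels, so this is unsupervised calibration — and
  it is the entire point: a supervised model can only discount nuisance
  directions it has seen varying, while EPO can remove a batch effect
  that first appears in the test fillets.
* **`c` defaults to 1** (one dominant parasitic direction when means are
  the interference) and is configurable; the salmon pipeline uses `c = 2`
  because its generator injects two batch-effect directions (thickness ×
  water band, composition × CH band).

## Chemometric models

* **PCA** — mean-centering only, no autoscaling (pre-treatments already
  normalize scale, and loadings should describe raw spectral variance).
  Sign convention: each loading's largest-magnitude element is positive.
  Scores refold into score images; foreground carries scores, background
  0.
* **PLSDA** — PLS2 on one-hot class indicators (NIPALS-style, via
  scikit-learn's `PLSRegression`, `scale=False`), class = argmax of the
  predicted indicator columns; no threshold or Bayes rule.  With as many
  latent variables as the rank, PLS2 equals multivariate least squares —
  the oracle that pins the implementation to 1e−6.  LV count is chosen by
  venetian-blinds cross-validation: fold *s* holds observations with
  index mod `n_splits` = *s* (default 10 splits), and the smallest LV
  count within 0.5 percentage points of the curve maximum wins.
* **SVM-ECOC** — one-vs-one (default) or one-vs-all codebooks over
  {−1, 0, +1}; the pluggable binary learner defaults to a linear SVC with
  C = 1.  Decoding minimizes the hinge-loss-weighted distance between a
  class codeword and the vector of binary margins; codeword ties resolve
  to the lowest class index and are counted.

## The CNNs

Both networks are a compact numpy implementation: im2col convolution
(single GEMM per layer), seeded Glorot-uniform init, inverted dropout,
minibatch SGD with momentum 0.9, cross-entropy loss, fixed-epoch protocol
("last epoch wins", no early stopping).  Convolution is the first layer in
both stacks, so its input gradient is never needed and the im2col matrix
of the training set is computed once and reused across epochs (bounded by
a 2 GB cap).  Defaults follow the reference protocol: learning rate 0.01,
batch 1024, 100 epochs, dropout 0.5.  Shape arithmetic is
`out = floor((in − f)/stride) + 1` everywhere and is validated at build
time; e.g. a 17×17×10 input maps to 7×7×20 after the 5×5/stride-2
convolution, 3×3×20 after 2×2/stride-2 pooling, 180 FC inputs.

The 2-D network (Conv → ReLU → MaxPool → Dropout → FC → Softmax) consumes
PCA score patches; the 3-D network (Conv3D → BatchNorm → ReLU → Dropout →
FC → Softmax) consumes raw spectral patches, with the band axis convolved
(filter 3×3×10, stride 1) — and, as listed, no pooling layer.  Batch norm
tracks running statistics (momentum 0.1) for inference.  Training history
records loss/accuracy per iteration for the training stream; validation
metrics are computed every `val_every` epochs (default 1; the pipeline
uses 5 for 2-D and 10 for 3-D runs, where a full validation forward pass
per epoch would dominate the runtime).

Patch extraction zero-pads the image border by (k−1)/2, consistent with
the 0 background fill of score projection: patches near the sample edge
contain background zeros, patches near the image border contain padding
zeros, and the center voxel always equals the source pixel.  Prediction
streams patches in memory-bounded batches so a full 3-D patch set is
never materialized; training-set thinning ("every m-th observation")
exists for the same reason.

## Synthetic scenes

The generator renders what the pipeline needs to be tested against, with
exact ground truth; it emulates data *structure*, not camera radiometry.

Pixel model: `class signature × multiplicative scatter + additive offset
+ Σ amplitude·thickness(x,y)·interference(λ) + N(0, σ)`, clipped to
[0, 1.2]; a configurable fraction of specular pixels is set near the 1.2
saturation ceiling.  Class signatures are a baseline minus a smooth
sigmoidal water-absorption edge (which also powers band-difference
masking) minus Gaussian dips at the NIR water (≈1450 nm) and CH
(≈1210 nm) bands.

**Sweets scenario** (101 bands, 943–1643 nm, step 7 nm): four classes
with distinct baselines (0.60–0.92), distinct parametric shapes
(mushroom, ellipse, teeth, bottle) and distinct binary surface textures
(stripes at two orientations, blobs at two scales) modulating brightness
by 15%.  Splits: 3 training + 1 validation cube per class (12 + 4), plus
mixed test scenes containing one object of every class.  Noise σ = 0.015,
scatter 0.95–1.05.

**Salmon scenario** (180 bands, 900–1700 nm): a fillet blob with a wavy
zebra-stripe partition into myocommata (bright, fatty: higher baseline,
shallower water dip, CH dip centered 1205 nm) and myotome (CH dip
centered 1235 nm).  The 1205-vs-1235 center shift is the discriminant
that survives EPO; the rest of the class contrast lies along the
interference directions.  Interference is two-dimensional —
thickness×water and composition×CH — with per-fillet amplitudes that are
**batch-structured**: training, validation and test fillets belong to
different batches (amplitude centers (0.06, 0.10), (0.18, −0.05),
(0.32, −0.22), jitter ±0.04), mirroring a study design in which the test
fillets come from batches never seen in training.  Noise σ = 0.045,
specular fraction 0.5%.

What the generator does **not** emulate: instrument line-scan artifacts,
wavelength miscalibration, nonlinear path-length effects (absorbance is
added linearly), spatially correlated noise, or realistic object shape
fidelity.  A pass on these scenes therefore demonstrates that every stage
implements its contract and that the pipeline separates the regimes it
was built to separate — not field performance on real produce.

## Reference experiment protocols (desk scale)

The experiments behind the acceptance numbers use reduced problem sizes
chosen once:

* Sweets: 48×48 scenes (~600–1000 foreground pixels each).  PCA-CNN with
  10 PCs, k = 17, and the full reference training protocol (lr 0.01,
  batch 1024, 100 epochs).  The spatial-only variant (all classes share
  one spectrum *and one shape*; only texture differs — equal shapes keep
  class priors equal so chance is exactly 1/C) trains its CNN for 40
  epochs, which is ample for the texture task.
* Salmon: 32×32 scenes, full 180 bands, 3 seeds.  PLSDA/SVM train on the
  pooled foreground spectra; PCA-CNN uses 5 PCs, k = 7, 100 epochs.  The
  3-D CNN uses k = 7 patches thinned to every 3rd observation (~700
  patches), epochs 25, batch 128, dropout 0.2, with inputs standardized
  per band using training-set foreground statistics (identically for
  every chain, so no arm is favoured): with a 42 750-feature FC layer and
  only a few hundred patches, unstandardized inputs plus dropout 0.5 and
  full-batch momentum SGD oscillate without converging in any reasonable
  epoch budget, so this arm deviates from the 0.5/1024 defaults and says
  so here.  Standardized, it reaches 100% training accuracy within the
  25-epoch budget on every arm.

## Numerical details and degenerate inputs

* `band_index` rejects targets farther than one median band spacing
  outside the grid and breaks ties toward the lower index.
* SNV raises on (near-)constant rows; PLSDA raises when the LV count
  exceeds the centered-matrix rank; EPO raises when `c` exceeds the
  interference rank; patch extraction raises on even windows or empty
  foreground; network construction raises when any layer dimension would
  become non-positive.
* Training aborts with a learning-rate hint on non-finite loss rather
  than producing NaN weights.
* All models serialize (portable `.npz` + JSON-able metadata; the SVM
  ensemble via joblib) and reload to bit-identical predictions.

## Known limitations

* The numpy CNNs are CPU-bound and intended for desk-scale experiments;
  they implement exactly the two reference architectures, not a general
  deep-learning layer zoo (no augmentation, no schedulers, no early
  stopping by design).
* The "manual per-tile threshold" ground-truth procedure for fillet score
  images has no published selection criterion; the automatic mode uses
  Otsu's minimal intra-class-variance threshold per tile and is labelled
  a stand-in.
* Venetian-blinds CV assumes pooled pixels are exchangeable across the
  interleaved folds; with strong within-scene autocorrelation the CV
  accuracy is optimistic (the scene-level train/validation/test split is
  what guards against leakage).
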