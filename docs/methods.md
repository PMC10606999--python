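# Methods

## Model

The verifier is a Siamese network: two weight-sharing copies of a small
convolutional backbone embed the two images, and the distance between the
embeddings is mapped to a dissimilarity score.

Backbone (`small-cnn`): three 3×3 same-padded convolutions with 12/24/48
output channels and ReLU; the first two are followed by 2×2 max pooling, the
last feeds a (1,1) average pool (global average pooling) directly, then a
dense layer of 256 ReLU units produces the embedding. Inputs are resized to
64×64 and scaled to [0,1]; no augmentation is applied by default. The
backbone registry is extensible, but only `small-cnn` ships: the package
targets desk-scale CPU experiments, and every gradient is hand-derived
numpy verified against finite differences, which is what makes the Grad-CAM
activation gradients exact rather than approximate.

Head: `d = σ(w·‖e_A − e_B‖ + b)` with scalar learned `w, b` — symmetric in
the two inputs by construction. An elementwise alternative
(`head='absdiff'`: `d = σ(w·|e_A − e_B| + b)`) is available; the scalar
distance head is the default because its symmetry needs no argument. The
head bias is initialized at −1 so the sigmoid midpoint sits at unit
embedding distance, the midpoint of the default margin (below).

## Training

Pairs follow the verification protocol: for every anchor image, one
uniformly drawn same-class mate (label 0) and one different-class mate
(label 1), never the anchor itself, giving a balanced 2·N pair set.
Duplicate pairs across anchors are allowed — deduplication would break the
two-pairs-per-anchor contract.

The loss is the contrastive pair loss
`L = ½(1−y)·Dw² + y·max(0, m−Dw)²` with margin `m = 2`; the ½ multiplies
only the same-class term. `Dw` is the raw embedding distance by default
(`loss_input='raw_distance'`). Feeding the sigmoid output instead
(`loss_input='output'`) is supported but trains unreliably: the margin
`m = 2` then lies outside the sigmoid's range, the different-pair term never
vanishes, and the opposing gradient pressures leave `d` poorly calibrated
around the 0.5 threshold within a 10-epoch budget (observed: 0.76–0.96 test
accuracy across seeds, versus 0.94–1.00 for the distance formulation). Both
modes use the identical printed loss formula; only the argument differs.

Because the raw-distance loss never touches the output unit, the head is
calibrated after training by logistic regression of the pair labels on the
embedding distances (Platt scaling, `C = 10`). This makes `d` a usable
probability of "different": without it, similarities saturate near 73% and a
confidence gate like "similarity > 80%" can never fire.

Optimization: Adam, learning rate 0.02 decayed linearly per epoch to 0,
batch size 16, 10 epochs, fully seeded and single-threaded. These defaults
were set by pilot runs on the synthetic study — the task is small, so a
relatively large, decayed step converges within the epoch budget. Model
selection keeps the epoch with the best validation pair accuracy; ties are
broken by the lower validation loss and then the earlier epoch. (With a
~32-pair validation set, accuracy ties are pervasive; breaking ties toward
the earliest epoch was observed to return under-trained weights, costing up
to 15 accuracy points on held-out pairs.)

Splits are stratified: per class, `round_half_up(n·test_frac)` test images
with a floor of one; the validation draw takes an exact total
(`round_half_up(pool·val_frac)`) apportioned across classes by largest
remainder, so the overall validation fraction is exact even when per-class
rounding would overshoot. Singleton classes go to train with a warning.

## Explanations

Grad-CAM at the last convolutional layer (configurable by name). Neuron
importance weights are the spatially averaged gradients of the target scalar
with respect to each activation map; the heatmap is the ReLU of the
weighted activation combination, min-max normalized (an all-zero map stays
zero; a constant positive map becomes all ones) and bilinearly upsampled to
image resolution.

The factual target is the model output `d`; the counterfactual target is
`1 − d`, implemented exactly as gradient negation, so the two raw maps are
ReLU(x) and ReLU(−x) of the same combination and never overlap. The choice
of `d` as "factual" is a convention: for a similar pair one can argue the
factual evidence is what drives similarity, i.e. the `s = 1 − d` target —
which is precisely the counterfactual map here, so both readings are always
available from one call. Both branches are explained from one backward pass
by reading each branch's activation gradients separately.

A caveat observed on the synthetic study: for highly similar pairs the
gradient of `d` is carried by the small difference between two nearly equal
embeddings, so the per-channel weights — and with them the map — can be
noisy for individual anchors (occasionally all-zero after the ReLU).
Aggregated over anchors the maps concentrate on the discriminative region
(2–3.3× the mass an unfocused map would place there, across seeds), but
single-pair maps should be read with that variance in mind.

## Crop refinement

For each anchor whose randomly drawn same-class mate scores similarity
strictly above 0.80 (up to 5 distinct mates are tried), the anchor's factual
heatmap is binarized at 0.5× its maximum, the largest 8-connected component
is taken, and its tight bounding box replaces the image. Degenerate boxes
(all-zero map, or area below 1% of the image) fall back to the full image;
boxes are grown to a minimum side of 8 px so crops remain valid inputs.
Anchors without a confident mate are kept unchanged, preserving dataset
cardinality, labels and ids. Train, validation and test sets are cropped
consistently, and a per-image log (mate, similarity, box, fallback flag)
is written.

On the synthetic study the crops keep ≥ 90% of the ground-truth shape
pixels on average while removing background — but retraining on the refined
data *costs* 9–30 accuracy points rather than helping. The mechanism is
measurable: box quality is bimodal (diffuse maps give near-full-frame boxes,
focused maps give tight crops), so same-class pairs mix zoom factors of up
to ~7×, and the small backbone cannot learn that scale invariance within 10
epochs. Retraining on ideal ground-truth-mask crops — uniformly tight —
reaches 100% held-out accuracy, confirming the procedure itself is sound
and the loss comes from heatmap-box heterogeneity. On photographic data,
where within-class variation gives coherent maps and objects fill more of
the frame, crop refinement is reported to help; the synthetic study shows
the opposite regime honestly rather than emulating it.

## Synthetic data

The generator emulates a multi-class labeled image dataset with a known
discriminative region: each class is a distinct colored shape (red disc,
green square, blue cross, yellow triangle, magenta ring, plus three more
combinations), drawn at a uniformly random position and size (16–28 px on a
64×64 canvas by default) over a gray background with uniform pixel noise
(level 0.25 of a ±64-intensity span). Shape colors are chosen so every
class differs from the background by more than the noise amplitude; every
mask is one 8-connected component. Defaults — 5 classes × 40 images — give
a study a small CNN separates within 10 CPU epochs, which keeps the test
suite and the acceptance script inside a few minutes.

What passing on this data does *not* show: robustness to photographic
texture, lighting, scale hierarchies, multi-object scenes, or class overlap
— within-class variation here is only position, size and noise, which also
makes same-pair gradients less informative than on natural images (see the
caveat above).

## Numerical choices

Float64 throughout; sigmoid computed in its numerically stable split form
with the pre-activation clipped to ±30 (the calibrated head can otherwise
saturate to exactly 0/1 in floating point). Zero embedding distance uses a
zero subgradient. Max-pool backward routes the gradient to the first argmax
within each window. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical inputs, config and seed reproduce
training bit for bit.

## Known limitations

- Single backbone at desk scale; no deep pretrained backbone.
- Grad-CAM variants with better map quality (e.g. gradient-free or
  higher-order weightings) are out of scope.
- Macro-averaged precision/recall are reported by default; per-class values
  are logged so any averaging convention can be reconstructed.
- AUC follows the Mann–Whitney convention (ties count ½) and is undefined
  (NaN, with a warning) for single-label pair sets.
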