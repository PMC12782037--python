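# Methods

## The pipeline and its assumptions

The package models a single-specimen workflow: every specimen is imaged,
weighed and individually sequenced, so species identity, abundance (one
specimen = one record) and biomass are all attributed per specimen. Three
assumptions run through the code:

* one specimen per imaging cuvette and per sequencing sample — multi-
  specimen frames and pooled samples are out of scope;
* the morphological identification is trusted at order level only; species
  identity comes exclusively from the dominant-OTU assignment;
* per-frame image features are in calibrated mm units via a known
  `px_per_mm`; any fixed positive rescaling would only shift log-space
  intercepts of the allometric fits.

## Taxonomic assignment rules

Non-macroinvertebrate OTUs (gut content, parasites, environmental
contamination) are filtered out first; the 1,000-read threshold is applied
afterwards, to the winning OTU's reads. A winner that fails the
order-consistency check removes the specimen rather than falling back to
the next-best OTU — rescuing from lower-read OTUs would require manual
arbitration that an automated pipeline cannot imitate. Ties break
lexicographically (smaller `otu_id`, smaller `sample_id`) so assignment is
deterministic and independent of input row order. A specimen with
no sequencing rows at all is counted as `insufficient_reads` with 0 reads.

## Morphometric conventions

Image-analysis libraries disagree by more than 10% on perimeter and Feret
conventions, so the package fixes its own and tests them against brute
force:

* **Coordinates**: row-major, origin top-left, a pixel is its integer
  center.
* **Segmentation**: Otsu's threshold by default (the synthetic frames are
  near-binary), fixed-threshold override for real images; largest
  8-connected component only.
* **MFD**: maximum Euclidean distance between boundary-pixel centers,
  computed on the convex hull of the boundary points; by construction it
  equals the O(n²) pairwise maximum (verified to 1e-9 on random blobs).
* **Perimeter**: length of the Moore-traced outer boundary polygon, unit
  steps for 4-neighbor moves and √2 for diagonals. A 5×5 square has
  perimeter 16; an isolated pixel has perimeter 0 (degenerate polygon).
* **Non-target flagging**: area and solidity bounds; frames are flagged,
  never deleted, and curation drops specimens only when no clean frame
  remains.

## Global-aspect resize

All frames are scaled by the single factor `T/G`, where `G` is the maximum
frame dimension over the whole curated dataset and `T` the network input
size. This preserves inter-specimen size ratios — the signal biomass
estimation depends on — at the cost of small specimens occupying few
pixels. `G` is stored in the dataset manifest so training and inference are
guaranteed to use the same scale. Padding samples pixels from the resized
frame's border under a fixed seed.

## Curation and splits

Exclusion rules apply in a fixed order, one logged reason per specimen:
unassigned → measured mass ≤ 0 mg (detection-limit rule; the balance's
readability is kept as metadata, not as a threshold, since sub-readability
specimens can still be weighed by subtraction) → species with fewer than 5
remaining specimens → no clean frames. Rare-species counts are computed
after the first two rules, mirroring a cleaning-then-recount sequence.

Folds are stratified by species with the specimen as the grouping unit; with
one species per specimen this reduces to a stratified k-fold over specimen
rows (scikit-learn's iterator). The validation set of fold *i* is the
rotation fold *i*+1 mod *k* — the natural deterministic choice when only
"train/validation/test in k folds" is specified. Classification and
regression reuse identical folds so their metrics are comparable.

## Conv-net design

The network is deliberately small — stride-2 3×3 convolution blocks
(default channels 16/32/64/64 on 64×64 inputs), ReLU, global mean+max
pooling, linear head — implemented directly in NumPy with exact analytic
gradients (verified against finite differences). Mean pooling carries
bulk/size information; max pooling detects distinctive local parts (legs,
case corners, the head-waist notch) wherever rotation placed them. AdamW
(weight decay 1e-4) with cosine learning-rate decay from 3e-3; batch 32;
~50 epochs for classification and ~40 for regression at desk scale. One
seed governs initialization, batch order and augmentation, so training is
bit-reproducible on CPU.

Augmentation is one random lattice op per image: the square's eight
symmetries for regression (apparent size must survive augmentation, since
size is the biomass signal), plus small cyclic translations and mild
rescaling (0.7–1.35×) for classification. The rescale op exists
specifically to break the absolute-size shortcut: without it the classifier
leans on specimen size, which overlaps between species, and whole specimens
of atypical size get misclassified.

Checkpointing keeps the parameters at the epoch with minimum validation
loss, together with the full loss curve. Transfer to regression swaps the
head for a single linear output; `frozen_base=True` restricts the
optimizer to the head, leaving the base bit-identical.

## Synthetic-data generator

The generator defines the study conditions the tests run under:

* **Taxonomy**: requested rank counts with surjective child→parent maps;
  orders come from a closed pool headed by the three EPT orders.
* **Shapes**: parametric silhouettes per species — an ellipse-like body
  with taper, optional leg pairs, cerci (mayflies), a rectangular case
  (alternate caddisflies) and an optional head-waist constriction. Species
  cycle through eight combinations of three strong axes (elongation 1.6 vs
  3.4, legs on/off, waist on/off) so classes are separable at 64×64 after
  the global resize; the waist is cut after appendages and case so it stays
  visible for every body plan, and it is subtractive so the maximum Feret
  extent still equals the body length. Camera 1 is the perpendicular view:
  the same body with width scaled by a per-specimen dorsoventral factor
  (≈0.8–0.92; close enough to 1 that the two views of one species stay more
  similar to each other than to the neighboring elongation class).
* **Sizes and masses**: per-species median lengths log-spaced over
  3.5–9 mm, lognormal spread 0.15 truncated at ±2.5σ (so extreme draws
  still fit the frame); mass follows `m = c_s L^{b_s} e^ε` with per-species
  `c_s` (0.015–0.06 mg/mm^b) and `b_s` (2.2–3.0) and lognormal noise
  σ = 0.1 — masses span roughly 0.1–30 mg, with the heavy right tail a
  real weight distribution shows.
* **Weighing**: additive Normal noise then quantization to the balance
  readability; readings near the detection limit can be zero or negative
  and are returned as-is (exclusion is curation's job). The noiseless path
  is exactly the power law, which the allometric-recovery tests exploit.
* **OTU tables**: dominant reads lognormal (median 2×10⁵), contaminants
  100× smaller, contaminant count Poisson; most contaminants carry a
  non-target flag. Failure modes are injected by construction — dominant
  reads drawn under the threshold, order swapped to another order's
  species, species rank truncated — and recorded in a truth ledger.
  Macroinvertebrate contaminants are capped strictly below the dominant
  reads so the injected status is recoverable specimen-by-specimen
  (the "well-separated" regime the recovery tests assume).
* **Seeding**: one root seed fans out through named substreams
  (taxonomy/specimens/frames/weights/otus), so each stage is independently
  reproducible.

What the generator does **not** emulate: photorealistic texture, lighting
and ethanol optics, partial occlusion and touching appendage self-overlap,
sequence-level errors (chimeras, index hopping), or inter-lab variation in
reference databases. Passing tests therefore demonstrate that the pipeline
machinery — assignment rules, split hygiene, checkpointing, transfer,
metric accounting — is correct under controlled conditions; they do not
certify performance on real imagery, where class separability is far lower.

## Problem sizes

The default end-to-end scenario is 8 species × 12 specimens × 16 frames
(two cameras), 128×128 rendered frames at 9 px/mm, 64×64 network inputs,
5 folds — chosen so a complete run with 5-fold training of both model
families finishes in roughly a quarter of an hour on one CPU while leaving
every stage non-trivial (failures are injected, junk frames are flagged,
curation actually drops specimens). The assignment simulation uses 2,000
specimens so the injected 7.2%/3.4%/3.1% failure rates are recovered within
3σ binomial error.

## Known limitations

* The conv net is a fixed small architecture; no learning-rate search or
  architecture search is included — the transfer/evaluation protocol, not
  the backbone, is the contract.
* Frame-level metrics treat frames of one specimen as independent; the
  specimen-median table is reported alongside as the conservative view.
* `order_mismatch` specimens are dropped, never rescued from lower-read
  OTUs.
* The generator's two views differ only by a width scaling; real
  perpendicular projections differ in silhouette detail.
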