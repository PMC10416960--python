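# Methods notes

This note records the model as implemented, the defaults and why they are
what they are, what the synthetic data does and does not emulate, and the
choices made where the design was genuinely open.

## Dilation arithmetic

The dilated-kernel side is computed as γ = ⌈(g + ε − 1)/ε⌉. The ceiling
matters: it keeps γ integral for every (g, ε) and guarantees the effective
extent γ′ = γ + (γ − 1)(ε − 1) ≥ g, i.e. the replacement layer never sees
less context than the dense layer it replaces. For the reference setting
(g = 7, ε = 3) the ratio is exact (9/3 = 3) and γ′ = 7 exactly.

Output feature extents use ⌈(d + 2P − γ′)/ξ + 1⌉. All convolutions in both
architectures are stride 1, where this coincides with ordinary valid
convolution; the stride-2 reductions happen in the 2×2 max pools, which are
ceil-mode (odd extents round up: 710 → 355 → 178 → 89 → 45 → 23). The
parameter audit counts γ²·C·O weights plus a bias per output channel for
every convolution, and no bias for the deconvolutions. These two
conventions (biased convs, bias-free bilinear upsamplers) are not
arbitrary: they are the unique combination under which the published layer
and whole-model counts (18,878,464 / 102,764,544 / 50.39 M / 134.31 M) are
all reproduced simultaneously. Totals in "M" are half-up rounded at two
decimals.

## Architecture

One declarative layer table (`arch.py`) drives three consumers — the
analytic audit, the analytic shape trace, and the trainable model — so they
cannot drift apart; a test asserts `model.num_params()` equals the audit.

Open points in the published table were resolved as follows:

- The skip rows are read FCN-style: each pool output passes a 1×1
  convolution to N channels, is multiplied by a fixed dampening scale, and
  is center-cropped to the running decoder extent before element-wise
  summation. The printed skip rows are not internally consistent (a
  64-channel 1×1 "Convolution" after Pool1, a 3-channel "Scale" before a
  64-channel pool), so this reading is an interpretation, not a
  transcription.
- The table prints the deconv-4 train extent as 302 and the inference
  extent as 320; deconvolution arithmetic ((d − 1)·2 + 4) gives 302 from
  150, and the implementation emits that single consistent value. The 320
  is recorded here as a presumed typographical inconsistency.
- Crops are centered (offsets rounded down), so the final crop returns
  exactly the input frame.
- Dropout (rate 0.5) follows conv6 and conv7, active only in training.
- Inputs in [0, 1] are centered by subtracting 0.5 before the first
  convolution — the usual mean-subtraction convention. Without it,
  bright-field tiles (mean ≈ 0.9) train an order of magnitude more slowly
  than dark-field tiles.

Skip-fusion dampening scales default to (1e−2, 1e−4, 1e−6, 1e−8) for the
pool4…pool1 branches at full scale, where training runs for many thousands
of iterations and the deep semantic path must dominate early. The toy
configurations used in tests and examples set all four scales to 1.0: at a
few hundred iterations the fine-resolution skip paths carry most of the
learnable signal, and the dampened defaults would leave them effectively
frozen. Both are exposed as one constructor argument.

## Loss

Per-pixel softmax followed by the ω-weighted negative log-likelihood of the
labeled class, averaged over all N pixels (background pixels included, with
weight φ_bg). The label index m(n) is read as pixel n's ground-truth
class — the only reading under which the expression is a cross-entropy.
Probabilities are floored at 1e−12 so a confidently wrong pixel yields a
large finite loss. Normalization is per pixel by default; a `sum` switch
reproduces the historic fully convolutional convention in which losses are
summed over pixels. The published learning rate of 1e−10 belongs to that
summed convention (1e−10 × N ≈ 1e−4..1e−3 per-pixel for 0.5–4 Mpx inputs);
the trainer documents this equivalence and never rewrites a configured
rate. Tuned toy-scale default: 1e−3 per-pixel with momentum 0.99.

## Soft labels

The structuring element is unspecified in the source material; the default
is a disk of radius 3 px (at 600× magnification a few pixels is the
plausible width of a drawn nucleus contour's uncertainty), configurable
per dataset, and the same element is used for erosion and dilation. Image
borders pad with background. Where annotations overlap, a pixel takes the
strongest applicable weight (core > band > background). An annotation
smaller than the element simply has an empty core — no Π pixels, no error.
The 64-px toy tiles use radius 1–2 elements so the band does not swallow
whole nuclei.

## Training, split, selection

SGD with momentum 0.99 and weight decay 5e−4, batch size one, samples drawn
by a seeded generator; the loss trace is bit-reproducible on one CPU for a
fixed (model seed, config) pair. The validation split holds out a fraction
ϵ (default 1/9) per stratum: after a seeded shuffle the first
⌊(1 − ϵ)·n⌋ positives and negatives go to fitting, the rest to validation.
Model selection trains one candidate per hyperparameter configuration and
keeps the highest validation Dice, ties to the earliest candidate.

Pixel metrics define precision/recall/Dice/IoU as 1 when both masks are
empty (perfect agreement; the source is silent on this case) and satisfy
Dice = 2·IoU/(1 + IoU) identically. Per-image metrics aggregate as an
unweighted mean ± SD.

## WSI pipeline

Coordinates are 0-based, a = x/column, b = y/row, tiles are half-open
[wα, (w+1)α); edge tiles are zero-padded for inference and cropped on
stitch; tiles process in row-major order so reports are reproducible. The
printed level-selection formula conflates a foreground fraction with a
level index; as implemented, Otsu's threshold is computed once on the
pyramid level whose extent is closest to a single unit tile, tissue is the
darker class on bright-field slides (the brighter on dark-field), each
tile's tissue fraction is measured on its thumbnail footprint, and a tile
survives only if its fraction strictly exceeds 0.70. A uniform thumbnail
(Otsu undefined) is treated as all background. Kept-tile inference runs at
full resolution only. A tile that raises during inference is logged, marked
failed in the report, and left as background.

## Synthetic data

The generators are pure functions of (config, seed). FISH/DISH-like tiles:
near-black vignetted background with Gaussian sensor noise (σ = 5/255),
non-overlapping blue-ish elliptical nuclei (class 1) containing 2–6 bright
orange dots (class 2) placed inside an eroded interior so targets sit
strictly within objects. Bright-field mosaics: tile-aligned, with an exact
seeded set of blank (glass-only) tiles and tissue tiles fully covered by
pink-ish texture holding irregular dark deposits (radius 0.12–0.26 of a
tile — metastasis-like regions are large relative to tiles). Boundary
jitter perturbs the signed distance transform with a smooth noise field
(σ = jitter/2, clipped at ±jitter) and re-thresholds, displacing contours
by at most the jitter amplitude.

What this does *not* emulate: stain variability, scanner artifacts, focus
blur, overlapping nuclei, weak or split hybridization signals, or the class
ambiguity of real annotations. Passing tests therefore demonstrate that the
pipeline's mechanics and optimization behave as specified, and that the
soft-label loss helps under boundary-noise at toy scale — not that clinical
performance figures transfer.

## Problem sizes in tests and examples

Toy models use the full DSL-FCN2s topology at base 8 / head 32 channels on
64-px tiles (≈ 0.25 M parameters), 12 training tiles, 400–1200 iterations —
sizes chosen so a complete training run takes tens of seconds on a single
CPU while still exercising every layer type, the soft-label loss and both
imaging regimes. The soft-vs-hard comparison uses five fixed seeds with
±2 px jittered nucleus annotations, 400 iterations per run, scored as the
mean over held-out tiles of the per-foreground-class Dice. Full-size
parameter audits are exact closed forms and run in milliseconds.

## Known limitations

- The NumPy network trains batch-1 on CPU only; it is meant for method
  verification and toy-scale studies, not production-scale training.
- No pretrained encoder weights; at full 512-px scale, training from
  scratch with this trainer would be impractically slow.
- The pyramid reader handles flat arrays, PNG and flat TIFF; vendor WSI
  container formats are out of scope.
- Π/Ω/φ_bg are fixed weights (2 / 1.5 / 1), not learned.
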