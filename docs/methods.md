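# Methods

This note documents the models, procedures, parameter choices and known
limitations of `ifcmorph`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory of external data.

## 1. The synthetic acquisition model

Real brightfield IFC data for this problem are not bundled, so the package
ships a generator whose output has the *statistical* structure the
analysis depends on, without attempting photorealism.

**Hierarchy.** An acquisition is bulls → ejaculates → files → images. The
default `HierarchySpec` is 6 bulls, 2 fresh ejaculates (spring/fall) plus
1 frozen ejaculate (summer) per bull, 2 files of 50,000 events per sample
— 1.8 million events. Bull- and ejaculate-level random effects are
multiplicative lognormal factors on morphometry means (defaults: SD 0.05
and 0.03 on the log scale), which makes images within a bull positively
correlated — the reason the evaluation uses a *cluster* bootstrap. A test
verifies the induced intraclass correlation directly (one-way
random-effects ICC on head length > 0.3 with bull SD 0.15, ≈ 0 with SD 0).

**Cells.** A cell is parameterized by `CellParams` (head length/width,
midpiece and tail length, tail curvature, droplet radius and position
along the midpiece, orientation, contrast; units are pixels on a 96 px
canvas). Base means (head 19×10 px, midpiece 14 px, tail 42 px) are
plausible for sperm heads at 40× but are *not* calibrated to measured
morphometry — no public quantitative morphometry table was available to
calibrate against, and classifier behaviour depends on class separability
rather than absolute sizes. Per-cell variation is lognormal with 8 % CV on
lengths.

**Defects and labels.** Ground truth per frame is a `DefectSet` (any
combination of seven atomic abnormalities plus multiplet/debris flags),
reflecting that real cells frequently carry several defects at once. It is
collapsed to one of 10 classes by a fixed total priority order

    debris > multiplet > CTM > AT > TEH > IHS > AM > PCD > DCD > NM,

which embeds the two scoring conventions of the field's protocol — coiling
of the tail/midpiece supersedes a plain abnormal tail, and a
twisted/elongated head supersedes other head irregularities — and resolves
every other conflict deterministically and auditable. The generator only
adds co-occurring defects of strictly lower priority (probability 0.15
each), so the label round-trips by construction; a property test checks
the round trip for 100 draws per class.

**Rendering.** Minimal geometry: head = rotated filled ellipse with edge
darkening (irregular heads get angular boundary lobes; twisted/elongated
heads are stretched and sheared), midpiece = thick segment (thicker and
bent when abnormal), tail = ~1 px-step integrated path (smooth quadratic
heading normally; a 55–95° kink for abnormal tails; a tight outward
spiral for coiled tails), cytoplasmic droplets = bright discs on the
midpiece (proximal < 0.5 of the way along it, distal > 0.5), debris = 1–4
irregular dark blobs, multiplets = two overlapping cells. Frames are
Gaussian-smoothed (σ 0.7), multiplied by an optional illumination
gradient, and degraded with additive Gaussian noise; 8-bit grayscale on a
white-ish (218) background. The deliberate consequence is that CTM/AT and
TEH/IHS share most of their geometry and are the natural confusion pairs.

**Domains.** A `DomainParams` is one breed × condition acquisition domain.
Defaults: breeds KW / SIM / AUL differ by ±10 % morphometry offsets;
frozen preparation has 1.5× noise SD, 0.85× contrast, a mild illumination
gradient, and a class mixture shifted toward coiled/bent tails (CTM
0.08 → 0.12, NM 0.45 → 0.40), emulating cryodamage. `default_domains(s)`
scales all offsets by `s` (0 = identical domains) for ablations; the
defaults (`s = 1`) define the study conditions used in tests.

**Determinism.** One root seed; per-file and per-image streams derive from
`numpy.random.SeedSequence` counter keys stored in the manifest
(`root_seed`, `file_uid`, `event_index`), so manifests and pixels are
byte-reproducible and images never need to exist on disk
(`generate_dataset` is metadata-level; `render_record` / `write_images`
materialize pixels on demand; `include_params=False` skips morphometry
draws when only the design arithmetic matters).

## 2. Preprocessing

QC discards frames whose shorter edge is **strictly** below 50 px — a
frame of exactly 50 survives; at smaller scales frames are mostly debris.
Standardization is: center short-edge square crop (floor offset on odd
remainders) → divide by 255 → separable bilinear resize to 224×224
(half-pixel convention, edge-clamped; verified against the scikit-image
bilinear resizer to 3e-5) → normalize (x − 0.5)/0.25 with fixed constants
identical at train and test time → replicate to 3 channels.

Augmentation (training split only, enforced by an assertion in
`augmented_inputs`): horizontal flip (p = 0.5), rotation uniform on ±10°
(bilinear, out-of-frame pixels filled with the border-median intensity —
black corners are alien to brightfield), then a random resized crop
retaining 80–100 % of area with up to ±10 % translation, in that fixed
order. All draws come from one seeded generator. The desk-scale trainer
defaults to *no* online augmentation: with the compact backbone the
benchmark pools are small enough that augmentation adds minutes of warps
per run without changing any ordering the tests assert; the stack is
available for configurations that want it and fully tested.

## 3. The compact backbone and training regimes

No deep-learning framework is part of the runtime: the bundled backbone
is a small CNN written directly in numpy (hand-derived backward passes,
verified against finite differences), which keeps the whole pipeline
deterministic and installable anywhere. Architecture:

- **stem** (fixed, parameter-free): mean over the three replicated
  channels, 8×8 average pooling 224 → 28, per-frame median centring so
  the background maps to ≈ 0;
- **blocks**: four 3×3 same-padding convolutions (widths 16/32/64/64)
  with a modulus activation |x| and 2×2 average pooling after the first
  three blocks; features = flattened 64×3×3 output (576 dims), passed
  through a frozen per-feature standardization fitted once on the
  training features;
- **head**: one linear layer, zero-initialized (the probing objective is
  convex; a zero start avoids a random-logit noise floor).

The modulus activation is the scattering-transform choice: with zero-mean
random filters the signed responses are symmetric, and keeping their
magnitude makes the *untrained* backbone a usable random-feature
extractor, which is exactly what linear probing needs here — there are no
ImageNet-pretrained weights at this scale, so "frozen backbone" means the
seed-fixed random initialisation. The four named ImageNet backbones
(MobileNetV3-Large, EfficientNetV2-S, ResNet-50, ConvNeXt-Tiny) are
accepted in `TrainConfig` as plug-in identifiers for deployments that
provide an external runtime and weights, and raise a clear error
otherwise.

**Regimes.** LP trains only the head (features precomputed once);
LP-FT continues end-to-end with every conv and head parameter trainable
at a reduced learning rate. Optimizer AdamW (decoupled weight decay 1e-4,
applied to weights only), cross-entropy loss, batch size 64, lr 1e-3 (LP)
and 1e-4 (FT), epoch budgets 30 + 30 by default with early stopping at
patience 5 on validation accuracy; the best checkpoint is the highest
validation accuracy, ties broken toward the earliest epoch. Fine-tuning
logs its starting point as epoch 0 and includes it in checkpoint
selection, so the returned LP-FT model is never worse on validation than
the probe it started from. Benchmarked runs in the tests and the
acceptance script cap fine-tuning at 12 epochs (patience 4): on the
~2,000-image pools used there the validation curve plateaus well inside
that budget, and the full 30-epoch default is unnecessary.

Class order is fixed everywhere to the `MorphClass` enumeration order,
preventing silent label permutation. Training is bit-reproducible on CPU:
same config + seed → identical logs, parameters and metrics.

## 4. Sampling design

`quota_sample` draws exactly N rows per class × breed × condition stratum
(default 200), uniformly at random within stratum; a shortfall is an
error unless explicitly allowed, because silent shortfalls would skew the
class balance the protocol is designed to guarantee.
`stratified_split` partitions 80/10/10 with largest-remainder rounding
per stratum (deterministic, sums exactly). `lobo_folds` holds out each
breed once and splits the remainder 80/20 into train/val, stratified by
class. `fraction_subsets` returns *nested* subsets (0.1 ⊂ 0.2 ⊂ 0.5 ⊂
1.0), each class-stratified: nesting means learning-curve differences
reflect data volume rather than sample identity. `balanced_batches`
samples classes uniformly, then images within class with replacement
(minority over-sampling), after applying optional per-class/per-breed/
per-bull caps by uniform subsampling; caps have no hidden defaults.

## 5. Evaluation statistics

Metrics come from the confusion matrix (rows = true, columns =
predicted): accuracy = trace/n; per-class precision and recall with the
0/0 → 0 convention; F1 = 2PR/(P+R) (0 when P+R = 0); macro-F1 = the
unweighted mean over the evaluated class list — including MULTI/DEBRIS
when they are evaluated; biological profiling excludes them downstream.
A fuzz test checks equivalence with a brute-force per-record recount on
1,000 random inputs, and against scikit-learn's implementations.

**Hierarchical cluster bootstrap.** Accuracy CIs resample bulls with
replacement (as many as observed), then ejaculates within each drawn
bull, then images within each drawn ejaculate; the statistic is the
overall mean correctness and the CI is the percentile interval (BCa was
not used; with B = 5,000 and 95 % level the percentile interval is the
plain reading of the procedure). Drawing n images with replacement from
an ejaculate with k/n correct and summing is exactly Binomial(n, k/n), so
the implementation samples that binomial directly instead of
materializing image indices — a statistically identical shortcut that
makes B = 5,000 cheap. In the degenerate single-bull/single-ejaculate
case the procedure reduces to the ordinary iid bootstrap (verified
against an independent flat-bootstrap oracle to 0.01 on the CI
endpoints); on clustered simulations (6 bulls, between-bull accuracy SD
0.05) its empirical coverage of the true mean is ≈ 0.93 over 500
replicates — imperfect, as any 6-cluster bootstrap is, but far better
than the flat bootstrap, which ignores the between-bull floor entirely.
Significance of a difference uses the shared-resample (paired) or
independent (unpaired) bootstrap distribution of the difference and the
CI-excludes-zero rule.

**Generalization matrices.** One model per domain (condition, or breed
within condition), each trained under an equal effective budget (the
smallest domain's training-split size, class-stratified subsampling) on
its own fixed 80/10/10 split, evaluated on every domain's test split;
cells are means over seeds. `gap` reports signed percentage points,
accuracy(train→alt) − accuracy(train→ref). Reports print accuracies in
percent with two decimals.

## 6. Problem sizes in tests and the acceptance script

The benchmark pool is ~2,000 images (quota 33 per stratum over 60
strata), rendered once per session and shared across regime comparisons,
the LOBO fraction sweep (3 folds × 4 fractions × 3 seeds) and the
cross-condition matrix (2 domains × 3 seeds); coverage simulations use
500 replicates with B = 400 inside. These sizes give stable orderings —
LP-FT ≥ LP, accuracy increasing in the labeled fraction, in-domain above
cross-domain — while keeping the full suite and the acceptance script in
the minutes range on a single core.

## 7. What the synthetic results do and do not show

Passing tests demonstrate that the *pipeline* is correct: the sampling
arithmetic, the training contracts (freezing, checkpointing,
reproducibility), the metric definitions, the cluster-bootstrap
behaviour, and the qualitative orderings that follow from the generator's
built-in structure. They do not validate biology: the generator's
morphometry is uncalibrated, its domain shifts are stylized (real
breed/condition differences mix biology with instrument and operator
effects), rendering ignores optics (defocus, diffraction, halos), debris
is geometrically crude, and absolute accuracies on synthetic frames say
nothing about accuracies on real IFC data. Real deployments should also
expect label noise and rater disagreement, which the generator does not
model.
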