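# Methods

## Model and training objective

The system couples three modules through a shared feature space. A feature
extractor FE maps a tile to a D-dimensional vector F; an MSI head predicts
MSI-H vs MSS from F; and one adversarial bias head per protected variable
(source project, patient identity, TMA glass) tries to predict that
variable's indicator encoding from F. The training objective is the
min-max game

    min_{θfe, θmsi}  max_{θbe}   L_msi − λ Σₙ L_beₙ

with the summed cross-entropy `L_msi = −Σᵢ Σₘ y_im log ŷ_im` and, per
head, `L_be = −Σₖ corr²(b_k, b̂_k)`, the negative sum of squared Pearson
correlations across the K columns of the bias encoding. Correlation is a
population-level quantity, so both it and its gradient are computed per
training batch. Each iteration runs three sub-steps in a fixed order:
first the classification update of θfe and θmsi; then, with θfe frozen,
one minimisation step of each head's L_be; finally, with the heads frozen,
one ascent step on each L_be with respect to θfe, scaled by λ — the
"fooling" step that distils the bias signature out of the features. Heads
are processed consecutively in their declared order.

All adversarial steps are restricted to the ρ-conditioned sub-batch, by
default the MSS tiles. Conditioning matters: a bias that is correlated
with the label cannot be removed outright without destroying the label
signal itself, so the heads model (and the FE unlearns) only the
*within-class* batch-effect structure, making F conditionally independent
of each bias given the label. Sub-batches smaller than `min_bias_batch`
(default 8) skip the adversarial steps for that iteration. At λ = 0 the
fooling step is skipped entirely, and because the sampler and the FE/MSI
initialisation depend only on the seed — never on how many heads are
attached — the ablated trainer then reproduces the baseline's parameter
trajectory bit for bit (a tested invariant).

## Monitoring: squared distance correlation

Dependence between features and protected variables is measured with the
squared distance correlation (the classical biased V-statistic): pairwise
Euclidean distance matrices are double-centered and
`dc = dCov²/sqrt(dVar²·dVar²)`, in [0, 1], zero in the population iff
independent. The V-statistic was chosen over the unbiased U-statistic
because its [0, 1] range makes training curves directly comparable; the
cost is a positive small-sample bias: for independent data the null mean
scales like c/N, with c growing with dimension (≈3 for univariate pairs,
≈6–10 for the matrix-vs-indicator audits used here). Audits therefore
either use N ≥ 512 or compare paired models at identical N, never absolute
small-sample values. Distances are computed by explicit differences
(`scipy.spatial.distance.cdist`) rather than the Gram expansion, which
keeps agreement with a direct-summation oracle at the 1e-12 level. The
audit subsamples cohorts above 1500 rows (the statistic is O(N²) in
memory), deterministically under the run seed.

Categorical variables are indicator-encoded, one column per level present
(sorted order); a level absent from a batch would be an all-zero constant
column and is dropped by the audit encoder, while the training-time
encoder keeps the full training-cohort level set so head widths stay
fixed — constant columns contribute zero loss and zero gradient by the
explicit zero-variance convention (ε = 1e-8 guards). The subgroup audit
recomputes dc within each level of each grouping variable and flags an
interaction when a subgroup exceeds the global value by 0.10 (a monitoring
heuristic, configurable).

## Network and optimisation

The desk-scale backbone is a fully connected stack over block-averaged
pixels: tiles are average-pooled to 16×16×3, centred to [−0.5, 0.5] (the
all-positive pixel scale otherwise saturates the first ReLU layer and
stalls learning), and passed through two ReLU layers (768→256→128), giving
D = 128 features; the MSI and bias heads have two hidden ReLU layers of
128 and a linear output (2 logits, softmax, for MSI; K outputs for a
K-level bias). The adversarial mechanism is backbone-agnostic, and the
head shapes mirror a full-scale design with a pretrained convolutional
trunk and D = 512. Everything is double precision with hand-derived
gradients (verified against central finite differences in the test
suite), so runs are bit-stable under a fixed seed and thread pinning.

Optimisation is Adam throughout, lr 3e-4 for FE and MSI and 1e-3 for the
bias heads (heads must track the moving features they predict); one
optimiser per module, the FE optimiser shared between the classification
and fooling steps, as Eq-level reading of the single objective implies.
Batch size 128 by default (64 in the paired benchmark); an "epoch" is
`ceil(N_train / batch)` draws of the composite-weighted sampler, with
replacement. Tile weights are `1/(tiles of patient × patients in class)`,
which balances classes 1:1 and patients uniformly within class
simultaneously. Partitions are patient-grouped k-fold (k = 5): patients
are shuffled under the seed and dealt into near-equal groups, so no
patient's tiles ever span train and validation.

## Synthetic cohorts

The generator emulates the batch-effect anatomy of a TMA study: each
patient carries an MSI label (default prevalence 7.4%, a population-based
colorectal cohort), belongs to a project and a glass, and contributes
tiles in two spots. The *only* biological class signal is morphological:
MSI-H tiles carry a higher density of dark elliptical nuclei and more
mucin-like pale pools, scaled by `signal_strength` and by tissue
specificity (full-strength in tumour epithelium, 0.4 in lymphocytic and
mucinous tiles — which reproduces their higher false-positive rates at
tile level). Nuisance factors are colour/texture overlays: a per-project
RGB stain shift, a per-glass tint, a per-patient smooth texture field plus
hue offset, and optional per-tile hue jitter. All hue overlays live in
the colour plane orthogonal to the nucleus-darkness axis at fixed angles,
so they carry no morphological information — the defining property of a
confound that is removable in principle. `project_confound` sets the
probability that a patient's project follows their class;
`glass_class_purity` the probability of landing on an own-class glass
(1.0 = single-class glasses); `confound_flip` reverses the class→project
association for counterfactual test cohorts. Lower magnifications are
average-pooled and re-upsampled views of the same field; "x0" denotes a
whole-spot thumbnail. Same seed and config give byte-identical pixels.

What the generator does **not** emulate: real nuclear morphology and
texture (overlays are additive and low-frequency), scanner optics,
compression artifacts, annotation noise, or batch effects entangled with
morphology itself. Passing tests therefore demonstrate the *mechanics* of
auditing and ablation under known ground truth, not performance on real
slides.

## The paired benchmarks

The removable-confound benchmark fixes one set of study conditions:
200 patients × 35–45 tiles at 64 px, 15% MSI-H prevalence, two projects
with confound 0.9 and stain shift 0.10, eight glasses with purity 0.6 and
tint 0.08, patient texture 0.05, signal 0.7, single ×20 magnification.
Training uses λ = 2, batch 64, six epochs (a desk-scale epoch is ~125
iterations versus thousands at full scale, so the epoch budget is raised
to give the min-max game a comparable number of moves). Baseline and
ablated models share data, folds, seed and initialisation; the
MSS-conditioned dc between features and each bias is measured on the
training cohort, and both models are additionally scored on an
independent cohort whose class→project association is deterministically
reversed (a probe that penalises a model exactly in proportion to its
reliance on the project colour shortcut).

Across paired seeds the ablated model's MSS-conditioned dependence on
project, patient and glass falls to roughly 0.1–0.3 of the baseline's with
validation AUC essentially unchanged — the core removal claim. The
bias-flipped probe, by contrast, shows *no* systematic gain for the
ablated model: ρ-conditioned ablation deliberately preserves the
label-correlated component of each bias, and the task head amplifies
residual colour directions whose feature-level dc is tiny, so
prediction-level robustness to a reversed confound is not a property this
training scheme confers at this scale (an unconditioned adversary behaves
the same in a control experiment). The corresponding acceptance test
states the stronger expectation and is left failing rather than weakened;
the benchmark reports both AUCs so the behaviour stays visible.

The degenerate-glass control isolates the logically inseparable case:
glass purity 1.0 with glasses given *no* appearance signature of their own
(tint 0, project confound 0, patient texture 0.02), so the entire
feature–glass dependence is routed through the label the glass
determines. The audit uses a class-balanced subsample (prevalence would
otherwise dilute a label-mediated dependence). Ablation neither can nor
does remove it: the ablated dc stays within 0.05 of the baseline's. With
tints present this band cannot be expected — their removable component is
legitimately stripped (collaterally, via the shared hue plane), which is a
different phenomenon than the one under test.

## Preprocessing contracts

Tiling downsamples the native raster by `target_mpp / mpp` (×40 ≙ 0.25
µm/px, halving per step), cuts a top-left-anchored row-major grid and
discards partial border tiles, so counts follow floor division; a cheap
background pre-filter drops tiles with more than 80% of pixels below HSV
saturation 0.05. Macenko normalization estimates stain vectors from the
optical-density cloud (threshold β = 0.15, robust angle percentile α = 1),
rescales per-pixel concentrations to the reference's 99th percentiles and
rebuilds the image with the reference stain matrix; blank tiles pass
through unchanged with a warning. Dataset-statistics normalization is an
exactly invertible channel-wise affine map (no clipping). Augmentation
draws rotations up to 90°, a dihedral flip with probability 0.5,
perspective warps up to 0.2 and hue shifts up to 0.15, deterministically
from the supplied generator; right-angle rotations take an exact
permutation path. The tissue classifier shares the FE architecture so its
trunk is reusable, and ROI selection keeps TUM/LYM/MUC tiles and excludes
any spot left without tumour epithelium.

Patient-level calls are majority votes over hard tile labels at the 0.5
operating point, ties broken toward MSI-H (a screening context favours
sensitivity; mean-probability thresholding is available), with the mean
tile probability as the patient score for AUC. Prevalence-dependent
metrics are reported at an assumed 15% population prevalence through the
closed forms `acc = S·P + E(1−P)`, `PPV = S·P/(S·P+(1−E)(1−P))`,
`NPV = E(1−P)/(E(1−P)+(1−S)·P)`; sensitivity, specificity and accuracy
get exact Clopper–Pearson intervals (Beta quantiles), the predictive
values standard logit intervals via the delta method. Stratified
false-positive/negative rates are computed per tissue type and
magnification, per fold, undefined strata marked as NaN.

## Known limitations

The MLP backbone sees 16×16 block means, so fine nuclear texture is out of
reach and colour overlays are its easiest cues — which is what makes the
benchmark sharp, but also means absolute AUCs say nothing about real
tissue. The V-statistic's small-sample bias makes dc values comparable
only at matched N. The adversarial equilibrium is delicate: overly long
or strongly weighted fooling (λ ≳ 3 with extended training) can collapse
the features entirely (dc → 0 with chance-level AUC), so λ and the epoch
budget should be monitored via the per-iteration dc trace that
`train_model` records. Bias heads with many levels (patient identity)
learn from few active indicator columns per batch and converge more
slowly than few-level heads.
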