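# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic cohort does and does not emulate,
and the design choices made where the design was genuinely open.

## Federated model

A federation is one *server* center holding the global model and K ≥ 1
*client* centers holding personalized local models of possibly different
architectures. Parameters are never exchanged between different
architectures; all cross-model coupling happens in **pooled channel space**:
each backbone declares tap stages, and the spatial activation map of a
tapped stage is average-pooled to one value per channel.

**Stage matching.** Two models' tap stages are paired by ordinal position
(first tap with first tap, and so on, up to the shorter list). Pooled-channel
space sidesteps spatial misalignment between heterogeneous trunks, at the
cost of discarding spatial structure from the transferred signal.

**Interaction projections.** For each (direction, stage) pair an affine map
`W s + b` carries source channels into target channel space. Projections are
owned and SGD-trained by the receiving side together with its model, and are
initialized near zero (Gaussian, SD 0.01) so transfer pressure grows
smoothly from nothing rather than jolting a freshly initialized model.
A per-round least-squares refit of the projections was evaluated and
rejected: with desk-scale sample counts close to the channel count it
overfits, making every client's features look equally predictive.

**Transfer weights.** For a target stage with C channels, channel relevance
is `|AUC_c − 0.5|` of the projected source features against the data
labels (chosen over correlation for invariance to monotone feature
transforms). The top `⌈q·C⌉` channels are kept (ties to the lower index),
softmaxed at temperature τ, the rest zeroed; the result sums to one. An
all-zero relevance vector — including the degenerate single-class or
constant-feature cases — yields uniform weights over the kept set.
Weights are recomputed once per round, not per epoch.

**Transfer loss.** `L = Σ_c w_c · mean_n (t_{n,c} − proj(s)_{n,c})²`,
nonnegative, zero exactly when target equals projected source on every
positive-weight channel, and linear in the weight vector.

**Client round.** Each client minimizes
`CE_local + λ · Σ_stages L_transfer(local ← frozen global)` for E epochs of
minibatch SGD. The frozen global model's pooled features on the client's
training data are computed once per round; the global model is never
modified by a client.

**Server round.** The global model trains on the server center's data with
`CE_server + λ_g · Σ_k α_k · Σ_stages L_transfer(global ← frozen client k)`,
with server-side transfer weights computed from the server's own data.
Before training, each client's marginal effect is probed: one SGD step on
that client's transfer term alone, then the change in cross-entropy
`ΔCE_k` on a held-out 20% tail of the server training split (a fixed,
unambiguous measurement protocol); probe steps are discarded. Aggregation
weights update multiplicatively, `α_k ← α_k·exp(−η·(ΔCE_k − mean ΔCE))`,
are floored at ε by exact projection (floored entries sit at ε, the rest
renormalized to the remaining mass), and sum to one. The update is
invariant to adding a constant to all ΔCE values.

The server center also trains a local model of its own each round; it takes
no part in aggregation weighting and exists for per-center evaluation
symmetry (`server_trains_local` turns this off).

## Backbones

Full scale: a ResNet-18-style global trunk (stages of 64/128/256/512
channels, basic residual blocks, batch normalization) and a VGG-16-style
local trunk (blocks of 64/128/256/512/512 channels). The global feature
contract taps stages 3 and 4 and pools each by **both** average and maximum,
giving 2×(256+512) = 1,536 dimensions — the minimal tap configuration
reproducing that contract; the local contract taps all five blocks with
average pooling only, 64+128+256+512+512 = 1,472 dimensions, the unique
natural reading. Concatenation order is ascending stage, average before
maximum within a stage.

Tiny variants replicate the topological contrast (residual vs plain trunk)
at 8/16/32 channels with 64×64×1 inputs for desk-scale federation studies.
All trunks carry batch normalization: without it, per-channel pooled-feature
variation is two orders of magnitude smaller than the feature means and
gradient training cannot leave the base-rate plateau. ImageNet-pretrained
weights are not used; all experiments start from seeded He initialization.

ROI preprocessing resizes bilinearly to a square (224 per side at full
scale), replicates grayscale to three channels when needed, and min-max
normalizes to [0,1] (constant inputs map to all zeros). Grad-CAM weights the
last tapped stage's channel maps by spatially averaged gradients of the
chosen class logit, rectifies, upsamples bilinearly, and max-normalizes.

## Synthetic cohort

The generator emulates the statistical shape of a four-hospital early-stage
lung-cancer cohort: center sizes 455/188/141/108 (train/test splits
276/179, 104/84, 78/63, 60/48) with progression counts 47/33, 19/18, 16/9,
9/7; age ≈ 60 ± 10 years; smoking ≈ 25–35%; CEA-positive ≈ 20%. Lesions are
star-convex: boundary `r(θ) = r0·(1 + a·Σ_k c_k cos((k+2)θ + φ_k)/√5)` with
class-specific irregularity amplitude a (0.20 progressive vs 0.10
non-progressive) and internal texture SD (0.10 vs 0.05). These contrasts
were fixed once so that the class signal is learnable but not saturated at
desk scale (untrained-backbone downstream AUC ≈ 0.7–0.9). Center effects
are an additive intensity offset, Gaussian blur, and pixel noise; the noise
field is always drawn so random streams stay aligned across settings.

What the generator does **not** emulate: CT physics, 3-D structure,
scanner-specific artifacts, segmentation variability, or any correlation
between covariates and image content beyond a mild label-dependent shift in
age and CEA. Results on this cohort therefore demonstrate that the
machinery behaves as specified under a known class signal — not clinical
performance.

The adversarial validation split proposes class-stratified random splits
(sizes `round(n·f)` and the remainder, prevalence preserved within one
record) and accepts the first whose 3-fold cross-validated logistic
discriminator — 8 image summary statistics plus the 4 covariates — has AUC
within tolerance of 0.5, else returns the closest.

## Downstream classification

Per center, the designated model (the personalized local model for clients,
the global model for the server center; a switch selects the global pathway
everywhere) produces train/test feature tables. Selection and fitting use
training data only:

* **Mann-Whitney U**, two-sided, exact enumeration when both groups ≤ 8
  else normal approximation with tie and continuity corrections; constant
  features get p = 1; α = 0.05. If nothing passes, the smallest-p feature
  is kept and flagged.
* **mRMR**, greedy MID (difference) variant: first pick maximizes I(f; y),
  later picks maximize `I(f; y) − mean_{s∈S} I(f; s)`; mutual information on
  4-bin equal-frequency discretizations; ties to the lower column index;
  default k = 15 (10 at desk scale).
* **Sparse Bayesian ELM**: features standardized by training moments;
  hidden weights/biases uniform(−1,1) from the seed; logistic-link ARD —
  alternating IRLS for the Laplace posterior mode and precision updates
  `α_i ← γ_i/β_i²` with `γ_i = 1 − α_i Σ_ii`, until the relative evidence
  change is below 1e-6 or 50 outer iterations; units with precision above
  1e6 pruned; the bias column carries a diffuse fixed prior and is never
  pruned. The Laplace evidence is tracked per outer iteration and is
  non-decreasing in practice (asserted to 1e-8 slack in tests).

## Evaluation statistics

DeLong variance uses the structural-components estimator (placement values
of positives against negatives, ties counted one half) with a Wald 95% CI
clipped to [0,1]; degenerate zero-variance configurations give a zero-width
interval. Cutoffs maximize Youden's index over midpoints of adjacent unique
training scores, ties to the lower threshold; prediction at a threshold is
`score ≥ t` project-wide. IDI is the change in discrimination slope; NRI is
the continuous (category-free) form; both use the standard asymptotic
variance estimators and two-tailed normal tests. Decision curves use
`NB(pt) = TP/n − (FP/n)·pt/(1−pt)` on a 0.01–0.60 grid (step 0.01).
Calibration uses equal-width bins. Cross-validation is stratified 5-fold
with the entire selection+classifier chain refit per fold; a fold missing a
class triggers a redraw with the next sub-seed. Subgroup comparisons use the
unpaired DeLong z-test (different patients per stratum); age strata split at
the median.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| R (rounds) | 20 | federation rounds (5 in the desk-scale studies) |
| E, E_g | 1 | local / server epochs per round |
| λ, λ_g | 0.1 | client / server transfer strength |
| η | 1.0 | aggregation-weight learning rate |
| τ | 0.05 | transfer-weight softmax temperature |
| q | 0.5 | fraction of channels transferred |
| ε | 0.01 | aggregation-weight floor |
| batch | 16 | minibatch size |
| lr | 0.1 | SGD step size (chosen by a loss-trajectory sweep at desk scale) |
| probe fraction | 0.2 | server hold-out used for the ΔCE probe |

All are exposed in `FederationConfig` and the run config file.

## Desk-scale study sizes

The shipped desk-scale study uses 4 centers of 40 records each (30 train
with 8 progressive, 10 test with 3), 64×64×1 images, tiny backbones, R = 5,
and 10 seeds for test-suite studies (3 for the reproduction script). The
full-scale cohort profiles (892 patients, 224×224×3) are available through
`default_profiles("full")` and the full-scale backbone specs.

## Known limitations

* Transfer operates on pooled channel features; spatial feature structure
  is not exchanged.
* The ΔCE probe measures a client's effect through its *features*. A
  label-shuffled client preserves its label marginal and, at desk-scale
  training depth, measurably retains the class relevance of its pooled
  features (which is largely input-driven); its per-round ΔCE therefore
  exceeds the clean clients' only ~60% of the time, and its aggregation
  weight drifts below uniform in most but not all seeded runs. Detecting
  such clients reliably would need either much deeper local training (so
  label noise actually corrupts the extractor) or a probe sensitive to the
  client's classifier head, which the feature-transfer design deliberately
  does not touch.
* Single-center test splits at desk scale hold 10 records; per-center AUCs
  are correspondingly noisy and only seed-averaged comparisons are stable.
* The sparse Bayesian ELM uses the Laplace approximation throughout;
  predictive probabilities are MAP point estimates, not moderated.
* The federation is simulated in-process: no transport, stragglers,
  differential privacy, or secure aggregation.
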