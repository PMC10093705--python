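# Methods

## Model

The classifier is a fuzzy min–max neural network: three layers FA
(input features), FB (hyperbox fuzzy sets) and FC (class nodes). Each
hyperbox `H_j = (V_j, W_j, class)` lives in the unit hypercube; the
connection weights between FA and FB are exactly the corner matrices V
and W, and the binary matrix U between FB and FC routes each box to its
one class (one 1 per row). A class node's activation is the maximum
membership over its boxes and prediction is winner-take-all.

Membership of pattern `a` in box `(v, w)` averages, over dimensions,
two saturated penalty terms — one for overshooting `w`, one for
undershooting `v`:

    b(a) = (1/2n) Σᵢ [ max(0, 1 − max(0, γ·min(1, aᵢ − wᵢ)))
                     + max(0, 1 − max(0, γ·min(1, vᵢ − aᵢ))) ]

Consequences used by the tests: membership is exactly 1 on the closed
box; for a point outside in exactly one dimension by `d ≤ 1/γ` it is
`1 − γd/(2n)` (closed form); it is non-increasing as a coordinate moves
away from the box along an axis.

### Training (one pass)

Per sample, in presentation order:

1. **Expansion.** Same-class boxes are visited in descending membership
   (ties broken by box index, for determinism). The first box whose
   enclosing span satisfies `Σᵢ [max(wᵢ, aᵢ) − min(vᵢ, aᵢ)] ≤ n·θ`
   absorbs the pattern by elementwise min/max. If none qualifies, a
   point box `v = w = a` is created. A `1e-12` slack on the comparison
   guards exactly-at-bound expansions (notably `θ = 0` with a repeated
   pattern) against float round-off.
2. **Overlap test.** Only after an expansion (a fresh point box has
   zero volume and cannot positively overlap anything), the grown box
   is tested against every box of a different class. Two boxes overlap
   iff every dimension's interval intersection has positive width;
   sharing a face is *not* overlap — it is the target state of
   contraction. Per dimension the overlap measure is
   `δᵢ = min(w_jᵢ − v_kᵢ, w_kᵢ − v_jᵢ)` (equal to the intersection
   width for partial overlaps, to the cheaper cut depth for
   containments); the contraction dimension Δ minimizes δᵢ, lowest
   index on ties.
3. **Contraction.** Only dimension Δ changes. With j and k ordered by
   the case test: partial overlaps split the overlap interval at its
   midpoint (case 1: `w_jΔ = v_kΔ = (v_kΔ + w_jΔ)/2`; case 2
   symmetric); containments cut the containing box back to a face of
   the contained one on whichever side loses less extent. Equal-corner
   degeneracies (identical or flush boxes) are folded into the
   containment cases so contraction is total on any positively
   overlapping pair; the soundness property (re-test reports no
   overlap; other dimensions untouched) is enforced by randomized and
   property-based tests rather than assumed.

Same-class overlap is left in place: with winner-take-all routing
through U it cannot change a decision, and removing it would only
shrink boxes.

Two count laws follow and are tested exactly: `θ = 0` yields one point
box per distinct training pattern (hence resubstitution accuracy 1.0
when no duplicate pattern carries conflicting labels), and `θ = 1`
yields exactly one box per class, since the first box of a class then
always admits expansion.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| θ | cap on a box's summed edge lengths (`n·θ`); granularity knob | sweep 0…1 step 0.1 | the sweep grid is the protocol; single-model default 0.3 sits in the well-generalizing mid-range |
| γ | membership decay slope outside a box | 1.0 | no principled prior; 1.0 makes the penalty equal the axis distance; exposed in config/CLI |
| split ratio | train fraction of the single stratified split | 0.7 | conventional 70/30 screening split; seed recorded |
| positive class | which label is "positive" in the metrics | `abnormal` | screening context: malignant is the detection target |

Presentation order matters for any online FMMN; the training rows are
shuffled once with the split seed and the same order is reused for
every θ in a sweep, so sweeps isolate θ's effect. Tie-breaks
(prediction ties → first-seen class; candidate ties → lowest box index;
Δ ties → lowest dimension) are all deterministic, making training and
reports bit-reproducible for a fixed seed.

## Normalization

Min–max rescaling per feature with *training* statistics; the training
minimum maps to exactly 0 and the maximum to exactly 1. Test values
outside the fitted range are clipped to [0, 1], because the hyperbox
geometry presupposes the unit hypercube. A constant training feature is
undefined under the formula; it maps to 0 with a warning (it carries no
class information either way). Baselines consume raw features by
default — normalization is the fuzzy net's own geometric prerequisite,
not part of the baselines' contract — with a config switch to share the
normalized view.

## Feature extraction

The four backbone adapters (`alexnet_fc7` 4096, `googlenet_loss3` 1000,
`resnet18_pool5` 512, `resnet50_fc1000` 1000 features) follow the
frozen-backbone transfer-learning pattern: read activations at the
named layer of an ImageNet-pretrained network, no gradient updates.
They require the optional torch/torchvision runtime plus local weights
and otherwise fail with a clear error; gradient fine-tuning is out of
scope by design. The `toy` extractor is the tested, fully deterministic
path: resize to 32×32 grayscale, convolve with a fixed bank of six 3×3
edge/blob/corner filters, average-pool each response on a 4×4 grid,
append an 8-bin intensity histogram (104 base features), then truncate
or tile to the requested width (default 24). No randomness anywhere, so
extraction is bitwise reproducible.

## Synthetic data

Blob fixtures draw isotropic Gaussians around centers inside the open
unit hypercube, clipped to [0, 1]; class overlap is controlled by
center spacing vs. spread. The recovery setting used in tests — two
classes 0.4 apart on the unit-square diagonal, σ = 0.05, 400 points,
70/30 split — is a cleanly separable regime in which any reasonable θ
in 0.1–0.3 should exceed 0.95 held-out accuracy.

Toy cell images emulate single-cell cytology crops: a cytoplasm disc
with an elliptical nucleus, where the abnormal class has an enlarged,
irregular (12-gon with jittered radii) nucleus and a higher
nucleus-to-cytoplasm ratio — the morphological cue real screening uses.
They do **not** emulate staining variation, overlapping cells, debris,
focus artifacts, or class-imbalanced priors, so a passing end-to-end
test demonstrates the pipeline's plumbing and the classifier's
geometry, not clinical-grade performance on real slides. Accuracies on
these fixtures (typically 0.95–1.0) must not be read as estimates for
Herlev or Sipakmed.

For the real datasets only the directory-layout manifests are built in:
the Herlev seven-category map (normal squamous, intermediate squamous,
columnar → normal, 242 images; mild/moderate/severe dysplasia and
carcinoma in situ → abnormal, 675 of 917) and the Sipakmed five-category
map (superficial-intermediate, parabasal → normal; koilocytotic,
dyskeratotic → abnormal; metaplastic is benign and defaults to normal
with a config override, since published binary totals for it are not
stated; 4049 images total).

## Baselines

The seven-name bench (BayesNet, Naive Bayes, random forest, random
tree, decision table, PART, simple logistic) mirrors a classic
workbench lineup. Exact replication of those implementations is a
non-goal; each name maps to a documented scikit-learn analogue
(LDA, GaussianNB, RandomForest, random-split tree, depth-4 tree,
unrestricted tree, LogisticRegression) and every result row carries an
`analogue` flag. All classifiers see byte-identical splits; baseline
hyperparameters are library defaults and are recorded with the run log
(seed, split sizes, extractor, library versions).

## Evaluation

Confusion counts with abnormal as the positive class (configurable),
then accuracy, sensitivity, specificity, precision and F1. A
zero-denominator ratio is reported as 0.0 with the metric name listed
in an `undefined` flag instead of propagating NaN. Reports store full
doubles; rendered tables round for display only. Every report row is
re-derivable from the persisted per-sample predictions file.

## Problem sizes

Randomized property checks run at: 100 datasets (n ≤ 200, d ≤ 8) for
the count laws, 10⁵ random (box, pattern, γ) triples for
membership-oracle agreement (tolerance 1e−12), 10⁴ overlapping pairs
for contraction soundness, 50 datasets for the resubstitution law, and
a 200-image toy pipeline with the full 11-value θ grid and all seven
baselines. These sizes keep the whole suite and the acceptance script
comfortably within a few minutes on one CPU while exercising every
branch of the case analysis thousands of times.

## Known limitations

- Single fixed seeded split (a repeat-k option would average over
  splits); the θ-sweep protocol reports one split per θ by design.
- The original Simpson contraction can, in adversarial orders, erode
  boxes so that earlier-absorbed patterns fall outside every same-class
  box; no post-hoc repair is attempted (matching the classic
  algorithm).
- Backbone adapters are contracts without a bundled weight runtime;
  the toy extractor is not a stand-in for CNN features, only a
  deterministic pipeline exerciser.
- Multiclass operation works (the bench and net accept any label set)
  but all shipped protocols target the binary screening case.
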