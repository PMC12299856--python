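# Methods

This note documents the models implemented by `nodulekit`, the parameter
choices that matter, the numerical conventions, and what the synthetic
experiments do and do not show.

## Box geometry and the penalised-IoU family

Boxes are axis-aligned rectangles in continuous corner coordinates
`(x1, y1, x2, y2)`, y growing down (image convention). No pixel
convention applies to the geometry: areas are products of real side
lengths, and all pairwise quantities (IoU, squared center distance ρ²,
squared enclosing diagonal c²) are exact closed forms. A deliberately
naive rasterized oracle — pixel-center membership counting on a
1000×1000 lattice over the enclosing box, O(grid²) per pair — exists
solely as an independent cross-check; it converges to the analytic IoU
as the grid grows and agrees within 2×10⁻³ at grid 1000.

The scores all share the pattern `IoU − penalties`:

| variant | penalty terms |
|---|---|
| `iou`   | none |
| `giou`  | enclosing-box gap `(|C| − |U|)/|C|` |
| `diou`  | `ρ²/c²` |
| `ciou`  | `ρ²/c² + α·v`, `α = v/((1−IoU)+v)` by default |
| `eapiou`| `ρ²/c² + λ·v + λ·(w/h − w_gt/h_gt)²` |

with `v = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))² ∈ [0, 1]` and
`λ ∈ [0, 1]`, default 0.1 (enforced at construction). The training loss
is `1 − score`; the gradient is identical to `−score` up to the constant.
The squared-ratio penalty is convex and symmetric in the ratio gap and —
unlike `v`, whose derivative decays as `1/r²` — keeps an `O(r)` gradient
at large mismatch: at ratio 10 against a square target the magnitude
ratio of the two derivatives exceeds 3×10³. With `λ = 0` the score and
its gradient reduce exactly (bitwise) to DIoU.

The CIoU baseline defaults to the original adaptive trade-off
`α = v/((1−IoU)+v)`, differentiated in full (no dropped factors, no
detached α) so that the analytic gradient matches finite differences;
a constant-λ weighting of `v` is available via `ciou_alpha_mode`.

**Numerical conventions.** Denominators are floored, not shifted:
`r = w / max(h, ε)` and `ρ²/max(c², ε)` with `ε = 10⁻⁷`. A floor keeps
every ratio *exactly* invariant under joint positive scaling of both
boxes away from the degenerate limit (an additive `h + ε` guard would
bias small boxes and break scale invariance at the 10⁻⁶ level) while
still bounding the loss for zero-height inputs. Degenerate boxes have
area 0 and IoU 0 against anything; a pair collapsing to one identical
point raises an error rather than dividing by c² = 0. At the exact
optimum `pred = gt` the IoU term is non-smooth; its subgradient is taken
as 0 so the optimum is stationary. For disjoint boxes the IoU term has
zero gradient and the distance term supplies the pull, as in DIoU — no
special-casing.

Gradients are hand-derived chain rules over the closed forms, in two
parameterizations — raw corners and `(cx, cy, log w, log h)` — and are
verified against central finite differences (`h = 10⁻⁶·scale`) to better
than 10⁻⁵ relative on hundreds of random pairs. Min/max tie subgradients
use the active-side convention noted in the code; ties are measure-zero
for continuous inputs.

## SSE attention forward pass

The module is a reference forward computation, not a trainable layer:
channel squeeze-and-excitation (global average pool → two-layer
bottleneck with ReLU and sigmoid → per-channel rescale), followed by
spatial attention computed *on the channel-recalibrated map*: per-pixel
max and mean over channels, stacked, convolved with one k×k kernel
(cross-correlation, stride 1, zero padding (k−1)/2, scalar bias) and
squashed, then broadcast-multiplied over channels. The sequential order
(channel first, spatial on X′) follows the defining equations; an
alternative parallel-additive reading exists in prose descriptions of
such modules but contradicts the multiplicative, sequential equations
and is not implemented.

Choices where the design was open:

* **Reduction ratio** `r = 16` (the standard SE default; the bottleneck
  width floors at one channel), exposed as config.
* **Kernel size** `k = 7` by default — the empirically favoured setting
  for this module family — configurable to any odd size; shape is
  preserved for all of {3, 5, 7, 9, 11}.
* **Biases** are included in both FC layers and the convolution,
  initialised to zero.
* **Initialisation** is seeded uniform `[−1/√fan_in, +1/√fan_in]`, giving
  reproducible reference fixtures; no training is performed.
* Pooling for the spatial descriptors is over channels only, per batch
  element — never over the batch.

Structural guarantees verified by the tests: output shape equals input
shape; both gates lie strictly in (0, 1) for finite inputs, so the
output is an elementwise contraction of the input; channel-permutation
equivariance; interior translation equivariance of the spatial map; and
agreement to 10⁻¹² with a straight-loop reference implementation.

## Detection metrics

Single-class evaluation with the standard greedy protocol: detections
sorted by confidence (ties keep input order), each claiming the
unmatched ground-truth box of highest IoU at or above the threshold,
one-to-one, IoU ties to the lowest ground-truth index. AP is the area
under the monotone non-increasing precision envelope over recall
(all-point interpolation, as in modern YOLO-family evaluators — not
11-point). `map50` is AP at threshold 0.5; `map50_90` averages the
inclusive grid {0.50, 0.55, …, 0.90} (9 thresholds); the COCO-style
0.50–0.95 grid is a config option. With zero predictions precision is
reported as 0 with an explicit flag rather than left undefined.
Multi-class input is supported structurally (per-class AP mean) but
exercised only for the single "nodule" class.

## Box-regression simulator

The simulator is the desk-scale analogue of training-time loss
comparisons: instead of detector mAP on CT datasets it measures
convergence statistics (steps to tolerance, final IoU, convergence rate)
of pure box regression under each loss variant and λ, and its outputs
are labelled as such. Findings transfer to detector training only to the
extent that box-regression dynamics dominate; classification and feature
learning effects are outside its scope.

Optimization runs in `(cx, cy, log w, log h)` — widths and heights stay
positive without constraints — with two numerical devices:

* **Preconditioning.** The losses are scale invariant, so center
  gradients carry a 1/length² factor relative to the log-size
  coordinates. Steps follow `diag(c², c², 1, 1)·grad` with `c²` the
  target's squared diagonal, restoring commensurate units; with a plain
  Euclidean step the center coordinates crawl.
* **Backtracking with kink handling.** A proposed step is halved (≤ 40
  times) until the loss decreases, so accepted steps never increase the
  loss; the accepted size seeds the next step (doubling on success). The
  IoU surface is non-smooth along corner-tie manifolds, and iterates can
  land on a tie where both one-sided derivatives of some coordinate are
  adverse (a V-shaped kink minimum). When full-gradient backtracking
  fails, one-sided slopes are probed per coordinate and V-kink
  coordinates are frozen, so descent continues along the manifold; the
  run stops only when no descending direction remains.

Start configurations are drawn in named strata so claims are scoped:
`benign` (initial IoU ≥ 0.2, aspect mismatch ≤ ×2), `aspect_mismatched`
(×4 ratio mismatch), `disjoint_start`. Targets have ratios in [1/4, 4];
inits jitter center (≤ half the target diagonal), scale (×[0.5, 2]) and
ratio. Defaults: `lr = 0.05`, `max_steps = 1000`, `tol = 0.1` (stop at
IoU ≥ 0.9), λ grid {0.001, 0.01, 0.1, 0.5, 1}. Experiments are factorial
sweeps, deterministic given the config seed down to byte-identical CSV.
The default problem sizes (tens of targets, a couple of inits each) keep
a full sweep in seconds on one core; they are statistics over dozens,
not thousands, of runs, and per-λ rankings at a single seed should be
read accordingly.

## Synthetic data

All generators are deterministic under their seed, byte-identical on
regeneration, and self-validating (sampled box pairs are re-measured
against the requested IoU and ratio-quotient ranges; infeasible requests
raise with the achieved coverage).

The nodule scenes emulate the statistical shape of thoracic CT slices
for this package's purposes — small bright blobs (anti-aliased rotated
ellipses, blurred rims, configurable radius, eccentricity and contrast)
on smoothed Gaussian background noise, with tight axis-aligned boxes —
at a default 320×320, intensities in [0, 1], written as 16-bit PNG.
They are *not* a physical CT simulation: no Hounsfield calibration, no
anatomy, no 3D context, no reconstruction artefacts, no inter-reader
label noise. Passing metrics and loss tests on these scenes therefore
demonstrates correctness of the computations and plausible behaviour on
blob-like single-class data, not clinical performance.

Prediction corruption (for exercising the evaluator) jitters surviving
ground-truth boxes with Gaussian noise, assigns confidence decaying in
the realised jitter magnitude, drops boxes at the miss rate and adds
false positives drawn with the nodule size distribution.

## Known limitations

* The EAPIoU aspect penalty is unbounded (quadratic in the ratio gap);
  at λ near 1 and extreme mismatch the loss landscape is dominated by
  shape before overlap. This is inherent to the formulation.
* SSE weights are never trained here; conclusions about attention
  quality on real data require a training loop this package does not
  provide.
* The evaluator implements no non-maximum suppression or confidence
  sweeping; inputs are scored as given.
* WIoU / EIoU / SIoU variants are not implemented.
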