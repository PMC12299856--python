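"""Seeded synthetic inputs: box pairs, feature maps, nodule scenes, noisy predictions.

Everything in the package is testable without external data: this module
generates (a) random box pairs with controlled overlap and aspect-ratio
mismatch, (b) random feature maps for the attention module, (c) CT-slice-
like images containing bright elliptical "nodules" on a noisy background
with tight box labels, and (d) corrupted copies of a ground-truth label
set that behave like an imperfect detector's output.  All generators are
fully deterministic under their seed.

The nodule scenes are a statistical stand-in for thoracic CT slices --
small bright blobs of varied eccentricity on correlated noise -- not a
physical CT simulation; see the package methods note for what that does
and does not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .boxgeom import Box, iou
from .detection_metrics import Detection

__all__ = [
    "SceneParams",
    "NoduleScene",
    "sample_box_pairs",
    "gen_feature_map",
    "gen_nodule_scene",
    "corrupt_gt_to_predictions",
]


class GenerationError(RuntimeError):
    """A generator exhausted its retry budget before meeting its contract."""


# ---------------------------------------------------------------------------
# Box pairs with controlled overlap / aspect mismatch
# ---------------------------------------------------------------------------

def _random_box(rng: np.random.Generator, span: float = 100.0) -> Box:
    cx, cy = rng.uniform(0, span, size=2)
    w = rng.uniform(2.0, span / 3)
    ratio = np.exp(rng.uniform(np.log(0.25), np.log(4.0)))
    h = w / ratio
    return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def sample_box_pairs(n: int,
                     iou_range: tuple[float, float] = (0.0, 1.0),
                     ratio_mismatch_range: tuple[float, float] = (0.25, 4.0),
                     seed: int | None = 0,
                     max_retries: int = 20_000) -> list[tuple[Box, Box]]:
    """Draw n box pairs whose measured IoU and ratio quotient hit the ranges.

    The first box of each pair is sampled freely; the second is derived by
    jittering center, scale and aspect ratio, then both are re-measured and
    the pair is kept only if IoU(a, b) lies in ``iou_range`` and
    ``r1/r2`` (width/height-ratio quotient) lies in
    ``ratio_mismatch_range`` (rejection sampling).  Raises
    :class:`GenerationError` with the achieved coverage if the ranges
    prove infeasible within ``max_retries`` draws.
    """
    lo, hi = iou_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"iou_range must satisfy 0 <= lo <= hi <= 1, got {iou_range}")
    qlo, qhi = ratio_mismatch_range
    if not (0.0 < qlo <= qhi):
        raise ValueError(f"ratio_mismatch_range must be positive, got {ratio_mismatch_range}")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[Box, Box]] = []
    attempts = 0
    while len(pairs) < n:
        if attempts >= max_retries:
            raise GenerationError(
                f"sample_box_pairs: produced {len(pairs)}/{n} pairs after "
                f"{attempts} draws; requested IoU range {iou_range} with ratio "
                f"quotient range {ratio_mismatch_range} appears infeasible")
        attempts += 1
        a = _random_box(rng)
        if hi >= 1.0 and lo >= 1.0:
            pairs.append((a, a))
            continue
        # jitter second box around the first; tight IoU ranges rely on rejection
        dx, dy = rng.normal(0.0, 0.35 * max(a.width, a.height), size=2)
        scale = np.exp(rng.uniform(np.log(0.6), np.log(1.6)))
        ratio_mult = np.exp(rng.uniform(np.log(qlo), np.log(qhi)))
        w = a.width * scale * np.sqrt(ratio_mult)
        h = a.height * scale / np.sqrt(ratio_mult)
        cx = 0.5 * (a.x1 + a.x2) + dx
        cy = 0.5 * (a.y1 + a.y2) + dy
        b = Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        measured = iou(a, b)
        if not (lo <= measured <= hi):
            continue
        ra = a.width / a.height
        rb = b.width / b.height
        if not (qlo - 1e-12 <= ra / rb <= qhi + 1e-12):
            continue
        pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# Feature maps
# ---------------------------------------------------------------------------

def gen_feature_map(B: int, C: int, H: int, W: int,
                    distribution: str = "normal",
                    seed: int | None = 0,
                    constant: float = 0.0) -> np.ndarray:
    """Seeded (B, C, H, W) array: standard normal, uniform[0,1] or constant."""
    if min(B, C, H, W) < 1:
        raise ValueError("all dimensions must be positive")
    rng = np.random.default_rng(seed)
    shape = (B, C, H, W)
    if distribution == "normal":
        return rng.standard_normal(shape)
    if distribution == "uniform":
        return rng.uniform(0.0, 1.0, size=shape)
    if distribution == "constant":
        return np.full(shape, float(constant))
    raise ValueError(f"unknown distribution {distribution!r}")


# ---------------------------------------------------------------------------
# CT-slice-like nodule scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneParams:
    """Knobs of the nodule-scene generator.

    Radii are in pixels (semi-major axis range); ``ellipticity_range``
    bounds the minor/major axis quotient; ``contrast`` is the minimum
    brightness the nodule interior adds above the local background mean;
    ``noise_sd`` the background Gaussian noise level before smoothing.
    """

    height: int = 320
    width: int = 320
    n_nodules: int = 3
    radius_range: tuple[float, float] = (4.0, 16.0)
    ellipticity_range: tuple[float, float] = (0.5, 1.0)
    contrast: float = 0.4
    noise_sd: float = 0.08
    background_level: float = 0.25
    edge_blur: float = 1.0
    max_overlap: float = 0.0
    seed: int | None = 0
    max_attempts: int = 2_000


@dataclass
class NoduleScene:
    """One rendered slice with its tight ground-truth boxes."""

    image: np.ndarray
    gt_boxes: list[Box]
    params: SceneParams = field(default_factory=SceneParams)


def _render_ellipse(h: int, w: int, cx: float, cy: float,
                    a: float, b: float, theta: float) -> np.ndarray:
    """Anti-aliased filled ellipse via 2x2 supersampled membership."""
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w))
    ct, st = np.cos(theta), np.sin(theta)
    for oy in (-0.25, 0.25):
        for ox in (-0.25, 0.25):
            dx = xx + ox - cx
            dy = yy + oy - cy
            u = (dx * ct + dy * st) / a
            v = (-dx * st + dy * ct) / b
            mask += (u * u + v * v <= 1.0)
    return mask / 4.0


def _ellipse_extent(a: float, b: float, theta: float) -> tuple[float, float]:
    """Half-extents of the tight axis-aligned box of a rotated ellipse."""
    ct, st = np.cos(theta), np.sin(theta)
    ex = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    return ex, ey


def gen_nodule_scene(params: SceneParams | None = None) -> NoduleScene:
    """Render a noisy slice with bright elliptical nodules and tight boxes.

    Background is smoothed, clipped Gaussian noise around
    ``background_level``; each nodule is an anti-aliased rotated ellipse
    of brightness ``background_level + contrast + margin`` with a blurred
    rim.  Nodules are placed by rejection so that their boxes overlap at
    most ``max_overlap`` (IoU); exhausting ``max_attempts`` raises
    :class:`GenerationError`.
    """
    p = params or SceneParams()
    if p.radius_range[0] < 2.0:
        raise ValueError("nodule radii must be >= 2 px")
    rng = np.random.default_rng(p.seed)
    h, w = p.height, p.width
    image = p.background_level + p.noise_sd * rng.standard_normal((h, w))
    image = gaussian_filter(image, sigma=1.0)

    boxes: list[Box] = []
    blobs = np.zeros((h, w))
    attempts = 0
    while len(boxes) < p.n_nodules:
        if attempts >= p.max_attempts:
            raise GenerationError(
                f"gen_nodule_scene: placed {len(boxes)}/{p.n_nodules} nodules "
                f"in {attempts} attempts")
        attempts += 1
        a = rng.uniform(*p.radius_range)
        b = a * rng.uniform(*p.ellipticity_range)
        theta = rng.uniform(0.0, np.pi)
        ex, ey = _ellipse_extent(a, b, theta)
        margin = p.edge_blur * 2.0
        if 2 * ex + 2 * margin >= w or 2 * ey + 2 * margin >= h:
            continue
        cx = rng.uniform(ex + margin, w - 1 - ex - margin)
        cy = rng.uniform(ey + margin, h - 1 - ey - margin)
        cand = Box(cx - ex, cy - ey, cx + ex, cy + ey)
        if any(iou(cand, bx) > p.max_overlap for bx in boxes):
            continue
        blobs = np.maximum(blobs, _render_ellipse(h, w, cx, cy, a, b, theta))
        boxes.append(cand)

    if p.edge_blur > 0:
        blobs = gaussian_filter(blobs, sigma=p.edge_blur)
    # extra headroom over the configured contrast so the blurred rim
    # cannot pull the interior mean below the contract
    image = image + (p.contrast + 0.15) * blobs
    image = np.clip(image, 0.0, 1.0)
    return NoduleScene(image=image, gt_boxes=boxes, params=p)


# ---------------------------------------------------------------------------
# Corrupted predictions
# ---------------------------------------------------------------------------

def corrupt_gt_to_predictions(gt_boxes: list[Box],
                              jitter_sd: float = 1.0,
                              fp_rate: float = 0.0,
                              fn_rate: float = 0.0,
                              conf_model: str = "jitter_decay",
                              seed: int | None = 0,
                              image_id: str = "img",
                              image_size: tuple[float, float] = (320.0, 320.0),
                              ) -> list[Detection]:
    """Turn a ground-truth label set into plausible detector output.

    Each surviving box (dropped with probability ``fn_rate``) is jittered
    in center and size by Gaussian noise of ``jitter_sd`` pixels, with
    confidence decreasing in the realised jitter magnitude
    (``conf_model='jitter_decay'``) or uniform in [0.5, 1]
    (``'uniform'``).  False positives are added as ``fp_rate`` extra
    random boxes per ground truth, drawn with the same size distribution.
    """
    if not (0.0 <= fp_rate and 0.0 <= fn_rate <= 1.0):
        raise ValueError("fp_rate must be >= 0 and fn_rate in [0, 1]")
    rng = np.random.default_rng(seed)
    W, H = image_size
    dets: list[Detection] = []
    sizes: list[tuple[float, float]] = []
    for b in gt_boxes:
        sizes.append((b.width, b.height))
        if rng.uniform() < fn_rate:
            continue
        dx, dy, dw, dh = rng.normal(0.0, jitter_sd, size=4)
        w = max(b.width + dw, 1.0)
        h = max(b.height + dh, 1.0)
        cx = 0.5 * (b.x1 + b.x2) + dx
        cy = 0.5 * (b.y1 + b.y2) + dy
        jb = Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        if conf_model == "jitter_decay":
            mag = float(np.sqrt(dx * dx + dy * dy + dw * dw + dh * dh))
            conf = float(np.clip(np.exp(-0.2 * mag), 0.05, 1.0))
        elif conf_model == "uniform":
            conf = float(rng.uniform(0.5, 1.0))
        else:
            raise ValueError(f"unknown conf_model {conf_model!r}")
        dets.append(Detection(image_id=image_id, box=jb, confidence=conf))

    n_fp = rng.binomial(max(len(gt_boxes), 1), min(fp_rate, 1.0)) if fp_rate <= 1.0 \
        else int(round(fp_rate * max(len(gt_boxes), 1)))
    for _ in range(n_fp):
        if sizes:
            w, h = sizes[rng.integers(len(sizes))]
        else:
            w = h = rng.uniform(8.0, 32.0)
        cx = rng.uniform(w / 2, W - w / 2)
        cy = rng.uniform(h / 2, H - h / 2)
        dets.append(Detection(
            image_id=image_id,
            box=Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
            confidence=float(rng.uniform(0.05, 0.6))))
    return dets
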