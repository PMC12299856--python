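"""Penalised-IoU scores and losses for bounding-box regression.

The headline score is the explicit aspect-ratio-penalty IoU (EAPIoU):

    EAPIoU = IoU - rho^2/c^2 - lambda * v - lambda * (w/h - wgt/hgt)^2

where ``rho^2`` is the squared center distance, ``c^2`` the squared
diagonal of the smallest enclosing box, ``v`` the angular aspect term
``(4/pi^2)(arctan(wgt/hgt) - arctan(w/h))^2`` and the last addend a
squared difference of raw width/height ratios.  The coefficient
``lambda`` in [0, 1] weights both aspect penalties; 0.1 is the
recommended default.  The training loss is ``L = 1 - score``.

The module also provides the IoU / GIoU / DIoU / CIoU baselines the new
score is compared against, exact analytic gradients in two box
parameterizations (verified against central finite differences in the
test-suite), and vectorized batch entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .boxgeom import EPS, Box, pair_geometry

__all__ = [
    "LossConfig",
    "LossValue",
    "aspect_v",
    "aspect_penalty",
    "eapiou_score",
    "baseline_score",
    "score",
    "loss_and_grad",
    "batch_scores",
    "params_to_box",
    "box_to_params",
]

Variant = Literal["eapiou", "ciou", "diou", "giou", "iou"]
Parameterization = Literal["corner", "center_log"]

_VARIANTS = ("eapiou", "ciou", "diou", "giou", "iou")


@dataclass(frozen=True)
class LossConfig:
    """Configuration of a penalised-IoU score.

    ``lambda_`` weights both aspect penalties of the EAPIoU score and must
    lie in [0, 1].  ``ciou_alpha_mode`` selects how the CIoU baseline
    weights its angular term: ``"original_alpha"`` uses the adaptive
    trade-off ``alpha = v / ((1 - IoU) + v)`` of the original CIoU;
    ``"paper_lambda"`` uses the plain constant ``lambda_`` instead.
    """

    variant: Variant = "eapiou"
    lambda_: float = 0.1
    eps: float = EPS
    ciou_alpha_mode: Literal["original_alpha", "paper_lambda"] = "original_alpha"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {_VARIANTS}")
        if not (0.0 <= self.lambda_ <= 1.0):
            raise ValueError(f"lambda_ must lie in [0, 1], got {self.lambda_}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.ciou_alpha_mode not in ("original_alpha", "paper_lambda"):
            raise ValueError(f"unknown ciou_alpha_mode {self.ciou_alpha_mode!r}")


@dataclass(frozen=True)
class LossValue:
    """A penalised-IoU score plus its decomposition.

    ``terms`` holds the raw (unweighted) addends: ``iou``, the normalized
    distance penalty ``distance_term``, the angular aspect term ``v_term``
    and the squared-ratio penalty ``aspect_term``; the applied weights are
    in ``weights`` so that ``score = iou - sum(weights[k] * terms[k])``
    over the penalty terms.
    """

    score: float
    loss: float
    terms: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)


def aspect_v(pred: Box, gt: Box, eps: float = EPS) -> float:
    """Angular aspect-ratio term ``v`` of CIoU, in [0, 1]."""
    r1 = pred.width / max(pred.height, eps)
    r2 = gt.width / max(gt.height, eps)
    d = np.arctan(r2) - np.arctan(r1)
    return float((4.0 / np.pi ** 2) * d * d)


def aspect_penalty(pred: Box, gt: Box, eps: float = EPS) -> float:
    """Squared width/height-ratio difference ``(w1/h1 - w2/h2)^2``."""
    r1 = pred.width / max(pred.height, eps)
    r2 = gt.width / max(gt.height, eps)
    return float((r1 - r2) ** 2)


def eapiou_score(pred: Box, gt: Box, cfg: LossConfig | None = None) -> LossValue:
    """EAPIoU score, loss ``1 - score`` and the four raw terms."""
    cfg = cfg or LossConfig()
    if cfg.variant != "eapiou":
        raise ValueError(f"eapiou_score called with variant {cfg.variant!r}")
    return score(pred, gt, cfg)


def baseline_score(pred: Box, gt: Box, cfg: LossConfig) -> LossValue:
    """IoU / GIoU / DIoU / CIoU baseline score under ``cfg``."""
    if cfg.variant not in ("iou", "giou", "diou", "ciou"):
        raise ValueError(f"baseline_score called with variant {cfg.variant!r}")
    return score(pred, gt, cfg)


def score(pred: Box, gt: Box, cfg: LossConfig | None = None) -> LossValue:
    """Penalised-IoU score of any supported variant."""
    cfg = cfg or LossConfig()
    g = pair_geometry(pred, gt, cfg.eps)
    terms = {"iou": g.iou, "distance_term": 0.0, "v_term": 0.0, "aspect_term": 0.0}
    weights = {"distance_term": 0.0, "v_term": 0.0, "aspect_term": 0.0}

    if cfg.variant == "iou":
        s = g.iou
    elif cfg.variant == "giou":
        # enclosing-box gap (|C| - |U|) / |C|, stored in the distance slot
        cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
        ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
        c_area = cw * ch
        iw = min(pred.x2, gt.x2) - max(pred.x1, gt.x1)
        ih = min(pred.y2, gt.y2) - max(pred.y1, gt.y1)
        inter = max(iw, 0.0) * max(ih, 0.0)
        union = pred.width * pred.height + gt.width * gt.height - inter
        gap = (c_area - union) / max(c_area, cfg.eps)
        terms["distance_term"] = gap
        weights["distance_term"] = 1.0
        s = g.iou - gap
    else:
        dist = g.rho_sq / max(g.c_sq, cfg.eps)
        terms["distance_term"] = dist
        weights["distance_term"] = 1.0
        s = g.iou - dist
        if cfg.variant == "ciou":
            terms["v_term"] = g.v
            if cfg.ciou_alpha_mode == "original_alpha":
                alpha = g.v / ((1.0 - g.iou) + g.v) if g.v > 0 else 0.0
            else:
                alpha = cfg.lambda_
            weights["v_term"] = alpha
            s -= alpha * g.v
        elif cfg.variant == "eapiou":
            terms["v_term"] = g.v
            terms["aspect_term"] = g.aspect_sq
            weights["v_term"] = cfg.lambda_
            weights["aspect_term"] = cfg.lambda_
            s -= cfg.lambda_ * g.v + cfg.lambda_ * g.aspect_sq
    return LossValue(score=float(s), loss=float(1.0 - s), terms=terms, weights=weights)


# ---------------------------------------------------------------------------
# Analytic gradients
# ---------------------------------------------------------------------------

def params_to_box(params: np.ndarray, parameterization: Parameterization) -> Box:
    """Decode a 4-vector into a Box under the given parameterization."""
    p = np.asarray(params, dtype=float)
    if parameterization == "corner":
        return Box(p[0], p[1], p[2], p[3])
    if parameterization == "center_log":
        # overflow yields inf corners, rejected by Box validation
        with np.errstate(over="ignore"):
            cx, cy, w, h = p[0], p[1], np.exp(p[2]), np.exp(p[3])
        return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
    raise ValueError(f"unknown parameterization {parameterization!r}")


def box_to_params(b: Box, parameterization: Parameterization) -> np.ndarray:
    if parameterization == "corner":
        return b.as_array()
    if parameterization == "center_log":
        if b.width <= 0 or b.height <= 0:
            raise ValueError("center_log parameterization requires a non-degenerate box")
        cx = 0.5 * (b.x1 + b.x2)
        cy = 0.5 * (b.y1 + b.y2)
        return np.array([cx, cy, np.log(b.width), np.log(b.height)], dtype=float)
    raise ValueError(f"unknown parameterization {parameterization!r}")


def _corner_term_grads(pred: Box, gt: Box, eps: float) -> dict:
    """Values and corner-space gradients of every loss ingredient.

    Gradients are with respect to the predicted corners (x1, y1, x2, y2);
    the ground truth is held fixed.  Subgradients at the (measure-zero)
    min/max ties follow the active-side convention noted inline.
    """
    x1, y1, x2, y2 = pred.x1, pred.y1, pred.x2, pred.y2
    X1, Y1, X2, Y2 = gt.x1, gt.y1, gt.x2, gt.y2
    w1, h1 = pred.width, pred.height
    w2, h2 = gt.width, gt.height

    a1 = w1 * h1
    a2 = w2 * h2
    dA = np.array([-h1, -w1, h1, w1])

    iw = min(x2, X2) - max(x1, X1)
    ih = min(y2, Y2) - max(y1, Y1)
    if iw > 0 and ih > 0:
        inter = iw * ih
        # derivative of the intersection extent w.r.t. pred corners;
        # at a tie the pred corner is taken as the active one
        diw = np.array([-1.0 if x1 >= X1 else 0.0, 0.0,
                        1.0 if x2 <= X2 else 0.0, 0.0])
        dih = np.array([0.0, -1.0 if y1 >= Y1 else 0.0,
                        0.0, 1.0 if y2 <= Y2 else 0.0])
        dI = ih * diw + iw * dih
    else:
        inter = 0.0
        dI = np.zeros(4)
    union = a1 + a2 - inter
    dU = dA - dI
    if union > 0:
        iou_val = inter / union
        dIoU = (dI * union - inter * dU) / (union * union)
    else:
        iou_val = 0.0
        dIoU = np.zeros(4)

    cx, cy = 0.5 * (x1 + x2), 0.5 * (y1 + y2)
    CX, CY = 0.5 * (X1 + X2), 0.5 * (Y1 + Y2)
    rho_sq = (cx - CX) ** 2 + (cy - CY) ** 2
    dRho = np.array([cx - CX, cy - CY, cx - CX, cy - CY])

    cw = max(x2, X2) - min(x1, X1)
    ch = max(y2, Y2) - min(y1, Y1)
    c_sq = cw * cw + ch * ch
    dcw = np.array([-1.0 if x1 <= X1 else 0.0, 0.0,
                    1.0 if x2 >= X2 else 0.0, 0.0])
    dch = np.array([0.0, -1.0 if y1 <= Y1 else 0.0,
                    0.0, 1.0 if y2 >= Y2 else 0.0])
    dCsq = 2.0 * cw * dcw + 2.0 * ch * dch

    cg = max(c_sq, eps)
    dist = rho_sq / cg
    dDist = (dRho * cg - rho_sq * dCsq) / (cg * cg)

    hg = max(h1, eps)
    r1 = w1 / hg
    r2 = w2 / max(h2, eps)
    dr1 = np.array([-1.0 / hg, w1 / (hg * hg), 1.0 / hg, -w1 / (hg * hg)])

    datan = np.arctan(r2) - np.arctan(r1)
    v = (4.0 / np.pi ** 2) * datan * datan
    dv_dr1 = -(8.0 / np.pi ** 2) * datan / (1.0 + r1 * r1)
    dV = dv_dr1 * dr1

    aspect = (r1 - r2) ** 2
    dAspect = 2.0 * (r1 - r2) * dr1

    c_area = cw * ch
    dCarea = ch * dcw + cw * dch
    gap_den = max(c_area, eps)
    gap = (c_area - union) / gap_den
    dGap = ((dCarea - dU) * gap_den - (c_area - union) * dCarea) / (gap_den * gap_den)

    return {
        "iou": (iou_val, dIoU),
        "distance_term": (dist, dDist),
        "v_term": (v, dV),
        "aspect_term": (aspect, dAspect),
        "giou_gap": (gap, dGap),
    }


def loss_and_grad(pred_params: np.ndarray, gt: Box, cfg: LossConfig | None = None,
                  parameterization: Parameterization = "corner",
                  ) -> tuple[float, np.ndarray]:
    """Loss ``1 - score`` and its exact analytic gradient.

    ``pred_params`` encodes the predicted box: corners ``(x1, y1, x2, y2)``
    or ``(cx, cy, log w, log h)``.  At the exact optimum (pred == gt) the
    IoU term is non-smooth; its subgradient is taken as 0, making the
    optimum a stationary point.  Raises ``FloatingPointError`` naming the
    first term whose gradient is non-finite.
    """
    cfg = cfg or LossConfig()
    pred = params_to_box(pred_params, parameterization)
    if pred.is_degenerate:
        raise ValueError("predicted box is degenerate; gradients undefined")

    if pred == gt:
        val = score(pred, gt, cfg)
        return float(val.loss), np.zeros(4)

    t = _corner_term_grads(pred, gt, cfg.eps)
    iou_val, dIoU = t["iou"]

    s = iou_val
    dS = dIoU.copy()
    if cfg.variant == "giou":
        gap, dGap = t["giou_gap"]
        s -= gap
        dS -= dGap
    elif cfg.variant in ("diou", "ciou", "eapiou"):
        dist, dDist = t["distance_term"]
        s -= dist
        dS -= dDist
        if cfg.variant == "ciou":
            v, dV = t["v_term"]
            if cfg.ciou_alpha_mode == "original_alpha":
                den = (1.0 - iou_val) + v
                if den > 0:
                    alpha = v / den
                    # full derivative of alpha*v, alpha = v / ((1-IoU)+v)
                    dAlpha = (dV * (1.0 - iou_val) + v * dIoU) / (den * den)
                    s -= alpha * v
                    dS -= alpha * dV + v * dAlpha
            else:
                s -= cfg.lambda_ * v
                dS -= cfg.lambda_ * dV
        elif cfg.variant == "eapiou":
            v, dV = t["v_term"]
            aspect, dAspect = t["aspect_term"]
            s -= cfg.lambda_ * (v + aspect)
            dS -= cfg.lambda_ * (dV + dAspect)

    grad_corner = -dS  # loss = 1 - score

    if parameterization == "corner":
        grad = grad_corner
    else:
        w, h = pred.width, pred.height
        # rows of dp/dq for q = (cx, cy, log w, log h)
        jac = np.array([
            [1.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, 0.0, 1.0],
            [-w / 2, 0.0, w / 2, 0.0],
            [0.0, -h / 2, 0.0, h / 2],
        ])
        grad = jac @ grad_corner

    if not np.all(np.isfinite(grad)):
        for name in ("iou", "distance_term", "v_term", "aspect_term", "giou_gap"):
            if name in t and not np.all(np.isfinite(t[name][1])):
                raise FloatingPointError(f"non-finite gradient in term {name!r}")
        raise FloatingPointError("non-finite gradient after parameterization change")
    return float(1.0 - s), grad


# ---------------------------------------------------------------------------
# Vectorized batch entry point
# ---------------------------------------------------------------------------

def batch_scores(pred: np.ndarray, gt: np.ndarray, cfg: LossConfig | None = None
                 ) -> dict[str, np.ndarray]:
    """Vectorized scores/losses for N predicted vs N ground-truth boxes.

    ``pred`` and ``gt`` are (N, 4) corner arrays.  Returns ``scores``,
    ``losses`` and ``iou`` arrays of length N.
    """
    cfg = cfg or LossConfig()
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    gt = np.atleast_2d(np.asarray(gt, dtype=float))
    if pred.shape != gt.shape or pred.shape[1] != 4:
        raise ValueError(f"expected matching (N, 4) arrays, got {pred.shape} and {gt.shape}")
    eps, lam = cfg.eps, cfg.lambda_

    w1 = pred[:, 2] - pred[:, 0]
    h1 = pred[:, 3] - pred[:, 1]
    w2 = gt[:, 2] - gt[:, 0]
    h2 = gt[:, 3] - gt[:, 1]
    iw = np.minimum(pred[:, 2], gt[:, 2]) - np.maximum(pred[:, 0], gt[:, 0])
    ih = np.minimum(pred[:, 3], gt[:, 3]) - np.maximum(pred[:, 1], gt[:, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    union = w1 * h1 + w2 * h2 - inter
    iou = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)

    if cfg.variant == "iou":
        s = iou
    elif cfg.variant == "giou":
        cw = np.maximum(pred[:, 2], gt[:, 2]) - np.minimum(pred[:, 0], gt[:, 0])
        ch = np.maximum(pred[:, 3], gt[:, 3]) - np.minimum(pred[:, 1], gt[:, 1])
        c_area = cw * ch
        s = iou - (c_area - union) / np.maximum(c_area, eps)
    else:
        cx1 = 0.5 * (pred[:, 0] + pred[:, 2])
        cy1 = 0.5 * (pred[:, 1] + pred[:, 3])
        cx2 = 0.5 * (gt[:, 0] + gt[:, 2])
        cy2 = 0.5 * (gt[:, 1] + gt[:, 3])
        rho_sq = (cx1 - cx2) ** 2 + (cy1 - cy2) ** 2
        cw = np.maximum(pred[:, 2], gt[:, 2]) - np.minimum(pred[:, 0], gt[:, 0])
        ch = np.maximum(pred[:, 3], gt[:, 3]) - np.minimum(pred[:, 1], gt[:, 1])
        c_sq = cw * cw + ch * ch
        s = iou - rho_sq / np.maximum(c_sq, eps)
        if cfg.variant in ("ciou", "eapiou"):
            r1 = w1 / np.maximum(h1, eps)
            r2 = w2 / np.maximum(h2, eps)
            d = np.arctan(r2) - np.arctan(r1)
            v = (4.0 / np.pi ** 2) * d * d
            if cfg.variant == "ciou":
                if cfg.ciou_alpha_mode == "original_alpha":
                    alpha = np.where(v > 0, v / ((1.0 - iou) + v), 0.0)
                else:
                    alpha = lam
                s = s - alpha * v
            else:
                s = s - lam * v - lam * (r1 - r2) ** 2
    return {"scores": s, "losses": 1.0 - s, "iou": iou}
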