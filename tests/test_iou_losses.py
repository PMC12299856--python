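"""Penalised-IoU scores: frozen fixtures, invariants, analytic gradients.

Fixture values were computed by an independent term-by-term script using
only the math module and the documented epsilon convention (heights and
c^2 floored at 1e-7 before division); that arithmetic is reproduced
inline as ``_oracle_terms`` so the check stays independent of the numpy
implementation path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulekit.boxgeom import Box
from nodulekit.iou_losses import (LossConfig, aspect_penalty, aspect_v,
                                  baseline_score, batch_scores, box_to_params,
                                  eapiou_score, loss_and_grad, params_to_box,
                                  score)
from .conftest import random_box, random_box_pairs

EPS = 1e-7


def _oracle_terms(pred, gt, lam):
    """Independent term-by-term arithmetic (math module only)."""
    x1, y1, x2, y2 = pred
    X1, Y1, X2, Y2 = gt
    w1, h1, w2, h2 = x2 - x1, y2 - y1, X2 - X1, Y2 - Y1
    iw = min(x2, X2) - max(x1, X1)
    ih = min(y2, Y2) - max(y1, Y1)
    inter = max(iw, 0) * max(ih, 0)
    union = w1 * h1 + w2 * h2 - inter
    iou = inter / union if union > 0 else 0.0
    rho2 = ((x1 + x2) / 2 - (X1 + X2) / 2) ** 2 + ((y1 + y2) / 2 - (Y1 + Y2) / 2) ** 2
    cw = max(x2, X2) - min(x1, X1)
    ch = max(y2, Y2) - min(y1, Y1)
    c2 = max(cw * cw + ch * ch, EPS)
    r1, r2 = w1 / max(h1, EPS), w2 / max(h2, EPS)
    v = (4 / math.pi ** 2) * (math.atan(r2) - math.atan(r1)) ** 2
    return iou - rho2 / c2 - lam * v - lam * (r1 - r2) ** 2


class TestAspectTerms:
    def test_aspect_v_zero_for_equal_ratios(self):
        assert aspect_v(Box(0, 0, 2, 2), Box(5, 5, 9, 9)) == pytest.approx(0.0, abs=1e-12)

    def test_aspect_v_known_value_ratio_1_vs_2(self):
        # independent scripted arctan evaluation under the eps convention
        got = aspect_v(Box(0, 0, 1, 1), Box(0, 0, 2, 1))
        assert got == pytest.approx(0.04195646149429056, abs=1e-12)

    def test_aspect_v_saturates_toward_one_in_crossed_limit(self):
        # w/h -> inf against wgt/hgt -> 0: arctan gap approaches pi/2
        v = aspect_v(Box(0, 0, 1e6, 1), Box(0, 0, 1, 1e6))
        assert 0.99 < v <= 1.0

    def test_aspect_penalty_values_and_symmetry(self):
        sq = Box(0, 0, 2, 2)
        assert aspect_penalty(sq, Box(1, 1, 3, 3)) == pytest.approx(0.0, abs=1e-12)
        wide, tall = Box(0, 0, 4, 1), Box(0, 0, 1, 4)
        assert aspect_penalty(wide, tall) == pytest.approx(14.0625, rel=1e-6)
        assert aspect_penalty(wide, tall) == aspect_penalty(tall, wide)

    def test_aspect_penalty_convex_in_r1(self):
        """Second differences of (r1 - r2)^2 are non-negative on any grid."""
        h = 1.0
        r2_box = Box(0, 0, 1.7, h)
        grid = np.linspace(0.1, 8.0, 60)
        vals = [aspect_penalty(Box(0, 0, r, h), r2_box) for r in grid]
        second = np.diff(vals, 2)
        assert np.all(second >= -1e-9)


class TestEapiouScore:
    def test_identity_scores_one_for_any_lambda(self):
        b = Box(3, 4, 10, 9)
        for lam in (0.0, 0.1, 0.5, 1.0):
            val = eapiou_score(b, b, LossConfig(lambda_=lam))
            assert val.score == pytest.approx(1.0, abs=1e-12)
            assert val.loss == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("pred, gt, expected", [
        # concentric, same ratio: only IoU survives
        ((-1, -1, 1, 1), (-2, -2, 2, 2), 0.25),
        # crossed 4:1 vs 1:4 at lambda=0.1 (independent term-by-term script)
        ((0, 0, 4, 1), (0, 0, 1, 4), -1.451363744480019),
    ])
    def test_worked_fixtures(self, pred, gt, expected):
        got = eapiou_score(Box(*pred), Box(*gt), LossConfig(lambda_=0.1))
        assert got.score == pytest.approx(expected, abs=1e-9)
        assert got.score == pytest.approx(_oracle_terms(pred, gt, 0.1), abs=1e-12)

    def test_terms_reconstruct_score(self):
        for a, b in random_box_pairs(seed=3, n=30):
            val = eapiou_score(a, b, LossConfig(lambda_=0.37))
            rebuilt = val.terms["iou"] - sum(
                val.weights[k] * val.terms[k]
                for k in ("distance_term", "v_term", "aspect_term"))
            assert val.score == pytest.approx(rebuilt, abs=1e-12)
            assert val.loss == pytest.approx(1.0 - val.score, abs=1e-12)

    def test_score_never_exceeds_iou(self):
        for lam in (0.0, 0.1, 1.0):
            for a, b in random_box_pairs(seed=5, n=30):
                val = eapiou_score(a, b, LossConfig(lambda_=lam))
                assert val.score <= val.terms["iou"] + 1e-12

    def test_swap_symmetry_exact(self):
        for a, b in random_box_pairs(seed=9, n=30):
            assert eapiou_score(a, b).score == eapiou_score(b, a).score

    def test_perturbing_any_corner_strictly_decreases_score(self):
        gt = Box(0, 0, 6, 4)
        for i in range(4):
            for delta in (+0.3, -0.3):
                c = gt.as_array()
                c[i] += delta
                if c[2] <= c[0] or c[3] <= c[1]:
                    continue
                assert eapiou_score(Box(*c), gt).score < 1.0 - 1e-6

    def test_monotone_in_aspect_mismatch_other_terms_fixed(self):
        """Substituting a growing aspect gap into the same base terms
        strictly lowers the score (the penalty is lambda * gap^2)."""
        base = eapiou_score(Box(0, 0, 2, 2), Box(1, 1, 3, 3), LossConfig(lambda_=0.1))
        fixed = (base.terms["iou"] - base.weights["distance_term"] * base.terms["distance_term"]
                 - base.weights["v_term"] * base.terms["v_term"])
        gaps = [0.0, 0.5, 1.0, 2.0, 4.0]
        scores = [fixed - 0.1 * g ** 2 for g in gaps]
        assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]))

    def test_translation_scale_invariance(self):
        for a, b in random_box_pairs(seed=13, n=20):
            v0 = eapiou_score(a, b).score
            v1 = eapiou_score(a.translate(5, -3).scale(2.5),
                              b.translate(5, -3).scale(2.5)).score
            assert v1 == pytest.approx(v0, rel=1e-9, abs=1e-9)

    def test_variant_guard(self):
        with pytest.raises(ValueError):
            eapiou_score(Box(0, 0, 1, 1), Box(0, 0, 1, 1), LossConfig(variant="diou"))


class TestBaselines:
    def test_all_variants_score_one_at_identity(self):
        b = Box(1, 2, 5, 7)
        for var in ("iou", "giou", "diou", "ciou"):
            assert baseline_score(b, b, LossConfig(variant=var)).score == pytest.approx(1.0, abs=1e-9)

    def test_giou_negative_for_disjoint(self):
        a, b = Box(0, 0, 1, 1), Box(5, 5, 6, 6)
        assert baseline_score(a, b, LossConfig(variant="iou")).score == 0.0
        assert baseline_score(a, b, LossConfig(variant="giou")).score < 0.0

    def test_diou_offset_value(self):
        got = baseline_score(Box(0, 0, 2, 2), Box(1, 1, 3, 3), LossConfig(variant="diou"))
        # 1/7 - 2/18 under the eps convention, from the independent script
        assert got.score == pytest.approx(0.031746031746031744, abs=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(variant="wiou")
        with pytest.raises(ValueError):
            baseline_score(Box(0, 0, 1, 1), Box(0, 0, 1, 1), LossConfig(variant="eapiou"))

    def test_lambda_validation(self):
        for bad in (-0.1, 1.5, np.nan):
            with pytest.raises(ValueError):
                LossConfig(lambda_=bad)

    def test_lambda_zero_equals_diou(self):
        for a, b in random_box_pairs(seed=17, n=30):
            e = score(a, b, LossConfig(variant="eapiou", lambda_=0.0)).score
            d = score(a, b, LossConfig(variant="diou")).score
            assert e == pytest.approx(d, abs=1e-12)

    def test_eapiou_reduces_to_plain_iou_when_all_penalties_vanish(self):
        # lambda 0 + identical centers and aspect ratios: only IoU remains
        a, b = Box(-1, -1, 1, 1), Box(-2, -2, 2, 2)
        e = score(a, b, LossConfig(variant="eapiou", lambda_=0.0)).score
        assert e == pytest.approx(0.25, abs=1e-12)

    def test_ciou_alpha_modes_differ(self):
        a, b = Box(0, 0, 4, 1), Box(1, 1, 3, 4)
        orig = score(a, b, LossConfig(variant="ciou", ciou_alpha_mode="original_alpha"))
        lam = score(a, b, LossConfig(variant="ciou", ciou_alpha_mode="paper_lambda", lambda_=0.1))
        assert orig.score != pytest.approx(lam.score, abs=1e-6)


def _fd_grad(params, gt, cfg, parameterization):
    fd = np.zeros(4)
    for i in range(4):
        h = 1e-6 * max(1.0, abs(params[i]))
        pp, pm = params.copy(), params.copy()
        pp[i] += h
        pm[i] -= h
        fd[i] = (loss_and_grad(pp, gt, cfg, parameterization)[0]
                 - loss_and_grad(pm, gt, cfg, parameterization)[0]) / (2 * h)
    return fd


class TestGradients:
    def test_zero_gradient_at_optimum(self):
        b = Box(0, 0, 4, 3)
        loss, grad = loss_and_grad(b.as_array(), b, LossConfig(), "corner")
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert np.all(grad == 0.0)

    @pytest.mark.parametrize("parameterization", ["corner", "center_log"])
    @pytest.mark.parametrize("variant", ["eapiou", "ciou", "diou", "giou", "iou"])
    def test_matches_finite_differences(self, parameterization, variant):
        cfg = LossConfig(variant=variant)
        for a, b in random_box_pairs(seed=21, n=25):
            p = box_to_params(a, parameterization)
            _, grad = loss_and_grad(p, b, cfg, parameterization)
            fd = _fd_grad(p, b, cfg, parameterization)
            assert np.linalg.norm(grad - fd) <= 1e-5 * max(np.linalg.norm(fd), 1e-8)

    def test_degenerate_pred_rejected(self):
        with pytest.raises(ValueError):
            loss_and_grad(np.array([0.0, 0.0, 0.0, 5.0]), Box(0, 0, 1, 1), LossConfig(), "corner")

    def test_saturation_contrast_at_extreme_ratio(self):
        """Against a square target the squared-ratio penalty keeps an O(r)
        gradient while the angular term's vanishes as 1/r^2."""
        gt = Box(0, 0, 1, 1)
        for r in (10.0, 100.0):
            h = 1e-6
            d_asp = (aspect_penalty(Box(0, 0, r + h, 1), gt)
                     - aspect_penalty(Box(0, 0, r - h, 1), gt)) / (2 * h)
            d_v = (aspect_v(Box(0, 0, r + h, 1), gt)
                   - aspect_v(Box(0, 0, r - h, 1), gt)) / (2 * h)
            assert abs(d_asp) / abs(d_v) > 100
        # dv/dr -> 0 while d(r-1)^2/dr grows without bound
        d_v_10 = abs((aspect_v(Box(0, 0, 10 + 1e-6, 1), gt)
                      - aspect_v(Box(0, 0, 10 - 1e-6, 1), gt)) / 2e-6)
        d_v_100 = abs((aspect_v(Box(0, 0, 100 + 1e-6, 1), gt)
                       - aspect_v(Box(0, 0, 100 - 1e-6, 1), gt)) / 2e-6)
        assert d_v_100 < d_v_10

    def test_parameterization_encodings_agree(self):
        b = Box(2, 3, 8, 5)
        for par in ("corner", "center_log"):
            assert params_to_box(box_to_params(b, par), par).as_array() == pytest.approx(
                b.as_array(), abs=1e-12)


class TestBatch:
    def test_batch_matches_scalar(self):
        pairs = random_box_pairs(seed=31, n=40)
        pred = np.array([a.as_array() for a, _ in pairs])
        gt = np.array([b.as_array() for _, b in pairs])
        for var in ("eapiou", "ciou", "diou", "giou", "iou"):
            cfg = LossConfig(variant=var)
            batch = batch_scores(pred, gt, cfg)
            scalar = np.array([score(a, b, cfg).score for a, b in pairs])
            assert batch["scores"] == pytest.approx(scalar, abs=1e-12)
            assert batch["losses"] == pytest.approx(1.0 - scalar, abs=1e-12)

    def test_batch_shape_guard(self):
        with pytest.raises(ValueError):
            batch_scores(np.zeros((3, 4)), np.zeros((2, 4)))


@settings(max_examples=60, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 1.0))
def test_property_score_bounded_by_iou(seed, lam):
    rng = np.random.default_rng(seed)
    a, b = random_box(rng), random_box(rng)
    val = eapiou_score(a, b, LossConfig(lambda_=lam))
    assert val.score <= val.terms["iou"] + 1e-12
    assert 0.0 <= val.terms["v_term"] <= 1.0
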