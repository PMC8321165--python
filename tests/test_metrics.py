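"""Tversky index/loss, volumetric metrics, summaries and ANOVA."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.spatial.distance import cdist

from fibroseg.metrics import (
    TverskyParams,
    anova_dsc,
    assd,
    compute_metrics,
    confusion_counts,
    summarize,
    surface_voxels,
    tversky_index,
    tversky_loss,
)
from fibroseg.volume import MaskVolume


# ---------------------------------------------------------------------------
# Tversky index / loss
# ---------------------------------------------------------------------------

def test_tversky_perfect_overlap_is_one(rng):
    m = (rng.random((6, 6)) < 0.5).astype(int)
    m[0, 0] = 1
    for params in (TverskyParams(0.3, 0.7), TverskyParams(1.0, 0.2)):
        assert tversky_index(m, m, params) == 1.0


def test_tversky_hand_example_2x2():
    # TP=1, FP=1, FN=1 -> 1 / (1 + 0.3 + 0.7) = 0.5
    p = np.array([[1, 1], [0, 0]])
    g = np.array([[0, 1], [0, 1]])
    assert tversky_index(p, g, TverskyParams(0.3, 0.7)) == pytest.approx(0.5)


def test_tversky_half_half_equals_dice(rng):
    for _ in range(200):
        p = (rng.random((5, 5)) < rng.random()).astype(int)
        g = (rng.random((5, 5)) < rng.random()).astype(int)
        tp = int((p & g).sum())
        fp = int((p & ~g).sum())
        fn = int((~p & g).sum())
        dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
        assert tversky_index(p, g, TverskyParams(0.5, 0.5)) == pytest.approx(dice, rel=1e-12)


def test_tversky_symmetry_under_alpha_beta_swap(rng):
    p = (rng.random((7, 7)) < 0.4).astype(int)
    g = (rng.random((7, 7)) < 0.6).astype(int)
    a = tversky_index(p, g, TverskyParams(0.2, 0.8))
    b = tversky_index(g, p, TverskyParams(0.8, 0.2))
    assert a == pytest.approx(b, rel=1e-12)


def test_tversky_monotone_in_errors():
    g = np.zeros((4, 4), int)
    g[:2] = 1
    base = tversky_index(g, g, TverskyParams(0.3, 0.7))
    worse = g.copy()
    worse[3, 3] = 1  # one extra FP
    assert tversky_index(worse, g, TverskyParams(0.3, 0.7)) < base


def test_tversky_both_empty_convention():
    z = np.zeros((3, 3), int)
    assert tversky_index(z, z) == 1.0


def test_tversky_loss_hand_example_three_pixels():
    p0 = np.array([0.8, 0.4, 0.1])
    g0 = np.array([1.0, 1.0, 0.0])
    t = 1.2 / (1.2 + 0.3 * 0.1 + 0.7 * 0.8)
    assert tversky_loss(p0, g0, TverskyParams(0.3, 0.7), smooth=0.0) == pytest.approx(1 - t)


def test_tversky_loss_zero_for_perfect_hard_prediction():
    g0 = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert tversky_loss(g0, g0, smooth=0.0) == pytest.approx(0.0)


def test_tversky_loss_alpha_beta_half_is_one_minus_dice(rng):
    p = (rng.random(20) < 0.5).astype(float)
    g = (rng.random(20) < 0.5).astype(float)
    tp = (p * g).sum()
    fp = (p * (1 - g)).sum()
    fn = ((1 - p) * g).sum()
    dice = 2 * tp / (2 * tp + fp + fn)
    assert tversky_loss(p, g, TverskyParams(0.5, 0.5), smooth=0.0) == pytest.approx(1 - dice)


def test_tversky_loss_is_differentiable_var():
    from fibroseg.nn.autodiff import Var
    p0 = Var(np.array([0.8, 0.4, 0.1]))
    loss = tversky_loss(p0, np.array([1.0, 1.0, 0.0]), smooth=0.0)
    loss.backward()
    assert p0.grad is not None and p0.grad.shape == (3,)
    assert p0.grad[0] < 0  # raising a true-lung probability lowers the loss


# ---------------------------------------------------------------------------
# confusion counts and volumetric metrics
# ---------------------------------------------------------------------------

def _loop_confusion(p, g):
    tp = fp = fn = tn = 0
    for a, b in zip(p.ravel(), g.ravel()):
        if a and b:
            tp += 1
        elif a and not b:
            fp += 1
        elif not a and b:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def test_confusion_counts_match_loop_oracle(rng):
    p = (rng.random((4, 4, 2)) < 0.5).astype(np.uint8)
    g = (rng.random((4, 4, 2)) < 0.5).astype(np.uint8)
    assert confusion_counts(p, g) == _loop_confusion(p, g)


def test_confusion_counts_identity_and_complement(rng):
    g = (rng.random((3, 3, 3)) < 0.5).astype(np.uint8)
    tp, fp, fn, tn = confusion_counts(g, g)
    assert fp == fn == 0
    tp2, fp2, fn2, tn2 = confusion_counts(1 - g, g)
    assert tp2 == tn2 == 0


def test_metrics_identity_case(rng):
    g = (rng.random((6, 6, 4)) < 0.4).astype(np.uint8)
    g[2:4, 2:4, 1:3] = 1
    m = MaskVolume(g, (1, 1, 1))
    rep = compute_metrics(m, m)
    assert rep.sensitivity == rep.ppv == rep.dsc == 100.0
    assert rep.voe == 0.0 and rep.vd == 0.0 and rep.assd == 0.0


def test_vd_sign_convention_oversegmentation_positive():
    g = np.zeros((10, 10, 4), np.uint8)
    g[2:7, 2:6, 1:3] = 1            # |G| = 40
    p = g.copy()
    extra = np.argwhere(g == 0)
    need = int(round(0.27 * g.sum()))
    for i, j, k in extra[:need]:
        p[i, j, k] = 1              # |P| = 1.27 |G|
    rep = compute_metrics(MaskVolume(p, (1, 1, 1)), MaskVolume(g, (1, 1, 1)))
    assert rep.vd == pytest.approx(27.0, abs=0.5)


def _assd_bruteforce(p, g, spacing):
    sp = np.argwhere(surface_voxels(p)) * np.asarray(spacing)
    sg = np.argwhere(surface_voxels(g)) * np.asarray(spacing)
    d = cdist(sp, sg)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sp) + len(sg))


def test_assd_unit_cubes_offset_matches_all_pairs_oracle():
    p = np.zeros((6, 6, 6), np.uint8)
    g = np.zeros((6, 6, 6), np.uint8)
    p[1:3, 1:3, 1:3] = 1
    g[2:4, 1:3, 1:3] = 1  # offset by one voxel along x
    got = assd(p, g, (1.0, 1.0, 1.0))
    assert got == pytest.approx(_assd_bruteforce(p, g, (1, 1, 1)), rel=1e-12)


def test_assd_symmetric_and_zero_on_equal_surfaces(rng):
    a = (rng.random((5, 5, 5)) < 0.5).astype(np.uint8)
    a[2, 2, 2] = 1
    b = (rng.random((5, 5, 5)) < 0.5).astype(np.uint8)
    b[1, 1, 1] = 1
    assert assd(a, b) == pytest.approx(assd(b, a))
    assert assd(a, a) == 0.0


def test_assd_respects_spacing():
    p = np.zeros((4, 4, 4), np.uint8)
    g = np.zeros((4, 4, 4), np.uint8)
    p[1, 1, 1] = 1
    g[2, 1, 1] = 1  # one voxel apart along x
    assert assd(p, g, (3.0, 1.0, 1.0)) == pytest.approx(3.0)


def test_voe_jaccard_and_dice_identity(rng):
    p = (rng.random((6, 6, 3)) < 0.5).astype(np.uint8)
    g = (rng.random((6, 6, 3)) < 0.5).astype(np.uint8)
    p[0, 0, 0] = g[0, 0, 0] = 1
    rep = compute_metrics(MaskVolume(p, (1, 1, 1)), MaskVolume(g, (1, 1, 1)))
    jacc = 1 - rep.voe / 100
    assert rep.dsc / 100 == pytest.approx(2 * jacc / (1 + jacc), rel=1e-12)


def test_empty_truth_flags_undefined_not_raises():
    p = np.zeros((3, 3, 3), np.uint8)
    p[1, 1, 1] = 1
    rep = compute_metrics(MaskVolume(p, (1, 1, 1)), MaskVolume(np.zeros((3, 3, 3), np.uint8), (1, 1, 1)))
    assert np.isnan(rep.sensitivity) and np.isnan(rep.vd)


# ---------------------------------------------------------------------------
# summaries and ANOVA
# ---------------------------------------------------------------------------

def test_summarize_examples():
    s = summarize([1.0, 2.0, 3.0])
    assert (s.mean, s.std) == (2.0, 1.0)
    assert s.ci95 == pytest.approx(1.96 / np.sqrt(3))
    c = summarize([4.0, 4.0, 4.0])
    assert c.std == 0.0 and c.ci95 == 0.0
    one = summarize([7.0])
    assert one.mean == 7.0 and one.std == 0.0
    with pytest.raises(ValueError):
        summarize([])


def _anova_ss_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    allv = np.concatenate([a, b])
    grand = allv.mean()
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    return (ssb / 1) / (ssw / (len(allv) - 2))


def test_anova_matches_ss_oracle_and_t_squared(rng):
    for _ in range(20):
        a = rng.normal(0.9, 0.05, rng.integers(3, 9))
        b = rng.normal(0.88, 0.05, rng.integers(3, 9))
        res = anova_dsc(a, b)
        assert res.F == pytest.approx(_anova_ss_oracle(a, b), rel=1e-10)
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)
        f = sps.f_oneway(a, b)
        assert res.F == pytest.approx(f.statistic, rel=1e-10)


def test_anova_identical_groups():
    res = anova_dsc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.F == 0.0 and res.p_value == 1.0
    assert not res.significant


def test_anova_fcrit_is_f_distribution_quantile():
    res = anova_dsc([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert res.F_crit == pytest.approx(sps.f.ppf(0.95, 1, 4))
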