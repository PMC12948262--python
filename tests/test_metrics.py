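"""Regression/classification metrics vs independent brute-force oracles."""

import numpy as np
import pytest

from dualgraph_dta.training_eval import (
    MetricsReport,
    classification_metrics,
    concordance_index,
    regression_metrics,
    rm_squared,
)


# -- independent oracles (deliberately naive implementations) ---------------

def ci_brute_force(y, y_hat):
    num = den = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            if y[i] > y[j]:
                den += 1
                if y_hat[i] > y_hat[j]:
                    num += 1
                elif y_hat[i] == y_hat[j]:
                    num += 0.5
    return num / den


def rm2_step_by_step(y, p):
    n = len(y)
    my, mp = sum(y) / n, sum(p) / n
    sxy = sum((a - my) * (b - mp) for a, b in zip(y, p))
    sxx = sum((a - my) ** 2 for a in y)
    syy = sum((b - mp) ** 2 for b in p)
    r2 = (sxy / np.sqrt(sxx * syy)) ** 2
    k = sum(a * b for a, b in zip(y, p)) / sum(b * b for b in p)
    ss_res = sum((a - k * b) ** 2 for a, b in zip(y, p))
    r0_2 = 1 - ss_res / sxx
    return r2 * (1 - np.sqrt(abs(r2 - r0_2)))


def auc_pairwise(y, p):
    pos = [p[i] for i in range(len(y)) if y[i] == 1]
    neg = [p[i] for i in range(len(y)) if y[i] == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def confusion_counts(y, pred):
    tp = sum(1 for a, b in zip(y, pred) if a == 1 and b == 1)
    tn = sum(1 for a, b in zip(y, pred) if a == 0 and b == 0)
    fp = sum(1 for a, b in zip(y, pred) if a == 0 and b == 1)
    fn = sum(1 for a, b in zip(y, pred) if a == 1 and b == 0)
    return tp, tn, fp, fn


# ---------------------------------------------------------------------------
# concordance index
# ---------------------------------------------------------------------------

def test_ci_perfect_and_reversed(rng):
    y = rng.permutation(np.arange(20, dtype=float))
    assert concordance_index(y, y) == 1.0
    assert concordance_index(y, -y) == 0.0


def test_ci_matches_brute_force_exactly(rng):
    for _ in range(5):
        y = rng.normal(size=100)
        p = rng.normal(size=100)
        p[rng.integers(0, 100, 10)] = p[0]  # inject prediction ties
        assert concordance_index(y, p) == ci_brute_force(y, p)


def test_ci_all_equal_labels_is_error():
    with pytest.raises(ValueError):
        concordance_index(np.ones(5), np.arange(5.0))


def test_ci_of_random_predictor_is_near_half(rng):
    vals = [concordance_index(rng.normal(size=40), rng.normal(size=40))
            for _ in range(100)]
    assert 0.45 < np.mean(vals) < 0.55


# ---------------------------------------------------------------------------
# rm^2
# ---------------------------------------------------------------------------

def test_rm2_identity_is_one(rng):
    y = rng.normal(size=30)
    assert rm_squared(y, y) == pytest.approx(1.0, abs=1e-12)


def test_rm2_penalises_origin_shift(rng):
    # a pure positive scaling is through-origin-perfect (k absorbs it): rm2 = 1
    y = rng.normal(loc=5.0, size=50)
    assert rm_squared(y, 2.0 * y) == pytest.approx(1.0, abs=1e-12)
    # an additive offset is not: r^2 stays 1 but r0^2 drops, so rm2 < 1
    val = rm_squared(y, y + 2.0)
    assert val < 1.0
    assert val == pytest.approx(rm2_step_by_step(list(y), list(y + 2.0)), abs=1e-10)


def test_rm2_matches_formula_oracle(rng):
    for _ in range(5):
        y = rng.normal(size=50)
        p = 0.7 * y + rng.normal(size=50) * 0.5
        assert rm_squared(y, p) == pytest.approx(rm2_step_by_step(list(y), list(p)),
                                                 abs=1e-10)


def test_rm2_average_variant_is_symmetric(rng):
    y = rng.normal(size=40)
    p = 0.5 * y + rng.normal(size=40)
    assert rm_squared(y, p, variant="average") == pytest.approx(
        rm_squared(p, y, variant="average"), abs=1e-12
    )


def test_rm2_zero_variance_is_error():
    with pytest.raises(ValueError):
        rm_squared(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# bundled regression metrics
# ---------------------------------------------------------------------------

def test_perfect_prediction_metrics(rng):
    y = rng.normal(size=30)
    m = regression_metrics(y, y)
    assert m["mse"] == 0 and m["mae"] == 0
    assert m["pearson_r"] == pytest.approx(1.0)
    assert m["ci"] == 1.0 and m["rm2"] == pytest.approx(1.0)


def test_constant_shift_metrics(rng):
    y = rng.normal(size=50)
    m = regression_metrics(y, y + 1)
    assert m["mse"] == pytest.approx(1.0)
    assert m["mae"] == pytest.approx(1.0)
    assert m["pearson_r"] == pytest.approx(1.0)


def test_regression_metrics_match_textbook_oracles(rng):
    y = rng.normal(size=100)
    p = 0.6 * y + rng.normal(size=100)
    m = regression_metrics(y, p)
    assert m["mse"] == pytest.approx(np.mean((y - p) ** 2), abs=1e-12)
    assert m["mae"] == pytest.approx(np.mean(np.abs(y - p)), abs=1e-12)
    r_manual = np.sum((y - y.mean()) * (p - p.mean())) / np.sqrt(
        np.sum((y - y.mean()) ** 2) * np.sum((p - p.mean()) ** 2)
    )
    assert m["pearson_r"] == pytest.approx(r_manual, abs=1e-10)
    assert m["ci"] == ci_brute_force(y, p)
    assert m["rm2"] == pytest.approx(rm2_step_by_step(list(y), list(p)), abs=1e-10)


def test_metrics_invariant_to_joint_permutation(rng):
    y = rng.normal(size=60)
    p = 0.5 * y + rng.normal(size=60)
    perm = rng.permutation(60)
    m1 = regression_metrics(y, p)
    m2 = regression_metrics(y[perm], p[perm])
    for k in m1:
        assert m1[k] == pytest.approx(m2[k], abs=1e-12)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def test_perfectly_separated_classifier(rng):
    y = np.array([0] * 10 + [1] * 10)
    p = np.concatenate([rng.uniform(0, 0.4, 10), rng.uniform(0.6, 1.0, 10)])
    m = classification_metrics(y, p)
    assert m == {"acc": 1.0, "auc": 1.0, "ba": 1.0, "mcc": 1.0, "f1": 1.0}


def test_constant_predictor_on_balanced_set():
    y = np.array([0, 1] * 20)
    m = classification_metrics(y, np.ones(40))
    assert m["acc"] == 0.5
    assert m["mcc"] == 0.0


def test_classification_matches_confusion_and_rank_oracles(rng):
    y = (rng.random(200) < 0.6).astype(int)
    p = np.clip(0.3 * y + rng.random(200) * 0.7, 0, 1)
    p[rng.integers(0, 200, 10)] = 0.5  # threshold-boundary ties
    m = classification_metrics(y, p)
    pred = (p >= 0.5).astype(int)
    tp, tn, fp, fn = confusion_counts(y, pred)
    assert m["acc"] == (tp + tn) / 200
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    assert m["ba"] == pytest.approx((sens + spec) / 2, abs=1e-12)
    assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)
    mcc_den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    assert m["mcc"] == pytest.approx((tp * tn - fp * fn) / mcc_den, abs=1e-12)
    assert m["auc"] == pytest.approx(auc_pairwise(y, p), abs=1e-12)


def test_single_class_is_error():
    with pytest.raises(ValueError):
        classification_metrics(np.ones(10, dtype=int), np.random.rand(10))


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

def test_metrics_report_mean_sd():
    rep = MetricsReport(task="regression")
    rep.per_fold = [{"mse": 1.0, "mae": 1.0, "pearson_r": 0.9, "ci": 0.8, "rm2": 0.7},
                    {"mse": 3.0, "mae": 2.0, "pearson_r": 0.7, "ci": 0.6, "rm2": 0.5}]
    assert rep.mean("mse") == 2.0
    assert rep.sd("mse") == 1.0
    assert rep.summary()["ci"] == {"mean": pytest.approx(0.7), "sd": pytest.approx(0.1)}
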