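"""Metrics, gap arithmetic, and cluster-bootstrap behavior."""

import numpy as np
import pandas as pd
import pytest

from helpers import brute_force_metrics, flat_bootstrap_ci, simulate_clustered_records

from ifcmorph.evaluation import (
    BootstrapCI,
    GeneralizationMatrix,
    confusion,
    evaluate_predictions,
    f1_score,
    format_generalization_report,
    gap,
    generalization_matrix_from_table,
    hier_bootstrap,
    metrics,
    significant_difference,
    summarize_learning_curve,
)

CLASSES = ("A", "B", "C")


# ---------------------------------------------------------------------------
# confusion + metrics


def test_perfect_predictions_give_diagonal_matrix_and_unit_metrics():
    labels = ["A", "B", "C", "A"]
    cm = confusion(labels, labels, classes=CLASSES)
    assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)
    res = metrics(cm)
    assert res.accuracy == 1.0 and res.macro_f1 == 1.0


def test_confusion_counts_by_enumeration():
    cm = confusion(preds=["A", "B", "B"], labels=["A", "A", "B"], classes=CLASSES)
    assert cm.counts[0, 0] == 1  # true A predicted A
    assert cm.counts[0, 1] == 1  # true A predicted B
    assert cm.counts[1, 1] == 1  # true B predicted B
    assert cm.n == 3
    norm = cm.normalized()
    nonempty = cm.counts.sum(axis=1) > 0
    assert np.allclose(norm[nonempty].sum(axis=1), 1.0)
    assert np.allclose(norm[~nonempty], 0.0)


def test_confusion_rejects_mismatched_or_unknown_labels():
    with pytest.raises(ValueError, match="equal length"):
        confusion(["A"], ["A", "B"], classes=CLASSES)
    with pytest.raises(ValueError, match="outside"):
        confusion(["Z"], ["A"], classes=CLASSES)


def test_f1_formula_values():
    assert f1_score(0.5, 0.5) == pytest.approx(0.5)
    assert f1_score(0.8, 0.6) == pytest.approx(0.6857, abs=5e-5)
    assert f1_score(0.0, 0.0) == 0.0


def test_metrics_match_brute_force_recount_on_fuzzed_inputs():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = int(rng.integers(1, 30))
        k = int(rng.integers(2, 5))
        classes = tuple(f"c{i}" for i in range(k))
        labels = [classes[i] for i in rng.integers(0, k, size=n)]
        preds = [classes[i] for i in rng.integers(0, k, size=n)]
        res = evaluate_predictions(preds, labels, classes=classes)
        ref = brute_force_metrics(preds, labels, classes)
        assert res.accuracy == pytest.approx(ref["accuracy"])
        assert res.macro_f1 == pytest.approx(ref["macro_f1"])
        for c in classes:
            p, r, f = ref["per_class"][c]
            assert res.precision[c] == pytest.approx(p)
            assert res.recall[c] == pytest.approx(r)
            assert res.f1[c] == pytest.approx(f)


def test_metrics_agree_with_sklearn_cross_check():
    from sklearn.metrics import accuracy_score, f1_score as sk_f1

    rng = np.random.default_rng(7)
    labels = rng.integers(0, 4, size=500)
    preds = np.where(rng.random(500) < 0.7, labels, rng.integers(0, 4, size=500))
    classes = tuple("abcd")
    res = evaluate_predictions(
        [classes[i] for i in preds], [classes[i] for i in labels], classes=classes
    )
    assert res.accuracy == pytest.approx(accuracy_score(labels, preds))
    assert res.macro_f1 == pytest.approx(
        sk_f1(labels, preds, average="macro", labels=range(4))
    )


def test_macro_f1_tracks_accuracy_on_balanced_uniform_sets():
    """With balanced classes and uniform per-class behavior, macro-F1 stays
    within 2 percentage points of accuracy."""
    rng = np.random.default_rng(0)
    k, per = 10, 200
    classes = tuple(f"c{i}" for i in range(k))
    labels = np.repeat(np.arange(k), per)
    wrong = rng.integers(1, k, size=labels.size)
    preds = np.where(
        rng.random(labels.size) < 0.8, labels, (labels + wrong) % k
    )
    res = evaluate_predictions(
        [classes[i] for i in preds], [classes[i] for i in labels], classes=classes
    )
    assert abs(res.macro_f1 - res.accuracy) < 0.02


def test_empty_confusion_rejected():
    cm = confusion([], [], classes=CLASSES)
    with pytest.raises(ValueError):
        metrics(cm)


# ---------------------------------------------------------------------------
# gaps


def _aggregated_matrix():
    table = pd.DataFrame(
        {
            "train": ["frozen", "frozen", "fresh", "fresh"],
            "test": ["frozen", "fresh", "fresh", "frozen"],
            "accuracy": [83.58, 68.75, 76.39, 66.12],
        }
    )
    return generalization_matrix_from_table(table)


def test_cross_condition_gaps_in_percentage_points():
    gm = _aggregated_matrix()
    assert gap(gm, "frozen", "frozen", "fresh") == pytest.approx(-14.83)
    assert gap(gm, "fresh", "fresh", "frozen") == pytest.approx(-10.27)
    assert gap(gm, "fresh", "fresh", "fresh") == 0.0


def test_gap_requires_existing_cells():
    gm = _aggregated_matrix()
    with pytest.raises(KeyError):
        gap(gm, "frozen", "frozen", "thawed")


def test_generalization_report_is_pure(tmp_path):
    gm = _aggregated_matrix()
    assert format_generalization_report(gm) == format_generalization_report(gm)
    assert "83.58" in format_generalization_report(gm)


def test_learning_curve_summary_shape():
    table = pd.DataFrame(
        {
            "fraction": [0.1, 0.1, 1.0, 1.0],
            "fold": ["KW", "SIM", "KW", "SIM"],
            "seed": [0, 0, 0, 0],
            "accuracy": [0.3, 0.4, 0.6, 0.7],
        }
    )
    out = summarize_learning_curve(table)
    assert list(out["fraction"]) == [0.1, 1.0]
    assert out["mean_accuracy"].tolist() == pytest.approx([0.35, 0.65])


# ---------------------------------------------------------------------------
# hierarchical bootstrap


def test_all_correct_records_give_degenerate_interval():
    recs = pd.DataFrame(
        {"bull_id": "b0", "ejaculate_id": "e0", "correct": [1] * 50}
    )
    ci = hier_bootstrap(recs, B=200, seed=0)
    assert ci.point == 1.0 and ci.lower == 1.0 and ci.upper == 1.0


def test_single_cluster_reduces_to_flat_bootstrap():
    rng = np.random.default_rng(5)
    correct = (rng.random(400) < 0.75).astype(int)
    recs = pd.DataFrame(
        {"bull_id": "b0", "ejaculate_id": "e0", "correct": correct}
    )
    ci = hier_bootstrap(recs, B=2000, seed=9)
    lo, hi = flat_bootstrap_ci(correct, B=2000, seed=123)
    assert ci.lower == pytest.approx(lo, abs=0.01)
    assert ci.upper == pytest.approx(hi, abs=0.01)


def test_bootstrap_input_validation():
    recs = pd.DataFrame({"bull_id": [], "ejaculate_id": [], "correct": []})
    with pytest.raises(ValueError):
        hier_bootstrap(recs, B=10)
    ok = pd.DataFrame({"bull_id": ["b"], "ejaculate_id": ["e"], "correct": [1]})
    with pytest.raises(ValueError):
        hier_bootstrap(ok, B=0)
    with pytest.raises(ValueError):
        BootstrapCI(point=0.5, lower=0.6, upper=0.4)


def test_ci_width_shrinks_with_images_only_without_bull_effects():
    widths = []
    for n_img in (25, 400):
        recs = simulate_clustered_records(
            seed=3, n_images=n_img, bull_sd=0.0
        )
        ci = hier_bootstrap(recs, B=400, seed=1)
        widths.append(ci.upper - ci.lower)
    assert widths[1] < widths[0] / 2

    # with dominant bull effects the width hits the between-bull floor
    floor_widths = []
    for n_img in (100, 1600):
        recs = simulate_clustered_records(seed=4, n_images=n_img, bull_sd=0.08)
        ci = hier_bootstrap(recs, B=400, seed=1)
        floor_widths.append(ci.upper - ci.lower)
    assert floor_widths[1] > floor_widths[0] * 0.5


def test_identical_paired_records_are_never_significant():
    recs = simulate_clustered_records(seed=8, n_images=50)
    diff, ci, sig = significant_difference(recs, recs, paired=True, B=200, seed=0)
    assert diff == 0.0 and not sig and ci.lower == 0.0 == ci.upper


def test_ci_containing_zero_is_not_significant():
    a = simulate_clustered_records(seed=10, p=0.8, n_images=30)
    b = simulate_clustered_records(seed=11, p=0.8, n_images=30)
    _, ci, sig = significant_difference(a, b, B=300, seed=2)
    assert sig == ci.excludes_zero
    assert sig == (ci.lower > 0 or ci.upper < 0)


def test_true_difference_is_detected_with_high_power():
    """A 0.15 accuracy difference across ~5,000 images and 6 bulls is
    declared significant in nearly every simulation replicate."""
    hits = 0
    reps = 100
    for r in range(reps):
        a = simulate_clustered_records(seed=2 * r, p=0.80, n_images=278,
                                       bull_sd=0.03)
        b = simulate_clustered_records(seed=2 * r + 1, p=0.65, n_images=278,
                                       bull_sd=0.03)
        _, _, sig = significant_difference(a, b, B=200, seed=r)
        hits += sig
    assert hits / reps >= 0.95


def test_paired_mode_requires_aligned_structures():
    a = simulate_clustered_records(seed=1, n_bulls=6, n_images=10)
    b = simulate_clustered_records(seed=2, n_bulls=5, n_images=10)
    with pytest.raises(ValueError, match="aligned"):
        significant_difference(a, b, paired=True, B=10, seed=0)
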