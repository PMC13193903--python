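"""Quota sampling, balanced exposure, splits, LOBO folds, fraction nesting."""

import numpy as np
import pandas as pd
import pytest

from ifcmorph.sampling import (
    CapSpec,
    QuotaSpec,
    SplitSpec,
    balanced_batches,
    fraction_subsets,
    lobo_folds,
    quota_sample,
    save_assignments,
    stratified_split,
)
from ifcmorph.synth import HierarchySpec, generate_dataset


@pytest.fixture(scope="module")
def labeled_manifest():
    h = HierarchySpec(
        n_bulls=6,
        ejaculates_per_bull={"fresh": 2, "frozen": 1},
        files_per_ejaculate=2,
        events_per_file=2000,
        seed=3,
    )
    return generate_dataset(h, include_params=False)


# ---------------------------------------------------------------------------
# quota sampling


def test_quota_yields_exactly_quota_rows_per_stratum(labeled_manifest):
    pool = quota_sample(labeled_manifest, QuotaSpec(per_stratum_quota=40), 1)
    sizes = pool.groupby(
        ["label", "breed", "condition"], observed=True
    ).size()
    assert (sizes == 40).all()
    assert len(pool) == 40 * 10 * 3 * 2


def test_quota_zero_yields_empty_selection(labeled_manifest):
    assert len(quota_sample(labeled_manifest, QuotaSpec(0), 0)) == 0


def test_quota_shortfall_errors_naming_stratum_unless_allowed():
    small = pd.DataFrame(
        {"label": ["NM"] * 3 + ["CTM"] * 8, "breed": "KW", "condition": "fresh"}
    )
    spec = QuotaSpec(per_stratum_quota=5)
    with pytest.raises(ValueError, match="NM"):
        quota_sample(small, spec, 0)
    pool = quota_sample(
        small, QuotaSpec(5, allow_short=True), 0
    )
    by_label = pool.groupby("label").size()
    assert by_label["NM"] == 3 and by_label["CTM"] == 5


def test_quota_never_duplicates_and_differs_across_seeds(labeled_manifest):
    a = quota_sample(labeled_manifest, QuotaSpec(30), 1)
    b = quota_sample(labeled_manifest, QuotaSpec(30), 2)
    assert a["image_id"].is_unique
    assert not a["image_id"].equals(b["image_id"])
    assert a.equals(quota_sample(labeled_manifest, QuotaSpec(30), 1))


# ---------------------------------------------------------------------------
# class-balanced batches


def test_balanced_pool_stays_balanced(labeled_manifest):
    pool = quota_sample(labeled_manifest, QuotaSpec(50), 0)
    counts: dict[str, int] = {}
    total = 0
    for batch in balanced_batches(pool, batch_size=64, rng_seed=0, n_draws=4000):
        for lab, c in batch["label"].value_counts().items():
            counts[str(lab)] = counts.get(str(lab), 0) + int(c)
        total += len(batch)
    freqs = np.array([counts.get(c, 0) for c in sorted(counts)]) / total
    assert total == 4000
    assert np.all(np.abs(freqs - 0.1) < 0.03)


def test_imbalanced_pool_is_rebalanced_with_replacement(labeled_manifest):
    nm = labeled_manifest[labeled_manifest.label == "NM"].head(900)
    ctm = labeled_manifest[labeled_manifest.label == "CTM"].head(100)
    pool = pd.concat([nm, ctm])
    counts = {"NM": 0, "CTM": 0}
    total = 0
    for batch in balanced_batches(pool, batch_size=64, rng_seed=1, n_draws=10_000):
        vc = batch["label"].value_counts()
        counts["NM"] += int(vc.get("NM", 0))
        counts["CTM"] += int(vc.get("CTM", 0))
        total += len(batch)
    assert abs(counts["NM"] / total - 0.5) < 0.02
    assert abs(counts["CTM"] / total - 0.5) < 0.02


def test_per_bull_cap_limits_distinct_contributions(labeled_manifest):
    pool = labeled_manifest.head(3000)
    seen: dict[str, set] = {}
    for batch in balanced_batches(
        pool, CapSpec(per_bull_cap=100), batch_size=64, rng_seed=0, n_draws=3000
    ):
        for bull, ids in batch.groupby("bull_id", observed=True)["image_id"]:
            seen.setdefault(str(bull), set()).update(ids)
    assert all(len(v) <= 100 for v in seen.values())


def test_invalid_batch_and_cap_settings():
    with pytest.raises(ValueError):
        CapSpec(per_class_cap=0)
    with pytest.raises(ValueError):
        list(balanced_batches(pd.DataFrame({"label": ["NM"]}), batch_size=0))


# ---------------------------------------------------------------------------
# stratified split


def test_split_fractions_800_100_100():
    manifest = pd.DataFrame({"label": ["NM"] * 1000, "image_id": range(1000)})
    tr, va, te = stratified_split(manifest, SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (800, 100, 100)


def test_split_is_a_partition(labeled_manifest):
    pool = quota_sample(labeled_manifest, QuotaSpec(30), 0)
    tr, va, te = stratified_split(pool, SplitSpec(seed=5))
    ids = [set(p["image_id"]) for p in (tr, va, te)]
    assert ids[0] | ids[1] | ids[2] == set(pool["image_id"])
    assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])


def test_split_applies_per_stratum():
    manifest = pd.DataFrame(
        {
            "label": np.repeat([f"c{i}" for i in range(10)], 100),
            "image_id": range(1000),
        }
    )
    tr, va, te = stratified_split(manifest, SplitSpec(seed=1))
    assert (tr.groupby("label").size() == 80).all()
    assert (va.groupby("label").size() == 10).all()
    assert (te.groupby("label").size() == 10).all()


def test_split_rejects_tiny_stratum():
    manifest = pd.DataFrame({"label": ["NM", "NM", "CTM"], "image_id": range(3)})
    with pytest.raises(ValueError, match="too small"):
        stratified_split(manifest, SplitSpec(seed=0))


def test_split_spec_validation():
    with pytest.raises(ValueError):
        SplitSpec(fractions=(0.5, 0.5, 0.1))


# ---------------------------------------------------------------------------
# LOBO folds


def test_one_fold_per_breed_with_exclusion(labeled_manifest):
    pool = quota_sample(labeled_manifest, QuotaSpec(30), 0)
    folds = lobo_folds(pool)
    assert sorted(f["held_out"] for f in folds) == ["AUL", "KW", "SIM"]
    for f in folds:
        held = f["held_out"]
        assert (f["test"]["breed"] == held).all()
        assert not (f["train"]["breed"] == held).any()
        assert not (f["val"]["breed"] == held).any()
        n_rest = len(f["train"]) + len(f["val"])
        assert abs(len(f["val"]) / n_rest - 0.2) < 0.02


def test_lobo_requires_at_least_two_groups():
    single = pd.DataFrame(
        {"breed": ["KW"] * 10, "label": ["NM"] * 10, "image_id": range(10)}
    )
    with pytest.raises(ValueError, match=">= 2"):
        lobo_folds(single)


# ---------------------------------------------------------------------------
# fraction subsets


def test_fractions_are_nested_stratified_and_full_at_one(labeled_manifest):
    pool = quota_sample(labeled_manifest, QuotaSpec(50), 0)
    subs = fraction_subsets(pool, rng_seed=7)
    assert set(subs) == {0.1, 0.2, 0.5, 1.0}
    assert subs[1.0]["image_id"].tolist() == pool["image_id"].tolist()
    ids = {f: set(s["image_id"]) for f, s in subs.items()}
    assert ids[0.1] <= ids[0.2] <= ids[0.5] <= ids[1.0]
    per_class = subs[0.2].groupby("label", observed=True).size()
    assert (per_class == 0.2 * 50 * 6).all()  # class-balanced at every f


def test_fraction_validation():
    with pytest.raises(ValueError):
        fraction_subsets(pd.DataFrame({"label": ["NM"]}), fractions=(0.0, 1.0))


def test_assignments_replay_bit_exactly(tmp_path, labeled_manifest):
    pool = quota_sample(labeled_manifest, QuotaSpec(20), 0)
    tr, va, te = stratified_split(pool, SplitSpec(seed=2))
    path = tmp_path / "splits.csv"
    save_assignments({"train": tr, "val": va, "test": te}, path)
    save_assignments({"train": tr, "val": va, "test": te}, tmp_path / "b.csv")
    assert path.read_bytes() == (tmp_path / "b.csv").read_bytes()
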