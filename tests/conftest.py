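"""Shared fixtures: synthetic pools sized for minutes-scale CPU runs.

The benchmark pool mirrors the acquisition design (6 bulls x 3 breeds x
2 conditions, 2 fresh + 1 frozen ejaculates, 2 files each) at reduced
events-per-file, quota-sampled to a class x breed x condition-balanced
labeled set of ~2,000 images. Stem tensors are rendered once per session
and shared across training tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ifcmorph.data import ImageDataset
from ifcmorph.sampling import QuotaSpec, SplitSpec, quota_sample, stratified_split
from ifcmorph.synth import (
    DomainParams,
    HierarchySpec,
    default_domains,
    generate_dataset,
)

BENCH_SEED = 11


@pytest.fixture(scope="session")
def bench():
    """~2,000-image balanced 10-class pool with default domain shifts."""
    h = HierarchySpec(
        n_bulls=6,
        ejaculates_per_bull={"fresh": 2, "frozen": 1},
        files_per_ejaculate=2,
        events_per_file=1200,
        seed=BENCH_SEED,
    )
    doms = default_domains(1.0)
    manifest = generate_dataset(h, doms)
    pool = quota_sample(manifest, QuotaSpec(per_stratum_quota=33), rng_seed=2)
    dataset = ImageDataset(pool, doms)
    dataset.stem_array()
    return {"manifest": manifest, "pool": pool, "dataset": dataset, "doms": doms}


@pytest.fixture(scope="session")
def bench_splits(bench):
    tr, va, te = stratified_split(bench["pool"], SplitSpec(seed=3))
    ds = bench["dataset"]
    return {
        "train": ds.subset(tr),
        "val": ds.subset(va),
        "test": ds.subset(te),
        "test_manifest": te,
    }


@pytest.fixture(scope="session")
def twoclass():
    """Low-noise NM vs CTM pool (~400 images) with fixed 80/10/10 split."""
    doms = [
        DomainParams(breed=b, condition=c, noise_sd=2.0)
        for b in ("KW", "SIM", "AUL")
        for c in ("fresh", "frozen")
    ]
    h = HierarchySpec(
        n_bulls=3,
        ejaculates_per_bull={"fresh": 1},
        files_per_ejaculate=1,
        events_per_file=900,
        seed=7,
    )
    m = generate_dataset(h, doms)
    sub = quota_sample(
        m[m.label.isin(["NM", "CTM"])],
        QuotaSpec(67, ("label", "breed"), allow_short=True),
        rng_seed=0,
    )
    tr, va, te = stratified_split(sub, SplitSpec(seed=1))
    ds = ImageDataset(sub, doms)
    ds.stem_array()
    return {
        "pool": sub,
        "dataset": ds,
        "train": ds.subset(tr),
        "val": ds.subset(va),
        "test": ds.subset(te),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
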