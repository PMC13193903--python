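"""Stratified quota sampling, class-balanced exposure, and fixed splits.

The labeling protocol draws a fixed quota per stratum (class x breed x
condition, 200 by default) so the labeled pool is exactly uniform across
strata. Training exposure is then equalized with class-balanced sampling
under optional per-class / per-breed / per-bull caps, and experiments use
either fixed stratified 80/10/10 splits or leave-one-breed-out folds with a
20 % validation share. All selections are deterministic at a fixed seed and
persist/replay bit-exactly from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

DEFAULT_STRATA = ("label", "breed", "condition")


@dataclass(frozen=True)
class QuotaSpec:
    per_stratum_quota: int = 200
    strata_keys: tuple[str, ...] = DEFAULT_STRATA
    allow_short: bool = False

    def __post_init__(self) -> None:
        if self.per_stratum_quota < 0:
            raise ValueError("quota must be >= 0")


@dataclass(frozen=True)
class CapSpec:
    """Per-epoch exposure caps; ``None`` means uncapped."""

    per_class_cap: int | None = None
    per_breed_cap: int | None = None
    per_bull_cap: int | None = None

    def __post_init__(self) -> None:
        for v in (self.per_class_cap, self.per_breed_cap, self.per_bull_cap):
            if v is not None and v < 1:
                raise ValueError("caps must be >= 1 when set")


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    stratify_keys: tuple[str, ...] = ("label",)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1 within 1e-9")


def _group_iter(manifest: pd.DataFrame, keys) -> Iterator:
    gb = manifest.groupby(list(keys), observed=True, sort=True, dropna=False)
    yield from gb


def quota_sample(
    manifest: pd.DataFrame, q: QuotaSpec, rng_seed: int = 0
) -> pd.DataFrame:
    """Draw exactly ``per_stratum_quota`` rows per stratum, uniformly.

    Emulates labeling "until N quality images per class x breed x condition":
    the output is exactly uniform across strata. A stratum smaller than the
    quota raises (naming the stratum) unless ``allow_short`` is set, in
    which case the whole stratum is taken.
    """
    if q.per_stratum_quota == 0 or len(manifest) == 0:
        return manifest.iloc[0:0].copy()
    rng = np.random.default_rng(rng_seed)
    picks = []
    for key, grp in _group_iter(manifest, q.strata_keys):
        if len(grp) < q.per_stratum_quota and not q.allow_short:
            raise ValueError(
                f"stratum {dict(zip(q.strata_keys, np.atleast_1d(key)))} has "
                f"{len(grp)} rows < quota {q.per_stratum_quota}"
            )
        n = min(q.per_stratum_quota, len(grp))
        idx = rng.choice(len(grp), size=n, replace=False)
        picks.append(grp.iloc[np.sort(idx)])
    return pd.concat(picks).sort_index()


def _capped_pool(train: pd.DataFrame, caps: CapSpec, rng: np.random.Generator):
    """Apply per-class / per-breed / per-bull caps by uniform subsampling."""
    pool = train
    for cap, key in (
        (caps.per_class_cap, "label"),
        (caps.per_breed_cap, "breed"),
        (caps.per_bull_cap, "bull_id"),
    ):
        if cap is None or key not in pool.columns:
            continue
        kept = []
        for _, grp in _group_iter(pool, [key]):
            if len(grp) > cap:
                idx = rng.choice(len(grp), size=cap, replace=False)
                grp = grp.iloc[np.sort(idx)]
            kept.append(grp)
        pool = pd.concat(kept).sort_index()
    return pool


def balanced_batches(
    train: pd.DataFrame,
    caps: CapSpec | None = None,
    batch_size: int = 64,
    rng_seed: int = 0,
    n_draws: int | None = None,
) -> Iterator[pd.DataFrame]:
    """One epoch of class-balanced batches over the (capped) pool.

    Each draw picks a class uniformly, then an image uniformly within that
    class — i.e. sampling with replacement, so minority classes are
    over-sampled to equal exposure. ``n_draws`` defaults to the capped pool
    size. Yields manifest-row batches.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    caps = caps or CapSpec()
    rng = np.random.default_rng(rng_seed)
    pool = _capped_pool(train, caps, rng)
    labels = np.asarray(pool["label"])
    classes = sorted(set(labels))
    if not classes:
        raise ValueError("empty training pool after caps")
    grp_pos = {c: np.flatnonzero(labels == c) for c in classes}
    n_draws = len(pool) if n_draws is None else int(n_draws)
    for start in range(0, n_draws, batch_size):
        k = min(batch_size, n_draws - start)
        cls_idx = rng.integers(0, len(classes), size=k)
        positions = np.empty(k, dtype=int)
        for ci in np.unique(cls_idx):
            sel = np.flatnonzero(cls_idx == ci)
            pos = grp_pos[classes[ci]]
            positions[sel] = pos[rng.integers(0, len(pos), size=len(sel))]
        yield pool.iloc[positions]


def _largest_remainder(n: int, fractions) -> np.ndarray:
    """Integer allocation of n by largest remainder; sums to n exactly."""
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _stratified_partition(
    manifest: pd.DataFrame, fractions, stratify_keys, seed: int
) -> list[pd.DataFrame]:
    """Disjoint, exhaustive n-way partition, stratified and deterministic."""
    rng = np.random.default_rng(seed)
    parts: list[list[pd.DataFrame]] = [[] for _ in fractions]
    for key, grp in _group_iter(manifest, stratify_keys):
        counts = _largest_remainder(len(grp), fractions)
        if (counts == 0).any():
            raise ValueError(
                f"stratum {key!r} with {len(grp)} rows is too small for "
                f"fractions {tuple(fractions)}"
            )
        perm = rng.permutation(len(grp))
        edges = np.cumsum(counts)[:-1]
        for part, chunk in zip(parts, np.split(perm, edges)):
            part.append(grp.iloc[np.sort(chunk)])
    return [pd.concat(p).sort_index() for p in parts]


def stratified_split(
    manifest: pd.DataFrame, s: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fixed stratified train/val/test partition (80/10/10 by default).

    Per-stratum counts follow the fractions with largest-remainder rounding;
    the partition is disjoint and exhaustive and deterministic at a fixed
    seed. A stratum too small to place one row in every part raises.
    """
    train, val, test = _stratified_partition(
        manifest, s.fractions, s.stratify_keys, s.seed
    )
    return train, val, test


def lobo_folds(
    manifest: pd.DataFrame,
    group_key: str = "breed",
    val_fraction: float = 0.2,
    stratify_keys: tuple[str, ...] = ("label",),
    seed: int = 0,
) -> list[dict]:
    """Leave-one-group-out folds (leave-one-breed-out by default).

    Each group level is held out once as the test set; the remaining rows
    are split (1 - val_fraction)/val_fraction into train/val, stratified by
    class. Returns a list of dicts with keys
    ``held_out, train, val, test``.
    """
    levels = [
        k if np.isscalar(k) else k[0] for k, _ in _group_iter(manifest, [group_key])
    ]
    if len(levels) < 2:
        raise ValueError(f"need >= 2 levels of {group_key!r}, got {levels}")
    folds = []
    for level in levels:
        mask = manifest[group_key] == level
        rest = manifest.loc[~mask]
        tr, val = _stratified_partition(
            rest, (1.0 - val_fraction, val_fraction), stratify_keys, seed
        )
        folds.append(
            {
                "held_out": level,
                "train": tr,
                "val": val,
                "test": manifest.loc[mask],
            }
        )
    return folds


def fraction_subsets(
    train: pd.DataFrame,
    fractions=(0.1, 0.2, 0.5, 1.0),
    rng_seed: int = 0,
    stratify_keys: tuple[str, ...] = ("label",),
) -> dict[float, pd.DataFrame]:
    """Nested stratified subsets of the training pool.

    Subsets are nested (smaller fractions are contained in larger ones) so
    learning-curve differences reflect data volume only; each subset is
    stratified by class and f = 1.0 is the full pool.
    """
    fractions = sorted(float(f) for f in fractions)
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    # one permutation per stratum; a fraction takes its leading slice
    ranked: list[pd.Index] = []
    for _, grp in _group_iter(train, stratify_keys):
        perm = rng.permutation(len(grp))
        ranked.append(grp.index[perm])
    out: dict[float, pd.DataFrame] = {}
    for f in fractions:
        if f == 1.0:
            out[f] = train.copy()
            continue
        take: list[pd.Index] = []
        for order in ranked:
            k = int(round(f * len(order)))
            take.append(order[:k])
        idx = take[0].append(take[1:]) if len(take) > 1 else take[0]
        out[f] = train.loc[idx.sort_values()]
    return out


def save_assignments(folds_or_splits: dict[str, pd.DataFrame], path) -> None:
    """Persist split/fold membership as CSV (image_id, part) for replay."""
    rows = []
    for part, df in folds_or_splits.items():
        rows.append(pd.DataFrame({"image_id": df["image_id"], "part": part}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
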