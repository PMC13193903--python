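"""Morphology profiling of labeled or automatically-labeled pools.

After a classifier labels an unlabeled pool, the biologically meaningful
summary is the proportion of each of the eight morphology classes per
group of interest (condition, season, breed, bull, ...). The residual
MULTI and DEBRIS categories are frame-level artifacts, not sperm biology:
they are tallied and reported as exclusions, never silently dropped, and
the per-class proportions are computed over biological frames only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classes import BIOLOGICAL_CLASSES, MorphClass

logger = logging.getLogger(__name__)

_BIO = tuple(c.value for c in BIOLOGICAL_CLASSES)


def profile_counts(
    labels: pd.Series | np.ndarray,
    group_frame: pd.DataFrame | None = None,
    group_keys: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-group class proportions over the 8 biological classes.

    ``labels`` are predicted (or true) class labels per record;
    ``group_frame`` carries the grouping columns, aligned positionally.
    Output: one row per group with the grouping keys, ``prop_<class>``
    columns, ``n_biological`` and ``n_excluded`` (MULTI + DEBRIS). Empty
    groups are omitted with a warning. Proportions over biological frames
    sum to 1; record order does not matter.
    """
    labels = pd.Series(np.asarray(labels).astype(str), name="label")
    if group_keys:
        if group_frame is None:
            raise ValueError("group_keys given but no group_frame")
        df = group_frame.reset_index(drop=True)[list(group_keys)].copy()
        df["label"] = labels.to_numpy()
        grouped = df.groupby(list(group_keys), observed=True, sort=True)
        groups = [
            (dict(zip(group_keys, np.atleast_1d(key))), g["label"])
            for key, g in grouped
        ]
    else:
        groups = [({}, labels)]
    rows = []
    for key, labs in groups:
        if len(labs) == 0:
            logger.warning("profile group %s is empty; omitted", key)
            continue
        counts = labs.value_counts()
        n_excluded = int(
            counts.get(MorphClass.MULTI.value, 0)
            + counts.get(MorphClass.DEBRIS.value, 0)
        )
        n_bio = int(len(labs) - n_excluded)
        row = dict(key)
        for c in _BIO:
            row[f"prop_{c}"] = (
                float(counts.get(c, 0)) / n_bio if n_bio > 0 else np.nan
            )
        row["n_biological"] = n_bio
        row["n_excluded"] = n_excluded
        rows.append(row)
    return pd.DataFrame(rows)


def profile_pool(
    model,
    dataset,
    group_keys: tuple[str, ...] = ("condition", "season"),
    batch_size: int = 256,
) -> pd.DataFrame:
    """Automatically label every record and summarize morphology per group.

    ``dataset`` is an :class:`~ifcmorph.data.ImageDataset` over a
    preprocessed manifest; ``model`` a trained classifier. Mirrors the
    deployment use: a frozen / fresh-by-season breakdown of predicted
    morphology proportions, with residual categories counted separately.
    """
    from .training import predict

    preds, _ = predict(model, dataset, batch_size=batch_size)
    return profile_counts(
        np.asarray(preds), dataset.manifest, group_keys=group_keys
    )


def condition_totals(manifest: pd.DataFrame) -> pd.DataFrame:
    """Record counts per condition plus a grand total row.

    The totaling routine behind dataset-size consistency reports
    (e.g. fresh + frozen = overall pool size).
    """
    counts = (
        manifest.groupby("condition", observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    total = pd.DataFrame({"condition": ["total"], "n": [len(manifest)]})
    return pd.concat([counts, total], ignore_index=True)


def sum_condition_counts(counts: pd.DataFrame) -> int:
    """Total record count from a per-condition count table (n column)."""
    body = counts[counts["condition"] != "total"] if "condition" in counts else counts
    return int(body["n"].sum())


def profile_report_markdown(profile: pd.DataFrame) -> str:
    """Markdown rendering of a profile table. Pure function of its input."""
    df = profile.copy()
    for c in df.columns:
        if str(c).startswith("prop_"):
            df[c] = (100.0 * df[c]).map(lambda v: f"{v:.1f}")
    cols = [str(c) for c in df.columns]
    lines = [
        "| " + " | ".join(cols) + " |",
        "| " + " | ".join("---" for _ in cols) + " |",
    ]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
    return "\n".join(lines) + "\n"
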