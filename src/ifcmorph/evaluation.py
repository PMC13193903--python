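"""Evaluation statistics: confusion matrices, macro-F1, learning curves,
generalization matrices, and hierarchical cluster bootstrap CIs.

Accuracy alone hides structure, so every evaluation carries a full
confusion matrix and per-class precision/recall/F1 with
F1 = 2 * P * R / (P + R) and macro-F1 the unweighted class mean. Because
images from the same bull (and the same ejaculate) are statistically
dependent, confidence intervals for accuracies come from a hierarchical
cluster bootstrap — resampling bulls, then ejaculates within bulls, then
images within ejaculates, B = 5,000 — and a difference is called
significant when its 95 % CI excludes zero.

Cross-domain generalization (fresh vs frozen preparation, or breed within a
condition) is summarized as a train-domain x test-domain accuracy matrix
with signed percentage-point gaps relative to the in-domain cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classes import CLASS_ORDER, MorphClass

# ---------------------------------------------------------------------------
# confusion + metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Row-normalized counts; all-zero rows stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass(frozen=True)
class EvalResult:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    confusion: ConfusionMatrix
    n: int


def _as_label(x) -> str:
    return x.value if isinstance(x, MorphClass) else str(x)


def confusion(preds, labels, classes=None) -> ConfusionMatrix:
    """Count co-occurrences of (true label, predicted label)."""
    if len(preds) != len(labels):
        raise ValueError("preds and labels must have equal length")
    classes = tuple(
        _as_label(c) for c in (classes if classes is not None else CLASS_ORDER)
    )
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, t in zip(preds, labels):
        p, t = _as_label(p), _as_label(t)
        if p not in index or t not in index:
            raise ValueError(f"label outside class list: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> EvalResult:
    """Accuracy, per-class P/R/F1 and macro-F1 from a confusion matrix.

    Per-class precision/recall are 0 when their denominator is 0; macro-F1
    averages F1 over the full evaluated class list, unweighted.
    """
    counts = cm.counts
    if cm.n < 1:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    pred_tot = counts.sum(axis=0).astype(float)
    true_tot = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
    f1 = np.array([f1_score(p, r) for p, r in zip(prec, rec)])
    return EvalResult(
        accuracy=float(tp.sum() / cm.n),
        precision=dict(zip(cm.classes, prec)),
        recall=dict(zip(cm.classes, rec)),
        f1=dict(zip(cm.classes, f1)),
        macro_f1=float(f1.mean()),
        confusion=cm,
        n=cm.n,
    )


def evaluate_predictions(preds, labels, classes=None) -> EvalResult:
    return metrics(confusion(preds, labels, classes=classes))


# ---------------------------------------------------------------------------
# hierarchical cluster bootstrap


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    level: float = 0.95
    B: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower CI bound above upper bound")

    @property
    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0


def _cluster_tree(records: pd.DataFrame) -> list[list[tuple[int, int]]]:
    """records -> per-bull list of (n_images, n_correct) per ejaculate."""
    tree: list[list[tuple[int, int]]] = []
    for _, bull_grp in records.groupby("bull_id", observed=True):
        ejs = [
            (len(g), int(g["correct"].sum()))
            for _, g in bull_grp.groupby("ejaculate_id", observed=True)
        ]
        tree.append(ejs)
    return tree


def _resample_mean(
    tree: list[list[tuple[int, int]]], rng: np.random.Generator
) -> float:
    """One hierarchical resample: bulls, then ejaculates, then images.

    Resampled counts equal the observed counts of each drawn unit. Drawing
    n images with replacement from an ejaculate with k/n correct and
    summing successes is Binomial(n, k/n); sampling it directly avoids
    materializing per-image draws.
    """
    n_tot = 0
    k_tot = 0
    n_bulls = len(tree)
    for b in rng.integers(0, n_bulls, size=n_bulls):
        ejs = tree[b]
        for e in rng.integers(0, len(ejs), size=len(ejs)):
            n, k = ejs[e]
            if n == 0:
                continue
            k_tot += rng.binomial(n, k / n)
            n_tot += n
    return k_tot / n_tot if n_tot else np.nan


def hier_bootstrap(
    records: pd.DataFrame,
    B: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile CI for mean correctness under bull/ejaculate clustering.

    ``records`` needs columns bull_id, ejaculate_id, correct (bool/0-1).
    Each resample draws bulls with replacement, ejaculates with replacement
    within each drawn bull, and images with replacement within each drawn
    ejaculate; the statistic is the overall mean.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(records) == 0:
        raise ValueError("no records to bootstrap")
    tree = _cluster_tree(records)
    rng = np.random.default_rng(seed)
    stats = np.array([_resample_mean(tree, rng) for _ in range(B)])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return BootstrapCI(
        point=float(records["correct"].mean()),
        lower=float(lo),
        upper=float(hi),
        level=level,
        B=B,
        seed=seed,
    )


def significant_difference(
    a_records: pd.DataFrame,
    b_records: pd.DataFrame,
    paired: bool = False,
    B: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, BootstrapCI, bool]:
    """Bootstrap CI for the accuracy difference a - b; significant when the
    CI excludes 0.

    Paired mode reuses one stream of cluster resampling indices for both
    record sets (they must share the bull/ejaculate structure); unpaired
    mode resamples the two sets independently.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(a_records) == 0 or len(b_records) == 0:
        raise ValueError("empty record set")
    tree_a = _cluster_tree(a_records)
    tree_b = _cluster_tree(b_records)
    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    if paired:
        if len(tree_a) != len(tree_b) or any(
            len(x) != len(y) for x, y in zip(tree_a, tree_b)
        ):
            raise ValueError("paired mode requires aligned cluster structures")
        for i in range(B):
            state = rng.bit_generator.state
            ma = _resample_mean(tree_a, rng)
            rng.bit_generator.state = state  # same cluster draws for both
            mb = _resample_mean(tree_b, rng)
            diffs[i] = ma - mb
    else:
        for i in range(B):
            diffs[i] = _resample_mean(tree_a, rng) - _resample_mean(tree_b, rng)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    diff = float(a_records["correct"].mean() - b_records["correct"].mean())
    ci = BootstrapCI(
        point=diff, lower=float(lo), upper=float(hi), level=level, B=B, seed=seed
    )
    return diff, ci, ci.excludes_zero


# ---------------------------------------------------------------------------
# generalization matrices


@dataclass
class GeneralizationMatrix:
    """Accuracies (and optional CIs) by train-domain x test-domain."""

    domains: tuple[str, ...]
    cells: dict[tuple[str, str], dict] = field(default_factory=dict)

    def accuracy(self, train_domain: str, test_domain: str) -> float:
        key = (train_domain, test_domain)
        if key not in self.cells:
            raise KeyError(f"no cell for train={train_domain} test={test_domain}")
        return self.cells[key]["accuracy"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tr, te), cell in sorted(self.cells.items()):
            row = {"train": tr, "test": te, "accuracy": cell["accuracy"]}
            ci = cell.get("ci")
            if ci is not None:
                row["ci_lower"], row["ci_upper"] = ci.lower, ci.upper
            rows.append(row)
        return pd.DataFrame(rows)


def gap(
    m: GeneralizationMatrix, train_domain: str, ref_test: str, alt_test: str
) -> float:
    """Signed accuracy gap in percentage points:
    100 * (acc(train->alt_test) - acc(train->ref_test))."""
    return 100.0 * (
        m.accuracy(train_domain, alt_test) - m.accuracy(train_domain, ref_test)
    )


def generalization_matrix_from_table(table: pd.DataFrame) -> GeneralizationMatrix:
    """Build a matrix from a (train, test, accuracy) table.

    Accuracies may be fractions in [0, 1] or percentages (detected by
    values > 1 and divided by 100).
    """
    doms = tuple(dict.fromkeys(table["train"]))
    gm = GeneralizationMatrix(domains=doms)
    for _, row in table.iterrows():
        acc = float(row["accuracy"])
        if acc > 1.0:
            acc /= 100.0
        gm.cells[(str(row["train"]), str(row["test"]))] = {"accuracy": acc}
    return gm


def generalization_run(
    pool_dataset,
    domain_key: str,
    cfg,
    split_seed: int = 0,
    seeds: tuple[int, ...] = (0,),
    bootstrap_B: int = 0,
    budget: int | None = None,
) -> GeneralizationMatrix:
    """Train one model per domain and evaluate on every domain's test split.

    The pool is partitioned by ``domain_key`` (e.g. condition or breed);
    within each domain a fixed stratified 80/10/10 split is drawn, the
    training budget is equalized across domains (the smallest domain's
    train size, class-stratified), one model per listed seed is trained,
    and every (train domain, test domain) cell holds the mean test accuracy
    over seeds. ``bootstrap_B > 0`` adds a hierarchical-bootstrap CI from
    the pooled per-image correctness records of the last seed.
    """
    from .sampling import SplitSpec, fraction_subsets, stratified_split
    from .training import train as train_model
    from .training import with_seed

    manifest = pool_dataset.manifest
    levels = [
        str(v) for v in pd.unique(manifest[domain_key].astype(str))
    ]
    if any((manifest[domain_key].astype(str) == lv).sum() == 0 for lv in levels):
        raise ValueError("every domain must have rows")
    splits = {}
    for lv in levels:
        dom_rows = manifest[manifest[domain_key].astype(str) == lv]
        tr, va, te = stratified_split(
            dom_rows, SplitSpec(stratify_keys=("label",), seed=split_seed)
        )
        splits[lv] = {"train": tr, "val": va, "test": te}
    min_train = min(len(s["train"]) for s in splits.values())
    if budget is not None:
        min_train = min(min_train, budget)
    gm = GeneralizationMatrix(domains=tuple(levels))
    for lv in levels:
        tr = splits[lv]["train"]
        frac = min(1.0, min_train / len(tr))
        if frac < 1.0:
            subs = fraction_subsets(tr, fractions=(frac,), rng_seed=split_seed)
            tr = subs[min(subs)]
        dtr = pool_dataset.subset(tr)
        dva = pool_dataset.subset(splits[lv]["val"])
        acc_by_test: dict[str, list[float]] = {t: [] for t in levels}
        records_by_test: dict[str, pd.DataFrame] = {}
        for seed in seeds:
            model = train_model((dtr, dva), with_seed(cfg, seed))
            for tv in levels:
                te = splits[tv]["test"]
                dte = pool_dataset.subset(te)
                from .training import predict

                preds, _ = predict(model, dte)
                correct = np.asarray(preds) == np.asarray(
                    te["label"].astype(str)
                )
                acc_by_test[tv].append(float(correct.mean()))
                records_by_test[tv] = pd.DataFrame(
                    {
                        "bull_id": np.asarray(te["bull_id"]),
                        "ejaculate_id": np.asarray(te["ejaculate_id"]),
                        "correct": correct,
                    }
                )
        for tv in levels:
            cell = {"accuracy": float(np.mean(acc_by_test[tv]))}
            if bootstrap_B > 0:
                cell["ci"] = hier_bootstrap(
                    records_by_test[tv], B=bootstrap_B, seed=split_seed
                )
            gm.cells[(lv, tv)] = cell
    return gm


# ---------------------------------------------------------------------------
# learning curves


def learning_curve(
    pool_dataset,
    cfg,
    fractions=(0.1, 0.2, 0.5, 1.0),
    group_key: str = "breed",
    seeds: tuple[int, ...] = (0, 1, 2),
    fold_seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-group-out x fraction x seed accuracy table.

    For every fold (one per held-out group) and every labeled-data fraction
    (nested subsets of the fold's training pool), one model per seed is
    trained and evaluated on the fold's fixed held-out test set. Returns
    one row per (fraction, fold, seed) with accuracy and macro-F1.
    """
    from .sampling import fraction_subsets, lobo_folds
    from .training import predict
    from .training import train as train_model
    from .training import with_seed

    folds = lobo_folds(pool_dataset.manifest, group_key=group_key, seed=fold_seed)
    rows = []
    for fold in folds:
        subsets = fraction_subsets(fold["train"], fractions, rng_seed=fold_seed)
        dva = pool_dataset.subset(fold["val"])
        dte = pool_dataset.subset(fold["test"])
        true = np.asarray(fold["test"]["label"].astype(str))
        for f, sub in subsets.items():
            dtr = pool_dataset.subset(sub)
            for seed in seeds:
                model = train_model((dtr, dva), with_seed(cfg, seed))
                preds, _ = predict(model, dte)
                res = evaluate_predictions(preds, true)
                rows.append(
                    {
                        "backbone": cfg.backbone_id,
                        "regime": cfg.regime,
                        "fraction": f,
                        "fold": fold["held_out"],
                        "seed": seed,
                        "n_train": len(sub),
                        "accuracy": res.accuracy,
                        "macro_f1": res.macro_f1,
                    }
                )
    return pd.DataFrame(rows)


def summarize_learning_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Mean over seeds, then mean and SD over folds, per fraction."""
    per_fold = (
        table.groupby(["fraction", "fold"], observed=True)["accuracy"]
        .mean()
        .reset_index()
    )
    out = (
        per_fold.groupby("fraction")["accuracy"]
        .agg(mean_accuracy="mean", sd_across_folds="std")
        .reset_index()
    )
    return out


def format_generalization_report(gm: GeneralizationMatrix) -> str:
    """Markdown report: train, test, accuracy % [95 % CI]. Pure function."""
    lines = ["| Train | Test | Accuracy (%) [95% CI] |", "| --- | --- | --- |"]
    for (tr, te), cell in sorted(gm.cells.items()):
        acc = 100.0 * cell["accuracy"]
        ci = cell.get("ci")
        ci_txt = (
            f" [{100 * ci.lower:.1f}-{100 * ci.upper:.1f}]" if ci is not None else ""
        )
        lines.append(f"| {tr} | {te} | {acc:.2f}{ci_txt} |")
    return "\n".join(lines) + "\n"
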