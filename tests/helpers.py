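"""Test-side oracles and simulators, independent of library internals."""

from __future__ import annotations

import numpy as np
import pandas as pd


def simulate_clustered_records(
    seed: int,
    n_bulls: int = 6,
    n_ejaculates: int = 3,
    n_images: int = 100,
    p: float = 0.8,
    bull_sd: float = 0.05,
) -> pd.DataFrame:
    """Per-image correctness records with a bull-level random effect.

    Each bull's accuracy is p + N(0, bull_sd) (clipped); images are
    Bernoulli draws at that per-bull rate, nested in ejaculates.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for b in range(n_bulls):
        pb = float(np.clip(p + rng.normal(0.0, bull_sd), 0.01, 0.99))
        for e in range(n_ejaculates):
            correct = (rng.random(n_images) < pb).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "bull_id": f"b{b}",
                        "ejaculate_id": f"b{b}e{e}",
                        "correct": correct,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def flat_bootstrap_ci(
    correct: np.ndarray, B: int, seed: int, level: float = 0.95
) -> tuple[float, float]:
    """Ordinary iid percentile bootstrap of a mean, as an oracle."""
    rng = np.random.default_rng(seed)
    n = len(correct)
    stats = np.array(
        [correct[rng.integers(0, n, size=n)].mean() for _ in range(B)]
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def brute_force_metrics(preds, labels, classes) -> dict:
    """Per-record recount of accuracy, P/R/F1, macro-F1 (no matrix algebra)."""
    n = len(labels)
    acc = sum(p == t for p, t in zip(preds, labels)) / n
    per_class = {}
    f1s = []
    for c in classes:
        tp = sum(1 for p, t in zip(preds, labels) if p == c and t == c)
        fp = sum(1 for p, t in zip(preds, labels) if p == c and t != c)
        fn = sum(1 for p, t in zip(preds, labels) if p != c and t == c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = (prec, rec, f1)
        f1s.append(f1)
    return {"accuracy": acc, "per_class": per_class, "macro_f1": np.mean(f1s)}
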