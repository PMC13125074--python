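"""Correspondence metrics between generated and original FNC vectors, and
paired model comparisons (Wilcoxon signed-rank with Bonferroni correction)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return np.nan
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


def reconstruction_metrics(
    generated: np.ndarray,
    original: np.ndarray,
    groups: np.ndarray | list | None = None,
    sample_ids: list | None = None,
) -> pd.DataFrame:
    """Per-pair Pearson r and MSE between generated and original vectors.

    Rows of ``generated`` and ``original`` are paired.  Pairs where either
    vector has zero variance get ``r = NaN`` and ``degenerate = True``
    rather than being dropped.  The frame carries one row per pair with
    columns ``sample_id, group, pearson_r, mse, degenerate``.
    """
    G = np.atleast_2d(np.asarray(generated, dtype=float))
    O = np.atleast_2d(np.asarray(original, dtype=float))
    if G.shape != O.shape:
        raise ValueError(f"paired arrays must share a shape: {G.shape} vs {O.shape}")
    n = G.shape[0]
    groups = ["all"] * n if groups is None else list(groups)
    sample_ids = list(range(n)) if sample_ids is None else list(sample_ids)
    rows = []
    for i in range(n):
        degenerate = G[i].std() == 0 or O[i].std() == 0
        rows.append({
            "sample_id": sample_ids[i],
            "group": groups[i],
            "pearson_r": np.nan if degenerate else _pearson(G[i], O[i]),
            "mse": float(np.mean((G[i] - O[i]) ** 2)),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def summarize_metrics(df: pd.DataFrame) -> pd.DataFrame:
    """Mean/median of r and MSE per group (degenerate pairs excluded from r)."""
    out = df.groupby("group").agg(
        n=("sample_id", "size"),
        mean_r=("pearson_r", "mean"),
        median_r=("pearson_r", "median"),
        mean_mse=("mse", "mean"),
        median_mse=("mse", "median"),
    )
    return out.reset_index()


def threshold_fractions(df: pd.DataFrame, thresholds=(0.6, 0.8)) -> dict[float, float]:
    """Fraction of pairs with Pearson r above each threshold."""
    r = df["pearson_r"].to_numpy()
    valid = ~np.isnan(r)
    return {t: float(np.mean(r[valid] > t)) if valid.any() else np.nan
            for t in thresholds}


@dataclass
class PairedComparison:
    name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    degenerate: bool
    n: int


def compare_models(
    metric_lists: dict[str, np.ndarray],
    reference: str | None = None,
    alternative: str = "two-sided",
) -> list[PairedComparison]:
    """Pairwise Wilcoxon signed-rank tests between methods' paired metrics.

    ``metric_lists`` maps method name -> per-seed (or per-subject) metric
    values, all the same length and paired by position.  When ``reference``
    is given, only reference-vs-other comparisons are run; otherwise all
    unordered pairs.  Raw p-values are Bonferroni-multiplied by the number
    of comparisons.  All-zero difference vectors are flagged degenerate and
    reported with p = 1.
    """
    names = list(metric_lists)
    if len(names) < 2:
        raise ValueError("need at least two methods")
    lengths = {len(v) for v in metric_lists.values()}
    if len(lengths) != 1:
        raise ValueError("all metric lists must be the same length")
    if reference is not None:
        pairs = [(reference, n) for n in names if n != reference]
    else:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = len(pairs)
    out = []
    for a, b in pairs:
        d = np.asarray(metric_lists[a], float) - np.asarray(metric_lists[b], float)
        if np.all(d == 0):
            out.append(PairedComparison(f"{a} vs {b}", 0.0, 1.0, 1.0, True, d.size))
            continue
        stat, p = stats.wilcoxon(d, alternative=alternative)
        out.append(PairedComparison(
            f"{a} vs {b}", float(stat), float(p), float(min(1.0, p * m)),
            False, d.size,
        ))
    return out
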