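"""Per-study differential expression: SAM relative-difference score.

The score is d_g = (mean_high - mean_low) / (se_g + s0), where se_g is the
two-sample pooled standard error of the mean difference and s0 a small
variance-stabilizing "fudge" constant that damps scores of low-variance
genes. Significance comes from label permutations whose null scores are
pooled across genes, so p-values far below 1/n_perm are resolvable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import StudyDataset

S0_PERCENTILE = 5.0  # default s0 = 5th percentile of the gene-wise SEs


def _group_arrays(ds: StudyDataset) -> tuple[np.ndarray, np.ndarray]:
    X = ds.matrix.to_numpy(dtype=float)
    labels = (ds.groups.to_numpy() == "high")
    return X[:, labels], X[:, ~labels]


def _pooled_se(x1: np.ndarray, x0: np.ndarray) -> np.ndarray:
    n1, n0 = x1.shape[1], x0.shape[1]
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    return np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))


def resolve_s0(se: np.ndarray, s0: float | str) -> float:
    if isinstance(s0, str):
        if s0 == "auto":
            return float(np.percentile(se, S0_PERCENTILE))
        if s0 == "tune":
            return tune_s0(se)
        raise ValueError(f"unknown s0 mode {s0!r}")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    return float(s0)


def tune_s0(se: np.ndarray, n_candidates: int = 21) -> float:
    """Pick s0 minimizing the spread of |d|'s scale across SE magnitude bins.

    A light version of the classic SAM tuning: candidates are percentiles of
    the SE distribution; for each, genes are binned into SE deciles and the
    coefficient of variation of the per-bin median |d|-denominator is
    minimized. Exposed behind ``s0="tune"``; the default remains the 5th
    percentile.
    """
    candidates = np.percentile(se, np.linspace(0, 100, n_candidates))
    order = np.argsort(se)
    bins = np.array_split(order, 10)
    best, best_cv = candidates[0], np.inf
    for s0 in candidates:
        scales = np.array([np.median(se[b] + s0) for b in bins if len(b)])
        cv = scales.std() / scales.mean() if scales.mean() > 0 else np.inf
        if cv < best_cv:
            best, best_cv = s0, cv
    return float(best)


def sam_statistics(ds: StudyDataset, s0: float | str = "auto") -> tuple[pd.DataFrame, float]:
    """Observed SAM statistics per gene plus the resolved s0.

    Returns a DataFrame indexed by gene with columns ``d``, ``mean_high``,
    ``mean_low``, ``se``.
    """
    x1, x0 = _group_arrays(ds)
    if x1.shape[1] < 2 or x0.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    se = _pooled_se(x1, x0)
    s0_val = resolve_s0(se, s0)
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m1 - m0) / (se + s0_val)
    stats = pd.DataFrame(
        {"d": d, "mean_high": m1, "mean_low": m0, "se": se}, index=ds.matrix.index
    )
    return stats, s0_val


def sam_scores(ds: StudyDataset, s0: float | str = "auto") -> pd.Series:
    """Gene -> relative-difference score d."""
    stats, _ = sam_statistics(ds, s0)
    return stats["d"]


def _permuted_abs_scores(
    X: np.ndarray, n1: int, n0: int, s0_val: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """|d*| for all genes x permutations, via matrix products.

    For each permutation an indicator column assigns n1 samples to "high";
    group means and variances for every gene come from two matmuls against
    X and X**2.
    """
    n = n1 + n0
    A = np.zeros((n, n_perm))
    for j in range(n_perm):
        A[rng.permutation(n)[:n1], j] = 1.0
    B = 1.0 - A

    X2 = X * X
    s1, s0_ = X @ A, X @ B
    ss1, ss0 = X2 @ A, X2 @ B
    m1, m0 = s1 / n1, s0_ / n0
    v1 = (ss1 - n1 * m1 * m1) / (n1 - 1)
    v0 = (ss0 - n0 * m0 * m0) / (n0 - 1)
    np.clip(v1, 0.0, None, out=v1)
    np.clip(v0, 0.0, None, out=v0)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m1 - m0) / (se + s0_val)
    return np.abs(d)


def sam_test(
    ds: StudyDataset,
    n_perm: int = 1000,
    s0: float | str = "auto",
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """SAM scores with pooled-permutation p-values.

    The null |d*| scores from all genes and all permutations form one pooled
    reference; p_g = (1 + #{|d*| >= |d_g|}) / (1 + n_perm * n_genes). The
    plus-one smoothing keeps p strictly positive so downstream log
    transforms are safe. Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stats, s0_val = sam_statistics(ds, s0)
    n_genes = stats.shape[0]
    if n_perm * n_genes == 0:
        raise ValueError("no permutations x genes to build a null")

    X = ds.matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null_abs = _permuted_abs_scores(X, ds.n_high, ds.n_low, s0_val, n_perm, rng)
    null_sorted = np.sort(null_abs, axis=None)
    n_null = null_sorted.size

    abs_d = np.abs(stats["d"].to_numpy())
    n_ge = n_null - np.searchsorted(null_sorted, abs_d, side="left")
    p = (1.0 + n_ge) / (1.0 + n_null)
    out = stats.copy()
    out["p"] = p
    return out, s0_val


def sam_permutation_p(
    ds: StudyDataset, n_perm: int = 1000, s0: float | str = "auto", seed: int = 0
) -> pd.Series:
    """Gene -> pooled-permutation p-value."""
    out, _ = sam_test(ds, n_perm=n_perm, s0=s0, seed=seed)
    return out["p"]
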