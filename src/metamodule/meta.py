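"""Gene-level meta-analysis across studies.

Two complementary combiners, mirroring standard expression meta-analysis
practice:

* Fisher's method: chi2 = -2 * sum(ln p_i) ~ chi2 with 2k df under the null,
  combining the per-study permutation p-values.
* Effect-size pooling: per-study standardized mean differences (Hedges' g)
  pooled by inverse variance, with Cochran's Q / I**2 gating between a
  fixed-effects and a DerSimonian–Laird random-effects model; the pooled
  z = SMD / SE gives a two-sided normal p-value.

Both p-value families are corrected by Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

HETEROGENEITY_ALPHA = 0.05  # Q-test p below this -> random effects
I2_THRESHOLD = 50.0  # percent; I^2 above this -> random effects


def fisher_combine(p_list) -> tuple[float, float]:
    """Fisher's combined statistic -2*sum(ln p) and its chi2_{2k} upper tail."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; smooth zeros before combining")
    stat = max(float(-2.0 * np.sum(np.log(p))), 0.0)
    return stat, float(stats.chi2.sf(stat, 2 * p.size))


def fisher_combine_matrix(p_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Fisher combination of a genes-by-studies p-value matrix."""
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim != 2 or p.shape[1] == 0:
        raise ValueError("need a genes x studies matrix")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum(axis=1)
    return stat, stats.chi2.sf(stat, 2 * p.shape[1])


def hedges_j(n_high: int, n_low: int) -> float:
    """Small-sample bias correction J = 1 - 3/(4*(n1+n2-2) - 1)."""
    df = n_high + n_low - 2
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def smd_per_study(n_high, n_low, mean_high, mean_low, sd_high, sd_low,
                  hedges: bool = True):
    """Standardized mean difference (Hedges' g) and its variance.

    Cohen's d = (mean_high - mean_low) / S_pooled; with ``hedges`` the
    correction J shrinks d to g = J*d and the variance
    (n1+n2)/(n1*n2) + d^2/(2*(n1+n2-2)) is scaled by J^2. Accepts scalars or
    aligned arrays; zero pooled SD raises for scalar input and yields NaN
    (flagged gene) for array input.
    """
    n1, n0 = int(n_high), int(n_low)
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 samples per group")
    mh = np.asarray(mean_high, dtype=float)
    ml = np.asarray(mean_low, dtype=float)
    s1 = np.asarray(sd_high, dtype=float)
    s0 = np.asarray(sd_low, dtype=float)
    df = n1 + n0 - 2
    sp = np.sqrt(((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / df)
    scalar = sp.ndim == 0
    if scalar and sp == 0:
        raise ValueError("zero pooled SD: SMD undefined for this gene")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sp > 0, (mh - ml) / np.where(sp > 0, sp, 1.0), np.nan)
    j = hedges_j(n1, n0) if hedges else 1.0
    g = j * d
    var = (j**2) * ((n1 + n0) / (n1 * n0) + d**2 / (2.0 * df))
    if scalar:
        return float(g), float(var)
    return g, var


def heterogeneity(smds, variances) -> tuple[float, float]:
    """Cochran's Q and I^2 (percent) for one gene across k >= 2 studies."""
    g = np.asarray(smds, dtype=float)
    v = np.asarray(variances, dtype=float)
    if g.size < 2:
        raise ValueError("need k >= 2 studies")
    if np.any(v <= 0):
        raise ValueError("all variances must be positive")
    w = 1.0 / v
    gw = np.sum(w * g) / np.sum(w)
    q = float(np.sum(w * (g - gw) ** 2))
    i2 = 0.0 if q == 0 else max(0.0, (q - (g.size - 1)) / q) * 100.0
    return q, i2


def pool_effect(smds, variances, q: float | None = None, i2: float | None = None):
    """Pool per-study SMDs; heterogeneity decides fixed vs random effects.

    Random effects (DerSimonian–Laird tau^2) when the Q test is significant
    at 0.05 or I^2 > 50%, else fixed effects with inverse-variance weights.
    Returns (model, pooled_smd, pooled_se, z, es_p).
    """
    g = np.asarray(smds, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q is None or i2 is None:
        q, i2 = heterogeneity(g, v)
    k = g.size
    q_p = float(stats.chi2.sf(q, k - 1))
    random_model = (q_p < HETEROGENEITY_ALPHA) or (i2 > I2_THRESHOLD)

    w = 1.0 / v
    if random_model:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * g) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / se
    es_p = float(2.0 * stats.norm.sf(abs(z)))
    return ("random" if random_model else "fixed"), pooled, se, z, max(es_p, np.nextafter(0, 1))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving on the input index."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def study_group_stats(ds) -> dict:
    """Per-group means/SDs and sizes needed for SMD computation."""
    X = ds.matrix
    hi, lo = ds.high_samples, ds.low_samples
    return {
        "n_high": len(hi),
        "n_low": len(lo),
        "mean_high": X[hi].mean(axis=1).to_numpy(),
        "mean_low": X[lo].mean(axis=1).to_numpy(),
        "sd_high": X[hi].std(axis=1, ddof=1).to_numpy(),
        "sd_low": X[lo].std(axis=1, ddof=1).to_numpy(),
        "genes": list(X.index),
    }


def meta_analyze(
    sam_results: dict[str, pd.DataFrame],
    datasets: list,
    hedges: bool = True,
) -> pd.DataFrame:
    """Merge per-study SAM p-values and SMDs into one per-gene meta table.

    ``sam_results`` maps study_id to the DataFrame from :func:`sam.sam_test`
    (columns d, p, mean_high, mean_low, se). Genes are the intersection of
    all studies. Columns include per-study p/smd/var plus Fisher and
    effect-size summaries with BH q-values.
    """
    if not sam_results:
        raise ValueError("no studies")
    by_id = {ds.study_id: ds for ds in datasets}
    study_ids = [ds.study_id for ds in datasets if ds.study_id in sam_results]
    if len(study_ids) != len(sam_results):
        raise ValueError("sam_results and datasets disagree on study IDs")

    genes = None
    for sid in study_ids:
        idx = set(sam_results[sid].index)
        genes = idx if genes is None else genes & idx
    genes = sorted(genes)
    k = len(study_ids)

    P = np.empty((len(genes), k))
    G = np.empty_like(P)
    V = np.empty_like(P)
    for j, sid in enumerate(study_ids):
        res = sam_results[sid].loc[genes]
        ds = by_id[sid]
        P[:, j] = res["p"].to_numpy()
        st = study_group_stats(ds)
        gene_pos = pd.Index(st["genes"]).get_indexer(genes)
        g, v = smd_per_study(
            st["n_high"], st["n_low"],
            st["mean_high"][gene_pos], st["mean_low"][gene_pos],
            st["sd_high"][gene_pos], st["sd_low"][gene_pos],
            hedges=hedges,
        )
        G[:, j], V[:, j] = g, v

    fisher_stat, fisher_p = fisher_combine_matrix(P)
    fisher_p = np.maximum(fisher_p, np.nextafter(0, 1))

    rows = []
    for i in range(len(genes)):
        gi, vi = G[i], V[i]
        ok = np.isfinite(gi) & np.isfinite(vi) & (vi > 0)
        if ok.sum() >= 2:
            q, i2 = heterogeneity(gi[ok], vi[ok])
            model, pooled, se, z, es_p = pool_effect(gi[ok], vi[ok], q, i2)
        else:
            q = i2 = np.nan
            model, pooled, se, z, es_p = "fixed", np.nan, np.nan, np.nan, np.nan
        rows.append((q, i2, model, pooled, se, z, es_p))
    het = pd.DataFrame(
        rows, columns=["Q", "I2", "model", "pooled_smd", "pooled_se", "z", "es_p"],
        index=genes,
    )

    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for j, sid in enumerate(study_ids):
        out[f"p_{sid}"] = P[:, j]
        out[f"smd_{sid}"] = G[:, j]
        out[f"var_{sid}"] = V[:, j]
    out["k"] = k
    out["fisher_stat"] = fisher_stat
    out["fisher_p"] = fisher_p
    out["fisher_q"] = bh_fdr(out["fisher_p"].to_numpy())
    out = out.join(het)
    valid = out["es_p"].notna()
    out["es_q"] = np.nan
    if valid.any():
        out.loc[valid, "es_q"] = bh_fdr(out.loc[valid, "es_p"].to_numpy())
    return out


def forest_data(meta_table: pd.DataFrame, gene: str, study_ids: list[str]) -> pd.DataFrame:
    """Per-study SMD with 95% CI plus the pooled row, for forest plotting."""
    if gene not in meta_table.index:
        raise KeyError(f"gene {gene!r} not in meta table")
    row = meta_table.loc[gene]
    recs = []
    for sid in study_ids:
        g = row[f"smd_{sid}"]
        se = np.sqrt(row[f"var_{sid}"])
        recs.append((sid, g, g - 1.96 * se, g + 1.96 * se))
    pooled, se = row["pooled_smd"], row["pooled_se"]
    recs.append((f"pooled ({row['model']})", pooled, pooled - 1.96 * se, pooled + 1.96 * se))
    return pd.DataFrame(recs, columns=["study", "smd", "ci_low", "ci_high"])
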