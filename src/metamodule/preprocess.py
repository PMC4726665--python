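"""Probe-to-gene collapsing and sample outlier screening.

Operates on already-normalized log2 expression matrices. Probe collapsing
keeps, for each gene symbol, the probe with the largest interquartile range
across samples; outlier screening projects samples onto the first two
principal components and removes those far from the center in robust-z
(median/MAD) units.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import StudyDataset

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # makes MAD consistent with the SD under normality


def iqr(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Interquartile range with linear-interpolation (type-7) quantiles."""
    q75, q25 = np.percentile(values, [75, 25], axis=axis)
    return q75 - q25


def collapse_probes(matrix: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-by-sample matrix to gene-by-sample by maximal IQR.

    For genes measured by several probes, the retained row is the probe with
    the largest IQR across all samples; ties go to the lexicographically
    smaller probe ID. Probes absent from ``probe_map`` are dropped; mapped
    probes absent from the matrix are ignored with a warning.
    """
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    if not probe_map:
        raise ValueError("probe map is empty")

    missing = sorted(set(probe_map) - set(matrix.index))
    if missing:
        logger.warning("%d mapped probes not present in the matrix (e.g. %s)",
                       len(missing), missing[:3])

    probes = sorted(set(probe_map) & set(matrix.index))
    if not probes:
        raise ValueError("probe map covers no probe in the matrix")

    sub = matrix.loc[probes]
    probe_iqr = pd.Series(iqr(sub.to_numpy(), axis=1), index=sub.index)
    gene_of = pd.Series({p: probe_map[p] for p in probes})
    # probes are sorted, so idxmax resolves IQR ties to the smallest probe ID
    best = probe_iqr.groupby(gene_of).idxmax()
    out = sub.loc[best.to_numpy()]
    out.index = pd.Index(best.index, name="gene")
    return out.sort_index()


def screen_outliers(
    ds: StudyDataset, z_cut: float = 5.0
) -> tuple[StudyDataset, list[str]]:
    """Remove samples lying > ``z_cut`` robust-z units from the center on PC1 or PC2.

    Robust z is |x - median| / (1.4826 * MAD) per component; samples at zero
    deviation score 0 even when the MAD is 0. A removal that would leave a
    phenotype group with fewer than 2 samples is suppressed and the sample
    retained with a warning.
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    n = ds.matrix.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples to screen outliers")

    X = ds.matrix.to_numpy().T  # samples x genes
    X = X - X.mean(axis=0)
    n_comp = min(2, n - 1, X.shape[1])
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    z = np.zeros_like(scores)
    for j in range(scores.shape[1]):
        col = scores[:, j]
        dev = np.abs(col - np.median(col))
        scale = MAD_SCALE * np.median(dev)
        with np.errstate(divide="ignore", invalid="ignore"):
            zj = np.where(dev == 0, 0.0, dev / scale if scale > 0 else np.inf)
        z[:, j] = zj
    worst = z.max(axis=1)

    samples = list(ds.matrix.columns)
    candidates = [s for s, w in zip(samples, worst) if w > z_cut]
    # remove worst-first so the group-size floor binds deterministically
    candidates.sort(key=lambda s: -worst[samples.index(s)])

    counts = {"high": ds.n_high, "low": ds.n_low}
    removed: list[str] = []
    for s in candidates:
        g = ds.groups[s]
        if counts[g] - 1 < 2:
            logger.warning("%s: outlier %s retained (group '%s' would drop below 2)",
                           ds.study_id, s, g)
            continue
        removed.append(s)
        counts[g] -= 1

    kept = [s for s in samples if s not in set(removed)]
    return ds.subset_samples(kept), removed


def common_genes(datasets: list[StudyDataset]) -> list[str]:
    """Sorted intersection of the studies' post-collapse gene universes."""
    if not datasets:
        raise ValueError("no datasets")
    universe = set(datasets[0].matrix.index)
    for ds in datasets[1:]:
        universe &= set(ds.matrix.index)
    return sorted(universe)


def restrict_to_common_genes(datasets: list[StudyDataset]) -> list[StudyDataset]:
    genes = common_genes(datasets)
    return [
        StudyDataset(ds.study_id, ds.matrix.loc[genes], ds.groups, ds.platform_tag)
        for ds in datasets
    ]
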