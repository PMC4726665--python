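"""Downstream interpretation: pathway enrichment, candidate selection, GWAS replication.

Enrichment is a one-sided hypergeometric test of module genes against gene
sets (e.g. KEGG pathways from a GMT file) with Bonferroni correction over
the sets tested; candidate genes must pass both meta-analysis p-value
gates and sit inside the consensus module; replication maps each gene to
the most significant SNP among its assigned SNPs in a GWAS association
table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Module

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


def hypergeom_enrich(
    query: set[str],
    gene_sets: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P(X >= k) with X ~ Hypergeom(N background, m set genes, n query
    genes); sets and the query are restricted to the background first.
    Bonferroni ``p_adj = min(1, p * n_sets_tested)``. Rows sorted by p.
    """
    if not query:
        raise ValueError("empty query gene set")
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    if not background:
        raise ValueError("empty background universe")

    outside = query - background
    if outside:
        logger.warning("%d query genes outside the background dropped (e.g. %s)",
                       len(outside), sorted(outside)[:3])
    q = query & background
    if not q:
        raise ValueError("no query genes inside the background")

    N, n = len(background), len(q)
    rows = []
    for name, members in gene_sets.items():
        mset = members & background
        m = len(mset)
        overlap = sorted(q & mset)
        k = len(overlap)
        # P(X >= k); sf(k-1) is the exact upper tail of the pmf summation
        p = float(stats.hypergeom.sf(k - 1, N, m, n)) if k > 0 else 1.0
        rows.append((name, ",".join(overlap), k, m, n, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_genes", "k_overlap", "m_set",
                 "n_query", "N_background", "p"],
    )
    out["p_adj"] = np.minimum(1.0, out["p"] * len(gene_sets))
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def select_candidates(
    meta_table: pd.DataFrame, module: Module, alpha: float = ALPHA_DEFAULT
) -> list[str]:
    """Genes passing all three gates, sorted by Fisher combined p.

    (1) effect-size meta-analysis p < alpha, (2) Fisher's combined p <
    alpha, (3) membership in the consensus module.
    """
    if not module.nodes:
        return []
    in_module = meta_table.index.isin(module.nodes)
    passing = meta_table[
        in_module
        & (meta_table["es_p"] < alpha)
        & (meta_table["fisher_p"] < alpha)
    ]
    return list(passing.sort_values("fisher_p", kind="mergesort").index)


def gene_level_gwas_p(assocs: pd.DataFrame, genes: list[str],
                      alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Most-significant-SNP gene-level p per trait, with an association flag.

    ``assocs`` columns: snp_id, gene, trait, p. A gene's p for a trait is
    the minimum over its SNPs; genes with no SNPs get NaN (not 1.0). The
    gene is flagged associated when min p <= alpha for at least one trait.
    """
    if assocs.empty:
        raise ValueError("empty SNP association table")
    required = {"snp_id", "gene", "trait", "p"}
    if not required <= set(assocs.columns):
        raise ValueError(f"association table needs columns {sorted(required)}")
    if (assocs["p"] <= 0).any() or (assocs["p"] > 1).any():
        raise ValueError("SNP p-values must lie in (0, 1]")

    sub = assocs[assocs["gene"].isin(genes)]
    wide = sub.pivot_table(index="gene", columns="trait", values="p", aggfunc="min")
    wide = wide.reindex(genes)
    wide.columns.name = None
    wide["associated"] = (wide.le(alpha)).any(axis=1) & wide.notna().any(axis=1)
    return wide
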