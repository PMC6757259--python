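"""Per-gene-set summaries linking heteromer proportion to CRISPR score.

Each gene set is summarised by its paralog-pair content (a pair belongs to a
set when both members do, by default), the proportion of those pairs that
heteromerize, the mean CS of member paralog genes split by heteromer status,
and a two-sided Welch t-test for the heteromer vs non-heteromer difference.
Across sets, the heteromer proportion is correlated (Spearman) with the mean
paralog CS.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .robustness import StatResult

logger = logging.getLogger(__name__)

__all__ = ["summarize_sets", "per_set_difference_test", "proportion_cs_correlation"]


def per_set_difference_test(cs_het: pd.Series, cs_non: pd.Series) -> tuple[float, float]:
    """Two-sided Welch t-test between heteromer and non-heteromer member CS.

    Returns (t, p); NA when either subgroup has fewer than two genes.
    """
    if len(cs_het) < 2 or len(cs_non) < 2:
        return np.nan, np.nan
    t, p = stats.ttest_ind(cs_het, cs_non, equal_var=False)
    return float(t), float(p)


def summarize_sets(
    sets: pd.DataFrame,
    pairs: pd.DataFrame,
    gene_cs: pd.Series,
    min_pairs: int = 10,
    membership: str = "both",
) -> pd.DataFrame:
    """One summary row per gene set meeting the minimum pair count.

    ``sets`` is a (set_id, gene_id) table; ``pairs`` needs gene_a, gene_b and
    heteromer columns. ``membership='both'`` counts a pair only when both
    members are set members (conservative); ``'either'`` when at least one is.
    CS averages are over member paralog genes.
    """
    if membership not in ("both", "either"):
        raise ValueError("membership must be 'both' or 'either'")
    rows = []
    members_by_set = sets.groupby("set_id")["gene_id"].agg(set)
    for sid, members in members_by_set.items():
        in_a = pairs["gene_a"].isin(members)
        in_b = pairs["gene_b"].isin(members)
        sel = (in_a & in_b) if membership == "both" else (in_a | in_b)
        sub = pairs.loc[sel]
        if len(sub) == 0:
            logger.info("gene set %s has no member pairs; skipped", sid)
            continue
        if len(sub) < min_pairs:
            continue
        het_genes = set(sub.loc[sub["heteromer"], "gene_a"]) | set(
            sub.loc[sub["heteromer"], "gene_b"])
        non_genes = (set(sub.loc[~sub["heteromer"], "gene_a"])
                     | set(sub.loc[~sub["heteromer"], "gene_b"])) - het_genes
        cs_het = gene_cs.loc[gene_cs.index.intersection(sorted(het_genes))].dropna()
        cs_non = gene_cs.loc[gene_cs.index.intersection(sorted(non_genes))].dropna()
        cs_all = pd.concat([cs_het, cs_non])
        t, p = per_set_difference_test(cs_het, cs_non)
        rows.append(
            {
                "set_id": sid,
                "n_pairs": len(sub),
                "n_heteromer_pairs": int(sub["heteromer"].sum()),
                "proportion_heteromer": float(sub["heteromer"].mean()),
                "mean_cs_paralogs": float(cs_all.mean()) if len(cs_all) >= 2 else np.nan,
                "mean_cs_heteromer": float(cs_het.mean()) if len(cs_het) >= 2 else np.nan,
                "mean_cs_non_heteromer": float(cs_non.mean()) if len(cs_non) >= 2 else np.nan,
                "t_het_vs_non": t,
                "p_het_vs_non": p,
            }
        )
    return pd.DataFrame(rows)


def proportion_cs_correlation(summaries: pd.DataFrame, min_sets: int = 5) -> StatResult:
    """Spearman correlation across sets of heteromer proportion vs mean CS."""
    df = summaries.dropna(subset=["proportion_heteromer", "mean_cs_paralogs"])
    if len(df) < min_sets:
        raise ValueError(f"need at least {min_sets} summarised sets, have {len(df)}")
    if df["proportion_heteromer"].nunique() < 2:
        return StatResult("proportion_cs_spearman", np.nan, np.nan,
                          n={"sets": len(df)}, extra={"flag": "constant-proportion"})
    rho, p = stats.spearmanr(df["proportion_heteromer"], df["mean_cs_paralogs"])
    return StatResult("proportion_cs_spearman", float(rho), float(p), n={"sets": len(df)})
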