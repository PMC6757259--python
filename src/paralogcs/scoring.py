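"""Guide-level read counts -> per-gene, per-cell-line CRISPR scores (CS).

The scoring chain is: drop multi-hit guides, library-size normalise each
sample, average replicates, take the log2 fold change final/T0 with a
pseudocount, summarise guides per gene, and z-score the pooled per-dataset
values. Depletion of a guide gives a negative fold change, so a lower CS
means a more deleterious loss-of-function with no sign flip needed.

Heterogeneous datasets are put on a common distribution by quantile
normalization over shared genes (column-wise, each cell-line column mapped
onto the mean of sorted columns; ties get the mean of the reference values
they span) and merged by gene identifier with mean aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .config import ScoringConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CrisprScoreTable",
    "filter_multi_hit_guides",
    "normalize_counts",
    "guide_log_fold_change",
    "gene_scores",
    "zscore",
    "quantile_normalize",
    "merge_and_aggregate",
    "score_dataset",
    "score_study",
]


@dataclass
class CrisprScoreTable:
    """Gene x cell-line CRISPR scores (z-units, lower = more deleterious)."""

    data: pd.DataFrame
    dataset: str
    provenance: str = "raw"

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise ValueError("duplicated gene in CRISPR score table")


def filter_multi_hit_guides(library: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only guides that target exactly one gene.

    Returns the filtered library and a removal report with, per gene, the
    number of guides removed and retained. Genes left with zero guides are
    reported (``n_kept == 0``) and will drop out of scoring.
    """
    targets = library["gene_ids"].str.split(";")
    n_targets = targets.str.len()
    keep = n_targets == 1
    removed = library.loc[~keep]
    kept = library.loc[keep].copy()
    kept["gene_id"] = targets[keep].str[0]

    rem_counts: dict[str, int] = {}
    for tl in targets[~keep]:
        for g in tl:
            rem_counts[g] = rem_counts.get(g, 0) + 1
    kept_counts = kept["gene_id"].value_counts().to_dict()
    all_genes = sorted(set(rem_counts) | set(kept_counts))
    report = pd.DataFrame(
        {
            "gene_id": all_genes,
            "n_removed": [rem_counts.get(g, 0) for g in all_genes],
            "n_kept": [kept_counts.get(g, 0) for g in all_genes],
        }
    )
    lost = report.loc[report["n_kept"] == 0, "gene_id"]
    if len(lost):
        logger.warning("%d genes lost all guides to multi-hit filtering", len(lost))
    logger.info("removed %d of %d guides as multi-hit", len(removed), len(library))
    return kept, report


def normalize_counts(counts: pd.DataFrame, config: ScoringConfig | None = None) -> pd.DataFrame:
    """Scale every sample column to a common read total (library-size norm)."""
    config = config or ScoringConfig()
    config.validate()
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero count column(s): {list(zero)}")
    return counts * (config.scale_total / totals)


def guide_log_fold_change(
    norm_counts: pd.DataFrame, sample_map: pd.DataFrame, config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Per-guide, per-cell-line log2 fold change final/T0.

    Replicate columns are averaged before the ratio; the pseudocount is added
    to both numerator and denominator. Depletion gives negative values.
    """
    config = config or ScoringConfig()
    out = {}
    for line, grp in sample_map.groupby("cell_line"):
        t0_cols = grp.loc[grp["timepoint"] == "T0", "sample"].tolist()
        fin_cols = grp.loc[grp["timepoint"] == "final", "sample"].tolist()
        if not t0_cols or not fin_cols:
            raise ValueError(f"cell line {line!r} lacks a T0 or final sample")
        t0 = norm_counts[t0_cols].mean(axis=1)
        fin = norm_counts[fin_cols].mean(axis=1)
        out[line] = np.log2((fin + config.pseudocount) / (t0 + config.pseudocount))
    return pd.DataFrame(out)


def gene_scores(
    guide_fc: pd.DataFrame, guide_map: pd.Series, config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Summarise guide fold changes per gene (mean by default)."""
    config = config or ScoringConfig()
    config.validate()
    missing = guide_fc.index.difference(guide_map.index)
    if len(missing):
        raise ValueError(f"{len(missing)} guides lack a gene mapping")
    gene = guide_map.loc[guide_fc.index]
    grouped = guide_fc.groupby(gene.to_numpy())
    table = grouped.median() if config.gene_summary == "median" else grouped.mean()
    table.index.name = "gene_id"
    return table


def zscore(table: pd.DataFrame, config: ScoringConfig | None = None,
           dataset: str = "", provenance: str = "raw") -> CrisprScoreTable:
    """Pool all values of a gene x cell-line table and z-score them.

    Population standard deviation by default (``zscore_ddof = 0``); constant
    input is rejected. Ranks are preserved (affine transform).
    """
    config = config or ScoringConfig()
    vals = table.to_numpy(float)
    flat = vals[~np.isnan(vals)]
    if flat.size < 2 or np.unique(flat).size < 2:
        raise ValueError("z-score requires at least two distinct values")
    mu = flat.mean()
    sd = flat.std(ddof=config.zscore_ddof)
    return CrisprScoreTable(data=(table - mu) / sd, dataset=dataset, provenance=provenance)


def _qn_reference(columns: List[np.ndarray]) -> np.ndarray:
    return np.mean([np.sort(c) for c in columns], axis=0)


def _qn_map_column(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="mergesort")
    out = np.empty_like(ref, dtype=float)
    sorted_vals = col[order]
    # tied entries receive the mean of the reference values their ranks span
    i = 0
    n = len(col)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        out[order[i:j + 1]] = ref[i:j + 1].mean()
        i = j + 1
    return out


def quantile_normalize(tables: Sequence[pd.DataFrame]) -> List[pd.DataFrame]:
    """Map every cell-line column of every table onto a common distribution.

    Tables are first restricted to their shared genes; the reference is the
    across-column mean of sorted values. After normalization the sorted value
    vector of every column is identical (exactly), and reapplying the
    operation is a no-op.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to quantile normalize")
    shared = tables[0].index
    for t in tables[1:]:
        shared = shared.intersection(t.index)
    if len(shared) == 0:
        raise ValueError("tables share no genes")
    shared = shared.sort_values()
    restricted = [t.loc[shared] for t in tables]
    cols = [t[c].to_numpy(float) for t in restricted for c in t.columns]
    ref = _qn_reference(cols)
    out = []
    for t in restricted:
        mapped = {c: _qn_map_column(t[c].to_numpy(float), ref) for c in t.columns}
        out.append(pd.DataFrame(mapped, index=shared))
    return out


def merge_and_aggregate(
    tables: Sequence[pd.DataFrame], method: str = "mean"
) -> tuple[pd.Series, pd.DataFrame]:
    """Join per-dataset tables by gene and aggregate across all cell lines.

    Returns ``(aggregated per-gene CS, merged per-cell-line table)``. Genes
    absent from some dataset are aggregated over their available cell lines
    and logged.
    """
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    merged = pd.concat(list(tables), axis=1, join="outer")
    incomplete = merged.index[merged.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("%d genes missing from some dataset; aggregated over available lines",
                       len(incomplete))
    agg = merged.median(axis=1) if method == "median" else merged.mean(axis=1)
    agg.name = "cs"
    return agg, merged


def score_dataset(
    library: pd.DataFrame,
    counts: pd.DataFrame,
    sample_map: pd.DataFrame,
    config: ScoringConfig | None = None,
    dataset: str = "",
) -> tuple[CrisprScoreTable, pd.DataFrame]:
    """Full scoring chain for one dataset; returns (CS table, removal report)."""
    config = config or ScoringConfig()
    filtered, report = filter_multi_hit_guides(library)
    norm = normalize_counts(counts.loc[filtered["guide_id"]], config)
    fc = guide_log_fold_change(norm, sample_map, config)
    genes = gene_scores(fc, filtered.set_index("guide_id")["gene_id"], config)
    return zscore(genes, config, dataset=dataset, provenance="raw"), report


def score_study(study, config: ScoringConfig | None = None, filter_multi_hit: bool = True):
    """Score every screen of a synthetic study and merge the datasets.

    Returns a dict with per-dataset CS tables, the quantile-normalized
    tables, the merged per-cell-line table and the aggregated per-gene CS.
    ``filter_multi_hit=False`` scores multi-hit guides by attributing them to
    their first-listed target (the biased variant the multi-hit filter
    exists to avoid).
    """
    config = config or ScoringConfig()
    tables, reports = {}, {}
    for scr in study.screens:
        if filter_multi_hit:
            cs, rep = score_dataset(scr.library, scr.counts, scr.samples, config, scr.name)
        else:
            lib = scr.library.copy()
            lib["gene_id"] = lib["gene_ids"].str.split(";").str[0]
            norm = normalize_counts(scr.counts, config)
            fc = guide_log_fold_change(norm, scr.samples, config)
            genes = gene_scores(fc, lib.set_index("guide_id")["gene_id"], config)
            cs = zscore(genes, config, dataset=scr.name)
            rep = pd.DataFrame(columns=["gene_id", "n_removed", "n_kept"])
        tables[scr.name] = cs
        reports[scr.name] = rep
    if len(tables) > 1:
        qn = quantile_normalize([t.data for t in tables.values()])
    else:
        qn = [t.data for t in tables.values()]
    agg, merged = merge_and_aggregate(qn)
    return {
        "per_dataset": tables,
        "reports": reports,
        "quantile_normalized": {name: q for name, q in zip(tables, qn)},
        "merged": merged,
        "aggregated": agg,
    }
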