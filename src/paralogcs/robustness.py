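"""Comparison battery for robustness analyses.

Group comparisons (Mann-Whitney U with exact enumeration at small n),
contingency analyses (Fisher's exact test, ancestral-homomer table), partial
Spearman correlations between CRISPR score, expression and interaction
degree, expression-binned class comparisons, and the 2-D robustness
landscape of CS over (log2 expression, log2 degree) with per-class kernel
densities.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "LandscapeGrid",
    "mann_whitney_u",
    "compare_classes",
    "cellwise_means",
    "fishers_exact_2x2",
    "ancestral_homomer_contingency",
    "partial_spearman",
    "expression_bin_comparison",
    "build_landscape",
    "class_density",
    "age_stratified_comparison",
]


@dataclass
class StatResult:
    """One statistical comparison: statistic, p-value and bookkeeping."""

    name: str
    value: float
    p_value: float
    n: Dict[str, int] = field(default_factory=dict)
    groups: tuple = ()
    covariates: tuple = ()
    extra: Dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "statistic": self.name,
            "value": self.value,
            "p_value": self.p_value,
            "groups": "|".join(map(str, self.groups)),
            "covariates": "|".join(map(str, self.covariates)),
        }
        for k, v in self.n.items():
            row[f"n_{k}"] = v
        row.update(self.extra)
        return row


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (i, j) with a_i > b_j, ties counting 1/2."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates every way of splitting the pooled values into groups of the
    observed sizes (handles ties naturally) and doubles the smaller tail
    probability, capping at 1.
    """
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)
    ranks = stats.rankdata(pooled)
    const = na * (na + 1) / 2.0
    us = np.array([
        ranks[list(idx)].sum() - const for idx in itertools.combinations(range(n), na)
    ])
    total = len(us)
    eps = 1e-9
    p_le = np.sum(us <= u_obs + eps) / total
    p_ge = np.sum(us >= u_obs - eps) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(a: Sequence[float], b: Sequence[float], exact_max_n: int = 12) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration when the pooled sample size is at most
    ``exact_max_n``; otherwise the normal approximation with tie correction
    and a 0.5 continuity correction.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    na, nb = len(a), len(b)
    if na + nb <= exact_max_n:
        p = _exact_mwu_p(a, b, u)
        method = "exact"
    else:
        mean_u = na * nb / 2.0
        pooled = np.concatenate([a, b])
        n = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var_u = na * nb / 12.0 * (n + 1 - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (u - mean_u - np.sign(u - mean_u) * 0.5) / math.sqrt(var_u)
            p = 2.0 * stats.norm.sf(abs(z))
        method = "normal"
    return StatResult(
        name="mann_whitney_u",
        value=float(u),
        p_value=float(min(p, 1.0)),
        n={"a": na, "b": nb},
        extra={"median_a": float(np.median(a)), "median_b": float(np.median(b)),
               "method": method},
    )


def compare_classes(
    cs: pd.DataFrame | pd.Series,
    labels: pd.Series,
    pairings: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Mann-Whitney comparisons of CS between label groups, per dataset.

    ``cs`` is either a per-gene Series (one dataset) or a DataFrame whose
    columns are datasets of per-gene aggregated CS. Direction is recorded as
    the difference of medians (group a minus group b).
    """
    if isinstance(cs, pd.Series):
        cs = cs.to_frame(cs.name or "cs")
    rows = []
    for dataset in cs.columns:
        vec = cs[dataset].dropna()
        lab = labels.reindex(vec.index)
        for ga, gb in pairings:
            va = vec[lab == ga]
            vb = vec[lab == gb]
            if len(va) < 2 or len(vb) < 2:
                raise ValueError(f"label {ga if len(va) < 2 else gb!r} has <2 scored genes")
            res = mann_whitney_u(va, vb)
            rows.append(
                {
                    "dataset": dataset,
                    "group_a": ga,
                    "group_b": gb,
                    "U": res.value,
                    "p_value": res.p_value,
                    "n_a": res.n["a"],
                    "n_b": res.n["b"],
                    "median_a": res.extra["median_a"],
                    "median_b": res.extra["median_b"],
                    "median_diff": res.extra["median_a"] - res.extra["median_b"],
                }
            )
    return pd.DataFrame(rows)


def cellwise_means(cs: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Mean CS per class per cell line (one row per cell line).

    Classes absent from a cell line are skipped (NaN) and logged.
    """
    lab = labels.reindex(cs.index)
    out = {}
    for klass, idx in lab.groupby(lab).groups.items():
        out[klass] = cs.loc[idx].mean(axis=0)
    df = pd.DataFrame(out)
    if df.isna().any().any():
        logger.warning("some classes have no scored genes in some cell lines")
    df.index.name = "cell_line"
    return df


def diagonal_fractions(means: pd.DataFrame, class_x: str, class_y: str) -> Dict[str, float]:
    """Fraction of cell lines above/on/below the y = x diagonal for two classes."""
    x = means[class_x]
    y = means[class_y]
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    return {
        "above": float((y[ok] > x[ok]).sum() / n),
        "on": float((y[ok] == x[ok]).sum() / n),
        "below": float((y[ok] < x[ok]).sum() / n),
        "n_lines": n,
    }


# ---------------------------------------------------------------------------
# Fisher's exact test


def fishers_exact_2x2(table: Sequence[Sequence[float]]) -> StatResult:
    """Sample odds ratio (ad)/(bc) and two-sided Fisher exact p.

    The two-sided p follows the probability-mass convention (sum of
    hypergeometric probabilities of tables at most as probable as the
    observed one). Zero margins give p = 1 with an undefined odds ratio flag;
    a zero cell yields an infinite or zero odds ratio, flagged.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValueError("need a non-negative integer 2x2 table")
    a, b, c, d = t.ravel()
    flag = ""
    if min(a + b, c + d, a + c, b + d) == 0:
        return StatResult("fisher_exact", np.nan, 1.0,
                          n={"total": int(t.sum())}, extra={"flag": "zero-margin"})
    if b * c == 0 and a * d > 0:
        oratio, flag = np.inf, "infinite-odds-ratio"
    elif a * d == 0 and b * c > 0:
        oratio, flag = 0.0, "zero-odds-ratio"
    else:
        oratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(np.rint(t).astype(int), alternative="two-sided")
    return StatResult(
        "fisher_exact", float(oratio), float(p),
        n={"total": int(t.sum())}, extra={"flag": flag},
    )


def ancestral_homomer_contingency(pairs: pd.DataFrame) -> tuple[pd.DataFrame, StatResult]:
    """Association between both-member homomerization and heteromer status.

    Rows: both members homomer vs neither member homomer (pairs with exactly
    one homomeric member are excluded); columns: heteromer vs not. The odds
    ratio estimates how much more likely heteromers of paralogs derive from
    ancestral homomers.
    """
    need = {"homomer_a", "homomer_b", "heteromer"}
    if not need.issubset(pairs.columns):
        raise ValueError(f"pairs table must have columns {sorted(need)}")
    both = pairs["homomer_a"].astype(bool) & pairs["homomer_b"].astype(bool)
    neither = ~pairs["homomer_a"].astype(bool) & ~pairs["homomer_b"].astype(bool)
    het = pairs["heteromer"].astype(bool)
    table = pd.DataFrame(
        {
            "heteromer": [int((both & het).sum()), int((neither & het).sum())],
            "not_heteromer": [int((both & ~het).sum()), int((neither & ~het).sum())],
        },
        index=["both_homomer", "neither_homomer"],
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        logger.warning("empty stratum in ancestral-homomer contingency table")
    res = fishers_exact_2x2(table.to_numpy())
    res.extra["n_excluded_mixed"] = int(len(pairs) - both.sum() - neither.sum())
    return table, res


# ---------------------------------------------------------------------------
# partial Spearman correlation


def partial_spearman(
    x: Sequence[float], y: Sequence[float], covariates: pd.DataFrame | None = None
) -> StatResult:
    """Spearman correlation of x and y controlling for covariates.

    All variables are rank-transformed (average ranks on ties); the partial
    correlation comes from the inverse correlation matrix of the ranks, and
    the p-value from the t approximation with n - 2 - k degrees of freedom.
    With no covariates this reduces exactly to the ordinary Spearman rho.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    cov = pd.DataFrame(index=range(len(x))) if covariates is None else pd.DataFrame(covariates)
    mat = np.column_stack([x, y] + [cov[c].to_numpy(float) for c in cov.columns])
    ok = ~np.isnan(mat).any(axis=1)
    mat = mat[ok]
    n, k = len(mat), mat.shape[1] - 2
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, have {n}")
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)
    if (ranks.std(axis=0) == 0).any():
        raise ValueError("constant variable in partial Spearman")
    corr = np.corrcoef(ranks, rowvar=False)
    if abs(corr[0, 1]) >= 1.0 - 1e-12:
        # perfectly (anti)correlated ranks: partial correlation degenerates
        rho = float(np.sign(corr[0, 1]))
    else:
        prec = np.linalg.pinv(corr)
        rho = -prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1])
        rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult(
        "partial_spearman", rho, float(p), n={"obs": n},
        covariates=tuple(cov.columns),
    )


# ---------------------------------------------------------------------------
# expression bins


def expression_bin_comparison(
    cs: pd.Series,
    expression: pd.Series,
    labels: pd.Series,
    class_a: str = "paralog",
    class_b: str = "singleton",
    n_bins: int = 5,
) -> pd.DataFrame:
    """Per-expression-bin class comparison of CS.

    Expression is cut into ``n_bins`` equal-count bins; within each bin the
    median CS of each class is reported with a two-sided Mann-Whitney test
    between the two classes. Bins where a class is empty give an NA row.
    """
    common = cs.index.intersection(expression.index)
    cs = cs.loc[common]
    expr = expression.loc[common]
    lab = labels.reindex(common)
    bins = pd.qcut(expr.rank(method="first"), n_bins, labels=False)
    rows = []
    for i in range(n_bins):
        sel = bins == i
        va = cs[sel & (lab == class_a)]
        vb = cs[sel & (lab == class_b)]
        row = {
            "bin": i,
            "n_bin": int(sel.sum()),
            f"median_{class_a}": float(va.median()) if len(va) else np.nan,
            f"median_{class_b}": float(vb.median()) if len(vb) else np.nan,
        }
        if len(va) and len(vb):
            res = mann_whitney_u(va, vb)
            row["U"], row["p_value"] = res.value, res.p_value
        else:
            row["U"], row["p_value"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# robustness landscape


@dataclass
class LandscapeGrid:
    """2-D binned CS landscape over (log2 expression, log2 degree)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_cs: np.ndarray  # shape (nx, ny); NaN where count < min_count
    counts: np.ndarray
    min_count: int

    def cell_means_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = []
        for i, xv in enumerate(xc):
            for j, yv in enumerate(yc):
                rows.append((i, j, xv, yv, self.mean_cs[i, j], self.counts[i, j]))
        return pd.DataFrame(rows, columns=["ix", "iy", "x", "y", "mean_cs", "count"])


def build_landscape(
    cs: pd.Series,
    expression: pd.Series,
    degree: pd.Series,
    n_bins: int = 20,
    min_count: int = 5,
    smooth_sigma: float = 0.0,
    percentile_window: tuple[float, float] = (1.0, 99.0),
) -> LandscapeGrid:
    """Mean CS binned on log2(expression) x log2(degree + 1).

    The grid spans the 1st-99th percentile window by default; cells with
    fewer than ``min_count`` genes are masked. ``smooth_sigma > 0`` applies a
    Gaussian smoothing of the cell means (NaN-aware).
    """
    common = cs.index.intersection(expression.index).intersection(degree.index)
    if len(common) == 0:
        raise ValueError("no genes shared between CS, expression and degree")
    c = cs.loc[common].to_numpy(float)
    x = np.log2(expression.loc[common].to_numpy(float) + 2.0**-10)
    y = np.log2(degree.loc[common].to_numpy(float) + 1.0)
    lo, hi = percentile_window
    x_edges = np.linspace(*np.percentile(x, [lo, hi]), n_bins + 1)
    y_edges = np.linspace(*np.percentile(y, [lo, hi]), n_bins + 1)
    sums, _, _, _ = stats.binned_statistic_2d(x, y, c, statistic="sum",
                                              bins=[x_edges, y_edges])
    counts, _, _, _ = stats.binned_statistic_2d(x, y, c, statistic="count",
                                                bins=[x_edges, y_edges])
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    if smooth_sigma > 0:
        filled = np.where(counts > 0, means, 0.0)
        weight = (counts > 0).astype(float)
        means = gaussian_filter(filled, smooth_sigma) / np.maximum(
            gaussian_filter(weight, smooth_sigma), 1e-12
        )
    means = np.where(counts >= min_count, means, np.nan)
    return LandscapeGrid(x_edges=x_edges, y_edges=y_edges, mean_cs=means,
                         counts=counts.astype(int), min_count=min_count)


def landscape_trend(grid: LandscapeGrid) -> StatResult:
    """Spearman correlation of cell mean CS with position along the grid
    diagonal (sum of bin indices); negative means CS drops toward the
    high-expression, high-degree corner."""
    df = grid.cell_means_frame().dropna(subset=["mean_cs"])
    df = df[df["count"] >= grid.min_count]
    rho, p = stats.spearmanr(df["ix"] + df["iy"], df["mean_cs"])
    return StatResult("landscape_trend", float(rho), float(p), n={"cells": len(df)})


def class_density(
    genes: Iterable[str],
    expression: pd.Series,
    degree: pd.Series,
    grid: LandscapeGrid,
) -> np.ndarray:
    """Gaussian product-kernel density of a gene class on the landscape grid.

    Bandwidth by Scott's rule; the returned grid is normalized so that its
    integral over the evaluation window is 1.
    """
    genes = [g for g in genes if g in expression.index and g in degree.index]
    if len(genes) < 5:
        raise ValueError("need at least 5 genes for a class density")
    x = np.log2(expression.loc[genes].to_numpy(float) + 2.0**-10)
    y = np.log2(degree.loc[genes].to_numpy(float) + 1.0)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance class; density undefined")
    kde = stats.gaussian_kde(np.vstack([x, y]))  # Scott's rule default
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    cell = (xc[1] - xc[0]) * (yc[1] - yc[0])
    total = dens.sum() * cell
    return dens / total


# ---------------------------------------------------------------------------
# age stratification


def age_stratified_comparison(
    pairs: pd.DataFrame,
    cs_per_line: pd.DataFrame,
    essential: pd.Series,
    min_pairs: int = 2,
) -> dict:
    """Age-group analyses of paralog pairs.

    (i) Mann-Whitney comparison of the age-group distribution (ordinal) of
    paralog genes labelled essential vs non-essential. (ii) Per age group,
    the median CS (median across cell lines per gene) of heteromer vs
    non-heteromer paralog genes. Pairs with dS > 5 are excluded from
    dS-based quantities upstream; age groups with fewer than ``min_pairs``
    pairs are skipped.
    """
    gene_age = {}
    gene_het = {}
    for _, pr in pairs.iterrows():
        for g in (pr["gene_a"], pr["gene_b"]):
            gene_age[g] = pr["age_group"]
            gene_het[g] = bool(pr["heteromer"])
    age = pd.Series(gene_age, name="age_group")
    het = pd.Series(gene_het, name="heteromer")

    ess = essential.reindex(age.index)
    a = age[ess == "essential"]
    b = age[ess == "non-essential"]
    age_test = mann_whitney_u(a, b) if len(a) and len(b) else None

    med_cs = cs_per_line.median(axis=1)
    rows = []
    for grp, members in age.groupby(age).groups.items():
        sub = pd.Index(members).intersection(med_cs.index)
        if len(sub) < 2 * min_pairs:
            logger.info("age group %s skipped (too few pairs)", grp)
            continue
        hsel = het.reindex(sub).fillna(False).astype(bool)
        vh = med_cs.loc[sub[hsel]]
        vn = med_cs.loc[sub[~hsel]]
        rows.append(
            {
                "age_group": grp,
                "n_heteromer": len(vh),
                "n_non_heteromer": len(vn),
                "median_cs_heteromer": float(vh.median()) if len(vh) else np.nan,
                "median_cs_non_heteromer": float(vn.median()) if len(vn) else np.nan,
            }
        )
    return {"age_essentiality": age_test, "per_age_group": pd.DataFrame(rows)}
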