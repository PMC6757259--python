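"""Expression-asymmetry analyses of paralog pairs.

For a pair with expression e1 >= e2, P1 is the higher-expressed member and
the asymmetry is A = (P1 - P2)/(P1 + P2) in [0, 1]. The analyses relate A to
the CRISPR-score difference dCS = CS(P1) - CS(P2) within and across cell
lines, quantify pair coexpression and post-transcriptional coregulation, and
correlate heteromer interface size with pair deleteriousness.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .robustness import StatResult, mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = [
    "asymmetry",
    "assign_p1_p2",
    "pair_line_table",
    "p1_p2_cs_comparison",
    "binned_p1_gt_p2_probability",
    "asym_deltaCS_relationship",
    "per_pair_asym_cs_correlation",
    "coexpression",
    "protein_coregulation",
    "interface_cs_correlation",
]


def asymmetry(e1, e2):
    """Expression asymmetry |e1 - e2| / (e1 + e2); NaN when both are zero.

    Symmetric in its arguments and invariant to scaling both expressions by
    the same positive constant.
    """
    e1 = np.asarray(e1, float)
    e2 = np.asarray(e2, float)
    if (e1 < 0).any() or (e2 < 0).any():
        raise ValueError("expressions must be non-negative")
    total = e1 + e2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, np.abs(e1 - e2) / np.where(total > 0, total, 1.0), np.nan)
    return out if out.ndim else float(out)


def assign_p1_p2(pairs: pd.DataFrame, expression: pd.Series) -> pd.DataFrame:
    """Orient each pair so that P1 is the higher-expressed member.

    ``expression`` is the expression in the chosen context (one cell line or
    an across-line mean). Ties are broken lexicographically by gene id and
    flagged; pairs with missing expression are skipped and logged.
    """
    rows = []
    skipped = 0
    for pid, pr in pairs.iterrows():
        a, b = pr["gene_a"], pr["gene_b"]
        if a not in expression.index or b not in expression.index or \
                pd.isna(expression[a]) or pd.isna(expression[b]):
            skipped += 1
            continue
        ea, eb = float(expression[a]), float(expression[b])
        tie = ea == eb
        if ea > eb or (tie and a < b):
            p1, p2, e1, e2 = a, b, ea, eb
        else:
            p1, p2, e1, e2 = b, a, eb, ea
        rows.append({"pair_id": pid, "p1": p1, "p2": p2, "expr_p1": e1, "expr_p2": e2,
                     "asymmetry": asymmetry(e1, e2), "tie": tie})
    if skipped:
        logger.warning("%d pairs skipped for missing expression", skipped)
    return pd.DataFrame(rows).set_index("pair_id") if rows else pd.DataFrame(
        columns=["p1", "p2", "expr_p1", "expr_p2", "asymmetry", "tie"])


def pair_line_table(
    pairs: pd.DataFrame, expression: pd.DataFrame, cs: pd.DataFrame
) -> pd.DataFrame:
    """Long table of per-(pair, cell line) orientation, asymmetry and dCS.

    Orientation is per cell line (P1 = member with higher expression in that
    line, ties lexicographic). Columns: pair_id, cell_line, p1, p2,
    asymmetry, cs_p1, cs_p2, delta_cs.
    """
    lines = [c for c in expression.columns if c in cs.columns]
    frames = []
    for line in lines:
        orient = assign_p1_p2(pairs, expression[line])
        if not len(orient):
            continue
        cs_line = cs[line]
        ok = orient["p1"].isin(cs_line.dropna().index) & orient["p2"].isin(cs_line.dropna().index)
        o = orient[ok]
        cs1 = cs_line.loc[o["p1"]].to_numpy()
        cs2 = cs_line.loc[o["p2"]].to_numpy()
        frames.append(pd.DataFrame({
            "pair_id": o.index,
            "cell_line": line,
            "p1": o["p1"].to_numpy(),
            "p2": o["p2"].to_numpy(),
            "asymmetry": o["asymmetry"].to_numpy(),
            "cs_p1": cs1,
            "cs_p2": cs2,
            "delta_cs": cs1 - cs2,
        }))
    if not frames:
        return pd.DataFrame(columns=["pair_id", "cell_line", "p1", "p2", "asymmetry",
                                     "cs_p1", "cs_p2", "delta_cs"])
    return pd.concat(frames, ignore_index=True)


def p1_p2_cs_comparison(table: pd.DataFrame) -> StatResult:
    """Pooled comparison of CS(P1) vs CS(P2) over (pair, cell line) points.

    Two-sided Mann-Whitney; degenerate inputs (fewer than two observations
    per side) are flagged rather than tested.
    """
    a = table["cs_p1"].dropna()
    b = table["cs_p2"].dropna()
    if len(a) < 2 or len(b) < 2:
        return StatResult("p1_p2_mwu", np.nan, np.nan, n={"a": len(a), "b": len(b)},
                          extra={"flag": "degenerate"})
    return mann_whitney_u(a, b)


def binned_p1_gt_p2_probability(table: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Probability that loss of P1 is less deleterious than loss of P2,
    per equal-count bin of expression asymmetry.

    Each (pair, cell line) observation contributes once; CS ties count 0.5.
    Also reports the mean dCS per bin. Under no coupling the probability sits
    near 0.5 in every bin.
    """
    t = table.dropna(subset=["asymmetry", "delta_cs"]).copy()
    if len(t) < n_bins:
        raise ValueError("need at least n_bins observations")
    t["bin"] = pd.qcut(t["asymmetry"].rank(method="first"), n_bins, labels=False)
    rows = []
    for i, grp in t.groupby("bin"):
        gt = (grp["cs_p1"] > grp["cs_p2"]).sum() + 0.5 * (grp["cs_p1"] == grp["cs_p2"]).sum()
        rows.append({
            "bin": int(i),
            "n": len(grp),
            "mean_asymmetry": float(grp["asymmetry"].mean()),
            "p_cs_p1_gt_p2": float(gt / len(grp)),
            "mean_delta_cs": float(grp["delta_cs"].mean()),
        })
    return pd.DataFrame(rows)


def asym_deltaCS_relationship(
    table: pd.DataFrame, n_bins: int = 10
) -> pd.DataFrame:
    """Across-pair relationship between asymmetry and dCS: equal-count bins of
    asymmetry with the mean dCS and its normal-approximation 95% CI."""
    t = table.dropna(subset=["asymmetry", "delta_cs"]).copy()
    if len(t) < n_bins:
        raise ValueError("need at least n_bins observations")
    t["bin"] = pd.qcut(t["asymmetry"].rank(method="first"), n_bins, labels=False)
    rows = []
    for i, grp in t.groupby("bin"):
        m = grp["delta_cs"].mean()
        sem = grp["delta_cs"].std(ddof=1) / math.sqrt(len(grp)) if len(grp) > 1 else np.nan
        rows.append({
            "bin": int(i),
            "n": len(grp),
            "mean_asymmetry": float(grp["asymmetry"].mean()),
            "mean_delta_cs": float(m),
            "ci_low": float(m - 1.96 * sem) if sem == sem else np.nan,
            "ci_high": float(m + 1.96 * sem) if sem == sem else np.nan,
        })
    return pd.DataFrame(rows)


def per_pair_asym_cs_correlation(table: pd.DataFrame, min_lines: int = 4) -> pd.Series:
    """Per-pair Spearman correlation of asymmetry with dCS across cell lines.

    Pairs observed in fewer than ``min_lines`` cell lines, or with constant
    asymmetry, yield NaN and are excluded from the returned Series.
    """
    out = {}
    for pid, grp in table.groupby("pair_id"):
        g = grp.dropna(subset=["asymmetry", "delta_cs"])
        if len(g) < min_lines:
            continue
        if g["asymmetry"].nunique() < 2 or g["delta_cs"].nunique() < 2:
            out[pid] = np.nan
            continue
        rho, _ = stats.spearmanr(g["asymmetry"], g["delta_cs"])
        out[pid] = float(rho)
    s = pd.Series(out, name="rs_asym_dcs", dtype=float)
    return s.dropna()


def compare_correlation_distributions(
    per_pair: pd.Series, heteromer: pd.Series
) -> StatResult:
    """Mann-Whitney comparison of per-pair correlation distributions,
    heteromer vs non-heteromer pairs."""
    het_mask = heteromer.reindex(per_pair.index).fillna(False).astype(bool)
    a = per_pair[het_mask]
    b = per_pair[~het_mask]
    res = mann_whitney_u(a, b)
    res.groups = ("heteromer", "non-heteromer")
    return res


def coexpression(pairs: pd.DataFrame, mrna: pd.DataFrame, min_lines: int = 4) -> pd.Series:
    """Per-pair Pearson correlation of members' z-scored mRNA across lines.

    Per-gene z-scoring across cell lines leaves the Pearson correlation
    unchanged (affine invariance) but matches the convention of reporting
    coexpression on normalized profiles. Zero-variance members give NaN.
    """
    out = {}
    for pid, pr in pairs.iterrows():
        a, b = pr["gene_a"], pr["gene_b"]
        if a not in mrna.index or b not in mrna.index:
            continue
        xa = mrna.loc[a].to_numpy(float)
        xb = mrna.loc[b].to_numpy(float)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() < min_lines:
            continue
        xa, xb = xa[ok], xb[ok]
        if xa.std() == 0 or xb.std() == 0:
            out[pid] = np.nan
            continue
        za = (xa - xa.mean()) / xa.std()
        zb = (xb - xb.mean()) / xb.std()
        out[pid] = float(np.corrcoef(za, zb)[0, 1])
    return pd.Series(out, name="coexpression_r", dtype=float)


def _partial_pearson(x: np.ndarray, y: np.ndarray, covs: np.ndarray) -> float:
    """Partial Pearson correlation of x and y given covariate columns."""
    if covs.size == 0:
        return float(np.corrcoef(x, y)[0, 1])
    X = np.column_stack([np.ones(len(x)), covs])
    beta_x, *_ = np.linalg.lstsq(X, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    rx = x - X @ beta_x
    ry = y - X @ beta_y
    # residuals at numerical-noise level mean the covariates explain
    # everything; the partial correlation is undefined
    if rx.std() <= 1e-8 * max(x.std(), 1e-12) or ry.std() <= 1e-8 * max(y.std(), 1e-12):
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def protein_coregulation(
    pairs: pd.DataFrame,
    protein: pd.DataFrame,
    mrna: pd.DataFrame,
    min_lines: int = 6,
) -> pd.Series:
    """Per-pair partial Pearson correlation of members' z-scored protein
    levels, controlling for both members' mRNA levels across shared lines.

    A positive residual correlation for heteromers indicates
    post-transcriptional coregulation beyond what mRNA explains. Pairs with
    fewer than ``min_lines`` shared cell lines give NaN (excluded).
    """
    lines = [c for c in protein.columns if c in mrna.columns]
    out = {}
    for pid, pr in pairs.iterrows():
        a, b = pr["gene_a"], pr["gene_b"]
        if a not in protein.index or b not in protein.index:
            continue
        pa = protein.loc[a, lines].to_numpy(float)
        pb = protein.loc[b, lines].to_numpy(float)
        ma = mrna.loc[a, lines].to_numpy(float)
        mb = mrna.loc[b, lines].to_numpy(float)
        ok = ~(np.isnan(pa) | np.isnan(pb) | np.isnan(ma) | np.isnan(mb))
        if ok.sum() < min_lines:
            continue
        pa, pb, ma, mb = pa[ok], pb[ok], ma[ok], mb[ok]
        if pa.std() == 0 or pb.std() == 0:
            out[pid] = np.nan
            continue
        za = (pa - pa.mean()) / pa.std()
        zb = (pb - pb.mean()) / pb.std()
        out[pid] = _partial_pearson(za, zb, np.column_stack([ma, mb]))
    return pd.Series(out, name="protein_partial_r", dtype=float).dropna()


def interface_cs_correlation(
    pairs: pd.DataFrame, gene_cs: pd.Series, min_pairs: int = 5
) -> StatResult:
    """Spearman correlation between heteromer interface size and pair CS.

    Pair CS is the unweighted mean of the two members' aggregated CS. A
    negative correlation means larger interfaces (stronger interactions)
    associate with more deleterious loss-of-function.
    """
    het = pairs.dropna(subset=["interface_size"])
    rows = []
    for pid, pr in het.iterrows():
        a, b = pr["gene_a"], pr["gene_b"]
        if a in gene_cs.index and b in gene_cs.index:
            rows.append((pr["interface_size"], (gene_cs[a] + gene_cs[b]) / 2.0))
    if len(rows) < min_pairs:
        raise ValueError(
            f"only {len(rows)} heteromer pairs with interface data; need >= {min_pairs}"
        )
    arr = np.asarray(rows, float)
    rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
    return StatResult("interface_cs_spearman", float(rho), float(p), n={"pairs": len(rows)})
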