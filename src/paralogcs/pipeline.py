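"""End-to-end orchestration: simulate -> score -> classify -> stats ->
asymmetry -> model -> gene sets, with per-stage caching and a run manifest.

Each stage writes its outputs as TSV under ``<outdir>/<stage>/`` along with a
``_complete.json`` marker holding the stage hash (config section + upstream
hashes). Re-running with an unchanged config skips completed stages; changing
a config section invalidates that stage and everything downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymmetry as asym
from . import deleteriousness as dm
from . import gene_classes as gc
from . import genesets as gs
from . import robustness as rb
from . import scoring as sc
from .config import ScoringConfig, SimulationConfig, config_hash
from .simulate import generate_study, read_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "render_report", "STAGES"]

STAGES = ("simulate", "score", "classify", "stats", "asymmetry", "model", "genesets")



def _stage_hash(name: str, config: SimulationConfig, upstream: list[str]) -> str:
    blob = json.dumps([name, config.to_dict(), upstream], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _is_complete(stage_dir: Path, h: str) -> bool:
    marker = stage_dir / "_complete.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("hash") == h
    except json.JSONDecodeError:
        return False


def _mark_complete(stage_dir: Path, h: str, files: list[str]) -> None:
    (stage_dir / "_complete.json").write_text(
        json.dumps({"hash": h, "files": sorted(files)}, indent=2, sort_keys=True)
    )


def _tsv(df, path: Path, index=True):
    df.to_csv(path, sep="\t", index=index)
    return path.name


def run_pipeline(
    config: SimulationConfig,
    outdir,
    scoring: ScoringConfig | None = None,
    force: bool = False,
) -> dict:
    """Run all stages in dependency order; returns the run manifest."""
    scoring = scoring or ScoringConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": int(config.seed),
        "stages": {},
        "files": {},
    }
    upstream: list[str] = []
    study = None
    results: dict = {}

    for stage in STAGES:
        h = _stage_hash(stage, config, upstream)
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        t0 = time.perf_counter()
        cached = _is_complete(stage_dir, h) and not force
        if cached:
            logger.info("stage %s: cache hit (%s)", stage, h)
        else:
            try:
                _run_stage(stage, stage_dir, config, scoring, results)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
            files = [p.name for p in stage_dir.iterdir() if p.name != "_complete.json"]
            _mark_complete(stage_dir, h, files)
        if stage == "simulate" and "study" not in results:
            results["study"] = read_dataset(stage_dir)
        if stage == "score" and "scores" not in results:
            results["scores"] = _load_scores(stage_dir)
        if stage == "classify" and "classes" not in results:
            results["classes"] = _load_classes(stage_dir)
        wall = time.perf_counter() - t0
        files = json.loads((stage_dir / "_complete.json").read_text())["files"]
        manifest["stages"][stage] = {"hash": h, "cached": cached, "wall_time_s": round(wall, 3)}
        manifest["files"][stage] = files
        upstream.append(h)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage, stage_dir, config, scoring, results):
    if stage == "simulate":
        study = generate_study(config)
        write_dataset(study, stage_dir)
        results["study"] = study
    elif stage == "score":
        _stage_score(stage_dir, results["study"], scoring)
        results["scores"] = _load_scores(stage_dir)
    elif stage == "classify":
        _stage_classify(stage_dir, results["study"])
        results["classes"] = _load_classes(stage_dir)
    elif stage == "stats":
        _stage_stats(stage_dir, config, results)
    elif stage == "asymmetry":
        _stage_asymmetry(stage_dir, results)
    elif stage == "model":
        _stage_model(stage_dir, config, results)
    elif stage == "genesets":
        _stage_genesets(stage_dir, results)


# --------------------------------------------------------------- score stage


def _stage_score(stage_dir: Path, study, scoring: ScoringConfig) -> None:
    res = sc.score_study(study, scoring)
    for name, table in res["per_dataset"].items():
        _tsv(table.data, stage_dir / f"cs_{name}.tsv")
        _tsv(res["reports"][name], stage_dir / f"removal_report_{name}.tsv", index=False)
    _tsv(res["merged"], stage_dir / "cs_merged.tsv")
    _tsv(res["aggregated"].to_frame(), stage_dir / "cs_aggregated.tsv")


def _load_scores(stage_dir: Path) -> dict:
    merged = pd.read_csv(stage_dir / "cs_merged.tsv", sep="\t", index_col=0)
    agg = pd.read_csv(stage_dir / "cs_aggregated.tsv", sep="\t", index_col=0)["cs"]
    return {"merged": merged, "aggregated": agg}


# ------------------------------------------------------------ classify stage


def _stage_classify(stage_dir: Path, study) -> None:
    lengths = study.catalog["protein_length"]
    singletons = gc.classify_singletons(study.hits, lengths)
    ssd = study.pairs.loc[study.pairs["origin"].isin(["SSD", "both"]), ["gene_a", "gene_b"]]
    wgd = study.pairs.loc[study.pairs["origin"].isin(["WGD", "both"]), ["gene_a", "gene_b"]]
    pair_reg, labels = gc.build_pair_registry(
        ssd, wgd, singletons=singletons, all_genes=study.catalog.index
    )
    pair_reg.index = study.pairs.index  # registry preserves pair order by construction

    ess = gc.classify_essential(
        [study.essential_refs["essential_ref1"], study.essential_refs["essential_ref2"]],
        [study.essential_refs["nonessential_ref1"], study.essential_refs["nonessential_ref2"]],
        study.catalog.index,
    )

    flags = {}
    degrees = {}
    homomers = {}
    for source in sorted(study.ppi["source"].unique()):
        edges = study.ppi[study.ppi["source"] == source]
        for mode in ("all", "direct"):
            filtered = gc.filter_ppi(edges, mode=mode)
            hom, het = gc.call_homomers_heteromers(filtered, study.pairs)
            flags[(source, mode)] = het
            homomers[(source, mode)] = hom
            degrees[(source, mode)] = gc.ppi_degree(filtered)

    sources = sorted({s for s, _ in flags})
    merged_all = gc.merge_sources(flags[(sources[0], "all")], flags[(sources[1], "all")])
    merged_direct = gc.merge_sources(flags[(sources[0], "direct")],
                                     flags[(sources[1], "direct")])

    pairs_out = study.pairs[["gene_a", "gene_b", "origin", "ds", "age_group",
                             "interface_size"]].copy()
    for (source, mode), het in flags.items():
        pairs_out[f"heteromer_{source}_{mode}"] = het.to_numpy()
    pairs_out["heteromer_merged_all"] = merged_all.to_numpy()
    pairs_out["heteromer_merged_direct"] = merged_direct.to_numpy()
    hom_ref = homomers[(sources[0], "all")]
    pairs_out["homomer_a"] = pairs_out["gene_a"].isin(hom_ref)
    pairs_out["homomer_b"] = pairs_out["gene_b"].isin(hom_ref)

    catalog_out = pd.DataFrame(index=study.catalog.index)
    catalog_out["class"] = labels.reindex(catalog_out.index)
    catalog_out["essential"] = ess.reindex(catalog_out.index)
    deg = degrees[(sources[0], "all")]
    catalog_out["ppi_degree_all"] = deg.reindex(catalog_out.index).fillna(0).astype(int)
    deg_d = degrees[(sources[0], "direct")]
    catalog_out["ppi_degree_direct"] = deg_d.reindex(catalog_out.index).fillna(0).astype(int)
    catalog_out["homomer"] = catalog_out.index.isin(hom_ref)

    _tsv(pairs_out, stage_dir / "pairs_classified.tsv")
    _tsv(catalog_out, stage_dir / "catalog_classified.tsv")


def _load_classes(stage_dir: Path) -> dict:
    return {
        "pairs": pd.read_csv(stage_dir / "pairs_classified.tsv", sep="\t", index_col=0),
        "catalog": pd.read_csv(stage_dir / "catalog_classified.tsv", sep="\t", index_col=0),
    }


def _gene_labels(classes: dict) -> pd.Series:
    """Per-gene labels: singleton / unclassified / heteromer / non-heteromer
    (paralog genes split by the single-source all-PPI heteromer flag)."""
    catalog = classes["catalog"]
    pairs = classes["pairs"]
    het_col = [c for c in pairs.columns if c.startswith("heteromer_db_a_all")]
    hetflag = pairs[het_col[0]] if het_col else pairs["heteromer_merged_all"]
    het_genes = set(pairs.loc[hetflag.astype(bool), "gene_a"]) | set(
        pairs.loc[hetflag.astype(bool), "gene_b"])
    labels = catalog["class"].copy()
    is_par = labels == "paralog"
    labels[is_par & labels.index.isin(het_genes)] = "heteromer"
    labels[is_par & ~labels.index.isin(het_genes)] = "non-heteromer"
    return labels


# --------------------------------------------------------------- stats stage


def _stage_stats(stage_dir: Path, config: SimulationConfig, results: dict) -> None:
    study = results["study"]
    scores = results["scores"]
    classes = results["classes"]
    catalog = classes["catalog"]
    agg = scores["aggregated"]
    merged = scores["merged"]
    labels = _gene_labels(classes)
    class3 = catalog["class"]

    ds_cols = {s.name: [c for c in s.cell_lines if c in merged.columns]
               for s in study.screens}
    cs_by_ds = pd.DataFrame({name: merged[cols].mean(axis=1)
                             for name, cols in ds_cols.items()})

    class_pairs = [("paralog", "singleton"), ("paralog", "unclassified")]
    het_pairs = [("heteromer", "non-heteromer")]
    # heteromer+homomer vs homomer-only among homomeric paralog genes
    hom = catalog["homomer"].astype(bool)
    hom_labels = pd.Series(pd.NA, index=catalog.index, dtype=object)
    hom_labels[hom & (labels == "heteromer")] = "heteromer+homomer"
    hom_labels[hom & (labels == "non-heteromer")] = "homomer-only"
    frames = [
        rb.compare_classes(cs_by_ds, class3, class_pairs),
        rb.compare_classes(cs_by_ds, labels, het_pairs),
        rb.compare_classes(agg.rename("aggregated"), class3, class_pairs),
        rb.compare_classes(agg.rename("aggregated"), labels, het_pairs),
    ]
    if (hom_labels == "heteromer+homomer").sum() >= 2 and \
            (hom_labels == "homomer-only").sum() >= 2:
        frames.append(rb.compare_classes(agg.rename("aggregated"), hom_labels,
                                         [("heteromer+homomer", "homomer-only")]))
    comp = pd.concat(frames, ignore_index=True)
    _tsv(comp, stage_dir / "class_comparisons.tsv", index=False)

    means = rb.cellwise_means(merged, class3)
    _tsv(means, stage_dir / "cellwise_class_means.tsv")
    diag = rb.diagonal_fractions(means, "singleton", "paralog")
    (stage_dir / "diagonal_summary.json").write_text(json.dumps(diag, indent=2, sort_keys=True))

    pairs = classes["pairs"]
    het_col = "heteromer_db_a_all" if "heteromer_db_a_all" in pairs.columns \
        else "heteromer_merged_all"
    ctab, fisher = rb.ancestral_homomer_contingency(
        pairs.rename(columns={het_col: "heteromer"}))
    _tsv(ctab, stage_dir / "ancestral_homomer_table.tsv")
    _tsv(pd.DataFrame([fisher.as_row()]), stage_dir / "ancestral_homomer_test.tsv", index=False)

    # partial Spearman battery: CS ~ heteromer status | {none, expr, degree, both}
    par_genes = labels.index[(labels == "heteromer") | (labels == "non-heteromer")]
    mean_expr = np.log2(study.mrna.mean(axis=1) + 2.0**-10)
    degree = np.log2(catalog["ppi_degree_all"] + 1.0)
    base = pd.DataFrame({
        "cs": agg.reindex(par_genes),
        "het": (labels.reindex(par_genes) == "heteromer").astype(float),
        "expr": mean_expr.reindex(par_genes),
        "deg": degree.reindex(par_genes),
    }).dropna()
    rows = []
    for ctl_name, ctl in [("none", []), ("expression", ["expr"]),
                          ("interaction", ["deg"]), ("both", ["expr", "deg"])]:
        res = rb.partial_spearman(base["cs"], base["het"],
                                  base[ctl] if ctl else None)
        rows.append({"controlling": ctl_name, "rho": res.value, "p_value": res.p_value,
                     "n": res.n["obs"]})
    # pairwise trio, each controlling for the third
    trio = {"cs": base["cs"], "expr": base["expr"], "deg": base["deg"]}
    for x, y, z in [("cs", "expr", "deg"), ("cs", "deg", "expr"), ("expr", "deg", "cs")]:
        res = rb.partial_spearman(trio[x], trio[y], base[[z]])
        rows.append({"controlling": f"{x}~{y}|{z}", "rho": res.value,
                     "p_value": res.p_value, "n": res.n["obs"]})
    _tsv(pd.DataFrame(rows), stage_dir / "partial_spearman.tsv", index=False)

    ebc = rb.expression_bin_comparison(agg, mean_expr, class3)
    _tsv(ebc, stage_dir / "expression_bin_comparison.tsv", index=False)

    grid = rb.build_landscape(agg, study.mrna.mean(axis=1), catalog["ppi_degree_all"])
    _tsv(grid.cell_means_frame(), stage_dir / "landscape_grid.tsv", index=False)
    trend = rb.landscape_trend(grid)
    (stage_dir / "landscape_trend.json").write_text(json.dumps(
        {"rho": trend.value, "p_value": trend.p_value, "n_cells": trend.n["cells"]},
        indent=2, sort_keys=True))
    dens_rows = []
    for klass in ("paralog", "singleton"):
        genes = class3.index[class3 == klass]
        try:
            d = rb.class_density(genes, study.mrna.mean(axis=1),
                                 catalog["ppi_degree_all"], grid)
            dens_rows.append(pd.DataFrame({
                "class": klass,
                "ix": np.repeat(np.arange(d.shape[0]), d.shape[1]),
                "iy": np.tile(np.arange(d.shape[1]), d.shape[0]),
                "density": d.ravel(),
            }))
        except ValueError as err:
            logger.warning("density for class %s skipped: %s", klass, err)
    if dens_rows:
        _tsv(pd.concat(dens_rows, ignore_index=True),
             stage_dir / "class_densities.tsv", index=False)

    age = rb.age_stratified_comparison(
        pairs.rename(columns={het_col: "heteromer"}).loc[pairs["ds"] <= 5.0],
        merged, catalog["essential"])
    _tsv(age["per_age_group"], stage_dir / "age_group_cs.tsv", index=False)
    if age["age_essentiality"] is not None:
        _tsv(pd.DataFrame([age["age_essentiality"].as_row()]),
             stage_dir / "age_essentiality_test.tsv", index=False)


# ----------------------------------------------------------- asymmetry stage


def _stage_asymmetry(stage_dir: Path, results: dict) -> None:
    study = results["study"]
    classes = results["classes"]
    merged = results["scores"]["merged"]
    pairs = classes["pairs"]
    het_col = "heteromer_db_a_all" if "heteromer_db_a_all" in pairs.columns \
        else "heteromer_merged_all"
    het = pairs[het_col].astype(bool)

    table = asym.pair_line_table(pairs, study.mrna, merged)
    _tsv(table, stage_dir / "pair_line_table.tsv", index=False)

    res = asym.p1_p2_cs_comparison(table)
    _tsv(pd.DataFrame([res.as_row()]), stage_dir / "p1_p2_test.tsv", index=False)

    n_obs = len(table.dropna(subset=["asymmetry", "delta_cs"]))
    if n_obs >= 10:
        _tsv(asym.binned_p1_gt_p2_probability(table, n_bins=min(10, max(2, n_obs // 5))),
             stage_dir / "binned_p1_gt_p2.tsv", index=False)
        _tsv(asym.asym_deltaCS_relationship(table, n_bins=min(10, max(2, n_obs // 5))),
             stage_dir / "asym_deltacs_bins.tsv", index=False)

    per_pair = asym.per_pair_asym_cs_correlation(table)
    df = per_pair.to_frame()
    df["heteromer"] = het.reindex(per_pair.index).fillna(False).to_numpy()
    _tsv(df, stage_dir / "per_pair_correlations.tsv")
    if df["heteromer"].nunique() == 2 and len(df) >= 4:
        comp = asym.compare_correlation_distributions(per_pair, het)
        _tsv(pd.DataFrame([comp.as_row()]), stage_dir / "rs_het_vs_non_test.tsv", index=False)

    coex = asym.coexpression(pairs, study.mrna)
    cdf = coex.to_frame()
    cdf["heteromer"] = het.reindex(coex.index).fillna(False).to_numpy()
    _tsv(cdf, stage_dir / "coexpression.tsv")

    try:
        prot = asym.protein_coregulation(pairs, study.protein, study.mrna)
        pdf = prot.to_frame()
        pdf["heteromer"] = het.reindex(prot.index).fillna(False).to_numpy()
        _tsv(pdf, stage_dir / "protein_coregulation.tsv")
    except ValueError as err:
        logger.warning("protein coregulation skipped: %s", err)
    if len(pairs.dropna(subset=["interface_size"])) >= 5:
        ires = asym.interface_cs_correlation(
            pairs.loc[het], results["scores"]["aggregated"])
        _tsv(pd.DataFrame([ires.as_row()]), stage_dir / "interface_cs.tsv", index=False)


# --------------------------------------------------------------- model stage


def _stage_model(stage_dir: Path, config: SimulationConfig, results: dict) -> None:
    study = results["study"]
    classes = results["classes"]
    agg = results["scores"]["aggregated"]
    catalog = classes["catalog"]
    labels = _gene_labels(classes)

    ess = set(catalog.index[catalog["essential"] == "essential"])
    non = set(catalog.index[catalog["essential"] == "non-essential"])
    cutoff = dm.compute_cutoff(agg, ess, non)
    y_all = dm.label_targets(agg, cutoff)

    par_genes = labels.index[(labels == "heteromer") | (labels == "non-heteromer")]
    feats = pd.DataFrame({
        "heteromer": (labels.reindex(par_genes) == "heteromer").astype(float),
        "expression": np.log2(study.mrna.mean(axis=1).reindex(par_genes) + 2.0**-10),
        "degree": np.log2(catalog["ppi_degree_all"].reindex(par_genes) + 1.0),
    }).dropna()
    y = y_all.reindex(feats.index).dropna().astype(int)
    feats = feats.loc[y.index]
    report = dm.evaluate_models(feats, y, seed=config.seed)
    _tsv(report.to_frame(), stage_dir / "model_report.tsv", index=False)
    (stage_dir / "model_report.json").write_text(json.dumps(
        {
            "cutoff": cutoff.cutoff,
            "min_cs_nonessential": cutoff.min_cs_nonessential,
            "max_cs_essential": cutoff.max_cs_essential,
            "n_runs": report.n_runs,
            "seed": report.seed,
            "auc_mean": report.auc_mean,
            "auc_sd": report.auc_sd,
            "importances": report.importances,
        }, indent=2, sort_keys=True))


# ------------------------------------------------------------ genesets stage


def _stage_genesets(stage_dir: Path, results: dict) -> None:
    study = results["study"]
    classes = results["classes"]
    agg = results["scores"]["aggregated"]
    pairs = classes["pairs"]
    het_col = "heteromer_db_a_all" if "heteromer_db_a_all" in pairs.columns \
        else "heteromer_merged_all"
    p = pairs.rename(columns={het_col: "heteromer"})
    summaries = gs.summarize_sets(study.gene_sets, p, agg,
                                  min_pairs=study.config.min_set_pairs)
    _tsv(summaries, stage_dir / "geneset_summaries.tsv", index=False)
    if len(summaries) >= 5:
        res = gs.proportion_cs_correlation(summaries)
        _tsv(pd.DataFrame([res.as_row()]), stage_dir / "proportion_cs_test.tsv", index=False)


# ------------------------------------------------------------------- report


def render_report(outdir, figdir=None) -> list[str]:
    """Render figures from the pipeline's TSV outputs (pure views).

    Returns the list of figure files written. Missing stage outputs skip the
    corresponding figure with a log message.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    figdir = Path(figdir) if figdir else out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(fig, name):
        path = figdir / name
        fig.savefig(path, dpi=100, metadata={"Software": None})
        plt.close(fig)
        written.append(str(path))

    means_p = out / "stats" / "cellwise_class_means.tsv"
    if means_p.exists():
        means = pd.read_csv(means_p, sep="\t", index_col=0)
        if {"paralog", "singleton"}.issubset(means.columns):
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(means["singleton"], means["paralog"])
            lims = [means[["singleton", "paralog"]].min().min(),
                    means[["singleton", "paralog"]].max().max()]
            ax.plot(lims, lims, "--", color="gray")  # diagonal reference
            ax.set_xlabel("mean CS, singletons")
            ax.set_ylabel("mean CS, paralogs")
            fig.tight_layout()
            save(fig, "cellwise_class_means.png")
    else:
        logger.warning("cellwise means missing; figure skipped")

    grid_p = out / "stats" / "landscape_grid.tsv"
    if grid_p.exists():
        grid = pd.read_csv(grid_p, sep="\t")
        piv = grid.pivot(index="iy", columns="ix", values="mean_cs")
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(piv.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
        fig.colorbar(im, ax=ax, label="mean CS")
        ax.set_xlabel("log2 expression bin")
        ax.set_ylabel("log2 degree bin")
        fig.tight_layout()
        save(fig, "landscape.png")
    else:
        logger.warning("landscape grid missing; figure skipped")

    comp_p = out / "stats" / "class_comparisons.tsv"
    if comp_p.exists():
        comp = pd.read_csv(comp_p, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 4))
        lbl = comp["group_a"] + " vs " + comp["group_b"] + " (" + comp["dataset"] + ")"
        ax.barh(lbl, comp["median_diff"])
        ax.set_xlabel("median CS difference (a - b)")
        fig.tight_layout()
        save(fig, "class_median_differences.png")

    bins_p = out / "asymmetry" / "asym_deltacs_bins.tsv"
    if bins_p.exists():
        b = pd.read_csv(bins_p, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        yerr = np.vstack([b["mean_delta_cs"] - b["ci_low"], b["ci_high"] - b["mean_delta_cs"]])
        ax.errorbar(b["mean_asymmetry"], b["mean_delta_cs"], yerr=yerr, fmt="o-")
        ax.axhline(0, color="gray", ls="--")
        ax.set_xlabel("expression asymmetry (binned)")
        ax.set_ylabel("mean dCS (P1 - P2)")
        fig.tight_layout()
        save(fig, "asymmetry_deltacs.png")
    return written
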