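"""Forward simulation of a multi-screen CRISPR loss-of-function study.

The generator emits every input the downstream analysis consumes — a gene
catalog with paralog pairs, a protein-similarity hit table, evidence-coded
protein-interaction edges from two sources, mRNA/protein expression matrices,
guide libraries with read-count matrices per screen dataset, reference
essential/non-essential gene lists, gene-set memberships and interface sizes —
together with a truth table of the planted effects, so that each pipeline
stage can be tested for recovery of known ground truth.

Planted structure (all magnitudes set in :class:`~paralogcs.config.SimulationConfig`):

* heteromeric paralogs have higher mean expression and more interaction
  partners than non-heteromeric paralogs;
* fitness effects of gene loss follow the configured effect model (more
  expression / more partners / heteromer -> more deleterious; paralog ->
  buffered);
* heteromer pairs have more symmetric expression, higher coexpression, and a
  pair-shared protein-level residual on top of the mRNA-driven signal;
* a fraction of guides on low-dS pairs hits both members (double knockout,
  additive effect by default);
* for heteromer pairs only, per-cell-line expression asymmetry couples to the
  CRISPR-score difference between the higher- (P1) and lower-expressed (P2)
  member: the more asymmetric the pair in a cell line, the more deleterious
  the loss of P1 relative to P2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .config import SimulationConfig, config_hash, load_config, save_config
from .gene_classes import DIRECT_METHODS, INDIRECT_METHODS, EXCLUDED_METHODS

logger = logging.getLogger(__name__)

__all__ = [
    "Screen",
    "TruthTable",
    "SyntheticStudy",
    "generate_catalog",
    "generate_ppi",
    "generate_expression",
    "generate_screen",
    "generate_gene_sets",
    "generate_study",
    "write_dataset",
    "read_dataset",
]

_KEPT_METHODS = sorted(DIRECT_METHODS | INDIRECT_METHODS)
_DIRECT = sorted(DIRECT_METHODS)
_EXCLUDED = sorted(EXCLUDED_METHODS)


@dataclass
class Screen:
    """One synthetic screen dataset: guide library, counts and sample map."""

    name: str
    library: pd.DataFrame  # guide_id, gene_ids (';'-separated), dataset
    counts: pd.DataFrame  # guides x samples, integer reads
    samples: pd.DataFrame  # sample, cell_line, timepoint, replicate
    cell_lines: List[str]


@dataclass
class TruthTable:
    """Planted ground truth: per-gene fitness/class, per-pair flags."""

    genes: pd.DataFrame  # index gene_id: fitness, class, heteromer_gene, homomer, essential
    pairs: pd.DataFrame  # index pair_id: heteromer, asymmetry, ds


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    catalog: pd.DataFrame
    pairs: pd.DataFrame
    truth: TruthTable
    hits: pd.DataFrame
    ppi: pd.DataFrame
    mrna: pd.DataFrame
    protein: pd.DataFrame
    screens: List[Screen]
    gene_sets: pd.DataFrame  # set_id, gene_id
    set_info: pd.DataFrame  # set_id, requested_heteromer_proportion
    essential_refs: Dict[str, List[str]]
    cell_lines: List[str] = field(default_factory=list)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one root seed, expanded per stage so stages stay independent
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Overdispersed counts, var = m + dispersion * m^2 (gamma-Poisson).

    ``dispersion <= 0`` switches the generator to its noise-free limit: the
    rounded expectation, which the degenerate-configuration contracts rely on.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return np.rint(mean).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) * dispersion)
    return rng.poisson(lam).astype(np.int64)


def _truncated_exp(rng: np.random.Generator, scale: float, upper: float, size: int) -> np.ndarray:
    u = rng.uniform(0.0, 1.0, size)
    return -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))


# ---------------------------------------------------------------------------
# catalog


def generate_catalog(config: SimulationConfig):
    """Genes, paralog pairs, similarity hits and the planted truth table.

    Returns ``(catalog, pairs, truth, hits)``. The catalog holds per-gene
    class labels, protein length, baseline log2 expression, planted partner
    count, homomer/heteromer flags and the fitness effect of loss. The hit
    table is constructed to be exactly consistent with the class labels under
    the singleton rule (paralogs and unclassified genes carry a qualifying
    hit; singletons do not).
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(n)])

    n_pairs = config.n_pairs
    n_paralog = 2 * n_pairs
    n_single = int(round(config.singleton_fraction * n))
    n_single = min(n_single, n - n_paralog)
    klass = np.array(["unclassified"] * n, dtype=object)
    klass[:n_paralog] = "paralog"
    klass[n_paralog:n_paralog + n_single] = "singleton"

    pair_a = genes[0:n_paralog:2]
    pair_b = genes[1:n_paralog:2]
    pair_id = np.array([f"P{i:04d}" for i in range(n_pairs)])
    ds = _truncated_exp(rng, config.ds_scale, config.ds_max, n_pairs)
    # ordinal age groups by dS quantile (no real phylogeny in the simulator)
    q = pd.qcut(ds, config.n_age_groups, labels=False, duplicates="drop")
    age_group = np.asarray(q, dtype=int) + 1
    origin = rng.choice(["SSD", "WGD"], size=n_pairs)
    heteromer = rng.uniform(size=n_pairs) < config.heteromer_fraction_of_pairs

    het_gene = np.zeros(n, dtype=bool)
    het_gene[:n_paralog:2] = heteromer
    het_gene[1:n_paralog:2] = heteromer

    # homomers: heteromer pairs are biased toward both-member homomers,
    # planting the ancestral-homomer association
    homomer = rng.uniform(size=n) < config.homomer_rate
    both_hom = heteromer & (rng.uniform(size=n_pairs) < config.ancestral_homomer_rate)
    homomer[:n_paralog:2] |= np.repeat(both_hom, 1)
    homomer[1:n_paralog:2] |= both_hom

    # baseline log2 expression; pair structure controls asymmetry
    mu = rng.normal(config.expr_mean, config.expr_sd, n)
    pair_mean = rng.normal(
        config.expr_mean + config.het_expr_shift * heteromer, config.expr_sd, n_pairs
    )
    halfdiff_sd = np.where(
        heteromer, config.het_pair_halfdiff_sd, config.pair_halfdiff_sd
    )
    halfdiff = rng.normal(0.0, 1.0, n_pairs) * halfdiff_sd
    mu[:n_paralog:2] = pair_mean + halfdiff
    mu[1:n_paralog:2] = pair_mean - halfdiff

    # planted interaction-partner counts, shifted up for heteromer genes
    log_k = rng.normal(
        config.degree_log_mean + config.het_degree_shift * het_gene, config.degree_log_sd, n
    )
    degree = np.maximum(np.rint(np.exp(log_k)).astype(int), 1)

    protein_length = np.maximum(
        np.rint(np.exp(rng.normal(np.log(450.0), 0.4, n))).astype(int), 50
    )

    em = config.effect_model
    z_expr = (mu - mu.mean()) / mu.std()
    logd = np.log2(degree + 1.0)
    z_deg = (logd - logd.mean()) / logd.std()
    latent = (
        em.intercept
        + em.b_expr * z_expr
        + em.b_degree * z_deg
        + em.b_heteromer * het_gene
        - em.b_paralog * (klass == "paralog")
        + rng.normal(0.0, em.noise_sd, n)
    )
    fitness = -_softplus(latent)

    catalog = pd.DataFrame(
        {
            "gene_id": genes,
            "class": klass,
            "protein_length": protein_length,
            "mu_expr_log2": mu,
            "planted_degree": degree,
            "heteromer_gene": het_gene,
            "homomer": homomer,
            "fitness": fitness,
        }
    ).set_index("gene_id")

    # planted pair asymmetry from the baseline means
    ea, eb = 2.0 ** mu[:n_paralog:2], 2.0 ** mu[1:n_paralog:2]
    asymmetry = np.abs(ea - eb) / (ea + eb)

    fa = fitness[:n_paralog:2]
    fb = fitness[1:n_paralog:2]
    interface = np.full(n_pairs, np.nan)
    pair_f = (fa + fb) / 2.0
    interface[heteromer] = np.clip(
        np.rint(40.0 - 60.0 * pair_f[heteromer] + rng.normal(0, 12, heteromer.sum())),
        5,
        None,
    )

    pairs = pd.DataFrame(
        {
            "pair_id": pair_id,
            "gene_a": pair_a,
            "gene_b": pair_b,
            "origin": origin,
            "ds": ds,
            "age_group": age_group,
            "heteromer": heteromer,
            "asymmetry": asymmetry,
            "interface_size": interface,
        }
    ).set_index("pair_id")

    # essentiality truth + two overlapping reference sources per category
    ess_cut = np.quantile(fitness, 0.15)
    non_cut = np.quantile(fitness, 0.7)
    essential = np.where(fitness <= ess_cut, "essential",
                         np.where(fitness >= non_cut, "non-essential", "unknown"))

    truth_genes = catalog[["fitness", "class", "heteromer_gene", "homomer"]].copy()
    truth_genes["essential"] = essential
    truth_pairs = pairs[["heteromer", "asymmetry", "ds"]].copy()
    truth = TruthTable(genes=truth_genes, pairs=truth_pairs)

    hits = _make_hits(rng, catalog)
    return catalog, pairs, truth, hits


def _make_hits(rng: np.random.Generator, catalog: pd.DataFrame) -> pd.DataFrame:
    """Similarity hit table consistent with the class labels.

    Paralogs hit their partner with a qualifying alignment; unclassified genes
    hit another unclassified gene (homology outside the curated pair lists);
    singletons only get sub-threshold hits. Self-hits are included for
    realism and must be ignored by the singleton rule.
    """
    genes = catalog.index.to_numpy()
    lengths = catalog["protein_length"]
    rows = []
    # self-hits for everyone
    for g in genes:
        rows.append((g, g, 0.0, int(lengths[g])))
    klass = catalog["class"]
    paralogs = genes[klass == "paralog"]
    for a, b in zip(paralogs[::2], paralogs[1::2]):
        ml = min(lengths[a], lengths[b])
        aln = int(np.ceil(0.75 * ml)) + 1
        e = 10.0 ** rng.uniform(-60, -10)
        rows.append((a, b, e, aln))
    unclassified = genes[klass == "unclassified"]
    for i, g in enumerate(unclassified):
        partner = unclassified[(i + 1) % len(unclassified)]
        if partner == g:
            continue
        ml = min(lengths[g], lengths[partner])
        rows.append((g, partner, 10.0 ** rng.uniform(-30, -5), int(np.ceil(0.7 * ml)) + 1))
    singles = genes[klass == "singleton"]
    for g in singles:
        partner = genes[rng.integers(len(genes))]
        if partner == g:
            continue
        ml = min(lengths[g], lengths[partner])
        # fails either the E-value or the alignment-length criterion
        if rng.uniform() < 0.5:
            rows.append((g, partner, rng.uniform(0.01, 2.0), int(np.ceil(0.7 * ml))))
        else:
            rows.append((g, partner, 10.0 ** rng.uniform(-8, -4), int(0.4 * ml)))
    return pd.DataFrame(rows, columns=["query", "subject", "e_value", "alignment_length"])


# ---------------------------------------------------------------------------
# protein-protein interaction network


def generate_ppi(catalog: pd.DataFrame, pairs: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Evidence-coded edge table from two sources.

    Background edges follow an expected-degree (Chung-Lu style) model around
    the planted partner counts; edges that would join the two members of a
    *non*-heteromer pair are removed so that the planted heteromer flags are
    exactly recoverable; every heteromer pair gets an inter-member edge and
    every homomer gene a self-edge in both sources. A fraction of extra edges
    carries excluded detection methods, to exercise the filtering step.
    """
    rng = _rng(config, 2)
    genes = catalog.index.to_numpy()
    k = catalog["planted_degree"].to_numpy(float)
    non_het = pairs.loc[~pairs["heteromer"]]
    forbidden = set(zip(non_het["gene_a"], non_het["gene_b"]))

    def sample_edges(m: int) -> np.ndarray:
        p = k / k.sum()
        a = rng.choice(len(genes), size=int(m * 1.3), p=p)
        b = rng.choice(len(genes), size=int(m * 1.3), p=p)
        mask = a != b
        lo, hi = np.minimum(a[mask], b[mask]), np.maximum(a[mask], b[mask])
        seen = set()
        out = []
        for i, j in zip(lo, hi):
            key = (i, j)
            if key in seen:
                continue
            pr = (genes[i], genes[j])
            if pr in forbidden:
                continue
            seen.add(key)
            out.append(key)
            if len(out) >= m:
                break
        return np.array(out, dtype=int)

    m = int(k.sum() / 2)
    frames = []
    base = sample_edges(m)
    for source, keep_frac in (("db_a", 1.0), ("db_b", 0.7)):
        if keep_frac < 1.0:
            sel = rng.uniform(size=len(base)) < keep_frac
            eidx = base[sel]
        else:
            eidx = base
        methods = rng.choice(_KEPT_METHODS, size=len(eidx))
        df = pd.DataFrame(
            {
                "gene_a": genes[eidx[:, 0]],
                "gene_b": genes[eidx[:, 1]],
                "method": methods,
                "source": source,
            }
        )
        # noise edges with excluded methods (dropped by every filter mode)
        n_noise = int(0.1 * len(eidx))
        noise = sample_edges(n_noise)
        frames.append(df)
        if len(noise):
            frames.append(
                pd.DataFrame(
                    {
                        "gene_a": genes[noise[:, 0]],
                        "gene_b": genes[noise[:, 1]],
                        "method": rng.choice(_EXCLUDED, size=len(noise)),
                        "source": source,
                    }
                )
            )
        het = pairs.loc[pairs["heteromer"]]
        het_methods = np.where(
            rng.uniform(size=len(het)) < 0.7,
            rng.choice(_DIRECT, size=len(het)),
            rng.choice(sorted(INDIRECT_METHODS), size=len(het)),
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_a": het["gene_a"].to_numpy(),
                    "gene_b": het["gene_b"].to_numpy(),
                    "method": het_methods,
                    "source": source,
                }
            )
        )
        hom = catalog.index[catalog["homomer"]]
        frames.append(
            pd.DataFrame(
                {
                    "gene_a": hom,
                    "gene_b": hom,
                    "method": rng.choice(_DIRECT, size=len(hom)),
                    "source": source,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression


def _cell_line_names(config: SimulationConfig) -> List[str]:
    total = int(sum(config.n_cell_lines))
    return [f"CL{i + 1:03d}" for i in range(total)]


def generate_expression(catalog: pd.DataFrame, pairs: pd.DataFrame, config: SimulationConfig):
    """mRNA (all cell lines) and protein (subset) expression matrices, FPKM-like.

    log2 expression = gene baseline + cell-line offset + pair-shared and
    gene-private fluctuations; the pair-shared weight is larger for heteromer
    pairs (higher coexpression). Protein log2 values are an affine function of
    mRNA log2 values plus, for heteromer pairs, a pair-shared residual
    (post-transcriptional coregulation) and private noise.
    """
    rng = _rng(config, 3)
    lines = _cell_line_names(config)
    n, L = len(catalog), len(lines)
    mu = catalog["mu_expr_log2"].to_numpy()

    line_eff = rng.normal(0.0, config.line_effect_sd, L)
    shared = rng.normal(0.0, 1.0, (len(pairs), L))
    private = rng.normal(0.0, 1.0, (n, L))

    w = np.zeros(n)
    pair_row = np.full(n, -1, dtype=int)
    gene_pos = {g: i for i, g in enumerate(catalog.index)}
    for r, (_, pr) in enumerate(pairs.iterrows()):
        wgt = config.het_coexpr_weight if pr["heteromer"] else config.coexpr_weight
        for g in (pr["gene_a"], pr["gene_b"]):
            w[gene_pos[g]] = wgt
            pair_row[gene_pos[g]] = r

    fluct = np.sqrt(1.0 - w)[:, None] * private
    has_pair = pair_row >= 0
    fluct[has_pair] += np.sqrt(w[has_pair])[:, None] * shared[pair_row[has_pair]]
    log_mrna = mu[:, None] + line_eff[None, :] + config.expr_noise_sd * fluct
    mrna = pd.DataFrame(2.0 ** log_mrna, index=catalog.index, columns=lines)

    n_prot = max(1, int(round(config.protein_line_fraction * L)))
    prot_lines = lines[:n_prot]
    shared_resid = rng.normal(0.0, 1.0, (len(pairs), n_prot)) * config.het_protein_shared_sd
    log_prot = config.protein_slope * log_mrna[:, :n_prot].copy()
    het_pair = pairs["heteromer"].to_numpy()
    mask = has_pair & het_pair[np.maximum(pair_row, 0)]
    log_prot[mask] += shared_resid[pair_row[mask]]
    log_prot += rng.normal(0.0, 1.0, (n, n_prot)) * config.protein_noise_sd
    protein = pd.DataFrame(2.0 ** log_prot, index=catalog.index, columns=prot_lines)
    return mrna, protein


# ---------------------------------------------------------------------------
# screens


def _per_line_fitness(
    catalog: pd.DataFrame, pairs: pd.DataFrame, mrna: pd.DataFrame, config: SimulationConfig,
    lines: List[str],
) -> pd.DataFrame:
    """Per-gene, per-cell-line fitness; heteromer pairs get the planted
    asymmetry->deleteriousness coupling (the higher-expressed member P1 in a
    given line becomes more deleterious in proportion to the pair's expression
    asymmetry in that line)."""
    f = pd.DataFrame(
        np.repeat(catalog["fitness"].to_numpy()[:, None], len(lines), axis=1),
        index=catalog.index,
        columns=lines,
    )
    if config.asymmetry_coupling == 0:
        return f
    het = pairs.loc[pairs["heteromer"]]
    if not len(het):
        return f
    ea = mrna.loc[het["gene_a"], lines].to_numpy()
    eb = mrna.loc[het["gene_b"], lines].to_numpy()
    asym = np.abs(ea - eb) / (ea + eb)
    adj = 0.5 * config.asymmetry_coupling * asym
    a_is_p1 = ea >= eb
    fa = f.loc[het["gene_a"], lines].to_numpy()
    fb = f.loc[het["gene_b"], lines].to_numpy()
    fa_new = np.where(a_is_p1, fa - adj, fa + adj)
    fb_new = np.where(a_is_p1, fb + adj, fb - adj)
    f.loc[het["gene_a"], lines] = fa_new
    f.loc[het["gene_b"], lines] = fb_new
    return f


def generate_screen(
    catalog: pd.DataFrame,
    pairs: pd.DataFrame,
    config: SimulationConfig,
    mrna: pd.DataFrame,
    dataset_index: int,
    lines: List[str],
    n_replicates: int = 2,
) -> Screen:
    """Guide library and read counts for one screen dataset.

    Each gene gets ``guides_per_gene`` guides; guides on genes in low-dS
    pairs hit both members with probability ``multi_hit_rate`` (double
    knockout; effects combine additively). T0 counts are overdispersed draws
    around ``library_size``; final counts have expectation
    ``T0 * 2**(fitness * doublings)``.
    """
    if config.doublings <= 0:
        raise ValueError("doublings must be > 0")
    rng = _rng(config, 10 + dataset_index)
    name = f"CS{dataset_index + 1}"
    genes = catalog.index.to_numpy()

    partner = {}
    low_ds = pairs.loc[pairs["ds"] < config.multi_hit_ds_max]
    for _, pr in low_ds.iterrows():
        partner[pr["gene_a"]] = pr["gene_b"]
        partner[pr["gene_b"]] = pr["gene_a"]

    guide_rows = []
    for g in genes:
        for j in range(config.guides_per_gene):
            gid = f"{g}_sg{j + 1}_{name}"
            if g in partner and rng.uniform() < config.multi_hit_rate:
                targets = f"{g};{partner[g]}"
            else:
                targets = g
            guide_rows.append((gid, targets, name))
    library = pd.DataFrame(guide_rows, columns=["guide_id", "gene_ids", "dataset"])

    f_line = _per_line_fitness(catalog, pairs, mrna, config, lines)
    # per-guide effect = sum over targets (additive double-knockout model)
    target_lists = library["gene_ids"].str.split(";")
    eff = np.zeros((len(library), len(lines)))
    fmat = f_line.to_numpy()
    gpos = {g: i for i, g in enumerate(f_line.index)}
    for i, tl in enumerate(target_lists):
        for t in tl:
            eff[i] += fmat[gpos[t]]

    cols, data, srows = [], [], []
    ratio = 2.0 ** (eff * config.doublings)
    for li, line in enumerate(lines):
        for r in range(1, n_replicates + 1):
            t0 = _negbin(rng, np.full(len(library), config.library_size), config.count_dispersion)
            fin = _negbin(rng, t0 * ratio[:, li], config.count_dispersion)
            cols += [f"{name}:{line}:T0:r{r}", f"{name}:{line}:final:r{r}"]
            data += [t0, fin]
            srows.append((cols[-2], line, "T0", r))
            srows.append((cols[-1], line, "final", r))
    counts = pd.DataFrame(
        np.column_stack(data), index=library["guide_id"].to_numpy(), columns=cols
    )
    counts.index.name = "guide_id"
    samples = pd.DataFrame(srows, columns=["sample", "cell_line", "timepoint", "replicate"])
    return Screen(name=name, library=library, counts=counts, samples=samples,
                  cell_lines=list(lines))


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(catalog: pd.DataFrame, pairs: pd.DataFrame, config: SimulationConfig):
    """Pair-based gene sets spanning heteromer proportions in [0, 1].

    Returns ``(membership, set_info)``: membership is a (set_id, gene_id)
    table; set_info records each set's requested heteromer proportion.
    """
    rng = _rng(config, 4)
    het_pool = pairs.index[pairs["heteromer"]].to_numpy()
    non_pool = pairs.index[~pairs["heteromer"]].to_numpy()
    n_sets = config.n_gene_sets
    rows, info = [], []
    for j in range(n_sets):
        q = j / max(n_sets - 1, 1)
        size = int(rng.integers(config.min_set_pairs, 2 * config.min_set_pairs + 1))
        # shrink rather than pad when a pool runs short, so extreme requested
        # proportions stay exact
        n_het = min(int(round(q * size)), len(het_pool))
        n_non = min(size - int(round(q * size)), len(non_pool))
        chosen = list(rng.choice(het_pool, size=n_het, replace=False)) + list(
            rng.choice(non_pool, size=n_non, replace=False)
        )
        sid = f"SET{j:03d}"
        for pid in chosen:
            rows.append((sid, pairs.at[pid, "gene_a"]))
            rows.append((sid, pairs.at[pid, "gene_b"]))
        info.append((sid, q, n_het + n_non))
    membership = pd.DataFrame(rows, columns=["set_id", "gene_id"])
    set_info = pd.DataFrame(info, columns=["set_id", "requested_proportion", "n_pairs"])
    return membership, set_info


# ---------------------------------------------------------------------------
# orchestration and I/O


def _essential_refs(rng: np.random.Generator, truth_genes: pd.DataFrame) -> Dict[str, List[str]]:
    ess = truth_genes.index[truth_genes["essential"] == "essential"].to_numpy()
    non = truth_genes.index[truth_genes["essential"] == "non-essential"].to_numpy()
    take = lambda pool: sorted(rng.choice(pool, size=int(0.8 * len(pool)), replace=False))
    return {
        "essential_ref1": take(ess),
        "essential_ref2": take(ess),
        "nonessential_ref1": take(non),
        "nonessential_ref2": take(non),
    }


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator stage and assemble the full synthetic study."""
    config.validate()
    catalog, pairs, truth, hits = generate_catalog(config)
    ppi = generate_ppi(catalog, pairs, config)
    mrna, protein = generate_expression(catalog, pairs, config)
    lines = _cell_line_names(config)
    screens, start = [], 0
    for d, nl in enumerate(config.n_cell_lines):
        ds_lines = lines[start:start + int(nl)]
        start += int(nl)
        screens.append(generate_screen(catalog, pairs, config, mrna, d, ds_lines))
    gene_sets, set_info = generate_gene_sets(catalog, pairs, config)
    refs = _essential_refs(_rng(config, 5), truth.genes)
    return SyntheticStudy(
        config=config,
        catalog=catalog,
        pairs=pairs,
        truth=truth,
        hits=hits,
        ppi=ppi,
        mrna=mrna,
        protein=protein,
        screens=screens,
        gene_sets=gene_sets,
        set_info=set_info,
        essential_refs=refs,
        cell_lines=lines,
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_dataset(study: SyntheticStudy, directory) -> dict:
    """Write every table of the study as UTF-8 TSV plus a JSON manifest.

    The manifest records the seed, the config hash and every file written;
    :func:`read_dataset` round-trips the values exactly.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def put(name: str, df: pd.DataFrame, index: bool = True):
        path = out / name
        _write_tsv(df, path, index)
        files[name.rsplit(".", 1)[0]] = name

    put("catalog.tsv", study.catalog)
    put("pairs.tsv", study.pairs)
    put("truth_genes.tsv", study.truth.genes)
    put("truth_pairs.tsv", study.truth.pairs)
    put("hits.tsv", study.hits, index=False)
    put("ppi.tsv", study.ppi, index=False)
    put("mrna.tsv", study.mrna)
    put("protein.tsv", study.protein)
    put("gene_sets.tsv", study.gene_sets, index=False)
    put("set_info.tsv", study.set_info, index=False)
    for scr in study.screens:
        put(f"library_{scr.name}.tsv", scr.library, index=False)
        put(f"counts_{scr.name}.tsv", scr.counts)
        put(f"samples_{scr.name}.tsv", scr.samples, index=False)
    for key, gl in study.essential_refs.items():
        put(f"{key}.tsv", pd.DataFrame({"gene_id": gl}), index=False)
    save_config(study.config, out / "config.yaml")
    files["config"] = "config.yaml"
    manifest = {
        "seed": int(study.config.seed),
        "config_hash": config_hash(study.config),
        "datasets": [s.name for s in study.screens],
        "cell_lines": study.cell_lines,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_dataset(directory) -> SyntheticStudy:
    """Load a study written by :func:`write_dataset`."""
    out = Path(directory)
    manifest = json.loads((out / "manifest.json").read_text())
    config = load_config(out / "config.yaml")

    def get(name, **kw):
        return pd.read_csv(out / manifest["files"][name], sep="\t", **kw)

    catalog = get("catalog", index_col=0)
    pairs = get("pairs", index_col=0)
    truth = TruthTable(genes=get("truth_genes", index_col=0),
                       pairs=get("truth_pairs", index_col=0))
    screens = []
    for name in manifest["datasets"]:
        lib = get(f"library_{name}")
        counts = get(f"counts_{name}", index_col=0)
        samples = get(f"samples_{name}")
        screens.append(Screen(name=name, library=lib, counts=counts, samples=samples,
                              cell_lines=sorted(samples["cell_line"].unique())))
    refs = {
        key: get(key)["gene_id"].tolist()
        for key in ("essential_ref1", "essential_ref2", "nonessential_ref1", "nonessential_ref2")
    }
    return SyntheticStudy(
        config=config,
        catalog=catalog,
        pairs=pairs,
        truth=truth,
        hits=get("hits"),
        ppi=get("ppi"),
        mrna=get("mrna", index_col=0),
        protein=get("protein", index_col=0),
        screens=screens,
        gene_sets=get("gene_sets"),
        set_info=get("set_info"),
        essential_refs=refs,
        cell_lines=manifest["cell_lines"],
    )
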