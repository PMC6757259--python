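"""Gene and pair labelling: paralog/singleton/unclassified, homomer and
heteromer calls from evidence-coded protein-interaction edges, essentiality.

The interaction-method vocabulary distinguishes three groups:

* excluded methods — assays that do not strictly capture physical
  protein-protein contact (co-fractionation, protein-RNA, co-localization,
  proximity label-MS, affinity capture-RNA); edges carrying these are dropped
  from every analysis mode.
* direct methods — assays detecting direct physical contact (two-hybrid,
  biochemical activity, protein-peptide, PCA, Far Western).
* indirect methods — remaining physical-interaction assays (e.g. affinity
  capture-MS); kept in the "all" mode only.

Method strings are matched case-insensitively and hyphen/space/underscore
insensitively.
"""

from __future__ import annotations

import logging
from typing import Iterable, Set

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EXCLUDED_METHODS",
    "DIRECT_METHODS",
    "INDIRECT_METHODS",
    "KNOWN_METHODS",
    "normalize_method",
    "classify_singletons",
    "build_pair_registry",
    "filter_ppi",
    "call_homomers_heteromers",
    "merge_sources",
    "classify_essential",
    "ppi_degree",
    "canonical_pair_index",
]


def normalize_method(method: str) -> str:
    """Canonicalise a detection-method code (case/hyphen/space-insensitive)."""
    return " ".join(str(method).lower().replace("-", " ").replace("_", " ").split())


EXCLUDED_METHODS: Set[str] = {
    "co fractionation",
    "protein rna",
    "co localization",
    "proximity label ms",
    "affinity capture rna",
}

DIRECT_METHODS: Set[str] = {
    "two hybrid",
    "biochemical activity",
    "protein peptide",
    "pca",
    "far western",
}

INDIRECT_METHODS: Set[str] = {
    "affinity capture ms",
    "affinity capture western",
    "co crystal structure",
    "reconstituted complex",
    "fret",
}

KNOWN_METHODS: Set[str] = EXCLUDED_METHODS | DIRECT_METHODS | INDIRECT_METHODS


def canonical_pair_index(a: Iterable, b: Iterable) -> pd.Index:
    """Order-independent (min, max) tuple index for gene pairs."""
    a = np.asarray(list(a), dtype=object)
    b = np.asarray(list(b), dtype=object)
    lo = np.where(a <= b, a, b)
    hi = np.where(a <= b, b, a)
    return pd.Index(list(zip(lo, hi)), tupleize_cols=False)


def classify_singletons(hits: pd.DataFrame, protein_lengths: pd.Series) -> Set[str]:
    """Identify singletons from an all-against-all protein similarity table.

    A gene is a singleton iff it has no non-self hit with E-value < 0.001
    over an aligned segment longer than 0.6 times the shorter of the two
    proteins. ``hits`` needs columns query, subject, e_value,
    alignment_length; ``protein_lengths`` maps gene id -> residues.
    """
    required = {"query", "subject", "e_value", "alignment_length"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hit table must have columns {sorted(required)}")
    unknown = (set(hits["query"]) | set(hits["subject"])) - set(protein_lengths.index)
    if unknown:
        raise ValueError(f"hits reference proteins of unknown length: {sorted(unknown)[:5]}")
    h = hits[hits["query"] != hits["subject"]]
    min_len = np.minimum(
        protein_lengths.loc[h["query"]].to_numpy(float),
        protein_lengths.loc[h["subject"]].to_numpy(float),
    )
    passing = h[(h["e_value"].to_numpy(float) < 1e-3)
                & (h["alignment_length"].to_numpy(float) > 0.6 * min_len)]
    with_homolog = set(passing["query"]) | set(passing["subject"])
    return set(protein_lengths.index) - with_homolog


def build_pair_registry(
    ssd_pairs: pd.DataFrame,
    wgd_pairs: pd.DataFrame,
    singletons: Set[str] | None = None,
    all_genes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Union the duplication-origin pair lists into a non-redundant registry.

    Both inputs need columns gene_a, gene_b. Pairs are deduplicated
    irrespective of member order; a pair present in both lists gets origin
    ``both``. Returns (pair table, per-gene class labels). Genes in any pair
    are labelled ``paralog`` (taking precedence over a conflicting singleton
    call, which is logged); singletons come from the provided set; everything
    else in ``all_genes`` is ``unclassified``.
    """
    frames = []
    for origin, df in (("SSD", ssd_pairs), ("WGD", wgd_pairs)):
        if len(df) and (df["gene_a"] == df["gene_b"]).any():
            raise ValueError("self-pair (a == a) in pair list")
        idx = canonical_pair_index(df["gene_a"], df["gene_b"])
        frames.append(pd.DataFrame({"origin": origin}, index=idx))
    merged = pd.concat(frames)
    origin = merged.groupby(level=0)["origin"].agg(
        lambda s: "both" if len(set(s)) > 1 else s.iloc[0]
    )
    pairs = pd.DataFrame(
        {
            "gene_a": [p[0] for p in origin.index],
            "gene_b": [p[1] for p in origin.index],
            "origin": origin.to_numpy(),
        }
    ).reset_index(drop=True)

    paralog_genes = set(pairs["gene_a"]) | set(pairs["gene_b"])
    singletons = set(singletons or ())
    conflicts = paralog_genes & singletons
    if conflicts:
        logger.warning(
            "%d genes pass the singleton rule but appear in a paralog pair; "
            "labelled paralog", len(conflicts)
        )
    universe = set(all_genes) if all_genes is not None else paralog_genes | singletons
    labels = pd.Series("unclassified", index=sorted(universe), name="class")
    labels[labels.index.isin(singletons - paralog_genes)] = "singleton"
    labels[labels.index.isin(paralog_genes)] = "paralog"
    return pairs, labels


def filter_ppi(edges: pd.DataFrame, mode: str = "all", unknown: str = "strict") -> pd.DataFrame:
    """Restrict an edge table to an analysis mode.

    ``all`` keeps every edge except those detected by the excluded methods;
    ``direct`` keeps only the direct-contact methods. Unknown method codes
    raise (``strict``) or are treated as indirect and logged (``lenient``).
    """
    if mode not in ("all", "direct"):
        raise ValueError(f"mode must be 'all' or 'direct', got {mode!r}")
    methods = edges["method"].map(normalize_method)
    unknown_mask = ~methods.isin(KNOWN_METHODS)
    if unknown_mask.any():
        codes = sorted(methods[unknown_mask].unique())
        if unknown == "strict":
            raise ValueError(f"unknown detection-method codes: {codes}")
        logger.warning("treating %d unknown method codes as indirect: %s", len(codes), codes)
    if mode == "all":
        keep = ~methods.isin(EXCLUDED_METHODS)
    else:
        keep = methods.isin(DIRECT_METHODS)
    return edges.loc[keep].copy()


def call_homomers_heteromers(
    edges: pd.DataFrame, pairs: pd.DataFrame
) -> tuple[Set[str], pd.Series]:
    """Homomer genes (self-edge present) and per-pair heteromer flags.

    A pair is heteromeric iff an edge joins its two members in the (already
    filtered) network. Returns (homomer gene set, boolean Series indexed like
    ``pairs``).
    """
    self_mask = edges["gene_a"] == edges["gene_b"]
    homomers = set(edges.loc[self_mask, "gene_a"])
    edge_idx = set(canonical_pair_index(edges.loc[~self_mask, "gene_a"],
                                        edges.loc[~self_mask, "gene_b"]))
    pair_idx = canonical_pair_index(pairs["gene_a"], pairs["gene_b"])
    het = pd.Series([p in edge_idx for p in pair_idx], index=pairs.index, name="heteromer")
    return homomers, het


def merge_sources(flags_src1: pd.Series, flags_src2: pd.Series) -> pd.Series:
    """Intersection merge: positive only where both sources call positive."""
    common = flags_src1.index.intersection(flags_src2.index)
    if len(common) < len(flags_src1) or len(common) < len(flags_src2):
        logger.warning(
            "flag universes differ (%d vs %d); restricting to %d common pairs",
            len(flags_src1), len(flags_src2), len(common),
        )
    return (flags_src1.loc[common].astype(bool) & flags_src2.loc[common].astype(bool)).rename(
        "heteromer"
    )


def classify_essential(
    essential_refs: Iterable[Iterable[str]],
    nonessential_refs: Iterable[Iterable[str]],
    all_genes: Iterable[str],
) -> pd.Series:
    """Essentiality labels from the union of reference sets per category.

    Genes in both unions are conflicts: labelled ``unknown`` and logged.
    """
    ess: Set[str] = set().union(*[set(s) for s in essential_refs])
    non: Set[str] = set().union(*[set(s) for s in nonessential_refs])
    conflict = ess & non
    if conflict:
        logger.warning("%d genes in both essential and non-essential unions -> unknown",
                       len(conflict))
    labels = pd.Series("unknown", index=pd.Index(sorted(set(all_genes))), name="essential")
    labels[labels.index.isin(ess - conflict)] = "essential"
    labels[labels.index.isin(non - conflict)] = "non-essential"
    return labels


def ppi_degree(edges: pd.DataFrame) -> pd.Series:
    """Distinct interaction partners per gene; self-edges do not count.

    Homomerization is tracked as a separate flag, so a gene whose only edge
    is a self-edge has degree 0.
    """
    e = edges[edges["gene_a"] != edges["gene_b"]]
    idx = canonical_pair_index(e["gene_a"], e["gene_b"]).unique()
    a = pd.Series([p[0] for p in idx])
    b = pd.Series([p[1] for p in idx])
    all_genes = pd.Index(sorted(set(edges["gene_a"]) | set(edges["gene_b"])))
    deg = pd.concat([a, b]).value_counts().reindex(all_genes).fillna(0).astype(int)
    deg.name = "ppi_degree"
    deg.index.name = "gene_id"
    return deg
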