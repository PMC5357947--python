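"""Primary-response and memory-responsive gene classification.

A gene is a primary-response gene (PRG) when its log2 expression in the
stimulated state (ST) exceeds both the non-stimulated (NS) and
re-stimulated (RS) states by at least 0.5; a memory-responsive gene (MRG)
mirrors this for RS.  The two rules are mutually exclusive by construction.
Gene classes are then associated with accessibility region sets by asking
whether a gene's TSS lies within 50 kb of any region of the set, with a
Fisher exact test against the all-genes background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_CONDITIONS = ("NS", "ST", "RS")
DEFAULT_THRESHOLD = 0.5  # log2 units
DEFAULT_WINDOW = 50_000  # bp


def classify_genes(expr: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Classify genes as PRG, MRG or other from a log2 expression matrix.

    ``expr`` is genes x conditions and must contain NS, ST and RS columns.
    Returns a DataFrame indexed by gene with ``gene_class`` and the four
    pairwise log2 margins.
    """
    missing = [c for c in REQUIRED_CONDITIONS if c not in expr.columns]
    if missing:
        raise ValueError(f"expression matrix missing condition(s): {missing}")
    ns = expr["NS"].to_numpy(dtype=float)
    st = expr["ST"].to_numpy(dtype=float)
    rs = expr["RS"].to_numpy(dtype=float)
    if not np.isfinite(np.concatenate([ns, st, rs])).all():
        raise ValueError("expression values must be finite")
    st_ns, st_rs = st - ns, st - rs
    rs_ns, rs_st = rs - ns, rs - st
    prg = (st_ns >= threshold) & (st_rs >= threshold)
    mrg = (rs_ns >= threshold) & (rs_st >= threshold)
    cls = np.where(prg, "PRG", np.where(mrg, "MRG", "other"))
    return pd.DataFrame(
        {
            "gene_class": cls,
            "margin_st_ns": st_ns,
            "margin_st_rs": st_rs,
            "margin_rs_ns": rs_ns,
            "margin_rs_st": rs_st,
        },
        index=expr.index.rename("gene_id"),
    )


def tss_within_window(
    gene_tss: pd.DataFrame,
    set_regions: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.Series:
    """True per gene iff its TSS is within ``window`` bp of any region edge.

    ``gene_tss`` needs columns chrom/tss (one row per gene, indexed by
    gene); distance is TSS to the nearest region edge (zero inside a
    region), window inclusive.
    """
    result = pd.Series(False, index=gene_tss.index, name="within")
    for chrom, regs in set_regions.groupby("chrom"):
        genes = gene_tss[gene_tss["chrom"] == chrom]
        if len(genes) == 0:
            continue
        starts = regs["start"].to_numpy()
        ends = regs["end"].to_numpy()
        tss = genes["tss"].to_numpy()[:, None]
        # gap to region: 0 when tss in [start, end); edge distance otherwise
        gap = np.maximum(starts[None, :] - tss, 0) + np.maximum(tss - (ends[None, :] - 1), 0)
        result.loc[genes.index] = (gap <= window).any(axis=1)
    return result


def min_distance_to_set(
    gene_tss: pd.DataFrame, set_regions: pd.DataFrame
) -> pd.Series:
    """Minimum TSS-to-region-edge distance per gene (inf on empty set)."""
    result = pd.Series(np.inf, index=gene_tss.index, name="min_distance")
    for chrom, regs in set_regions.groupby("chrom"):
        genes = gene_tss[gene_tss["chrom"] == chrom]
        if len(genes) == 0:
            continue
        starts = regs["start"].to_numpy()
        ends = regs["end"].to_numpy()
        tss = genes["tss"].to_numpy()[:, None]
        gap = np.maximum(starts[None, :] - tss, 0) + np.maximum(tss - (ends[None, :] - 1), 0)
        result.loc[genes.index] = gap.min(axis=1)
    return result


@dataclass
class ProximityEnrichment:
    """2x2 Fisher enrichment of a gene class near a region set vs background."""

    set_label: str
    gene_class: str
    n_class_within: int
    n_class_total: int
    n_background_within: int
    n_background_total: int
    fisher_p: float
    odds_ratio: float

    @property
    def percent_within(self) -> float:
        return 100.0 * self.n_class_within / self.n_class_total


def proximity_enrichment(
    classes: pd.DataFrame,
    within: pd.Series,
    set_label: str,
    gene_class: str,
    alternative: str = "two-sided",
) -> ProximityEnrichment:
    """Fisher exact test: is the gene class nearer the set than expected?

    The reported background counts cover every gene on the array (the
    class included); the 2x2 Fisher table itself contrasts the class with
    its complement so the margins are disjoint.  The odds ratio uses the
    cross-product with a 0.5 Haldane correction applied only when a cell
    is zero.
    """
    if len(classes) == 0:
        raise ValueError("empty background")
    is_class = classes["gene_class"] == gene_class
    if not is_class.any():
        raise ValueError(f"no genes in class {gene_class!r}")
    w = within.reindex(classes.index).fillna(False).astype(bool)
    a = int((is_class & w).sum())          # class, within
    b = int((is_class & ~w).sum())         # class, outside
    c = int((~is_class & w).sum())         # non-class, within
    d = int((~is_class & ~w).sum())
    table = np.array([[a, b], [c, d]])
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    if (table == 0).any():
        ta, tb, tc, td = (x + 0.5 for x in (a, b, c, d))
    else:
        ta, tb, tc, td = a, b, c, d
    odds = (ta * td) / (tb * tc)
    return ProximityEnrichment(
        set_label, gene_class, a, int(is_class.sum()), int(w.sum()), len(classes),
        p, float(odds),
    )


def enrichment_table(
    classes: pd.DataFrame,
    gene_tss: pd.DataFrame,
    regions: pd.DataFrame,
    assignments: pd.DataFrame,
    set_labels: list[str] | None = None,
    gene_classes: tuple[str, ...] = ("PRG", "MRG"),
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """One enrichment row per (region set, gene class).

    Skips classes with no genes and sets with no regions.
    """
    regions = regions.set_index("region_id") if "region_id" in regions.columns else regions
    labels = set_labels or sorted(set(assignments["set_label"]) - {"unchanged"})
    rows = []
    for lbl in labels:
        rids = assignments.index[assignments["set_label"] == lbl]
        set_regs = regions.loc[regions.index.intersection(rids)]
        if len(set_regs) == 0:
            continue
        w = tss_within_window(gene_tss, set_regs, window)
        for gc in gene_classes:
            if not (classes["gene_class"] == gc).any():
                continue
            e = proximity_enrichment(classes, w, lbl, gc)
            rows.append(
                {
                    "set_label": lbl, "gene_class": gc,
                    "n_class_within": e.n_class_within, "n_class_total": e.n_class_total,
                    "percent_within": e.percent_within,
                    "n_background_within": e.n_background_within,
                    "n_background_total": e.n_background_total,
                    "fisher_p": e.fisher_p, "odds_ratio": e.odds_ratio,
                }
            )
    return pd.DataFrame(rows)


def nearby_gene_report(
    assignments: pd.DataFrame,
    regions: pd.DataFrame,
    classes: pd.DataFrame,
    gene_tss: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    gene_classes: tuple[str, ...] = ("PRG", "MRG"),
) -> pd.DataFrame:
    """Every (set, gene, class, min distance) pair within the window.

    A gene appears at most once per set, at its minimum distance; rows are
    sorted by set then distance.
    """
    regions = regions.set_index("region_id") if "region_id" in regions.columns else regions
    keep = classes["gene_class"].isin(gene_classes)
    genes = gene_tss.loc[gene_tss.index.intersection(classes.index[keep])]
    rows = []
    for lbl in sorted(set(assignments["set_label"]) - {"unchanged"}):
        rids = assignments.index[assignments["set_label"] == lbl]
        set_regs = regions.loc[regions.index.intersection(rids)]
        if len(set_regs) == 0 or len(genes) == 0:
            continue
        dist = min_distance_to_set(genes, set_regs)
        near = dist[dist <= window]
        for gene_id, d in near.items():
            rows.append(
                {
                    "set_label": lbl,
                    "gene_id": gene_id,
                    "gene_class": classes.loc[gene_id, "gene_class"],
                    "min_distance": int(d),
                }
            )
    out = pd.DataFrame(rows, columns=["set_label", "gene_id", "gene_class", "min_distance"])
    return out.sort_values(["set_label", "min_distance"], kind="mergesort").reset_index(drop=True)
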