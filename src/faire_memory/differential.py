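"""Differential accessibility calling and the transcriptional-memory set taxonomy.

A region is called changed between two samples when its normalised fold
change reaches ``fc_cutoff`` (default 1.75) and the larger of the two
normalised counts reaches ``min_reads`` (default 30).  The three
state-vs-NS call directions then place each changed region into one of the
sets a-g (increases) or h-n (decreases); sets b, e, i and l are subdivided
by whether accessibility is >=1.75-fold higher in primary stimulation
(suffix 1) or re-stimulation (suffix 2), with an explicit residual suffix 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .region_core import RegionCountMatrix

logger = logging.getLogger(__name__)

#: up/down pattern over (ST, SW, RS) vs NS -> set label.
INCREASED_PATTERNS = {
    (1, 0, 0): "a", (1, 0, 1): "b", (0, 0, 1): "c", (1, 1, 0): "d",
    (1, 1, 1): "e", (0, 1, 1): "f", (0, 1, 0): "g",
}
DECREASED_PATTERNS = {
    (1, 0, 0): "h", (1, 0, 1): "i", (0, 0, 1): "j", (1, 1, 0): "k",
    (1, 1, 1): "l", (0, 1, 1): "m", (0, 1, 0): "n",
}
INCREASED_SETS = frozenset("abcdefg") | {"b1", "b2", "b0", "e1", "e2", "e0"}
DECREASED_SETS = frozenset("hijklmn") | {"i1", "i2", "i0", "l1", "l2", "l0"}
SUBDIVIDED = ("b", "e", "i", "l")

META_GROUPS = {
    "a": "primary_enriched", "b1": "primary_enriched", "e1": "primary_enriched",
    "b2": "secondary_enriched", "c": "secondary_enriched", "e2": "secondary_enriched",
    "f": "sw_enriched", "g": "sw_enriched",
    "b0": "other_increased", "e0": "other_increased", "d": "other_increased",
    "unchanged": "unchanged",
}
META_GROUPS.update({lbl: "decreased" for lbl in DECREASED_SETS})


def call_change(
    norm_counts: RegionCountMatrix,
    test: str,
    ref: str,
    fc_cutoff: float = 1.75,
    min_reads: float = 30,
    c0: float = 0.5,
) -> pd.DataFrame:
    """Call per-region accessibility change between two samples.

    Returns a DataFrame indexed by region_id with columns ``fold_change``
    (test/ref on the normalised scale, pseudocount ``c0``), ``max_count``
    (max of the two normalised counts) and ``direction`` in
    {up, down, unchanged}.
    """
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must be > 1")
    t = norm_counts.counts[test].to_numpy(dtype=float)
    r = norm_counts.counts[ref].to_numpy(dtype=float)
    fold = (t + c0) / (r + c0)
    max_count = np.maximum(t, r)
    direction = np.where(
        (fold >= fc_cutoff) & (max_count >= min_reads), "up",
        np.where((fold <= 1.0 / fc_cutoff) & (max_count >= min_reads), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "fold_change": fold,
            "max_count": max_count,
            "direction": direction,
            "test": test,
            "ref": ref,
        },
        index=norm_counts.counts.index.rename("region_id"),
    )


@dataclass
class FprCalibration:
    """Empirical false-positive calibration from a biologically null pair.

    The number of changed calls on a null comparison (NS DMSO vs NS
    rottlerin) estimates the false positives any real comparison carries;
    dividing it by each real comparison's call count gives a per-comparison
    false-positive rate, summarised as a (min, max) range.
    """

    null_comparison: tuple[str, str]
    n_null_called: int
    n_total_regions: int
    fp_rate_per_comparison: dict[str, float]

    @property
    def expected_fp(self) -> int:
        return self.n_null_called

    @property
    def rate_range(self) -> tuple[float, float]:
        rates = [r for r in self.fp_rate_per_comparison.values() if np.isfinite(r)]
        if not rates:
            return (float("nan"), float("nan"))
        return (min(rates), max(rates))


def calibrate_fpr(
    null_calls: pd.DataFrame,
    real_calls_by_comparison: dict[str, pd.DataFrame],
) -> FprCalibration:
    """Derive expected false positives and per-comparison FP rates."""
    n_null = int((null_calls["direction"] != "unchanged").sum())
    rates: dict[str, float] = {}
    for name, calls in real_calls_by_comparison.items():
        n_called = int((calls["direction"] != "unchanged").sum())
        if n_called == 0:
            logger.warning("calibrate_fpr: comparison %s has zero calls; rate undefined", name)
            rates[name] = float("nan")
        else:
            rate = n_null / n_called
            if rate > 1:
                logger.warning("calibrate_fpr: rate > 1 for %s (%.2f)", name, rate)
            rates[name] = rate
    null_pair = (str(null_calls["test"].iloc[0]), str(null_calls["ref"].iloc[0])) if len(null_calls) else ("", "")
    return FprCalibration(null_pair, n_null, len(null_calls), rates)


def classify_sets(
    calls_st: pd.DataFrame, calls_sw: pd.DataFrame, calls_rs: pd.DataFrame
) -> pd.DataFrame:
    """Assign each region its a-n set label from the three vs-NS directions.

    Increases map through patterns a-g and decreases mirror to h-n.  A
    region with both up and down calls across the three comparisons takes
    the majority direction (ties resolved toward up) and is flagged
    ``ambiguous``; with no calls at all it is ``unchanged``.
    """
    idx = calls_st.index
    if not (idx.equals(calls_sw.index) and idx.equals(calls_rs.index)):
        raise ValueError("the three call lists must cover the same regions in the same order")
    dirs = np.stack(
        [c["direction"].to_numpy() for c in (calls_st, calls_sw, calls_rs)], axis=1
    )
    up = dirs == "up"
    down = dirs == "down"
    n_up = up.sum(axis=1)
    n_down = down.sum(axis=1)

    labels = np.full(len(idx), "unchanged", dtype=object)
    ambiguous = (n_up > 0) & (n_down > 0)
    use_up = (n_up >= n_down) & (n_up > 0)
    use_down = (n_down > n_up)
    for i in np.flatnonzero(use_up):
        labels[i] = INCREASED_PATTERNS[tuple(up[i].astype(int))]
    for i in np.flatnonzero(use_down):
        labels[i] = DECREASED_PATTERNS[tuple(down[i].astype(int))]
    return pd.DataFrame(
        {"set_label": labels, "ambiguous": ambiguous},
        index=idx.rename("region_id"),
    )


def subdivide_by_st_rs(
    assignments: pd.DataFrame,
    norm_counts: RegionCountMatrix,
    st_sample: str = "ST_DMSO",
    rs_sample: str = "RS_DMSO",
    ratio_cutoff: float = 1.75,
    c0: float = 0.5,
) -> pd.DataFrame:
    """Split sets b, e, i, l by the ST/RS accessibility ratio.

    RS/ST >= cutoff appends suffix 2, ST/RS >= cutoff suffix 1, neither
    suffix 0 (kept as its own residual label).  Other labels pass through.
    """
    out = assignments.copy()
    st = norm_counts.counts[st_sample].reindex(out.index).to_numpy(dtype=float)
    rs = norm_counts.counts[rs_sample].reindex(out.index).to_numpy(dtype=float)
    rs_over_st = (rs + c0) / (st + c0)
    labels = out["set_label"].to_numpy(dtype=object).copy()
    for base in SUBDIVIDED:
        sel = labels == base
        if not sel.any():
            continue
        suffix = np.where(
            rs_over_st[sel] >= ratio_cutoff, "2",
            np.where(1.0 / rs_over_st[sel] >= ratio_cutoff, "1", "0"),
        )
        labels[sel] = np.char.add(base, suffix)
    out["set_label"] = labels
    return out


def assign_meta_groups(assignments: pd.DataFrame) -> pd.DataFrame:
    """Tag each subdivided set label with its memory meta-group.

    Primary-enriched (a, b1, e1), secondary-enriched (b2, c, e2),
    SW-enriched (f, g); all decreased sets collapse to ``decreased``; the
    residual increased labels (b0, e0, d) report as ``other_increased``.
    """
    out = assignments.copy()
    labels = out["set_label"]
    unknown = sorted(set(labels) - set(META_GROUPS))
    if unknown:
        raise ValueError(f"unknown set labels (run subdivide_by_st_rs first?): {unknown}")
    out["meta_group"] = labels.map(META_GROUPS)
    return out


def flag_rottlerin_sensitive(
    assignments: pd.DataFrame,
    norm_counts: RegionCountMatrix,
    calls_by_state: dict[str, pd.DataFrame],
    attenuation_cutoff: float = 1.75,
    c0: float = 0.5,
) -> pd.DataFrame:
    """Flag called changes whose magnitude collapses under rottlerin.

    For a region called up in DMSO state X vs NS, the change is rottlerin
    sensitive iff DMSO_X / ROTT_X >= cutoff; for a down call the ratio is
    inverted.  One boolean column per state (``rott_sensitive_ST`` ...).
    States lacking a matched rottlerin sample are skipped with a warning.
    """
    out = assignments.copy()
    meta = norm_counts.sample_meta
    for state, calls in calls_by_state.items():
        dmso = meta[(meta["state"] == state) & (meta["treatment"] == "DMSO")].index
        rott = meta[(meta["state"] == state) & (meta["treatment"] == "ROTT")].index
        col = f"rott_sensitive_{state}"
        if len(dmso) == 0 or len(rott) == 0:
            logger.warning("flag_rottlerin_sensitive: no matched DMSO/ROTT pair for %s; skipped", state)
            continue
        d = norm_counts.counts[dmso[0]].reindex(out.index).to_numpy(dtype=float)
        r = norm_counts.counts[rott[0]].reindex(out.index).to_numpy(dtype=float)
        ratio = (d + c0) / (r + c0)
        direction = calls["direction"].reindex(out.index).to_numpy()
        sensitive = np.where(
            direction == "up", ratio >= attenuation_cutoff,
            np.where(direction == "down", 1.0 / ratio >= attenuation_cutoff, False),
        )
        out[col] = sensitive.astype(bool)
    return out


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p with continuity correction (normal approximation)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each subset needs at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        logger.warning("wilcoxon_rank_sum: all values tied; p = 1")
        return 1.0
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True).pvalue
    )


def rs_vs_st_ratio_distribution(
    assignments: pd.DataFrame,
    norm_counts: RegionCountMatrix,
    subset_a: pd.Index,
    subset_b: pd.Index,
    st_sample: str = "ST_DMSO",
    rs_sample: str = "RS_DMSO",
    c0: float = 0.5,
) -> dict:
    """RS/ST accessibility ratios for two region subsets plus a rank-sum p.

    Used to ask whether e.g. rottlerin-sensitive ST increases sit higher in
    RS than the full ST>NS population does.
    """
    st = norm_counts.counts[st_sample]
    rs = norm_counts.counts[rs_sample]
    ratio = (rs + c0) / (st + c0)
    ra = ratio.reindex(subset_a).to_numpy(dtype=float)
    rb = ratio.reindex(subset_b).to_numpy(dtype=float)
    return {"ratios_a": ra, "ratios_b": rb, "p_value": wilcoxon_rank_sum(ra, rb)}
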