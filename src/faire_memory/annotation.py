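"""Genomic annotation of accessibility regions.

Covers nearest-transcript TSS annotation with a fixed feature priority
(5'UTR > 3'UTR > exon > intron > promoter > upstream > intergenic),
chromatin-state segmentation lookup with coarse mark-based grouping and
state-transition tables between cell types, and histone tag profiles in
100-bp bins +/-1 kb around region midpoints scaled per million mapped
reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

FEATURE_PRIORITY = ["utr5", "utr3", "exon", "intron", "promoter", "upstream", "intergenic"]
PROMOTER_WINDOW = (-1000, 0)     # bp relative to TSS, promoter = [-1 kb, 0)
UPSTREAM_WINDOW = (-10000, -1000)  # upstream = [-10 kb, -1 kb)
NO_TRANSCRIPT_DISTANCE = np.iinfo(np.int64).max  # sentinel


@dataclass
class TranscriptModel:
    """Minimal transcript model: TSS/TES plus exon and UTR intervals.

    Intervals are 0-based half-open genomic coordinates; ``tss`` is the
    strand-aware transcription start (the right end of the gene body on the
    minus strand).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def body(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def signed_distance(self, pos: int) -> int:
        """Orientation-aware distance from TSS; negative means upstream."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


def region_midpoints(regions: pd.DataFrame) -> np.ndarray:
    return ((regions["start"].to_numpy() + regions["end"].to_numpy()) // 2).astype(np.int64)


def annotate_nearest_tss(
    regions: pd.DataFrame, transcripts: list[TranscriptModel]
) -> pd.DataFrame:
    """Nearest-TSS annotation of region midpoints.

    Nearest = minimal absolute midpoint-to-TSS distance on the same
    chromosome; ties break to the lexicographically smallest transcript_id.
    Regions on a chromosome with no transcripts get an intergenic sentinel
    distance and a warning.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t.tss, t.transcript_id))

    mids = region_midpoints(regions)
    rows = []
    warned = set()
    for (_, reg), mid in zip(regions.iterrows(), mids):
        cands = by_chrom.get(reg["chrom"])
        if not cands:
            if reg["chrom"] not in warned:
                logger.warning("no transcripts on %s; regions there are intergenic", reg["chrom"])
                warned.add(reg["chrom"])
            rows.append((reg["region_id"], None, NO_TRANSCRIPT_DISTANCE))
            continue
        best = min(cands, key=lambda t: (abs(mid - t.tss), t.transcript_id))
        rows.append((reg["region_id"], best.transcript_id, best.signed_distance(mid)))
    return pd.DataFrame(
        rows, columns=["region_id", "nearest_transcript_id", "signed_tss_distance"]
    ).set_index("region_id")


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def classify_feature(midpoint: int, chrom: str, transcripts: list[TranscriptModel]) -> str:
    """Feature class of a region midpoint under the fixed priority order.

    The midpoint is tested against every transcript on its chromosome and
    the highest-priority satisfied class wins, so a point inside one
    transcript's exon outranks another transcript's promoter.
    """
    best = len(FEATURE_PRIORITY) - 1  # intergenic
    for t in transcripts:
        if t.chrom != chrom:
            continue
        cls = "intergenic"
        lo, hi = t.body
        d = t.signed_distance(midpoint)
        if _in_any(midpoint, t.utr5):
            cls = "utr5"
        elif _in_any(midpoint, t.utr3):
            cls = "utr3"
        elif _in_any(midpoint, t.exons):
            cls = "exon"
        elif lo <= midpoint < hi:
            cls = "intron"
        elif PROMOTER_WINDOW[0] <= d < PROMOTER_WINDOW[1]:
            cls = "promoter"
        elif UPSTREAM_WINDOW[0] <= d < UPSTREAM_WINDOW[1]:
            cls = "upstream"
        best = min(best, FEATURE_PRIORITY.index(cls))
    return FEATURE_PRIORITY[best]


def annotate_features(
    regions: pd.DataFrame, transcripts: list[TranscriptModel]
) -> pd.DataFrame:
    """Full feature annotation: nearest TSS, signed distance, feature class."""
    ann = annotate_nearest_tss(regions, transcripts)
    mids = region_midpoints(regions)
    classes = [
        classify_feature(int(mid), reg["chrom"], transcripts)
        for (_, reg), mid in zip(regions.iterrows(), mids)
    ]
    ann["feature_class"] = classes
    return ann


# ---------------------------------------------------------------------------
# chromatin states

#: coarse grouping by defining histone mark; keys are example segmentation
#: labels, real runs supply their own map covering the dialect in use.
DEFAULT_STATE_GROUPS = {
    "Quies": "quiescent",
    "ReprPC": "repressive",        # H3K27me3
    "Tx": "transcription",         # H3K36me3
    "Enh": "enhancer",             # H3K4me1 (/H3K27ac)
    "EnhWk": "enhancer",
    "EnhA": "enhancer",
    "EnhPois": "enhancer",
    "Tss": "permissive",           # H3K4me3
    "TssFlnk": "permissive",
    "Het": "heterochromatin",      # H3K9me3
}
STATE_GROUP_NAMES = (
    "quiescent", "repressive", "transcription", "enhancer", "permissive", "heterochromatin"
)


def group_chromatin_states(segments: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """Attach the coarse mark-based group to every segment.

    ``segments`` needs columns chrom/start/end/state_label; any label
    missing from ``group_map`` is an error listing the offenders.
    """
    out = segments.copy()
    if len(out) == 0:
        out["group"] = pd.Series(dtype=object)
        return out
    unmapped = sorted(set(out["state_label"]) - set(group_map))
    if unmapped:
        raise ValueError(f"state labels missing from group_map: {unmapped}")
    out["group"] = out["state_label"].map(group_map)
    return out


def _state_at_midpoints(regions: pd.DataFrame, segments: pd.DataFrame) -> pd.Series:
    """State label at each region midpoint; 'unannotated' where uncovered."""
    mids = region_midpoints(regions)
    result = np.full(len(regions), "unannotated", dtype=object)
    for chrom, seg in segments.groupby("chrom"):
        sel = (regions["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        seg = seg.sort_values("start")
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        labels = seg["state_label"].to_numpy()
        pos = mids[sel]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        vals = np.full(len(pos), "unannotated", dtype=object)
        vals[ok] = labels[idx[ok]]
        result[sel] = vals
    return pd.Series(result, index=regions["region_id"].to_numpy(), name="state")


def annotate_region_states(
    regions: pd.DataFrame,
    segments_by_cell_type: dict[str, pd.DataFrame],
    group_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Per-region chromatin state per cell type plus transition tables.

    The state is read at the region midpoint.  For every ordered pair of
    cell types a transition table counts regions by (state in A -> state in
    B); row percentages are in a parallel ``*_pct`` table accessible via
    ``.attrs['row_pct']``.
    """
    cols = {}
    for cell_type, segments in segments_by_cell_type.items():
        states = _state_at_midpoints(regions, segments)
        cols[f"state_{cell_type}"] = states
        if group_map is not None:
            full_map = dict(group_map)
            full_map.setdefault("unannotated", "unannotated")
            unmapped = sorted(set(states.unique()) - set(full_map))
            if unmapped:
                raise ValueError(f"state labels missing from group_map: {unmapped}")
            cols[f"group_{cell_type}"] = states.map(full_map).rename(None)
    per_region = pd.DataFrame(cols)
    per_region.index.name = "region_id"

    transitions: dict[tuple[str, str], pd.DataFrame] = {}
    cell_types = list(segments_by_cell_type)
    for i, ct1 in enumerate(cell_types):
        for ct2 in cell_types[i + 1:]:
            tab = pd.crosstab(per_region[f"state_{ct1}"], per_region[f"state_{ct2}"])
            row_pct = tab.div(tab.sum(axis=1), axis=0) * 100
            tab.attrs["row_pct"] = row_pct
            transitions[(ct1, ct2)] = tab
    return per_region, transitions


# ---------------------------------------------------------------------------
# tag profiles


def profile_tags(
    midpoints: np.ndarray,
    chroms: np.ndarray,
    tags: pd.DataFrame,
    total_mapped: int,
    flank: int = 1000,
    bin_size: int = 100,
) -> np.ndarray:
    """Histone tag profile around region midpoints.

    Tags (columns chrom/pos) falling in [midpoint - flank, midpoint + flank)
    are binned at ``bin_size`` resolution — bin index
    floor((pos - midpoint + flank)/bin) — and scaled by 1e6/total_mapped.
    Returns a (n_regions, 2*flank/bin) matrix.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    n_bins = 2 * flank // bin_size
    out = np.zeros((len(midpoints), n_bins), dtype=float)
    tags_by_chrom = {c: g["pos"].to_numpy() for c, g in tags.groupby("chrom")}
    for i, (mid, chrom) in enumerate(zip(midpoints, chroms)):
        pos = tags_by_chrom.get(chrom)
        if pos is None:
            continue
        rel = pos - int(mid) + flank
        in_window = (rel >= 0) & (rel < 2 * flank)
        if in_window.any():
            out[i] = np.bincount(rel[in_window] // bin_size, minlength=n_bins)
    return out * (1e6 / total_mapped)


def average_profile(profiles: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Per-bin mean profile over the regions selected by a boolean mask."""
    sel = profiles[np.asarray(membership, dtype=bool)]
    if len(sel) == 0:
        return np.zeros(profiles.shape[1])
    return sel.mean(axis=0)


def compare_profiles(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p (continuity-corrected) between two
    profile value vectors, e.g. a histone mark's signal over two region sets."""
    return wilcoxon_rank_sum(values_a, values_b)
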