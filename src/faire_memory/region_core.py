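"""Region handling for accessibility count data.

Regions are pandas DataFrames with columns ``chrom`` (str), ``start`` /
``end`` (0-based, half-open) and ``region_id``.  Reads are DataFrames with
``chrom``, ``start`` (0-based leftmost mapped base), ``strand`` and
``sample``.  Counts live in a :class:`RegionCountMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REGION_COLUMNS = ["chrom", "start", "end", "region_id"]

#: 4-state model metadata: (state, treatment) per canonical sample id.
CANONICAL_SAMPLES = {
    "NS_DMSO": ("NS", "DMSO"), "ST_DMSO": ("ST", "DMSO"),
    "SW_DMSO": ("SW", "DMSO"), "RS_DMSO": ("RS", "DMSO"),
    "NS_ROTT": ("NS", "ROTT"), "ST_ROTT": ("ST", "ROTT"),
    "SW_ROTT": ("SW", "ROTT"), "RS_ROTT": ("RS", "ROTT"),
}


@dataclass
class RegionCountMatrix:
    """Per-region read counts across samples.

    Parameters
    ----------
    counts
        DataFrame indexed by region_id with one column per sample.  Raw
        counts are non-negative integers; normalised counts are reals.
    sample_meta
        DataFrame indexed by sample id with columns ``state`` (NS/ST/SW/RS)
        and ``treatment`` (DMSO/ROTT).
    total_mapped
        Total mapped reads per sample (library size), used for tag-profile
        scaling; populated by :func:`count_reads`.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    total_mapped: dict[str, int] = field(default_factory=dict)
    normalised: bool = False

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample(self, sample_id: str) -> pd.Series:
        return self.counts[sample_id]

    def copy(self) -> "RegionCountMatrix":
        return RegionCountMatrix(
            self.counts.copy(), self.sample_meta.copy(),
            dict(self.total_mapped), self.normalised,
        )


def make_sample_meta(sample_ids=None) -> pd.DataFrame:
    """Metadata table for the canonical 8-sample (4 states x 2 treatments) design."""
    ids = list(sample_ids) if sample_ids is not None else list(CANONICAL_SAMPLES)
    rows = []
    for sid in ids:
        if sid in CANONICAL_SAMPLES:
            state, treatment = CANONICAL_SAMPLES[sid]
        else:
            parts = sid.split("_")
            state, treatment = parts[0], parts[1] if len(parts) > 1 else "DMSO"
        rows.append((sid, state, treatment))
    return pd.DataFrame(rows, columns=["sample_id", "state", "treatment"]).set_index("sample_id")


def _validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    if not (regions["start"] < regions["end"]).all():
        bad = regions[~(regions["start"] < regions["end"])]
        raise ValueError(f"malformed region coordinates (start >= end):\n{bad.head()}")
    return regions


def merge_regions(region_lists: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool region lists and merge overlapping intervals into one.

    Two intervals merge iff they share at least one base; book-ended
    intervals (end == next start) stay separate, matching half-open BED
    semantics.  Output is sorted, disjoint, and gets fresh sequential
    ``region_id`` values (``region_00001`` ...).
    """
    frames = [df[["chrom", "start", "end"]] for df in region_lists if len(df)]
    if not frames:
        return pd.DataFrame(columns=REGION_COLUMNS)
    pooled = pd.concat(frames, ignore_index=True)
    _validate_regions(pooled)
    pooled = pooled.sort_values(["chrom", "start", "end"], kind="mergesort")

    out_chrom, out_start, out_end = [], [], []
    for chrom, grp in pooled.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # sweep: a new block starts where start > running max of previous ends
        run_end = np.maximum.accumulate(ends)
        new_block = np.ones(len(starts), dtype=bool)
        new_block[1:] = starts[1:] > run_end[:-1] - 1  # overlap needs >=1 shared base
        first = np.flatnonzero(new_block)
        last = np.append(first[1:] - 1, len(starts) - 1)
        # within a block run_end equals the block's own max end (a new block
        # only opens past the previous running maximum)
        out_chrom.extend([chrom] * len(first))
        out_start.extend(starts[first].tolist())
        out_end.extend(run_end[last].tolist())
    merged = pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})
    width = max(5, len(str(len(merged))))
    merged["region_id"] = [f"region_{i + 1:0{width}d}" for i in range(len(merged))]
    return merged


def filter_chromosomes(
    regions: pd.DataFrame, exclude_patterns: tuple[str, ...] = ("chrM", "chrUn")
) -> pd.DataFrame:
    """Drop regions whose chromosome name starts with any excluded prefix.

    Mitochondrial (chrM) and unplaced (chrUn*) contigs are removed by
    default before counting.
    """
    if not exclude_patterns:
        return regions.copy()
    keep = ~regions["chrom"].astype(str).str.startswith(tuple(exclude_patterns))
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_chromosomes: removed %d region(s) on %s", n_removed, exclude_patterns)
    return regions[keep].reset_index(drop=True)


def extend_reads(reads: pd.DataFrame, extension: int = 200) -> pd.DataFrame:
    """Extend each read to ``extension`` bp in its 3' direction.

    Plus strand: [start, start+extension).  Minus strand: the extended
    interval ends at the read's 3'-most base + 1, i.e. [end-extension, end)
    where ``end`` is start + read_length (an ``end`` column is used when
    present, else ``read_length`` defaults to 50).  Unknown strand is
    treated as plus with a warning.
    """
    strand = reads["strand"].astype(str).to_numpy()
    unknown = ~np.isin(strand, ["+", "-"])
    if unknown.any():
        logger.warning("extend_reads: %d read(s) with unknown strand counted as plus", unknown.sum())
    start = reads["start"].to_numpy()
    if "end" in reads.columns:
        end = reads["end"].to_numpy()
    else:
        end = start + int(reads.attrs.get("read_length", 50))
    minus = strand == "-"
    ext_start = np.where(minus, end - extension, start)
    out = reads.copy()
    out["ext_start"] = ext_start
    out["ext_end"] = ext_start + extension
    return out


def count_reads(
    regions: pd.DataFrame,
    reads: pd.DataFrame,
    extension: int = 200,
    sample_meta: pd.DataFrame | None = None,
) -> RegionCountMatrix:
    """Count extended reads per region and sample.

    A read contributes 1 to every region its extended interval overlaps by
    at least one base (any-overlap rule, not midpoint).  Because every
    extended read has identical length, overlap with a region [s, e) is
    equivalent to the extended start lying in (s - extension, e), which is
    counted with two binary searches per region.
    """
    _validate_regions(regions)
    if extension <= 0:
        raise ValueError("extension must be positive")
    ext = extend_reads(reads, extension)
    samples = sorted(ext["sample"].unique())
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    totals = ext.groupby("sample").size().to_dict()

    region_idx = {c: g for c, g in regions.groupby("chrom").groups.items()}
    for j, sample in enumerate(samples):
        sub = ext[ext["sample"] == sample]
        for chrom, grp in sub.groupby("chrom"):
            if chrom not in region_idx:
                continue
            ridx = region_idx[chrom]
            starts_sorted = np.sort(grp["ext_start"].to_numpy())
            rs = regions.loc[ridx, "start"].to_numpy()
            re_ = regions.loc[ridx, "end"].to_numpy()
            hi = np.searchsorted(starts_sorted, re_, side="left")
            lo = np.searchsorted(starts_sorted, rs - extension, side="right")
            counts[regions.index.get_indexer(ridx), j] = hi - lo

    cdf = pd.DataFrame(counts, index=regions["region_id"].to_numpy(), columns=samples)
    meta = sample_meta if sample_meta is not None else make_sample_meta(samples)
    return RegionCountMatrix(cdf, meta.loc[samples], {s: int(totals.get(s, 0)) for s in samples})


def ma_normalize(
    counts: RegionCountMatrix,
    reference: str = "NS_DMSO",
    method: str = "median",
    c0: float = 0.5,
    loess_frac: float = 0.4,
) -> RegionCountMatrix:
    """MA-normalise every sample to a common reference.

    With A = (log2 s + log2 ref)/2 and M = log2 s - log2 ref over regions
    (zero counts padded by the pseudocount ``c0`` so the logs exist; positive
    counts enter unpadded, which makes a pure rescaling normalise exactly),
    the systematic M trend is removed by subtracting either median(M)
    (``method="median"``) or a loess fit of M on A (``method="loess"``),
    then back-transforming to the count scale.  The reference column is
    returned unchanged, and the post-normalisation median M against the
    reference is ~0.
    """
    if reference not in counts.sample_ids:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    if method not in ("median", "loess"):
        raise ValueError(f"unknown method {method!r}")
    ref = counts.counts[reference].to_numpy(dtype=float)
    ref_pad = np.where(ref > 0, ref, c0)
    log_ref = np.log2(ref_pad)
    out = counts.counts.astype(float).copy()
    for sample in counts.sample_ids:
        if sample == reference:
            continue
        s = counts.counts[sample].to_numpy(dtype=float)
        s_pad = np.where(s > 0, s, c0)
        log_s = np.log2(s_pad)
        m = log_s - log_ref
        a = 0.5 * (log_s + log_ref)
        use = method
        if use == "loess" and (np.ptp(a) == 0 or np.ptp(m) == 0):
            logger.warning("ma_normalize: degenerate sample %s, falling back to median", sample)
            use = "median"
        if use == "median":
            correction = np.median(m)
        else:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            correction = lowess(m, a, frac=loess_frac, return_sorted=False)
        out[sample] = np.maximum(s_pad * np.exp2(-correction) - np.where(s > 0, 0.0, c0), 0.0)
    result = counts.copy()
    result.counts = out
    result.normalised = True
    return result


def sample_correlation(counts: RegionCountMatrix) -> pd.DataFrame:
    """Spearman rank correlation between all sample pairs.

    Ties get average ranks.  Requires at least 3 regions.
    """
    if len(counts.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if len(counts.counts) < 3:
        raise ValueError("need at least 3 regions for a meaningful rank correlation")
    rho = stats.spearmanr(counts.counts.to_numpy(), axis=0)[0]
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=counts.sample_ids, columns=counts.sample_ids)
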