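"""PWM motif scanning and combinatorial set-composition statistics.

Regions are standardised to a fixed width (300 bp, or 500 bp for
co-occupancy questions) around their midpoints, scanned on both strands
with log2-odds position weight matrices, and the resulting occurrence
table feeds three analyses: the set-composition shift of motif
combinations across the a-n accessibility taxonomy, Fisher enrichment of a
motif in a target region collection against a background collection, and a
GSEA-style running-sum enrichment over fold-change-ranked regions with
region-permutation significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PositionWeightMatrix:
    """Probability PWM with uniform-default background and log2-odds scoring.

    ``probabilities`` is 4 x L in A, C, G, T row order.  A pseudocount
    (fraction per cell, renormalised) smooths zero probabilities before
    log-odds are taken.
    """

    motif_id: str
    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudo: float = 0.01

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A,C,G,T)")
        colsums = self.probabilities.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"PWM columns must sum to 1 (got {colsums})")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.probabilities.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds matrix after pseudocount smoothing."""
        smoothed = self.probabilities + self.pseudo
        smoothed /= smoothed.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore"):  # zero prob -> -inf is intended
            return np.log2(smoothed / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=0))

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, **kw) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id, counts / counts.sum(axis=0, keepdims=True), **kw)


def read_jaspar(path_or_handle) -> list[PositionWeightMatrix]:
    """Read JASPAR-format PFMs (via Biopython) into probability PWMs."""
    from Bio import motifs as bio_motifs

    if hasattr(path_or_handle, "read"):
        records = bio_motifs.parse(path_or_handle, "jaspar")
    else:
        with open(path_or_handle) as fh:
            records = list(bio_motifs.parse(fh, "jaspar"))
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        name = m.matrix_id or m.name
        out.append(PositionWeightMatrix.from_counts(str(name), counts))
    return out


def write_jaspar(pwms: list[PositionWeightMatrix], path, scale: int = 100) -> None:
    """Write PWMs as JASPAR PFM text (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id} {p.motif_id}\n")
            counts = np.round(p.probabilities * scale).astype(int)
            for i, base in enumerate(BASES):
                row = " ".join(str(c) for c in counts[i])
                fh.write(f"{base}  [ {row} ]\n")


def standardize_regions(
    regions: pd.DataFrame, width: int = 300, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Resize every region to ``width`` bp centred on its midpoint.

    Midpoints of odd-length regions round down.  Regions running off a
    chromosome end are clipped and flagged in the ``clipped`` column.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if width % 2 != 0:
        raise ValueError("width must be even")
    mid = (regions["start"].to_numpy() + regions["end"].to_numpy()) // 2
    start = mid - width // 2
    end = mid + width // 2
    clipped = start < 0
    start = np.maximum(start, 0)
    if chrom_sizes:
        limits = regions["chrom"].map(chrom_sizes).to_numpy()
        clipped |= end > limits
        end = np.minimum(end, limits)
    out = regions.copy()
    out["start"] = start
    out["end"] = end
    out["clipped"] = clipped
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; anything outside ACGT (incl. N) -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        codes[arr == ord(base)] = i
    return codes


def _score_positions(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; windows containing non-ACGT -> -inf."""
    L = log_odds.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        window = codes[j : j + n]
        ok = window >= 0
        valid &= ok
        scores += np.where(ok, log_odds[np.clip(window, 0, 3), j], 0.0)
    scores[~valid] = -np.inf
    return scores


@dataclass
class MotifOccurrence:
    region_id: str
    motif_id: str
    count: int
    best_score_bits: float
    positions: list[int]
    strands: list[str]


def scan_pwm(
    sequence: str,
    pwm: PositionWeightMatrix,
    score_threshold_bits: float | None = None,
    relative_threshold: float = 0.8,
    both_strands: bool = True,
) -> MotifOccurrence:
    """Scan one sequence with one PWM.

    The default threshold is 80% of the motif's maximum attainable log2-odds
    score; pass ``score_threshold_bits`` for an absolute cutoff.  Both
    strands are scanned; minus-strand hits report the plus-strand offset of
    the motif's left edge.
    """
    threshold = (
        score_threshold_bits
        if score_threshold_bits is not None
        else relative_threshold * pwm.max_score
    )
    lo = pwm.log_odds
    positions: list[int] = []
    strands: list[str] = []
    best = -np.inf
    codes = _encode(sequence)
    fwd = _score_positions(codes, lo)
    for i in np.flatnonzero(fwd >= threshold):
        positions.append(int(i))
        strands.append("+")
    if len(fwd):
        best = max(best, float(fwd.max()))
    if both_strands:
        rc = _encode(reverse_complement(sequence))
        rev = _score_positions(rc, lo)
        L = pwm.length
        n = len(sequence)
        for i in np.flatnonzero(rev >= threshold):
            positions.append(int(n - L - i))
            strands.append("-")
        if len(rev):
            best = max(best, float(rev.max()))
    order = np.argsort(positions, kind="stable")
    return MotifOccurrence(
        region_id="",
        motif_id=pwm.motif_id,
        count=len(positions),
        best_score_bits=best,
        positions=[positions[i] for i in order],
        strands=[strands[i] for i in order],
    )


def scan_regions(
    sequences: dict[str, str],
    pwms: list[PositionWeightMatrix],
    score_threshold_bits: float | None = None,
    relative_threshold: float = 0.8,
) -> pd.DataFrame:
    """Occurrence table: one row per (region, motif) with count and best score."""
    rows = []
    for region_id, seq in sequences.items():
        for pwm in pwms:
            occ = scan_pwm(seq, pwm, score_threshold_bits, relative_threshold)
            rows.append(
                {
                    "region_id": region_id,
                    "motif_id": pwm.motif_id,
                    "count": occ.count,
                    "best_score_bits": occ.best_score_bits,
                    "positions": ",".join(map(str, occ.positions)),
                    "strands": "".join(occ.strands),
                }
            )
    return pd.DataFrame(rows)


def occurrence_matrix(occurrences: pd.DataFrame, min_count: int = 1) -> pd.DataFrame:
    """Boolean region x motif presence matrix at a minimum occurrence count."""
    pivot = occurrences.pivot_table(
        index="region_id", columns="motif_id", values="count", fill_value=0, aggfunc="sum"
    )
    return pivot >= min_count


@dataclass
class MotifCombinationStat:
    required_motifs: frozenset
    excluded_motifs: frozenset
    per_set_counts: pd.Series
    per_set_percent: pd.Series
    baseline_counts: pd.Series
    baseline_percent: pd.Series
    n_regions: int
    empty: bool = False


def combination_composition(
    occurrences: pd.DataFrame,
    assignments: pd.DataFrame,
    required: set[str],
    excluded: set[str] = frozenset(),
    min_count: int = 1,
) -> MotifCombinationStat:
    """Set composition of changed regions carrying a motif combination.

    Among regions in the changed sets (a-n and their subdivisions) that
    contain every required motif and none of the excluded ones, tabulate
    the count per set as a percentage of all selected regions; the
    unconditional composition of all changed regions is reported alongside
    as the baseline.
    """
    changed = assignments[assignments["set_label"] != "unchanged"]
    presence = occurrence_matrix(occurrences, min_count=min_count)
    presence = presence.reindex(changed.index, fill_value=False)
    mask = pd.Series(True, index=changed.index)
    for m in required:
        mask &= presence[m] if m in presence.columns else False
    for m in excluded:
        mask &= ~presence[m] if m in presence.columns else True
    selected = changed[mask]
    baseline_counts = changed["set_label"].value_counts().sort_index()
    baseline_pct = 100 * baseline_counts / baseline_counts.sum()
    if len(selected) == 0:
        logger.warning("combination_composition: no region matches the combination")
        empty_counts = baseline_counts * 0
        return MotifCombinationStat(
            frozenset(required), frozenset(excluded),
            empty_counts, empty_counts.astype(float),
            baseline_counts, baseline_pct, 0, empty=True,
        )
    counts = (
        selected["set_label"].value_counts().reindex(baseline_counts.index, fill_value=0)
    )
    pct = 100 * counts / counts.sum()
    return MotifCombinationStat(
        frozenset(required), frozenset(excluded), counts, pct,
        baseline_counts, baseline_pct, int(len(selected)),
    )


def background_motif_enrichment(
    target_presence: pd.Series,
    background_presence: pd.Series,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> dict:
    """Fisher enrichment of one motif in target vs background regions.

    Both inputs are boolean per-region presence vectors.  Returns the
    two-sided Fisher p, fold enrichment of presence rates (NaN when the
    motif is absent everywhere) and a significance flag at ``alpha``.
    """
    if len(target_presence) == 0 or len(background_presence) == 0:
        raise ValueError("both region collections must be non-empty")
    a = int(target_presence.sum())
    b = int(len(target_presence) - a)
    c = int(background_presence.sum())
    d = int(len(background_presence) - c)
    if a + c == 0:
        return {"p_value": 1.0, "fold_enrichment": float("nan"), "significant": False,
                "table": (a, b, c, d)}
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
    rate_t = a / (a + b)
    rate_b = c / (c + d)
    fold = rate_t / rate_b if rate_b > 0 else float("inf")
    return {"p_value": p, "fold_enrichment": fold, "significant": p <= alpha,
            "table": (a, b, c, d)}


@dataclass
class RegionGseaResult:
    motif_id: str
    region_set_size: int
    es: float
    nes: float
    p_perm: float
    n_permutations: int
    seed: int
    running_sum: np.ndarray = field(repr=False, default=None)


def _enrichment_score(order_is_hit: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed max deviation of the weighted hit/miss running sum.

    ``weights`` are |score|^exponent in ranking order; hits step up by
    their weight share, misses step down by 1/(N - n_hits).
    """
    n = len(order_is_hit)
    n_hit = int(order_is_hit.sum())
    hit_mass = weights[order_is_hit].sum()
    hit_steps = weights / hit_mass if hit_mass > 0 else np.full(n, 1.0 / n_hit)
    steps = np.where(order_is_hit, hit_steps, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def region_gsea(
    ranked_regions: pd.DataFrame,
    member_set: set[str],
    motif_id: str = "",
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    permutation: str = "sample",
) -> RegionGseaResult:
    """GSEA-style enrichment of a region set in a fold-change ranking.

    ``ranked_regions`` has columns region_id and score (the ranking
    statistic, e.g. log fold change); rows are sorted by descending score
    internally.  Significance is by permuting set membership over regions
    (region permutation): p = (1 + #{|ES*| >= |ES|}) / (1 + n_perm); NES is
    ES over the mean |ES*| of the same sign.  With
    ``permutation="exhaustive"`` every distinct membership of the same size
    is enumerated instead of sampled (small rankings only).
    """
    ids = ranked_regions["region_id"].to_numpy()
    scores = ranked_regions["score"].to_numpy(dtype=float)
    order = np.argsort(-scores, kind="stable")
    ids, scores = ids[order], scores[order]
    hits = np.isin(ids, list(member_set))
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("member_set has no region in the ranking")
    if n_hit == len(ids):
        raise ValueError("member_set must be a proper subset of the ranking")
    weights = np.abs(scores) ** weight_exponent
    es, running = _enrichment_score(hits, weights)

    idx = np.arange(len(ids))
    if permutation == "exhaustive":
        from itertools import combinations

        memberships = list(combinations(idx, n_hit))
        n_perm = len(memberships)
        perm_es = np.empty(n_perm)
        for k, combo in enumerate(memberships):
            perm_hits = np.zeros(len(ids), dtype=bool)
            perm_hits[list(combo)] = True
            perm_es[k], _ = _enrichment_score(perm_hits, weights)
    elif permutation == "sample":
        rng = np.random.default_rng(seed)
        perm_es = np.empty(n_perm)
        for k in range(n_perm):
            perm_hits = np.zeros(len(ids), dtype=bool)
            perm_hits[rng.choice(idx, size=n_hit, replace=False)] = True
            perm_es[k], _ = _enrichment_score(perm_hits, weights)
    else:
        raise ValueError(f"unknown permutation mode {permutation!r}")
    p = (1 + int((np.abs(perm_es) >= abs(es)).sum())) / (1 + n_perm)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(perm_es).mean()
    nes = es / denom if denom > 0 else 0.0
    return RegionGseaResult(motif_id, n_hit, es, float(nes), float(p), n_perm, seed, running)
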