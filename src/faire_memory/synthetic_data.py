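"""Synthetic FAIRE-seq fixture generator with planted ground truth.

Emulates the data the downstream analysis consumes: genomic regions with
negative-binomial read counts over the 8-sample design (4 T-cell states x
DMSO/rottlerin), raw read positions that round-trip exactly through the
extended-read counter, transcript models, a log2 expression matrix with
planted primary-response (PRG) and memory-responsive (MRG) genes, and
region sequences with planted motif instances.

Noise model
-----------
Count overdispersion is decomposed Gamma-Poisson style: a per-region
accessibility propensity g_i ~ Gamma(mean 1) shared by all samples carries
most of ``nb_dispersion`` (region-to-region variability in how open a
region is), and a smaller per-sample negative-binomial component
(``sample_dispersion_fraction`` of the total) models library-to-library
technical noise.  Marginally each count is negative binomial with
dispersion ~``nb_dispersion``; between-sample fold changes carry only the
technical component, and a biologically null sample pair (NS DMSO vs NS
rottlerin) shows a small, fold-cutoff-monotone false-positive rate as real
data does.  ``nb_dispersion = 0`` switches noise off entirely (counts are
rounded means).

Every output is a pure function of ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .differential import DECREASED_PATTERNS, INCREASED_PATTERNS
from .motifs import PositionWeightMatrix
from .region_core import RegionCountMatrix, make_sample_meta

STATES = ("NS", "ST", "SW", "RS")
SAMPLES = tuple(f"{st}_{tr}" for tr in ("DMSO", "ROTT") for st in STATES)

#: which state-vs-NS comparisons carry the planted effect, per set label
SET_EFFECTS: dict[str, dict[str, int]] = {"unchanged": {}}
for _pat, _lbl in INCREASED_PATTERNS.items():
    SET_EFFECTS[_lbl] = {st: up for st, up in zip(("ST", "SW", "RS"), _pat) if up}
for _pat, _lbl in DECREASED_PATTERNS.items():
    SET_EFFECTS[_lbl] = {st: -dn for st, dn in zip(("ST", "SW", "RS"), _pat) if dn}

#: study-composition default: half the regions unchanged, the changed half
#: split between increases (observed a-g composition) and mirrored decreases
_INCREASED_WEIGHTS = {"a": 832, "b": 1013, "c": 1430, "d": 92, "e": 579, "f": 492, "g": 899}


def default_set_proportions() -> dict[str, float]:
    total = sum(_INCREASED_WEIGHTS.values())
    props = {"unchanged": 0.5}
    for up_lbl, dn_lbl in zip("abcdefg", "hijklmn"):
        w = 0.25 * _INCREASED_WEIGHTS[up_lbl] / total
        props[up_lbl] = w
        props[dn_lbl] = w
    return props


#: small consensus-derived PWM library for fixtures (0.94 on the consensus base)
DEFAULT_MOTIF_CONSENSUS = {
    "NFAT": "TTTCCA",
    "GATA": "AGATAA",
    "NFKB": "GGGACTTTCC",
    "ETS": "CAGGAAGT",
    "AP1": "TGACTCA",
}


def consensus_pwm(motif_id: str, consensus: str, major: float = 0.94) -> PositionWeightMatrix:
    minor = (1 - major) / 3
    probs = np.full((4, len(consensus)), minor)
    for j, base in enumerate(consensus):
        probs["ACGT".index(base), j] = major
    return PositionWeightMatrix(motif_id, probs)


def default_pwms() -> list[PositionWeightMatrix]:
    return [consensus_pwm(m, c) for m, c in DEFAULT_MOTIF_CONSENSUS.items()]


@dataclass
class SyntheticDatasetSpec:
    """Parameters of the synthetic study; the defaults are the fixture
    conditions used throughout the test-suite and acceptance runs."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 10_000_000
    n_regions: int = 1000
    region_width_range: tuple[int, int] = (200, 600)
    set_proportions: dict[str, float] = field(default_factory=default_set_proportions)
    baseline_mean: float = 200.0
    nb_dispersion: float = 0.05
    sample_dispersion_fraction: float = 0.2
    library_size_factors: dict[str, float] | None = None
    effect_fold: float = 3.0
    n_genes: int = 1000
    prg_fraction: float = 0.1
    mrg_fraction: float = 0.1
    expression_effect: float = 1.0
    expression_noise_sd: float = 0.2
    expression_baseline: tuple[float, float] = (7.0, 1.0)  # mean, sd of log2 level
    motif_plant_prob: dict[tuple[str, str], float] = field(default_factory=dict)
    rottlerin_attenuation: float = 1.0
    rottlerin_sensitive_fraction: float = 0.3
    background_read_density: float = 5e-5  # reads/bp outside regions, per sample
    read_length: int = 50
    extension: int = 200
    mrg_near_sets: tuple[str, ...] = ("b", "c", "e", "f")
    mrg_near_fraction: float = 0.8
    proximity_window: int = 50_000

    def __post_init__(self) -> None:
        total = sum(self.set_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"set_proportions must sum to 1 (got {total})")
        for lbl, frac in self.set_proportions.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"proportion for {lbl!r} outside [0,1]")
            if lbl not in SET_EFFECTS:
                raise ValueError(f"unknown set label {lbl!r}")
        planted = any(l != "unchanged" and f > 0 for l, f in self.set_proportions.items())
        if planted and self.effect_fold <= 1.75:
            raise ValueError("effect_fold must exceed the 1.75 call cutoff for recoverable plants")
        if (self.prg_fraction > 0 or self.mrg_fraction > 0) and self.expression_effect < 0.5:
            raise ValueError("expression_effect < 0.5 makes planted gene classes unrecoverable")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.sample_dispersion_fraction <= 1:
            raise ValueError("sample_dispersion_fraction must be in [0,1]")

    @property
    def samples(self) -> tuple[str, ...]:
        return SAMPLES

    def library_factor(self, sample: str) -> float:
        if self.library_size_factors is None:
            return 1.0
        return float(self.library_size_factors.get(sample, 1.0))

    def _rng(self, stream: int) -> np.random.Generator:
        # independent deterministic stream per generation stage
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticDatasetSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "motif_plant_prob" in raw:
            raw["motif_plant_prob"] = {
                (k.split("/")[0], k.split("/")[1]): v
                for k, v in raw["motif_plant_prob"].items()
            }
        for key in ("region_width_range", "expression_baseline", "mrg_near_sets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif_plant_prob"] = {f"{m}/{s}": p for (m, s), p in self.motif_plant_prob.items()}
        return d


def _mean_matrix(spec: SyntheticDatasetSpec, labels: np.ndarray,
                 sensitive: np.ndarray) -> np.ndarray:
    """Expected count per region x sample before the region propensity."""
    n = len(labels)
    means = np.empty((n, len(SAMPLES)))
    log_fold_cache = {}
    for j, sample in enumerate(SAMPLES):
        state, treatment = sample.split("_")
        col = np.full(n, spec.baseline_mean * spec.library_factor(sample))
        for i in range(n):
            eff = SET_EFFECTS[labels[i]].get(state, 0)
            if eff == 0:
                continue
            fold = spec.effect_fold if eff > 0 else 1.0 / spec.effect_fold
            if treatment == "ROTT" and sensitive[i]:
                fold = fold ** (1.0 - spec.rottlerin_attenuation)
            col[i] *= fold
        means[:, j] = col
    return means


def generate_regions_and_counts(
    spec: SyntheticDatasetSpec,
) -> tuple[pd.DataFrame, RegionCountMatrix, pd.DataFrame]:
    """Place non-overlapping regions, plant set effects, draw counts.

    Returns (regions, counts, truth); ``truth`` holds the planted base set
    label and the rottlerin-sensitivity flag per region.  Regions are laid
    out with inter-region gaps of at least the read extension so that reads
    emitted for one region can never be counted in another.
    """
    rng = spec._rng(1)
    lo, hi = spec.region_width_range
    per_chrom = np.full(spec.n_chromosomes, spec.n_regions // spec.n_chromosomes)
    per_chrom[: spec.n_regions % spec.n_chromosomes] += 1

    rows = []
    min_gap = spec.extension + 1
    for c, n_c in enumerate(per_chrom):
        widths = rng.integers(lo, hi + 1, size=n_c)
        needed = widths.sum() + (n_c + 1) * min_gap
        if needed > spec.chromosome_length:
            raise ValueError(
                f"chromosome_length {spec.chromosome_length} too small for "
                f"{n_c} regions (need >= {needed})"
            )
        slack = spec.chromosome_length - needed
        extra = np.sort(rng.integers(0, slack + 1, size=n_c + 1)) if slack > 0 else np.zeros(n_c + 1, int)
        extra = np.diff(np.concatenate([[0], extra]))  # non-negative partition of slack
        pos = min_gap + extra[0]
        for i in range(n_c):
            rows.append((f"chr{c + 1}", int(pos), int(pos + widths[i])))
            pos += widths[i] + min_gap + extra[i + 1]
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    width = max(5, len(str(len(regions))))
    regions["region_id"] = [f"region_{i + 1:0{width}d}" for i in range(len(regions))]

    labels_pool = list(spec.set_proportions)
    probs = np.array([spec.set_proportions[l] for l in labels_pool])
    labels = rng.choice(labels_pool, size=len(regions), p=probs)
    sensitive = (labels != "unchanged") & (
        rng.random(len(regions)) < spec.rottlerin_sensitive_fraction
    )

    means = _mean_matrix(spec, labels, sensitive)
    alpha = spec.nb_dispersion
    if alpha == 0:
        counts = np.rint(means).astype(np.int64)
    else:
        alpha_s = alpha * spec.sample_dispersion_fraction
        alpha_r = alpha - alpha_s
        g = rng.gamma(1.0 / alpha_r, alpha_r, size=len(regions)) if alpha_r > 0 else np.ones(len(regions))
        mu = means * g[:, None]
        if alpha_s > 0:
            n_param = 1.0 / alpha_s
            counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
        else:
            counts = rng.poisson(mu)

    count_df = pd.DataFrame(counts, index=regions["region_id"].to_numpy(), columns=list(SAMPLES))
    matrix = RegionCountMatrix(count_df, make_sample_meta(SAMPLES))
    truth = pd.DataFrame(
        {"set_label": labels, "rott_sensitive": sensitive},
        index=regions["region_id"].to_numpy(),
    )
    truth.index.name = "region_id"
    return regions, matrix, truth


def generate_reads_for_regions(
    spec: SyntheticDatasetSpec, regions: pd.DataFrame, counts: RegionCountMatrix
) -> pd.DataFrame:
    """Emit one read per counted event plus uniform background reads.

    Region reads are placed so their ``extension``-bp extension overlaps
    the region by at least one base; background reads fall entirely inside
    inter-region gaps.  Counting the output with the same extension
    reproduces the count matrix exactly.
    """
    too_wide = regions["end"] - regions["start"] > spec.chromosome_length
    if too_wide.any():
        raise ValueError("region wider than chromosome")
    rng = spec._rng(2)
    ext, rl = spec.extension, spec.read_length
    out_chrom, out_start, out_strand, out_sample = [], [], [], []

    cmat = counts.counts
    for _, reg in regions.iterrows():
        rid = reg["region_id"]
        # extended interval [es, es+ext) overlaps [start,end) iff es in (start-ext, end)
        lo = reg["start"] - ext + 1
        hi = reg["end"] - 1
        for sample in counts.sample_ids:
            c = int(cmat.at[rid, sample])
            if c == 0:
                continue
            es = rng.integers(lo, hi + 1, size=c)
            minus = rng.random(c) < 0.5
            starts = np.where(minus, es + ext - rl, es)
            out_chrom.extend([reg["chrom"]] * c)
            out_start.extend(starts.tolist())
            out_strand.extend(np.where(minus, "-", "+").tolist())
            out_sample.extend([sample] * c)

    # background: extended intervals strictly inside gaps between regions
    for chrom, grp in regions.groupby("chrom", sort=True):
        bounds = [0] + sorted(
            x for se in zip(grp["start"], grp["end"]) for x in se
        ) + [spec.chromosome_length]
        gaps = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
        for gs, ge in gaps:
            usable = ge - gs - ext
            if usable <= 0:
                continue
            for sample in counts.sample_ids:
                n_bg = rng.poisson(spec.background_read_density * (ge - gs))
                if n_bg == 0:
                    continue
                es = rng.integers(gs, gs + usable + 1, size=n_bg)
                minus = rng.random(n_bg) < 0.5
                starts = np.where(minus, es + ext - rl, es)
                out_chrom.extend([chrom] * n_bg)
                out_start.extend(starts.tolist())
                out_strand.extend(np.where(minus, "-", "+").tolist())
                out_sample.extend([sample] * n_bg)

    reads = pd.DataFrame(
        {"chrom": out_chrom, "start": out_start, "strand": out_strand, "sample": out_sample}
    )
    reads["end"] = reads["start"] + rl
    reads.attrs["read_length"] = rl
    return reads.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def generate_transcripts(
    spec: SyntheticDatasetSpec, regions: pd.DataFrame, truth: pd.DataFrame
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """One transcript per gene; planted-MRG TSSs biased near designated sets.

    Returns the transcript models plus a gene table (chrom, tss, strand,
    planted_class) indexed by gene id.  A ``mrg_near_fraction`` share of
    planted MRG genes get their TSS within ``proximity_window`` of a region
    whose planted set is in ``mrg_near_sets``; everything else lands
    uniformly.
    """
    rng = spec._rng(3)
    n = spec.n_genes
    n_prg = int(round(n * spec.prg_fraction))
    n_mrg = int(round(n * spec.mrg_fraction))
    classes = np.array(["PRG"] * n_prg + ["MRG"] * n_mrg + ["other"] * (n - n_prg - n_mrg))
    rng.shuffle(classes)

    near_pool = regions.merge(
        truth[truth["set_label"].isin(spec.mrg_near_sets)], left_on="region_id", right_index=True
    )
    models: list[TranscriptModel] = []
    rows = []
    width = max(4, len(str(n)))
    for i in range(n):
        gene_id = f"gene_{i + 1:0{width}d}"
        cls = classes[i]
        strand = "+" if rng.random() < 0.5 else "-"
        if cls == "MRG" and len(near_pool) and rng.random() < spec.mrg_near_fraction:
            reg = near_pool.iloc[int(rng.integers(len(near_pool)))]
            offset = int(rng.integers(-spec.proximity_window // 2, spec.proximity_window // 2 + 1))
            tss = int(np.clip(reg["start"] + offset, 0, spec.chromosome_length - 1))
            chrom = reg["chrom"]
        else:
            chrom = f"chr{int(rng.integers(spec.n_chromosomes)) + 1}"
            tss = int(rng.integers(0, spec.chromosome_length))
        length = int(rng.integers(5_000, 50_001))
        if strand == "+":
            tes = min(tss + length, spec.chromosome_length)
            body = (tss, tes)
        else:
            tes = max(tss - length, 0)
            body = (tes, tss)
        # simple 2-exon structure with terminal UTRs
        lo, hi = body
        span = hi - lo
        e1 = (lo, lo + max(span // 5, 1))
        e2 = (hi - max(span // 5, 1), hi)
        utr_len = max(span // 20, 1)
        if strand == "+":
            utr5 = [(lo, lo + utr_len)]
            utr3 = [(hi - utr_len, hi)]
        else:
            utr5 = [(hi - utr_len, hi)]
            utr3 = [(lo, lo + utr_len)]
        models.append(
            TranscriptModel(
                transcript_id=f"tx_{i + 1:0{width}d}", gene_id=gene_id, chrom=chrom,
                strand=strand, tss=tss, tes=tes, exons=[e1, e2], utr5=utr5, utr3=utr3,
            )
        )
        rows.append((gene_id, chrom, tss, strand, cls))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "strand", "planted_class"]
    ).set_index("gene_id")
    return models, genes


def generate_expression(
    spec: SyntheticDatasetSpec, genes: pd.DataFrame
) -> pd.DataFrame:
    """Log2 expression (genes x NS/ST/SW/RS) realising the planted classes.

    Planted MRG: RS = max(NS, ST) + expression_effect (+ its own noise),
    so the memory response rides on whatever the realised baseline levels
    are; PRG mirrored for ST.  Unplanted genes get independent noise around
    a common baseline.
    """
    rng = spec._rng(4)
    n = len(genes)
    mu, sd = spec.expression_baseline
    base = rng.normal(mu, sd, size=n)
    noise = rng.normal(0, spec.expression_noise_sd, size=(n, 4)) if spec.expression_noise_sd > 0 else np.zeros((n, 4))
    ns = base + noise[:, 0]
    st = base + noise[:, 1]
    sw = base + noise[:, 2]
    rs = base + noise[:, 3]
    cls = genes["planted_class"].to_numpy()
    is_prg = cls == "PRG"
    is_mrg = cls == "MRG"
    st = np.where(is_prg, np.maximum(ns, rs) + spec.expression_effect + noise[:, 1], st)
    rs = np.where(is_mrg, np.maximum(ns, st) + spec.expression_effect + noise[:, 3], rs)
    return pd.DataFrame(
        {"NS": ns, "ST": st, "SW": sw, "RS": rs}, index=genes.index
    )


def generate_sequences_with_motifs(
    spec: SyntheticDatasetSpec,
    regions: pd.DataFrame,
    truth: pd.DataFrame,
    pwms: list[PositionWeightMatrix] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-background sequences with consensus motif instances planted.

    For each (motif, set) pair in ``motif_plant_prob`` (a ``"*"`` set key
    is a default for unlisted sets) a Bernoulli(p) subset of that set's
    regions gets the motif's consensus embedded at a uniform offset.
    Returns ``{region_id: sequence}`` plus the planted-occurrence table.
    """
    rng = spec._rng(5)
    pwms = pwms if pwms is not None else default_pwms()
    widths = (regions["end"] - regions["start"]).to_numpy()
    for p in pwms:
        if (p.length > widths).any():
            raise ValueError(f"motif {p.motif_id} longer than the narrowest region")
    labels = truth["set_label"].reindex(regions["region_id"]).to_numpy()
    seqs: dict[str, str] = {}
    planted_rows = []
    bases = np.array(list("ACGT"))
    for (_, reg), lbl in zip(regions.iterrows(), labels):
        w = int(reg["end"] - reg["start"])
        seq = rng.integers(0, 4, size=w)
        rid = reg["region_id"]
        for pwm in pwms:
            prob = spec.motif_plant_prob.get(
                (pwm.motif_id, lbl), spec.motif_plant_prob.get((pwm.motif_id, "*"), 0.0)
            )
            if prob <= 0 or rng.random() >= prob:
                continue
            cons = pwm.consensus
            offset = int(rng.integers(0, w - len(cons) + 1))
            seq[offset : offset + len(cons)] = [_b_index(b) for b in cons]
            planted_rows.append((rid, pwm.motif_id, offset))
        seqs[rid] = "".join(bases[seq])
    planted = pd.DataFrame(planted_rows, columns=["region_id", "motif_id", "offset"])
    return seqs, planted


def _b_index(base: str) -> int:
    return "ACGT".index(base)


def generate_state_segments(
    spec: SyntheticDatasetSpec,
    cell_types: tuple[str, ...] = ("naive", "memory"),
    mean_segment_length: int = 2000,
    state_labels: tuple[str, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """Random chromatin-state tilings per cell type.

    Each chromosome is tiled by consecutive segments with exponential-ish
    lengths and states drawn from ``state_labels`` (defaults to the keys of
    the built-in group map), so every position is covered.
    """
    from .annotation import DEFAULT_STATE_GROUPS

    rng = spec._rng(6)
    labels = list(state_labels) if state_labels else list(DEFAULT_STATE_GROUPS)
    out: dict[str, pd.DataFrame] = {}
    for ct in cell_types:
        rows = []
        for c in range(spec.n_chromosomes):
            chrom = f"chr{c + 1}"
            pos = 0
            while pos < spec.chromosome_length:
                length = int(rng.exponential(mean_segment_length)) + 200
                end = min(pos + length, spec.chromosome_length)
                rows.append((chrom, pos, end, labels[int(rng.integers(len(labels)))], ct))
                pos = end
        out[ct] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "state_label", "cell_type"]
        )
    return out


@dataclass
class SyntheticDataset:
    """The full fixture bundle produced by :func:`generate_dataset`."""

    spec: SyntheticDatasetSpec
    regions: pd.DataFrame
    counts: RegionCountMatrix
    truth: pd.DataFrame
    transcripts: list[TranscriptModel]
    genes: pd.DataFrame
    expression: pd.DataFrame
    reads: pd.DataFrame | None = None
    sequences: dict[str, str] | None = None
    planted_motifs: pd.DataFrame | None = None
    pwms: list[PositionWeightMatrix] | None = None


def generate_dataset(
    spec: SyntheticDatasetSpec,
    with_reads: bool = False,
    with_sequences: bool = False,
    pwms: list[PositionWeightMatrix] | None = None,
) -> SyntheticDataset:
    """Generate the complete fixture (reads and sequences optional)."""
    regions, counts, truth = generate_regions_and_counts(spec)
    transcripts, genes = generate_transcripts(spec, regions, truth)
    expression = generate_expression(spec, genes)
    reads = generate_reads_for_regions(spec, regions, counts) if with_reads else None
    sequences = planted = None
    use_pwms = pwms if pwms is not None else default_pwms()
    if with_sequences:
        sequences, planted = generate_sequences_with_motifs(spec, regions, truth, use_pwms)
    return SyntheticDataset(
        spec, regions, counts, truth, transcripts, genes, expression,
        reads, sequences, planted, use_pwms,
    )
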