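"""End-to-end orchestration of the memory-accessibility analysis.

``run_pipeline`` executes the stages in dependency order from a single
config (merge -> count -> normalize -> call -> calibrate -> classify ->
annotate -> genes -> associate -> scan -> combos -> motif-gsea), writing
TSV outputs plus a JSON manifest with parameters, input checksums, the
seed, and per-stage row counts.  ``make_demo`` generates the synthetic
fixture, runs the full pipeline on it, and reports planted-truth recovery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, differential, expression, io, motifs, region_core
from .synthetic_data import (
    SyntheticDataset, SyntheticDatasetSpec, default_pwms,
    generate_dataset, generate_state_segments,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "merge", "count", "normalize", "call", "calibrate", "classify",
    "annotate", "genes", "associate", "scan", "combos", "motif_gsea",
)

DEFAULT_PARAMS = dict(
    extension=200,
    exclude_chroms=["chrM", "chrUn"],
    reference="NS_DMSO",
    norm_method="median",
    fc_cutoff=1.75,
    min_reads=30,
    ratio_cutoff=1.75,
    attenuation_cutoff=1.75,
    window=50_000,
    expression_threshold=0.5,
    motif_width=300,
    relative_threshold=0.8,
    combo_min_count=1,
    gsea_min_count=1,
    n_perm=1000,
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (normally loaded from YAML)."""

    outdir: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    seed: int | None = None
    combos: list[dict] = field(default_factory=lambda: [{"required": ["NFAT", "GATA"]}])

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage toggle(s): {sorted(unknown)}")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        if self.enabled("motif_gsea") and self.seed is None:
            raise ValueError("a seed is required when the motif-gsea stage is enabled")
        for key, path in self.inputs.items():
            if key == "chromatin_states":
                for p in path.values():
                    if not Path(p).exists():
                        raise FileNotFoundError(f"input {key}/{p} does not exist")
            elif isinstance(path, list):
                for p in path:
                    if not Path(p).exists():
                        raise FileNotFoundError(f"input {key}/{p} does not exist")
            elif not Path(path).exists():
                raise FileNotFoundError(f"input {key}={path} does not exist")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "seed": config.seed,
        "params": p,
        "inputs": {},
        "stages": {},
    }
    for key, path in config.inputs.items():
        if key == "chromatin_states":
            manifest["inputs"][key] = {ct: _sha256(pp) for ct, pp in path.items()}
        elif isinstance(path, list):
            manifest["inputs"][key] = [_sha256(pp) for pp in path]
        else:
            manifest["inputs"][key] = _sha256(path)

    state: dict = {}
    try:
        for stage in STAGE_ORDER:
            if not config.enabled(stage):
                continue
            n = _STAGES[stage](config, state, out)
            manifest["stages"][stage] = {"rows": n}
            logger.info("stage %s done (%s rows)", stage, n)
    except Exception:
        logger.error("pipeline failed at stage %r; partial outputs kept in %s", stage, out)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# --- stage implementations -------------------------------------------------


def _stage_merge(config, state, out):
    lists = [io.read_bed(p) for p in config.inputs["region_beds"]]
    merged = region_core.merge_regions(lists)
    merged = region_core.filter_chromosomes(merged, tuple(config.params["exclude_chroms"]))
    io.write_bed(merged, out / "merged_regions.bed")
    state["regions"] = merged
    return len(merged)


def _stage_count(config, state, out):
    reads = io.read_reads(config.inputs["reads"])
    counts = region_core.count_reads(state["regions"], reads, config.params["extension"])
    io.write_counts(counts, out / "counts.tsv")
    state["counts"] = counts
    return len(counts.counts)


def _stage_normalize(config, state, out):
    norm = region_core.ma_normalize(
        state["counts"], config.params["reference"], config.params["norm_method"]
    )
    io.write_counts(norm, out / "norm_counts.tsv")
    state["norm"] = norm
    corr = region_core.sample_correlation(norm)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t")
    state["correlation"] = corr
    return len(norm.counts)


def _stage_call(config, state, out):
    norm = state["norm"]
    p = config.params
    calls = {}
    for st in ("ST", "SW", "RS"):
        calls[st] = differential.call_change(
            norm, f"{st}_DMSO", "NS_DMSO", p["fc_cutoff"], p["min_reads"]
        )
    null_calls = differential.call_change(
        norm, "NS_ROTT", "NS_DMSO", p["fc_cutoff"], p["min_reads"]
    )
    state["calls"] = calls
    state["null_calls"] = null_calls
    combined = pd.concat(
        [c.assign(comparison=f"{st}_vs_NS") for st, c in calls.items()]
        + [null_calls.assign(comparison="NS_ROTT_vs_NS_DMSO")]
    )
    combined.to_csv(out / "calls.tsv", sep="\t")
    return len(combined)


def _stage_calibrate(config, state, out):
    fpr = differential.calibrate_fpr(
        state["null_calls"], {f"{st}_vs_NS": c for st, c in state["calls"].items()}
    )
    state["fpr"] = fpr
    with open(out / "fpr_calibration.json", "w") as fh:
        json.dump(
            {
                "null_comparison": list(fpr.null_comparison),
                "expected_fp": fpr.expected_fp,
                "n_total_regions": fpr.n_total_regions,
                "fp_rate_per_comparison": fpr.fp_rate_per_comparison,
                "rate_range": list(fpr.rate_range),
            },
            fh, indent=2,
        )
    return fpr.expected_fp


def _stage_classify(config, state, out):
    p = config.params
    calls = state["calls"]
    assign = differential.classify_sets(calls["ST"], calls["SW"], calls["RS"])
    assign = differential.subdivide_by_st_rs(
        assign, state["norm"], ratio_cutoff=p["ratio_cutoff"]
    )
    assign = differential.assign_meta_groups(assign)
    assign = differential.flag_rottlerin_sensitive(
        assign, state["norm"], calls, p["attenuation_cutoff"]
    )
    assign.to_csv(out / "assignments.tsv", sep="\t")
    state["assignments"] = assign
    return len(assign)


def _stage_annotate(config, state, out):
    transcripts = io.read_transcripts(config.inputs["transcripts"])
    state["transcripts"] = transcripts
    ann = annotation.annotate_features(state["regions"], transcripts)
    ann.to_csv(out / "feature_annotation.tsv", sep="\t")
    state["annotation"] = ann
    seg_inputs = config.inputs.get("chromatin_states", {})
    if seg_inputs:
        segments = {ct: io.read_state_segments(p, ct) for ct, p in seg_inputs.items()}
        group_map = dict(annotation.DEFAULT_STATE_GROUPS)
        per_region, transitions = annotation.annotate_region_states(
            state["regions"], segments, group_map
        )
        per_region.to_csv(out / "chromatin_states.tsv", sep="\t")
        for (a, b), tab in transitions.items():
            tab.to_csv(out / f"state_transitions_{a}_to_{b}.tsv", sep="\t")
        state["region_states"] = per_region
    return len(ann)


def _stage_genes(config, state, out):
    expr = io.read_expression(config.inputs["expression"])
    classes = expression.classify_genes(expr, config.params["expression_threshold"])
    classes.to_csv(out / "gene_classes.tsv", sep="\t")
    state["classes"] = classes
    return len(classes)


def _stage_associate(config, state, out):
    transcripts = state["transcripts"]
    gene_tss = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in transcripts],
            "chrom": [t.chrom for t in transcripts],
            "tss": [t.tss for t in transcripts],
        }
    ).drop_duplicates("gene_id").set_index("gene_id")
    state["gene_tss"] = gene_tss
    table = expression.enrichment_table(
        state["classes"], gene_tss, state["regions"], state["assignments"],
        window=config.params["window"],
    )
    table.to_csv(out / "proximity_enrichment.tsv", sep="\t", index=False)
    report = expression.nearby_gene_report(
        state["assignments"], state["regions"], state["classes"], gene_tss,
        config.params["window"],
    )
    report.to_csv(out / "nearby_genes.tsv", sep="\t", index=False)
    state["enrichment"] = table
    return len(table)


def _stage_scan(config, state, out):
    p = config.params
    sequences = io.read_fasta(config.inputs["sequences"])
    pwms = motifs.read_jaspar(config.inputs["pwms"])
    occurrences = motifs.scan_regions(
        sequences, pwms, relative_threshold=p["relative_threshold"]
    )
    occurrences.to_csv(out / "motif_occurrences.tsv", sep="\t", index=False)
    state["occurrences"] = occurrences
    state["pwms"] = pwms
    return len(occurrences)


def _stage_combos(config, state, out):
    rows = []
    for combo in config.combos:
        stat = motifs.combination_composition(
            state["occurrences"], state["assignments"],
            required=set(combo.get("required", [])),
            excluded=set(combo.get("excluded", [])),
            min_count=config.params["combo_min_count"],
        )
        for lbl in stat.per_set_counts.index:
            rows.append(
                {
                    "required": "+".join(sorted(stat.required_motifs)),
                    "excluded": "+".join(sorted(stat.excluded_motifs)),
                    "set_label": lbl,
                    "count": int(stat.per_set_counts[lbl]),
                    "percent": float(stat.per_set_percent[lbl]),
                    "baseline_percent": float(stat.baseline_percent[lbl]),
                    "n_regions": stat.n_regions,
                }
            )
        state.setdefault("combo_stats", []).append(stat)
    df = pd.DataFrame(rows)
    df.to_csv(out / "motif_combinations.tsv", sep="\t", index=False)
    return len(df)


def _stage_motif_gsea(config, state, out):
    """Rank changed regions by RS-vs-NS fold change; test each motif's
    region set (>= gsea_min_count occurrences) for rank enrichment."""
    p = config.params
    changed = state["assignments"].index[state["assignments"]["set_label"] != "unchanged"]
    calls_rs = state["calls"]["RS"]
    ranked = pd.DataFrame(
        {
            "region_id": changed,
            "score": np.log2(calls_rs["fold_change"].reindex(changed).to_numpy()),
        }
    )
    presence = motifs.occurrence_matrix(state["occurrences"], min_count=p["gsea_min_count"])
    rows = []
    for k, motif_id in enumerate(sorted(presence.columns)):
        members = set(presence.index[presence[motif_id]]) & set(changed)
        if not members or len(members) >= len(changed):
            logger.warning("motif_gsea: skipping %s (degenerate member set)", motif_id)
            continue
        res = motifs.region_gsea(
            ranked, members, motif_id, n_perm=p["n_perm"],
            seed=int(np.random.SeedSequence((config.seed, 7, k)).generate_state(1)[0] % (2**31)),
        )
        rows.append(
            {
                "motif_id": motif_id, "region_set_size": res.region_set_size,
                "es": res.es, "nes": res.nes, "p_perm": res.p_perm,
                "n_permutations": res.n_permutations, "seed": res.seed,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "motif_gsea.tsv", sep="\t", index=False)
    state["gsea"] = df
    return len(df)


_STAGES = {
    "merge": _stage_merge, "count": _stage_count, "normalize": _stage_normalize,
    "call": _stage_call, "calibrate": _stage_calibrate, "classify": _stage_classify,
    "annotate": _stage_annotate, "genes": _stage_genes, "associate": _stage_associate,
    "scan": _stage_scan, "combos": _stage_combos, "motif_gsea": _stage_motif_gsea,
}


# --- demo ------------------------------------------------------------------

DEMO_MOTIF_PLANT = {
    ("NFAT", "c"): 0.8, ("NFAT", "*"): 0.1,
    ("GATA", "c"): 0.5, ("GATA", "*"): 0.2,
}


def demo_spec(seed: int, n_regions: int = 1000) -> SyntheticDatasetSpec:
    """The demo fixture: standard study conditions plus motif plants."""
    return SyntheticDatasetSpec(
        seed=seed, n_regions=n_regions,
        motif_plant_prob=dict(DEMO_MOTIF_PLANT),
    )


def write_fixture(dataset: SyntheticDataset, fixture_dir: Path) -> dict:
    """Write the synthetic dataset to disk; returns pipeline input paths."""
    fixture_dir.mkdir(parents=True, exist_ok=True)
    io.write_bed(dataset.regions, fixture_dir / "regions.bed")
    io.write_reads(dataset.reads, fixture_dir / "reads.tsv")
    io.write_transcripts(dataset.transcripts, fixture_dir / "transcripts.tsv")
    io.write_expression(dataset.expression, fixture_dir / "expression.tsv")
    io.write_fasta(dataset.sequences, fixture_dir / "sequences.fa")
    motifs.write_jaspar(dataset.pwms, fixture_dir / "motifs.jaspar")
    dataset.truth.to_csv(fixture_dir / "truth_regions.tsv", sep="\t")
    dataset.genes.to_csv(fixture_dir / "truth_genes.tsv", sep="\t")
    states = generate_state_segments(dataset.spec)
    state_paths = {}
    for ct, seg in states.items():
        path = fixture_dir / f"states_{ct}.bed"
        seg[["chrom", "start", "end", "state_label"]].to_csv(
            path, sep="\t", header=False, index=False
        )
        state_paths[ct] = str(path)
    return {
        "region_beds": [str(fixture_dir / "regions.bed")],
        "reads": str(fixture_dir / "reads.tsv"),
        "transcripts": str(fixture_dir / "transcripts.tsv"),
        "expression": str(fixture_dir / "expression.tsv"),
        "sequences": str(fixture_dir / "sequences.fa"),
        "pwms": str(fixture_dir / "motifs.jaspar"),
        "chromatin_states": state_paths,
    }


def recovery_summary(dataset: SyntheticDataset, outdir: Path) -> dict:
    """Compare pipeline outputs in ``outdir`` against the planted truth."""
    assignments = pd.read_csv(outdir / "assignments.tsv", sep="\t", index_col=0)
    merged = io.read_bed(outdir / "merged_regions.bed")
    # map merged region ids back to generated ones by coordinates
    key = ["chrom", "start", "end"]
    mapping = merged.merge(
        dataset.regions, on=key, suffixes=("_merged", "_orig")
    ).set_index("region_id_merged")["region_id_orig"]
    truth = dataset.truth["set_label"].reindex(mapping.to_numpy())
    recovered = assignments["set_label"].rename(index=mapping).str.replace(
        r"([beil])[012]$", r"\1", regex=True
    )
    planted = truth[truth != "unchanged"]
    set_recovery = float((recovered.reindex(planted.index) == planted).mean())

    classes = pd.read_csv(outdir / "gene_classes.tsv", sep="\t", index_col=0)
    gene_truth = dataset.genes["planted_class"]
    gene_recovery = float(
        (classes["gene_class"].reindex(gene_truth.index) == gene_truth).mean()
    )
    null_frac = None
    fpr_path = outdir / "fpr_calibration.json"
    if fpr_path.exists():
        with open(fpr_path) as fh:
            fpr = json.load(fh)
        null_frac = fpr["expected_fp"] / max(fpr["n_total_regions"], 1)
    return {
        "n_regions": int(len(dataset.regions)),
        "n_planted": int(len(planted)),
        "set_label_recovery": set_recovery,
        "gene_class_recovery": gene_recovery,
        "null_call_fraction": null_frac,
    }


def make_demo(seed: int, outdir, n_regions: int = 1000) -> dict:
    """Generate the standard fixture, run the full pipeline, report recovery."""
    outdir = Path(outdir)
    spec = demo_spec(seed, n_regions)
    dataset = generate_dataset(spec, with_reads=True, with_sequences=True)
    inputs = write_fixture(dataset, outdir / "fixture")
    config = PipelineConfig(
        outdir=str(outdir / "results"), inputs=inputs, seed=seed,
        params={"n_perm": 200},
    )
    manifest = run_pipeline(config)
    summary = recovery_summary(dataset, outdir / "results")
    summary["seed"] = seed
    with open(outdir / "recovery_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(
        f"demo seed={seed}: {summary['n_planted']} planted regions, "
        f"set-label recovery {summary['set_label_recovery']:.3f}, "
        f"gene-class recovery {summary['gene_class_recovery']:.3f}, "
        f"null call fraction {summary['null_call_fraction']:.4f}"
    )
    summary["manifest"] = manifest
    return summary
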