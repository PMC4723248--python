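"""End-to-end synthetic reproduction runs from a single configuration.

``run_pipeline`` generates synthetic inputs, executes the selected stages
(MS enrichment calling, expression-array analysis, inclusion scoring) and
writes tables plus a JSON manifest recording every parameter, derived
seed, software version and output checksum.  Identical (config, seed)
pairs produce byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import arrays as arr
from . import imaging as img
from . import proteomics as ms
from . import synthetic as syn

logger = logging.getLogger(__name__)

STAGES = ("ms", "arrays", "imaging")

MS_DEFAULTS = {
    "n_proteins": 500,
    "n_planted": 2,
    "planted_fold": 10.0,
    "baseline_mean": 20.0,
    "n_replicates": 3,
    "min_probability": ms.DEFAULT_MIN_PROBABILITY,
    "fold_min": ms.DEFAULT_FOLD_MIN,
    "p_max": ms.DEFAULT_P_MAX,
    "peptides_per_protein": 3,
    "low_prob_fraction": 0.1,
}

ARRAYS_DEFAULTS = {
    "n_genes": 600,
    "replicate_sd": 0.22,
    "k": arr.DEFAULT_K,
    "n_replicates": 2,
    "self_self_n": 15000,
    "strains": ["wt", "tup1KR", "cyc8KR"],
    "timepoints": [0, 30, 60],
    # planted mutant effects at 30 min: 16 up genes (15 telomere-proximal)
    # for the first mutant, 21 up genes for the second
    "n_up_first_mutant": 16,
    "n_up_second_mutant": 21,
    "planted_log2": 2.0,
    "aneuploid_n_genes": 20,
    "aneuploid_shift": 0.8,
    # elevation cutoff for the aneuploidy scan, in null-SD units: low enough
    # that a copy-number shift comfortably clears it gene by gene, while a
    # >=min_run null run above it is still essentially impossible
    "aneuploid_k": 2.0,
    "min_run": arr.DEFAULT_MIN_RUN,
    "telomere_max_distance_bp": arr.DEFAULT_TELOMERE_DISTANCE_BP,
    "two_fold_log2": 1.0,
}

IMAGING_DEFAULTS = {
    "trajectory": {0: 0.0, 15: 0.6, 60: 0.05},
    "fields_per_timepoint": 6,
    "n_cells": 40,
    "shape": [256, 256],
    "min_prominence": img.DEFAULT_MIN_PROMINENCE,
    "min_sigma": img.DEFAULT_MIN_SIGMA,
    "max_sigma": img.DEFAULT_MAX_SIGMA,
    "spot_amplitude": 150.0,
    "spot_sigma": 2.0,
    "noise_sd": 5.0,
    "nuclear_enrichment": 2.0,
    "spots_per_positive_cell": 1,
}


class PipelineError(RuntimeError):
    """A stage failed; the manifest records what completed."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    outdir: str
    stage: str = "all"
    seed: int = 0
    ms: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)
    imaging: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES + ("all",):
            raise ValueError(f"unknown stage {self.stage!r}")
        for name, block, defaults in (
            ("ms", self.ms, MS_DEFAULTS),
            ("arrays", self.arrays, ARRAYS_DEFAULTS),
            ("imaging", self.imaging, IMAGING_DEFAULTS),
        ):
            unknown = set(block) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def params(self, stage: str) -> dict:
        defaults = {"ms": MS_DEFAULTS, "arrays": ARRAYS_DEFAULTS, "imaging": IMAGING_DEFAULTS}[stage]
        return {**defaults, **getattr(self, stage)}


def stress_dilution(
    initial_concentration: float,
    added_concentration: float,
    volume_ratio: float = 1.0,
) -> float:
    """Final concentration after mixing culture with stress medium.

    ``volume_ratio`` is added-medium volume over culture volume; the
    result is the volume-weighted mean concentration.  Mixing equal
    volumes of culture (0 M) and 2.4 M sorbitol medium gives 1.2 M.
    """
    if initial_concentration < 0 or added_concentration < 0:
        raise ValueError("concentrations must be non-negative")
    if volume_ratio <= 0:
        raise ValueError("volume_ratio must be positive")
    return (initial_concentration + added_concentration * volume_ratio) / (
        1.0 + volume_ratio
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seeds(master_seed: int) -> dict[str, int]:
    rng = np.random.default_rng(master_seed)
    vals = rng.integers(0, 2**31 - 1, size=4)
    return {
        "ms": int(vals[0]),
        "self_self": int(vals[1]),
        "arrays": int(vals[2]),
        "imaging": int(vals[3]),
    }


# ---------------------------------------------------------------------------
# stages


def _run_ms(params: dict, seed: int, outdir: Path) -> dict:
    prots = syn.protein_ids(params["n_proteins"])
    planted = tuple(prots[: params["n_planted"]])
    truth = syn.SpectralTruth(
        n_proteins=params["n_proteins"],
        planted_proteins=planted,
        planted_fold=params["planted_fold"],
        baseline_mean=params["baseline_mean"],
        n_replicates=params["n_replicates"],
        seed=seed,
        peptides_per_protein=params["peptides_per_protein"],
        low_prob_fraction=params["low_prob_fraction"],
    )
    table, _ = syn.gen_spectral_counts(truth, params["min_probability"])
    ms.write_peptide_table(table, outdir / "peptides.tsv")

    kept = ms.filter_peptides(table, params["min_probability"])
    matrix = ms.sum_counts(kept)
    calls = ms.call_enriched(
        ms.test_enrichment(matrix),
        fold_min=params["fold_min"],
        p_max=params["p_max"],
    )
    ms.write_calls(calls, outdir / "ms_calls.tsv")
    called = set(calls.index[calls["passes"]])
    return {
        "n_peptide_records": int(len(table)),
        "n_records_passing_filter": int(len(kept)),
        "n_proteins_called": len(called),
        "planted_proteins_called": sorted(set(planted) & called),
        "planted_recall": len(set(planted) & called) / max(len(planted), 1),
    }


def _plant_array_effects(params: dict) -> tuple[dict, list[str], list[str]]:
    """Choose planted up-regulated genes deterministically.

    First mutant: 15 telomere-proximal genes plus one interior gene (16
    total); second mutant: interior genes (21 by default).  Gene choices
    avoid each other and the aneuploid segment.
    """
    genes, lengths = syn.synthetic_annotation(params["n_genes"])
    proximal = arr.telomere_proximity(
        genes, lengths, params["telomere_max_distance_bp"]
    )
    strains = list(params["strains"])
    mut1, mut2 = strains[1], strains[2]
    tp = sorted(params["timepoints"])[1]  # the mid (30 min) timepoint

    seg_ids = set(
        genes.index[
            params["n_genes"] - params["aneuploid_n_genes"] - 30 : params["n_genes"] - 30
        ]
    )
    prox_ids = [g for g in genes.index[proximal] if g not in seg_ids]
    interior = [g for g in genes.index[~proximal] if g not in seg_ids]

    n1, n2 = params["n_up_first_mutant"], params["n_up_second_mutant"]
    up1 = prox_ids[: min(15, n1)] + interior[: max(n1 - 15, 0)]
    used = set(up1)
    up2 = [g for g in interior if g not in used][:n2]

    effects: dict = {}
    for g in up1:
        effects.setdefault(g, {})[(mut1, tp)] = params["planted_log2"]
    for g in up2:
        effects.setdefault(g, {})[(mut2, tp)] = params["planted_log2"]
    return effects, up1, up2


def _run_arrays(params: dict, seeds: dict, outdir: Path) -> dict:
    null = syn.gen_self_self(params["self_self_n"], params["replicate_sd"], seeds["self_self"])
    thr = arr.derive_threshold(null, k=params["k"])

    strains = tuple(params["strains"])
    timepoints = tuple(params["timepoints"])
    effects_map, up1, up2 = _plant_array_effects(params)
    n = params["n_genes"]
    seg = syn.AneuploidSegment(
        chrom="chrIII",
        first_index=n - params["aneuploid_n_genes"] - 30,
        last_index=n - 31,
        shift=params["aneuploid_shift"],
        strain=strains[1],
    )
    truth = syn.ArrayTruth(
        n_genes=n,
        replicate_sd=params["replicate_sd"],
        planted_effects=effects_map,
        aneuploid_segment=seg,
        seed=seeds["arrays"],
    )
    expr, _ = syn.gen_array_experiment(
        truth, strains=strains, timepoints=timepoints,
        n_replicates=params["n_replicates"], wild_type=strains[0],
    )
    arr.write_expression_tsv(expr, outdir / "expression.tsv")

    regions, masked = arr.detect_aneuploid_region(
        expr, strain=seg.strain,
        elevation_cutoff=params["aneuploid_k"] * thr.null_sd,
        min_run=params["min_run"],
    )
    arr.write_bed(regions, outdir / "aneuploid_regions.bed")

    avg = arr.average_replicates(masked)
    avg.values.to_csv(outdir / "averaged.tsv", sep="\t")
    effects = arr.mutant_effect(avg, wild_type=strains[0])
    effects.to_csv(outdir / "mutant_effects.tsv", sep="\t")

    # significance: averaged ratios at time 0, mutant effects at 30/60 min
    sig0 = arr.call_significant(
        avg.values.loc[:, avg.values.columns.get_level_values("timepoint") == timepoints[0]],
        thr.log2_threshold,
    )
    later = [t for t in timepoints if t != timepoints[0]]
    sig_eff = arr.call_significant(
        effects.loc[:, effects.columns.get_level_values("timepoint").isin(later)],
        thr.log2_threshold,
    )
    mid = sorted(timepoints)[1]
    two_fold_up = arr.call_significant(
        effects.loc[:, effects.columns.get_level_values("timepoint") == mid],
        params["two_fold_log2"],
        direction="up",
    )
    proximal = arr.telomere_proximity(
        masked.genes, masked.chrom_lengths, params["telomere_max_distance_bp"]
    )

    mut1, mut2 = strains[1], strains[2]
    up1_called = two_fold_up[(mut1, mid)]
    up2_called = two_fold_up[(mut2, mid)]
    overlaps = arr.set_overlaps({mut1: up1_called, mut2: up2_called})

    with open(outdir / "gene_sets.tsv", "w") as fh:
        fh.write("set\tgene_id\ttelomere_proximal\n")
        for name, genes_set in [
            (f"{mut1}_2fold_up_{mid}min", up1_called),
            (f"{mut2}_2fold_up_{mid}min", up2_called),
        ]:
            for g in sorted(genes_set):
                fh.write(f"{name}\t{g}\t{int(proximal.get(g, False))}\n")

    # cluster genes significant in any mutant-effect column
    union = sorted(set().union(*sig_eff.values()))
    clustered = 0
    if len(union) >= 2:
        sub = effects.loc[union].fillna(0.0)
        tree = arr.hcluster_average(sub.to_numpy())
        sub_named = sub.copy()
        sub_named.columns = [f"{s}_{t}" for s, t in sub.columns]
        arr.write_cdt_gtr(sub_named, tree, outdir / "clustered.cdt", outdir / "clustered.gtr")
        clustered = len(union)

    return {
        "null_sd": thr.null_sd,
        "log2_threshold": thr.log2_threshold,
        "fold_threshold": round(thr.fold_threshold, 2),
        "aneuploid_regions": [
            {"chrom": r.chrom, "first_gene": r.first_gene, "last_gene": r.last_gene,
             "n_genes": len(r.gene_ids), "span_bp": r.span_bp}
            for r in regions
        ],
        "n_genes_masked": n - len(masked.genes),
        "significant_at_t0": {f"{s}_{t}": len(v) for (s, t), v in sig0.items()},
        "significant_effects": {f"{s}_{t}": len(v) for (s, t), v in sig_eff.items()},
        "two_fold_up_counts": {
            f"{mut1}_{mid}min": len(up1_called),
            f"{mut2}_{mid}min": len(up2_called),
        },
        "planted_up_counts": {mut1: len(up1), mut2: len(up2)},
        "telomere_proximal_up_first_mutant": int(
            sum(bool(proximal.get(g, False)) for g in up1_called)
        ),
        "overlap_2fold_up": overlaps["pairwise"][(mut1, mut2)],
        "n_genes_clustered": clustered,
    }


def _run_imaging(params: dict, seed: int, outdir: Path) -> dict:
    template = syn.FieldTruth(
        n_cells=params["n_cells"],
        spot_amplitude=params["spot_amplitude"],
        spot_sigma=params["spot_sigma"],
        noise_sd=params["noise_sd"],
        nuclear_enrichment=params["nuclear_enrichment"],
        spots_per_positive_cell=params["spots_per_positive_cell"],
        seed=seed,
    )
    trajectory = {int(k): float(v) for k, v in params["trajectory"].items()}
    fields = syn.gen_timecourse_fields(
        trajectory, params["fields_per_timepoint"], template,
        shape=tuple(params["shape"]),
    )
    detector = {
        "min_prominence": params["min_prominence"],
        "min_sigma": params["min_sigma"],
        "max_sigma": params["max_sigma"],
    }
    per_field_rows = []
    summaries = {}
    by_tp: dict[int, list] = {}
    for f in fields:
        by_tp.setdefault(f.metadata["timepoint"], []).append(f)
    for tp in sorted(by_tp):
        s = img.summarize_inclusion_fractions(by_tp[tp], **detector)
        summaries[tp] = s
        pf = s.per_field.copy()
        pf.insert(0, "timepoint", tp)
        per_field_rows.append(pf)
    per_field = pd.concat(per_field_rows, ignore_index=True)
    per_field.to_csv(outdir / "inclusion_per_field.csv", index=False)
    summary = pd.DataFrame(
        [
            {
                "timepoint": tp,
                "mean_fraction": s.mean_fraction,
                "sd_fraction": s.sd_fraction,
                "n_fields": s.n_fields,
                "total_cells": s.total_cells,
                "underpowered": s.underpowered,
                "true_fraction": trajectory[tp],
            }
            for tp, s in summaries.items()
        ]
    )
    summary.to_csv(outdir / "inclusion_summary.csv", index=False)

    tps = sorted(summaries)
    p_onset = img.compare_conditions(
        summaries[tps[0]].per_field["fraction"],
        summaries[tps[1]].per_field["fraction"],
    )

    # colocalization demo: a two-channel field with complete spot overlap
    coloc_truth = dataclasses.replace(
        template, n_channels=2, channel_overlap=1.0, inclusion_fraction=0.5,
        seed=(seed + 1) % 2**31,
    )
    coloc_field = syn.gen_image_field(coloc_truth, shape=tuple(params["shape"]))
    overlap, n_px = img.manders_overlap(
        coloc_field.channels[0], coloc_field.channels[1], coloc_field.cell_mask > 0
    )
    nc = img.nc_ratio(coloc_field)
    return {
        "detector": detector,
        "mean_fractions": {int(tp): s.mean_fraction for tp, s in summaries.items()},
        "sd_fractions": {int(tp): s.sd_fraction for tp, s in summaries.items()},
        "welch_p_first_vs_second_timepoint": p_onset,
        "manders_overlap_shared_spots": overlap,
        "manders_n_pixels": n_px,
        "mean_nc_ratio": float(nc["ratio"].mean()),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)
    stages = STAGES if config.stage == "all" else (config.stage,)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "stage_selection": config.stage,
        "stress_conditions": {
            "sorbitol_M": stress_dilution(0.0, 2.4),
            "ethanol_percent": stress_dilution(0.0, 20.0),
        },
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    failure: Exception | None = None
    for stage in stages:
        params = config.params(stage)
        before = set(outdir.iterdir())
        try:
            if stage == "ms":
                metrics = _run_ms(params, seeds["ms"], outdir)
            elif stage == "arrays":
                metrics = _run_arrays(params, seeds, outdir)
            else:
                metrics = _run_imaging(params, seeds["imaging"], outdir)
        except Exception as exc:  # record partial progress, then re-raise
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            failure = exc
            break
        new_files = sorted(p.name for p in set(outdir.iterdir()) - before)
        manifest["stages"][stage] = {
            "status": "completed",
            "parameters": params,
            "outputs": {name: _sha256(outdir / name) for name in new_files},
            "metrics": metrics,
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    if failure is not None:
        raise PipelineError(f"stage failed: {failure}") from failure
    return manifest
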