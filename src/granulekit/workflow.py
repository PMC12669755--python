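"""Configuration-driven orchestration of the analysis stages.

A YAML config selects stages and overrides their parameters; a run
executes the requested stages in dependency order, writes byte-stable
TSV/JSON outputs (floats serialized at 9 significant digits), and
emits a run report with parameter echo, per-stage status and a
checksummed output manifest. Identical (config, seed) runs produce
byte-identical data files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from . import __version__
from .dipeptides import SegmentScanParams, scan_fasta
from .enrichment import enrichment_matrix
from .imaging import (
    SegmentationParams,
    granule_cytoplasm_ratio,
    make_cytoplasm_mask,
    perinuclear_ring_metric,
    segment_granules,
)
from .simulate import (
    FgSequenceSpec,
    GranuleImageSpec,
    SrnaExperimentSpec,
    generate_fg_sequences,
    generate_granule_image,
    generate_srna_experiment,
)
from .targets import (
    TargetCallingParams,
    call_targets,
    compare_target_sets,
    metagene_profile,
    profile_similarity,
)

__all__ = ["ConfigError", "PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

logger = logging.getLogger("granulekit")

STAGE_ORDER = [
    "simulate_images",
    "quantify",
    "simulate_srna",
    "targets",
    "enrich",
    "simulate_sequences",
    "fgscan",
]

STAGE_DEPENDENCIES = {
    "quantify": ["simulate_images"],
    "targets": ["simulate_srna"],
    "enrich": ["targets"],
    "fgscan": ["simulate_sequences"],
}

#: Demo-scale defaults per stage. Analysis-rule defaults (5 RPM, 2-fold,
#: 100 bins) are the published thresholds.
STAGE_DEFAULTS: dict[str, dict] = {
    "simulate_images": {
        "n_nuclei": 2,
        "granules_per_nucleus": 4,
        "query_enrichment_ratio": 3.0,
        "n_planes": 24,
        "cytoplasm_level": 100.0,
    },
    "quantify": {"log_sigma_um": 0.2, "band_um": 0.5, "min_area_px": 4},
    "simulate_srna": {
        "n_genes": 300,
        "n_replicates": 3,
        "library_depth": 200000,
        "ip_enrichment_fold": 4.0,
        "n_default_targets": 60,
    },
    "targets": {
        "min_rpm": 5.0,
        "min_fold_change": 2.0,
        "pseudocount_rpm": 0.1,
        "bins": 100,
    },
    "enrich": {"epsilon": 0.5, "significance": 0.05},
    "simulate_sequences": {
        "n_sequences": 8,
        "length": 400,
        "planted_start": 150,
        "planted_end": 250,
        "fg_density": 0.25,
    },
    "fgscan": {"threshold": 0.005, "p_max": 0.001, "focus_residue": "G"},
}

_PARAM_CHECKS = {
    ("simulate_images", "n_nuclei"): lambda v: v >= 1 or "must be >= 1",
    ("simulate_images", "n_planes"): lambda v: v >= 1 or "must be >= 1",
    ("simulate_images", "query_enrichment_ratio"): lambda v: v >= 0 or "must be >= 0",
    ("simulate_images", "cytoplasm_level"): lambda v: v > 0 or "must be > 0",
    ("quantify", "log_sigma_um"): lambda v: v > 0 or "must be > 0",
    ("quantify", "band_um"): lambda v: v > 0 or "must be > 0",
    ("quantify", "min_area_px"): lambda v: v >= 0 or "must be >= 0",
    ("simulate_srna", "n_genes"): lambda v: v >= 1 or "must be >= 1",
    ("simulate_srna", "library_depth"): lambda v: v > 0 or "must be > 0",
    ("simulate_srna", "ip_enrichment_fold"): lambda v: v >= 1 or "must be >= 1",
    ("targets", "min_rpm"): lambda v: v >= 0 or "must be >= 0",
    ("targets", "min_fold_change"): lambda v: v >= 1 or "must be >= 1",
    ("targets", "pseudocount_rpm"): lambda v: v >= 0 or "must be >= 0",
    ("targets", "bins"): lambda v: v >= 1 or "must be >= 1",
    ("enrich", "significance"): lambda v: 0 < v < 1 or "must be in (0, 1)",
    ("simulate_sequences", "fg_density"): lambda v: 0 <= v <= 0.5 or "must be in [0, 0.5]",
    ("fgscan", "threshold"): lambda v: 0 < v <= 1 or "must be in (0, 1]",
    ("fgscan", "p_max"): lambda v: 0 < v <= 1 or "must be in (0, 1]",
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries all violations found."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid config:\n  " + "\n  ".join(violations))


@dataclass
class PipelineConfig:
    """A validated pipeline configuration with defaults filled in."""

    seed: int = 0
    stages: dict[str, dict] = field(default_factory=dict)


@dataclass
class RunReport:
    """Per-stage status, parameter echo and checksummed output manifest."""

    seed: int
    version: str
    stage_status: dict[str, str] = field(default_factory=dict)
    parameters: dict[str, dict] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)
    wall_time_s: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "stage_status": self.stage_status,
            "parameters": self.parameters,
            "manifest": self.manifest,
            "wall_time_s": self.wall_time_s,
        }

    @property
    def ok(self) -> bool:
        return not any(
            s.startswith(("failed", "skipped")) for s in self.stage_status.values()
        )


def validate_config(config_text: str) -> PipelineConfig:
    """Parse and validate a YAML pipeline config.

    All violations — unknown keys, unknown stages or parameters, and
    out-of-range values — are collected and reported together.
    """
    try:
        raw = yaml.safe_load(config_text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError([f"unparseable YAML: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    violations: list[str] = []
    known_top = {"seed", "stages"}
    for key in set(raw) - known_top:
        violations.append(f"unknown top-level key: {key!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        violations.append("seed must be an integer")
        seed = 0

    stages_raw = raw.get("stages", {name: {} for name in STAGE_ORDER})
    if not isinstance(stages_raw, dict):
        violations.append("stages must be a mapping of stage name -> params")
        stages_raw = {}

    stages: dict[str, dict] = {}
    for name, params in stages_raw.items():
        if name not in STAGE_ORDER:
            violations.append(f"unknown stage: {name!r}")
            continue
        if params is None or params is True:
            params = {}
        if params is False:
            continue
        if not isinstance(params, dict):
            violations.append(f"stage {name!r}: params must be a mapping")
            continue
        effective = dict(STAGE_DEFAULTS[name])
        for pname, value in params.items():
            if pname not in STAGE_DEFAULTS[name]:
                violations.append(f"stage {name!r}: unknown parameter {pname!r}")
                continue
            check = _PARAM_CHECKS.get((name, pname))
            if check is not None:
                verdict = check(value)
                if verdict is not True:
                    violations.append(f"stage {name!r}: {pname} = {value!r} {verdict}")
                    continue
            effective[pname] = value
        stages[name] = effective

    for name, deps in STAGE_DEPENDENCIES.items():
        if name in stages:
            for dep in deps:
                if dep not in stages:
                    violations.append(
                        f"stage {name!r} requires stage {dep!r} to be enabled"
                    )

    if violations:
        raise ConfigError(violations)
    return PipelineConfig(seed=seed, stages=stages)


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Execute the configured stages in dependency order.

    Stage failures are recorded; dependent stages are skipped while
    independent ones still run. Every produced file enters the manifest
    with its SHA-256 checksum.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__)
    context: dict[str, object] = {}

    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    try:
        for name in STAGE_ORDER:
            if name not in config.stages:
                report.stage_status[name] = "disabled"
                continue
            deps = STAGE_DEPENDENCIES.get(name, [])
            if any(report.stage_status.get(d, "").startswith(("failed", "skipped"))
                   for d in deps):
                report.stage_status[name] = "skipped (dependency failed)"
                continue
            params = config.stages[name]
            report.parameters[name] = params
            logger.info("stage %s: %s", name, params)
            t0 = time.perf_counter()
            try:
                files = _STAGE_RUNNERS[name](params, config.seed, outdir, context)
                for f in files:
                    report.manifest[str(Path(f).name)] = gio.sha256_file(f)
                report.stage_status[name] = "ok"
            except Exception as exc:  # noqa: BLE001 - report and continue
                logger.exception("stage %s failed", name)
                report.stage_status[name] = f"failed: {exc}"
            report.wall_time_s[name] = round(time.perf_counter() - t0, 3)
    finally:
        logger.removeHandler(handler)
        handler.close()

    gio.write_json(report.to_dict(), outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# stage runners (params, seed, outdir, shared context) -> list of files
# ---------------------------------------------------------------------------

def _stage_simulate_images(params, seed, outdir, ctx):
    spec = GranuleImageSpec(
        n_nuclei=params["n_nuclei"],
        granules_per_nucleus=params["granules_per_nucleus"],
        query_enrichment_ratio=params["query_enrichment_ratio"],
        n_planes=params["n_planes"],
        cytoplasm_level=params["cytoplasm_level"],
    )
    stack, truth = generate_granule_image(spec, seed)
    ctx["stack"], ctx["image_truth"] = stack, truth
    tiff = outdir / "granule_stack.tif"
    stack.to_tiff(tiff)
    sidecar = outdir / "granule_truth.json"
    gio.write_json(
        {
            "true_ratio": truth.true_ratio,
            "granule_centers_um": truth.granule_centers,
            "n_nuclei": int(truth.nucleus_masks.max()),
        },
        sidecar,
    )
    return [tiff, sidecar]


def _stage_quantify(params, seed, outdir, ctx):
    stack, truth = ctx["stack"], ctx["image_truth"]
    seg = segment_granules(
        stack,
        "marker",
        SegmentationParams(
            log_sigma_um=params["log_sigma_um"], min_area_px=params["min_area_px"]
        ),
    )
    granules = seg.mask & (truth.nucleus_masks == 0)
    cyto = make_cytoplasm_mask(
        np.ones_like(granules), truth.nucleus_masks, granules
    )
    result = granule_cytoplasm_ratio(stack, "query", granules, cyto)
    per_plane = pd.DataFrame(
        {"plane_ratio": result.per_plane_ratio}
    ).rename_axis("used_plane").reset_index()
    f1 = outdir / "partition_per_plane.tsv"
    gio.write_tsv(per_plane, f1)
    rings = perinuclear_ring_metric(
        stack, "query", truth.nucleus_masks, band_um=params["band_um"]
    )
    f2 = outdir / "ring_sd.tsv"
    gio.write_tsv(
        pd.DataFrame(
            [
                {"nucleus": r.nucleus_label, "plane": r.plane, "sd": r.sd,
                 "clipped": r.clipped}
                for r in rings
            ]
        ),
        f2,
    )
    f3 = outdir / "partition_summary.json"
    gio.write_json(
        {
            "mean_ratio": result.mean_ratio,
            "sd_ratio": result.sd_ratio,
            "n_planes_used": result.n_planes_used,
            "n_planes_skipped": result.n_planes_skipped,
            "true_ratio": truth.true_ratio,
        },
        f3,
    )
    return [f1, f2, f3]


def _stage_simulate_srna(params, seed, outdir, ctx):
    rng = np.random.default_rng(seed + 1)
    n = params["n_genes"]
    genes = [f"g{i:05d}" for i in range(n)]
    base = set(rng.choice(genes, size=params["n_default_targets"], replace=False))
    lost = set(rng.choice(sorted(base), size=max(1, len(base) // 6), replace=False))
    spec = SrnaExperimentSpec(
        n_genes=n,
        n_replicates=params["n_replicates"],
        library_depth=params["library_depth"],
        ip_enrichment_fold=params["ip_enrichment_fold"],
        true_targets={"WT": base, "mutant": base - lost},
        positional_bias={
            "uniform": np.ones(10),
            "5p": np.linspace(2.0, 0.5, 10),
        },
    )
    experiment, coverage, truth = generate_srna_experiment(spec, seed + 1)
    ctx["experiment"], ctx["coverage"], ctx["srna_truth"] = experiment, coverage, truth
    ctx["library_depth"] = params["library_depth"]
    f1, f2 = outdir / "counts.tsv", outdir / "design.tsv"
    gio.write_counts(experiment, f1, f2)
    f3 = outdir / "srna_truth.tsv"
    gio.write_tsv(truth.reset_index(), f3)
    return [f1, f2, f3]


def _stage_targets(params, seed, outdir, ctx):
    experiment = ctx["experiment"]
    calling = TargetCallingParams(
        min_rpm=params["min_rpm"],
        min_fold_change=params["min_fold_change"],
        pseudocount_rpm=params["pseudocount_rpm"],
    )
    files = []
    sets = {}
    for cond in experiment.conditions:
        called, evidence = call_targets(experiment, cond, calling)
        sets[cond] = called
        f = outdir / f"evidence_{cond}.tsv"
        gio.write_tsv(evidence.rename_axis("gene").reset_index(), f)
        files.append(f)
    ctx["called_sets"] = sets
    conds = experiment.conditions
    if len(conds) >= 2:
        a, b = conds[0], conds[1]
        venn = compare_target_sets(sets[a], sets[b])
        f = outdir / "venn.json"
        gio.write_json(
            {"condition_a": a, "condition_b": b, **venn.sizes, **venn.percent_exclusive},
            f,
        )
        files.append(f)
        ctx["venn"] = venn

    coverage = ctx["coverage"]
    depth = ctx["library_depth"]
    rows = []
    similarity = {}
    profiles = {}
    for cond in conds:
        for role in ("IP", "input"):
            libs = experiment.libraries(cond, role).index
            per_rep = [
                metagene_profile(
                    coverage[lib], sets[cond], depth, n_bins=params["bins"],
                    track_role=role,
                )
                for lib in libs
                if sets[cond]
            ]
            if not per_rep:
                continue
            mean_bins = np.mean([p.bins for p in per_rep], axis=0)
            profiles[(cond, role)] = mean_bins
            for i, v in enumerate(mean_bins):
                rows.append(
                    {"condition": cond, "role": role, "bin": i, "mean_rpm": v}
                )
    if len(conds) >= 2 and (conds[0], "IP") in profiles and (conds[1], "IP") in profiles:
        from .targets import MetageneProfile

        similarity["ip_profile_pearson"] = profile_similarity(
            MetageneProfile(profiles[(conds[0], "IP")], 0),
            MetageneProfile(profiles[(conds[1], "IP")], 0),
        )
    f = outdir / "metagene.tsv"
    gio.write_tsv(pd.DataFrame(rows), f)
    files.append(f)
    if similarity:
        f = outdir / "profile_similarity.json"
        gio.write_json(similarity, f)
        files.append(f)
    return files


def _stage_enrich(params, seed, outdir, ctx):
    venn = ctx["venn"]
    truth = ctx["srna_truth"]
    universe = set(truth.index)
    row_sets = {
        "a_only": venn.a_only,
        "b_only": venn.b_only,
        "shared": venn.shared,
    }
    col_sets = {
        label: set(truth.index[truth["geneset_label"] == label])
        for label in ("specific", "shared")
    }
    matrix = enrichment_matrix(
        row_sets, col_sets, universe,
        epsilon=params["epsilon"], significance=params["significance"],
    )
    f = outdir / "enrichment_matrix.tsv"
    gio.write_tsv(matrix, f)
    return [f]


def _stage_simulate_sequences(params, seed, outdir, ctx):
    spec = FgSequenceSpec(
        n_sequences=params["n_sequences"],
        length=params["length"],
        planted_segments=[
            (params["planted_start"], params["planted_end"], params["fg_density"])
        ],
        seed=seed + 2,
    )
    records, truth = generate_fg_sequences(spec)
    ctx["fg_records"], ctx["fg_truth"] = records, truth
    f1 = outdir / "sequences.fasta"
    gio.write_fasta(records, f1)
    f2 = outdir / "sequences_truth.json"
    gio.write_json(truth, f2)
    return [f1, f2]


def _stage_fgscan(params, seed, outdir, ctx):
    records = ctx["fg_records"]
    table = scan_fasta(
        records,
        scan_params=SegmentScanParams(
            focus_residue=params["focus_residue"], p_max=params["p_max"]
        ),
        threshold=params["threshold"],
    )
    f = outdir / "fgscan.tsv"
    gio.write_tsv(table, f)
    return [f]


_STAGE_RUNNERS = {
    "simulate_images": _stage_simulate_images,
    "quantify": _stage_quantify,
    "simulate_srna": _stage_simulate_srna,
    "targets": _stage_targets,
    "enrich": _stage_enrich,
    "simulate_sequences": _stage_simulate_sequences,
    "fgscan": _stage_fgscan,
}
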