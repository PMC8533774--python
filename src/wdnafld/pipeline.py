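"""Stage orchestration behind one YAML configuration.

Stages run in dependency order (simulate -> deg -> {rjg, cluster, overlap};
histo; mri) and write plain-text tables plus a run manifest (config hash,
seed, package version) that suffices to reproduce every output
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clustering, diffexpr, histoquant, io, mrit1, rjg, synth, xspecies
from .design import make_design

log = logging.getLogger("wdnafld")

ALL_STAGES = ("simulate", "deg", "rjg", "cluster", "overlap", "histo", "mri")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "thresholds": {
        "deg_fold": 1.5,
        "deg_fdr": 0.001,
        "rjg_fold": 4.0,
        "rjg_fdr": 0.05,
        "rjg_corr": 0.9,
        "top_n": 1000,
        "k_range": [2, 10],
        "min_diameter": 2.3,
        "min_roundness": 0.5,
        "crown_min_diameter": 4.42,
        "crown_coverage": 0.3,
        "annulus_um": 3.0,
        "margin": 20.0,
    },
    "convention": "results_text",
    "synthetic": {
        "design": {},
        "counts": {
            "n_null": 2000, "n_monotone_up": 50, "n_monotone_down": 70,
            "n_two_peak": 20, "n_rjg_up": 30, "n_rjg_down": 30,
            "log2fc": 2.5, "dispersion": 0.05,
        },
        "lists": {"target_recall": 0.38, "target_precision": 0.19,
                  "diseases": ["NAFLD", "HCC"]},
        "slide": {"n_droplets": 30, "fraction_crowned": 0.4, "n_kupffer": 3},
        "vfa": {"t1_pre_ms": 1000.0, "t1_post_ms": 210.0, "shape": [32, 32],
                "noise_sd": 0.0},
    },
    "inputs": {},  # optional paths: counts_tsv, sample_sheet
}


class ConfigError(ValueError):
    pass


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _merge(base: dict, override: dict, _path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        # synthetic sub-blocks are kwargs to generator dataclasses that carry
        # their own defaults: a user-provided block replaces the default one
        if isinstance(v, dict) and isinstance(out.get(k), dict) and _path != "synthetic":
            out[k] = _merge(out[k], v, _path=k)
        else:
            out[k] = v
    return out


def load_config(config) -> dict:
    if config is None:
        cfg = {}
    elif isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text()) or {}
    elif isinstance(config, dict):
        cfg = config
    else:
        raise ConfigError(f"unsupported config type {type(config)!r}")
    merged = _merge(DEFAULT_CONFIG, cfg)
    thr = merged["thresholds"]
    for key in ("deg_fold", "deg_fdr", "rjg_fold", "rjg_fdr", "rjg_corr",
                "top_n", "min_diameter", "crown_min_diameter", "margin"):
        if not thr[key] > 0:
            raise ConfigError(f"threshold {key} must be positive")
    unknown = set(merged["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    if merged["convention"] not in xspecies.CONVENTIONS:
        raise ConfigError(f"unknown convention {merged['convention']!r}")
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, sep="\t", float_format=io.FLOAT_FMT, **kw)


def run_pipeline(config=None, out_dir="wdnafld_out", seed: int | None = None) -> ReportBundle:
    """Execute the configured stages and write a report bundle."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    stages = [s for s in ALL_STAGES if s in cfg["stages"]]
    thr = cfg["thresholds"]
    bundle = ReportBundle(out, {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "stages": stages,
    })
    state: dict = {}

    try:
        for stage in stages:
            t0 = time.perf_counter()
            log.info("stage %s started", stage)
            _STAGES[stage](cfg, thr, seed, out, state, bundle)
            log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()

    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    return bundle


def _need(state: dict, key: str, stage: str):
    if key not in state:
        raise RuntimeError(
            f"stage {stage!r} needs output {key!r}; run its upstream stage or "
            f"provide the input in the config"
        )
    return state[key]


def _stage_simulate(cfg, thr, seed, out, state, bundle):
    syn = cfg["synthetic"]
    design = make_design(seed=seed, **syn.get("design", {}))
    counts, truths = synth.simulate_counts(design, synth.GeneSpec(**syn["counts"]), seed)
    state["design"], state["counts"], state["truths"] = design, counts, truths
    io.write_sample_sheet(design, out / "samples.csv")
    io.write_counts_tsv(counts, out / "counts.tsv")
    truth_frame = pd.DataFrame(
        [(t.gene_id, t.archetype, t.jump_level or "", t.true_log2fc,
          t.baseline_mean, t.dispersion) for t in truths],
        columns=["gene", "archetype", "jump_level", "true_log2fc",
                 "baseline_mean", "dispersion"],
    )
    _write(truth_frame, out / "gene_truth.tsv", index=False)
    bundle.tables["gene_truth"] = truth_frame

    lists_cfg = dict(syn.get("lists", {}))
    diseases = lists_cfg.pop("diseases", ["NAFLD"])
    lists, overlap_truth = synth.simulate_disease_lists(
        truths, seed=seed + 1, diseases=diseases, **lists_cfg
    )
    state["disease_lists"] = lists
    for disease, per_dir in lists.items():
        io.write_gene_list_tsv(per_dir, out / f"human_{disease}.tsv")


def _stage_deg(cfg, thr, seed, out, state, bundle):
    if "counts" not in state and cfg["inputs"].get("counts_tsv"):
        state["counts"] = io.read_counts_tsv(cfg["inputs"]["counts_tsv"])
        state["design"] = io.read_sample_sheet(cfg["inputs"]["sample_sheet"])
    counts = _need(state, "counts", "deg")
    design = _need(state, "design", "deg")
    plan = diffexpr.run_comparison_plan(counts, design, thr["deg_fold"], thr["deg_fdr"])
    state["plan"] = plan
    rows = []
    for label, degset in plan.deg_sets.items():
        rows.append((label, len(degset.up), len(degset.down)))
    summary = pd.DataFrame(rows, columns=["comparison", "n_up", "n_down"])
    _write(summary, out / "deg_summary.tsv", index=False)
    bundle.tables["deg_summary"] = summary
    deg_dir = out / "deg"
    deg_dir.mkdir(exist_ok=True)
    for label, res in plan.results.items():
        fname = label.replace(" ", "_") + ".tsv"
        _write(res.table, deg_dir / fname)


def _stage_rjg(cfg, thr, seed, out, state, bundle):
    counts = _need(state, "counts", "rjg")
    design = _need(state, "design", "rjg")
    result = rjg.scan_rjg(
        counts, design,
        fold_threshold=thr["rjg_fold"],
        fdr_threshold=thr["rjg_fdr"],
        corr_threshold=thr["rjg_corr"],
    )
    state["rjg"] = result
    _write(result.hits, out / "rjg_hits.tsv", index=False)
    bundle.tables["rjg_hits"] = result.hits


def _stage_cluster(cfg, thr, seed, out, state, bundle):
    counts = _need(state, "counts", "cluster")
    design = _need(state, "design", "cluster")
    sf = diffexpr.size_factors(counts)
    expr = clustering.vst(counts, sf)
    n = min(int(thr["top_n"]), counts.shape[0])
    top = clustering.top_variable_genes(expr, n)
    sub = clustering.ExpressionMatrix(expr.values.loc[top], expr.provenance)
    ts = rjg.order_series(design)
    means = clustering.condition_means(sub, design, level_order=ts.labels)
    lo, hi = thr["k_range"]
    scan = clustering.silhouette_scan(means, range(int(lo), int(hi) + 1), seed=seed)
    k = int(cfg.get("k") or (scan.local_optima[-1] if scan.local_optima else scan.best_k))
    result = clustering.kmeans_profiles(means, k, seed=seed)
    state["clusters"] = result
    _write(scan.scores, out / "silhouette.tsv", index=False)
    assignments = result.assignments.rename_axis("gene").reset_index()
    _write(assignments, out / "clusters.tsv", index=False)
    _write(result.centroids, out / "cluster_centroids.tsv")
    bundle.tables["silhouette"] = scan.scores
    bundle.tables["clusters"] = assignments


def _stage_overlap(cfg, thr, seed, out, state, bundle):
    plan = _need(state, "plan", "overlap")
    lists = _need(state, "disease_lists", "overlap")
    deg_map = {}
    for label, degset in plan.deg_sets.items():
        if label.endswith(" vs SD3") and label.startswith("WD"):
            week = int(label.split(" ")[0][2:])
            deg_map[week] = {"up": degset.up, "down": degset.down}
    table = xspecies.overlap_timecourse(deg_map, lists, cfg["convention"])
    _write(table, out / "overlap.tsv", index=False)
    bundle.tables["overlap"] = table


def _stage_histo(cfg, thr, seed, out, state, bundle):
    spec = synth.SlideSpec(**cfg["synthetic"].get("slide", {}))
    channels, truth = synth.simulate_histology_image(spec, seed + 2)
    pixel_map = histoquant.classify_pixels(channels)
    lipid = pixel_map.mask("lipid")
    lipid = histoquant.exclude_margin(
        lipid, channels.tissue_mask, thr["margin"], spec.um_per_px
    )
    labels = histoquant.separate_droplets(lipid, spec.um_per_px)
    droplets = histoquant.measure_and_filter(
        labels, thr["min_diameter"], thr["min_roundness"]
    )
    droplets = histoquant.classify_crowns(
        droplets, pixel_map.mask("macrophage"),
        thr["annulus_um"], thr["crown_coverage"], thr["crown_min_diameter"],
    )
    summary = histoquant.zonal_quantification(droplets, pixel_map, channels.tissue_mask)
    state["histo"] = (droplets, summary, truth)
    obj_frame = pd.DataFrame(
        [(o.label, o.centroid_um[0], o.centroid_um[1], o.area_um2,
          o.equivalent_diameter_um, o.roundness, o.zone, o.crowned, o.crown_coverage)
         for o in droplets.objects],
        columns=["label", "x_um", "y_um", "area_um2", "diameter_um",
                 "roundness", "zone", "crowned", "coverage"],
    )
    _write(obj_frame, out / "droplets.tsv", index=False)
    zone_frame = pd.DataFrame(
        [(z, s.lipid_area_fraction, s.droplet_count, s.lipogranuloma_count,
          s.lipogranuloma_density_per_mm2) for z, s in summary.zones.items()],
        columns=["zone", "lipid_area_fraction", "droplet_count",
                 "lipogranuloma_count", "lipogranuloma_density_per_mm2"],
    )
    _write(zone_frame, out / "zonal_summary.tsv", index=False)
    io.write_label_tiff(droplets.labels.labels, spec.um_per_px, out / "droplet_labels.tif")
    bundle.tables["droplets"] = obj_frame
    bundle.tables["zonal_summary"] = zone_frame


def _stage_mri(cfg, thr, seed, out, state, bundle):
    vcfg = cfg["synthetic"].get("vfa", {})
    shape = tuple(vcfg.get("shape", [32, 32]))
    t1_pre = np.full(shape, float(vcfg.get("t1_pre_ms", 1000.0)))
    t1_post = np.full(shape, float(vcfg.get("t1_post_ms", 210.0)))
    m0 = np.ones(shape)
    noise = float(vcfg.get("noise_sd", 0.0))
    pre = synth.simulate_vfa_stack(t1_pre, m0, noise_sd=noise, seed=seed + 3)
    post = synth.simulate_vfa_stack(t1_post, m0, noise_sd=noise, seed=seed + 4)
    fit_pre = mrit1.fit_t1_vfa(pre)
    fit_post = mrit1.fit_t1_vfa(post)
    re_map = mrit1.relative_enhancement(fit_pre, fit_post)
    rois = {"liver": np.ones(shape, dtype=bool)}
    stats = pd.concat(
        {
            "t1_pre_ms": mrit1.roi_stats(fit_pre, rois),
            "t1_post_ms": mrit1.roi_stats(fit_post, rois),
            "re": mrit1.roi_stats(re_map, rois),
        },
        names=["map"],
    )
    state["mri"] = (fit_pre, fit_post, re_map)
    _write(stats.reset_index(), out / "mri_summary.tsv", index=False)
    bundle.tables["mri_summary"] = stats.reset_index()


_STAGES = {
    "simulate": _stage_simulate,
    "deg": _stage_deg,
    "rjg": _stage_rjg,
    "cluster": _stage_cluster,
    "overlap": _stage_overlap,
    "histo": _stage_histo,
    "mri": _stage_mri,
}
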