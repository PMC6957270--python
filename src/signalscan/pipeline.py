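"""End-to-end orchestration: standardize -> filter -> LOO classify ->
occlusion scan -> heatmaps -> metrics -> composite rendering.

Every run serializes its configuration into the output directory and stamps
each artifact with the configuration hash, so a directory of outputs is
self-describing and mismatched artifacts are detectable. Stage failures
abort with a stage-labeled error and leave a FAILED marker beside any
partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (
    SYMPATRIC_PRESETS,
    aggregate_heatmap,
    compute_metrics,
    render_composite,
    select_species_subset,
)
from .facespace import compute_averages, loo_evaluate
from .images import (
    ColorTransform,
    Manifest,
    apply_color_transform,
    filter_min_individuals,
    load_manifest,
    resize_standard,
    split_manifest_hemifaces,
    write_image16,
    write_png8,
)
from .occlusion import UNTESTED, OccluderSpec, scan_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (serialized verbatim into outputs)."""

    manifest: str
    out_dir: str
    width: int = 392
    height: int = 297
    color_matrix: tuple | None = None  # 3x3 rows; None = identity
    min_individuals: int = 4
    side: str = "left"  # left | right | whole
    radius: int = 30
    fill: str = "species-mean"  # 'species-mean' or '#rrggbb'
    classification_mode: str = "distinct_images"
    subset_target: str | None = None  # use the sympatric preset for this species
    colormap: str = "viridis"
    alpha: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "color_matrix" in raw and raw["color_matrix"] is not None:
            raw["color_matrix"] = tuple(tuple(row) for row in raw["color_matrix"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        if d["color_matrix"] is not None:
            d["color_matrix"] = [list(r) for r in d["color_matrix"]]
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def occluder(self) -> OccluderSpec:
        if self.fill == "species-mean":
            return OccluderSpec(radius=self.radius)
        color = self.fill.lstrip("#")
        if len(color) != 6:
            raise ValueError(f"fill must be 'species-mean' or '#rrggbb', got {self.fill!r}")
        rgb = tuple(int(color[i : i + 2], 16) / 255.0 for i in (0, 2, 4))
        return OccluderSpec(radius=self.radius, fill_policy="fixed_color", fixed_color=rgb)


def _write_csv(path: str, df: pd.DataFrame, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_artifact_csv(path: str) -> tuple[pd.DataFrame, str | None]:
    """Read a pipeline CSV and the config hash from its comment header."""
    config_hash = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# config_hash="):
            config_hash = first.strip().split("=", 1)[1]
    return pd.read_csv(path, comment="#"), config_hash


def run_pipeline(cfg: RunConfig) -> str:
    """Run the full workflow; returns the artifact directory.

    Stage order: standardize, filter, classify (leave-one-out), scan,
    aggregate, metrics, render. Raises StageError on the first failure.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    chash = cfg.config_hash
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        fh.write(cfg.to_yaml())
    counts: dict[str, int] = {}
    try:
        stage = "standardize"
        manifest = load_manifest(cfg.manifest)
        counts["images_loaded"] = len(manifest)
        transform = (
            ColorTransform(np.asarray(cfg.color_matrix, dtype=float))
            if cfg.color_matrix is not None
            else ColorTransform.identity()
        )
        records = []
        for r in manifest:
            r = apply_color_transform(r, transform)
            records.append(resize_standard(r, cfg.width, cfg.height))
        manifest = Manifest(tuple(records))
        if cfg.side in ("left", "right"):
            left, right = split_manifest_hemifaces(manifest)
            manifest = left if cfg.side == "left" else right
        logger.info("standardize: %d images at %dx%d side=%s",
                    len(manifest), cfg.height, cfg.width, cfg.side)

        stage = "filter"
        manifest = filter_min_individuals(manifest, cfg.min_individuals)
        if cfg.subset_target is not None:
            preset = SYMPATRIC_PRESETS.get(cfg.subset_target)
            if preset is None:
                raise ValueError(
                    f"no sympatric preset for {cfg.subset_target!r}; "
                    f"available: {sorted(SYMPATRIC_PRESETS)}"
                )
            manifest = select_species_subset(manifest, cfg.subset_target, preset)
        counts["images_after_filter"] = len(manifest)
        counts["species"] = len(manifest.species_index)
        counts["individuals"] = len(manifest.individual_index)
        logger.info("filter: %d species, %d individuals, %d images",
                    counts["species"], counts["individuals"], len(manifest))

        stage = "classify"
        loo = loo_evaluate(manifest, mode="distinct_images")
        counts["images_classified"] = len(loo.table)
        counts["images_correct"] = int(loo.table["correct"].sum())
        _write_csv(os.path.join(out, "loo_classification.csv"),
                   loo.table.drop(columns=["tie"]), chash)
        if cfg.classification_mode == "individual_averages":
            loo_avg = loo_evaluate(manifest, mode="individual_averages")
            _write_csv(os.path.join(out, "loo_individual_averages.csv"),
                       loo_avg.table.drop(columns=["tie"]), chash)
        logger.info("classify: %d/%d correct (%.2f%%)", counts["images_correct"],
                    counts["images_classified"], loo.percent_correct)

        stage = "scan"
        occluder = cfg.occluder()
        maps = scan_dataset(manifest, loo, occluder)
        counts["occlusion_maps"] = len(maps)
        map_dir = os.path.join(out, "occlusion_maps")
        os.makedirs(map_dir, exist_ok=True)
        meta_rows = []
        for mp in maps:
            # 0 = misclassified, 255 = correct, mid-gray = untested
            png = np.where(
                mp.values == UNTESTED, 128, mp.values.astype(np.int16) * 255
            ).astype(np.uint8)
            from PIL import Image

            Image.fromarray(png, mode="L").save(
                os.path.join(map_dir, f"{mp.image_id}.png")
            )
            meta_rows.append(
                {
                    "image_id": mp.image_id,
                    "individual_id": mp.individual_id,
                    "species_id": mp.species_id,
                    "radius": occluder.radius,
                    "fill_policy": occluder.fill_policy,
                    "n_tested": int(mp.tested_mask.sum()),
                    "n_misclassified": int((mp.values == 0).sum()),
                }
            )
        _write_csv(os.path.join(map_dir, "maps.csv"), pd.DataFrame(meta_rows), chash)
        logger.info("scan: %d occlusion maps (radius %d)", len(maps), occluder.radius)

        stage = "aggregate"
        avg = compute_averages(manifest)
        heat_dir = os.path.join(out, "heatmaps")
        comp_dir = os.path.join(out, "composites")
        os.makedirs(heat_dir, exist_ok=True)
        os.makedirs(comp_dir, exist_ok=True)
        metric_rows = []
        for sp in manifest.species_index:
            sp_maps = [mp for mp in maps if mp.species_id == sp]
            if not sp_maps:
                logger.warning("aggregate: no correctly classified images for %s", sp)
                continue
            hm = aggregate_heatmap(sp_maps, sp)
            safe = sp.replace(" ", "_").replace(".", "")
            grid = np.where(np.isnan(hm.values), 0.5, hm.values)
            write_image16(os.path.join(heat_dir, f"{safe}.png"), grid,
                          {"config_hash": chash})
            pd.DataFrame(hm.values).to_csv(
                os.path.join(heat_dir, f"{safe}_values.csv"), index=False,
                header=False, float_format="%.17g", na_rep="nan")

            stage = "metrics"
            row = compute_metrics(hm)
            metric_rows.append(asdict(row))

            stage = "render"
            comp = render_composite(hm, avg.species_averages[sp],
                                    cfg.colormap, cfg.alpha)
            write_png8(os.path.join(comp_dir, f"{safe}.png"), comp,
                       {"config_hash": chash})
            stage = "aggregate"
        metrics = pd.DataFrame(metric_rows)
        _write_csv(os.path.join(out, "metrics.csv"), metrics, chash)
        counts["heatmaps"] = len(metric_rows)
    except Exception as exc:
        with open(os.path.join(out, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    run_log = {
        "signalscan_version": __version__,
        "config_hash": chash,
        "counts": counts,
        "side": cfg.side,
        "seed": cfg.seed,
    }
    with open(os.path.join(out, "run.json"), "w") as fh:
        json.dump(run_log, fh, indent=2)
    failed = os.path.join(out, "FAILED")
    if os.path.exists(failed):
        os.remove(failed)
    return out


REQUIRED_ARTIFACTS = ("config.yaml", "run.json", "loo_classification.csv", "metrics.csv")


def report_summary(artifact_dir: str) -> str:
    """Human-readable summary of a completed run.

    Reports overall and per-species accuracy, the critical-region metric
    table, and the species with the maximum mean classification error.
    Raises if artifacts are missing or their config hashes disagree.
    """
    missing = [
        f for f in REQUIRED_ARTIFACTS
        if not os.path.exists(os.path.join(artifact_dir, f))
    ]
    if os.path.exists(os.path.join(artifact_dir, "FAILED")):
        missing.append("(run marked FAILED)")
    if missing:
        raise FileNotFoundError(
            f"incomplete run in {artifact_dir}; missing: {missing}"
        )
    with open(os.path.join(artifact_dir, "run.json")) as fh:
        run_log = json.load(fh)
    loo, h1 = read_artifact_csv(os.path.join(artifact_dir, "loo_classification.csv"))
    metrics, h2 = read_artifact_csv(os.path.join(artifact_dir, "metrics.csv"))
    hashes = {run_log["config_hash"], h1, h2} - {None}
    if len(hashes) > 1:
        raise ValueError(f"config hash mismatch across artifacts: {sorted(hashes)}")
    lines = [
        f"signalscan run {run_log['config_hash']} "
        f"(v{run_log['signalscan_version']}, side={run_log['side']})",
        f"species: {run_log['counts']['species']}  "
        f"individuals: {run_log['counts']['individuals']}  "
        f"images: {run_log['counts']['images_after_filter']}",
        f"overall LOO accuracy: {100.0 * loo['correct'].mean():.2f}% "
        f"({int(loo['correct'].sum())}/{len(loo)})",
        "",
        "per-species accuracy:",
    ]
    per_sp = loo.groupby("true_species", sort=False)["correct"].agg(["mean", "count"])
    for sp, row in per_sp.iterrows():
        lines.append(f"  {sp:30s} {100.0 * row['mean']:6.2f}%  (n={int(row['count'])})")
    lines += ["", "critical-region metrics:"]
    for r in metrics.itertuples(index=False):
        lines.append(
            f"  {r.species_id:30s} proportion_misclassified={r.proportion_misclassified:.4f}  "
            f"mean_classification_error={r.mean_classification_error:.4f}"
        )
    if len(metrics):
        top = metrics.loc[metrics["mean_classification_error"].idxmax()]
        lines += [
            "",
            f"max mean_classification_error: {top['species_id']} "
            f"({top['mean_classification_error']:.4f}) — its critical regions are "
            "the most essential for correct classification",
        ]
    return "\n".join(lines)
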