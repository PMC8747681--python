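"""End-to-end orchestration: simulate -> extract -> analyze -> cluster.

Each stage reads its inputs from ``outdir`` and writes CSV/Newick/JSON
artifacts back to it, so stages can be re-run individually from cached
intermediates.  A run manifest (config snapshot, master seed, per-stage
outputs with SHA-256 checksums) makes reruns verifiable: the same seed
must reproduce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import multivariate, stats, traits as traits_mod
from .chart import build_chart_layout
from .config import ConfigError, StudyConfig
from .imaging import (
    ContourFilters,
    apply_color_correction,
    extract_grain_contours,
    fit_color_correction,
    locate_chart,
    segment_grains,
)
from .synthetic import generate_germination, generate_study
from .traits import ALL_TRAITS, COLOR_TRAITS, SHAPE_TRAITS, SIZE_TRAITS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "analyze", "cluster")


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict[str, list[str]] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, paths: list[Path]) -> None:
        self.outputs[stage] = [str(p) for p in paths]
        for p in paths:
            self.checksums[str(p)] = hashlib.sha256(Path(p).read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing upstream artifact for {what}: {path}")
    return path


def stage_simulate(cfg: StudyConfig, outdir: Path) -> list[Path]:
    from .synthetic import genotype_baselines

    bundle = generate_study(cfg, outdir=outdir)
    rng = np.random.default_rng([cfg.seed, 0x6E12])
    germ = generate_germination(bundle.design, bundle.ground_truth,
                                cfg.germination, rng)
    germ.to_csv(outdir / "germination.csv", index=False, float_format="%.4f")
    genotype_baselines(cfg).to_csv(outdir / "genotypes.csv",
                                   float_format="%.4f")
    return [outdir / "design.csv", outdir / "ground_truth.csv",
            outdir / "germination.csv", outdir / "genotypes.csv",
            outdir / "config.json"]


def extract_image(
    image: np.ndarray, layout, image_id: str, genotype: str, year: int,
    filters: ContourFilters | None = None,
) -> dict:
    """Full imaging chain for one image; returns a compute_trait_table item."""
    measured, mm_per_px = locate_chart(image, layout)
    transform = fit_color_correction(measured, layout.reference_rgb)
    corrected = apply_color_correction(image, transform)
    mask = segment_grains(corrected, chart_bbox=layout.bbox)
    contours, rejected = extract_grain_contours(mask, filters, mm_per_px)
    return {
        "image_id": image_id, "genotype": genotype, "year": int(year),
        "corrected": corrected, "contours": contours, "rejected": rejected,
        "mm_per_px": mm_per_px, "transform": transform, "mask": mask,
    }


def stage_extract(cfg: StudyConfig, outdir: Path) -> list[Path]:
    design = pd.read_csv(_require(outdir / "design.csv", "extract"))
    layout = build_chart_layout(pitch_px=cfg.chart_pitch_px,
                                pitch_mm=cfg.chart_pitch_mm)
    items, reject_rows, geom_rows = [], [], []
    for _, row in design.iterrows():
        image = iio.imread(_require(Path(row.image_path), "extract"))
        item = extract_image(image, layout, row.image_id, row.genotype, row.year)
        items.append(item)
        for rej in item["rejected"]:
            reject_rows.append({"image_id": row.image_id, "label": rej.label,
                                "reason": rej.reason, "area_mm2": rej.area_mm2})
        for j, c in enumerate(item["contours"]):
            mm = item["mm_per_px"]
            geom_rows.append({
                "image_id": row.image_id, "grain_id": f"{row.image_id}_s{j:02d}",
                "area_mm2": c.area * mm**2, "perimeter_mm": c.perimeter * mm,
                "feret_mm": c.feret_max * mm, "rect_l_mm": c.rect_l * mm,
                "rect_w_mm": c.rect_w * mm,
            })
    table = traits_mod.compute_trait_table(items)
    table.to_csv(outdir / "traits.csv", index=False, float_format="%.6f")
    geom_cols = ["image_id", "grain_id", "area_mm2", "perimeter_mm",
                 "feret_mm", "rect_l_mm", "rect_w_mm"]
    pd.DataFrame(geom_rows, columns=geom_cols).to_csv(
        outdir / "contours.csv", index=False, float_format="%.6f")
    reject_cols = ["image_id", "label", "reason", "area_mm2"]
    pd.DataFrame(reject_rows, columns=reject_cols).to_csv(
        outdir / "rejections.csv", index=False)
    return [outdir / "traits.csv", outdir / "contours.csv",
            outdir / "rejections.csv"]


def stage_analyze(cfg: StudyConfig, outdir: Path, n_rep: int = 2000) -> list[Path]:
    table = pd.read_csv(_require(outdir / "traits.csv", "analyze"))
    rng = np.random.default_rng([cfg.seed, 0x5747])
    trend = stats.year_trend_analysis(table, n_rep=n_rep, rng=rng)
    trend.to_csv(outdir / "trend.csv", index=False, float_format="%.6f")

    anova_rows = []
    for trait in ALL_TRAITS:
        for factor in ("genotype", "year"):
            res = stats.one_way_anova(table[trait], table[factor])
            anova_rows.append({"trait": trait, "factor": factor, "F": res.F,
                               "df_between": res.df_between,
                               "df_within": res.df_within, "p": res.p})
    pd.DataFrame(anova_rows).to_csv(outdir / "anova.csv", index=False,
                                    float_format="%.6g")

    outputs = [outdir / "trend.csv", outdir / "anova.csv"]
    germ_path = outdir / "germination.csv"
    summary: dict = {"seed": cfg.seed, "n_seeds": len(table)}
    yr = trend[trend.scheme == "YearRank"].set_index("trait")
    for key in ("Lab_ma", "Lab_mL", "HSV_mH", "HSV_mV", "sL", "sRu"):
        if key in yr.index:
            summary[f"yearrank_r_{key}"] = float(yr.loc[key, "r"])
            summary[f"yearrank_significant_{key}"] = bool(yr.loc[key, "significant"])
    if germ_path.exists():
        germ = pd.read_csv(germ_path)
        res = stats.germination_analysis(germ, table, n_rep=n_rep, rng=rng)
        res["correlations"].to_csv(outdir / "germination_correlations.csv",
                                   index=False, float_format="%.6f")
        res["cells"].to_csv(outdir / "germination_cells.csv", index=False,
                            float_format="%.4f")
        outputs += [outdir / "germination_correlations.csv",
                    outdir / "germination_cells.csv"]
        corr = res["correlations"].dropna(subset=["r"])
        top = corr.loc[corr["r"].idxmin()]
        summary["germination_most_negative_trait"] = str(top["trait"])
        summary["germination_most_negative_r"] = float(top["r"])
        summary["germination_n_seeds"] = int(res["n_seeds"])
        for key in ("Lab_ma", "HSV_mH"):
            sel = corr[corr.trait == key]
            if len(sel):
                summary[f"germination_r_{key}"] = float(sel["r"].iloc[0])
                summary[f"germination_significant_{key}"] = bool(
                    sel["significant"].iloc[0]
                )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    outputs.append(outdir / "summary.json")
    return outputs


def stage_cluster(cfg: StudyConfig, outdir: Path, k: int = 3) -> list[Path]:
    table = pd.read_csv(_require(outdir / "traits.csv", "cluster"))
    # traits as items: Euclidean distance between standardized trait columns
    z, kept = multivariate.standardize(table[list(ALL_TRAITS)].to_numpy(),
                                       ALL_TRAITS)
    trait_tree = multivariate.upgma_tree(z.T, labels=kept, is_distance=False)
    (outdir / "trait_tree.nwk").write_text(trait_tree.to_newick() + "\n")

    means = multivariate.genotype_trait_means(table, ALL_TRAITS)
    geno_tree = multivariate.upgma_tree(means.to_numpy(),
                                        labels=list(means.index))
    (outdir / "genotype_tree.nwk").write_text(geno_tree.to_newick() + "\n")
    k_eff = min(k, geno_tree.n_leaves)
    clusters = multivariate.cut_clusters(geno_tree, k_eff)
    cluster_df = pd.DataFrame({"genotype": means.index, "cluster": clusters})
    cluster_df.to_csv(outdir / "genotype_clusters.csv", index=False)

    outputs = [outdir / "trait_tree.nwk", outdir / "genotype_tree.nwk",
               outdir / "genotype_clusters.csv"]
    # LDA biplots (classes = UPGMA clusters of genotype means); classes
    # need >= 2 members, so singleton clusters are left out of the LDA
    counts = np.bincount(clusters)
    keep = counts[clusters] >= 2
    if keep.sum() < len(clusters):
        logger.info("LDA: dropping %d genotype(s) in singleton clusters",
                    int((~keep).sum()))
    kept_means = means[keep]
    kept_clusters = clusters[keep]
    if len(np.unique(kept_clusters)) >= 2:
        for name, subset in (("size_shape", SIZE_TRAITS + SHAPE_TRAITS),
                             ("color", COLOR_TRAITS)):
            bi = multivariate.lda_biplot(kept_means[list(subset)].to_numpy(),
                                         kept_clusters, trait_names=subset)
            axes = ["axis1", "axis2"][: bi.scores.shape[1]]
            scores = pd.DataFrame(bi.scores[:, :2], columns=axes)
            scores.insert(0, "genotype", kept_means.index)
            scores["cluster"] = kept_clusters
            scores.to_csv(outdir / f"lda_{name}_scores.csv", index=False,
                          float_format="%.6f")
            loadings = pd.DataFrame(bi.loadings[:, :2], columns=axes)
            loadings.insert(0, "trait", bi.trait_names)
            loadings.to_csv(outdir / f"lda_{name}_loadings.csv", index=False,
                            float_format="%.6f")
            outputs += [outdir / f"lda_{name}_scores.csv",
                        outdir / f"lda_{name}_loadings.csv"]
    else:
        logger.info("skipping LDA biplots: fewer than 2 usable clusters")
    return outputs


def run_pipeline(
    config: StudyConfig | str | Path | dict,
    outdir: str | Path,
    stages=STAGES,
    seed: int | None = None,
    n_rep: int = 2000,
) -> RunManifest:
    """Run the requested stages in order and write the run manifest.

    ``config`` may be a StudyConfig, a dict, or a path to a JSON file.
    ``seed`` overrides the config's seed.  Unknown stage names raise
    ConfigError; missing upstream artifacts raise DependencyError.
    """
    if isinstance(config, (str, Path)):
        cfg = StudyConfig.from_json(config)
    elif isinstance(config, dict):
        cfg = StudyConfig.from_dict(config)
    else:
        cfg = config
    if seed is not None:
        cfg = StudyConfig.from_dict({**asdict_config(cfg), "seed": int(seed)})
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict_config(cfg), seed=cfg.seed)
    runners = {
        "simulate": lambda: stage_simulate(cfg, outdir),
        "extract": lambda: stage_extract(cfg, outdir),
        "analyze": lambda: stage_analyze(cfg, outdir, n_rep=n_rep),
        "cluster": lambda: stage_cluster(cfg, outdir),
    }
    for stage in stages:
        t0 = time.perf_counter()
        paths = runners[stage]()
        dt = time.perf_counter() - t0
        manifest.timings[stage] = round(dt, 3)
        manifest.record(stage, paths)
        logger.info("stage %-8s finished in %.1fs (%d outputs)",
                    stage, dt, len(paths))
    manifest.write(outdir / "manifest.json")
    return manifest


def asdict_config(cfg: StudyConfig) -> dict:
    d = asdict(cfg)
    d["years"] = list(cfg.years)
    return d
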