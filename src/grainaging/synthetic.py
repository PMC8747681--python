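"""Synthetic seed-scatter study generator with known ground truth.

Emulated design: one image per genotype x harvest year, 17–20 ellipse-like
grains scattered without touching on a near-white background, a 24-patch
color chart at a fixed position, and an optional global diagonal color cast
applied to the whole scene (grains and chart alike) so the correction stage
has something to undo.

Coat color is modelled in CIELAB.  Each genotype carries a baseline
(L*, a*, b*); storage adds a monotone year-rank trend to redness (a*) and
lightness (L*).  The redness slope per rank is derived in closed form from
the configured target population correlation between year rank and
genotype-centered redness:

    r = beta * sd(rank) / sqrt(beta^2 sd(rank)^2 + s_cell^2 + s_grain^2)

Germination percentages are linearly coupled to the mean redness of each
genotype x year cell with a strong year-level offset (2009 depressed and
noisy), so the downstream germination analysis has a recoverable signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .chart import ChartLayout, build_chart_layout, render_chart
from .colorspaces import lab8_to_rgb
from .config import StudyConfig


class PlacementError(RuntimeError):
    """Grain placement by rejection sampling failed."""

    def __init__(self, placed: int, requested: int):
        super().__init__(
            f"placed only {placed} of {requested} grains without touching"
        )
        self.placed = placed
        self.requested = requested


@dataclass
class GroundTruthGrain:
    """Per-grain ground truth used by recovery tests."""

    image_id: str
    grain_id: str
    mask: np.ndarray               # boolean, full image frame
    axes_mm: tuple[float, float]   # (major, minor) full axis lengths
    mean_rgb: tuple[float, float, float]  # rendered coat mean, pre-cast
    redness: float                 # a* scalar driving the germination link


def _image_rng(seed: int, genotype: str, year: int) -> np.random.Generator:
    """Stable per-image stream: master seed + crc32(genotype) + year."""
    return np.random.default_rng(
        [int(seed), zlib.crc32(genotype.encode()), int(year)]
    )


def rank_slope(cfg: StudyConfig) -> float:
    """Per-rank redness slope implied by ``cfg.target_year_r``.

    The target is the population correlation between year rank and
    genotype-centered per-grain redness.  Centering by genotype removes
    1/n_years of the cell-level noise variance (each genotype's mean
    absorbs the average of its n_years cell effects), so the residual
    variance entering the correlation is
    ``(1 - 1/n_years) * s_cell^2 + s_grain^2``.
    """
    n_years = len(cfg.years)
    ranks = np.arange(1, n_years + 1, dtype=float)
    sd_rank = ranks.std()  # population SD, years equally represented
    resid = np.sqrt(
        (1.0 - 1.0 / n_years) * cfg.redness_cell_sd**2 + cfg.redness_grain_sd**2
    )
    r = cfg.target_year_r
    return r / np.sqrt(1.0 - r * r) * resid / sd_rank


def genotype_baselines(cfg: StudyConfig) -> pd.DataFrame:
    """Draw per-genotype size/shape/color baselines from the master seed.

    Baselines scatter around ``n_genotype_clusters`` archetypes (offsets
    on grain length, coat L* and b*), emulating families of seed-size /
    coat-tone types within the mapping population; redness (a*) carries
    no archetype offset.  The true archetype index is recorded in the
    ``cluster`` column for recovery checks.
    """
    rng = np.random.default_rng([int(cfg.seed), 0xBA5E])
    n = cfg.n_genotypes
    k = cfg.n_genotype_clusters
    arch_length = rng.normal(0.0, cfg.cluster_length_sd, k)
    arch_L = rng.normal(0.0, cfg.cluster_L_sd, k)
    arch_b = rng.normal(0.0, cfg.cluster_b_sd, k)
    assign = rng.permuted(np.arange(n) % k)  # balanced membership
    return pd.DataFrame(
        {
            "genotype": cfg.genotype_ids(),
            "cluster": assign + 1,
            "length_mm": np.clip(
                cfg.grain_length_mm + arch_length[assign]
                + rng.normal(0.0, cfg.grain_length_sd, n), 4.0, 9.0
            ),
            "aspect": np.clip(
                rng.normal(cfg.grain_aspect, cfg.grain_aspect_sd, n), 0.3, 0.65
            ),
            "coat_L": cfg.coat_L + arch_L[assign]
            + rng.normal(0.0, cfg.coat_L_sd, n),
            "coat_a": rng.normal(cfg.coat_a, cfg.coat_a_sd, n),
            "coat_b": cfg.coat_b + arch_b[assign]
            + rng.normal(0.0, cfg.coat_b_sd, n),
        }
    ).set_index("genotype")


def _grain_polygon(
    rng: np.random.Generator, a_px: float, b_px: float, amp: float
):
    """Closed boundary of a perturbed ellipse in local coordinates."""
    t = np.linspace(0.0, 2.0 * np.pi, 240, endpoint=False)
    s = np.ones_like(t)
    for k in (2, 3, 4):
        s += amp * rng.uniform(0.3, 1.0) / (k - 1) * np.sin(k * t + rng.uniform(0, 2 * np.pi))
    return a_px * s * np.cos(t), b_px * s * np.sin(t)


def draw_grain_params(
    cfg: StudyConfig,
    geno_row,
    cell_effects: dict,
    n_grains: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-grain scalar ground truth, drawn before any pixel work.

    Drawing the parameter block first (and placement/pixel noise after)
    means the scalar ground-truth table is identical whether or not the
    scene is actually rasterized.
    """
    length_mm = geno_row.length_mm * (
        1 + cfg.grain_jitter * rng.normal(size=n_grains)
    )
    aspect = geno_row.aspect * (
        1 + 0.5 * cfg.grain_jitter * rng.normal(size=n_grains)
    )
    redness = (
        geno_row.coat_a + cell_effects["da"]
        + cfg.redness_grain_sd * rng.normal(size=n_grains)
    )
    coat_b = geno_row.coat_b + 0.5 * rng.normal(size=n_grains)
    a_px = np.maximum(length_mm / 2.0 / cfg.mm_per_px, 4.0)
    b_px = np.maximum(a_px * aspect, 3.0)
    return pd.DataFrame(
        {
            "a_px": a_px, "b_px": b_px,
            "major_mm": 2 * a_px * cfg.mm_per_px,
            "minor_mm": 2 * b_px * cfg.mm_per_px,
            "redness": redness, "coat_b": coat_b,
            "coat_L": np.full(n_grains, geno_row.coat_L + cell_effects["dL"]),
        }
    )


def render_seed_image(
    cfg: StudyConfig,
    layout: ChartLayout,
    genotype: str,
    year: int,
    geno_row,
    cell_effects: dict,
    n_grains: int,
    rng: np.random.Generator,
    cast: np.ndarray | None = None,
) -> tuple[np.ndarray, list[GroundTruthGrain], np.ndarray]:
    """Render one genotype x year scene.

    Returns ``(uint8 image, ground-truth grains, 3x3 cast matrix)``.  Grain
    masks are pairwise disjoint and disjoint from the chart bounding box by
    construction (circumscribed-circle rejection sampling with a margin).
    """
    H, W = cfg.image_height, cfg.image_width
    image_id = f"{genotype}_{year}"

    params = draw_grain_params(cfg, geno_row, cell_effects, n_grains, rng)

    canvas = np.full((H, W, 3), cfg.background_level, dtype=float)
    canvas += rng.normal(0.0, cfg.background_noise_sd, canvas.shape)
    render_chart(canvas, layout)

    # placement by rejection sampling against chart bbox and prior grains
    br0, bc0, br1, bc1 = layout.bbox
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    grains: list[GroundTruthGrain] = []
    gap = 4.0
    for k in range(n_grains):
        p = params.iloc[k]
        a_px, b_px = float(p.a_px), float(p.b_px)
        radius = a_px * (1 + 2 * cfg.boundary_amp) + 1.0
        margin = radius + gap
        ok = False
        for _ in range(4000):
            r = rng.uniform(margin, H - margin)
            c = rng.uniform(margin, W - margin)
            if (br0 - margin) < r < (br1 + margin) and (bc0 - margin) < c < (bc1 + margin):
                continue
            if all(np.hypot(r - pr, c - pc) > radius + prad + gap
                   for pr, pc, prad in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(k, n_grains)
        placed.append((r, c, radius))

        theta = rng.uniform(0, np.pi)
        xs, ys = _grain_polygon(rng, a_px, b_px, cfg.boundary_amp)
        ct, st = np.cos(theta), np.sin(theta)
        rows = r + xs * st + ys * ct
        cols = c + xs * ct - ys * st
        rr, cc = draw_polygon(rows, cols, shape=(H, W))

        # per-pixel coat color in CIELAB with radial shading on L*
        xl = (cc - c) * ct + (rr - r) * st
        yl = -(cc - c) * st + (rr - r) * ct
        d2 = np.clip((xl / a_px) ** 2 + (yl / b_px) ** 2, 0.0, 1.2)
        npx = rr.size
        lab8 = np.empty((npx, 3))
        lab8[:, 0] = (p.coat_L * (1.0 - cfg.shading_depth * d2)
                      + rng.normal(0, cfg.pixel_noise_sd, npx)) * 255.0 / 100.0
        lab8[:, 1] = p.redness + 128.0 + rng.normal(0, 0.5 * cfg.pixel_noise_sd, npx)
        lab8[:, 2] = p.coat_b + 128.0 + rng.normal(0, 0.5 * cfg.pixel_noise_sd, npx)
        rgb = lab8_to_rgb(np.clip(lab8, 0, 255))
        canvas[rr, cc] = rgb

        mask = np.zeros((H, W), dtype=bool)
        mask[rr, cc] = True
        grains.append(
            GroundTruthGrain(
                image_id=image_id,
                grain_id=f"{image_id}_g{k:02d}",
                mask=mask,
                axes_mm=(float(p.major_mm), float(p.minor_mm)),
                mean_rgb=tuple(rgb.mean(axis=0)),
                redness=float(p.redness),
            )
        )

    if cast is None:
        cast = np.diag(rng.uniform(cfg.cast_min, cfg.cast_max, 3))
    cast = np.asarray(cast, dtype=float)
    out = np.clip(canvas @ cast.T, 0.0, 255.0)
    return np.rint(out).astype(np.uint8), grains, cast


@dataclass
class StudyBundle:
    """Outputs of :func:`generate_study`."""

    config: StudyConfig
    layout: ChartLayout
    design: pd.DataFrame        # image_path, image_id, genotype, year
    ground_truth: pd.DataFrame  # per-grain scalar ground truth
    masks: dict[str, list[GroundTruthGrain]]  # image_id -> grains (in-memory)
    outdir: Path | None


def generate_study(
    cfg: StudyConfig,
    outdir: str | Path | None = None,
    write_images: bool = True,
    layout: ChartLayout | None = None,
    render: bool = True,
) -> StudyBundle:
    """Generate the full study: one image per genotype x year.

    With ``outdir`` set, images are written as 8-bit PNG under
    ``outdir/images`` and the design / ground-truth tables as CSV.  The
    bundle always keeps the per-grain masks in memory for recovery tests.

    ``render=False`` skips rasterization entirely: the scalar ground-truth
    columns (axes, redness) are identical to a rendered run with the same
    seed because they are drawn before any pixel work, but masks are absent
    and the rendered-color columns are NaN.
    """
    if layout is None:
        layout = build_chart_layout(
            pitch_px=cfg.chart_pitch_px, pitch_mm=cfg.chart_pitch_mm
        )
    baselines = genotype_baselines(cfg)
    beta = rank_slope(cfg)
    ranks = {y: i + 1 for i, y in enumerate(cfg.years)}
    mean_rank = np.mean(list(ranks.values()))

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)

    design_rows, truth_rows = [], []
    masks: dict[str, list[GroundTruthGrain]] = {}
    for genotype in cfg.genotype_ids():
        geno_row = baselines.loc[genotype]
        for year in cfg.years:
            rng = _image_rng(cfg.seed, genotype, year)
            rc = ranks[year] - mean_rank
            cell_effects = {
                "da": beta * rc + cfg.redness_cell_sd * rng.normal(),
                "dL": cfg.lightness_rank_slope * rc
                + cfg.lightness_cell_sd * rng.normal(),
            }
            n_grains = int(rng.integers(cfg.grains_min, cfg.grains_max + 1))
            image_id = f"{genotype}_{year}"
            path = ""
            if render:
                image, grains, _ = render_seed_image(
                    cfg, layout, genotype, year, geno_row, cell_effects,
                    n_grains, rng,
                )
                if outdir is not None and write_images:
                    path = str(outdir / "images" / f"{image_id}.png")
                    iio.imwrite(path, image)
                masks[image_id] = grains
                for g in grains:
                    truth_rows.append(
                        {
                            "image_id": g.image_id, "grain_id": g.grain_id,
                            "genotype": genotype, "year": year,
                            "major_mm": g.axes_mm[0], "minor_mm": g.axes_mm[1],
                            "mean_R": g.mean_rgb[0], "mean_G": g.mean_rgb[1],
                            "mean_B": g.mean_rgb[2], "redness": g.redness,
                        }
                    )
            else:
                params = draw_grain_params(
                    cfg, geno_row, cell_effects, n_grains, rng
                )
                for k, p in params.iterrows():
                    truth_rows.append(
                        {
                            "image_id": image_id,
                            "grain_id": f"{image_id}_g{k:02d}",
                            "genotype": genotype, "year": year,
                            "major_mm": p.major_mm, "minor_mm": p.minor_mm,
                            "mean_R": np.nan, "mean_G": np.nan,
                            "mean_B": np.nan, "redness": p.redness,
                        }
                    )
            design_rows.append(
                {"image_path": path, "image_id": image_id,
                 "genotype": genotype, "year": year}
            )

    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame(truth_rows)
    if outdir is not None:
        design.to_csv(outdir / "design.csv", index=False)
        truth.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.6f")
        cfg.to_json(outdir / "config.json")
    return StudyBundle(
        config=cfg, layout=layout, design=design, ground_truth=truth,
        masks=masks, outdir=outdir,
    )


def generate_germination(
    design: pd.DataFrame,
    ground_truth: pd.DataFrame,
    link,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Germination table: one row per genotype x year x replicate.

    percent = clip(intercept + year_offset + slope * (cell mean redness
    - reference) + noise, 0, 100).  The cell mean redness is taken from the
    ground-truth table, keeping the link independent of the imaging
    pipeline under test.
    """
    cells = design[["image_id", "genotype", "year"]].drop_duplicates()
    truth_ids = set(ground_truth["image_id"])
    missing = set(cells["image_id"]) - truth_ids
    if missing:
        raise ValueError(f"design/ground-truth mismatch, no grains for {sorted(missing)[:5]}")
    mean_red = ground_truth.groupby("image_id")["redness"].mean()

    rows = []
    for _, cell in cells.iterrows():
        year = int(cell.year)
        offset = link.year_offsets.get(year, 0.0)
        cell_sd = link.cell_sd_by_year.get(year, link.cell_sd)
        mu = (
            link.intercept + offset
            + link.slope * (mean_red[cell.image_id] - link.reference_redness)
            + (cell_sd * rng.normal() if cell_sd > 0 else 0.0)
        )
        for rep in range(1, link.n_replicates + 1):
            rows.append(
                {
                    "genotype": cell.genotype, "year": year, "replicate": rep,
                    "percent": float(np.clip(mu + rng.normal(0, link.noise_sd), 0.0, 100.0)),
                }
            )
    return pd.DataFrame(rows)
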