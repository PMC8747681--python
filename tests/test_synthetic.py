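"""Generator checks: design shape, determinism, mask disjointness, the
forward cast model, the injected storage trend and the germination link."""

import numpy as np
import pandas as pd
import pytest

from grainaging.chart import ChartSpecError, build_chart_layout
from grainaging.config import ConfigError, GerminationLink, StudyConfig
from grainaging.stats import center_by_group, encode_year, pearson_r, year_encoding
from grainaging.synthetic import (
    PlacementError,
    generate_germination,
    generate_study,
    genotype_baselines,
    render_seed_image,
)
from .conftest import TINY_KW


def test_default_design_has_one_image_per_genotype_year():
    cfg = StudyConfig()
    bundle = generate_study(cfg, outdir=None, render=False)
    assert len(bundle.design) == 44 * 4 == 176
    counts = bundle.ground_truth.groupby("image_id").size()
    assert counts.min() >= 17 and counts.max() <= 20


def test_ground_truth_deterministic_across_runs_and_modes(tiny_cfg, tiny_study):
    again = generate_study(tiny_cfg, outdir=None, render=True)
    pd.testing.assert_frame_equal(
        tiny_study.ground_truth.drop(columns="image_id"),
        again.ground_truth.drop(columns="image_id"),
    )
    fast = generate_study(tiny_cfg, outdir=None, render=False)
    cols = ["grain_id", "major_mm", "minor_mm", "redness"]
    pd.testing.assert_frame_equal(
        tiny_study.ground_truth[cols], fast.ground_truth[cols]
    )


def test_masks_pairwise_disjoint_and_clear_of_chart(tiny_study):
    r0, c0, r1, c1 = tiny_study.layout.bbox
    for grains in tiny_study.masks.values():
        total = np.zeros_like(grains[0].mask, dtype=int)
        for g in grains:
            assert g.mask.sum() > 0
            total += g.mask
            assert not g.mask[r0:r1, c0:c1].any()
        assert total.max() == 1  # no overlaps


def test_diagonal_cast_scales_white_patch(tiny_cfg):
    layout = build_chart_layout(pitch_px=tiny_cfg.chart_pitch_px,
                                pitch_mm=tiny_cfg.chart_pitch_mm)
    baselines = genotype_baselines(tiny_cfg)
    row = baselines.iloc[0]
    gains = np.array([0.9, 1.0, 1.1])
    rng = np.random.default_rng(0)
    img, _, _ = render_seed_image(
        tiny_cfg, layout, "G001", 2003, row, {"da": 0.0, "dL": 0.0}, 5, rng,
        cast=np.diag(gains),
    )
    # white patch (index 18) mean should be reference * gains, within
    # rounding and background noise
    from grainaging.imaging import locate_chart

    # locate_chart needs the fiducial dark: gains keep black fiducial black
    measured, _ = locate_chart(img, layout)
    ref = layout.reference_rgb[18].astype(float)
    expect = np.clip(ref * gains, 0, 255)
    assert np.abs(measured[18] - expect).max() <= 1.0


def test_fixed_rng_gives_identical_pixels(tiny_cfg):
    layout = build_chart_layout(pitch_px=tiny_cfg.chart_pitch_px,
                                pitch_mm=tiny_cfg.chart_pitch_mm)
    row = genotype_baselines(tiny_cfg).iloc[0]
    imgs = []
    for _ in range(2):
        rng = np.random.default_rng(99)
        img, _, _ = render_seed_image(
            tiny_cfg, layout, "G001", 2003, row, {"da": 0.0, "dL": 0.0}, 5, rng
        )
        imgs.append(img)
    assert np.array_equal(imgs[0], imgs[1])


def test_placement_failure_reports_achieved_count():
    cfg = StudyConfig(n_genotypes=1, grains_min=40, grains_max=40,
                      image_height=300, image_width=300, seed=0)
    layout = build_chart_layout(pitch_px=cfg.chart_pitch_px,
                                pitch_mm=cfg.chart_pitch_mm)
    row = genotype_baselines(cfg).iloc[0]
    with pytest.raises(PlacementError) as exc:
        render_seed_image(cfg, layout, "G001", 2003, row,
                          {"da": 0.0, "dL": 0.0}, 40,
                          np.random.default_rng(0))
    assert 0 <= exc.value.placed < 40


def test_injected_year_trend_matches_target():
    """Brute-force check on the emitted ground-truth table at default n:
    the genotype-centered redness vs year-rank correlation sits within
    ±0.05 of the configured target."""
    cfg = StudyConfig(seed=0)
    bundle = generate_study(cfg, outdir=None, render=False)
    gt = bundle.ground_truth
    centered = center_by_group(gt["redness"], gt["genotype"])
    x = encode_year(gt["year"], year_encoding("YearRank", cfg.years))
    r = pearson_r(x, centered)
    assert r == pytest.approx(cfg.target_year_r, abs=0.05)


class TestGermination:
    def _study(self, **link_kw):
        cfg = StudyConfig(
            **{**TINY_KW, "n_genotypes": 25,
               "germination": GerminationLink(cell_sd_by_year={}, **link_kw)},
        )
        bundle = generate_study(cfg, outdir=None, render=False)
        germ = generate_germination(bundle.design, bundle.ground_truth,
                                    cfg.germination, np.random.default_rng(3))
        red = bundle.ground_truth.groupby("image_id")["redness"].mean()
        merged = germ.merge(
            bundle.design[["image_id", "genotype", "year"]],
            on=["genotype", "year"],
        )
        return merged["percent"].to_numpy(), red[merged["image_id"]].to_numpy()

    def test_zero_slope_gives_null_correlation(self):
        pct, red = self._study(slope=0.0, year_offsets={})
        assert len(pct) >= 300
        assert abs(pearson_r(red, pct)) < 0.1

    def test_negative_slope_gives_negative_correlation(self):
        pct, red = self._study(slope=-3.0, year_offsets={})
        assert pearson_r(red, pct) < -0.3

    def test_outputs_clipped_to_percent_range(self):
        pct, _ = self._study(intercept=99.0, noise_sd=30.0)
        assert pct.min() >= 0.0 and pct.max() <= 100.0

    def test_design_mismatch_rejected(self, tiny_study):
        bad_truth = tiny_study.ground_truth[
            tiny_study.ground_truth.image_id != tiny_study.design.image_id.iloc[0]
        ]
        with pytest.raises(ValueError, match="mismatch"):
            generate_germination(tiny_study.design, bad_truth,
                                 GerminationLink(), np.random.default_rng(0))


class TestChartLayout:
    def test_24_patches_row_major(self):
        layout = build_chart_layout()
        assert len(layout.centers) == 24
        # row-major: first row shares the row coordinate, columns increase
        assert np.allclose(layout.centers[:6, 0], layout.centers[0, 0])
        assert np.all(np.diff(layout.centers[:6, 1]) > 0)

    def test_four_patch_chart_allowed(self):
        layout = build_chart_layout(
            patch_rgb=[(0, 0, 0), (255, 0, 0), (0, 255, 0), (255, 255, 255)],
            n_rows=2, n_cols=2,
        )
        assert len(layout.centers) == 4

    def test_three_patches_rejected(self):
        with pytest.raises(ChartSpecError):
            build_chart_layout(
                patch_rgb=[(0, 0, 0), (255, 0, 0), (0, 255, 0)],
                n_rows=2, n_cols=2,
            )

    def test_scale_from_pitch(self):
        layout = build_chart_layout(pitch_px=40, pitch_mm=4.0)
        assert layout.mm_per_px == pytest.approx(0.1)


class TestConfigValidation:
    def test_years_must_increase(self):
        with pytest.raises(ConfigError, match="years"):
            StudyConfig(years=(2004, 2003))

    def test_grain_range(self):
        with pytest.raises(ConfigError, match="grains"):
            StudyConfig(grains_min=5, grains_max=4)

    def test_negative_sd(self):
        with pytest.raises(ConfigError, match="sd"):
            StudyConfig(coat_a_sd=-1)

    def test_unknown_key_listed(self):
        with pytest.raises(ConfigError, match="not_a_key"):
            StudyConfig.from_dict({"not_a_key": 1})
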