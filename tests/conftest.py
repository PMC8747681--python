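"""Shared fixtures: a tiny rendered study for imaging tests and a
demo-scale study (16 genotypes x 4 years) for end-to-end recovery tests.

Both are session-scoped; the demo study is only built when a test asks
for it (it renders, extracts and analyzes ~1200 grains).
"""

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from grainaging.config import StudyConfig
from grainaging.pipeline import extract_image
from grainaging.stats import germination_analysis, year_trend_analysis
from grainaging.synthetic import generate_germination, generate_study
from grainaging.traits import compute_trait_table

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


TINY_KW = dict(
    n_genotypes=3, grains_min=5, grains_max=6,
    image_height=500, image_width=700, seed=2,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> StudyConfig:
    return StudyConfig(**TINY_KW)


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg, tmp_path_factory):
    """3 genotypes x 4 years, 5-6 grains per image, written to disk."""
    out = tmp_path_factory.mktemp("tiny_study")
    bundle = generate_study(tiny_cfg, outdir=out)
    return bundle


@pytest.fixture(scope="session")
def tiny_extraction(tiny_study):
    """Full imaging chain over the tiny study, images read back from PNG."""
    items = []
    for _, row in tiny_study.design.iterrows():
        image = iio.imread(row.image_path)
        items.append(
            extract_image(image, tiny_study.layout, row.image_id,
                          row.genotype, row.year)
        )
    return items


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """Demo-scale study with the default storage-trend and germination
    link: simulate, extract, compute traits, run trend + germination
    analyses.  16 genotypes keep the run a few minutes while the ~1200
    seeds give the trend estimate a small enough sampling error."""
    cfg = StudyConfig(n_genotypes=16, seed=0)
    out = tmp_path_factory.mktemp("demo_study")
    bundle = generate_study(cfg, outdir=out)
    items = []
    for _, row in bundle.design.iterrows():
        image = iio.imread(row.image_path)
        items.append(
            extract_image(image, bundle.layout, row.image_id,
                          row.genotype, row.year)
        )
    table = compute_trait_table(items)
    germ = generate_germination(
        bundle.design, bundle.ground_truth, cfg.germination,
        np.random.default_rng([cfg.seed, 0x6E12]),
    )
    rng = np.random.default_rng([cfg.seed, 0x5747])
    trend = year_trend_analysis(table, n_rep=2000, rng=rng)
    germ_res = germination_analysis(germ, table, n_rep=2000, rng=rng)
    return {
        "cfg": cfg, "bundle": bundle, "items": items, "table": table,
        "germination": germ, "trend": trend, "germ_res": germ_res,
    }
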