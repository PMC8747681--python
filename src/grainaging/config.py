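"""Study configuration for the synthetic seed-aging experiment.

The defaults emulate the study design the pipeline is built for: 44 wheat
recombinant inbred lines (RILs) imaged once per harvest season
(2003, 2004, 2009, 2014), 17–20 non-touching grains per image on a white
background with a color-reference chart, a monotone storage trend on coat
redness (the a*-like CIELAB component) and lightness, and germination
percentages linearly coupled to coat redness with a strong year-level
offset (2009 depressed and noisy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


class ConfigError(ValueError):
    """Invalid study configuration; message lists the offending keys."""


@dataclass
class GerminationLink:
    """Linear coupling from mean cell redness to germination percent.

    percent = intercept + year_offset[year] + cell_effect
              + slope * (mean cell redness - reference_redness) + noise,
    clipped to [0, 100].  The default year offsets reproduce year means of
    roughly 92 / 98.6 / 64.9 / 88.2 percent.  ``cell_sd_by_year`` adds a
    genotype x year level disturbance; the large 2009 default makes that
    season erratic across genotypes, so some cells land beyond the
    [-15, 15] outlier band and exercise the exclusion rule.
    """

    intercept: float = 90.0
    slope: float = -1.5          # percent per a*-unit of redness
    reference_redness: float = 9.0
    year_offsets: dict[int, float] = field(
        default_factory=lambda: {2003: 2.0, 2004: 8.6, 2009: -25.1, 2014: -1.8}
    )
    noise_sd: float = 3.0        # replicate-level noise
    cell_sd: float = 0.0         # genotype x year cell-level noise
    cell_sd_by_year: dict[int, float] = field(default_factory=lambda: {2009: 10.0})
    n_replicates: int = 4


@dataclass
class StudyConfig:
    """Parameters of the synthetic study; all fields overridable via JSON."""

    n_genotypes: int = 44
    years: tuple[int, ...] = (2003, 2004, 2009, 2014)
    grains_min: int = 17
    grains_max: int = 20
    image_height: int = 850
    image_width: int = 1100
    seed: int = 0

    # chart geometry: mm_per_px = chart_pitch_mm / chart_pitch_px
    chart_pitch_px: int = 40
    chart_pitch_mm: float = 4.0

    # genotype baselines (population mean, between-genotype SD)
    grain_length_mm: float = 6.5
    grain_length_sd: float = 0.3      # within-archetype SD
    grain_aspect: float = 0.45        # width / length
    grain_aspect_sd: float = 0.04
    grain_jitter: float = 0.05        # within-image relative size jitter
    boundary_amp: float = 0.03        # sinusoidal boundary perturbation
    shading_depth: float = 0.12       # radial lightness falloff at grain edge

    coat_L: float = 55.0              # CIELAB L* baseline
    coat_L_sd: float = 2.0            # within-archetype SD
    coat_a: float = 9.0               # a* baseline ("redness")
    coat_a_sd: float = 1.5
    coat_b: float = 22.0
    coat_b_sd: float = 1.5            # within-archetype SD

    # genotype population structure: baselines scatter around a few
    # archetypes (distinct seed-size/coat-tone families) with roughly
    # twice the within-archetype spread, so genotype clustering has
    # recoverable but overlapping groups.  Offsets act on length, L* and
    # b* only; redness is kept archetype-free so the storage-trend target
    # is unaffected.
    n_genotype_clusters: int = 3
    cluster_length_sd: float = 0.6    # between-archetype SD, mm
    cluster_L_sd: float = 4.0
    cluster_b_sd: float = 3.0

    # storage (year-rank) trend.  target_year_r is the population Pearson
    # correlation between year rank and genotype-centered grain redness;
    # the per-rank slope is derived from it in closed form.
    target_year_r: float = -0.6
    redness_cell_sd: float = 0.8      # genotype x year residual on a*
    redness_grain_sd: float = 1.2     # per-grain residual on a*
    # weak lightening with storage: much smaller than the redness trend,
    # so the a*-like descriptors stay the dominant storage correlates
    lightness_rank_slope: float = -0.15  # L* per year rank (earlier = lighter)
    lightness_cell_sd: float = 0.6

    pixel_noise_sd: float = 1.2       # per-pixel Lab noise inside grains
    background_level: float = 250.0
    background_noise_sd: float = 1.5

    # per-image diagonal color cast sampled uniformly from this range
    cast_min: float = 0.94
    cast_max: float = 1.06

    germination: GerminationLink = field(default_factory=GerminationLink)

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        problems = []
        if self.n_genotypes < 1:
            problems.append("n_genotypes must be >= 1")
        if len(self.years) < 2 or any(
            b <= a for a, b in zip(self.years, self.years[1:])
        ):
            problems.append("years must be strictly increasing with >= 2 entries")
        if self.grains_min < 1 or self.grains_max < self.grains_min:
            problems.append("grains_per_image range invalid (need max >= min >= 1)")
        if self.chart_pitch_mm <= 0 or self.chart_pitch_px <= 0:
            problems.append("chart pitch must be positive")
        if self.n_genotype_clusters < 1:
            problems.append("n_genotype_clusters must be >= 1")
        for name in (
            "grain_length_sd", "grain_aspect_sd", "coat_L_sd", "coat_a_sd",
            "coat_b_sd", "redness_cell_sd", "redness_grain_sd",
            "lightness_cell_sd", "pixel_noise_sd", "background_noise_sd",
            "cluster_length_sd", "cluster_L_sd", "cluster_b_sd",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not -1.0 < self.target_year_r < 1.0:
            problems.append("target_year_r must lie in (-1, 1)")
        if min(self.image_height, self.image_width) < 64:
            problems.append("image size must be >= 64 px per side")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def mm_per_px(self) -> float:
        return self.chart_pitch_mm / self.chart_pitch_px

    def genotype_ids(self) -> list[str]:
        return [f"G{i + 1:03d}" for i in range(self.n_genotypes)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        germ = d.pop("germination", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = {k: v for k, v in d.items()}
        if germ is not None:
            if not isinstance(germ, dict):
                raise ConfigError("germination must be a mapping")
            germ = dict(germ)
            for key in ("year_offsets", "cell_sd_by_year"):
                if key in germ:
                    germ[key] = {int(y): float(v) for y, v in germ[key].items()}
            unknown = set(germ) - set(GerminationLink.__dataclass_fields__)
            if unknown:
                raise ConfigError(f"unknown germination keys: {sorted(unknown)}")
            cfg["germination"] = GerminationLink(**germ)
        return cls(**cfg)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        if not isinstance(payload, dict):
            raise ConfigError("config root must be a JSON object")
        if "years" in payload:
            payload["years"] = tuple(payload["years"])
        return cls.from_dict(payload)
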