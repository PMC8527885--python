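"""Synthetic data generation for every stage of the biofilm pipeline.

Four generators, each with ground truth, so that detection, quantification,
cohort statistics and assay scoring are all testable without any real data:

* confocal-like sections — BF+ sections carry roughly 10-fold more bacteria
  than BF− sections, concentrated in a band adjacent to the epithelium,
  while BF− bacteria sit beyond an intact-mucus standoff;
* surface-layer height profiles (thicker maxima in BF+ sections);
* multicenter screening cohorts with per-cohort, per-center biofilm
  prevalences and *R. gnavus* bloom indicators;
* crystal-violet microtiter plates with planted biofilm-former strains.

Randomness contract: every generator takes one root seed and splits it into
named substreams via :class:`numpy.random.SeedSequence`. Identical (config,
seed) gives identical output within this implementation; only
distributional equivalence is promised across implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .detect import ConfocalSection, EpitheliumTrace

__all__ = [
    "SectionSimConfig",
    "GroundTruth",
    "CohortSimConfig",
    "ConfigError",
    "TABLE2_ENROLMENT",
    "LOCATION_RATES",
    "COHORTS",
    "CENTERS",
    "gen_section",
    "gen_layer_profile",
    "gen_cohort",
    "gen_assay_plate",
    "write_ground_truth",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# --------------------------------------------------------------- sections


@dataclass(frozen=True)
class SectionSimConfig:
    """Parameters of the confocal-section simulator.

    The imaging geometry is a horizontal strip of ``n_fields`` contiguous
    square fields of ``field_size_um`` per side, with the epithelium
    running as a gently undulating polyline along the lower edge. Defaults
    give one field = 1024 px and a 10-fold BF+/BF− bacterial contrast.
    """

    field_size_um: float = 144.72
    pixel_size_um: float = 0.14133
    n_fields: int = 1
    bf_status: str = "BF+"
    mean_count_bfneg: float = 12.0
    fold_change: float = 10.0
    adherent_band_um: float = 15.0
    mucus_gap_um: float = 30.0
    psf_sigma_um: float = 0.5
    background_level: float = 100.0
    peak_intensity: float = 20000.0
    noise: str = "poisson"
    seed: int = 0
    adherent_fraction: float = 0.8
    epithelium_margin_um: float = 20.0
    epithelium_amplitude_um: float = 5.0
    epithelium_wavelength_um: float = 180.0
    layer_base_um: float = 0.0
    layer_amp_um: float | None = None  # None: 50 um for BF+, 15 um for BF−

    def __post_init__(self) -> None:
        for name in ("field_size_um", "pixel_size_um", "adherent_band_um",
                     "mucus_gap_um", "psf_sigma_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_fields < 1:
            raise ConfigError("n_fields must be >= 1")
        if self.fold_change < 1:
            raise ConfigError("fold_change must be >= 1")
        if self.mean_count_bfneg < 0:
            raise ConfigError("mean_count_bfneg must be nonnegative")
        if self.bf_status not in ("BF+", "BF-"):
            raise ConfigError("bf_status must be 'BF+' or 'BF-'")
        if self.noise not in ("none", "poisson"):
            raise ConfigError("noise must be 'none' or 'poisson'")
        if not 0.0 <= self.adherent_fraction <= 1.0:
            raise ConfigError("adherent_fraction must be in [0, 1]")
        ratio = self.field_size_um / self.pixel_size_um
        if abs(ratio - round(ratio)) > 0.05:
            raise ConfigError(
                f"field_size_um / pixel_size_um = {ratio:.3f} is more than "
                "0.05 px from an integer; pick a pixel size that tiles the "
                "field"
            )

    @property
    def field_px(self) -> int:
        return int(round(self.field_size_um / self.pixel_size_um))

    @property
    def width_px(self) -> int:
        return self.field_px * self.n_fields

    @property
    def height_px(self) -> int:
        return self.field_px

    @property
    def mean_count(self) -> float:
        """Expected bacteria per field for the configured biofilm status."""
        if self.bf_status == "BF+":
            return self.mean_count_bfneg * self.fold_change
        return self.mean_count_bfneg


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth accompanying one simulated section."""

    centroids: np.ndarray  # (n, 2) x_um, y_um
    epithelium: EpitheliumTrace
    layer_profile: np.ndarray  # (width_px,) height in um per column
    bf_status: str


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _gen_epithelium(cfg: SectionSimConfig,
                    rng: np.random.Generator) -> EpitheliumTrace:
    """Smooth sinusoidal polyline spanning the width near the lower edge."""
    width_um = cfg.n_fields * cfg.field_size_um
    n_pts = max(2, int(width_um / 2.0) + 1)
    x = np.linspace(0.0, width_um, n_pts)
    phase = rng.uniform(0, 2 * np.pi)
    y0 = cfg.field_size_um - cfg.epithelium_margin_um
    y = y0 + cfg.epithelium_amplitude_um * np.sin(
        2 * np.pi * x / cfg.epithelium_wavelength_um + phase)
    return EpitheliumTrace(np.column_stack([x, y]))


def _epithelium_y_at(trace: EpitheliumTrace, x: np.ndarray) -> np.ndarray:
    v = trace.vertices
    return np.interp(x, v[:, 0], v[:, 1])


def _place_bacteria(cfg: SectionSimConfig, trace: EpitheliumTrace,
                    counts: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample centroid coordinates per field, honouring the BF geometry.

    BF+: a fixed ``ceil(adherent_fraction * n)`` of each field's bacteria
    are placed within ``adherent_band_um`` (vertical offset, which bounds
    the Euclidean distance to the polyline from above); the rest anywhere
    above the epithelium. BF−: all bacteria at least ``mucus_gap_um`` from
    the epithelium (verified against the exact polyline distance).
    """
    line = shapely.LineString(trace.vertices)
    pts: list[np.ndarray] = []
    for i, n in enumerate(counts):
        if n == 0:
            continue
        x0 = i * cfg.field_size_um
        x = rng.uniform(x0, x0 + cfg.field_size_um, size=n)
        y_epi = _epithelium_y_at(trace, x)
        if cfg.bf_status == "BF+":
            n_adh = math.ceil(cfg.adherent_fraction * n)
            y = np.empty(n)
            d = rng.uniform(0.0, cfg.adherent_band_um, size=n_adh)
            y[:n_adh] = np.maximum(y_epi[:n_adh] - d, 0.0)
            y[n_adh:] = rng.uniform(0.0, y_epi[n_adh:])
        else:
            hi = y_epi - cfg.mucus_gap_um
            if np.any(hi <= 0):
                raise ConfigError(
                    "mucus_gap_um leaves no room above the epithelium")
            y = rng.uniform(0.0, hi)
            # undulation can bring the polyline closer than the vertical
            # offset suggests; resample the few offenders exactly
            for _ in range(100):
                dist = shapely.distance(
                    shapely.points(np.column_stack([x, y])), line)
                bad = dist < cfg.mucus_gap_um
                if not bad.any():
                    break
                y[bad] = rng.uniform(0.0, hi[bad])
        pts.append(np.column_stack([x, y]))
    if not pts:
        return np.empty((0, 2))
    return np.vstack(pts)


def _render(cfg: SectionSimConfig, centroids: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Render Gaussian spots on a constant background, optional shot noise."""
    h, w = cfg.height_px, cfg.width_px
    img = np.full((h, w), float(cfg.background_level))
    px = cfg.pixel_size_um
    sigma_px = cfg.psf_sigma_um / px
    halo = int(math.ceil(4 * sigma_px))
    for x_um, y_um in centroids:
        cx, cy = x_um / px - 0.5, y_um / px - 0.5
        c0, c1 = int(math.floor(cx)) - halo, int(math.floor(cx)) + halo + 1
        r0, r1 = int(math.floor(cy)) - halo, int(math.floor(cy)) + halo + 1
        c0, r0 = max(c0, 0), max(r0, 0)
        c1, r1 = min(c1, w), min(r1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        g = np.exp(-((rows[:, None] - cy) ** 2 + (cols[None, :] - cx) ** 2)
                   / (2 * sigma_px ** 2))
        img[r0:r1, c0:c1] += cfg.peak_intensity * g
    if cfg.noise == "poisson":
        img = rng.poisson(img).astype(float)
    return np.clip(img, 0, 65535)


def gen_section(cfg: SectionSimConfig) -> tuple[ConfocalSection, GroundTruth]:
    """Simulate one confocal section and its ground truth.

    Per-field bacterial counts are Poisson with mean ``mean_count_bfneg``
    (BF−) or ``mean_count_bfneg * fold_change`` (BF+). Each bacterium is
    rendered as a Gaussian spot of ``psf_sigma_um``.
    """
    rng_epi, rng_counts, rng_place, rng_noise, rng_prof = _streams(cfg.seed, 5)
    trace = _gen_epithelium(cfg, rng_epi)
    counts = rng_counts.poisson(cfg.mean_count, size=cfg.n_fields)
    centroids = _place_bacteria(cfg, trace, counts, rng_place)
    img = _render(cfg, centroids, rng_noise)
    profile = _layer_profile(cfg, rng_prof)
    section = ConfocalSection(img, cfg.pixel_size_um)
    truth = GroundTruth(centroids, trace, profile, cfg.bf_status)
    return section, truth


def _layer_profile(cfg: SectionSimConfig,
                   rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d

    amp = cfg.layer_amp_um
    if amp is None:
        amp = 50.0 if cfg.bf_status == "BF+" else 15.0
    w = cfg.width_px
    if amp == 0.0:
        return np.full(w, float(cfg.layer_base_um))
    noise = rng.standard_normal(w)
    smooth = gaussian_filter1d(noise, sigma=20.0 / cfg.pixel_size_um,
                               mode="wrap")
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:
        return np.full(w, float(cfg.layer_base_um))
    return cfg.layer_base_um + amp * (smooth - lo) / (hi - lo)


def gen_layer_profile(cfg: SectionSimConfig) -> np.ndarray:
    """Per-column surface-layer height (um), deterministic per seed.

    The profile is a min-max normalised smoothed Gaussian field scaled by
    ``layer_amp_um`` on top of ``layer_base_um``, so its maximum equals
    base + amplitude exactly; BF+ defaults have larger maxima than BF−.
    """
    rng_prof = _streams(cfg.seed, 5)[4]
    return _layer_profile(cfg, rng_prof)


def write_ground_truth(out_dir: str | Path, truth: GroundTruth,
                       pixel_size_um: float) -> None:
    """Write centroids, epithelium and layer profile as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.centroids, columns=["x_um", "y_um"]).to_csv(
        out / "centroids.csv", index=False)
    truth.epithelium.to_csv(out / "epithelium.csv")
    x = (np.arange(len(truth.layer_profile)) + 0.5) * pixel_size_um
    pd.DataFrame({"x_um": x, "height_um": truth.layer_profile}).to_csv(
        out / "layer_profile.csv", index=False)


# ----------------------------------------------------------------- cohorts

CENTERS = ("Austria", "Germany")

COHORTS = (
    "IBS", "UC", "post-transplant", "Crohn", "other", "adenoma",
    "portal-hypertension", "CRC", "diverticular", "GI-bleeding",
    "healthy-control",
)

#: Observed multicenter screening counts used as simulation defaults:
#: cohort -> center -> (biofilm-positive, total analysed).
TABLE2_ENROLMENT: dict[str, dict[str, tuple[int, int]]] = {
    "IBS": {"Austria": (52, 86), "Germany": (13, 28)},
    "UC": {"Austria": (30, 102), "Germany": (16, 34)},
    "post-transplant": {"Austria": (6, 28), "Germany": (3, 11)},
    "Crohn": {"Austria": (10, 82), "Germany": (20, 52)},
    "other": {"Austria": (7, 49), "Germany": (0, 1)},
    "adenoma": {"Austria": (24, 142), "Germany": (2, 66)},
    "portal-hypertension": {"Austria": (6, 48), "Germany": (2, 19)},
    "CRC": {"Austria": (4, 26), "Germany": (0, 13)},
    "diverticular": {"Austria": (3, 29), "Germany": (1, 63)},
    "GI-bleeding": {"Austria": (2, 52), "Germany": (1, 26)},
    "healthy-control": {"Austria": (8, 112), "Germany": (2, 43)},
}

#: Fraction of biofilm-positive patients with a biofilm in each segment.
LOCATION_RATES: dict[str, float] = {
    "cecum": 0.72, "terminal ileum": 0.71, "ascending": 0.45,
    "transverse": 0.18, "descending": 0.11, "sigmoid": 0.08, "rectum": 0.06,
}


def _default_enrolment() -> dict[str, dict[str, int]]:
    return {c: {ctr: n for ctr, (_, n) in d.items()}
            for c, d in TABLE2_ENROLMENT.items()}


def _default_prevalence() -> dict[str, dict[str, float]]:
    return {c: {ctr: (pos / n if n else 0.0)
                for ctr, (pos, n) in d.items()}
            for c, d in TABLE2_ENROLMENT.items()}


@dataclass(frozen=True)
class CohortSimConfig:
    """Multicenter cohort simulator settings.

    ``enrolment`` counts are the analysable records per (cohort, center) —
    those that survive the bowel-prep exclusions. Extra records destined
    for exclusion are appended on top at the per-rule failure fractions, so
    the screening pipeline has something to filter.
    """

    enrolment: dict[str, dict[str, int]] = field(
        default_factory=_default_enrolment)
    prevalence: dict[str, dict[str, float]] = field(
        default_factory=_default_prevalence)
    bloom_rate_bfpos: float = 0.51
    bloom_rate_bfneg: float = 0.18
    micro_rate_bfpos: float = 0.89
    micro_rate_bfneg: float = 0.40
    frac_low_bbps: float = 0.1
    frac_nonpeg: float = 0.1
    frac_no_cecum: float = 0.1
    location_rates: dict[str, float] = field(
        default_factory=lambda: dict(LOCATION_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        for cohort in self.enrolment:
            if cohort not in COHORTS:
                raise ConfigError(f"unknown cohort name: {cohort!r}")
        for cohort in self.prevalence:
            if cohort not in COHORTS:
                raise ConfigError(f"unknown cohort name: {cohort!r}")
        for d in self.enrolment.values():
            for n in d.values():
                if n < 0:
                    raise ConfigError("enrolment counts must be >= 0")
        rates = [p for d in self.prevalence.values() for p in d.values()]
        rates += [self.bloom_rate_bfpos, self.bloom_rate_bfneg,
                  self.micro_rate_bfpos, self.micro_rate_bfneg,
                  self.frac_low_bbps, self.frac_nonpeg, self.frac_no_cecum]
        rates += list(self.location_rates.values())
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigError("all prevalences and rates must be in [0, 1]")


def _sample_locations(rng: np.random.Generator,
                      rates: dict[str, float]) -> str:
    segs = list(rates)
    p = np.array([rates[s] for s in segs])
    for _ in range(1000):
        hit = rng.random(len(segs)) < p
        if hit.any():
            return ";".join(s for s, h in zip(segs, hit) if h)
    return segs[int(np.argmax(p))]


def gen_cohort(cfg: CohortSimConfig = CohortSimConfig()) -> pd.DataFrame:
    """Simulate one multicenter screening cohort as a patient table.

    Columns: patient_id, center, cohort, bbps, prep_type, cecum_reached,
    biofilm_status, biofilm_locations (';'-separated, empty for BF−),
    microscopic_biofilm, bloom. Reproducible per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    p_pass = ((1 - cfg.frac_low_bbps) * (1 - cfg.frac_nonpeg)
              * (1 - cfg.frac_no_cecum))
    rows: list[dict] = []
    pid = 0
    for cohort, centers in cfg.enrolment.items():
        for center, n_keep in centers.items():
            prev = cfg.prevalence.get(cohort, {}).get(center, 0.0)
            n_total = int(round(n_keep / p_pass)) if p_pass > 0 else n_keep
            for k in range(n_total):
                excluded = k >= n_keep
                if excluded:
                    while True:
                        f_bbps = rng.random() < cfg.frac_low_bbps
                        f_peg = rng.random() < cfg.frac_nonpeg
                        f_cec = rng.random() < cfg.frac_no_cecum
                        if f_bbps or f_peg or f_cec:
                            break
                else:
                    f_bbps = f_peg = f_cec = False
                bbps = int(rng.integers(0, 6) if f_bbps
                           else rng.integers(6, 10))
                bf_pos = rng.random() < prev
                status = "BF+" if bf_pos else "BF-"
                locations = (_sample_locations(rng, cfg.location_rates)
                             if bf_pos else "")
                micro = rng.random() < (cfg.micro_rate_bfpos if bf_pos
                                        else cfg.micro_rate_bfneg)
                bloom = rng.random() < (cfg.bloom_rate_bfpos if bf_pos
                                        else cfg.bloom_rate_bfneg)
                pid += 1
                rows.append({
                    "patient_id": f"P{pid:05d}",
                    "center": center,
                    "cohort": cohort,
                    "bbps": bbps,
                    "prep_type": "non-PEG" if f_peg else "PEG",
                    "cecum_reached": not f_cec,
                    "biofilm_status": status,
                    "biofilm_locations": locations,
                    "microscopic_biofilm": bool(micro),
                    "bloom": bool(bloom),
                })
    return pd.DataFrame(rows)


# ------------------------------------------------------------ assay plates


def gen_assay_plate(n_strains: int = 15, n_replicates: int = 8,
                    former_fraction: float = 0.4, seed: int = 0,
                    former_mean_ratio: float = 10.0,
                    nonformer_mean_ratio: float = 1.5,
                    strain_cv: float = 0.15,
                    well_cv: float = 0.15) -> pd.DataFrame:
    """Simulate a crystal-violet microtiter plate.

    Biofilm-former strains have a lognormal mean OD595/OD600 ratio around
    ``former_mean_ratio`` (> 5), non-formers around ``nonformer_mean_ratio``
    (< 5). Returns one row per well: strain_id, replicate, od595, od600,
    and the planted label ``is_former_true``.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if not 0.0 <= former_fraction <= 1.0:
        raise ConfigError("former_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_formers = int(round(former_fraction * n_strains))
    labels = np.zeros(n_strains, dtype=bool)
    labels[:n_formers] = True
    rng.shuffle(labels)
    rows = []
    for i in range(n_strains):
        mean = former_mean_ratio if labels[i] else nonformer_mean_ratio
        strain_ratio = mean * rng.lognormal(0.0, strain_cv)
        for rep in range(1, n_replicates + 1):
            od600 = float(np.clip(rng.normal(0.5, 0.05), 0.05, None))
            ratio = strain_ratio * rng.lognormal(0.0, well_cv)
            rows.append({
                "strain_id": f"S{i + 1:02d}",
                "replicate": rep,
                "od595": ratio * od600,
                "od600": od600,
                "is_former_true": bool(labels[i]),
            })
    return pd.DataFrame(rows)
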