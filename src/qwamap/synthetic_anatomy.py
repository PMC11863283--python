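"""Synthetic wood-anatomy generator and acquisition-method observation model.

Real quantitative-wood-anatomy comparisons hinge on samples that cannot be
shipped with a software package, so this module generates cell maps with the
statistical structure of the two broad-leaved anatomies:

* **diffuse-porous** — vessels of similar size spread through the ring, with
  a right-skewed (log-normal) lumen-area distribution and a multiplicative
  decline of expected vessel size from earlywood to latewood;
* **ring-porous** — a bimodal mixture of very large earlywood vessels
  confined to the first fraction of the ring and small latewood vessels in
  the remainder.

Fibre lumina (small, bounded above by the vessel threshold) are laid out on
a jittered quasi-regular grid, mimicking the near-crystalline packing of
fibre tissue, and thinned where they would overlap a vessel lumen.  The
grid spacing is chosen so fibre lumina occupy a target fraction of the
non-vessel area; the per-sector fibre lumen sum is thereby known ground
truth for the density-correction tests.

Acquisition methods are simulated by an observation model applied to the
ground truth: a size-dependent miss probability, multiplicative measurement
noise, pixel quantisation and a hard detection limit — the chain that makes
lower-resolution methods (micro-CT, surface pictures) blind to most fibres
while leaving large vessels essentially untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .core_data import RunConfig, SampleTable, compute_rad_dist, make_ring_table
from .errors import ConfigError, GenerationError
from .ring_metrics import compute_ring_metrics

_MAX_PLACEMENT_TRIES = 120


@dataclass(frozen=True)
class AnatomyModel:
    """Statistical description of one synthetic wood anatomy.

    Lumen-area distributions are log-normal (parameters on the natural-log
    scale of μm²).  For ring-porous anatomy the vessel population is a
    two-component mixture: the earlywood component (weight ``ew_weight``)
    is confined to the first ``ew_fraction`` of each ring, the latewood
    component fills the remainder.  ``radial_size_trend`` is the factor by
    which the expected vessel area at the bark-side end of a ring is
    multiplied relative to the ring start (1.0 = no trend); it applies to
    diffuse-porous anatomy.
    """

    porosity: str = "diffuse"  # "diffuse" | "ring_porous"
    n_rings: int = 12
    start_year: int = 2000
    ring_width_mean: float = 1800.0  # μm
    ring_width_sd: float = 300.0
    vessel_log_mean: float = np.log(1600.0)
    vessel_log_sd: float = 0.6
    ew_log_mean: float = np.log(30000.0)
    ew_log_sd: float = 0.35
    lw_log_mean: float = np.log(1500.0)
    lw_log_sd: float = 0.5
    ew_weight: float = 0.12
    ew_fraction: float = 0.25
    vessel_density_target: float = 120.0  # mm⁻²
    radial_size_trend: float = 0.45
    fibre_log_mean: float = np.log(130.0)
    fibre_log_sd: float = 0.35
    fibre_fill_fraction: float = 0.25
    vessel_eccentricity_range: tuple[float, float] = (0.75, 1.0)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.porosity not in ("diffuse", "ring_porous"):
            raise ConfigError(f"unknown porosity {self.porosity!r}")
        if self.porosity == "ring_porous" and self.ew_log_mean <= self.lw_log_mean:
            raise ConfigError("earlywood component mean must exceed latewood mean")
        if not (0 < self.ew_fraction < 1):
            raise ConfigError("ew_fraction must lie in (0, 1)")
        if not (0 <= self.ew_weight <= 1):
            raise ConfigError("ew_weight must lie in [0, 1]")
        if not (0 <= self.fibre_fill_fraction < 1):
            raise ConfigError("fibre_fill_fraction must lie in [0, 1)")
        for name in ("n_rings", "ring_width_mean", "vessel_density_target"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"AnatomyModel.{name} must be strictly positive")

    def replace(self, **kwargs) -> "AnatomyModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MethodObservation:
    """How one acquisition method observes the ground truth.

    The miss probability of a cell with true lumen area A is
    ``miss_max · exp(−A / miss_decay_area)`` — non-increasing in area, so
    small fibres are lost preferentially.  ``area_noise_cv`` is the
    coefficient of variation of mean-one multiplicative log-normal
    measurement noise; ``area_gain`` is a systematic multiplicative bias.
    Observed areas are floored to a multiple of ``pixel_area`` (0 disables
    quantisation) and cells below ``min_detectable_area`` are dropped.
    """

    method_label: str
    min_detectable_area: float = 0.0  # μm²
    miss_max: float = 0.0
    miss_decay_area: float = 300.0  # μm²
    area_noise_cv: float = 0.0
    pixel_area: float = 0.0  # μm² per pixel; 0 = no quantisation
    area_gain: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_max <= 1.0):
            raise ConfigError("miss_max must lie in [0, 1]")
        if self.min_detectable_area < self.pixel_area:
            raise ConfigError("min_detectable_area must be >= pixel_area")
        if self.area_gain <= 0 or self.miss_decay_area <= 0:
            raise ConfigError("area_gain and miss_decay_area must be strictly positive")

    def miss_prob(self, areas: np.ndarray) -> np.ndarray:
        areas = np.asarray(areas, dtype=float)
        return self.miss_max * np.exp(-areas / self.miss_decay_area)

    def replace(self, **kwargs) -> "MethodObservation":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground-truth sample plus the true per-ring parameter values.

    ``true_metrics`` is computed from the truth table by the ring-metrics
    module itself (classification + cut-off from ``config``), so identity
    observation must reproduce it with zero discrepancy.
    """

    table: SampleTable
    true_metrics: pd.DataFrame
    model: AnatomyModel
    config: RunConfig


def _draw_ring_widths(model: AnatomyModel, rng: np.random.Generator) -> np.ndarray:
    widths = rng.normal(model.ring_width_mean, model.ring_width_sd, model.n_rings)
    floor = max(4.0 * 120.0, model.ring_width_mean / 4.0)  # keep a few sectors per ring
    for _ in range(100):
        bad = widths < floor
        if not bad.any():
            break
        widths[bad] = rng.normal(model.ring_width_mean, model.ring_width_sd, bad.sum())
    return np.maximum(widths, floor)


def _draw_vessels(
    model: AnatomyModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (lumen areas, radial positions as fraction of ring width)."""
    if model.porosity == "diffuse":
        frac = rng.uniform(0.0, 1.0, n)
        scale = model.radial_size_trend**frac
        areas = rng.lognormal(model.vessel_log_mean, model.vessel_log_sd, n) * scale
    else:
        is_ew = rng.random(n) < model.ew_weight
        frac = np.where(
            is_ew,
            rng.uniform(0.0, model.ew_fraction, n),
            rng.uniform(model.ew_fraction, 1.0, n),
        )
        areas = np.where(
            is_ew,
            rng.lognormal(model.ew_log_mean, model.ew_log_sd, n),
            rng.lognormal(model.lw_log_mean, model.lw_log_sd, n),
        )
    return areas, frac


def _place_without_overlap(
    radii: np.ndarray,
    frac: np.ndarray,
    frac_lo: np.ndarray,
    frac_hi: np.ndarray,
    ring_start: float,
    ring_width: float,
    core_width: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy dart-throwing placement, large cells first; bounded retries."""
    order = np.argsort(-radii)
    n = len(radii)
    xs = np.empty(n)
    ys = np.empty(n)
    acc_x = np.empty(n)
    acc_y = np.empty(n)
    acc_r = np.empty(n)
    n_acc = 0
    for i in order:
        r = radii[i]
        placed = False
        f = frac[i]
        for attempt in range(_MAX_PLACEMENT_TRIES):
            x = ring_start + f * ring_width
            y = rng.uniform(0.0, core_width)
            if n_acc:
                dx = acc_x[:n_acc] - x
                dy = acc_y[:n_acc] - y
                if np.any(dx * dx + dy * dy < (acc_r[:n_acc] + r) ** 2):
                    f = rng.uniform(frac_lo[i], frac_hi[i])
                    continue
            xs[i], ys[i] = x, y
            acc_x[n_acc], acc_y[n_acc], acc_r[n_acc] = x, y, r
            n_acc += 1
            placed = True
            break
        if not placed:
            raise GenerationError(
                "could not place a vessel without lumen overlap after "
                f"{_MAX_PLACEMENT_TRIES} retries; lower vessel_density_target "
                "or the vessel-size distribution"
            )
    return xs, ys


def _draw_fibre_areas(
    model: AnatomyModel, n: int, threshold: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal fibre lumen areas truncated above at the vessel threshold."""
    upper = (np.log(threshold) - model.fibre_log_mean) / model.fibre_log_sd
    z = truncnorm.rvs(-np.inf, upper, size=n, random_state=rng)
    return np.exp(model.fibre_log_mean + model.fibre_log_sd * z)


def _mean_fibre_lumen(model: AnatomyModel) -> float:
    # mean of the untruncated log-normal; truncation at the vessel threshold
    # removes a negligible tail for realistic parameters
    return float(np.exp(model.fibre_log_mean + model.fibre_log_sd**2 / 2.0))


def _generate_fibres(
    model: AnatomyModel,
    ring_start: float,
    ring_width: float,
    core_width: float,
    vessel_xy: np.ndarray,
    vessel_r: np.ndarray,
    threshold: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jittered-grid fibre layout thinned against vessel lumina."""
    spacing = np.sqrt(_mean_fibre_lumen(model) / model.fibre_fill_fraction)
    gx = np.arange(ring_start + spacing / 2.0, ring_start + ring_width, spacing)
    gy = np.arange(spacing / 2.0, core_width, spacing)
    if len(gx) == 0 or len(gy) == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    x = xx.ravel() + rng.uniform(-0.25 * spacing, 0.25 * spacing, xx.size)
    y = yy.ravel() + rng.uniform(-0.25 * spacing, 0.25 * spacing, yy.size)
    x = np.clip(x, ring_start, np.nextafter(ring_start + ring_width, ring_start))
    y = np.clip(y, 0.0, core_width)
    areas = _draw_fibre_areas(model, x.size, threshold, rng)
    if len(vessel_r):
        tree = cKDTree(vessel_xy)
        k = min(8, len(vessel_r))
        dist, idx = tree.query(np.column_stack([x, y]), k=k)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        fr = np.sqrt(areas / np.pi)
        overlap = (dist < vessel_r[idx] + fr[:, None]).any(axis=1)
        x, y, areas = x[~overlap], y[~overlap], areas[~overlap]
    return x, y, areas


def generate_sample(
    model: AnatomyModel,
    config: RunConfig,
    sample_id: str = "synthetic",
    species: str = "synthetic",
) -> SyntheticTruth:
    """Generate a full ground-truth sample for one anatomy model.

    Rings are laid end to end from radial position 0 (pith side).  Vessel
    counts per ring are Poisson with mean ``vessel_density_target × ring
    area``; centroids are placed by dart throwing so lumen discs never
    overlap.  Vessels carry mildly elliptical major/minor axes consistent
    with their lumen area.  Reproducible given the seed
    (``model.rng_seed`` or, if unset, ``config.rng_seed``).
    """
    seed = model.rng_seed if model.rng_seed is not None else config.rng_seed
    rng = np.random.default_rng(seed)
    widths = _draw_ring_widths(model, rng)
    years = np.arange(model.start_year, model.start_year + model.n_rings)
    rings = make_ring_table(years, widths, core_width=config.core_width)
    starts = np.concatenate([[0.0], np.cumsum(widths)[:-1]])

    frames = []
    for year, start, width, area_um2 in zip(
        years, starts, widths, rings["ring_area_um2"].to_numpy()
    ):
        area_mm2 = area_um2 / 1e6
        n_vessels = rng.poisson(model.vessel_density_target * area_mm2)
        v_areas, v_frac = _draw_vessels(model, n_vessels, rng)
        # elliptical lumina: aspect ratio q, exact-area axes
        q = rng.uniform(*model.vessel_eccentricity_range, n_vessels)
        semi_major = np.sqrt(v_areas / (np.pi * q))
        semi_minor = q * semi_major
        if model.porosity == "ring_porous":
            is_ew = v_frac < model.ew_fraction
            lo = np.where(is_ew, 0.0, model.ew_fraction)
            hi = np.where(is_ew, model.ew_fraction, 1.0)
        else:
            lo = np.zeros(n_vessels)
            hi = np.ones(n_vessels)
        vx, vy = _place_without_overlap(
            semi_major, v_frac, lo, hi, start, width, config.core_width, rng
        )
        parts = [
            pd.DataFrame(
                {
                    "year": year,
                    "x_cal_um": vx,
                    "y_cal_um": vy,
                    "lumen_area_um2": v_areas,
                    "major_axis_um": 2.0 * semi_major,
                    "minor_axis_um": 2.0 * semi_minor,
                }
            )
        ]
        if model.fibre_fill_fraction > 0:
            fx, fy, f_areas = _generate_fibres(
                model,
                start,
                width,
                config.core_width,
                np.column_stack([vx, vy]),
                semi_major,
                config.fibre_threshold,
                rng,
            )
            parts.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "x_cal_um": fx,
                        "y_cal_um": fy,
                        "lumen_area_um2": f_areas,
                        "major_axis_um": np.nan,
                        "minor_axis_um": np.nan,
                    }
                )
            )
        frames.append(pd.concat(parts, ignore_index=True))

    cells = pd.concat(frames, ignore_index=True)
    cells.insert(0, "cell_id", np.arange(len(cells), dtype=int))
    cells["cell_class"] = "unclassified"
    cells = compute_rad_dist(cells, rings)
    table = SampleTable(
        sample_id=sample_id,
        species=species,
        method="synthetic_truth",
        resolution_ppum=1e6,  # effectively unlimited resolution
        cells=cells[
            [
                "cell_id",
                "year",
                "x_cal_um",
                "y_cal_um",
                "lumen_area_um2",
                "major_axis_um",
                "minor_axis_um",
                "rad_dist_um",
                "rad_dist_pct",
                "cell_class",
            ]
        ],
        rings=rings,
    )
    table.validate()
    true_metrics = compute_ring_metrics(table, config, use_cutoff=True)
    return SyntheticTruth(table=table, true_metrics=true_metrics, model=model, config=config)


def observe(
    truth: SyntheticTruth, obs: MethodObservation, config: RunConfig | None = None
) -> SampleTable:
    """Apply one acquisition method's observation model to the ground truth.

    Order of operations: miss draw → multiplicative noise (and systematic
    gain) → pixel quantisation (floor to a multiple of ``pixel_area``) →
    detection-limit filter.  The random stream depends only on the run seed
    and the method label, never on the thresholds, so tightening
    ``min_detectable_area`` yields nested subsets of the same noisy
    measurements.  Output cells are a subset of truth cells with their
    classification reset.
    """
    if config is None:
        config = truth.config
    label_salt = zlib.crc32(obs.method_label.encode("utf-8"))
    rng = np.random.default_rng([config.rng_seed, label_salt])
    cells = truth.table.cells.copy()
    areas = cells["lumen_area_um2"].to_numpy(dtype=float)
    n = len(areas)

    keep = rng.random(n) >= obs.miss_prob(areas)
    if obs.area_noise_cv > 0:
        sigma2 = np.log1p(obs.area_noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)
    else:
        noise = np.ones(n)
    observed = areas * obs.area_gain * noise
    if obs.pixel_area > 0:
        observed = np.floor(observed / obs.pixel_area) * obs.pixel_area
    keep &= observed > 0
    keep &= observed >= obs.min_detectable_area

    cells["lumen_area_um2"] = observed
    scale = np.sqrt(np.where(areas > 0, observed / areas, 1.0))
    for col in ("major_axis_um", "minor_axis_um"):
        cells[col] = cells[col].to_numpy(dtype=float) * scale
    cells = cells[keep].reset_index(drop=True)
    cells["cell_class"] = "unclassified"
    out = SampleTable(
        sample_id=truth.table.sample_id,
        species=truth.table.species,
        method=obs.method_label,
        resolution_ppum=(1.0 / np.sqrt(obs.pixel_area)) if obs.pixel_area > 0 else 1e6,
        cells=cells,
        rings=truth.table.rings.copy(),
    )
    return out.validate()


# ---------------------------------------------------------------------------
# Bundled presets: four anatomies loosely styled on the broad-leaved porosity
# classes (small-vessel diffuse, medium diffuse, semi-diffuse, ring-porous),
# and four acquisition methods spanning the resolution range from stained
# thin sections to macroscopic surface pictures.
# ---------------------------------------------------------------------------

ANATOMY_PRESETS: dict[str, AnatomyModel] = {
    "diffuse_small_vessel": AnatomyModel(
        porosity="diffuse",
        vessel_log_mean=np.log(900.0),
        vessel_log_sd=0.55,
        vessel_density_target=180.0,
        radial_size_trend=0.5,
    ),
    "diffuse_medium": AnatomyModel(
        porosity="diffuse",
        vessel_log_mean=np.log(1600.0),
        vessel_log_sd=0.6,
        vessel_density_target=120.0,
        radial_size_trend=0.45,
    ),
    "semi_diffuse": AnatomyModel(
        porosity="diffuse",
        vessel_log_mean=np.log(1300.0),
        vessel_log_sd=0.65,
        vessel_density_target=140.0,
        radial_size_trend=0.35,
    ),
    "ring_porous": AnatomyModel(
        porosity="ring_porous",
        vessel_density_target=18.0,
        ew_weight=0.12,
        ring_width_mean=2400.0,
        ring_width_sd=400.0,
        radial_size_trend=1.0,
    ),
}

CONFIG_PRESETS: dict[str, RunConfig] = {
    "diffuse_small_vessel": RunConfig(cutoff=1000.0, sector_width=120.0, fibre_lumen_area=138.0),
    "diffuse_medium": RunConfig(cutoff=1000.0, sector_width=120.0, fibre_lumen_area=138.0),
    "semi_diffuse": RunConfig(cutoff=1000.0, sector_width=120.0, fibre_lumen_area=138.0),
    "ring_porous": RunConfig(cutoff=5000.0, sector_width=450.0, fibre_lumen_area=138.0),
}

METHOD_PRESETS: dict[str, MethodObservation] = {
    "thin_section": MethodObservation(
        method_label="thin_section",
        min_detectable_area=20.0,
        miss_max=0.02,
        miss_decay_area=300.0,
        area_noise_cv=0.03,
        pixel_area=0.194,  # 2.27 px/μm slide scan
    ),
    "thin_section_full": MethodObservation(
        method_label="thin_section_full",
        min_detectable_area=20.0,
        miss_max=0.02,
        miss_decay_area=300.0,
        area_noise_cv=0.03,
        pixel_area=0.194,
    ),
    "micro_ct": MethodObservation(
        method_label="micro_ct",
        min_detectable_area=250.0,
        miss_max=0.35,
        miss_decay_area=800.0,
        area_noise_cv=0.06,
        pixel_area=9.0,  # 3 μm voxels
    ),
    "surface_picture": MethodObservation(
        method_label="surface_picture",
        min_detectable_area=450.0,
        miss_max=0.5,
        miss_decay_area=1500.0,
        area_noise_cv=0.08,
        pixel_area=17.64,  # 4.2 μm pixels
    ),
}

IDENTITY_OBSERVATION = MethodObservation(method_label="identity")


def preset(name: str) -> tuple[AnatomyModel, RunConfig]:
    """Return the (anatomy model, run configuration) pair for a preset name."""
    if name not in ANATOMY_PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {sorted(ANATOMY_PRESETS)}"
        )
    return ANATOMY_PRESETS[name], CONFIG_PRESETS[name]
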