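"""Domain types, validation and delimited-text I/O for per-cell tables.

The central container is :class:`SampleTable`: one analysed wood sample,
holding a per-cell measurement table (one row per detected xylem element,
with calibrated centroid coordinates, lumen area and radial position) and a
per-ring table (year, ring width, analysed area of interest).  The layout
emulates the tabular export of cell-detection software such as ROXAS, so
real exports can be ingested through a column-name dialect map.

Conventions
-----------
* All lengths are in μm and all areas in μm²; conversion to SI happens only
  inside the hydraulic operations of :mod:`qwamap.sector_profile`.
* The radial coordinate ``x_cal`` increases from pith to bark; radial
  distance is measured from the pith-side ring boundary, so distance 0 is
  the start of the earlywood.
* Ring intervals are half-open ``[start, start + width)``: a centroid
  exactly on a boundary belongs to the later ring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AssignmentError, ConfigError, FormatError, ValidationError

#: Canonical per-cell column order.  ``major_axis_um``/``minor_axis_um`` are
#: optional; ``cell_class`` defaults to ``"unclassified"``.
CELL_COLUMNS = [
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

MANDATORY_CELL_COLUMNS = ["year", "x_cal_um", "y_cal_um", "lumen_area_um2"]

RING_COLUMNS = ["year", "ring_width_um", "aoi_area_um2", "core_width_um", "ring_area_um2"]

CELL_CLASSES = ("vessel", "fibre", "unclassified")

#: Default dialect translating common ROXAS export column names to the
#: canonical names used throughout qwamap.
ROXAS_DIALECT: Mapping[str, str] = {
    "ID": "cell_id",
    "YEAR": "year",
    "Year": "year",
    "XCAL": "x_cal_um",
    "Xcal": "x_cal_um",
    "YCAL": "y_cal_um",
    "Ycal": "y_cal_um",
    "LA": "lumen_area_um2",
    "MAJAX": "major_axis_um",
    "MINAX": "minor_axis_um",
    "RADDISTR": "rad_dist_um",
    "RadDistR": "rad_dist_um",
    "RRADDISTR": "rad_dist_pct",
    "RRadDistR": "rad_dist_pct",
}

DEFAULT_CORE_WIDTH_UM = 5000.0


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration for one run.

    Parameters
    ----------
    fibre_threshold
        Lumen area (μm²) above which an element is classified as a vessel;
        at or below it is a fibre.  Default 500 μm².
    cutoff
        Lumen-area cut-off (μm²) applied before computing inter-annual ring
        parameters: 1000 μm² for diffuse-porous species, 5000 μm² for
        ring-porous species.
    sector_width
        Radial width of the sector boxes (μm): 120 μm for diffuse-porous
        species, 450 μm for ring-porous (large earlywood vessels).
    wall_density
        Density of the cell-wall material, g cm⁻³ (1.504 for wood).
    wall_thickness
        Fixed cell-wall thickness (μm) assumed when estimating the footprint
        of undetected fibres.
    viscosity
        Dynamic viscosity of water, Pa·s (0.001 at 20 °C).
    capillary_length
        Capillary length l (m) in the Hagen–Poiseuille conductance; 1 m so
        conductance is per metre of path.
    core_width
        Tangential width of the analysed core surface (μm); ring area is
        ``core_width × ring_width``.
    fibre_lumen_area
        Optional mean fibre lumen area (μm²) used by the undetected-fibre
        correction when too few fibres were detected to estimate it.
    rng_seed
        Seed for every stochastic stage (generation, observation, bootstrap).
    """

    fibre_threshold: float = 500.0
    cutoff: float = 1000.0
    sector_width: float = 120.0
    wall_density: float = 1.504
    wall_thickness: float = 4.0
    viscosity: float = 1e-3
    capillary_length: float = 1.0
    core_width: float = DEFAULT_CORE_WIDTH_UM
    fibre_lumen_area: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fibre_threshold",
            "cutoff",
            "sector_width",
            "wall_density",
            "wall_thickness",
            "viscosity",
            "capillary_length",
            "core_width",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ConfigError(f"RunConfig.{name} must be strictly positive, got {value!r}")
        if self.cutoff < self.fibre_threshold:
            raise ConfigError(
                f"cutoff ({self.cutoff}) must be >= fibre_threshold ({self.fibre_threshold})"
            )
        if self.fibre_lumen_area is not None and not self.fibre_lumen_area > 0:
            raise ConfigError("fibre_lumen_area must be strictly positive when given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def make_ring_table(
    years: Sequence[int],
    ring_widths: Sequence[float],
    aoi_areas: Sequence[float] | None = None,
    core_width: float = DEFAULT_CORE_WIDTH_UM,
) -> pd.DataFrame:
    """Build a validated ring table; ring area is ``core_width × ring_width``.

    When ``aoi_areas`` is omitted the analysed area of interest defaults to
    the full ring area.
    """
    years = np.asarray(years, dtype=int)
    widths = np.asarray(ring_widths, dtype=float)
    areas = widths * core_width
    aoi = areas if aoi_areas is None else np.asarray(aoi_areas, dtype=float)
    rings = pd.DataFrame(
        {
            "year": years,
            "ring_width_um": widths,
            "aoi_area_um2": aoi,
            "core_width_um": float(core_width),
            "ring_area_um2": areas,
        }
    )
    return rings


def ring_start_positions(rings: pd.DataFrame) -> pd.Series:
    """Pith-side start offset (μm) of each ring, rings laid end to end from 0."""
    rings = rings.sort_values("year")
    if len(rings) == 0:
        return pd.Series(dtype=float, name="ring_start_um")
    starts = np.concatenate([[0.0], np.cumsum(rings["ring_width_um"].to_numpy())[:-1]])
    return pd.Series(starts, index=rings["year"].to_numpy(), name="ring_start_um")


@dataclass
class SampleTable:
    """One analysed sample: per-cell and per-ring tables plus metadata."""

    sample_id: str
    species: str
    method: str
    resolution_ppum: float
    cells: pd.DataFrame
    rings: pd.DataFrame

    @property
    def t_range(self) -> tuple[int, int]:
        years = self.rings["year"]
        return int(years.min()), int(years.max())

    def copy(self) -> "SampleTable":
        return SampleTable(
            sample_id=self.sample_id,
            species=self.species,
            method=self.method,
            resolution_ppum=self.resolution_ppum,
            cells=self.cells.copy(),
            rings=self.rings.copy(),
        )

    def validate(self) -> "SampleTable":
        """Check every domain invariant; raise ValidationError on the first hit."""
        if not self.resolution_ppum > 0:
            raise ValidationError("resolution_ppum must be strictly positive")
        rings = self.rings
        for col in ("year", "ring_width_um", "aoi_area_um2"):
            if col not in rings.columns:
                raise FormatError(f"ring table missing column {col!r}")
        years = rings["year"].to_numpy()
        if len(years) and not np.all(np.diff(years) > 0):
            raise ValidationError("ring years must be strictly increasing")
        if (rings["ring_width_um"] <= 0).any():
            raise ValidationError("ring_width_um must be strictly positive")
        if (rings["aoi_area_um2"] <= 0).any():
            raise ValidationError("aoi_area_um2 must be strictly positive")
        expected = rings["core_width_um"] * rings["ring_width_um"]
        if not np.array_equal(rings["ring_area_um2"].to_numpy(), expected.to_numpy()):
            raise ValidationError("ring_area_um2 must equal core_width_um × ring_width_um")

        cells = self.cells
        for col in MANDATORY_CELL_COLUMNS:
            if col not in cells.columns:
                raise FormatError(f"cell table missing mandatory column {col!r}")
        if len(cells) == 0:
            return self
        bad = cells.index[cells["lumen_area_um2"] <= 0]
        if len(bad):
            raise ValidationError(f"non-positive lumen_area_um2 at row {bad[0]}")
        unknown_years = set(cells["year"].unique()) - set(years.tolist())
        if unknown_years:
            raise ValidationError(
                f"cell years absent from ring table: {sorted(unknown_years)}"
            )
        if "rad_dist_pct" in cells.columns:
            pct = cells["rad_dist_pct"].dropna()
            if ((pct < 0) | (pct > 100)).any():
                raise ValidationError("rad_dist_pct must lie in [0, 100]")
        if "rad_dist_um" in cells.columns:
            widths = cells["year"].map(rings.set_index("year")["ring_width_um"])
            rd = cells["rad_dist_um"]
            mask = rd.notna() & (rd > widths)
            if mask.any():
                raise ValidationError(
                    f"rad_dist_um exceeds ring width at row {cells.index[mask][0]}"
                )
        if "major_axis_um" in cells.columns and "minor_axis_um" in cells.columns:
            both = cells["major_axis_um"].notna() & cells["minor_axis_um"].notna()
            if both.any():
                maj = cells.loc[both, "major_axis_um"]
                mino = cells.loc[both, "minor_axis_um"]
                if ((mino <= 0) | (maj < mino)).any():
                    raise ValidationError("axes must satisfy major >= minor > 0")
                ellipse = np.pi * (maj / 2.0) * (mino / 2.0)
                ratio = ellipse / cells.loc[both, "lumen_area_um2"]
                if ((ratio < 0.5) | (ratio > 1.5)).any():
                    raise ValidationError(
                        "ellipse area from axes departs more than 50% from lumen area"
                    )
        if "cell_class" in cells.columns:
            bad_class = set(cells["cell_class"].unique()) - set(CELL_CLASSES)
            if bad_class:
                raise ValidationError(f"unknown cell_class values: {sorted(bad_class)}")
        return self


def _normalise_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes and fill optional columns of a raw cell frame."""
    cells = cells.copy()
    if "cell_id" not in cells.columns:
        cells["cell_id"] = np.arange(len(cells), dtype=int)
    if "cell_class" not in cells.columns:
        cells["cell_class"] = "unclassified"
    cells["cell_class"] = cells["cell_class"].fillna("unclassified")
    for col in ("major_axis_um", "minor_axis_um", "rad_dist_um", "rad_dist_pct"):
        if col not in cells.columns:
            cells[col] = np.nan
        cells[col] = cells[col].astype(float)
    for col in ("x_cal_um", "y_cal_um", "lumen_area_um2"):
        cells[col] = cells[col].astype(float)
    cells["cell_id"] = cells["cell_id"].astype(int)
    cells["year"] = cells["year"].astype(int)
    return cells[CELL_COLUMNS]


def compute_rad_dist(
    cells: pd.DataFrame,
    rings: pd.DataFrame,
    starts: pd.Series | Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Recompute radial distance of each centroid from its ring's start.

    ``rad_dist_um = x_cal − ring start`` and ``rad_dist_pct`` is the same
    distance as a percentage of the ring width.  Each centroid must fall in
    the half-open interval ``[start, start + width)`` of its assigned ring;
    a centroid exactly on the bark-side boundary belongs to the next ring
    and triggers an :class:`AssignmentError`.

    Idempotent: reapplying to its own output changes nothing.
    """
    if starts is None:
        starts = ring_start_positions(rings)
    starts = pd.Series(dict(starts) if not isinstance(starts, pd.Series) else starts)
    cells = cells.copy()
    if len(cells) == 0:
        return cells
    ring_index = rings.set_index("year")
    start = cells["year"].map(starts)
    width = cells["year"].map(ring_index["ring_width_um"])
    rd = cells["x_cal_um"].to_numpy() - start.to_numpy()
    w = width.to_numpy()
    outside = (rd < 0) | (rd >= w)
    if outside.any():
        row = cells.index[outside][0]
        raise AssignmentError(
            f"cell at row {row} (x_cal={cells.loc[row, 'x_cal_um']}) lies outside the "
            f"half-open interval of ring {cells.loc[row, 'year']}"
        )
    cells["rad_dist_um"] = rd
    cells["rad_dist_pct"] = 100.0 * rd / w
    return cells


def _apply_dialect(frame: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if dialect:
        frame = frame.rename(columns=dict(dialect))
    return frame


def read_cells(
    cell_path: str | Path,
    ring_path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sample_id: str = "sample",
    species: str = "unknown",
    method: str = "thin_section",
    resolution_ppum: float = 1.0,
) -> SampleTable:
    """Read a per-cell CSV plus its ring CSV into a validated SampleTable.

    ``dialect`` maps file column names (e.g. ROXAS ``"LA"``) to the canonical
    names; pass :data:`ROXAS_DIALECT` for raw ROXAS exports.  Radial-distance
    columns are recomputed from the ring layout when absent.  Row order is
    preserved.
    """
    cell_path, ring_path = Path(cell_path), Path(ring_path)
    if not cell_path.exists():
        raise FormatError(f"cell table not found: {cell_path}")
    if not ring_path.exists():
        raise FormatError(f"ring table not found: {ring_path}")
    raw = pd.read_csv(cell_path)
    raw = _apply_dialect(raw, dialect)
    for col in MANDATORY_CELL_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"cell table {cell_path} missing mandatory column {col!r}")
    rraw = pd.read_csv(ring_path)
    rraw = _apply_dialect(rraw, dialect)
    for col in ("year", "ring_width_um", "aoi_area_um2"):
        if col not in rraw.columns:
            raise FormatError(f"ring table {ring_path} missing column {col!r}")
    if "core_width_um" not in rraw.columns:
        rraw["core_width_um"] = DEFAULT_CORE_WIDTH_UM
    rraw["ring_area_um2"] = rraw["core_width_um"] * rraw["ring_width_um"]
    cells = _normalise_cells(raw)
    if len(cells) and cells["rad_dist_um"].isna().all():
        cells = compute_rad_dist(cells, rraw)
    table = SampleTable(
        sample_id=sample_id,
        species=species,
        method=method,
        resolution_ppum=resolution_ppum,
        cells=cells,
        rings=rraw[RING_COLUMNS],
    )
    return table.validate()


def write_cells(
    table: SampleTable, cell_path: str | Path, ring_path: str | Path | None = None
) -> None:
    """Write a SampleTable to CSV; round-trips through :func:`read_cells`.

    Optional axis columns that are entirely absent are omitted from the file
    and re-read as absent.  ``ring_path`` defaults to the cell path with a
    ``_rings`` suffix.
    """
    cell_path = Path(cell_path)
    if ring_path is None:
        ring_path = cell_path.with_name(cell_path.stem + "_rings" + cell_path.suffix)
    cells = table.cells.copy()
    for col in ("major_axis_um", "minor_axis_um"):
        if col in cells.columns and cells[col].isna().all():
            cells = cells.drop(columns=[col])
    cells.to_csv(cell_path, index=False)
    table.rings.to_csv(ring_path, index=False)
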