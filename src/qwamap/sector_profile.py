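"""Intra-annual sectorial radial profiles.

Each annual ring is tiled, from the pith-side boundary toward the bark, with
contiguous half-open sector boxes of fixed radial width (120 μm by default;
450 μm for ring-porous anatomy with its large earlywood vessels).  The last
sector is truncated at the ring boundary and kept with its true width.  For
every sector three quantities are derived from the member cells (those whose
centroid falls in the box):

* the **median lumen area** A_l (robust to the skewed vessel-size
  distribution; missing, not zero, for empty sectors);
* the **theoretical hydraulic conductance** K_H (Hagen–Poiseuille,
  ``π Σ d⁴ / (128 η l)`` over the member vessel diameters) and its
  area-normalised form **K_s = K_H / box area**, which is independent of the
  sector size and genuinely zero for vessel-free sectors;
* the **anatomical wood density** ρ = wall density × (non-lumen fraction of
  the box), with the wall-material density fixed at 1.504 g cm⁻³.

Two variants are produced: ``vessels_only`` uses threshold-classified
vessels, while ``fibre_corrected`` additionally accounts for detected fibres
and estimates the number of fibres the acquisition method failed to detect.
The estimate assumes each cell occupies its lumen plus a 4 μm wall band
around the equivalent-circle perimeter: whatever box area remains after the
detected-cell footprints and any crack area is attributed to undetected
fibres of mean footprint, and their lumina are added to the density
accounting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core_data import RunConfig, SampleTable
from .errors import AssignmentError, ConfigError, ValidationError
from .ring_metrics import cell_diameters, classify_cells

M2_PER_UM2 = 1e-12
MPA_S_PER_PA_S = 1e-6
M_PER_UM = 1e-6

VARIANTS = ("vessels_only", "fibre_corrected")


def sector_boxes_for_ring(ring_width: float, sector_width: float, core_width: float) -> pd.DataFrame:
    """Sector layout of one ring: contiguous half-open boxes covering [0, width)."""
    n_full = int(ring_width // sector_width)
    starts = np.arange(0, n_full + 1) * sector_width
    starts = starts[starts < ring_width]
    ends = np.minimum(starts + sector_width, ring_width)
    return pd.DataFrame(
        {
            "sector_index": np.arange(len(starts), dtype=int),
            "radial_start_um": starts,
            "radial_end_um": ends,
            "width_um": ends - starts,
            "box_area_um2": (ends - starts) * core_width,
        }
    )


def assign_sectors(
    table: SampleTable, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every cell to its sector box.

    Returns ``(cells, boxes)``: the cell table with a ``sector_index``
    column, and the per-ring sector layout (year, index, radial bounds,
    width, box area).  A cell with ``rad_dist_um`` in
    ``[k·w, (k+1)·w)`` belongs to sector ``k``; a radial distance at or
    beyond the ring width cannot be assigned.
    """
    cells = table.cells.copy()
    ring_widths = table.rings.set_index("year")["ring_width_um"]
    boxes = []
    for _, ring in table.rings.iterrows():
        b = sector_boxes_for_ring(
            float(ring["ring_width_um"]), config.sector_width, float(ring["core_width_um"])
        )
        b.insert(0, "year", int(ring["year"]))
        boxes.append(b)
    boxes = pd.concat(boxes, ignore_index=True)
    if len(cells):
        rd = cells["rad_dist_um"].to_numpy(dtype=float)
        if np.isnan(rd).any():
            raise AssignmentError("rad_dist_um must be computed before sector assignment")
        widths = cells["year"].map(ring_widths).to_numpy(dtype=float)
        if (rd >= widths).any():
            row = cells.index[rd >= widths][0]
            raise AssignmentError(f"cell at row {row} has rad_dist_um >= ring width")
        cells["sector_index"] = np.floor(rd / config.sector_width).astype(int)
    else:
        cells["sector_index"] = pd.Series(dtype=int)
    return cells, boxes


def sector_al(lumen_areas: np.ndarray | list[float]) -> float:
    """Median lumen area of the member cells (μm²); NaN for an empty sector."""
    a = np.asarray(lumen_areas, dtype=float)
    return float(np.median(a)) if a.size else float("nan")


def sector_kh(diameters_um: np.ndarray | list[float], config: RunConfig) -> float:
    """Hagen–Poiseuille conductance of the member lumina (m⁴ MPa⁻¹ s⁻¹).

    ``K_H = π Σ d⁴ / (128 η l)`` with diameters converted to metres and the
    water viscosity to MPa·s.  Additive over disjoint cell sets; zero for an
    empty sector.
    """
    d = np.asarray(diameters_um, dtype=float) * M_PER_UM
    eta_mpa_s = config.viscosity * MPA_S_PER_PA_S
    return float(np.pi * np.sum(d**4) / (128.0 * eta_mpa_s * config.capillary_length))


def sector_ks(kh: float, box_area_um2: float) -> float:
    """Specific conductivity K_s = K_H / box area (m² s⁻¹ MPa⁻¹)."""
    if not box_area_um2 > 0:
        raise ConfigError("sector box area must be strictly positive")
    return kh / (box_area_um2 * M2_PER_UM2)


def sector_density(
    lumen_sum_um2: float,
    box_area_um2: float,
    config: RunConfig,
    crack_area_um2: float = 0.0,
) -> float:
    """Anatomical wood density of a sector (g cm⁻³).

    ``ρ = wall_density × (box − lumen − cracks) / box``, clipped into
    ``[0, wall_density]`` with a warning when clipping was needed.  A lumen
    sum exceeding the box area indicates overlapping cells or a wrong sector
    and is a data error.
    """
    if lumen_sum_um2 > box_area_um2:
        raise ValidationError(
            f"total lumen area ({lumen_sum_um2:.1f} μm²) exceeds sector box area "
            f"({box_area_um2:.1f} μm²): overlapping cells or wrong sector"
        )
    # formulated so the zero-lumen limit is exactly wall_density
    rho = config.wall_density * (1.0 - (lumen_sum_um2 + crack_area_um2) / box_area_um2)
    if rho < 0.0 or rho > config.wall_density:
        warnings.warn("sector density clipped into [0, wall_density]", stacklevel=2)
        rho = min(max(rho, 0.0), config.wall_density)
    return rho


def _cell_footprint(lumen_areas: np.ndarray, wall_thickness: float) -> np.ndarray:
    """Area occupied by a cell: lumen plus a wall band around its perimeter."""
    r = np.sqrt(np.asarray(lumen_areas, dtype=float) / np.pi)
    return np.pi * (r + wall_thickness) ** 2


def fibre_correction(
    lumen_areas: np.ndarray | list[float],
    box_area_um2: float,
    config: RunConfig,
    mean_fibre_lumen: float | None = None,
    crack_area_um2: float = 0.0,
) -> dict[str, float]:
    """Estimate undetected fibres from the unaccounted sector area.

    ``lumen_areas`` are the lumina of *all* detected cells in the sector.
    Each is expanded to a footprint (lumen + 4 μm wall band by default);
    the residual ``box − Σ footprints − cracks`` is divided by the mean
    fibre footprint to estimate how many fibres the method missed, and the
    adjusted lumen total adds their lumina.

    Returns a dict with ``detected_lumen``, ``detected_footprint``,
    ``residual_area``, ``est_undetected_fibres`` and ``adjusted_lumen``.
    """
    if mean_fibre_lumen is None:
        mean_fibre_lumen = config.fibre_lumen_area
    if mean_fibre_lumen is None or not mean_fibre_lumen > 0:
        raise ConfigError(
            "fibre correction needs a mean fibre lumen area: none could be "
            "estimated from detected fibres and none is configured"
        )
    areas = np.asarray(lumen_areas, dtype=float)
    detected_lumen = float(areas.sum())
    detected_footprint = float(_cell_footprint(areas, config.wall_thickness).sum())
    residual = max(box_area_um2 - detected_footprint - crack_area_um2, 0.0)
    fibre_footprint = float(
        _cell_footprint(np.array([mean_fibre_lumen]), config.wall_thickness)[0]
    )
    est = residual / fibre_footprint
    return {
        "detected_lumen": detected_lumen,
        "detected_footprint": detected_footprint,
        "residual_area": residual,
        "est_undetected_fibres": est,
        "adjusted_lumen": detected_lumen + est * mean_fibre_lumen,
    }


def _ring_mean_fibre_lumen(ring_cells: pd.DataFrame, config: RunConfig) -> float | None:
    """Mean detected-fibre lumen of a ring, if at least 10 fibres were seen."""
    fibres = ring_cells[ring_cells["cell_class"] == "fibre"]
    if len(fibres) >= 10:
        return float(fibres["lumen_area_um2"].mean())
    return config.fibre_lumen_area


def build_sector_series(
    table: SampleTable,
    config: RunConfig,
    variant: str = "vessels_only",
    crack_areas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-sector radial profile for every ring of a sample.

    Returns a long-format DataFrame with one row per (year, sector):
    ``year, sector_index, radial_start_um, width_um, box_area_um2,
    rel_position, n_cells, n_vessels, al_median, kh, ks, rho, variant``.

    ``rel_position`` is the sector midpoint as a percentage of the ring
    width.  ``crack_areas`` may supply a per-sector crack area via columns
    (year, sector_index, crack_area_um2); cracks default to 0.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    table = classify_cells(table, config.fibre_threshold)
    cells, boxes = assign_sectors(table, config)
    ring_widths = table.rings.set_index("year")["ring_width_um"]

    if crack_areas is not None:
        crack_lookup = crack_areas.set_index(["year", "sector_index"])["crack_area_um2"]
    else:
        crack_lookup = None

    grouped = dict(iter(cells.groupby(["year", "sector_index"])))
    ring_groups = dict(iter(cells.groupby("year")))
    rows = []
    for _, box in boxes.iterrows():
        year, k = int(box["year"]), int(box["sector_index"])
        box_area = float(box["box_area_um2"])
        members = grouped.get((year, k), cells.iloc[0:0])
        vessels = members[members["cell_class"] == "vessel"]
        crack = float(crack_lookup.get((year, k), 0.0)) if crack_lookup is not None else 0.0

        al = sector_al(vessels["lumen_area_um2"].to_numpy())
        kh = sector_kh(cell_diameters(vessels), config)
        ks = sector_ks(kh, box_area)
        if variant == "vessels_only":
            lumen_sum = float(vessels["lumen_area_um2"].sum())
            rho = sector_density(lumen_sum, box_area, config, crack)
        else:
            ring_cells = ring_groups.get(year, cells.iloc[0:0])
            mean_fibre = _ring_mean_fibre_lumen(ring_cells, config)
            corr = fibre_correction(
                members["lumen_area_um2"].to_numpy(), box_area, config, mean_fibre, crack
            )
            adjusted = min(corr["adjusted_lumen"], box_area)
            rho = sector_density(adjusted, box_area, config, crack)

        mid = float(box["radial_start_um"]) + float(box["width_um"]) / 2.0
        rows.append(
            {
                "year": year,
                "sector_index": k,
                "radial_start_um": float(box["radial_start_um"]),
                "width_um": float(box["width_um"]),
                "box_area_um2": box_area,
                "rel_position": 100.0 * mid / float(ring_widths.loc[year]),
                "n_cells": len(members),
                "n_vessels": len(vessels),
                "al_median": al,
                "kh": kh,
                "ks": ks,
                "rho": rho,
                "variant": variant,
            }
        )
    return pd.DataFrame(rows)
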