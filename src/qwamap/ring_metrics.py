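"""Inter-annual per-ring parameters for quantitative wood anatomy.

For every annual ring the five standard parameters are computed from the
classified, cut-off-filtered cell table:

* **MLA** — mean lumen area of the retained cells (μm²);
* **VD** — vessel density, retained count per analysed area of interest
  (mm⁻²);
* **VN** — vessel number, VD × ring area (ring area = core width × ring
  width), reported un-rounded;
* **D_h** — hydraulically weighted mean vessel diameter,
  ``Σ d⁵ / Σ d⁴`` over cell hydraulic diameters, which weights large
  conduits according to their fourth-power contribution to laminar flow;
* **RCA** — relative conductive area, total retained lumen area divided by
  the analysed area of interest.

Classification uses a strict lumen-area threshold: an element is a vessel
iff its lumen area exceeds the fibre threshold (500 μm² by default); the
same strict inequality is applied to the cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import RunConfig, SampleTable
from .errors import ConfigError

UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class RingMetrics:
    """The five inter-annual parameters for one ring under one setting."""

    year: int
    mla: float  # μm²; NaN when no cell retained
    vd: float  # mm⁻²
    vn: float  # dimensionless, possibly fractional
    dh: float  # μm; NaN when no cell retained
    rca: float  # fraction of the analysed area of interest
    n_cells_used: int
    cutoff_applied: float | None


def classify_cells(table: SampleTable, fibre_threshold: float | None = None) -> SampleTable:
    """Label every cell vessel/fibre by the strict lumen-area threshold.

    ``cell_class = "vessel"`` iff ``lumen_area > threshold``; an element with
    area exactly at the threshold is a fibre.  No cells are removed.
    """
    if fibre_threshold is None:
        fibre_threshold = RunConfig().fibre_threshold
    if not fibre_threshold > 0:
        raise ConfigError(f"fibre threshold must be strictly positive, got {fibre_threshold}")
    out = table.copy()
    if len(out.cells):
        vessel = out.cells["lumen_area_um2"].to_numpy() > fibre_threshold
        out.cells["cell_class"] = np.where(vessel, "vessel", "fibre")
    return out


def apply_cutoff(table: SampleTable, cutoff: float, fibre_threshold: float = 0.0) -> SampleTable:
    """Retain only cells with lumen area strictly above the cut-off.

    Ring records are untouched.  The cut-off must not lie below the fibre
    threshold (it would re-admit fibres).
    """
    if cutoff < fibre_threshold:
        raise ConfigError(
            f"cutoff ({cutoff}) must not be below the fibre threshold ({fibre_threshold})"
        )
    out = table.copy()
    out.cells = out.cells[out.cells["lumen_area_um2"] > cutoff].reset_index(drop=True)
    return out


def dh_cell(
    lumen_area: float,
    major_axis: float | None = None,
    minor_axis: float | None = None,
) -> float:
    """Cell-specific hydraulic diameter (μm).

    With both axes present the lumen is treated as an ellipse with semi-axes
    ``a = major/2``, ``b = minor/2`` and the hydraulic diameter is
    ``(32 a³ b³ / (a² + b²))^(1/4)``, which reduces to the circle diameter
    when a = b.  Without axes (or with degenerate zero axes) the
    equivalent-circle diameter ``2 √(A/π)`` is used.
    """
    if major_axis is not None and minor_axis is not None:
        a, b = major_axis / 2.0, minor_axis / 2.0
        if a > 0 and b > 0:
            return float((32.0 * a**3 * b**3 / (a**2 + b**2)) ** 0.25)
    return float(2.0 * math.sqrt(lumen_area / math.pi))


def cell_diameters(cells: pd.DataFrame) -> np.ndarray:
    """Vectorised hydraulic diameter for every row of a cell table (μm)."""
    area = cells["lumen_area_um2"].to_numpy(dtype=float)
    d = 2.0 * np.sqrt(area / np.pi)
    if "major_axis_um" in cells.columns and "minor_axis_um" in cells.columns:
        a = cells["major_axis_um"].to_numpy(dtype=float) / 2.0
        b = cells["minor_axis_um"].to_numpy(dtype=float) / 2.0
        ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
        if ok.any():
            d = d.copy()
            d[ok] = (32.0 * a[ok] ** 3 * b[ok] ** 3 / (a[ok] ** 2 + b[ok] ** 2)) ** 0.25
    return d


def ring_dh(diameters: np.ndarray | list[float]) -> float:
    """Hydraulically weighted mean diameter ``Σ d⁵ / Σ d⁴`` (μm).

    Returns NaN for an empty set (undefined, not zero).  The result always
    lies between the smallest and largest cell diameter.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        return float("nan")
    d4 = d**4
    return float(np.sum(d4 * d) / np.sum(d4))


def ring_metrics_one(
    cells: pd.DataFrame, ring: pd.Series, cutoff_applied: float | None
) -> RingMetrics:
    """Metrics for one ring from its already-filtered cell rows."""
    aoi_mm2 = float(ring["aoi_area_um2"]) / UM2_PER_MM2
    ring_area_mm2 = float(ring["ring_area_um2"]) / UM2_PER_MM2
    n = len(cells)
    if n == 0:
        return RingMetrics(
            year=int(ring["year"]),
            mla=float("nan"),
            vd=0.0,
            vn=0.0,
            dh=float("nan"),
            rca=0.0,
            n_cells_used=0,
            cutoff_applied=cutoff_applied,
        )
    areas = cells["lumen_area_um2"].to_numpy(dtype=float)
    vd = n / aoi_mm2
    return RingMetrics(
        year=int(ring["year"]),
        mla=float(areas.mean()),
        vd=vd,
        vn=vd * ring_area_mm2,
        dh=ring_dh(cell_diameters(cells)),
        rca=float(areas.sum() / float(ring["aoi_area_um2"])),
        n_cells_used=n,
        cutoff_applied=cutoff_applied,
    )


def compute_ring_metrics(
    table: SampleTable,
    config: RunConfig,
    use_cutoff: bool = True,
) -> pd.DataFrame:
    """Per-ring metrics table for a whole sample.

    The cells are classified at ``config.fibre_threshold`` and, when
    ``use_cutoff`` is true, filtered at ``config.cutoff`` before the five
    parameters are computed.  With ``use_cutoff=False`` (the
    fibres-included thin-section variant) every detected element enters the
    statistics.

    Returns a DataFrame with one row per ring and columns
    ``year, mla, vd, vn, dh, rca, n_cells_used, cutoff_applied``.
    """
    table = classify_cells(table, config.fibre_threshold)
    if use_cutoff:
        table = apply_cutoff(table, config.cutoff, config.fibre_threshold)
        cutoff_applied: float | None = config.cutoff
    else:
        cutoff_applied = None
    groups = dict(iter(table.cells.groupby("year")))
    rows = []
    for _, ring in table.rings.iterrows():
        cells = groups.get(int(ring["year"]), table.cells.iloc[0:0])
        rows.append(ring_metrics_one(cells, ring, cutoff_applied).__dict__)
    return pd.DataFrame(rows)


def mla_convergence(
    tables: dict[str, SampleTable],
    candidate_cutoffs: np.ndarray | list[float],
    tolerance: float = 0.05,
) -> tuple[float | None, pd.DataFrame]:
    """Cut-off at which mean-ring MLA converges between acquisition methods.

    For each candidate cut-off the per-method mean over rings of the per-ring
    MLA (cells with lumen area strictly above the cut-off) is computed, and
    the maximum pairwise relative difference (|a−b| over the pair mean)
    recorded.  Returns the smallest candidate whose maximum difference falls
    below ``tolerance`` (or None if none does) together with the full
    difference-versus-cutoff curve.
    """
    if len(tables) < 2:
        raise ConfigError("mla_convergence needs tables from at least two methods")
    candidates = np.sort(np.asarray(candidate_cutoffs, dtype=float))
    methods = list(tables)
    records = []
    converged: float | None = None
    for c in candidates:
        means = {}
        for m in methods:
            cells = tables[m].cells
            kept = cells[cells["lumen_area_um2"] > c]
            per_ring = kept.groupby("year")["lumen_area_um2"].mean()
            means[m] = float(per_ring.mean()) if len(per_ring) else float("nan")
        max_rel = 0.0
        for i, mi in enumerate(methods):
            for mj in methods[i + 1 :]:
                a, b = means[mi], means[mj]
                if np.isnan(a) or np.isnan(b):
                    max_rel = float("nan")
                else:
                    denom = (a + b) / 2.0
                    rel = abs(a - b) / denom if denom else 0.0
                    if not np.isnan(max_rel):
                        max_rel = max(max_rel, rel)
        records.append({"cutoff": float(c), "max_rel_diff": max_rel, **means})
        if converged is None and not np.isnan(max_rel) and max_rel < tolerance:
            converged = float(c)
    return converged, pd.DataFrame(records)
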