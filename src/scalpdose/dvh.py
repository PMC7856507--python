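"""Cumulative dose-volume histograms and area hot-spot metrics.

Hot-spot doses on a scalp layer are reported per area (e.g. the minimum
dose in the hottest 0.05 cm^2 or 25 cm^2): the requested area is
converted to a volume through the layer thickness (area x thickness),
which for a 2 mm layer means 25 cm^2 corresponds to 5 cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, StructureMask

__all__ = [
    "CumulativeDVH",
    "cumulative_dvh",
    "dose_at_hottest_area",
    "v40_area_map",
    "DEFAULT_BIN_WIDTH_GY",
]

#: Default DVH bin width (Gy); well below the rounding precision of
#: reported dose metrics.
DEFAULT_BIN_WIDTH_GY = 0.05


@dataclass(frozen=True)
class CumulativeDVH:
    """Volume-at-or-above-dose curve for one structure.

    ``volume_at_or_above[i]`` is the structure volume (cm^3) receiving at
    least ``dose_edges[i]`` Gy. The curve is non-increasing, starts at the
    total structure volume (the first edge is 0 Gy) and ends at 0 (the
    last edge exceeds the maximum dose).
    """

    dose_edges: np.ndarray
    volume_at_or_above: np.ndarray
    total_volume_cc: float
    structure: str = ""

    def __post_init__(self):
        edges = np.asarray(self.dose_edges, dtype=np.float64)
        vols = np.asarray(self.volume_at_or_above, dtype=np.float64)
        if edges.shape != vols.shape or edges.ndim != 1 or edges.size < 2:
            raise ValueError("dose_edges and volume_at_or_above must be matching 1-D arrays")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("dose_edges must be strictly increasing")
        if np.any(np.diff(vols) > 1e-12):
            raise ValueError("volume_at_or_above must be non-increasing")
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume_at_or_above", vols)
        object.__setattr__(self, "total_volume_cc", float(self.total_volume_cc))

    def differential(self) -> tuple[np.ndarray, np.ndarray]:
        """Differential DVH: (bin-center doses Gy, bin volumes cm^3).

        Bin i spans [edge_i, edge_{i+1}) and holds the volume dropped by
        the cumulative curve across it; any volume at or above the last
        edge is assigned to a trailing bin at the last edge. The bin
        volumes sum to the first cumulative entry exactly.
        """
        edges = self.dose_edges
        vols = self.volume_at_or_above
        centers = 0.5 * (edges[:-1] + edges[1:])
        binvol = vols[:-1] - vols[1:]
        if vols[-1] > 0:
            centers = np.append(centers, edges[-1])
            binvol = np.append(binvol, vols[-1])
        return centers, binvol

    def volume_at(self, dose_gy: float) -> float:
        """Volume (cm^3) at or above ``dose_gy``, linearly interpolated."""
        d = float(dose_gy)
        if d <= self.dose_edges[0]:
            return float(self.volume_at_or_above[0])
        if d > self.dose_edges[-1]:
            return 0.0
        return float(np.interp(d, self.dose_edges, self.volume_at_or_above))

    @classmethod
    def from_dose_levels(
        cls,
        doses_gy,
        volumes_cc,
        structure: str = "",
    ) -> "CumulativeDVH":
        """Exact step DVH from discrete (dose, volume) levels.

        Convenience for analytic piecewise-uniform structures: places a
        pair of edges tightly around every dose level so the differential
        bin centers coincide with the levels to within 5e-7 Gy.
        """
        doses = np.asarray(doses_gy, dtype=np.float64)
        vols = np.asarray(volumes_cc, dtype=np.float64)
        if doses.shape != vols.shape or doses.ndim != 1:
            raise ValueError("doses and volumes must be matching 1-D arrays")
        if np.any(vols < 0) or np.any(doses < 0):
            raise ValueError("doses and volumes must be non-negative")
        doses, inverse = np.unique(doses, return_inverse=True)
        vols = np.bincount(inverse, weights=vols)
        eps = 1e-6
        edges = [0.0]
        for d in doses:
            edges.extend([max(d - eps / 2, edges[-1] + eps / 4), d + eps / 2])
        edges = np.array(edges)
        total = vols.sum()
        cum = []
        for e in edges:
            cum.append(vols[doses >= e].sum())
        return cls(edges, np.array(cum), total_volume_cc=float(total),
                   structure=structure)


def cumulative_dvh(
    grid: DoseGrid,
    mask: StructureMask,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    structure: str | None = None,
) -> CumulativeDVH:
    """Cumulative DVH of ``grid`` over ``mask``.

    Edges run from 0 Gy to beyond the maximum structure dose in steps of
    ``bin_width_gy``; the count at each edge is exact (voxels at a dose
    equal to an edge are counted as at-or-above it).

    Raises
    ------
    ValueError
        Empty mask or non-positive bin width.
    IncongruentGridsError
        Mask not congruent with the grid.
    """
    grid.congruent_with(mask)
    if bin_width_gy <= 0:
        raise ValueError(f"bin_width_gy must be positive, got {bin_width_gy}")
    doses = grid.values[mask.voxels]
    if doses.size == 0:
        raise ValueError(f"mask {mask.name!r} is empty")
    dmax = float(doses.max())
    n_bins = int(np.ceil(dmax / bin_width_gy)) + 1
    edges = np.arange(n_bins + 1) * bin_width_gy
    doses_sorted = np.sort(doses)
    counts = doses.size - np.searchsorted(doses_sorted, edges, side="left")
    volumes = counts * mask.voxel_volume_cc
    return CumulativeDVH(
        edges, volumes, total_volume_cc=mask.volume_cc,
        structure=mask.name if structure is None else structure,
    )


def dose_at_hottest_area(
    dvh: CumulativeDVH,
    area_cm2: float,
    thickness_mm: float = 2.0,
) -> float:
    """Minimum dose (Gy) in the hottest ``area_cm2`` of a layer.

    The area is converted to a volume through the layer thickness
    (v = area x thickness / 10 cm^3) and the curve is inverted with
    linear interpolation between edges: the result is the smallest dose
    D such that at least v cm^3 receives >= D. Non-increasing in area.

    Raises
    ------
    ValueError
        If the requested volume exceeds the structure volume.
    """
    if area_cm2 <= 0 or thickness_mm <= 0:
        raise ValueError("area_cm2 and thickness_mm must be positive")
    v_request = area_cm2 * thickness_mm / 10.0
    if v_request > dvh.total_volume_cc * (1 + 1e-9):
        raise ValueError(
            f"requested {area_cm2} cm^2 x {thickness_mm} mm = {v_request:.3f} cm^3 "
            f"exceeds the structure volume {dvh.total_volume_cc:.3f} cm^3"
        )
    vols = dvh.volume_at_or_above
    edges = dvh.dose_edges
    # invert the non-increasing curve; np.interp needs ascending x
    return float(np.interp(v_request, vols[::-1], edges[::-1]))


def v40_area_map(
    grid: DoseGrid,
    shell: StructureMask,
    threshold_gy: float = 40.0,
    thickness_mm: float = 2.0,
) -> tuple[float, StructureMask]:
    """Skin area (cm^2) of a shell at or above a dose threshold, plus its mask.

    The area is the volume of shell voxels at >= ``threshold_gy`` divided
    by the layer thickness; the mask of those voxels is returned for
    visualization of the hot region on the scalp.
    """
    grid.congruent_with(shell)
    if not shell.voxels.any():
        raise ValueError(f"shell {shell.name!r} is empty")
    hot = shell.voxels & (grid.values >= threshold_gy)
    hot_mask = shell.with_voxels(hot, name=f"{shell.name}_V{threshold_gy:g}")
    area_cm2 = hot_mask.volume_cc / (thickness_mm / 10.0)
    return area_cm2, hot_mask
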