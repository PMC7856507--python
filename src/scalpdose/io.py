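"""Volumetric raster I/O (NRRD/NIfTI via SimpleITK) and table I/O.

Internal arrays are indexed (x, y, z); SimpleITK buffers are (z, y, x),
so arrays are transposed on the way in and out. DICOM RT-Dose grids can
be imported through pydicom (dose = pixel array x DoseGridScaling).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import DoseGrid, StructureMask

__all__ = [
    "read_dose_grid",
    "write_dose_grid",
    "read_structure_mask",
    "write_structure_mask",
    "read_rtdose",
    "dvh_to_csv",
    "load_reference_table",
    "REFERENCE_TABLES",
]

#: Packaged cohort metric tables (patient x scenario), one CSV each:
#: hot-spot doses D0.05cm2 / D25cm2 (Gy), superficial-layer NTCP (%),
#: and gEUD (Gy) of the 0-2 mm and 2-4 mm scalp layers.
REFERENCE_TABLES = {
    "d005cm2_gy": "cohort_d005cm2_gy.csv",
    "d25cm2_gy": "cohort_d25cm2_gy.csv",
    "ntcp_0_2_pct": "cohort_ntcp_0_2_pct.csv",
    "geud_0_2_gy": "cohort_geud_0_2_gy.csv",
    "geud_2_4_gy": "cohort_geud_2_4_gy.csv",
}

SCENARIO_COLUMNS = ["sc1", "sc2", "sc3", "sc4", "sc5"]


def _sitk():
    import SimpleITK as sitk
    return sitk


def read_dose_grid(path: str | Path) -> DoseGrid:
    """Read a dose grid from NRRD/NIfTI (any SimpleITK-readable raster)."""
    sitk = _sitk()
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    return DoseGrid(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    sitk = _sitk()
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    sitk.WriteImage(img, str(path))


def read_structure_mask(path: str | Path, name: str = "") -> StructureMask:
    """Read a binary mask (nonzero voxels are inside)."""
    sitk = _sitk()
    img = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(img).T != 0
    return StructureMask(voxels, tuple(img.GetSpacing()), tuple(img.GetOrigin()),
                         name=name or Path(path).stem)


def write_structure_mask(mask: StructureMask, path: str | Path) -> None:
    sitk = _sitk()
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.voxels.T.astype(np.uint8))
    )
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path))


def read_rtdose(path: str | Path) -> DoseGrid:
    """Import a DICOM RT-Dose grid onto the internal dose raster."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(np.float64) * scaling  # (frames, rows, cols)
    values = np.transpose(values, (2, 1, 0))  # -> (x, y, z)
    dr, dc = (float(v) for v in ds.PixelSpacing)
    offsets = [float(v) for v in getattr(ds, "GridFrameOffsetVector", [0.0, 1.0])]
    dz = abs(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, (dc, dr, dz), origin)


def dvh_to_csv(dvhs, path: str | Path) -> None:
    """Export cumulative DVHs as CSV (structure, dose_gy, volume_cc)."""
    frames = []
    for dvh in dvhs:
        frames.append(pd.DataFrame({
            "structure": dvh.structure,
            "dose_gy": dvh.dose_edges,
            "volume_cc": dvh.volume_at_or_above,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one packaged cohort metric table by short name.

    Returns a frame indexed by patient with a ``ptv_cc`` column and one
    column per scenario (``sc1`` ... ``sc5``).
    """
    try:
        filename = REFERENCE_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown table {name!r}; available: {sorted(REFERENCE_TABLES)}"
        ) from None
    ref = resources.files("scalpdose.data").joinpath(filename)
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path)
    return frame.set_index("patient")


def reference_long_table() -> pd.DataFrame:
    """All packaged metrics in long form, one row per patient x scenario.

    Columns match the synthetic cohort result table
    (``ntcp_fraction`` is the packaged percent value / 100).
    """
    tables = {k: load_reference_table(k) for k in REFERENCE_TABLES}
    rows = []
    first = tables["ntcp_0_2_pct"]
    for patient in first.index:
        for i, sc in enumerate(SCENARIO_COLUMNS, start=1):
            rows.append({
                "patient": patient,
                "scenario": i,
                "ptv_cc": first.loc[patient, "ptv_cc"],
                "d005cm2_gy": tables["d005cm2_gy"].loc[patient, sc],
                "d25cm2_gy": tables["d25cm2_gy"].loc[patient, sc],
                "geud_0_2_gy": tables["geud_0_2_gy"].loc[patient, sc],
                "geud_2_4_gy": tables["geud_2_4_gy"].loc[patient, sc],
                "ntcp_fraction": tables["ntcp_0_2_pct"].loc[patient, sc] / 100.0,
            })
    return pd.DataFrame(rows)
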