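"""Tristimulus, chromaticity and CIELAB computation from spectra.

The colour-matching-function table is a parameter everywhere: the bundled
default is the 2-degree cone-fundamental-based CMF reconstruction shipped
with the package, and user-supplied tables (e.g. for other field sizes) are
read from the same CSV dialect (columns wavelength_nm, xbar, ybar, zbar).
All colorimetry is relative: tristimulus values are normalized so the flat
equal-energy white at 100% output has Y = 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import Spectrum, WavelengthGrid, resample
from .errors import FormatError, GridError, UndefinedChromaticityError

__all__ = [
    "CMFTable",
    "TristimulusValues",
    "ChromaticityPoint",
    "LabColor",
    "load_standard_cmfs",
    "load_cmfs_csv",
    "xyz_from_spectrum",
    "xy_from_xyz",
    "lab_from_xyz",
    "delta_lab",
]


@dataclass(frozen=True)
class CMFTable:
    """Colour-matching functions xbar, ybar, zbar on one grid."""

    grid: WavelengthGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    field_size_deg: float = 2.0
    provenance: str = ""

    def __post_init__(self):
        for name in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.grid.n_samples,):
                raise ValueError(f"{name}: wrong length for grid")
            if np.any(v < 0):
                raise ValueError(f"{name}: CMFs must be non-negative")
            object.__setattr__(self, name, v)

    def as_matrix(self) -> np.ndarray:
        return np.vstack([self.xbar, self.ybar, self.zbar])

    def on_grid(self, grid: WavelengthGrid) -> "CMFTable":
        if grid == self.grid:
            return self
        cols = []
        for v in (self.xbar, self.ybar, self.zbar):
            carrier = Spectrum(self.grid, np.asarray(v))
            cols.append(resample(carrier, grid).values)
        return CMFTable(grid, *cols, field_size_deg=self.field_size_deg,
                        provenance=self.provenance)


@dataclass(frozen=True)
class TristimulusValues:
    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class ChromaticityPoint:
    x: float
    y: float


@dataclass(frozen=True)
class LabColor:
    L_star: float
    a_star: float
    b_star: float
    white_reference: TristimulusValues

    def as_array(self) -> np.ndarray:
        return np.array([self.L_star, self.a_star, self.b_star])


def load_cmfs_csv(path, field_size_deg: float = 2.0) -> CMFTable:
    """Read a CMF table CSV (wavelength_nm, xbar, ybar, zbar)."""
    df = pd.read_csv(path)
    required = ["wavelength_nm", "xbar", "ybar", "zbar"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"{path}: expected columns {required}, got {list(df.columns)}")
    grid = WavelengthGrid.infer(df["wavelength_nm"].to_numpy())
    return CMFTable(
        grid,
        df["xbar"].to_numpy(float),
        df["ybar"].to_numpy(float),
        df["zbar"].to_numpy(float),
        field_size_deg=field_size_deg,
        provenance=str(path),
    )


def load_standard_cmfs(grid: WavelengthGrid | None = None) -> CMFTable:
    """The bundled 2-degree cone-fundamental CMF reconstruction."""
    ref = resources.files("melamet").joinpath("data", "xyz_cmf_2deg_synthetic.csv")
    with resources.as_file(ref) as path:
        table = load_cmfs_csv(path, field_size_deg=2.0)
    table = CMFTable(
        table.grid, table.xbar, table.ybar, table.zbar, 2.0,
        provenance="bundled synthetic cone-fundamental CMFs (see data README)",
    )
    return table.on_grid(grid) if grid is not None else table


def xyz_from_spectrum(p: Spectrum, cmf: CMFTable) -> TristimulusValues:
    """Tristimulus integration, normalized so flat-100 white gives Y = 100."""
    table = cmf.on_grid(p.grid) if cmf.grid != p.grid else cmf
    if table.grid != p.grid:
        raise GridError("could not reconcile spectrum and CMF grids")
    M = table.as_matrix()
    pw = np.full(p.grid.n_samples, 100.0)
    k = 100.0 / float(table.ybar @ pw)  # step cancels against the numerator
    X, Y, Z = k * (M @ p.values)
    return TristimulusValues(float(X), float(Y), float(Z))


def xy_from_xyz(t: TristimulusValues) -> ChromaticityPoint:
    total = t.X + t.Y + t.Z
    if total <= 0:
        raise UndefinedChromaticityError("X + Y + Z must be positive")
    return ChromaticityPoint(t.X / total, t.Y / total)


_DELTA = (6.0 / 29.0) ** 3


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA, np.cbrt(t), t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)


def lab_from_xyz(t: TristimulusValues, white: TristimulusValues) -> LabColor:
    """Standard CIELAB transform against the given reference white."""
    if min(white.X, white.Y, white.Z) <= 0:
        raise ValueError("reference white must have strictly positive components")
    fx, fy, fz = _lab_f(t.as_array() / white.as_array())
    return LabColor(
        L_star=116.0 * fy - 16.0,
        a_star=500.0 * (fx - fy),
        b_star=200.0 * (fy - fz),
        white_reference=white,
    )


def delta_lab(p1: Spectrum, p2: Spectrum, cmf: CMFTable,
              white: TristimulusValues | None = None) -> float:
    """Euclidean CIELAB distance between two spectra.

    The default white reference is the flat equal-energy spectrum at 100,
    pushed through the same CMF table.
    """
    if white is None:
        white = xyz_from_spectrum(Spectrum.flat(p1.grid), cmf)
    lab1 = lab_from_xyz(xyz_from_spectrum(p1, cmf), white)
    lab2 = lab_from_xyz(xyz_from_spectrum(p2, cmf), white)
    return float(np.linalg.norm(lab1.as_array() - lab2.as_array()))
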