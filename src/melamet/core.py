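"""Wavelength grids, sampled spectral functions and spectra CSV I/O.

Everything downstream — observers, the orthogonal basis, the gamut scan —
reduces to vectors sampled on a uniform wavelength grid and rectangle-rule
inner products between them.  Spectra are stored in percent-of-maximum-output
units (the reference "flat white" is 100 at every wavelength); sensitivity
functions are peak-normalized relative sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, GridError, RangeError, SpectrumValidationError

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SensitivityFunction",
    "DEFAULT_GRID",
    "resample",
    "inner_product",
    "read_spectra_csv",
    "write_spectra_csv",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid [start, stop] nm with spacing ``step`` nm."""

    start: float = 380.0
    stop: float = 780.0
    step: float = 5.0

    def __post_init__(self):
        if not self.start < self.stop:
            raise ValueError(f"start ({self.start}) must be < stop ({self.stop})")
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"(stop - start) = {self.stop - self.start} is not an integer "
                f"multiple of step = {self.step}"
            )

    @property
    def n_samples(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_samples)

    def covers(self, other: "WavelengthGrid") -> bool:
        return self.start <= other.start and self.stop >= other.stop

    @classmethod
    def from_string(cls, text: str) -> "WavelengthGrid":
        """Parse a ``start:stop:step`` string, e.g. ``380:780:5``."""
        try:
            start, stop, step = (float(tok) for tok in text.split(":"))
        except ValueError as exc:
            raise ValueError(f"cannot parse grid spec {text!r}") from exc
        return cls(start, stop, step)

    @classmethod
    def infer(cls, wavelengths: np.ndarray, atol: float = 1e-6) -> "WavelengthGrid":
        """Infer a uniform grid from a wavelength vector; error if non-uniform."""
        wl = np.asarray(wavelengths, dtype=float)
        if wl.size < 2:
            raise FormatError("need at least two wavelengths to infer a grid")
        diffs = np.diff(wl)
        step = diffs[0]
        if np.any(np.abs(diffs - step) > atol):
            bad = int(np.argmax(np.abs(diffs - step))) + 1
            raise FormatError(
                f"non-uniform wavelength column: spacing changes at row {bad} "
                f"(wavelength {wl[bad]} nm)"
            )
        return cls(float(wl[0]), float(wl[-1]), float(step))


DEFAULT_GRID = WavelengthGrid(380.0, 780.0, 5.0)


def _validate_sampled(grid: WavelengthGrid, values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size != grid.n_samples:
        raise SpectrumValidationError(
            f"{what}: expected {grid.n_samples} values on {grid}, got shape {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise SpectrumValidationError(f"{what}: non-finite values present")
    if np.any(values < 0):
        idx = np.where(values < 0)[0]
        wl = grid.wavelengths[idx]
        raise SpectrumValidationError(
            f"{what}: negative values at wavelengths {wl[:5].tolist()} nm"
            + (" ..." if idx.size > 5 else "")
        )
    return values


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral power distribution in percent-of-max-output units."""

    grid: WavelengthGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", _validate_sampled(self.grid, self.values, "Spectrum"))

    @classmethod
    def flat(cls, grid: WavelengthGrid = DEFAULT_GRID, level: float = 100.0,
             label: str = "flat") -> "Spectrum":
        """Equal-energy spectrum at a constant level (level=100 is the reference white)."""
        return cls(grid, np.full(grid.n_samples, float(level)), label)

    def scaled(self, k: float) -> "Spectrum":
        return replace(self, values=self.values * k)


@dataclass(frozen=True)
class SensitivityFunction:
    """A relative spectral sensitivity, conventionally peak-normalized to 1."""

    grid: WavelengthGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "values", _validate_sampled(self.grid, self.values, f"SensitivityFunction {self.name!r}")
        )

    def normalized(self) -> "SensitivityFunction":
        peak = self.values.max()
        if peak <= 0:
            raise SpectrumValidationError(f"sensitivity {self.name!r} is identically zero")
        return replace(self, values=self.values / peak)


def resample(fn, grid: WavelengthGrid):
    """Linearly interpolate a Spectrum or SensitivityFunction onto ``grid``.

    The source grid must cover the target range; values are clipped at zero
    from below (interpolation of non-negative data is non-negative anyway,
    the clip guards against round-off).  Returns a new object of the same
    type; the input is unmodified.
    """
    src = fn.grid
    if not src.covers(grid):
        raise RangeError(
            f"target range [{grid.start}, {grid.stop}] nm outside source "
            f"range [{src.start}, {src.stop}] nm"
        )
    if src == grid:
        return fn
    new_values = np.interp(grid.wavelengths, src.wavelengths, fn.values)
    return replace(fn, grid=grid, values=np.clip(new_values, 0.0, None))


def _coerce_values(a, grid: WavelengthGrid | None):
    if hasattr(a, "grid"):
        return a.grid, np.asarray(a.values, dtype=float)
    if grid is None:
        raise GridError("raw arrays require an explicit grid")
    return grid, np.asarray(a, dtype=float)


def inner_product(a, b, grid: WavelengthGrid | None = None) -> float:
    """Rectangle-rule inner product  Σ a(λk)·b(λk)·step.

    ``a`` and ``b`` may be Spectrum/SensitivityFunction objects (their grids
    must match) or raw arrays together with an explicit ``grid``.
    """
    ga, va = _coerce_values(a, grid)
    gb, vb = _coerce_values(b, grid)
    if ga != gb:
        raise GridError(f"grid mismatch: {ga} vs {gb}")
    if va.shape != vb.shape:
        raise GridError(f"length mismatch: {va.shape} vs {vb.shape}")
    return float(va @ vb) * ga.step


# ---------------------------------------------------------------------------
# Spectra CSV dialect: first column `wavelength_nm`, one column per spectrum.

WAVELENGTH_COLUMN = "wavelength_nm"


def read_spectra_csv(path, cls=Spectrum) -> list:
    """Read spectra (or sensitivities, with ``cls=SensitivityFunction``)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.columns[0] != WAVELENGTH_COLUMN:
        raise FormatError(
            f"{path}: first column must be {WAVELENGTH_COLUMN!r}, got {df.columns[0]!r}"
        )
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no spectrum columns present")
    if df.isna().any().any():
        row, col = next(
            (int(i), str(c)) for c in df.columns for i in df.index[df[c].isna()]
        )
        raise FormatError(f"{path}: missing cell at data row {row}, column {col!r}")
    grid = WavelengthGrid.infer(df[WAVELENGTH_COLUMN].to_numpy())
    out = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            rows = np.where(vals < 0)[0][:5].tolist()
            raise SpectrumValidationError(
                f"{path}: negative values in column {col!r} at data rows {rows}"
            )
        kw = {"label": str(col)} if cls is Spectrum else {"name": str(col)}
        out.append(cls(grid, vals, **kw))
    return out


def write_spectra_csv(spectra, path) -> None:
    """Write spectra sharing one grid to a CSV in the spectra dialect."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise GridError("all spectra must share one grid")
    data = {WAVELENGTH_COLUMN: grid.wavelengths}
    for i, s in enumerate(spectra):
        name = getattr(s, "label", "") or getattr(s, "name", "") or f"spectrum_{i}"
        base, k = name, 1
        while name in data:
            k += 1
            name = f"{base}_{k}"
        data[name] = s.values
    pd.DataFrame(data).to_csv(path, index=False)
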