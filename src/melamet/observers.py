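"""Five-photoreceptor observers and relative excitation computation.

An observer is an ordered set of peak-normalized spectral sensitivities on a
shared wavelength grid — for the standard observer: L-cone, M-cone, S-cone,
rod, ipRGC (melanopsin), in that fixed order.  Excitations of a spectrum are
expressed in percent of the excitation produced by the flat equal-energy
white at 100% output (the "flat white" convention): every receptor responds
100 to the flat white by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core import (
    DEFAULT_GRID,
    SensitivityFunction,
    Spectrum,
    WavelengthGrid,
    inner_product,
    read_spectra_csv,
    resample,
)
from .errors import DegeneracyError, GridError, RangeError
from .templates import pigment_template

__all__ = [
    "PhotoreceptorSet",
    "ExcitationVector",
    "RECEPTOR_ORDER",
    "load_standard_observer",
    "synthetic_observer",
    "excitations_percent",
]

RECEPTOR_ORDER = ("L", "M", "S", "rod", "ipRGC")

#: Gram-matrix condition number above which a sensitivity set is rejected.
GRAM_CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class PhotoreceptorSet:
    """An ordered, linearly independent set of sensitivities on one grid."""

    sensitivities: tuple
    provenance: str = ""

    def __post_init__(self):
        sens = tuple(self.sensitivities)
        if len(sens) < 2:
            raise ValueError("need at least two sensitivity functions")
        grid = sens[0].grid
        for s in sens[1:]:
            if s.grid != grid:
                raise GridError("all sensitivities must share one grid")
        object.__setattr__(self, "sensitivities", sens)
        cond = np.linalg.cond(self.gram_matrix())
        if not np.isfinite(cond) or cond > GRAM_CONDITION_LIMIT:
            raise DegeneracyError(
                f"sensitivity set is near-linearly-dependent "
                f"(Gram condition number {cond:.3g})"
            )

    @property
    def grid(self) -> WavelengthGrid:
        return self.sensitivities[0].grid

    @property
    def names(self) -> tuple:
        return tuple(s.name for s in self.sensitivities)

    def __len__(self) -> int:
        return len(self.sensitivities)

    def as_matrix(self) -> np.ndarray:
        """Sensitivities stacked as rows, shape (n_receptors, n_wavelengths)."""
        return np.vstack([s.values for s in self.sensitivities])

    def gram_matrix(self) -> np.ndarray:
        S = self.as_matrix()
        return (S @ S.T) * self.grid.step


@dataclass(frozen=True)
class ExcitationVector:
    """Relative excitations (percent of flat white) for the five receptors."""

    L: float
    M: float
    S: float
    R: float
    I: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.M, self.S, self.R, self.I])

    @classmethod
    def from_array(cls, arr) -> "ExcitationVector":
        L, M, S, R, I = (float(v) for v in arr)
        return cls(L, M, S, R, I)


_DATA_FILES = (
    ("lms_cone_fundamentals_2deg_synthetic.csv", ("L", "M", "S")),
    ("rod_scotopic.csv", ("rod",)),
    ("melanopic_synthetic.csv", ("ipRGC",)),
)


def _load_bundled(filename: str) -> list:
    ref = resources.files("melamet").joinpath("data", filename)
    with resources.as_file(ref) as path:
        return read_spectra_csv(path, cls=SensitivityFunction)


def load_standard_observer(grid: WavelengthGrid = DEFAULT_GRID) -> PhotoreceptorSet:
    """The bundled five-receptor standard observer, resampled to ``grid``.

    The bundled tables are synthetic reconstructions of the standard 2-degree
    cone fundamentals, the scotopic rod curve and the melanopic sensitivity
    (see the data README); they are stored at 1 nm and linearly resampled.
    """
    if grid.start < 380.0 or grid.stop > 780.0:
        raise RangeError(
            f"standard observer tables cover 380-780 nm; requested "
            f"[{grid.start}, {grid.stop}] nm"
        )
    sens = []
    for filename, names in _DATA_FILES:
        loaded = {s.name: s for s in _load_bundled(filename)}
        for name in names:
            sens.append(resample(loaded[name], grid).normalized())
    return PhotoreceptorSet(
        tuple(sens),
        provenance="synthetic reconstruction of the 2-degree standard observer "
        "(pigment templates + scotopic table); see melamet/data/README.md",
    )


def synthetic_observer(
    n_receptors: int,
    peak_wavelengths,
    bandwidths=None,
    seed: int = 0,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> PhotoreceptorSet:
    """Smooth unimodal synthetic sensitivities for testing the metamer math.

    Each curve is log-normal-shaped, exp(-(ln(lambda/peak)/width)^2 / 2),
    which mimics the asymmetry of real photoreceptor curves.  ``bandwidths``
    are dimensionless log-widths (a realistic value is 0.05-0.15); if omitted
    they are drawn uniformly from [0.06, 0.12] with the given ``seed``, so
    the observer is deterministic for a fixed seed.
    """
    if not 2 <= n_receptors <= 8:
        raise ValueError("n_receptors must be between 2 and 8")
    peaks = [float(p) for p in peak_wavelengths]
    if len(peaks) != n_receptors:
        raise ValueError("need one peak wavelength per receptor")
    lam = grid.wavelengths
    for p in peaks:
        if not lam[0] <= p <= lam[-1]:
            raise ValueError(f"peak {p} nm outside grid range")
    if bandwidths is None:
        rng = np.random.default_rng(seed)
        bandwidths = rng.uniform(0.06, 0.12, size=n_receptors)
    widths = [float(b) for b in bandwidths]
    if len(widths) != n_receptors:
        raise ValueError("need one bandwidth per receptor")
    sens = []
    for k, (peak, width) in enumerate(zip(peaks, widths)):
        v = np.exp(-0.5 * (np.log(lam / peak) / width) ** 2)
        sens.append(SensitivityFunction(grid, v / v.max(), name=f"syn{k}"))
    return PhotoreceptorSet(tuple(sens), provenance=f"synthetic(seed={seed})")


def excitations_percent(p: Spectrum, obs: PhotoreceptorSet):
    """Excitations of ``p`` in percent of the flat-100 white, per receptor.

    Component k equals 100 * <p, s_k> / <p_w, s_k> with p_w the flat white.
    Returns an ExcitationVector for five-receptor observers, else an ndarray.
    """
    if p.grid != obs.grid:
        raise GridError(f"spectrum grid {p.grid} != observer grid {obs.grid}")
    S = obs.as_matrix()
    pw = np.full(obs.grid.n_samples, 100.0)
    vals = 100.0 * (S @ p.values) / (S @ pw)
    if len(obs) == 5:
        return ExcitationVector.from_array(vals)
    return vals
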