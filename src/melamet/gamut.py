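"""Chromaticity-gamut scan of the feasible ipRGC modulation width.

For each xy chromaticity cell the scan solves a linear program: maximize the
ipRGC excitation difference between two spectra in the five-sensitivity span
that share cone and rod coefficients, respect the per-wavelength output
bounds, and whose chromaticity equals the cell's (x, y).  Cells are
classified into 1-percentage-point bands of modulation width, and stimulus
points for discrimination experiments are picked along hue directions in
a*b* space, from the white point outward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .colorimetry import (
    CMFTable,
    TristimulusValues,
    lab_from_xyz,
    xyz_from_spectrum,
)
from .core import Spectrum
from .engine import OrthogonalBasis, build_basis, _run_linprog
from .observers import PhotoreceptorSet

__all__ = [
    "GamutCell",
    "StimulusPointSet",
    "GamutScanner",
    "scan_gamut",
    "max_width_at",
    "classify_bands",
    "band_counts",
    "select_stimulus_points",
    "plot_gamut",
]

#: luminance (flat-white Y units) below which a cell counts as unreachable
_FEASIBLE_Y_TOL = 1e-6


@dataclass(frozen=True)
class GamutCell:
    x: float
    y: float
    feasible: bool
    max_width: float
    band: int = -1


@dataclass(frozen=True)
class StimulusPointSet:
    """Per hue group: up to four (cell, target width) selections."""

    groups: dict
    hue_angles: tuple
    targets: tuple


class GamutScanner:
    """Precomputed LP matrices for repeated per-chromaticity solves.

    The pair is parameterized as p1 = sum w_i e_i + a e5 and
    p2 = sum w_i e_i + b e5 (shared w1..w4, so cone and rod excitations
    match automatically); chromaticity equality constraints are applied to
    p1, and also to p2 when the CMF table is not a linear transform of the
    cone fundamentals.
    """

    def __init__(self, obs: PhotoreceptorSet, cmf: CMFTable, cap: float = 100.0,
                 basis: OrthogonalBasis | None = None):
        self.basis = basis if basis is not None else build_basis(obs)
        self.cmf = cmf.on_grid(self.basis.grid)
        self.cap = float(cap)
        n = self.basis.n
        nwl = self.basis.grid.n_samples
        E = self.basis.vectors
        ns = n - 1
        M = self.cmf.as_matrix()
        pw = np.full(nwl, 100.0)
        xyz_rows = 100.0 * M / float(self.cmf.ybar @ pw)
        self._A1 = np.hstack([E[:ns].T, E[ns:].T, np.zeros((nwl, 1))])
        self._A2 = np.hstack([E[:ns].T, np.zeros((nwl, 1)), E[ns:].T])
        self._A_box = np.vstack([self._A1, -self._A1, self._A2, -self._A2])
        self._b_box = np.concatenate([np.full(nwl, cap), np.zeros(nwl)] * 2)
        self._XYZ1 = xyz_rows @ self._A1
        self._XYZ2 = xyz_rows @ self._A2
        t_last = float(self.basis.excitation_matrix[ns, n - 1])
        self._c_width = np.zeros(ns + 2)
        self._c_width[ns] = -t_last
        self._c_width[ns + 1] = t_last
        self._c_lum = -self._XYZ1[1]
        self._constrain_both = not self._cmf_in_cone_span()
        self.locus = self._spectral_locus_path()

    def _spectral_locus_path(self) -> MplPath:
        M = self.cmf.as_matrix()
        totals = M.sum(axis=0)
        keep = totals > 1e-12 * totals.max()
        pts = (M[:2, keep] / totals[keep]).T
        return MplPath(np.vstack([pts, pts[0]]))

    def _cmf_in_cone_span(self, rtol: float = 1e-5) -> bool:
        cones = self.basis.observer.as_matrix()[:3]
        Q, _ = np.linalg.qr(cones.T)
        M = self.cmf.as_matrix()
        resid = M.T - Q @ (Q.T @ M.T)
        return bool(np.linalg.norm(resid) <= rtol * np.linalg.norm(M))

    def cell(self, x: float, y: float) -> GamutCell:
        """Solve the feasibility and width LPs for one chromaticity."""
        if not self.locus.contains_point((x, y), radius=1e-9):
            return GamutCell(float(x), float(y), False, 0.0)
        rows = [
            self._XYZ1[0] - x * self._XYZ1.sum(axis=0),
            self._XYZ1[1] - y * self._XYZ1.sum(axis=0),
        ]
        if self._constrain_both:
            rows += [
                self._XYZ2[0] - x * self._XYZ2.sum(axis=0),
                self._XYZ2[1] - y * self._XYZ2.sum(axis=0),
            ]
        A_eq = np.vstack(rows)
        b_eq = np.zeros(A_eq.shape[0])
        feas = _run_linprog(self._c_lum, self._A_box, self._b_box, A_eq, b_eq)
        if feas.status != 0 or -feas.fun < _FEASIBLE_Y_TOL:
            return GamutCell(float(x), float(y), False, 0.0)
        res = _run_linprog(self._c_width, self._A_box, self._b_box, A_eq, b_eq)
        if res.status != 0:
            return GamutCell(float(x), float(y), False, 0.0)
        return GamutCell(float(x), float(y), True, max(0.0, -res.fun))


def scan_gamut(obs: PhotoreceptorSet, cmf: CMFTable, resolution: float = 0.005,
               cap: float = 100.0, x_range=(0.0, 0.8), y_range=(0.0, 0.9)) -> list:
    """Scan xy space; per cell, the maximal metameric ipRGC width.

    Candidate cells are the regular grid of pitch ``resolution`` inside the
    spectral locus polygon of the CMF table; LP failures mark cells
    infeasible rather than aborting the scan.  Output is row-major in x then
    y, deterministically.
    """
    if not 0.001 < resolution < 0.05:
        raise ValueError("resolution must lie in (0.001, 0.05)")
    scanner = GamutScanner(obs, cmf, cap)
    xs = np.round(np.arange(x_range[0], x_range[1] + resolution / 2, resolution), 10)
    ys = np.round(np.arange(y_range[0], y_range[1] + resolution / 2, resolution), 10)
    return [scanner.cell(float(x), float(y)) for x in xs for y in ys]


def max_width_at(obs: PhotoreceptorSet, cmf: CMFTable, x: float, y: float,
                 cap: float = 100.0) -> GamutCell:
    """Single-chromaticity version of the scan (re-solves the LPs)."""
    return GamutScanner(obs, cmf, cap).cell(x, y)


def classify_bands(cells) -> list:
    """Assign half-open 1%-wide band labels: band = floor(width), clipped to [0, 4]."""
    out = []
    for c in cells:
        band = int(np.clip(np.floor(c.max_width), 0, 4)) if c.feasible else -1
        out.append(GamutCell(c.x, c.y, c.feasible, c.max_width, band))
    return out


def band_counts(cells) -> dict:
    counts: dict = {}
    for c in cells:
        if c.feasible:
            counts[c.band] = counts.get(c.band, 0) + 1
    return counts


def _cell_ab(cell: GamutCell, white: TristimulusValues, Y: float = 50.0):
    """a*, b* of a cell's chromaticity at a fixed probe luminance."""
    if cell.y <= 0:
        return 0.0, 0.0
    X = cell.x * Y / cell.y
    Z = (1.0 - cell.x - cell.y) * Y / cell.y
    lab = lab_from_xyz(TristimulusValues(X, Y, Z), white)
    return lab.a_star, lab.b_star


def select_stimulus_points(cells, cmf: CMFTable,
                           hue_angles=(0.0, 60.0, 120.0, 180.0, 240.0, 300.0),
                           targets=(1.0, 2.0, 3.0, 4.0),
                           angle_tolerance_deg: float = 20.0) -> StimulusPointSet:
    """Pick, per hue direction, the most saturated cell supporting each width.

    For each hue angle (degrees in a*b*) and each target width, the most
    chromatic feasible cell within the angular tolerance whose max_width
    meets the target is selected; unreachable targets are recorded as None
    (the modulation gamut is not symmetric across hues).
    """
    feas = [c for c in cells if c.feasible]
    if not feas:
        raise ValueError("no feasible cells to select from")
    white = xyz_from_spectrum(Spectrum.flat(cmf.grid), cmf)
    ab = np.array([_cell_ab(c, white) for c in feas])
    chroma = np.hypot(ab[:, 0], ab[:, 1])
    hue = np.degrees(np.arctan2(ab[:, 1], ab[:, 0]))
    widths = np.array([c.max_width for c in feas])
    groups = {}
    for angle in hue_angles:
        diff = (hue - angle + 180.0) % 360.0 - 180.0
        in_wedge = np.abs(diff) <= angle_tolerance_deg
        picks = []
        for t in targets:
            ok = in_wedge & (widths >= t)
            if not np.any(ok):
                picks.append(None)
                continue
            idx = np.flatnonzero(ok)
            best = idx[np.argmax(chroma[idx])]
            picks.append((feas[best], float(t)))
        groups[float(angle)] = picks
    return StimulusPointSet(groups=groups, hue_angles=tuple(hue_angles),
                            targets=tuple(targets))


def plot_gamut(cells, path=None, ax=None):
    """Scatter the scanned cells coloured by modulation-width band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {0: "lightblue", 1: "gold", 2: "green", 3: "blue", 4: "red"}
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for band, color in colors.items():
        pts = [(c.x, c.y) for c in cells if c.feasible and c.band == band]
        if pts:
            arr = np.array(pts)
            ax.scatter(arr[:, 0], arr[:, 1], s=4, c=color,
                       label=f"{band}-{band + 1}%" if band < 4 else ">=4%")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("metameric ipRGC modulation width")
    if path is not None:
        ax.figure.savefig(path, dpi=150)
    return ax
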