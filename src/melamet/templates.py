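"""Physiological spectral templates used to build the bundled observer tables.

The bundled standard-observer tables shipped in ``melamet/data`` are synthetic
reconstructions of the standard colorimetric curves, assembled from three
published building blocks:

* the Govardovskii et al. (2000) A1 visual-pigment nomogram (alpha + beta
  band) for the photopigment absorbance spectra,
* self-screening at standard axial optical densities and pre-receptoral
  filtering by lens and macular pigment (anchor tables interpolated with a
  shape-preserving monotone cubic),
* the CIE 1951 scotopic luminosity function V'(lambda), transcribed at 10 nm
  and interpolated in log space, which serves directly as the rod curve.

See ``melamet/data/README.md`` for provenance and accuracy caveats.  These
functions are also useful on their own for constructing realistic synthetic
observers.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "pigment_template",
    "pigment_absorptance",
    "scotopic_luminosity",
    "lens_density",
    "macular_density",
]


def pigment_template(wavelengths, peak_nm: float) -> np.ndarray:
    """Govardovskii A1 pigment absorbance template (quantal, peak = 1).

    Sum of the alpha band (a three-exponential sigmoid in x = peak/lambda)
    and the Gaussian beta band whose position and width track the alpha peak.
    """
    lam = np.asarray(wavelengths, dtype=float)
    x = peak_nm / lam
    a = 0.8795 + 0.0459 * np.exp(-((peak_nm - 300.0) ** 2) / 11940.0)
    alpha_band = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    beta_peak = 189.0 + 0.315 * peak_nm
    beta_width = -40.5 + 0.195 * beta_peak
    beta_band = 0.26 * np.exp(-(((lam - beta_peak) / beta_width) ** 2))
    return np.clip(alpha_band + beta_band, 0.0, None)


def pigment_absorptance(wavelengths, peak_nm: float, density: float) -> np.ndarray:
    """Axial absorptance 1 - 10^(-D * template): self-screening broadens the curve."""
    return 1.0 - 10.0 ** (-density * pigment_template(wavelengths, peak_nm))


# CIE 1951 scotopic luminosity V'(lambda), 10 nm table (peak 507 nm).
_SCOTOPIC_10NM = {
    380: 0.000589, 390: 0.002209, 400: 0.00929, 410: 0.03484, 420: 0.0966,
    430: 0.1998, 440: 0.3281, 450: 0.455, 460: 0.567, 470: 0.676,
    480: 0.793, 490: 0.904, 500: 0.982, 510: 0.997, 520: 0.935,
    530: 0.811, 540: 0.650, 550: 0.481, 560: 0.3288, 570: 0.2076,
    580: 0.1212, 590: 0.0655, 600: 0.03315, 610: 0.01593, 620: 0.00737,
    630: 0.003335, 640: 0.001497, 650: 0.000677, 660: 0.0003129,
    670: 0.0001480, 680: 0.0000715, 690: 0.00003533, 700: 0.00001780,
    710: 0.00000914, 720: 0.00000478, 730: 0.000002546, 740: 0.000001379,
    750: 0.000000760, 760: 0.000000425, 770: 0.000000241, 780: 0.000000139,
}


def scotopic_luminosity(wavelengths) -> np.ndarray:
    """V'(lambda) interpolated in log space from the 10 nm standard table."""
    xs = np.array(sorted(_SCOTOPIC_10NM), dtype=float)
    ys = np.log([_SCOTOPIC_10NM[int(x)] for x in xs])
    return np.exp(PchipInterpolator(xs, ys)(np.asarray(wavelengths, dtype=float)))


# Ocular media (lens et al.) optical density anchors, standard adult observer.
_LENS_ANCHORS = {
    380: 2.41, 390: 2.10, 400: 1.7649, 410: 1.258, 420: 0.8881, 430: 0.650,
    440: 0.512, 450: 0.410, 460: 0.3345, 470: 0.272, 480: 0.2197, 490: 0.1767,
    500: 0.1415, 510: 0.113, 520: 0.0885, 530: 0.068, 540: 0.0515, 550: 0.038,
    560: 0.028, 570: 0.021, 580: 0.0155, 590: 0.011, 600: 0.008, 610: 0.0062,
    620: 0.004, 630: 0.003, 640: 0.002, 650: 0.001, 660: 0.0006, 670: 0.0003,
    680: 0.0001, 690: 0.0, 780: 0.0,
}

# Macular pigment density relative to its 460 nm peak (2-degree field).
_MACULAR_ANCHORS = {
    380: 0.22, 390: 0.26, 400: 0.33, 410: 0.40, 420: 0.61, 430: 0.82,
    440: 0.94, 450: 0.95, 460: 1.00, 470: 0.93, 480: 0.73, 490: 0.51,
    500: 0.34, 510: 0.20, 520: 0.095, 530: 0.04, 540: 0.01, 550: 0.0,
    560: 0.0, 780: 0.0,
}


def _anchored(anchors, wavelengths, scale):
    xs = np.array(sorted(anchors), dtype=float)
    ys = np.array([anchors[int(x)] for x in xs])
    vals = PchipInterpolator(xs, ys)(np.asarray(wavelengths, dtype=float))
    return scale * np.clip(vals, 0.0, None)


def lens_density(wavelengths, scale: float = 1.0) -> np.ndarray:
    """Lens/ocular-media optical density (anchor table, pchip-interpolated)."""
    return _anchored(_LENS_ANCHORS, wavelengths, scale)


def macular_density(wavelengths, peak_density: float = 0.35) -> np.ndarray:
    """Macular pigment optical density scaled to ``peak_density`` at 460 nm."""
    return _anchored(_MACULAR_ANCHORS, wavelengths, peak_density)
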