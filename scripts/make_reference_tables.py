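"""Regenerate the bundled observer tables in src/melamet/data/.

The tables are synthetic reconstructions of the standard colorimetric curves
(see melamet/data/README.md).  This script is deterministic; re-running it
reproduces the shipped CSVs bit-for-bit.

Construction, frozen for this release:

* L, M, S cone fundamentals: Govardovskii A1 pigment templates at
  lambda_max = 558.9 / 530.3 / 420.7 nm with axial densities 0.50 / 0.50 /
  0.40, filtered by the lens anchor table and macular pigment at peak density
  0.35, converted to energy units (x lambda) and peak-normalized.
* rod: the transcribed CIE 1951 scotopic table, peak-normalized.
* melanopic (ipRGC): pigment template at lambda_max = 476 nm (no
  self-screening, no macular), lens-filtered, energy units, peak-normalized.
  The 476 nm value was selected from the 470-485 nm range reported for human
  melanopsin by agreement of the resulting orthogonalization coefficients
  with the published ones (see docs/methods.md).
* XYZ colour-matching functions: the fixed cone-fundamental-to-XYZ linear
  transform applied to the reconstructed L, M, S curves.  With the
  reconstructed (rather than official) fundamentals the standard transform
  leaves a small negative lobe in xbar near 500 nm; the M-cone coefficient
  of the xbar row is shrunk by the minimal factor that restores
  non-negativity, so the bundled CMFs remain an exact linear transform of
  the bundled fundamentals (several colorimetric identities rely on that).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from melamet.templates import (
    lens_density,
    macular_density,
    pigment_absorptance,
    pigment_template,
    scotopic_luminosity,
)

DATA_DIR = Path(__file__).resolve().parent.parent / "src" / "melamet" / "data"

# Cone-fundamental-based XYZ transform (2-degree), rows = xbar,ybar,zbar.
LMS_TO_XYZ = np.array(
    [
        [1.94735469, -1.41445123, 0.36476327],
        [0.68990272, 0.34832189, 0.0],
        [0.0, 0.0, 1.93485343],
    ]
)

CONES = {"L": (558.9, 0.50), "M": (530.3, 0.50), "S": (420.7, 0.40)}
MEL_PEAK_NM = 476.0


def build_tables(wavelengths: np.ndarray) -> dict[str, np.ndarray]:
    lam = np.asarray(wavelengths, dtype=float)
    media_cones = 10.0 ** (-(lens_density(lam) + macular_density(lam)))
    curves = {}
    for name, (peak, density) in CONES.items():
        v = lam * pigment_absorptance(lam, peak, density) * media_cones
        curves[name] = v / v.max()
    rod = scotopic_luminosity(lam)
    curves["rod"] = rod / rod.max()
    mel = lam * pigment_template(lam, MEL_PEAK_NM) * 10.0 ** (-lens_density(lam))
    curves["ipRGC"] = mel / mel.max()
    lms = np.vstack([curves["L"], curves["M"], curves["S"]])
    M = LMS_TO_XYZ.copy()
    # shrink the negative M-cone lobe of xbar just enough for xbar >= 0
    pos = M[0, 0] * lms[0] + M[0, 2] * lms[2]
    with np.errstate(divide="ignore"):
        kappa = np.min(pos / (-M[0, 1] * lms[1]))
    M[0, 1] *= min(1.0, kappa)
    xyz = M @ lms
    assert xyz.min() >= -1e-12
    curves["xbar"], curves["ybar"], curves["zbar"] = np.clip(xyz, 0.0, None)
    return curves


def write_csv(path: Path, lam: np.ndarray, cols: dict[str, np.ndarray]) -> None:
    df = pd.DataFrame({"wavelength_nm": lam, **cols})
    df.to_csv(path, index=False, float_format="%.9g")
    print(f"wrote {path} ({path.stat().st_size} bytes)")


def main() -> None:
    lam = np.arange(380.0, 781.0, 1.0)
    c = build_tables(lam)
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    write_csv(DATA_DIR / "lms_cone_fundamentals_2deg_synthetic.csv", lam,
              {k: c[k] for k in ("L", "M", "S")})
    write_csv(DATA_DIR / "rod_scotopic.csv", lam, {"rod": c["rod"]})
    write_csv(DATA_DIR / "melanopic_synthetic.csv", lam, {"ipRGC": c["ipRGC"]})
    write_csv(DATA_DIR / "xyz_cmf_2deg_synthetic.csv", lam,
              {k: c[k] for k in ("xbar", "ybar", "zbar")})


if __name__ == "__main__":
    main()
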