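# melamet

Design and analysis of **melanopsin (ipRGC) silent-substitution metamers** —
pairs of light spectra that stimulate the L-, M-, S-cones and rods
identically while differing only in the excitation of intrinsically
photosensitive retinal ganglion cells (ipRGCs).

## The problem

ipRGCs contain the photopigment melanopsin (peak sensitivity near 490 nm)
and drive circadian entrainment, the pupil reflex, and — increasingly
evidenced — aspects of visual perception. Isolating their contribution
requires stimuli in which melanopsin excitation changes while every other
photoreceptor signal is held fixed. Because the five spectral sensitivities
overlap heavily, such stimuli must be constructed, not found: this package
builds them for a multispectral (per-wavelength programmable) light source
whose output at each wavelength spans 0–100 % of maximum.

## The method

Let l(λ), m(λ), s(λ), r(λ), i(λ) be the five sensitivities on a common
wavelength grid (380–780 nm, 5 nm by default). Gram–Schmidt
orthogonalization *in that order* yields basis functions e₁…e₅ and an
upper-triangular coefficient matrix α with unit diagonal:

    [l m s r i] = [e₁ e₂ e₃ e₄ e₅] · α .

A stimulus is synthesized as p(λ) = ω₁e₁ + … + ω₅e₅. Since e₅ is
orthogonal to the cone and rod sensitivities, the cone/rod excitations
depend only on ω₁…ω₄ while ipRGC excitation alone varies with ω₅.
Excitations are reported in percent of the flat equal-energy white at 100 %
output, e.g. I = 100·∫p·i dλ / ∫p_w·i dλ.

On top of this parameterization the package computes, by closed-form
interval intersection and small linear programs:

* the **feasible ipRGC interval** at fixed (L, M, S, R) under
  0 ≤ p(λ) ≤ 100 — and metamer pairs at any achievable ΔI;
* the **global modulation capacity** (max ΔI over all bounded pairs, with
  or without rod matching);
* the **chromaticity gamut map** of achievable ΔI over the xy diagram,
  with 1 %-wide band classification and hue-wise stimulus-point selection;
* **pentamer pairs**: maximally different spectra with *all five*
  excitations equal (perturbations in the receptor null space);
* CIELAB verification of designed pairs, and discrimination-rate analysis
  (with a synthetic response generator) for perceptual experiments.

**Bundled tables.** The standard-observer tables shipped with the package
are *synthetic reconstructions* of the standard 2° cone fundamentals,
scotopic rod curve and melanopic sensitivity, built from published
physiological templates (see `src/melamet/data/README.md` and
`docs/methods.md`). Quantities dominated by fine spectral structure carry
reconstruction error of order tens of percent; official tables can be
substituted through the same CSV interfaces for exact work.

## Worked example

```python
from melamet import (load_standard_observer, load_standard_cmfs,
                     design_metamer_pair, excitations_percent, delta_lab)
from melamet.engine import feasible_iprgc_interval

obs = load_standard_observer()              # five curves, 380-780 nm @ 5 nm
cmf = load_standard_cmfs(obs.grid)

targets = [47.9, 36.4, 5.86, 14.9]          # L, M, S, rod (% of flat white)
iv = feasible_iprgc_interval(obs, targets)
pair = design_metamer_pair(obs, targets, requested_delta="max")
print(iv.i_min, iv.i_max, pair.delta_i)
print(delta_lab(pair.spectrum_max, pair.spectrum_min, cmf))
```

Output (run on the bundled tables):

```
feasible ipRGC interval: [9.85, 11.18] %  (width 1.32)
pair excitations (max): L=47.9 M=36.4 S=5.86 R=14.9 I=11.18
pair excitations (min): L=47.9 M=36.4 S=5.86 R=14.9 I=9.85
chromaticity: x=0.505 y=0.435   dLab between members: 5.28e-09
```

The two spectra agree in all cone and rod excitations (and hence in
chromaticity: ΔLab ≈ 0 through cone-derived colour-matching functions)
while ipRGC excitation differs by 1.32 percentage points — an orange
stimulus a human observer should find indistinguishable unless ipRGCs
contribute to colour discrimination.

The same operations are available from the shell:

```
melamet metamer design --L 47.9 --M 36.4 --S 5.86 --rod 14.9 --max
melamet metamer maxrange            # global capacity, rod-matched
melamet gamut scan --resolution 0.01 --out cells.csv --plot gamut.png
melamet psycho simulate --out trials.csv && melamet psycho analyze trials.csv
```

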