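# Bundled observer tables

All four CSVs are **synthetic reconstructions** of the corresponding standard
colorimetric curves, generated deterministically by
`scripts/make_reference_tables.py` on a 380–780 nm / 1 nm grid. They are not
copies of the official standard tables, which could not be redistributed
here; expect pointwise deviations of a few percent from the official data,
concentrated at the spectral tails. Quantities that depend on fine spectral
structure (in particular the small residual of the melanopic curve outside
the span of the cone and rod curves) inherit correspondingly larger relative
errors — see `docs/methods.md` for the quantitative discussion. For exact
work, substitute official tables in the same CSV dialect via the
user-supplied-table entry points.

| file | contents | construction |
| --- | --- | --- |
| `lms_cone_fundamentals_2deg_synthetic.csv` | L, M, S cone fundamentals, 2° field, energy units, peak-normalized | Govardovskii A1 pigment templates (λmax 558.9 / 530.3 / 420.7 nm, axial densities 0.50 / 0.50 / 0.40) behind lens and macular (peak 0.35) pigment anchor tables |
| `rod_scotopic.csv` | scotopic luminosity V′(λ), peak-normalized | transcription of the standard 10 nm scotopic table, log-space monotone-cubic interpolation |
| `melanopic_synthetic.csv` | melanopsin (ipRGC) sensitivity, energy units, peak-normalized | A1 template at λmax 476 nm, no self-screening, lens-filtered |
| `xyz_cmf_2deg_synthetic.csv` | cone-fundamental-based x̄, ȳ, z̄ | fixed LMS→XYZ linear transform of the reconstructed fundamentals, clipped at 0 |

Columns follow the package spectra dialect: `wavelength_nm` first, one curve
per following column.
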