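# Methods

## Model

A stimulus is a spectral power distribution p(λ) sampled on a uniform grid
(default 380–780 nm at 5 nm; 81 samples), in percent of the light source's
maximum per-wavelength output. The observer is an ordered set of
peak-normalized sensitivities — L-cone, M-cone, S-cone, rod, ipRGC
(melanopsin) — on the same grid. Excitation of receptor k is the
rectangle-rule integral ⟨p, s_k⟩ = Σ p(λ)s_k(λ)·Δλ, expressed in percent of
the excitation produced by the flat equal-energy white p_w ≡ 100:

    E_k(p) = 100 · ⟨p, s_k⟩ / ⟨p_w, s_k⟩ .

This normalization makes every excitation of the flat white exactly 100 and
is invariant to the grid step for smooth integrands (the step cancels in
the ratio up to interpolation error; tested at 5 nm vs 1 nm, < 0.5
percentage points).

### Orthogonal basis

Classical Gram–Schmidt over (l, m, s, r, i), *in that order*, produces
basis vectors e₁…e₅. Two conventions are implemented:

* **unit_diagonal** (default): residuals are kept unnormalized, so each
  sensitivity equals its own basis vector plus projections onto earlier
  ones, and the coefficient matrix α (sensitivities = [e]·α) is upper
  triangular with exact unit diagonal, α[i][j] = ⟨s_j, e_i⟩/⟨e_i, e_i⟩.
* **unit_norm**: residuals scaled to unit norm; α carries the norms on its
  diagonal.

The published form of the coefficient matrix has unit diagonal, which is
inconsistent with unit-norm residuals; the unit-diagonal convention is
therefore the default. Every physical quantity (feasible intervals,
metamer pairs, gamut widths) depends only on span(e₁…e_k) = span(s₁…s_k)
and is convention-independent — asserted in the tests by recomputing
intervals under both conventions (agreement to 1e-8).

Excitations are always computed through the percent convention above,
never by treating α itself as the coefficient-to-excitation map: the
matrix identity E = ω·α holds only under exact orthonormality, which the
unit-diagonal convention deliberately trades away. The structural fact the
basis guarantees — and the package's tests assert to 1e-10 — is that
E_L…E_R depend only on ω₁…ω₄ while ω₅ moves E_I alone ("silencing").

### Feasible ipRGC interval and metamer pairs

Fixing targets (L, M, S, R) determines ω₁…ω₄ uniquely (the excitation map
restricted to the first four receptors is triangular). With
q = Σ₁⁴ ω_i e_i, the device constraint 0 ≤ q(λ) + ω₅e₅(λ) ≤ cap is, per
wavelength, an interval in ω₅; their intersection is closed-form and maps
affinely (increasing) to ipRGC excitation. Degenerate targets whose
interval closes to a point within float tolerance (1e-7 relative) are
reported as a zero-width interval; genuinely empty intersections return an
explicit infeasible flag. The equivalence of this closed form with the
corresponding one-variable linear program is tested on 100 random feasible
targets (1e-9).

Note that the flat white itself is *not* inside the five-dimensional
sensitivity span, so all-100 excitation targets are infeasible under
cap = 100 (the span spectrum matching them peaks near 128 % with the
bundled tables); neutral targets are feasible below roughly 78 %.

### Global capacity, gamut scan, pentamers

* **Capacity**: maximize I(p₁) − I(p₂) over pairs sharing ω₁…ω₄ (ω₁…ω₃
  when rod matching is dropped) with 0 ≤ p ≤ cap per wavelength — one
  linear program in 6 (7) variables and 4·81 inequality rows, solved with
  HiGHS. Any optimal vertex is accepted; the tested quantity is the
  optimum value, not the argmax spectrum.
* **Gamut scan**: the same LP per xy chromaticity cell, plus two
  homogeneous equalities X − x(X+Y+Z) = 0, Y − y(X+Y+Z) = 0 applied to p₁.
  Because the bundled colour-matching functions are an exact linear
  transform of the bundled cone fundamentals, XYZ depends only on ω₁…ω₃
  and p₂ automatically shares p₁'s chromaticity; for user CMFs outside the
  cone span (relative residual > 1e-5) the constraints are applied to both
  members. A cell is declared infeasible when the luminance-maximizing LP
  at its chromaticity attains ≤ 1e-6 (the zero spectrum trivially satisfies
  the homogeneous constraints, so feasibility must be probed by a separate
  objective). Candidate cells are pre-filtered by the spectral-locus
  polygon. Bands are floor(width) clipped to [0, 4] (half-open
  boundaries). Default resolution 0.005 in xy runs in minutes on one core;
  tests and the acceptance battery use 0.02 and single-cell re-solves.
* **Stimulus-point selection**: cells are given a*b* coordinates at a fixed
  probe luminance (Y = 50, flat-white reference); for each of six hue
  angles (default 0°–300° in 60° steps, configurable — the experimental
  hue groups are qualitative) and each target width 1–4 %, the most
  chromatic cell within ±20° whose width meets the target is chosen;
  unreachable targets are reported as gaps, since large modulation extends
  much further toward blue than toward red or green.
* **Pentamer pairs**: perturbations d with ⟨d, s_k⟩ = 0 for all five
  receptors live in the 76-dimensional null space of the response map.
  Maximizing the L1 difference ‖d‖₁ subject to 0 ≤ base ± d/2 ≤ cap is a
  convex *maximization* (not a single LP); it is solved by iterative sign
  linearization — fix a sign pattern σ, solve the LP max σᵀd over the
  null-space coordinates, reset σ = sign(d), iterate to a fixed point —
  with deterministic restarts from the three leading null-space directions.
  This is a monotone ascent to a local maximum; the tests assert the
  properties that matter (exactly equal excitations, strictly positive
  spectral difference for interior base spectra, zero width at the cap),
  not global optimality.

## Bundled observer tables

No official colorimetric tables are redistributed; the package ships
deterministic synthetic reconstructions (`scripts/make_reference_tables.py`,
1 nm grid, 9 significant digits):

* **Cones**: Govardovskii A1 pigment templates (α and β bands) at λmax
  558.9 / 530.3 / 420.7 nm, self-screening densities 0.50 / 0.50 / 0.40,
  filtered by lens and macular (peak 0.35) density anchor tables, converted
  to energy units and peak-normalized.
* **Rod**: a transcription of the standard scotopic table at 10 nm,
  interpolated monotonically in log space.
* **Melanopic**: A1 template, no self-screening, lens-filtered. Its λmax
  (476 nm, within the 470–485 nm range reported for human melanopsin) was
  selected — together with the lens/macular configuration — by agreement of
  the resulting α matrix with the published coefficients, the only
  quantitative arbiter available for the reconstruction; downstream
  quantities were not consulted.
* **XYZ CMFs**: the standard cone-fundamental-to-XYZ transform of the
  reconstructed cones. With reconstructed (rather than official)
  fundamentals the x̄ row acquires a small negative lobe near 500 nm; its
  M-cone coefficient is shrunk by the minimal factor restoring
  non-negativity so that the CMFs remain an exact linear transform of the
  bundled fundamentals. Several identities rely on that exactness: metamer
  pairs are colorimetric metamers (ΔLab < 1e-6), and the gamut scan's
  single-member chromaticity constraint is valid.

**Accuracy.** Nine of the ten published α entries are reproduced within
±0.05 (the rod-on-e₂ entry deviates by 0.076); the per-entry comparison is
emitted by the acceptance test. Quantities governed by the coarse shape of
the curves — α entries, the upper portion of feasible intervals at strongly
coloured points — inherit errors of a few percent. Quantities governed by
*fine* structure are far more sensitive: the rod-matched global capacity is
proportional to the small residual of the melanopic curve outside
span(L, M, S, rod), so per-curve errors of a few percent inflate it by a
factor ≈ 2 (the package computes ≈ 10 % where ≈ 4.5 % is expected with
official tables, and ≈ 42 % vs ≈ 31 % without rod matching). Passing tests
therefore demonstrate the correctness of the *method* — orthogonality,
silencing, LP/closed-form agreement, colorimetric matching — on any
observer, while absolute gamut widths on the bundled tables are indicative
only. Substituting official tables via the CSV interfaces removes this
caveat.

## Synthetic observers and response simulation

`synthetic_observer` builds log-normal-shaped unimodal curves (asymmetric,
like real photoreceptor spectra) with configurable peaks and log-widths;
linear independence is enforced through the Gram-matrix condition number
(limit 1e12). All metamer machinery is tested against such observers,
including a disjoint-support observer with a closed-form capacity.

`simulate_responses` emulates the discrimination design (default 5
participants × 2 trials per pair, dummy catch trials interleaved). The
"different"-response probability is guess + (1 − guess)·d(slope·ΔI) with
the folded logistic d(x) = 2·expit(x) − 1, chosen so that d(0) = 0 — a
zero slope collapses metamer trials to the guessing rate, making the null
case exactly match the catch trials. Rates are reported raw (no
false-alarm correction; dummy rates are surfaced alongside), per-pair,
per-nominal-ΔI (rounded to 1–4 %), and per hue group; the trend statistic
is the least-squares slope plus Spearman rank correlation over the four ΔI
levels, with the correlation flagged undefined for constant rates. What
the simulation does *not* model: inter-participant sensitivity differences,
learning/fatigue, and response bias asymmetries — recovery tests show the
aggregation is faithful to the generative probabilities, not that human
data behave this way.

## Numerical choices

* Rectangle-rule integration on the uniform grid; trapezoid would differ
  only at the endpoints and is absorbed by the stated tolerances.
* Orthogonality asserted at 1e-9 relative; excitation equality of pair
  members at 1e-8; silencing at 1e-10; triangular inversion round-trip at
  1e-10.
* Device bound validation allows 1e-7·cap slack before reporting
  per-wavelength violations (LP vertices round onto the bounds).
* Gram-Schmidt degeneracy: relative residual below 1e-7 names the
  offending receptor and aborts.
* cap defaults to 100 (the source's per-wavelength output ceiling); it is
  a parameter everywhere, and feasible intervals are monotone in it
  (tested at 50/100/200).
* Problem sizes: all LPs are solved on the 81-sample grid; the full test
  suite runs in well under a minute, the gamut property checks using
  0.02-resolution scans and single-cell re-solves.

## Known limitations

* Bundled tables are reconstructions (above); fine-structure quantities
  are indicative. The 4.3° field-size analysis requires a user-supplied
  CMF table.
* Chromaticity cells are point constraints, not area integrals; at coarse
  resolution the scan under-samples narrow gamut regions near the locus.
* The pentamer solver returns a locally optimal sign pattern; different
  restarts may return different (equally valid) pairs.
* No device model beyond the per-wavelength 0–100 % box: no gamma,
  bit-depth, or spectral-smoothing constraints of a physical projector.
* Absolute radiometry (cd/m²) is out of scope; all quantities are relative
  to the flat white.
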