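import numpy as np
import pytest

from melamet import Spectrum, excitations_percent, synthetic_observer
from melamet.engine import (
    build_basis,
    coefficients_to_excitations,
    design_metamer_pair,
    excitations_to_coefficients,
    feasible_iprgc_interval,
    max_metamer_range,
    pentamer_pair,
    realize,
    synthesize,
)
from melamet.errors import CapacityError, ConstraintViolationError, DegeneracyError
from tests.conftest import random_feasible_targets


def _step_norm(v, step):
    return np.sqrt((v @ v) * step)


class TestBuildBasis:
    def test_pairwise_orthogonality(self, std_basis):
        E = std_basis.vectors
        step = std_basis.grid.step
        norms = np.sqrt(np.sum(E * E, axis=1) * step)
        for i in range(5):
            for j in range(i + 1, 5):
                ip = (E[i] @ E[j]) * step
                assert abs(ip) < 1e-9 * norms[i] * norms[j]

    def test_reconstruction_of_sensitivities(self, std_basis):
        S = std_basis.observer.as_matrix()
        recon = std_basis.alpha.T @ std_basis.vectors
        np.testing.assert_allclose(recon, S, atol=1e-10)

    def test_alpha_upper_triangular_unit_diagonal(self, std_basis):
        a = std_basis.alpha
        np.testing.assert_allclose(np.diag(a), 1.0)
        assert np.allclose(a, np.triu(a))

    def test_span_preserved(self, std_basis):
        """Mutual projection residuals of the two spans are ~0."""
        S = std_basis.observer.as_matrix()
        Qs, _ = np.linalg.qr(S.T)
        Qe, _ = np.linalg.qr(std_basis.vectors.T)
        resid1 = std_basis.vectors.T - Qs @ (Qs.T @ std_basis.vectors.T)
        resid2 = S.T - Qe @ (Qe.T @ S.T)
        assert np.linalg.norm(resid1) < 1e-9 * np.linalg.norm(std_basis.vectors)
        assert np.linalg.norm(resid2) < 1e-9 * np.linalg.norm(S)

    def test_orthogonal_inputs_give_identity_alpha(self, disjoint_observer):
        basis = build_basis(disjoint_observer)
        np.testing.assert_allclose(basis.alpha, np.eye(5), atol=1e-12)
        np.testing.assert_allclose(basis.vectors, disjoint_observer.as_matrix())

    def test_against_projection_oracle(self, grid):
        """Unit-diagonal Gram-Schmidt equals QR rescaled to unit diagonal."""
        obs = synthetic_observer(3, [450, 520, 600], [0.07, 0.09, 0.08], grid=grid)
        basis = build_basis(obs)
        S = obs.as_matrix()
        Q, R = np.linalg.qr(S.T)  # S.T = Q R, columns of Q orthonormal
        D = np.diag(np.diag(R))
        alpha_oracle = np.linalg.inv(D) @ R  # unit diagonal
        # sign convention: QR may flip signs; compare alphas elementwise
        np.testing.assert_allclose(basis.alpha, alpha_oracle, atol=1e-10)
        recon = basis.alpha.T @ basis.vectors
        np.testing.assert_allclose(recon, S, atol=1e-10)

    def test_degenerate_set_raises_with_receptor_name(self, grid):
        from melamet.core import SensitivityFunction
        from melamet.observers import PhotoreceptorSet

        lam = grid.wavelengths
        a = np.exp(-0.5 * ((lam - 500) / 40.0) ** 2)
        b = np.exp(-0.5 * ((lam - 600) / 40.0) ** 2)
        # third curve inside the span of the first two
        sens = (
            SensitivityFunction(grid, a, name="a"),
            SensitivityFunction(grid, b, name="b"),
            SensitivityFunction(grid, 0.5 * a + 0.5 * b, name="mix"),
        )
        with pytest.raises((DegeneracyError,)):
            build_basis(PhotoreceptorSet(sens))


class TestSynthesizeRealize:
    def test_zero_coefficients_give_zero_spectrum(self, std_basis):
        p = realize(std_basis, np.zeros(5))
        assert np.all(p.values == 0.0)

    def test_e1_only_is_realizable(self, std_basis):
        """e1 equals the L-cone curve, which is non-negative."""
        w = np.zeros(5)
        w[0] = 50.0 / std_basis.vectors[0].max()
        p = realize(std_basis, w)
        assert p.values.max() == pytest.approx(50.0)

    def test_out_of_bounds_reports_wavelengths(self, std_basis):
        w = np.zeros(5)
        w[4] = 1e6  # e5 oscillates; huge weight must violate bounds
        with pytest.raises(ConstraintViolationError) as err:
            realize(std_basis, w)
        assert len(err.value.violations) > 0

    def test_two_excitation_paths_agree(self, std_basis):
        """coefficients_to_excitations matches excitations of the realized spectrum."""
        rng = np.random.default_rng(5)
        obs = std_basis.observer
        for _ in range(5):
            targets = random_feasible_targets(obs, rng)
            w4 = excitations_to_coefficients(std_basis, targets)
            iv = feasible_iprgc_interval(obs, targets, basis=std_basis)
            w5 = 0.5 * sum(iv.omega5_bounds)
            w = np.append(w4, w5)
            direct = excitations_percent(realize(std_basis, w), obs).as_array()
            mapped = coefficients_to_excitations(std_basis, w).as_array()
            np.testing.assert_allclose(direct, mapped, atol=1e-9)


class TestCoefficientMaps:
    def test_inversion_round_trip(self, std_basis):
        rng = np.random.default_rng(3)
        for _ in range(10):
            w4 = rng.normal(scale=30.0, size=4)
            exc = coefficients_to_excitations(std_basis, np.append(w4, 0.0))
            back = excitations_to_coefficients(std_basis, exc.as_array()[:4])
            np.testing.assert_allclose(back, w4, atol=1e-10)

    def test_omega5_silences_cones_and_rod(self, std_basis):
        rng = np.random.default_rng(4)
        w = rng.normal(scale=10.0, size=5)
        base = coefficients_to_excitations(std_basis, w).as_array()
        for delta in (-100.0, 3.7, 250.0):
            w2 = w.copy()
            w2[4] += delta
            exc = coefficients_to_excitations(std_basis, w2).as_array()
            np.testing.assert_allclose(exc[:4], base[:4], atol=1e-10)
            slope = std_basis.excitation_matrix[4, 4]
            assert exc[4] - base[4] == pytest.approx(delta * slope, rel=1e-9)

    def test_flat_white_decomposition_gives_100s(self, std_basis):
        E = std_basis.vectors
        step = std_basis.grid.step
        pw = np.full(std_basis.grid.n_samples, 100.0)
        w = (E @ pw) / np.sum(E * E, axis=1)  # orthogonal projection coeffs
        exc = coefficients_to_excitations(std_basis, w).as_array()
        np.testing.assert_allclose(exc, 100.0, atol=1e-8)


class TestFeasibleInterval:
    def test_matches_brute_force_scan(self, std_basis):
        """Closed-form interval equals a fine grid search over omega5."""
        obs = std_basis.observer
        rng = np.random.default_rng(11)
        E = std_basis.vectors
        for _ in range(3):
            targets = random_feasible_targets(obs, rng)
            iv = feasible_iprgc_interval(obs, targets, basis=std_basis)
            assert iv.feasible
            w4 = excitations_to_coefficients(std_basis, targets)
            q = w4 @ E[:4]
            e5 = E[4]
            outer = (100.0 + np.abs(q).max()) / np.abs(e5).max()
            w5s = np.linspace(-outer, outer, 10_000)
            p = q[None, :] + w5s[:, None] * e5[None, :]
            ok = (p.min(axis=1) >= -1e-9) & (p.max(axis=1) <= 100.0 + 1e-9)
            slope = std_basis.excitation_matrix[4, 4]
            i0 = float(w4 @ std_basis.excitation_matrix[:4, 4])
            brute_lo = i0 + w5s[ok].min() * slope
            brute_hi = i0 + w5s[ok].max() * slope
            scan_res = (w5s[1] - w5s[0]) * slope
            assert iv.i_min == pytest.approx(brute_lo, abs=2 * scan_res)
            assert iv.i_max == pytest.approx(brute_hi, abs=2 * scan_res)

    def test_neutral_targets_feasible_below_span_limit(self, std_observer):
        """Equal excitations are feasible well below the cap, with the interval
        straddling the target level; at the full 100% level the equal-energy
        white lies outside the five-sensitivity span, so no bounded span
        spectrum reaches all-100 cone+rod excitations."""
        iv = feasible_iprgc_interval(std_observer, [60.0] * 4)
        assert iv.feasible
        assert iv.i_min - 1e-9 <= 60.0 <= iv.i_max + 1e-9
        assert not feasible_iprgc_interval(std_observer, [100.0] * 4).feasible

    def test_matches_single_variable_lp(self, std_basis):
        """Interval intersection equals the equivalent 1-variable LP."""
        from scipy.optimize import linprog

        obs = std_basis.observer
        rng = np.random.default_rng(21)
        E = std_basis.vectors
        for _ in range(20):
            targets = random_feasible_targets(obs, rng)
            iv = feasible_iprgc_interval(obs, targets, basis=std_basis)
            w4 = excitations_to_coefficients(std_basis, targets)
            q = w4 @ E[:4]
            A = np.concatenate([E[4], -E[4]])[:, None]
            b = np.concatenate([100.0 - q, q])
            for sign, expected_w5 in ((1.0, iv.omega5_bounds[1]), (-1.0, iv.omega5_bounds[0])):
                res = linprog(np.array([-sign]), A_ub=A, b_ub=b,
                              bounds=[(None, None)], method="highs")
                assert res.status == 0
                assert res.x[0] == pytest.approx(expected_w5, abs=1e-9 * (1 + abs(expected_w5)))

    def test_convention_independence(self, std_observer):
        """unit-norm and unit-diagonal bases give identical intervals."""
        b1 = build_basis(std_observer, "unit_diagonal")
        b2 = build_basis(std_observer, "unit_norm")
        rng = np.random.default_rng(8)
        for _ in range(5):
            targets = random_feasible_targets(std_observer, rng)
            iv1 = feasible_iprgc_interval(std_observer, targets, basis=b1)
            iv2 = feasible_iprgc_interval(std_observer, targets, basis=b2)
            assert iv1.i_min == pytest.approx(iv2.i_min, abs=1e-8)
            assert iv1.i_max == pytest.approx(iv2.i_max, abs=1e-8)

    def test_monotone_in_cap(self, std_observer):
        rng = np.random.default_rng(9)
        targets = random_feasible_targets(std_observer, rng)
        widths = [
            feasible_iprgc_interval(std_observer, targets, cap=cap).width
            for cap in (50.0, 100.0, 200.0)
        ]
        assert widths[0] <= widths[1] + 1e-9 <= widths[2] + 2e-9

    def test_infeasible_flag_not_negative_width(self, std_observer):
        iv = feasible_iprgc_interval(std_observer, [100.0, 0.0, 0.0, 0.0])
        assert not iv.feasible
        assert iv.width == 0.0


class TestDesignMetamerPair:
    def test_zero_delta_gives_identical_spectra(self, std_observer):
        pair = design_metamer_pair(std_observer, [50, 50, 50, 50], requested_delta=0.0)
        np.testing.assert_allclose(
            pair.spectrum_max.values, pair.spectrum_min.values, atol=1e-10
        )
        assert pair.delta_i == pytest.approx(0.0, abs=1e-12)

    def test_max_pair_matches_interval_width(self, std_observer):
        targets = [47.9, 36.4, 5.86, 14.9]
        iv = feasible_iprgc_interval(std_observer, targets)
        pair = design_metamer_pair(std_observer, targets, requested_delta="max")
        assert pair.delta_i == pytest.approx(iv.width, rel=1e-9)

    def test_pair_members_share_cone_and_rod_excitations(self, std_observer):
        rng = np.random.default_rng(13)
        targets = random_feasible_targets(std_observer, rng)
        pair = design_metamer_pair(std_observer, targets, requested_delta="max")
        e_hi = excitations_percent(pair.spectrum_max, std_observer).as_array()
        e_lo = excitations_percent(pair.spectrum_min, std_observer).as_array()
        np.testing.assert_allclose(e_hi[:4], e_lo[:4], atol=1e-8)
        assert e_hi[4] - e_lo[4] == pytest.approx(pair.delta_i, abs=1e-8)

    def test_excessive_delta_reports_achievable(self, std_observer):
        with pytest.raises(CapacityError) as err:
            design_metamer_pair(std_observer, [50, 50, 50, 50], requested_delta=99.0)
        assert err.value.achievable > 0


class TestMaxMetamerRange:
    def test_relaxation_inequality(self, std_observer):
        w_rod, _ = max_metamer_range(std_observer, match_rod=True)
        w_free, _ = max_metamer_range(std_observer, match_rod=False)
        assert w_free >= w_rod - 1e-9

    def test_dominates_random_fixed_target_widths(self, std_observer):
        """The global LP optimum bounds every per-chromaticity width."""
        w_max, _ = max_metamer_range(std_observer, match_rod=True)
        rng = np.random.default_rng(17)
        for _ in range(10):
            targets = random_feasible_targets(std_observer, rng)
            iv = feasible_iprgc_interval(std_observer, targets)
            assert iv.width <= w_max + 1e-7

    def test_argmax_pair_is_consistent(self, std_observer):
        width, pair = max_metamer_range(std_observer, match_rod=True)
        e_hi = excitations_percent(pair.spectrum_max, std_observer).as_array()
        e_lo = excitations_percent(pair.spectrum_min, std_observer).as_array()
        np.testing.assert_allclose(e_hi[:4], e_lo[:4], atol=1e-7)
        assert e_hi[4] - e_lo[4] == pytest.approx(width, abs=1e-6)

    def test_closed_form_toy_case(self, disjoint_observer):
        """With the 5th sensitivity orthogonal to the rest, the optimum is
        cap * <s5, s5> / <1, s5> (the free coefficient spans [0, cap])."""
        s5 = disjoint_observer.as_matrix()[4]
        analytic = 100.0 * (s5 @ s5) / (np.ones_like(s5) @ s5)
        width, _ = max_metamer_range(disjoint_observer, match_rod=True)
        assert width == pytest.approx(analytic, rel=1e-8)


class TestPentamerPair:
    def test_all_five_excitations_equal(self, std_observer):
        pair = pentamer_pair(std_observer, Spectrum.flat(std_observer.grid, 50.0))
        e_a = excitations_percent(pair.spectrum_a, std_observer).as_array()
        e_b = excitations_percent(pair.spectrum_b, std_observer).as_array()
        np.testing.assert_allclose(e_a, e_b, atol=1e-8)

    def test_interior_base_has_positive_l1_difference(self, std_observer):
        pair = pentamer_pair(std_observer, Spectrum.flat(std_observer.grid, 50.0))
        assert pair.l1_difference > 0.0
        assert np.max(np.abs(pair.spectrum_a.values - pair.spectrum_b.values)) > 1.0

    def test_base_at_cap_gives_zero_width(self, std_observer):
        pair = pentamer_pair(std_observer, Spectrum.flat(std_observer.grid, 100.0))
        assert pair.l1_difference == 0.0
        np.testing.assert_array_equal(pair.spectrum_a.values, pair.spectrum_b.values)
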