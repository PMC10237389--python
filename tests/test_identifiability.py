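"""Sensitivity matrix, SVD measures, error ratios and Monte Carlo spread."""

import numpy as np
import pytest

import nfkbid as nk
from nfkbid.identifiability import (
    SensitivityMatrix,
    _sigma_carlo,
    confidence_ellipse,
    error_ratios,
    perpendicular_norms,
    scaled_singular_values,
    sensitivity_norms,
)


def _random_sm(rng, n=40, p=13, dim=None):
    return SensitivityMatrix(rng.standard_normal((n, p)),
                             dim if dim is not None else n - 1,
                             tuple(range(n)),
                             tuple(f"p{i}" for i in range(p)))


class TestSensitivityMatrix:
    def test_shape_and_index(self, linear_report):
        S = linear_report.sensitivity
        assert S.S.shape == (50, 13)
        assert S.dim == 41
        assert len(S.row_index) == 50

    def test_normalization_forces_zero_column_sums_per_series(
            self, linear_report):
        S = linear_report.sensitivity
        series = {}
        for row, key in enumerate(S.row_index):
            series.setdefault(key[:3], []).append(row)
        for rows in series.values():
            assert np.abs(S.S[rows].sum(axis=0)).max() < 1e-6

    def test_entries_stable_under_step_refinement(self, on_off,
                                                  linear_report):
        fine = nk.sensitivity_matrix(nk.FITTED, on_off, rel_step=0.001)
        coarse = linear_report.sensitivity
        big = np.abs(fine.S) > 0.01
        rel = np.abs(coarse.S[big] - fine.S[big]) / np.abs(fine.S[big])
        assert rel.max() < 0.01
        assert np.abs(coarse.S[~big] - fine.S[~big]).max() < 2e-3

    def test_non_positive_parameters_rejected(self, on_off):
        bad = nk.FITTED.with_updates(k2=0.0)
        with pytest.raises(ValueError, match="positive"):
            nk.sensitivity_matrix(bad, on_off)


class TestScaledMeasures:
    def test_thirteen_descending_singular_values(self, linear_report):
        sv = linear_report.scaled_singular_values
        assert sv.shape == (13,)
        assert np.all(np.diff(sv) <= 0)
        assert np.all(sv >= 0)

    def test_protocol_repetition_leaves_scaled_values_unchanged(
            self, linear_report):
        S = linear_report.sensitivity
        doubled = S.stack(S)
        assert doubled.dim == 82
        assert np.allclose(scaled_singular_values(doubled),
                           linear_report.scaled_singular_values, rtol=1e-10)
        assert np.allclose(sensitivity_norms(doubled),
                           linear_report.scaled_norms, rtol=1e-10)

    def test_perpendicular_never_exceeds_full_norm(self, rng):
        sm = _random_sm(rng)
        assert np.all(perpendicular_norms(sm)
                      <= sensitivity_norms(sm) + 1e-12)

    def test_duplicated_column_kills_both_perpendicular_parts(self, rng):
        A = rng.standard_normal((30, 5))
        A[:, 3] = A[:, 1]
        sm = SensitivityMatrix(A, 29, tuple(range(30)),
                               tuple("abcde"))
        with pytest.warns(UserWarning, match="rank deficient"):
            perp = perpendicular_norms(sm)
        assert perp[1] == 0.0 and perp[3] == 0.0
        assert np.all(perp[[0, 2, 4]] > 0)


class TestErrorRatios:
    def test_orthonormal_columns_give_unit_ratios(self):
        Q = np.linalg.qr(np.random.default_rng(0)
                         .standard_normal((40, 13)))[0]
        sm = SensitivityMatrix(Q, 39, tuple(range(40)),
                               tuple(f"p{i}" for i in range(13)))
        assert np.allclose(error_ratios(sm), 1.0, rtol=1e-10)

    def test_qr_route_matches_direct_pseudo_inverse(self, rng):
        for _ in range(5):
            sm = _random_sm(rng)
            A = np.linalg.inv(sm.S.T @ sm.S) @ sm.S.T
            assert np.allclose(error_ratios(sm),
                               np.linalg.norm(A, axis=1), atol=1e-8)

    def test_rank_deficiency_raises(self, rng):
        A = rng.standard_normal((30, 5))
        A[:, 0] = 2 * A[:, 4]
        sm = SensitivityMatrix(A, 29, tuple(range(30)), tuple("abcde"))
        with pytest.raises(np.linalg.LinAlgError, match="non-identifiable"):
            error_ratios(sm)

    def test_sigma_linear_is_power_law_in_error_ratio(self, linear_report):
        R = linear_report.error_ratios
        assert np.array_equal(linear_report.sigma_linear(1.3), 1.3 ** R)
        assert np.allclose(linear_report.sigma_linear(1.0), 1.0)


class TestConfidenceEllipse:
    def test_no_noise_degenerates_to_point(self, linear_report):
        ell = confidence_ellipse(linear_report.sensitivity, nk.FITTED,
                                 1.0, ("delta", "epsilon"))
        assert np.allclose(ell.semi_axes, 0.0)

    def test_axes_follow_marginal_covariance_eigenvectors(self,
                                                          linear_report):
        sm = linear_report.sensitivity
        ell = confidence_ellipse(sm, nk.FITTED, 1.3, ("delta", "epsilon"))
        cov = np.log(1.3) ** 2 * np.linalg.inv(sm.S.T @ sm.S)
        i = sm.param_names.index("delta")
        j = sm.param_names.index("epsilon")
        sub = cov[np.ix_([i, j], [i, j])]
        evals = np.sort(np.linalg.eigvalsh(sub))[::-1]
        from scipy.stats import chi2
        expected = np.sqrt(evals * chi2.ppf(0.75, 2))
        assert np.allclose(np.sort(ell.semi_axes)[::-1], expected,
                           rtol=1e-10)
        assert ell.center == pytest.approx(
            np.log([nk.FITTED.delta, nk.FITTED.epsilon]))


    def test_csv_export_round_numbers(self, linear_report, tmp_path):
        from nfkbid.identifiability import ellipses_to_csv

        ell = confidence_ellipse(linear_report.sensitivity, nk.FITTED,
                                 1.3, ("delta", "epsilon"))
        path = tmp_path / "ellipses.csv"
        ellipses_to_csv([ell], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2 and lines[1].startswith("delta,epsilon,")


class TestMonteCarlo:
    def test_identical_estimates_give_unit_sigma(self):
        logs = np.tile(np.log([1.0, 2.0, 3.0]), (6, 1))
        assert np.allclose(_sigma_carlo(logs), 1.0)

    def test_two_point_spread_hand_value(self):
        # estimates theta and theta*e^2: SD(ln) with ddof=1 is sqrt(2)
        logs = np.array([[0.0], [2.0]])
        assert _sigma_carlo(logs)[0] == pytest.approx(np.exp(np.sqrt(2)),
                                                      rel=1e-12)

    def test_replicate_seeds_shared_across_levels(self, mc_result):
        assert mc_result.seeds[1.1] == mc_result.seeds[1.3]
        assert len(mc_result.seeds[1.3]) == 20

    def test_no_noise_level_collapses_to_single_estimate(self, mc_result):
        est = mc_result.estimates[1.0]
        assert np.allclose(est, est[0])
        assert np.allclose(mc_result.sigma_carlo[1.0], 1.0)

    def test_small_k_rejected(self, on_off):
        with pytest.raises(ValueError, match="k must"):
            nk.run_monte_carlo(nk.FITTED, on_off, k=1)
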