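"""Correlation primitives, the dependent-correlation Z test, multiverse records."""

import numpy as np
import pytest

from trendaffect.diffcorr import (DegenerateCorrelationError, fisher_z,
                                  multiverse_record, multiverse_table,
                                  pearson_r, spearman_rho,
                                  steiger_z_nonoverlapping)
from trendaffect.rsv import rank_transform

from conftest import make_series


class TestCorrelations:
    def test_linear_transform_gives_unity(self, rng):
        x = rng.normal(size=50)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_definition_oracle_small_vector(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 4])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert pearson_r(x, y) == pytest.approx(oracle)

    def test_constant_vector_flagged(self):
        with pytest.raises(DegenerateCorrelationError):
            pearson_r(np.full(10, 3.0), np.arange(10.0))

    def test_spearman_monotone_invariance(self, rng):
        x = rng.normal(size=40)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -x**3) == pytest.approx(-1.0)

    def test_spearman_equals_pearson_on_ranks_with_ties(self, rng):
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        assert spearman_rho(x, y) == pytest.approx(
            pearson_r(rank_transform(x), rank_transform(y)))


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_symmetry(self, rng):
        for r in rng.uniform(-0.99, 0.99, 20):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r))

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="clip"):
            fisher_z(1.0)


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_z_nonoverlapping(0.4, 0.4, 0.2, 0.1, 0.15, 0.3, n=118)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_sign_convention_2020_exceeds_2019(self):
        z, _ = steiger_z_nonoverlapping(0.6, 0.2, 0.2, 0.1, 0.1, 0.2, n=118)
        assert z > 0
        z, _ = steiger_z_nonoverlapping(0.2, 0.6, 0.2, 0.1, 0.1, 0.2, n=118)
        assert z < 0

    def test_type_i_error_calibrated_under_null(self, rng):
        """Equal population correlations: rejection rate ~ alpha.

        Smaller replicate of the full calibration in the acceptance suite.
        """
        R = np.array([[1.0, .4, .2, .2], [.4, 1.0, .2, .2],
                      [.2, .2, 1.0, .4], [.2, .2, .4, 1.0]])
        L = np.linalg.cholesky(R)
        n, reps, rej = 118, 2000, 0
        X = rng.standard_normal((reps, n, 4)) @ L.T
        for r in range(reps):
            C = np.corrcoef(X[r], rowvar=False)
            _, p = steiger_z_nonoverlapping(C[0, 1], C[2, 3], C[0, 2],
                                            C[0, 3], C[1, 2], C[1, 3], n)
            rej += p < 0.05
        assert 0.035 <= rej / reps <= 0.065

    def test_agrees_with_bootstrap_standard_error(self, rng):
        """Formula Z vs Z built from a bootstrap SD of the Fisher-z difference.

        The pooled covariance term assumes the two compared correlations are
        equal (the null the test addresses), so the oracle dataset is drawn
        with equal population correlations.
        """
        R = np.array([[1.0, .4, .3, .2], [.4, 1.0, .2, .3],
                      [.3, .2, 1.0, .4], [.2, .3, .4, 1.0]])
        X = rng.standard_normal((118, 4)) @ np.linalg.cholesky(R).T

        def zdiff(data):
            C = np.corrcoef(data, rowvar=False)
            return np.arctanh(C[0, 1]) - np.arctanh(C[2, 3])

        C = np.corrcoef(X, rowvar=False)
        z_formula, _ = steiger_z_nonoverlapping(
            C[0, 1], C[2, 3], C[0, 2], C[0, 3], C[1, 2], C[1, 3], n=118)
        boots = np.array([zdiff(X[rng.integers(0, 118, 118)])
                          for _ in range(3000)])
        z_boot = zdiff(X) / boots.std(ddof=1)
        assert abs(z_formula - z_boot) < 0.15

    def test_clips_degenerate_unit_correlation(self):
        with pytest.warns(UserWarning, match="clipped"):
            z, _ = steiger_z_nonoverlapping(1.0, 0.3, 0.1, 0.1, 0.1, 0.1,
                                            n=50)
        assert np.isfinite(z)


def _coupled_pair(rng, coupling, n=117):
    """Word/reference series pairs with 2020-only coupling of given sign."""
    pulse = 1 / (1 + np.exp(-0.3 * (np.arange(n) - 50)))
    ref19 = 5 + np.abs(rng.normal(0, 3, n))
    ref20 = 60 * pulse + rng.normal(0, 3, n) + 5
    w19 = 30 + rng.normal(0, 4, n)
    w20 = 30 + coupling * 50 * pulse + rng.normal(0, 4, n)
    mk = lambda t, y, v: make_series(t, y, np.clip(v, 0, None) * 100
                                     / np.clip(v, 0, None).max())
    return ((mk("w", 2019, w19), mk("w", 2020, w20)),
            (mk("c", 2019, ref19), mk("c", 2020, ref20)))


class TestMultiverseRecord:
    @pytest.mark.parametrize("coupling,sign", [(0.9, 1), (-0.9, -1)])
    def test_planted_coupling_signs_all_measures(self, rng, coupling, sign):
        word_pair, covid_pair = _coupled_pair(rng, coupling)
        rec = multiverse_record(word_pair, covid_pair)
        for m in ("r_diff", "rho_diff", "z_pears", "z_spear"):
            assert sign * getattr(rec, m) > 0, m

    def test_monotone_in_coupling_strength(self):
        values = {}
        for kappa in (0.2, 0.5, 0.8):
            rng = np.random.default_rng(123)   # same noise, stronger signal
            word_pair, covid_pair = _coupled_pair(rng, kappa)
            rec = multiverse_record(word_pair, covid_pair)
            values[kappa] = [rec.r_diff, rec.rho_diff, rec.z_pears,
                             rec.z_spear]
        for i in range(4):
            assert values[0.2][i] <= values[0.5][i] <= values[0.8][i]

    def test_shift_invariance_of_all_measures(self, rng):
        word_pair, covid_pair = _coupled_pair(rng, 0.6)
        rec1 = multiverse_record(word_pair, covid_pair)
        (w19, w20), (c19, c20) = word_pair, covid_pair
        shifted = make_series("w", 2020, np.clip(w20.values * 0.5 + 10,
                                                 0, 100))
        # pure shift: add a constant within bounds
        shifted = make_series("w", 2020, w20.values / 2 + 25)
        rec2 = multiverse_record((make_series("w", 2019, w19.values / 2 + 25),
                                  shifted), covid_pair)
        # halving+shifting both years rescales the differential series but
        # leaves every correlation-based measure unchanged
        assert rec2.z_pears == pytest.approx(rec1.z_pears, abs=1e-9)
        assert rec2.z_spear == pytest.approx(rec1.z_spear, abs=1e-9)
        assert rec2.r_diff == pytest.approx(rec1.r_diff, abs=1e-9)
        assert rec2.rho_diff == pytest.approx(rec1.rho_diff, abs=1e-9)

    def test_table_drops_and_reports_degenerate_words(self, rng):
        word_pair, covid_pair = _coupled_pair(rng, 0.5)
        flat = (make_series("flat", 2019, np.full(117, 42.0)),
                make_series("flat", 2020, np.full(117, 42.0)))
        table, flagged = multiverse_table({"w": word_pair, "flat": flat},
                                          covid_pair)
        assert list(table["word"]) == ["w"]
        assert "flat" in flagged
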