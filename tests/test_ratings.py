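"""Reliability, paired/per-word tests, meta-analysis, Welch ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trendaffect.ratings import (DIMENSIONS, effect_table, eta_squared_partial,
                                 internal_meta, paired_t_items, reliability,
                                 spearman_brown, split_half, welch_anova_items,
                                 welch_t_per_word)


def item_frame(values):
    return pd.DataFrame({d: values for d in DIMENSIONS},
                        index=[f"w{i}" for i in range(len(values))])


class TestReliability:
    def test_identity_gives_unity(self, rng):
        cur = item_frame(rng.normal(5, 1, 40))
        np.testing.assert_allclose(reliability(cur, cur), 1.0)

    def test_noise_calibrated_correlation(self, rng):
        # signal sd 1.5, noise chosen for population r ~ .95
        sd_noise = 1.5 * np.sqrt(1 / 0.95**2 - 1)
        rs = []
        for _ in range(100):
            signal = rng.normal(5, 1.5, 60)
            cur = item_frame(signal)
            nor = item_frame(signal + rng.normal(0, sd_noise, 60))
            rs.append(reliability(cur, nor)["valence"])
        assert np.mean(rs) == pytest.approx(0.95, abs=0.01)

    def test_independent_vectors_near_zero(self, rng):
        cur = item_frame(rng.normal(5, 1, 200))
        nor = item_frame(rng.normal(5, 1, 200))
        assert abs(reliability(cur, nor)["valence"]) < 0.2


class TestSplitHalf:
    @staticmethod
    def _long(matrix):
        P, W = matrix.shape
        return pd.DataFrame({
            "participant": np.repeat([f"p{i}" for i in range(P)], W),
            "word": np.tile([f"w{j}" for j in range(W)], P),
            "dimension": "valence",
            "value": matrix.ravel(),
        })

    def test_identical_participants_give_unity(self, rng):
        row = rng.normal(5, 1, 30)
        out = split_half(self._long(np.tile(row, (12, 1))),
                         n_randomizations=50, seed=1)
        assert out.loc["valence", "median"] == pytest.approx(1.0)

    def test_spearman_brown_closed_form(self):
        assert spearman_brown(0.5) == pytest.approx(2 / 3)
        assert spearman_brown(1.0) == 1.0

    def test_seed_reproducible_and_stable(self, rng):
        M = (rng.normal(5, 1, (71, 60))
             + rng.normal(0, 1, (71, 1)) + rng.normal(0, 0.6, (1, 60)))
        long = self._long(M)
        a = split_half(long, n_randomizations=400, seed=42)
        b = split_half(long, n_randomizations=400, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = split_half(long, n_randomizations=400, seed=43)
        assert abs(a.loc["valence", "median"]
                   - c.loc["valence", "median"]) < 0.01


class TestPairedTItems:
    @pytest.mark.parametrize("t_printed,d_printed", [
        (-10.27, -1.325), (-3.08, -0.397), (-7.32, -0.945),
    ])
    def test_standardized_change_convention(self, t_printed, d_printed):
        # d = t / sqrt(n) at n = 60 items
        assert t_printed / np.sqrt(60) == pytest.approx(d_printed, abs=1e-3)

    def test_full_computation_matches_scipy(self, rng):
        cur = rng.normal(4.5, 1.2, 60)
        nor = rng.normal(5.0, 1.2, 60)
        out = paired_t_items(cur, nor)
        ref = stats.ttest_rel(cur, nor)
        assert out["t"] == pytest.approx(ref.statistic)
        assert out["p"] == pytest.approx(ref.pvalue)
        assert out["d"] == pytest.approx(out["t"] / np.sqrt(60))
        assert out["d_ci"][0] < out["d"] < out["d_ci"][1]

    def test_zero_differences(self):
        x = np.arange(10.0)
        out = paired_t_items(x, x)
        assert out["t"] == 0.0 and out["d"] == 0.0

    def test_zero_variance_nonzero_mean_flagged(self):
        with pytest.raises(FloatingPointError):
            paired_t_items(np.arange(10.0) + 1, np.arange(10.0))


class TestWelchPerWord:
    def test_equal_samples_give_zero(self):
        rec = welch_t_per_word("w", "valence", np.array([4.0, 5.0, 6.0]),
                               norms_mean=5.0, norms_sd=1.0, norms_n=30)
        assert rec.welch_t == 0.0
        assert rec.cohens_d == 0.0

    def test_two_group_anova_equals_t_squared(self, rng):
        xa = rng.normal(4.2, 1.0, 40)
        xb = rng.normal(5.0, 1.4, 35)
        diffs = pd.DataFrame({
            "mean_diff": np.concatenate([xa, xb]),
            "group": ["a"] * 40 + ["b"] * 35,
        })
        res = welch_anova_items(diffs, posthoc=True)
        t = res.posthoc.iloc[0]
        assert res.f_value == pytest.approx(t["t"] ** 2, rel=1e-9)
        assert res.df2 == pytest.approx(t["df"], rel=1e-9)

    def test_d_unbiased_under_shift(self, rng):
        # standardized shift of .5 between equal-variance samples
        ds = []
        for _ in range(3000):
            x = rng.normal(0.5, 1.0, 35)
            rec = welch_t_per_word("w", "valence", x, 0.0, 1.0, 35)
            ds.append(rec.cohens_d)
        # small positive small-sample bias of uncorrected d ~ d*3/(4*df-1)
        assert np.mean(ds) == pytest.approx(0.5, abs=0.02)

    def test_d_sign_matches_mean_diff_and_ci_contains_d(self, rng):
        for _ in range(20):
            x = rng.normal(rng.uniform(3, 7), 1.0, 30)
            rec = welch_t_per_word("w", "arousal", x, 5.0, 1.3, 34)
            assert np.sign(rec.cohens_d) == np.sign(rec.mean_diff) \
                or rec.mean_diff == 0
            assert rec.d_ci_low <= rec.cohens_d <= rec.d_ci_high


class TestInternalMeta:
    def test_identical_records_combine_to_same_d(self):
        records = pd.DataFrame({
            "word": [f"w{i}" for i in range(9)],
            "cohens_d": -0.3, "d_var": 0.05,
        })
        groups = {f"w{i}": ["REL+", "REL-", "UNREL"][i % 3] for i in range(9)}
        table, q, q_df, q_p = internal_meta(records, groups)
        assert np.allclose(table["combined_d"], -0.3)
        assert q == pytest.approx(0.0)
        assert q_df == 2

    def test_two_study_hand_oracle(self):
        # hand-computed fixed-effect combination:
        # d = (.2/.04 + .5/.09)/(1/.04 + 1/.09) = 10.5555../36.1111..
        records = pd.DataFrame({"word": ["a", "b"],
                                "cohens_d": [0.2, 0.5],
                                "d_var": [0.04, 0.09]})
        table, q, q_df, q_p = internal_meta(records, {"a": "g1", "b": "g2"})
        w1, w2 = 1 / 0.04, 1 / 0.09
        d_pool = (0.2 * w1 + 0.5 * w2) / (w1 + w2)
        q_hand = w1 * (0.2 - d_pool) ** 2 + w2 * (0.5 - d_pool) ** 2
        assert q == pytest.approx(q_hand)
        combined = table.set_index("group")["combined_d"]
        assert combined["g1"] == pytest.approx(0.2)
        assert combined["g2"] == pytest.approx(0.5)

    def test_order_invariance_and_nonnegative_q(self, rng):
        records = pd.DataFrame({
            "word": [f"w{i}" for i in range(30)],
            "cohens_d": rng.normal(-0.3, 0.2, 30),
            "d_var": rng.uniform(0.03, 0.1, 30),
        })
        groups = {f"w{i}": ["REL+", "REL-", "UNREL"][i % 3] for i in range(30)}
        t1, q1, *_ = internal_meta(records, groups)
        t2, q2, *_ = internal_meta(records.sample(frac=1, random_state=3),
                                   groups)
        pd.testing.assert_frame_equal(t1, t2)
        assert q1 == pytest.approx(q2) and q1 >= 0

    def test_group_difference_detected_at_planted_pattern(self, rng):
        """Groups with true d -.35/-.35/-.18 and 20 words each: Q* should
        reject at alpha=.05 in a clear majority of replicates, and the
        combined d's should cover the planted values."""
        n1 = n2 = 35
        base_var = (n1 + n2) / (n1 * n2)
        rejections, cover = 0, 0
        reps = 200
        truths = {"REL+": -0.35, "REL-": -0.35, "UNREL": -0.18}
        groups = {f"w{i}": g for i, g in enumerate(
            [g for g in truths for _ in range(20)])}
        for _ in range(reps):
            d_obs = []
            for w, g in groups.items():
                d_true = truths[g]
                var = base_var + d_true**2 / (2 * (n1 + n2))
                d_obs.append(rng.normal(d_true, np.sqrt(var)))
            records = pd.DataFrame({"word": list(groups),
                                    "cohens_d": d_obs,
                                    "d_var": [base_var + d**2 / 140
                                              for d in d_obs]})
            table, q, q_df, q_p = internal_meta(records, groups)
            rejections += q_p < 0.05
            row = table.set_index("group").loc["UNREL"]
            cover += row["ci_low"] <= -0.18 <= row["ci_high"]
        assert rejections / reps > 0.5          # simulated power of Q*
        assert cover / reps > 0.85              # CI coverage of planted d


class TestWelchAnova:
    @pytest.mark.parametrize("f,df1,df2,expected", [
        (4.31, 2, 36.67, 0.190),   # valence
        (4.80, 2, 37.22, 0.205),   # arousal
        (1.52, 2, 37.41, 0.075),   # dominance
    ])
    def test_eta_squared_partial_from_printed_f(self, f, df1, df2, expected):
        assert eta_squared_partial(f, df1, df2) == pytest.approx(expected,
                                                                 abs=5e-4)

    def test_equal_group_means_give_zero_f(self):
        diffs = pd.DataFrame({
            "mean_diff": np.tile([-0.5, -0.3, -0.7, -0.5], 15),
            "group": np.repeat(["REL+", "REL-", "UNREL"], 20),
        })
        # make all three group means equal by construction
        diffs["mean_diff"] = diffs.groupby("group")["mean_diff"] \
            .transform(lambda s: s - s.mean() - 0.5)
        res = welch_anova_items(diffs)
        assert res.f_value == pytest.approx(0.0, abs=1e-12)
        assert res.eta_sq_partial == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_group_error(self):
        diffs = pd.DataFrame({"mean_diff": [0.5] * 5 + [1, 2, 3, 4, 5.0],
                              "group": ["a"] * 5 + ["b"] * 5})
        with pytest.raises(ValueError, match="a"):
            welch_anova_items(diffs)


class TestEffectTable:
    def test_table_covers_design(self, ratings_sim, central_norms):
        norms_long = []
        for dim in DIMENSIONS:
            norms_long.append(pd.DataFrame({
                "word": central_norms["word"], "dimension": dim,
                "mean": central_norms[dim],
                "sd": central_norms[f"{dim}_sd"],
                "n": central_norms[f"{dim}_n"]}))
        table = effect_table(ratings_sim.ratings, pd.concat(norms_long))
        assert len(table) == 60 * 3
        assert ((np.sign(table["cohens_d"]) == np.sign(table["mean_diff"]))
                | (table["mean_diff"] == 0)).all()
        assert ((table["d_ci_low"] <= table["cohens_d"])
                & (table["cohens_d"] <= table["d_ci_high"])).all()
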