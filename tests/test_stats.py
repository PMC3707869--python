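"""Extreme groups, ANOVA with Scheffe contrasts, t-tests, Mann-Whitney."""

import numpy as np
import pandas as pd
import pytest

import beatwalk as bw
from beatwalk.errors import InsufficientDataError
from beatwalk.stats import (
    ADJECTIVE_PAIRS,
    extreme_groups,
    feature_ttests,
    ratings_tests,
    speed_anova,
)
from beatwalk.synth import simulate_ratings


def _speeds(values, prefix="s"):
    ids = [f"{prefix}{i + 1:02d}" for i in range(len(values))]
    return pd.Series(values, index=ids, name="v_s")


class TestExtremeGroups:
    def test_monotone_speeds_give_rank_groups(self):
        v = _speeds(np.arange(52.0))
        g = extreme_groups(v)
        assert g.activating[0] == "s52"  # fastest ranked first
        assert set(g.activating) == {f"s{i}" for i in range(43, 53)}
        assert g.relaxing[0] == "s01"  # slowest ranked first
        assert set(g.relaxing) == {f"s{i:02d}" for i in range(1, 11)}
        # middle ranks 22..31 of 52
        assert set(g.neutral) == {f"s{i}" for i in range(22, 32)}

    def test_groups_pairwise_disjoint(self):
        g = extreme_groups(_speeds(np.random.default_rng(0).normal(100, 5, 52)))
        assert not (set(g.activating) & set(g.relaxing))
        assert not (set(g.activating) & set(g.neutral))
        assert not (set(g.relaxing) & set(g.neutral))

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(1)
        v = _speeds(rng.normal(100, 5, 40))
        g1 = extreme_groups(v)
        g2 = extreme_groups(v.sample(frac=1.0, random_state=7))
        assert set(g1.activating) == set(g2.activating)
        assert set(g1.relaxing) == set(g2.relaxing)
        assert set(g1.neutral) == set(g2.neutral)

    def test_too_few_songs_rejected(self):
        with pytest.raises(InsufficientDataError):
            extreme_groups(_speeds(np.arange(20.0)))


class TestSpeedAnova:
    @staticmethod
    def _textbook_F(samples):
        # independent oracle: explicit sum-of-squares ANOVA
        allv = np.concatenate(samples)
        grand = allv.mean()
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        df_b, df_w = len(samples) - 1, len(allv) - len(samples)
        return (ss_between / df_b) / (ss_within / df_w)

    def test_matches_textbook_sum_of_squares(self):
        rng = np.random.default_rng(3)
        v = _speeds(np.concatenate([rng.normal(m, 2.0, 10) for m in (89, 100, 107)])
                    )
        g = extreme_groups(v)
        res = speed_anova(v, g)
        samples = [v.loc[g.activating].to_numpy(), v.loc[g.relaxing].to_numpy(),
                   v.loc[g.neutral].to_numpy()]
        assert res["F"] == pytest.approx(self._textbook_F(samples), rel=1e-9)
        assert res["df"] == (2, 27)

    def test_study_like_group_separation_is_significant(self):
        # group means near 89.4 / 99.9 / 107.0 with small spread
        rng = np.random.default_rng(4)
        vals = np.concatenate([
            rng.normal(89.4, 2.5, 10), rng.normal(99.9, 2.5, 22),
            rng.normal(107.0, 2.5, 20),
        ])
        v = _speeds(vals)
        g = extreme_groups(v)
        res = speed_anova(v, g)
        assert res["F"] > 30 and res["p"] < 1e-6
        assert all(c["p"] < 0.01 for c in res["scheffe"].values())

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        v = _speeds(rng.normal(100.0, 3.0, 52))
        g = extreme_groups(v)
        shuffled = pd.Series(
            rng.permutation(v.to_numpy()), index=v.index, name="v_s"
        )
        res = speed_anova(shuffled, g)
        assert res["p"] > 0.001  # groups no longer ordered after shuffling

    def test_location_invariance(self):
        rng = np.random.default_rng(6)
        v = _speeds(rng.normal(100, 5, 52))
        g = extreme_groups(v)
        f1 = speed_anova(v, g)["F"]
        f2 = speed_anova(v + 37.0, g)["F"]
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_degenerate_variance_flagged(self):
        v = _speeds(np.repeat(100.0, 30))
        g = extreme_groups(v)
        res = speed_anova(v, g)
        assert res["degenerate_variance"] is True and res["p"] == 1.0


class TestFeatureTTests:
    def _frame(self, rng, shift=0.0):
        ids = [f"s{i + 1:02d}" for i in range(30)]
        X = pd.DataFrame(rng.normal(0, 1, (30, 3)), index=ids,
                         columns=["f1", "f2", "f3"])
        X.iloc[:10, 0] += shift  # first ten songs are the activating group
        return X, ids

    def test_sign_of_t_matches_mean_difference(self):
        rng = np.random.default_rng(7)
        X, ids = self._frame(rng, shift=2.0)
        g = bw.GroupAssignment(activating=ids[:10], relaxing=ids[10:20],
                               neutral=ids[20:30])
        out = feature_ttests(X, g)
        assert out.loc["f1", "t"] > 0
        assert np.sign(out["t"]).equals(
            np.sign(out["mean_activating"] - out["mean_relaxing"])
        )

    def test_two_pooled_sd_shift_detected_with_high_power(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X, ids = self._frame(rng, shift=2.0)
            g = bw.GroupAssignment(activating=ids[:10], relaxing=ids[10:20],
                                   neutral=ids[20:30])
            detected += feature_ttests(X, g).loc["f1", "p"] < 0.01
        assert detected >= 19

    def test_identical_groups_flagged_degenerate(self):
        ids = [f"s{i + 1:02d}" for i in range(30)]
        X = pd.DataFrame(np.ones((30, 2)), index=ids, columns=["f1", "f2"])
        g = bw.GroupAssignment(activating=ids[:10], relaxing=ids[10:20],
                               neutral=ids[20:30])
        out = feature_ttests(X, g)
        assert out["degenerate"].all()
        assert (out["p"] == 1.0).all()


class TestRatingsTests:
    def test_u_statistic_identity_for_10v10(self):
        ids = [f"s{i + 1:02d}" for i in range(30)]
        g = bw.GroupAssignment(activating=ids[:10], relaxing=ids[10:20],
                               neutral=ids[20:30])
        ratings = simulate_ratings(ids, g.activating, g.relaxing, seed=2)
        out = ratings_tests(ratings, g)
        for adj in ADJECTIVE_PAIRS:
            x = ratings.loc[g.activating, adj].to_numpy()
            z = ratings.loc[g.relaxing, adj].to_numpy()
            from scipy.stats import mannwhitneyu

            u_prime = mannwhitneyu(z, x, alternative="two-sided").statistic
            assert out.loc[adj, "U"] + u_prime == pytest.approx(100.0)

    def test_planted_shifts_flag_exactly_the_shifted_adjectives(self):
        shifted = ("good-bad", "tender-aggressive", "soft-loud", "slow-fast",
                   "stuttering-flowing")
        hits = 0
        for seed in range(10):
            ids = [f"s{i + 1:02d}" for i in range(30)]
            g = bw.GroupAssignment(activating=ids[:10], relaxing=ids[10:20],
                                   neutral=ids[20:30])
            ratings = simulate_ratings(ids, g.activating, g.relaxing, seed=seed)
            out = ratings_tests(ratings, g)
            flagged = set(out.index[out["p"] < 0.05])
            hits += flagged == set(shifted)
        assert hits >= 8

    def test_all_tied_ratings_flagged(self):
        ids = [f"s{i + 1:02d}" for i in range(30)]
        g = bw.GroupAssignment(activating=ids[:10], relaxing=ids[10:20],
                               neutral=ids[20:30])
        ratings = pd.DataFrame(
            np.full((30, 9), 50.0), index=ids, columns=list(ADJECTIVE_PAIRS)
        )
        out = ratings_tests(ratings, g)
        assert out["all_tied"].all() and (out["p"] == 1.0).all()
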