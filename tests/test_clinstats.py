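"""Predictor-family GLMs, ANOVA of aperiodic parameters, permutation
Spearman and pointwise spectrum tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stnio import clinstats
from stnio.clinstats import FAMILIES, fit_family


def _table(rng, n=60, noise=0.0, coef=(0.5, -0.3, 0.4, 0.2),
           order="zeroth", family="DeF"):
    members = FAMILIES[family]
    df = pd.DataFrame({m: rng.standard_normal(n) for m in members})
    Z = df.apply(clinstats.zscore)
    if order == "zeroth":
        y = Z.to_numpy() @ np.asarray(coef)
    elif order == "first":
        cols = [Z[a] * Z[b] for a, b in itertools.combinations(members, 2)]
        y = np.column_stack(cols) @ np.asarray(coef)
    df["resp"] = y + noise * rng.standard_normal(n)
    return df


class TestFitFamily:
    def test_noiseless_zeroth_order_recovery(self, rng):
        df = _table(rng)
        res = fit_family(df, "DeF", "resp", "zeroth")
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        # response is z-scored before fitting; coefficients scale by 1/sd(y)
        scale = np.std(df["resp"])
        np.testing.assert_allclose(res.coefficients.to_numpy(),
                                   np.array([0.5, -0.3, 0.4, 0.2]) / scale,
                                   atol=1e-8)

    def test_first_order_has_six_interaction_terms(self, rng):
        res = fit_family(_table(rng, noise=0.3), "DeF", "resp", "first")
        assert len(res.coefficients) == 6
        assert all("*" in t for t in res.coefficients.index)

    def test_higher_order_has_five_terms(self, rng):
        res = fit_family(_table(rng, noise=0.3), "DeF", "resp", "higher")
        assert len(res.coefficients) == 5

    def test_individual_predictor(self, rng):
        res = fit_family(_table(rng, noise=0.5), "LD", "resp")
        assert res.model_order == "individual"
        assert len(res.coefficients) == 1

    def test_truth_order_wins_aic(self, rng):
        """Data generated from pairwise interactions: the first-order model
        beats zeroth and higher order by AIC in most replicates."""
        coef6 = (0.8, -0.6, 0.5, 0.7, -0.4, 0.6)
        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            df = _table(rng, n=60, noise=0.5, coef=coef6, order="first")
            aics = {o: fit_family(df, "DeF", "resp", o).aic
                    for o in ("zeroth", "first", "higher")}
            wins += min(aics, key=aics.get) == "first"
        assert wins / n_rep >= 0.9

    def test_standardized_fit_invariant_to_predictor_rescaling(self, rng):
        df = _table(rng, noise=0.4)
        res1 = fit_family(df, "DeF", "resp", "zeroth")
        df2 = df.copy()
        df2["LD"] = df2["LD"] * 123.0 + 7.0
        res2 = fit_family(df2, "DeF", "resp", "zeroth")
        np.testing.assert_allclose(res1.coefficients, res2.coefficients,
                                   atol=1e-10)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="complete cases"):
            fit_family(_table(rng, n=4), "DeF", "resp", "zeroth")


class TestDerivedColumns:
    def test_differences_computed(self):
        df = pd.DataFrame({"LCF": [25.0], "SCF": [17.0], "LP": [2.0],
                           "SP": [1.0], "LO": [1.5], "SO": [0.5],
                           "LE": [2.2], "SE": [0.1]})
        out = clinstats.derive_difference_columns(df)
        assert out["LSCF"].iloc[0] == 8.0
        assert out["LSE"].iloc[0] == pytest.approx(2.1)

    def test_inconsistent_difference_is_a_data_error(self):
        df = pd.DataFrame({"LCF": [25.0], "SCF": [17.0], "LSCF": [3.0]})
        with pytest.raises(ValueError, match="inconsistent"):
            clinstats.derive_difference_columns(df)

    def test_zscore_idempotent(self, rng):
        x = rng.normal(5, 3, 100)
        z1 = clinstats.zscore(x)
        np.testing.assert_allclose(clinstats.zscore(z1), z1, atol=1e-12)


class TestAnova:
    def _fits(self, rng, lfp_mu=2.2, spk_mu=0.11, n=200):
        rows = []
        for stream, mu, sd in (("LFP", lfp_mu, 0.4), ("SPK", spk_mu, 0.22)):
            for sub in ("pre", "motor", "nonmotor"):
                for v in rng.normal(mu, sd, n):
                    rows.append((v, stream, sub))
        return map(np.array, zip(*rows))

    def test_large_separation_gives_tiny_p(self, rng):
        values, stream, sub = self._fits(rng)
        res = clinstats.anova_aperiodic(values, stream, sub)
        assert res["p_signal"] < 1e-10

    def test_location_invariance(self, rng):
        values, stream, sub = self._fits(rng, n=40)
        r1 = clinstats.anova_aperiodic(values, stream, sub)
        r2 = clinstats.anova_aperiodic(values.astype(float) + 5.0, stream, sub)
        assert r1["p_signal"] == pytest.approx(r2["p_signal"], rel=1e-6)
        assert r1["p_interaction"] == pytest.approx(r2["p_interaction"],
                                                    rel=1e-6)

    def test_posthoc_table_covers_all_cell_pairs(self, rng):
        values, stream, sub = self._fits(rng, n=20)
        res = clinstats.anova_aperiodic(values, stream, sub)
        assert len(res["posthoc"]) == 15  # C(6,2)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            clinstats.anova_aperiodic(
                np.ones(4), np.array(["LFP"] * 4),
                np.array(["pre", "pre", "motor", "motor"]))


class TestSpearman:
    def test_monotone_pairs_give_rho_one(self, rng):
        x = rng.uniform(size=50)
        res = clinstats.spearman_with_shuffle(x, np.exp(x), rng=rng)
        assert res["rho"] == pytest.approx(1.0)

    def test_shuffled_null_moments(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        res = clinstats.spearman_with_shuffle(x, y, n_shuffle=500, rng=rng)
        assert abs(res["null_mean"]) < 0.02
        assert res["null_sd"] == pytest.approx(1 / np.sqrt(99), rel=0.15)

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            clinstats.spearman_with_shuffle([1, 2], [3, 4], rng=rng)


class TestPointwise:
    def test_bonferroni_threshold(self, rng):
        res = clinstats.pointwise_psd_test(rng.standard_normal((10, 5)),
                                           rng.standard_normal((10, 5)))
        assert res["threshold"] == pytest.approx(0.05 / 3)

    def test_single_shifted_bin_flagged(self, rng):
        A = rng.standard_normal((20, 30))
        B = rng.standard_normal((20, 30))
        B[:, 7] += 10.0
        res = clinstats.pointwise_psd_test(A, B)
        assert res["significant"][7]
        assert res["significant"].sum() <= 3  # nominal false positives only

    def test_tiny_group_untestable(self):
        res = clinstats.pointwise_psd_test(np.ones((1, 4)), np.ones((5, 4)))
        assert res["untestable"].all()
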