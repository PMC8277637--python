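import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polypat import estimation
from polypat.errors import DataError
from polypat.estimation import (
    build_c_dataset,
    build_p_dataset,
    compact_letter_display,
    contrasts,
    correlate_c_p,
    deviance_table,
    donor_shares,
    estimate_p,
    fit_binomial_glm,
    group_contrast,
    impute_cell,
    impute_intra,
    inv_logit,
    ls_means,
    overdispersion_check,
    pair_counts,
    pairwise_contrasts,
)

from _oracles import clique_letters, irls_binomial, pearson_r_closed_form


def make_assignments(rows):
    """rows: (mother, father, block, year, n) expanded to one row per seed."""
    data = []
    i = 0
    for mg, fg, block, year, n in rows:
        for _ in range(n):
            data.append((f"s{i}", mg, block, year, "assigned", fg, 0))
            i += 1
    return pd.DataFrame(
        data,
        columns=["seed_id", "mother_genotype", "block", "year", "status",
                 "father_genotype", "n_ignored"],
    )


class TestCDataset:
    def test_block_arithmetic(self):
        asn = make_assignments([("m", "d", 1, 1, 40), ("m", "m", 1, 1, 56)])
        c = build_c_dataset(asn, genotypes=["d", "m"], blocks=[1], years=[1])
        row = c[c["MG"] == "m"].iloc[0]
        assert (row["n_cross"], row["n_self"]) == (40, 56)

    def test_empty_cell_is_zero_zero(self):
        asn = make_assignments([("m", "d", 1, 1, 5)])
        c = build_c_dataset(asn, genotypes=["d", "m"], blocks=[1, 2], years=[1])
        row = c[(c["MG"] == "m") & (c["block"] == 2)].iloc[0]
        assert (row["n_cross"], row["n_self"]) == (0, 0)

    def test_conservation(self, small_run):
        asn = small_run["assignments"]
        c = build_c_dataset(asn)
        assert (c["n_cross"] + c["n_self"]).sum() == (asn["status"] == "assigned").sum()
        assert len(c) == 64  # 8 genotypes x 8 blocks x 1 year


class TestImputation:
    def test_constant_counts(self):
        assert impute_cell([7] * 7) == 7.0

    def test_all_zero(self):
        assert impute_cell([0] * 7) == 0.0

    def test_arithmetic_identity(self):
        counts = [1, 2, 3, 4, 5, 6, 7]
        diag = impute_cell(counts)
        assert diag == 4.0
        total = sum(counts) + diag
        assert total == 32.0
        assert diag / total == pytest.approx(1 / 8, abs=1e-15)

    @settings(max_examples=100, deadline=None)
    @given(counts=st.lists(st.integers(0, 500), min_size=7, max_size=7))
    def test_diagonal_share_is_exactly_one_eighth(self, counts):
        diag = impute_cell(counts)
        total = sum(counts) + diag
        if total > 0:
            assert diag / total == pytest.approx(1 / 8, abs=1e-12)

    def test_table_level_imputation(self, small_run):
        counts = pair_counts(small_run["assignments"])
        imputed = impute_intra(counts)
        shares = donor_shares(imputed)
        diag = shares[shares["MG"] == shares["PG"]]["share"].dropna()
        assert np.allclose(diag, 1 / 8)
        # cell totals grew by 8/7
        raw = counts.groupby(["MG", "block", "year"])["seeds_sired"].sum()
        new = imputed.groupby(["MG", "block", "year"])["seeds_sired"].sum()
        assert np.allclose(new, raw * 8 / 7)


class TestPDataset:
    def test_512_rows_single_year(self, small_run):
        imputed = impute_intra(pair_counts(small_run["assignments"]))
        p = build_p_dataset(imputed)
        assert len(p) == 512

    def test_zero_total_cell(self):
        asn = make_assignments([("a", "b", 1, 1, 3)])
        counts = pair_counts(asn, genotypes=["a", "b", "c"], blocks=[1, 2],
                             years=[1])
        p = build_p_dataset(impute_intra(counts))
        empty = p[(p["MG"] == "a") & (p["block"] == 2)]
        assert (empty["n_cross"] == 0).all()
        assert (empty["n_rest"] == 0).all()

    def test_conservation_within_cell(self, small_run):
        imputed = impute_intra(pair_counts(small_run["assignments"]))
        p = build_p_dataset(imputed)
        for _, cell in p.groupby(["MG", "block", "year"]):
            total = cell["n_cross"].sum()
            assert np.allclose(cell["n_cross"] + cell["n_rest"], total)


class TestGLM:
    def test_saturated_one_factor(self):
        data = pd.DataFrame(
            {"f": ["a", "b"], "n_cross": [30, 70], "n_self": [70, 30]}
        )
        fit = fit_binomial_glm(data, ["f"])
        eta = fit.params[0], fit.params[0] + fit.params[1]
        assert eta[0] == pytest.approx(np.log(30 / 70), abs=1e-8)
        assert eta[1] == pytest.approx(np.log(70 / 30), abs=1e-8)
        assert fit.deviance == pytest.approx(0, abs=1e-8)

    def test_intercept_only_pooled_proportion(self):
        data = pd.DataFrame(
            {"f": ["a", "a", "a"], "n_cross": [10, 20, 30], "n_self": [30, 20, 10]}
        )
        fit = fit_binomial_glm(data, [])
        assert inv_logit(fit.params[0]) == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_irls(self, seed):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            {
                "A": rng.choice(["x", "y", "z"], size=40),
                "B": rng.choice(["u", "v"], size=40),
                "n_cross": rng.integers(1, 50, size=40).astype(float),
                "n_self": rng.integers(1, 50, size=40).astype(float),
            }
        )
        fit = fit_binomial_glm(data, ["A", "B"])
        X, _ = fit.design.matrix(data)
        beta, dev = irls_binomial(
            X, data["n_cross"].to_numpy(),
            (data["n_cross"] + data["n_self"]).to_numpy(),
        )
        assert np.allclose(fit.params, beta, atol=1e-6)
        assert fit.deviance == pytest.approx(dev, abs=1e-6)

    def test_negative_counts_rejected(self):
        data = pd.DataFrame({"f": ["a"], "n_cross": [-1], "n_self": [3]})
        with pytest.raises(DataError):
            fit_binomial_glm(data, ["f"])


class TestDevianceTable:
    def test_c_model_df_layout(self, small_run):
        c = build_c_dataset(small_run["assignments"])
        tab = deviance_table(c, ["MG", "block"])
        df = dict(zip(tab["term"], tab["df"]))
        assert df == {"Null": 63, "MG": 7, "block": 7, "Residual": 49}

    def test_p_model_df_layout(self, small_run):
        imputed = impute_intra(pair_counts(small_run["assignments"]))
        p = build_p_dataset(imputed)
        tab = deviance_table(p, ["PG", "MG", "PG:MG", "block"],
                             "n_cross", "n_rest")
        df = dict(zip(tab["term"], tab["df"]))
        assert df == {"Null": 511, "PG": 7, "MG": 7, "PG:MG": 49, "block": 7,
                      "Residual": 441}

    def test_deviance_additivity(self, small_run):
        c = build_c_dataset(small_run["assignments"])
        tab = deviance_table(c, ["MG", "block"])
        null = tab.loc[tab["term"] == "Null", "deviance"].iloc[0]
        parts = tab.loc[~tab["term"].isin(["Null"]), "deviance"].sum()
        assert parts == pytest.approx(null, abs=1e-8)

    def test_p_response_kills_mg_and_block_by_construction(self):
        # counts depend on PG only -> after PG the fit is exact and the
        # remaining terms add exactly zero deviance
        genotypes = [f"G{i}" for i in range(1, 9)]
        rows = []
        for mg, pg, block in itertools.product(genotypes, genotypes, range(1, 9)):
            if mg != pg:
                rows.append((mg, pg, block, 1, float(int(pg[1:]) * 2)))
            else:
                rows.append((mg, pg, block, 1, 0.0))
        table = pd.DataFrame(
            rows, columns=["MG", "PG", "block", "year", "seeds_sired"]
        )
        p = build_p_dataset(impute_intra(table))
        tab = deviance_table(p, ["PG", "MG", "block"], "n_cross", "n_rest")
        dev = dict(zip(tab["term"], tab["deviance"]))
        assert abs(dev["MG"]) < 1e-6
        assert abs(dev["block"]) < 1e-6

    def test_nested_block_df(self):
        rng = np.random.default_rng(0)
        rows = []
        for mg, block, year in itertools.product("abcd", range(1, 4), (1, 2)):
            rows.append((mg, block, year, rng.integers(5, 30), rng.integers(5, 30)))
        data = pd.DataFrame(rows, columns=["MG", "block", "year",
                                           "n_cross", "n_self"])
        tab = deviance_table(data, ["MG", "block(year)", "year", "year:MG"])
        df = dict(zip(tab["term"], tab["df"]))
        assert df["block(year)"] == 4  # 2 years x (3 blocks - 1)
        assert df["year"] == 1
        assert df["year:MG"] == 3


class TestLSMeans:
    def test_balanced_one_factor_equals_observed_logit(self):
        data = pd.DataFrame(
            {"f": ["a", "a", "b", "b"], "n_cross": [30, 30, 70, 70],
             "n_self": [70, 70, 30, 30]}
        )
        fit = fit_binomial_glm(data, ["f"])
        means = ls_means(fit, "f")
        assert means.loc[means["level"] == "a", "ls_mean_logit"].iloc[0] == \
            pytest.approx(np.log(30 / 70), abs=1e-8)
        assert means.loc[means["level"] == "b", "backtransformed"].iloc[0] == \
            pytest.approx(0.7, abs=1e-8)

    def test_inverse_logit_of_zero(self):
        assert inv_logit(0.0) == pytest.approx(0.5)

    def test_equal_weight_marginalization_matches_brute_force(self):
        rng = np.random.default_rng(3)
        rows = [
            (a, b, rng.integers(2, 40), rng.integers(2, 40))
            for a, b in itertools.product("pqr", "wxyz")
        ]
        data = pd.DataFrame(rows, columns=["A", "B", "n_cross", "n_self"])
        fit = fit_binomial_glm(data, ["A", "B", "A:B"])
        means = ls_means(fit, "A")
        # brute force: average the predicted logit over the full B grid
        X, _ = fit.design.matrix(data)
        eta = X @ fit.params
        for level, expected in means[["level", "ls_mean_logit"]].itertuples(
            index=False
        ):
            cell = eta[(data["A"] == level).to_numpy()]
            assert expected == pytest.approx(cell.mean(), abs=1e-8)

    def test_ci_ordering(self, small_run):
        c = build_c_dataset(small_run["assignments"])
        fit = fit_binomial_glm(c, ["MG", "block"])
        means = ls_means(fit, "MG")
        assert (means["ci_lo"] <= means["ls_mean_logit"]).all()
        assert (means["ls_mean_logit"] <= means["ci_hi"]).all()
        assert means["backtransformed"].between(0, 1).all()


class TestContrastsAndLetters:
    def test_bonferroni_multiplies(self):
        data = pd.DataFrame(
            {"f": ["a", "b", "c", "d"], "n_cross": [10, 40, 70, 90],
             "n_self": [90, 60, 30, 10]}
        )
        fit = fit_binomial_glm(data, ["f"])
        table, _, _ = pairwise_contrasts(fit, "f", family_size=3)
        assert np.allclose(
            table["p_adj"], np.minimum(1.0, 3 * table["p_value"])
        )

    def test_all_significant_gives_distinct_letters(self):
        sig = np.ones((4, 4), dtype=bool)
        np.fill_diagonal(sig, False)
        letters = compact_letter_display(list("abcd"), sig)
        assert len(set(letters.values())) == 4
        assert all(len(v) == 1 for v in letters.values())

    def test_none_significant_shares_one_letter(self):
        sig = np.zeros((4, 4), dtype=bool)
        letters = compact_letter_display(list("abcd"), sig)
        assert set(letters.values()) == {"a"}

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 7))
    def test_letters_match_clique_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        sig = np.zeros((n, n), dtype=bool)
        for i, j in itertools.combinations(range(n), 2):
            sig[i, j] = sig[j, i] = rng.random() < 0.4
        levels = [f"L{i}" for i in range(n)]
        letters = compact_letter_display(levels, sig)
        oracle = clique_letters(sig)
        for i, j in itertools.combinations(range(n), 2):
            share = bool(set(letters[levels[i]]) & set(letters[levels[j]]))
            oracle_share = bool(oracle[i] & oracle[j])
            assert share == (not sig[i, j])
            assert oracle_share == share

    def test_group_contrast_row(self):
        data = pd.DataFrame(
            {"f": ["a", "b", "c", "d"], "n_cross": [10, 40, 70, 90],
             "n_self": [90, 60, 30, 10]}
        )
        fit = fit_binomial_glm(data, ["f"])
        row = group_contrast(fit, "f", ["a", "b"], ["c", "d"])
        table = contrasts(fit, row[None, :], ["inbred - F1"])
        expected = (np.log(10 / 90) + np.log(40 / 60)) / 2 - (
            np.log(70 / 30) + np.log(90 / 10)
        ) / 2
        assert table["estimate"].iloc[0] == pytest.approx(expected, abs=1e-8)


class TestEstimateP:
    def test_shares_sum_to_one_and_diagonal_eighth(self, small_run):
        imputed = impute_intra(pair_counts(small_run["assignments"]))
        shares = donor_shares(imputed)
        sums = shares.groupby(["MG", "block", "year"])["share"].sum()
        assert np.allclose(sums.dropna(), 1.0)
        diag = shares[shares["MG"] == shares["PG"]]["share"].dropna()
        assert np.allclose(diag, 0.125)

    def test_p_estimates_average_near_one_eighth(self, small_run):
        imputed = impute_intra(pair_counts(small_run["assignments"]))
        p = build_p_dataset(imputed)
        fit = fit_binomial_glm(p, ["PG", "MG", "PG:MG", "block"],
                               "n_cross", "n_rest")
        est = estimate_p(fit)
        assert est["backtransformed"].mean() == pytest.approx(0.125, abs=0.007)


class TestOverdispersion:
    def test_saturated_ratio_zero(self):
        data = pd.DataFrame(
            {"f": ["a", "b", "c"], "n_cross": [3, 5, 7], "n_self": [7, 5, 3]}
        )
        # one row per level -> saturated, but df_resid is 0: undefined
        fit = fit_binomial_glm(data, ["f"])
        res = overdispersion_check(fit)
        assert np.isnan(res.deviance_ratio)
        data2 = pd.concat([data, data], ignore_index=True)
        fit2 = fit_binomial_glm(data2, ["f"])
        res2 = overdispersion_check(fit2)
        assert res2.deviance_ratio == pytest.approx(0, abs=1e-10)

    def test_binomial_data_ratio_near_one(self):
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(100):
            p_true = rng.uniform(0.2, 0.8, size=4)
            k = rng.binomial(80, np.repeat(p_true, 8))
            data = pd.DataFrame(
                {"f": np.repeat(list("abcd"), 8), "n_cross": k,
                 "n_self": 80 - k}
            )
            fit = fit_binomial_glm(data, ["f"])
            ratios.append(overdispersion_check(fit).deviance_ratio)
        assert 0.8 < np.mean(ratios) < 1.2

    def test_beta_binomial_flagged(self):
        rng = np.random.default_rng(2)
        p = rng.beta(2, 2, size=40)
        k = rng.binomial(100, p)
        data = pd.DataFrame(
            {"f": ["a"] * 40, "n_cross": k, "n_self": 100 - k}
        )
        fit = fit_binomial_glm(data, [])
        res = overdispersion_check(fit)
        assert res.flagged
        assert res.deviance_ratio > 1.5


class TestCorrelation:
    def test_perfect_positive(self):
        r = correlate_c_p({"a": 1, "b": 2, "c": 3}, {"a": 2, "b": 4, "c": 6})
        assert r.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r = correlate_c_p({"a": 1, "b": 2, "c": 3}, {"a": 6, "b": 4, "c": 2})
        assert r.r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        keys = [f"g{i}" for i in range(8)]
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = correlate_c_p(dict(zip(keys, x)), dict(zip(keys, y)))
        assert res.r == pytest.approx(pearson_r_closed_form(x, y), abs=1e-12)

    def test_zero_variance_is_na(self):
        res = correlate_c_p({"a": 1, "b": 1, "c": 1}, {"a": 1, "b": 2, "c": 3})
        assert np.isnan(res.r)

    def test_subset(self):
        res = correlate_c_p(
            {"a": 1, "b": 2, "c": 3, "d": 9},
            {"a": 2, "b": 4, "c": 6, "d": 0},
            subset=["a", "b", "c"],
            label="inbred",
        )
        assert res.r == pytest.approx(1.0)
        assert res.n == 3
        assert res.subset == "inbred"

    def test_too_few_pairs(self):
        with pytest.raises(DataError):
            correlate_c_p({"a": 1, "b": 2}, {"a": 1, "b": 2})
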