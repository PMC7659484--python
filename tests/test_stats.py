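import itertools

import numpy as np
import pandas as pd
import pytest

import cytofuzz as cf


def random_groups(seed, k=16, n=4, scale=0.1, loc=1.0):
    rng = np.random.default_rng(seed)
    return {f"c{i:02d}": loc + rng.normal(0, scale, n) for i in range(k)}


class TestPairwiseT:
    def test_identical_groups_give_p_one(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        p = cf.pairwise_t_tests(groups)
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_matrix_contract(self):
        p = cf.pairwise_t_tests(random_groups(1))
        off = ~np.eye(len(p), dtype=bool)
        vals = p.to_numpy()[off]
        assert ((vals >= 0) & (vals <= 1)).all()
        pd.testing.assert_frame_equal(p, p.T)
        assert np.isnan(np.diag(p)).all()

    def test_matches_pooled_sd_oracle(self):
        """Independent closed form: t = (xi - xj) / (sp sqrt(1/ni + 1/nj)),
        sp^2 = sum (ni-1) si^2 / sum (ni-1), df = N - k."""
        from scipy.stats import t as t_dist

        groups = random_groups(42)
        p = cf.pairwise_t_tests(groups)
        names = list(groups)
        sp2 = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups.values()) / sum(
            len(g) - 1 for g in groups.values()
        )
        df = sum(len(g) for g in groups.values()) - len(groups)
        for a, b in itertools.combinations(names, 2):
            ga, gb = np.asarray(groups[a]), np.asarray(groups[b])
            t = (ga.mean() - gb.mean()) / np.sqrt(
                sp2 * (1 / ga.size + 1 / gb.size)
            )
            expected = 2 * t_dist.sf(abs(t), df)
            assert p.loc[a, b] == pytest.approx(expected, abs=1e-10)

    def test_adjusted_p_never_smaller(self):
        groups = random_groups(3)
        raw = cf.pairwise_t_tests(groups)
        for method in ("holm", "bh"):
            adj = cf.pairwise_t_tests(groups, adjust=method)
            mask = ~np.eye(len(raw), dtype=bool)
            assert (adj.to_numpy()[mask] >= raw.to_numpy()[mask] - 1e-12).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cf.pairwise_t_tests({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError, match="'b'"):
            cf.pairwise_t_tests({"a": [1.0, 2.0], "b": [1.0]})


class TestDiagnostics:
    def test_shapiro_p_uniform_under_null(self):
        """Over seeded null replicates the Shapiro-Wilk p-value is uniform
        (Kolmogorov-Smirnov check)."""
        from scipy.stats import kstest

        pvals = []
        for seed in range(500):
            groups = random_groups(seed, k=16, n=4, scale=1.0)
            pvals.append(
                cf.normality_and_variance_checks(groups)["shapiro_p"]
            )
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_bartlett_detects_variance_ratio(self):
        """Groups with a 100x variance ratio are flagged nearly always."""
        import warnings

        hits = 0
        n_rep = 200
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # the advisory warns are the point
            for seed in range(n_rep):
                rng = np.random.default_rng(seed)
                groups = {
                    f"c{i}": rng.normal(0, 10.0 if i == 0 else 1.0, 4)
                    for i in range(16)
                }
                hits += cf.normality_and_variance_checks(groups)["bartlett_p"] < 0.05
        assert hits / n_rep >= 0.95

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            cf.normality_and_variance_checks({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    def test_warns_on_failure(self):
        rng = np.random.default_rng(0)
        groups = {
            f"c{i}": rng.normal(0, 30.0 if i == 0 else 1.0, 4) for i in range(16)
        }
        with pytest.warns(UserWarning, match="Bartlett"):
            cf.normality_and_variance_checks(groups)


def anova_fixture(seed, n_per=4, signal=None):
    rng = np.random.default_rng(seed)
    levels = {"il2": (1, 10, 15), "il7": (6, 36, 80), "il15": (6, 36, 80)}
    rows = []
    for d2 in levels["il2"]:
        for d7 in levels["il7"]:
            for d15 in levels["il15"][:2]:
                for _ in range(n_per):
                    y = rng.normal(0, 1)
                    if signal is not None:
                        y += signal(d2, d7, d15)
                    rows.append((d2, d7, d15, y))
    return pd.DataFrame(rows, columns=["il2", "il7", "il15", "normalized_rate"])


class TestFactorialAnova:
    def test_structure_and_ss_identity(self):
        data = anova_fixture(0)
        table = cf.factorial_anova(data)
        assert list(table.index) == list(cf.stats.ANOVA_TERMS)
        np.testing.assert_allclose(table.Df[:-1], 1.0)
        assert table.Df.sum() == len(data) - 1
        total_ss = np.sum(
            (data.normalized_rate - data.normalized_rate.mean()) ** 2
        )
        assert table["Sum Sq"].sum() == pytest.approx(total_ss, rel=1e-8)
        np.testing.assert_allclose(
            table["Mean Sq"], table["Sum Sq"] / table["Df"], rtol=1e-12
        )

    def test_matches_sequential_projection_oracle(self):
        """Type I SS from explicit nested least-squares fits."""
        data = anova_fixture(7)
        table = cf.factorial_anova(data)
        y = data.normalized_rate.to_numpy()
        cols = [np.ones(len(data))]
        rss_prev = np.sum((y - y.mean()) ** 2)

        def rss(mat):
            beta, *_ = np.linalg.lstsq(np.column_stack(mat), y, rcond=None)
            resid = y - np.column_stack(mat) @ beta
            return np.sum(resid**2)

        terms = {
            "il2": data.il2, "il7": data.il7, "il15": data.il15,
            "il2:il7": data.il2 * data.il7, "il2:il15": data.il2 * data.il15,
            "il7:il15": data.il7 * data.il15,
            "il2:il7:il15": data.il2 * data.il7 * data.il15,
        }
        for name, col in terms.items():
            cols.append(np.asarray(col, dtype=float))
            rss_new = rss(cols)
            assert table.loc[name, "Sum Sq"] == pytest.approx(
                rss_prev - rss_new, abs=1e-10 * max(1.0, rss_prev)
            )
            rss_prev = rss_new
        assert table.loc["Residuals", "Sum Sq"] == pytest.approx(
            rss_prev, rel=1e-10
        )

    def test_pure_single_term_response(self):
        data = anova_fixture(0)
        data["normalized_rate"] = 0.3 * data.il2
        table = cf.factorial_anova(data)
        total_ss = np.sum(
            (data.normalized_rate - data.normalized_rate.mean()) ** 2
        )
        assert table.loc["il2", "Sum Sq"] == pytest.approx(total_ss, rel=1e-10)
        assert table.loc["Residuals", "Sum Sq"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_dose_rejected(self):
        data = anova_fixture(0)
        data["il15"] = 6.0
        with pytest.raises(ValueError, match="il15"):
            cf.factorial_anova(data)

    def test_categorical_variant_has_factor_dfs(self):
        table = cf.factorial_anova(anova_fixture(1), categorical=True)
        assert table.loc["il2", "Df"] == 2  # 3 levels -> 2 df


class TestCompactLetterDisplay:
    @staticmethod
    def letters_ok(letters, pmat, alpha):
        for a, b in itertools.combinations(pmat.index, 2):
            shared = set(letters[a]) & set(letters[b])
            if pmat.loc[a, b] < alpha:
                assert not shared, (a, b)
            else:
                assert shared, (a, b)

    def test_all_significant_all_distinct(self):
        p = pd.DataFrame(
            0.001 * np.ones((3, 3)), index=list("abc"), columns=list("abc")
        )
        letters = cf.compact_letter_display(p)
        assert len({letters[k] for k in "abc"}) == 3
        assert all(len(letters[k]) == 1 for k in "abc")

    def test_none_significant_single_group(self):
        p = pd.DataFrame(
            0.9 * np.ones((4, 4)), index=list("abcd"), columns=list("abcd")
        )
        letters = cf.compact_letter_display(p)
        assert len({letters[k] for k in "abcd"}) == 1

    def test_three_node_chain_example(self):
        p = pd.DataFrame(
            [[np.nan, 0.5, 0.01], [0.5, np.nan, 0.5], [0.01, 0.5, np.nan]],
            index=list("xyz"), columns=list("xyz"),
        )
        letters = cf.compact_letter_display(p)
        assert letters == {"x": "a", "y": "ab", "z": "b"}

    def test_axioms_on_all_three_node_graphs(self):
        """Exhaustive check of the display axioms over every significance
        pattern on 3 conditions."""
        names = list("pqr")
        for pattern in itertools.product([0.01, 0.5], repeat=3):
            p = pd.DataFrame(np.nan, index=names, columns=names)
            for (a, b), val in zip(itertools.combinations(names, 2), pattern):
                p.loc[a, b] = p.loc[b, a] = val
            letters = cf.compact_letter_display(p)
            self.letters_ok(letters, p, 0.05)

    def test_axioms_on_random_graphs(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(4, 8))
            names = [f"n{i}" for i in range(k)]
            p = pd.DataFrame(np.nan, index=names, columns=names)
            for a, b in itertools.combinations(names, 2):
                val = float(rng.choice([0.001, 0.2]))
                p.loc[a, b] = p.loc[b, a] = val
            letters = cf.compact_letter_display(p)
            self.letters_ok(letters, p, 0.05)

    def test_order_controls_letter_assignment(self):
        p = pd.DataFrame(
            [[np.nan, 0.01], [0.01, np.nan]], index=["lo", "hi"], columns=["lo", "hi"]
        )
        letters = cf.compact_letter_display(p, order=["hi", "lo"])
        assert letters["hi"] == "a" and letters["lo"] == "b"
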