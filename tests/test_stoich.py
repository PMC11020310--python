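"""Quotas, ratios, ANOVA/PERMANOVA partitioning, multiple testing."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from protstoich import stoich, synth


def balanced_factors(n_rep=5):
    a = np.repeat(["N", "P"], 3 * n_rep)
    b = np.tile(np.repeat([20, 24, 28], n_rep), 2)
    return a, b


class TestQuotas:
    def test_unit_arithmetic(self):
        t = pd.DataFrame(
            {"POC": [10.0], "PON": [1.6], "POP": [0.1],
             "cell_density": [1e9], "FSC_H": [2.0]}
        )
        q = stoich.cell_quotas(t)
        assert q["Q_C"].iloc[0] == pytest.approx(10.0)
        assert q["Q_C:FSC_H"].iloc[0] == pytest.approx(5.0)

    def test_zero_density_rejected(self):
        t = pd.DataFrame({"POC": [1.0], "PON": [1.0], "POP": [1.0],
                          "cell_density": [0.0]})
        with pytest.raises(ValueError, match="cell_density"):
            stoich.cell_quotas(t)

    def test_simulated_quotas_recovered(self, design):
        """Quota computation inverts the generator's concentration step."""
        table = synth.simulate_elemental(design, noise_sd=0.0, seed=0)
        q = stoich.cell_quotas(table)
        eff = synth.ElementalEffects()
        for _, row in q.iterrows():
            assert row["Q_P"] == pytest.approx(
                eff.expected("Q_P", row["nutrient_regime"], row["temperature"])
            )


class TestRatios:
    def test_redfield_identity(self):
        t = pd.DataFrame({"Q_C": [106.0], "Q_N": [16.0], "Q_P": [1.0]})
        r = stoich.element_ratios(t)
        assert r["C:P"].iloc[0] == 106.0
        assert r["N:P"].iloc[0] == 16.0
        assert r["C:N"].iloc[0] == pytest.approx(6.625)

    def test_homogeneity(self):
        t = pd.DataFrame({"Q_C": [100.0], "Q_N": [10.0], "Q_P": [1.0]})
        t2 = t.assign(Q_P=2.0)
        assert stoich.element_ratios(t2)["C:P"].iloc[0] == stoich.element_ratios(t)["C:P"].iloc[0] / 2

    def test_zero_denominator_rejected(self):
        t = pd.DataFrame({"Q_C": [1.0], "Q_N": [1.0], "Q_P": [0.0]})
        with pytest.raises(ValueError):
            stoich.element_ratios(t)


def anova_ss_oracle(y, a, b):
    """Textbook balanced two-way SS by explicit group means."""
    y = np.asarray(y, float)
    gm = y.mean()
    ss_a = sum((y[a == l].mean() - gm) ** 2 * (a == l).sum() for l in np.unique(a))
    ss_b = sum((y[b == l].mean() - gm) ** 2 * (b == l).sum() for l in np.unique(b))
    ss_cells = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            m = (a == la) & (b == lb)
            ss_cells += m.sum() * (y[m].mean() - gm) ** 2
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((y - gm) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_tot - ss_cells


class TestTwoWayAnova:
    def test_pure_a_effect(self):
        a, b = balanced_factors()
        y = np.where(a == "N", 1.0, 5.0)
        y = y + 0.0  # no noise
        res = stoich.two_way_anova(y, a, b)
        assert res.fractions["nutrient"] == pytest.approx(1.0)
        assert res.fractions["other"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(0)
        a, b = balanced_factors()
        y = rng.normal(0, 1, a.size) + (a == "N") * 1.5 + (b == 28) * 0.7
        res = stoich.two_way_anova(y, a, b)
        ss_a, ss_b, ss_ab, ss_res = anova_ss_oracle(y, a, b)
        assert res.ss["nutrient"] == pytest.approx(ss_a)
        assert res.ss["temperature"] == pytest.approx(ss_b)
        assert res.ss["interaction"] == pytest.approx(ss_ab)
        assert res.ss["residual"] == pytest.approx(ss_res)

    def test_fractions_sum_to_one_and_affine_invariant(self):
        rng = np.random.default_rng(1)
        a, b = balanced_factors()
        y = rng.normal(0, 1, a.size) + (a == "N") * 2
        r1 = stoich.two_way_anova(y, a, b)
        r2 = stoich.two_way_anova(3.5 * y - 11.0, a, b)
        assert sum(r1.fractions.values()) == pytest.approx(1.0)
        for key in r1.fractions:
            assert r1.fractions[key] == pytest.approx(r2.fractions[key])

    def test_constant_response_rejected(self):
        a, b = balanced_factors()
        with pytest.raises(ValueError, match="constant"):
            stoich.two_way_anova(np.ones(a.size), a, b)

    def test_missing_cell_rejected(self):
        a, b = balanced_factors(2)
        keep = ~((a == "N") & (b == 20))
        with pytest.raises(ValueError, match="missing cells"):
            stoich.two_way_anova(np.arange(keep.sum(), dtype=float), a[keep], b[keep])


class TestPermanova:
    def test_single_variable_equals_anova(self):
        rng = np.random.default_rng(2)
        a, b = balanced_factors()
        y = rng.normal(0, 1, a.size) + (a == "N") * 2 + (b == 24) * 0.5
        anova = stoich.two_way_anova(y, a, b)
        perm = stoich.permanova_two_way(y - y.mean(), a, b, n_perm=9, seed=0)
        for key in ("nutrient", "temperature", "other"):
            assert perm.fractions[key] == pytest.approx(anova.fractions[key], abs=1e-9)

    def test_reproducible_p_under_seed(self):
        rng = np.random.default_rng(3)
        a, b = balanced_factors(3)
        X = rng.normal(0, 1, (a.size, 4)) + (a == "N")[:, None]
        p1 = stoich.permanova_two_way(X, a, b, n_perm=199, seed=5)
        p2 = stoich.permanova_two_way(X, a, b, n_perm=199, seed=5)
        assert p1.tests == p2.tests

    def test_null_p_not_extreme(self):
        """With no factor effect, permutation p-values should not be
        systematically small."""
        rng = np.random.default_rng(4)
        a, b = balanced_factors(3)
        ps = []
        for _ in range(10):
            X = rng.normal(0, 1, (a.size, 3))
            res = stoich.permanova_two_way(X, a, b, n_perm=99, seed=1)
            ps.append(res.tests["nutrient"]["p"])
        # 10 null p-values: mean near 0.5, not clustered at the tail
        assert 0.2 < np.mean(ps) < 0.8

    def test_matches_vegan_adonis2(self, tmp_path):
        """Independent oracle: R vegan::adonis2 sequential R² and pseudo-F."""
        rng = np.random.default_rng(6)
        a, b = balanced_factors(3)
        X = rng.normal(0, 1, (a.size, 5)) + 1.2 * (a == "N")[:, None] + 0.5 * (b == 28)[:, None]
        ours = stoich.permanova_two_way(X, a, b, n_perm=99, seed=0)
        pd.DataFrame(X).to_csv(tmp_path / "X.csv", index=False)
        pd.DataFrame({"A": a, "B": b}).to_csv(tmp_path / "f.csv", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            X <- as.matrix(read.csv("X.csv"))
            f <- read.csv("f.csv")
            f$A <- factor(f$A); f$B <- factor(f$B)
            res <- adonis2(X ~ A * B, data = f, permutations = 99,
                           method = "euclidean", by = "terms")
            cat(sprintf("%.12f", c(res$R2[1:3], res$F[1:3])), sep = ",")
        """)
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "oracle.R"], cwd=tmp_path, capture_output=True, text=True, check=True
        )
        r2_a, r2_b, r2_ab, f_a, f_b, f_ab = map(float, out.stdout.strip().split(","))
        assert ours.tests["nutrient"]["R2"] == pytest.approx(r2_a, abs=1e-8)
        assert ours.tests["temperature"]["R2"] == pytest.approx(r2_b, abs=1e-8)
        assert ours.tests["interaction"]["R2"] == pytest.approx(r2_ab, abs=1e-8)
        assert ours.tests["nutrient"]["pseudo_F"] == pytest.approx(f_a, abs=1e-8)
        assert ours.tests["temperature"]["pseudo_F"] == pytest.approx(f_b, abs=1e-8)
        assert ours.tests["interaction"]["pseudo_F"] == pytest.approx(f_ab, abs=1e-8)

    def test_too_few_replicates_rejected(self):
        a = np.array(["N", "N", "P"])
        b = np.array([20, 24, 20])
        with pytest.raises(ValueError, match="2 samples"):
            stoich.permanova_two_way(np.zeros((3, 2)), a, b)


class TestMultipleTesting:
    def test_bh_hand_computation(self):
        adj = stoich.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert stoich.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(stoich.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 20)
        assert (stoich.bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stoich.bh_adjust([1.5])


class TestPairwise:
    def test_identical_groups_not_significant(self):
        y = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 3)
        out = stoich.pairwise_comparisons(y, np.repeat(["a", "b", "c"], 5))
        assert not out["significant"].any()
        assert np.allclose(out["t"], 0.0)

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(9)
        y = np.concatenate([rng.normal(0, 1, 5), rng.normal(10, 1, 5)])
        out = stoich.pairwise_comparisons(y, np.repeat(["a", "b"], 5))
        assert out["significant"].all()

    def test_pair_count(self):
        y = np.arange(20, dtype=float)
        out = stoich.pairwise_comparisons(y, np.repeat(list("abcd"), 5))
        assert len(out) == 6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stoich.pairwise_comparisons(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))
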