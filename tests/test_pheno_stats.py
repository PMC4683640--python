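"""Modified z-scores, heritability, correlations and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repro_pheno import pheno_stats, simulate
from repro_pheno.pheno_stats import (
    classify_z,
    heritability,
    one_way_anova,
    pairwise_pearson,
    strain_summaries,
    two_way_anova,
)


def _table(strain_values: dict, age=100.0):
    rows = []
    for strain, vals in strain_values.items():
        for i, v in enumerate(vals):
            rows.append((f"{strain}{i}", strain, age, v))
    return pd.DataFrame(rows, columns=["animal_id", "strain", "age_days", "t"])


class TestModifiedZ:
    def test_strain_at_population_median_scores_zero(self):
        tab = _table({"A": [2.0, 2.0, 2.0, 9.0, -5.0], "B": [1.0, 2.0, 3.0]})
        za = {s.strain: s.z for s in strain_summaries(tab, "t")}
        assert za["A"] == 0.0  # strain median == pooled median == 2

    def test_printed_formula_hand_case(self):
        # strain A: median 4, MAD 1; pooled median 2 -> z = 0.6745*2/1 = 1.349
        tab = _table({"A": [3.0, 4.0, 5.0], "B": [0.0, 1.0, 2.0, 2.0, 2.0]})
        s = {x.strain: x for x in strain_summaries(tab, "t")}
        assert s["A"].median == 4.0 and s["A"].mad == 1.0
        assert float(np.median(tab["t"])) == 2.0
        assert s["A"].z == pytest.approx(1.349, abs=5e-4)
        assert s["A"].z_class == "high"

    def test_mad_zero_falls_back_to_mean_absolute_deviation(self):
        # strain A {5,5,7}: median 5, MAD 0, meanAD 2/3; pooled median 4
        tab = _table({"A": [5.0, 5.0, 7.0], "B": [2.0, 3.0, 4.0, 4.0]})
        s = {x.strain: x for x in strain_summaries(tab, "t")}
        assert float(np.median(tab["t"])) == 4.0
        assert s["A"].mad == 0.0 and s["A"].mean_ad == pytest.approx(2 / 3)
        assert s["A"].z == pytest.approx(0.98 * 1 / (2 / 3), abs=5e-4)  # 1.47

    def test_fully_degenerate_strain_warns_and_reports_infinite(self):
        tab = _table({"A": [5.0, 5.0, 5.0], "B": [1.0, 2.0, 3.0, 3.0]})
        with pytest.warns(RuntimeWarning):
            s = {x.strain: x for x in strain_summaries(tab, "t")}
        assert np.isinf(s["A"].z) and s["A"].z > 0
        assert s["A"].z_class == "very_high"

    def test_entirely_missing_trait_rejected(self):
        tab = _table({"A": [np.nan, np.nan], "B": [np.nan]})
        with pytest.raises(ValueError):
            strain_summaries(tab, "t")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(-1e3, 1e3), st.floats(0.1, 100.0))
    def test_shift_and_scale_invariance(self, shift, scale):
        base = _table({"A": [3.0, 4.0, 5.0], "B": [0.0, 1.0, 2.0, 2.0, 2.0]})
        transformed = base.copy()
        transformed["t"] = transformed["t"] * scale + shift
        z0 = [s.z for s in strain_summaries(base, "t")]
        z1 = [s.z for s in strain_summaries(transformed, "t")]
        np.testing.assert_allclose(z0, z1, rtol=1e-9, atol=1e-9)


class TestClassifyZ:
    @pytest.mark.parametrize(
        "z, expected",
        [
            (1.0, "normal"),  # strictly larger than 1 required
            (-1.0, "normal"),
            (3.0, "high"),
            (-3.0, "low"),
            (1.0001, "high"),
            (3.2, "very_high"),
            (-3.2, "very_low"),
            (0.0, "normal"),
        ],
    )
    def test_boundaries_exclusive(self, z, expected):
        assert classify_z(z) == expected


class TestHeritability:
    def test_zero_within_strain_variance_gives_one(self):
        tab = _table({"A": [1.0, 1.0, 1.0], "B": [5.0, 5.0, 5.0]})
        assert heritability(tab, "t").h2 == pytest.approx(1.0)

    def test_null_panel_estimates_near_zero(self):
        ests = [
            heritability(
                simulate.gen_phenotypes(
                    simulate.PhenoSimConfig(va=0.0, ve=1.0, n_strains=10,
                                            n_per_strain=50, seed=s)
                ),
                "trait",
            ).h2
            for s in range(30)
        ]
        assert np.mean(ests) < 0.12

    def test_default_panel_recovers_h2_07(self):
        ests = [
            heritability(
                simulate.gen_phenotypes(simulate.PhenoSimConfig(va=0.7, ve=0.3, seed=s)),
                "trait",
            ).h2
            for s in range(60)
        ]
        assert 0.55 <= np.mean(ests) <= 0.85

    def test_estimators_agree_on_balanced_panels(self):
        for seed in range(10):
            tab = simulate.gen_phenotypes(
                simulate.PhenoSimConfig(va=0.5, ve=0.5, n_per_strain=50, seed=seed)
            )
            a = heritability(tab, "trait", "strain_mean_variance").h2
            b = heritability(tab, "trait", "anova_mom").h2
            assert a == pytest.approx(b, abs=0.02)

    def test_constant_trait_rejected(self):
        tab = _table({"A": [1.0, 1.0], "B": [1.0, 1.0]})
        with pytest.raises(ValueError):
            heritability(tab, "t")

    def test_single_strain_rejected(self):
        tab = _table({"A": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            heritability(tab, "t")


class TestCorrelations:
    def _tab(self):
        return pd.DataFrame(
            {
                "animal_id": list("abcd"),
                "strain": ["A", "A", "B", "B"],
                "age_days": [100] * 4,
                "x": [1.0, 2.0, 3.0, 4.0],
                "y": [1.0, 2.0, np.nan, 8.0],
                "z": [3.0, 5.0, 7.0, 9.0],  # exactly 2x + 1
            }
        )

    def test_self_correlation_is_one(self):
        corr = pairwise_pearson(self._tab(), ["x", "z"])
        assert corr.r.loc["x", "x"] == 1.0

    def test_exact_linear_relation(self):
        corr = pairwise_pearson(self._tab(), ["x", "z"])
        assert corr.r.loc["x", "z"] == pytest.approx(1.0)

    def test_pairwise_complete_hand_case(self):
        corr = pairwise_pearson(self._tab(), ["x", "y"])
        # complete pairs: (1,1),(2,2),(4,8) -> r ~ 0.9934
        expected = np.corrcoef([1, 2, 4], [1, 2, 8])[0, 1]
        assert corr.r.loc["x", "y"] == pytest.approx(expected, abs=1e-6)
        assert corr.n.loc["x", "y"] == 3

    def test_too_few_pairs_reported_missing(self):
        tab = self._tab()
        tab.loc[0, "y"] = np.nan  # only 2 complete pairs remain
        corr = pairwise_pearson(tab, ["x", "y"])
        assert np.isnan(corr.r.loc["x", "y"])

    def test_symmetry_and_unit_diagonal(self):
        table = simulate.gen_phenotype_panel(
            [
                simulate.PhenoSimConfig(trait_name="a", missing_rate=0.2, seed=1),
                simulate.PhenoSimConfig(trait_name="b", missing_rate=0.1),
                simulate.PhenoSimConfig(trait_name="c"),
            ]
        )
        corr = pairwise_pearson(table, ["a", "b", "c"])
        np.testing.assert_allclose(corr.r.values, corr.r.values.T)
        np.testing.assert_allclose(np.diag(corr.r.values), 1.0)


class TestAnova:
    def test_one_way_hand_case(self):
        tab = _table({"A": [1.0, 2.0, 3.0], "B": [4.0, 5.0, 6.0]})
        res = one_way_anova(tab, "t", "strain")
        row = res.table.loc["strain"]
        assert row["df"] == 1
        assert row["F"] == pytest.approx(13.5)
        assert res.table.loc["Residual", "df"] == 4

    def test_identical_groups_give_zero_f(self):
        tab = _table({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        res = one_way_anova(tab, "t", "strain")
        assert res.table.loc["strain", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_one_level_rejected(self):
        tab = _table({"A": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            one_way_anova(tab, "t", "strain")

    def test_age_effect_detected_continuously(self):
        cfg = simulate.PhenoSimConfig(va=0.0, ve=0.05, age_slope=0.02, seed=1)
        tab = simulate.gen_phenotypes(cfg)
        res = one_way_anova(tab, "trait", "age_days")
        assert res.table.loc["age_days", "p"] < 1e-6

    def test_two_way_terms_present_in_order(self):
        tab = simulate.gen_phenotypes(simulate.PhenoSimConfig(seed=0, age_slope=0.01))
        res = two_way_anova(tab, "trait")
        assert list(res.table.index) == ["strain", "age", "strain:age", "Residual"]
        assert ((res.table["p"].dropna() >= 0) & (res.table["p"].dropna() <= 1)).all()

    def test_strong_strain_effect_significant(self):
        hits = 0
        for seed in range(20):
            tab = simulate.gen_phenotypes(
                simulate.PhenoSimConfig(va=5.0, ve=0.1, seed=seed)
            )
            if two_way_anova(tab, "trait").table.loc["strain", "p"] < 0.001:
                hits += 1
        assert hits >= 19

    def test_null_pvalues_roughly_uniform(self):
        """With no strain or age effect the strain p-values follow U(0,1)."""
        from scipy.stats import kstest

        pvals = []
        for seed in range(60):
            tab = simulate.gen_phenotypes(
                simulate.PhenoSimConfig(va=0.0, ve=1.0, age_slope=0.0,
                                        n_per_strain=10, seed=seed)
            )
            pvals.append(two_way_anova(tab, "trait").table.loc["strain", "p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_trait_rejected(self):
        tab = _table({"A": [1.0, 1.0], "B": [1.0, 1.0]}, age=100.0)
        tab.loc[1, "age_days"] = 200.0
        with pytest.raises(ValueError):
            two_way_anova(tab, "t")


def test_validate_phenotype_table_reports_problems():
    good = simulate.gen_phenotypes(simulate.PhenoSimConfig(seed=0))
    assert pheno_stats.validate_phenotype_table(good) == []
    bad = good.drop(columns=["strain"])
    assert any("strain" in p for p in pheno_stats.validate_phenotype_table(bad))
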