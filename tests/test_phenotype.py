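"""qPCR, geNorm, western blot, MRI and behaviour quantification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisomap import synthetic_data as sd
from trisomap.phenotype import (
    behaviour_stats,
    comparative_ct,
    fold_induction,
    genorm_select,
    induction_summary,
    mri_compare,
    nor_chance_test,
    normalized_volumes,
    wb_relative,
)


def _ct_table(cts, genes=("gene1",)):
    rows = []
    for gi, gene in enumerate(genes):
        for si, ct in enumerate(cts[gi] if len(genes) > 1 else cts):
            rows.append({"sample": f"s{si}", "gene": gene, "ct": float(ct)})
    return pd.DataFrame(rows)


class TestComparativeCt:
    def test_minimum_ct_sample_has_quantity_one(self):
        out = comparative_ct(_ct_table([20.0, 22.0, 25.0]))
        q = out.set_index("sample")["quantity"]
        assert q["s0"] == 1.0
        assert q.max() == 1.0

    def test_two_cycles_above_minimum_quarter(self):
        out = comparative_ct(_ct_table([20.0, 22.0]))
        assert out.set_index("sample")["quantity"]["s1"] == pytest.approx(0.25)

    def test_equal_cts_all_one(self):
        out = comparative_ct(_ct_table([21.0, 21.0, 21.0]))
        assert (out["quantity"] == 1.0).all()

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            comparative_ct(_ct_table([20.0, 21.0]), efficiency=1.0)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=-5, max_value=5))
    def test_invariant_to_constant_ct_shift_per_gene(self, shift):
        base = comparative_ct(_ct_table([20.0, 21.5, 23.0]))
        shifted = comparative_ct(_ct_table([20.0 + shift, 21.5 + shift, 23.0 + shift]))
        np.testing.assert_allclose(base["quantity"], shifted["quantity"], rtol=1e-9)


class TestGenorm:
    @staticmethod
    def _brute_force_m(quant):
        logs = np.log2(quant)
        out = {}
        for j in quant.columns:
            vs = []
            for k in quant.columns:
                if k == j:
                    continue
                ratio = logs[j] - logs[k]
                vs.append(float(np.std(ratio, ddof=1)))
            out[j] = float(np.mean(vs))
        return out

    def test_proportional_candidates_have_zero_pairwise_variation(self):
        quant = pd.DataFrame(
            {"r1": [1.0, 2.0, 4.0], "r2": [0.5, 1.0, 2.0], "r3": [1.0, 1.3, 0.2]},
            index=["s1", "s2", "s3"],
        )
        res = genorm_select(quant)
        # r1 and r2 are perfectly proportional: their M comes only from r3
        logs = np.log2(quant)
        assert float((logs["r1"] - logs["r2"]).std(ddof=1)) == pytest.approx(0.0)
        assert set(res.selected) == {"r1", "r2"}

    def test_m_values_match_direct_formula_exhaustively(self):
        rng = np.random.default_rng(50)
        for n_cand, n_samp in itertools.product(range(3, 6), range(2, 7)):
            quant = pd.DataFrame(
                rng.lognormal(0, 0.5, size=(n_samp, n_cand)),
                columns=[f"r{i}" for i in range(n_cand)],
            )
            res = genorm_select(quant)
            brute = self._brute_force_m(quant)
            for gene, m in brute.items():
                assert res.m_values[gene] == pytest.approx(m, rel=1e-9)

    def test_unstable_candidate_excluded_first(self):
        rng = np.random.default_rng(51)
        stable = rng.lognormal(0, 0.05, size=(6, 3))
        unstable = rng.lognormal(0, 2.0, size=(6, 1))
        quant = pd.DataFrame(
            np.hstack([stable, unstable]), columns=["r1", "r2", "r3", "bad"]
        )
        res = genorm_select(quant, n_keep=2)
        assert res.exclusion_order[0] == "bad"
        assert "bad" not in res.selected

    def test_normalization_factor_is_geometric_mean(self):
        quant = pd.DataFrame(
            {"r1": [1.0, 4.0], "r2": [4.0, 1.0], "r3": [2.0, 2.0]}, index=["s1", "s2"]
        )
        res = genorm_select(quant, n_keep=3, m_threshold=100.0)
        np.testing.assert_allclose(res.normalization_factor, [2.0, 2.0])

    def test_zero_quantity_rejected(self):
        quant = pd.DataFrame({"r1": [1.0, 0.0], "r2": [1.0, 1.0], "r3": [2.0, 1.0]})
        with pytest.raises(ValueError, match="zero"):
            genorm_select(quant)


class TestFoldInduction:
    def _table(self):
        rows = []
        for genotype, q_dark, q_light in (("wt", [1.0, 2.0], [3.0]), ("tg", [2.0, 2.0], [8.0])):
            for i, q in enumerate(q_dark):
                rows.append({"sample": f"{genotype}_d{i}", "genotype": genotype,
                             "condition": "dark", "gene": "g", "normalized_quantity": q})
            for i, q in enumerate(q_light):
                rows.append({"sample": f"{genotype}_l{i}", "genotype": genotype,
                             "condition": "1h", "gene": "g", "normalized_quantity": q})
        return pd.DataFrame(rows)

    def test_direct_division_by_genotype_baseline(self):
        out = fold_induction(self._table())
        fi = out.set_index("sample")["fold_induction"]
        assert fi["wt_l0"] == pytest.approx(3.0 / 1.5)
        assert fi["tg_l0"] == pytest.approx(4.0)

    def test_dark_group_averages_to_one(self):
        out = fold_induction(self._table())
        dark = out[out["condition"] == "dark"]
        means = dark.groupby("genotype")["fold_induction"].mean()
        np.testing.assert_allclose(means, 1.0)

    def test_missing_baseline_rejected(self):
        table = self._table()
        table = table[~((table["genotype"] == "tg") & (table["condition"] == "dark"))]
        with pytest.raises(ValueError, match="baseline"):
            fold_induction(table)

    def test_summary_reports_mean_and_sem(self):
        out = induction_summary(fold_induction(self._table()))
        row = out[(out["genotype"] == "wt") & (out["condition"] == "dark")].iloc[0]
        assert row["mean"] == pytest.approx(1.0)
        assert row["sem"] > 0


class TestWesternBlot:
    def test_wt_mean_is_one(self):
        signal = pd.Series([1.0, 1.0, 2.0, 1.0], index=["w1", "w2", "w3", "m1"])
        loading = pd.Series(1.0, index=signal.index)
        out = wb_relative(signal, loading, ["w1", "w2", "w3"])
        assert out[["w1", "w2", "w3"]].mean() == pytest.approx(1.0)
        assert out["m1"] == pytest.approx(0.75)

    def test_scale_invariance(self):
        signal = pd.Series([1.2, 0.8, 1.5], index=["w1", "w2", "m1"])
        loading = pd.Series([1.0, 0.9, 1.1], index=signal.index)
        a = wb_relative(signal, loading, ["w1", "w2"])
        b = wb_relative(signal * 7.3, loading, ["w1", "w2"])
        np.testing.assert_allclose(a, b)

    def test_empty_wt_group_rejected(self):
        signal = pd.Series([1.0], index=["m1"])
        with pytest.raises(ValueError, match="wild-type"):
            wb_relative(signal, pd.Series([1.0], index=["m1"]), [])


class TestMri:
    def test_identical_groups_not_significant(self):
        design = sd.PhenotypeDesign(n_per_group=8, mri_effect={})
        morpho = sd.simulate_morphometry(design, seed=52)
        out = mri_compare(morpho)
        assert (out["q"] > 0.05).all()

    def test_planted_enlargement_detected(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            design = sd.PhenotypeDesign(n_per_group=8, mri_effect={"s03": 1.2})
            morpho = sd.simulate_morphometry(design, seed=100 + seed)
            out = mri_compare(morpho).set_index("structure")
            if out.loc["s03", "q"] < 0.05 and (out.drop("s03")["q"] > 0.05).all():
                hits += 1
        assert hits >= int(0.9 * n_runs)

    def test_q_monotone_in_p(self):
        design = sd.PhenotypeDesign(n_per_group=6, mri_effect={"s01": 1.1})
        out = mri_compare(sd.simulate_morphometry(design, seed=53)).sort_values("p")
        assert out["q"].is_monotonic_increasing

    def test_structure_larger_than_brain_rejected(self):
        bad = pd.DataFrame(
            {"animal": ["a1", "a2", "b1", "b2"], "group": ["wt", "wt", "tg", "tg"],
             "whole_brain": [100.0] * 4, "s01": [150.0, 90.0, 90.0, 90.0]}
        )
        with pytest.raises(ValueError, match="whole brain"):
            normalized_volumes(bad)


class TestBehaviourStats:
    def test_identical_groups_no_posthoc(self):
        rng = np.random.default_rng(54)
        table = pd.DataFrame(
            {"group": ["a"] * 10 + ["b"] * 10, "score": rng.normal(50, 5, 20)}
        )
        rep = behaviour_stats(table, "score")
        assert rep.p_value > 0.05
        assert rep.posthoc is None

    def test_two_group_anova_f_equals_t_squared(self):
        rng = np.random.default_rng(55)
        table = pd.DataFrame(
            {
                "group": ["a"] * 12 + ["b"] * 12,
                "score": np.concatenate([rng.normal(50, 5, 12), rng.normal(58, 5, 12)]),
            }
        )
        rep = behaviour_stats(table, "score")
        from scipy import stats as sps

        a = table.loc[table["group"] == "a", "score"]
        b = table.loc[table["group"] == "b", "score"]
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert rep.test == "anova"
        assert rep.statistic == pytest.approx(t**2, rel=1e-9)

    def test_posthoc_runs_only_when_omnibus_passes(self):
        rng = np.random.default_rng(56)
        table = pd.DataFrame(
            {
                "group": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                "score": np.concatenate(
                    [rng.normal(50, 4, 10), rng.normal(50, 4, 10), rng.normal(65, 4, 10)]
                ),
            }
        )
        rep = behaviour_stats(table, "score")
        assert rep.test == "anova" and rep.p_value < 0.05
        assert rep.posthoc is not None
        sig = rep.posthoc[rep.posthoc["p"] < 0.05]
        assert {"a", "b"} <= set(sig["group_a"]) | set(sig["group_b"])

    def test_nonnormal_data_goes_nonparametric(self):
        rng = np.random.default_rng(57)
        table = pd.DataFrame(
            {
                "group": ["a"] * 15 + ["b"] * 15,
                "score": np.concatenate(
                    [rng.lognormal(0, 2.0, 15), rng.lognormal(0.5, 2.0, 15)]
                ),
            }
        )
        rep = behaviour_stats(table, "score")
        assert rep.test == "kruskal"

    def test_small_group_forces_nonparametric(self):
        table = pd.DataFrame(
            {"group": ["a", "a", "b", "b", "b"], "score": [1.0, 2.0, 3.0, 4.0, 5.0]}
        )
        rep = behaviour_stats(table, "score")
        assert rep.test == "kruskal"
        assert any("n < 3" in n for n in rep.notes)

    def test_pure_function_of_table(self):
        rng = np.random.default_rng(58)
        table = pd.DataFrame(
            {"group": ["a"] * 8 + ["b"] * 8, "score": rng.normal(50, 5, 16)}
        )
        a = behaviour_stats(table, "score")
        b = behaviour_stats(table.copy(), "score")
        assert (a.test, a.statistic, a.p_value) == (b.test, b.statistic, b.p_value)

    def test_nor_at_chance_level(self):
        values = np.array([48.0, 52.0, 50.0, 49.0, 51.0])
        t, p = nor_chance_test(values)
        assert abs(t) < 0.5
        assert p > 0.5

    def test_nor_detects_preference(self):
        rng = np.random.default_rng(59)
        values = rng.normal(65, 5, 12)
        _, p = nor_chance_test(values)
        assert p < 0.001
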