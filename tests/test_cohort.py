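import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stemindex import cohort as co
from stemindex import synthetic as syn
from oracles import fisher_two_sided_oracle, one_way_anova_oracle


def _result(indices, cbc=None):
    idx = [f"s{i:03d}" for i in range(len(indices))]
    return pd.DataFrame(
        {
            "cbc_score": cbc if cbc is not None else np.zeros(len(indices)),
            "rsc_score": np.zeros(len(indices)),
            "stem_cell_index": np.asarray(indices, dtype=float),
        },
        index=idx,
    )


class TestPolarizedDeciles:
    def test_extremes_selected(self):
        tab = _result(np.arange(20.0))
        da = co.polarized_deciles(tab)
        assert da.n_per_decile == 2
        assert set(da.table.index[da.table["decile"] == "CBC-enriched"]) == {"s000", "s001"}
        assert set(da.table.index[da.table["decile"] == "RSC-enriched"]) == {"s018", "s019"}

    def test_negating_index_swaps_deciles(self):
        tab = _result(np.arange(20.0) - 10.0)
        a = co.polarized_deciles(tab).table["decile"]
        b = co.polarized_deciles(_result(-(np.arange(20.0) - 10.0))).table["decile"]
        swapped = b.map(
            {"CBC-enriched": "RSC-enriched", "RSC-enriched": "CBC-enriched", "middle": "middle"}
        )
        assert (a == swapped).all()

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(17)
        idx = rng.normal(size=100)
        tab = _result(idx)
        da = co.polarized_deciles(tab)
        order = np.argsort(idx, kind="stable")
        low = set(tab.index[order[:10]])
        high = set(tab.index[order[-10:]])
        assert set(da.table.index[da.table["decile"] == "CBC-enriched"]) == low
        assert set(da.table.index[da.table["decile"] == "RSC-enriched"]) == high

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            co.polarized_deciles(_result(np.arange(9.0)))

    def test_ties_broken_by_cbc_score_then_id(self):
        tab = _result([0.0] * 20, cbc=np.linspace(1, 0, 20))
        da = co.polarized_deciles(tab)
        # higher cbc_score sorts first -> lands in the CBC-enriched decile
        assert set(da.table.index[da.table["decile"] == "CBC-enriched"]) == {"s000", "s001"}


class TestCategorizeCnv:
    @pytest.mark.parametrize(
        "value,expected",
        [(-0.31, -1), (-0.3, 0), (0.3, 0), (0.31, 1), (0.0, 0), (-5.0, -1), (5.0, 1)],
    )
    def test_thresholds_strict(self, value, expected):
        out = co.categorize_cnv(pd.DataFrame({"value": [value]}))
        assert out["category"].iloc[0] == expected

    def test_manual_oracle(self):
        vals = [-0.6, -0.31, -0.3, -0.1, 0.0, 0.1, 0.3, 0.31, 0.8, 2.0]
        out = co.categorize_cnv(pd.DataFrame({"value": vals}))
        assert list(out["category"]) == [-1, -1, 0, 0, 0, 0, 0, 1, 1, 1]

    def test_non_finite_errors(self):
        with pytest.raises(ValueError, match="non-finite"):
            co.categorize_cnv(pd.DataFrame({"value": [np.nan]}))


class TestPathwayPrevalence:
    def _deciles(self, n=20):
        return co.polarized_deciles(_result(np.arange(float(n))))

    def test_counting(self):
        da = co.polarized_deciles(_result(np.arange(100.0)))
        cbc_samples = list(da.table.index[da.table["decile"] == "CBC-enriched"])
        muts = pd.DataFrame(
            {
                "sample": cbc_samples[:6],
                "gene": ["APC"] * 6,
                "pathogenic": [True] * 6,
            }
        )
        prev = co.pathway_prevalence(muts, {"Wnt": ["APC", "CTNNB1"]}, da)
        row = prev[(prev["pathway"] == "Wnt") & (prev["decile"] == "CBC-enriched")].iloc[0]
        assert row["n_samples"] == 10
        assert row["n_mutated"] == 6
        assert row["prevalence"] == pytest.approx(0.6)

    def test_empty_pathway_zero_with_warning(self):
        da = self._deciles()
        muts = pd.DataFrame({"sample": ["s000"], "gene": ["APC"], "pathogenic": [True]})
        with pytest.warns(UserWarning, match="no gene"):
            prev = co.pathway_prevalence(muts, {"Empty": ["ZZZ"]}, da)
        assert (prev["prevalence"] == 0).all()

    def test_planted_rates_recovered(self):
        rng = np.random.default_rng(2)
        da = co.polarized_deciles(_result(np.arange(200.0)))
        dec = da.table["decile"]
        rates = {"CBC-enriched": 0.7, "RSC-enriched": 0.2, "middle": 0.4}
        rows = []
        for s in dec.index:
            if rng.random() < rates[dec[s]]:
                rows.append({"sample": s, "gene": "KRAS", "pathogenic": True})
        muts = pd.DataFrame(rows)
        prev = co.pathway_prevalence(muts, {"MAPK": ["KRAS"]}, da)
        for d, r in rates.items():
            got = prev[(prev["decile"] == d)]["prevalence"].iloc[0]
            n = prev[(prev["decile"] == d)]["n_samples"].iloc[0]
            assert abs(got - r) <= 3 * np.sqrt(r * (1 - r) / n)


class TestClassifyPlasticity:
    def test_sign_flip_is_plastic(self):
        calls = co.classify_plasticity(
            pd.DataFrame({"patient": ["a"], "pre_index": [0.2], "post_index": [-0.1]})
        )
        assert calls[0].group == "plastic"
        assert calls[0].pre_class == "RSC-positive"
        assert calls[0].post_class == "CBC-positive"

    def test_same_sign_is_static(self):
        calls = co.classify_plasticity(
            pd.DataFrame({"patient": ["a"], "pre_index": [0.2], "post_index": [0.05]})
        )
        assert calls[0].group == "static"

    def test_zero_index_is_cbc_positive(self):
        calls = co.classify_plasticity(
            pd.DataFrame({"patient": ["a"], "pre_index": [0.0], "post_index": [-0.2]})
        )
        assert calls[0].pre_class == "CBC-positive"
        assert calls[0].group == "static"

    def test_planted_labels_fully_recovered(self):
        pairs, _, truth = syn.simulate_paired(syn.PairedSimConfig(seed=3))
        calls = co.classify_plasticity(pairs)
        got = {c.patient: c.group for c in calls}
        assert all(got[p] == g for p, g in zip(truth["patient"], truth["group"]))
        assert len(calls) == 75

    def test_missing_pair_member_errors(self):
        with pytest.raises(ValueError, match="pt2"):
            co.classify_plasticity(
                pd.DataFrame(
                    {"patient": ["pt1", "pt2"], "pre_index": [0.1, 0.2], "post_index": [0.1, np.nan]}
                )
            )


class TestFisherAssociation:
    def _calls_labels(self, table):
        calls, rows = [], []
        k = 0
        for i, group in enumerate(["static", "plastic"]):
            for j, resp in enumerate([True, False]):
                for _ in range(table[i][j]):
                    pid = f"p{k}"
                    k += 1
                    calls.append(
                        co.PlasticityCall(pid, 0.1, 0.1 if group == "static" else -0.1,
                                          "RSC-positive", "RSC-positive" if group == "static" else "CBC-positive",
                                          group)
                    )
                    rows.append({"patient": pid, "responder": resp})
        return calls, pd.DataFrame(rows)

    def test_balanced_table_p_one(self):
        calls, labels = self._calls_labels([[5, 5], [5, 5]])
        table, p, odds = co.fisher_association(calls, labels)
        assert p == pytest.approx(1.0)
        assert table.tolist() == [[5, 5], [5, 5]]

    @pytest.mark.parametrize("tab", [[[3, 7], [8, 2]], [[1, 9], [5, 5]], [[0, 4], [6, 1]]])
    def test_matches_hypergeometric_enumeration(self, tab):
        calls, labels = self._calls_labels(tab)
        _, p, _ = co.fisher_association(calls, labels)
        assert p == pytest.approx(fisher_two_sided_oracle(tab), abs=1e-12)
        assert 0 < p <= 1

    def test_row_swap_invariance(self):
        calls1, labels1 = self._calls_labels([[3, 7], [8, 2]])
        calls2, labels2 = self._calls_labels([[8, 2], [3, 7]])
        _, p1, _ = co.fisher_association(calls1, labels1)
        _, p2, _ = co.fisher_association(calls2, labels2)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_transposition_invariance(self):
        t1 = [[3, 7], [8, 2]]
        t2 = [[3, 8], [7, 2]]
        assert fisher_two_sided_oracle(t1) == pytest.approx(fisher_two_sided_oracle(t2), abs=1e-12)
        calls1, labels1 = self._calls_labels(t1)
        _, p1, _ = co.fisher_association(calls1, labels1)
        calls2, labels2 = self._calls_labels(t2)
        _, p2, _ = co.fisher_association(calls2, labels2)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_margin_warns_p_one(self):
        calls, labels = self._calls_labels([[5, 5], [0, 0]])
        with pytest.warns(UserWarning, match="degenerate"):
            _, p, _ = co.fisher_association(calls, labels)
        assert p == 1.0

    def test_haldane_odds_ratio_with_zero_cell(self):
        calls, labels = self._calls_labels([[0, 4], [6, 1]])
        _, _, odds = co.fisher_association(calls, labels)
        assert odds == pytest.approx((0.5 * 1.5) / (4.5 * 6.5))

    def test_response_grades_map_to_flags(self):
        assert not co.responder_flag("none")
        assert not co.responder_flag("mild")
        assert co.responder_flag("moderate")
        assert co.responder_flag("marked")
        with pytest.raises(ValueError):
            co.responder_flag("extreme")


class TestReproStats:
    def test_identical_within_tumors(self):
        tab = pd.DataFrame(
            {"tumor": ["a", "a", "b", "b"], "biopsy": list("1212"), "index": [1.0, 1.0, 3.0, 3.0]}
        )
        st_ = co.repro_stats(tab)
        assert st_.icc == pytest.approx(1.0)
        assert st_.within_cv == pytest.approx(0.0)

    def test_all_identical_returns_zero_with_warning(self):
        tab = pd.DataFrame(
            {"tumor": ["a", "a", "b", "b"], "biopsy": list("1212"), "index": [2.0] * 4}
        )
        with pytest.warns(UserWarning, match="zero total variance"):
            st_ = co.repro_stats(tab)
        assert st_.icc == 0.0

    def test_hand_anova_toy(self):
        tab = pd.DataFrame(
            {
                "tumor": ["T1", "T1", "T2", "T2", "T3", "T3"],
                "biopsy": list("121212"),
                "index": [1.0, 1.2, 2.0, 2.4, 3.1, 2.9],
            }
        )
        st_ = co.repro_stats(tab)
        assert st_.icc == pytest.approx(0.9569892473118279, abs=1e-12)
        assert st_.sigma2_between == pytest.approx(0.89, abs=1e-12)
        assert st_.sigma2_within == pytest.approx(0.04, abs=1e-12)
        assert st_.within_cv == pytest.approx(9.523809523809524, abs=1e-9)
        assert st_.between_cv == pytest.approx(44.92371967646002, abs=1e-9)

    def test_matches_anova_oracle_unbalanced(self):
        rng = np.random.default_rng(21)
        rows = []
        groups = []
        for t, n in enumerate([2, 5, 3, 4]):
            vals = rng.normal(5.0 + t, 0.5, size=n)
            groups.append(vals)
            rows += [{"tumor": f"T{t}", "biopsy": f"B{b}", "index": v} for b, v in enumerate(vals)]
        st_ = co.repro_stats(pd.DataFrame(rows))
        oracle = one_way_anova_oracle(groups)
        assert st_.icc == pytest.approx(oracle["icc"], abs=1e-12)
        assert st_.sigma2_between == pytest.approx(oracle["s2b"], abs=1e-12)

    def test_matches_pingouin_icc1_balanced(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(30)
        rows = []
        for t in range(12):
            mu = rng.normal(2.0, 1.0)
            for b in range(4):
                rows.append({"tumor": f"T{t:02d}", "biopsy": f"B{b}", "index": mu + rng.normal(0, 0.4)})
        tab = pd.DataFrame(rows)
        st_ = co.repro_stats(tab)
        icc1 = pingouin.intraclass_corr(
            data=tab, targets="tumor", raters="biopsy", ratings="index"
        ).set_index("Type").loc["ICC(1,1)", "ICC"]
        assert st_.icc == pytest.approx(icc1, abs=1e-6)

    def test_near_zero_mean_cvs_undefined(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(
            {
                "tumor": np.repeat([f"T{i}" for i in range(10)], 3),
                "biopsy": list("012") * 10,
                "index": rng.normal(0, 1, 30) - rng.normal(0, 1, 30).mean(),
            }
        )
        tab["index"] -= tab["index"].mean()  # force grand mean to 0
        with pytest.warns(UserWarning, match="grand mean"):
            st_ = co.repro_stats(tab)
        assert np.isnan(st_.within_cv) and np.isnan(st_.between_cv)
        assert -1 <= st_.icc <= 1

    def test_single_tumor_errors(self):
        tab = pd.DataFrame({"tumor": ["a", "a"], "biopsy": ["1", "2"], "index": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">= 2 tumors"):
            co.repro_stats(tab)
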