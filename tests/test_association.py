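"""Contingency-table association statistics and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from pesuscept import (
    GenoSimConfig,
    SnpModel,
    allele_association,
    allele_counts,
    carrier_test,
    chi_square,
    combined_genotype_association,
    generate_genotype_dataset,
    genotype_association,
    genotype_counts_from_records,
    hwe_test,
    odds_ratio,
    risk_marker_association,
)
from pesuscept.association import DegenerateTableError, GenotypeCounts
from pesuscept import study_counts as sc


class TestAlleleCounts:
    def test_reference_control_margins(self):
        tab = allele_counts(sc.RS2069740)
        assert tab.loc["control", "A"] == 47
        assert tab.loc["control", "T"] == 253

    def test_reference_case_margins(self):
        tab = allele_counts(sc.RS2069740)
        assert tab.loc["case", "A"] == 26
        assert tab.loc["case", "T"] == 274

    def test_all_het_group(self):
        gc = GenotypeCounts("x", "T", "A", control=(0, 12, 0), case=(0, 5, 0))
        tab = allele_counts(gc)
        assert tab.loc["control", "T"] == tab.loc["control", "A"] == 12
        assert tab.loc["case", "T"] == tab.loc["case", "A"] == 5

    def test_chromosome_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ctrl = tuple(rng.integers(0, 80, size=3))
            case = tuple(rng.integers(0, 80, size=3))
            gc = GenotypeCounts("x", "C", "A", ctrl, case)
            tab = allele_counts(gc)
            assert tab.loc["control"].sum() == 2 * sum(ctrl)
            assert tab.loc["case"].sum() == 2 * sum(case)


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        res = chi_square([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_scipy_uncorrected(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            tab = rng.integers(1, 60, size=(rng.integers(2, 4), rng.integers(2, 4)))
            res = chi_square(tab)
            s, p, df, _ = chi2_contingency(tab, correction=False)
            assert res.statistic == pytest.approx(s)
            assert res.p_value == pytest.approx(p)
            assert res.df == df

    def test_permutation_oracle_2x2(self):
        # compare against a margin-preserving permutation null
        tab = np.array([[18, 32], [31, 19]])
        res = chi_square(tab)
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], tab.sum(axis=1))
        cols = np.repeat([0, 1], tab.sum(axis=0))
        stat_obs = res.statistic
        n_reps = 20000
        hits = 0
        for _ in range(n_reps):
            rng.shuffle(cols)
            perm = np.zeros((2, 2))
            np.add.at(perm, (labels, cols), 1)
            e = np.outer(perm.sum(1), perm.sum(0)) / perm.sum()
            stat = ((perm - e) ** 2 / e).sum()
            hits += stat >= stat_obs - 1e-9
        p_perm = hits / n_reps
        assert res.p_value == pytest.approx(p_perm, abs=0.01)

    def test_empty_line_dropped_then_degenerate(self):
        with pytest.warns(UserWarning, match="empty"):
            with pytest.raises(DegenerateTableError):
                chi_square([[0, 0], [5, 9]])

    def test_yates_requires_2x2(self):
        with pytest.raises(ValueError):
            chi_square(np.ones((2, 3), dtype=int), correction="yates")

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=4)
    )
    @settings(max_examples=80, deadline=None)
    def test_yates_never_exceeds_uncorrected(self, cells):
        tab = np.array(cells).reshape(2, 2)
        if (tab.sum(0) == 0).any() or (tab.sum(1) == 0).any():
            return
        assert (
            chi_square(tab, "yates").statistic
            <= chi_square(tab, "none").statistic + 1e-12
        )

    @given(
        st.lists(st.integers(min_value=1, max_value=40), min_size=6, max_size=6),
        st.permutations([0, 1]),
        st.permutations([0, 1, 2]),
    )
    @settings(max_examples=60, deadline=None)
    def test_row_column_permutation_invariance(self, cells, rperm, cperm):
        tab = np.array(cells).reshape(2, 3)
        base = chi_square(tab)
        perm = chi_square(tab[np.array(rperm)][:, np.array(cperm)])
        assert perm.statistic == pytest.approx(base.statistic)


class TestStudyTables:
    """The published counts reproduce the printed statistics."""

    def test_rs2069740_alleles(self):
        res = allele_association(sc.RS2069740)
        assert round(res.p_value, 3) == 0.009
        assert res.correction == "none"

    def test_rs2069740_genotypes(self):
        assert round(genotype_association(sc.RS2069740).p_value, 3) == 0.099

    def test_rs34255686_genotypes(self):
        assert round(genotype_association(sc.RS34255686).p_value, 3) == 0.002

    def test_rs34255686_alleles_below_half_percent(self):
        # printed as "0.00"; derived-from-genotype counts give p << 0.005
        assert allele_association(sc.RS34255686).p_value < 0.005

    def test_tt_aa_combined_yates(self):
        res = carrier_test(0, 150, 13, 150)
        assert res.correction == "yates"
        assert round(res.p_value, 3) == 0.001

    def test_tt_cc_combined_uncorrected(self):
        res = carrier_test(117, 150, 106, 150)
        assert res.correction == "none"
        assert res.p_value == pytest.approx(0.146, abs=0.001)

    def test_hellp_marker(self):
        tab = sc.RISK_MARKER_TABLES["rs34255686"]["hellp"]
        assert round(chi_square(tab).p_value, 3) == 0.008

    def test_edema_marker(self):
        tab = sc.RISK_MARKER_TABLES["rs34255686"]["edema"]
        assert round(chi_square(tab).p_value, 3) == 0.047

    def test_risk_marker_from_subject_records(self):
        tab = sc.RISK_MARKER_TABLES["rs34255686"]["edema"]
        rec = sc.expand_records(tab, "rs34255686", "edema")
        res = risk_marker_association(rec, "edema", "rs34255686", sc.RS34255686)
        assert res.p_value == pytest.approx(chi_square(tab).p_value)
        assert res.df == 6

    def test_risk_marker_single_level_degenerate(self):
        rec = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "status": ["case", "case"],
                "edema": ["absent", "absent"],
                "rs34255686": ["CC", "CA"],
            }
        )
        with pytest.raises(DegenerateTableError):
            risk_marker_association(rec, "edema", "rs34255686", sc.RS34255686)

    def test_qc_flags_hwe_violations(self):
        notes = sc.qc_warnings()
        assert any("rs2069740 control" in n for n in notes)
        assert any("allele rows conflict" in n for n in notes)


class TestCombinedGenotypes:
    def test_subject_level_pipeline(self):
        # simulate subjects at both SNPs and verify carrier tables add up
        cfg = GenoSimConfig(
            snps=(
                SnpModel("rs2069740", "T", "A", 0.2, 1.0),
                SnpModel("rs34255686", "C", "A", 0.1, 2.0),
            ),
            seed=5,
        )
        rec = generate_genotype_dataset(cfg)
        gc1 = genotype_counts_from_records(rec, "rs2069740", "T", "A")
        gc2 = genotype_counts_from_records(rec, "rs34255686", "C", "A")
        results = combined_genotype_association(rec, gc1, gc2)
        assert results["_excluded"] == 0
        total_carriers = {"case": 0, "control": 0}
        for name, res in results.items():
            if name == "_excluded":
                continue
            for group in ("case", "control"):
                row = res.table.loc[group]
                assert row.sum() == 150
                total_carriers[group] += row["carrier"]
        assert total_carriers == {"case": 150, "control": 150}

    def test_absent_combination_flagged(self):
        rec = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "status": ["case", "case", "control", "control"],
                "s1": ["TT", "TT", "TT", "TT"],
                "s2": ["CC", "CC", "CC", "CC"],
            }
        )
        gc1 = genotype_counts_from_records(rec, "s1", "T", "A")
        gc2 = genotype_counts_from_records(rec, "s2", "C", "A")
        results = combined_genotype_association(rec, gc1, gc2)
        assert not results["AA-AA"].estimable
        assert results["TT-CC"].table.loc["case", "carrier"] == 2

    def test_missing_genotype_excluded_with_count(self):
        rec = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c", "d"],
                "status": ["case", "case", "control", "control"],
                "s1": ["TT", None, "TT", "AT"],
                "s2": ["CC", "CC", "CA", "CC"],
            }
        )
        gc1 = GenotypeCounts("s1", "T", "A", (1, 1, 0), (1, 0, 0))
        gc2 = GenotypeCounts("s2", "C", "A", (1, 1, 0), (1, 0, 0))
        results = combined_genotype_association(rec, gc1, gc2)
        assert results["_excluded"] == 1


class TestHweTest:
    def test_exact_proportions_give_zero(self):
        res = hwe_test((25, 50, 25))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_reference_control_violation(self):
        # expectations 106.68 / 39.64 / 3.68 computed by hand from q=0.157
        res = hwe_test(sc.RS2069740.control)
        assert res.statistic == pytest.approx(101.7, abs=0.1)
        assert res.p_value < 1e-3
        assert np.allclose(res.table["expected"], [106.68, 39.64, 3.68], atol=0.01)

    def test_monomorphic_not_estimable(self):
        res = hwe_test((30, 0, 0))
        assert not res.estimable

    def test_nominal_type_one_error(self):
        rng = np.random.default_rng(17)
        q = 0.2
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        rej = 0
        reps = 1000
        for _ in range(reps):
            draw = rng.multinomial(150, probs)
            res = hwe_test(tuple(draw))
            rej += res.estimable and res.p_value < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.025)


class TestOddsRatio:
    def test_symmetric_table_unity(self):
        res = odds_ratio([[10, 10], [10, 10]])
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low < 1 < res.ci_high

    def test_reference_allele_table(self):
        # case A=26 / T=274 against control A=47 / T=253
        res = odds_ratio([[26, 274], [47, 253]])
        assert res.estimate == pytest.approx((26 * 253) / (274 * 47), rel=1e-12)
        assert res.estimate == pytest.approx(0.511, abs=0.001)

    def test_zero_cell_haldane_ci_excludes_one(self):
        res = odds_ratio([[13, 137], [0, 150]])
        assert res.haldane
        assert np.isfinite(res.estimate)
        assert res.ci_low > 1.0

    def test_matches_statsmodels_on_positive_tables(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(3)
        for _ in range(10):
            tab = rng.integers(1, 50, size=(2, 2))
            mine = odds_ratio(tab)
            theirs = sm.Table2x2(tab)
            assert mine.estimate == pytest.approx(theirs.oddsratio)
            lo, hi = theirs.oddsratio_confint()
            assert mine.ci_low == pytest.approx(lo, rel=1e-6)
            assert mine.ci_high == pytest.approx(hi, rel=1e-6)

    def test_full_zero_line_not_estimable(self):
        with pytest.raises(DegenerateTableError):
            odds_ratio([[0, 10], [0, 20]])
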