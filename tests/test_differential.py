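"""Detection G test, equalizing imputation, moderated t, FDR, DAP calls."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

from plaqueomics import (
    bh_fdr,
    call_daps,
    differential_analysis,
    equalizing_impute,
    g_test,
    log2fc_zscores,
    moderated_paired_ttest,
    tracer_correlation_screen,
)
from plaqueomics.differential import _equalize_row, fit_variance_prior
from plaqueomics.matrix import IntensityMatrix

from conftest import make_matrix


class TestGTest:
    def test_identical_proportions(self):
        g, p = g_test(5, 10, 5, 10)
        assert g == 0.0 and p == 1.0

    def test_complete_separation_closed_form(self):
        g, p = g_test(10, 10, 0, 10)
        assert g == pytest.approx(40 * np.log(2), abs=1e-12)
        assert p == pytest.approx(sp_stats.chi2.sf(40 * np.log(2), 1), rel=1e-10)

    def test_partial_table(self):
        g, p = g_test(8, 10, 3, 10)
        assert g == pytest.approx(5.30, abs=0.01)
        assert p == pytest.approx(0.021, abs=0.001)

    def test_degenerate_margins(self):
        assert g_test(10, 10, 10, 10) == (0.0, 1.0)  # all detected
        assert g_test(0, 10, 0, 10) == (0.0, 1.0)  # all missing

    def test_matches_likelihood_ratio_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n1, n2 = rng.integers(2, 30, 2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            g, p = g_test(int(k1), int(n1), int(k2), int(n2))
            obs = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            if obs.sum(axis=0).min() == 0:
                assert (g, p) == (0.0, 1.0)
                continue
            ref = sp_stats.chi2_contingency(obs, correction=False,
                                            lambda_="log-likelihood")
            assert g == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invalid_table(self):
        with pytest.raises(ValueError):
            g_test(11, 10, 3, 10)


class TestEqualizingImpute:
    def _matrix(self, row):
        vals = np.vstack([row, np.full(len(row), 5.0)])  # second protein sets floors
        return make_matrix(vals, protein_ids=["X", "FLOOR"])

    def test_gate_closed_no_imputation(self):
        m = self._matrix([np.nan, 10, np.nan, 10, np.nan, 10, 10, 10])
        g1 = list(m.sample_ids[:4]); g2 = list(m.sample_ids[4:])
        row, imputed = equalizing_impute(m, "X", g1, g2, g_p=0.5)
        assert imputed == []
        assert row.equals(m.values.loc["X"])

    def test_deficient_group_equalized(self):
        row = np.array([10.0] * 10 + [11.0] * 4 + [np.nan] * 6)
        vals = np.vstack([row, np.full(20, 5.0)])
        m = make_matrix(vals, protein_ids=["X", "FLOOR"], ages=(3, 8))
        g1, g2 = list(m.sample_ids[:10]), list(m.sample_ids[10:])
        new_row, imputed = equalizing_impute(m, "X", g1, g2, g_p=0.01)
        assert len(imputed) == 6
        assert new_row[g2].notna().sum() == 10
        assert (new_row[imputed] == 5.0).all()  # sample minimum across proteins
        assert new_row[g1].equals(m.values.loc["X", g1])  # better group untouched

    def test_already_equal_no_change(self):
        row = np.array([10, np.nan, 10, 10, 10, np.nan, 10, 10], dtype=float)
        m = self._matrix(row)
        g1, g2 = list(m.sample_ids[:4]), list(m.sample_ids[4:])
        _, imputed = equalizing_impute(m, "X", g1, g2, g_p=0.01)
        assert imputed == []

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_contract_properties(self, data):
        """The better-detected group is never touched and the detection
        imbalance never increases."""
        n1 = data.draw(st.integers(2, 10))
        n2 = data.draw(st.integers(2, 10))
        det1 = data.draw(st.integers(0, n1))
        det2 = data.draw(st.integers(0, n2))
        g1 = [f"a{i:02d}" for i in range(n1)]
        g2 = [f"b{i:02d}" for i in range(n2)]
        row = pd.Series(
            [10.0 if i < det1 else np.nan for i in range(n1)]
            + [10.0 if i < det2 else np.nan for i in range(n2)],
            index=g1 + g2,
        )
        minima = pd.Series(3.0, index=g1 + g2)
        new_row, imputed = _equalize_row(row, g1, g2, minima, g_p=0.01, alpha=0.05)
        better = g1 if det1 >= det2 else g2
        assert new_row[better].equals(row[better])
        d_before = abs(det1 - det2)
        d_after = abs(int(new_row[g1].notna().sum()) - int(new_row[g2].notna().sum()))
        assert d_after <= d_before
        # full equalization whenever enough missing cells existed
        deficient_missing = (n2 - det2) if det2 < det1 else (n1 - det1)
        if deficient_missing >= d_before:
            assert d_after == 0


class TestModeratedT:
    def test_classical_limit_d0_zero(self):
        res = moderated_paired_ttest(pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"]),
                                     d0=0.0, s2_0=0.0)
        t_ref, p_ref = sp_stats.ttest_1samp([1.0, 2.0, 3.0], 0.0)
        assert res.loc["A", "t_mod"] == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-10)
        assert res.loc["A", "t_mod"] == pytest.approx(t_ref, abs=1e-10)
        assert res.loc["A", "p"] == pytest.approx(p_ref, abs=1e-10)
        assert res.loc["A", "df_total"] == 2

    def test_zero_diffs_null(self):
        res = moderated_paired_ttest(pd.DataFrame([[0.0, 0.0, 0.0]], index=["A"]),
                                     d0=0.0, s2_0=0.0)
        assert res.loc["A", "t_mod"] == 0.0
        assert res.loc["A", "p"] == 1.0

    def test_plug_in_prior(self):
        res = moderated_paired_ttest(pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"]),
                                     d0=3.0, s2_0=1.0)
        assert res.loc["A", "s2_post"] == pytest.approx(1.0)
        assert res.loc["A", "t_mod"] == pytest.approx(3.464, abs=1e-3)
        assert res.loc["A", "df_total"] == 5

    def test_large_d0_shrinks_to_prior(self):
        rng = np.random.default_rng(4)
        diffs = pd.DataFrame(rng.normal(0, 1, (50, 6)))
        res = moderated_paired_ttest(diffs, d0=1e6, s2_0=0.7)
        assert np.allclose(res["s2_post"], 0.7, atol=1e-4)

    def test_too_few_pairs_untested(self):
        diffs = pd.DataFrame([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0]], index=["A", "B"])
        res = moderated_paired_ttest(diffs, min_pairs=3)
        assert not res.loc["A", "tested"] and res.loc["B", "tested"]
        assert "fewer than 3" in res.loc["A", "reason"]

    def test_prior_fit_matches_limma(self, tmp_path):
        """Method-of-moments prior agrees with Bioconductor limma's
        fitFDist on the same variances."""
        rng = np.random.default_rng(7)
        s2 = 0.3 * (rng.chisquare(9, 200) / 9) / (rng.chisquare(6, 200) / 6)
        d0, s2_0 = fit_variance_prior(s2, np.full(200, 9.0))
        s2_file = tmp_path / "s2.txt"
        np.savetxt(s2_file, s2)
        r = subprocess.run(
            ["Rscript", "-e",
             f"s2 <- scan('{s2_file}'); suppressMessages(library(limma));"
             "f <- fitFDist(s2, df1=9); cat(f$df2, f$scale)"],
            capture_output=True, text=True, check=True,
        )
        ref_d0, ref_s2_0 = map(float, r.stdout.split())
        assert d0 == pytest.approx(ref_d0, rel=1e-4)
        assert s2_0 == pytest.approx(ref_s2_0, rel=1e-4)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_nan_excluded(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_fdr([0.01, 0.04]))


class TestZScores:
    def test_already_standardized(self):
        assert np.allclose(log2fc_zscores([-1, 0, 1]), [-1, 0, 1])

    def test_worked_example(self):
        assert np.allclose(log2fc_zscores([0, 0, 0, 5]), [-0.5, -0.5, -0.5, 1.5])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            log2fc_zscores([2.0, 2.0, 2.0])


class TestCallDaps:
    @pytest.mark.parametrize(
        "q,z,z_threshold,expected",
        [
            (0.01, 3.0, 2.5, True),   # mouse, both thresholds passed
            (0.01, 2.2, 2.5, False),  # mouse threshold
            (0.01, 2.2, 2.0, True),   # human threshold
            (0.10, 3.0, 2.5, False),  # FDR fails
        ],
    )
    def test_thresholds(self, q, z, z_threshold, expected):
        rec = pd.DataFrame({"protein_id": ["A"], "log2fc": [1.0], "q": [q], "z": [z]})
        out = call_daps(rec, fdr_threshold=0.05, z_threshold=z_threshold)
        assert bool(out["is_dap"].iloc[0]) is expected
        assert out["direction"].iloc[0] == "up_in_plaque"

    def test_untested_never_dap(self):
        rec = pd.DataFrame({"protein_id": ["A"], "log2fc": [-1.0],
                            "q": [np.nan], "z": [np.nan]})
        out = call_daps(rec)
        assert not out["is_dap"].iloc[0]
        assert out["direction"].iloc[0] == "down_in_plaque"


class TestFullStage:
    def test_row_order_invariance(self, qc_cohort):
        _, m, _ = qc_cohort
        sub = m.subset_proteins(list(m.protein_ids[:300]))
        shuffled_ids = list(sub.protein_ids)
        rng = np.random.default_rng(0)
        rng.shuffle(shuffled_ids)
        shuffled = IntensityMatrix(sub.values.loc[shuffled_ids], sub.samples.copy())
        a = differential_analysis(sub).set_index(["protein_id", "age_months"])
        b = differential_analysis(shuffled).set_index(["protein_id", "age_months"])
        b = b.loc[a.index]
        assert np.allclose(a["q"], b["q"], equal_nan=True)
        assert (a["is_dap"] == b["is_dap"]).all()

    def test_imputed_counts_only_when_gate_open(self, qc_cohort):
        _, m, _ = qc_cohort
        res = differential_analysis(m.stratum("5xFAD", 14))
        gated = res["g_p"] >= 0.05
        assert (res.loc[gated, "imputed_count"] == 0).all()


class TestTracerScreen:
    def test_self_similarity_and_sign(self, qc_cohort):
        cfg, m, _ = qc_cohort
        tracer = m.values.loc[cfg.tracer_id]
        twin = m.values.copy()
        twin.loc["TWIN"] = tracer + 1.0
        twin.loc["ANTI"] = -tracer
        m2 = IntensityMatrix(twin, m.samples.copy())
        scr = tracer_correlation_screen(m2, cfg.tracer_id)
        top = scr.iloc[0]
        assert top["protein_id"] == "TWIN" and top["r"] == pytest.approx(1.0)
        anti = scr.set_index("protein_id").loc["ANTI"]
        assert anti["r"] == pytest.approx(-1.0)
        assert not anti["above_threshold"]

    def test_matches_pearson_oracle(self, qc_cohort):
        cfg, m, _ = qc_cohort
        sub = m.subset_proteins(list(m.protein_ids[:40]) + [cfg.tracer_id])
        scr = tracer_correlation_screen(sub, cfg.tracer_id).set_index("protein_id")
        meta = sub.meta()
        cols = meta.index[meta["region"] == "plaque"]
        tracer = sub.values.loc[cfg.tracer_id, cols]
        for pid in sub.protein_ids[:40]:
            x = sub.values.loc[pid, cols]
            ok = x.notna() & tracer.notna()
            if ok.sum() < 6 or x[ok].std() == 0:
                continue
            ref = sp_stats.pearsonr(x[ok], tracer[ok]).statistic
            assert scr.loc[pid, "r"] == pytest.approx(ref, abs=1e-12)

    def test_planted_followers_found(self, qc_cohort):
        cfg, m, truth = qc_cohort
        scr = tracer_correlation_screen(m, cfg.tracer_id)
        hits = set(scr.loc[scr["above_threshold"], "protein_id"])
        followers = {p for p, e in truth.effects.iterrows()
                     if p != cfg.tracer_id and truth.temporal_class.get(p) ==
                     truth.temporal_class.get(cfg.tracer_id)
                     and (truth.effects.loc[p] == truth.effects.loc[cfg.tracer_id]).all()}
        assert followers, "cohort must plant tracer followers"
        assert len(followers & hits) >= 0.8 * len(followers)
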