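import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from concordia import diffexp
from concordia.datamodel import PROTEIN, TRANSCRIPT, CohortDesign, ExpressionMatrix
from concordia.simulate import generate_cohort, null_scenario


def bh_bruteforce(p):
    """Literal min-over-suffix definition of the step-up q-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for i in range(m):
        rank = np.flatnonzero(order == i)[0] + 1
        suffix = [p[order[j - 1]] * m / j for j in range(rank, m + 1)]
        q[i] = min(1.0, min(suffix))
    return q


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert diffexp.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_stepup_example(self):
        np.testing.assert_allclose(diffexp.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffexp.bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_bruteforce_and_dominates_p(self, p):
        q = diffexp.bh_adjust(p)
        np.testing.assert_allclose(q, bh_bruteforce(p), rtol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.random(500)
        np.testing.assert_allclose(diffexp.bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   rtol=1e-12)


class TestDetectionCounts:
    def test_protein_counts_non_missing(self, protein_matrix, design10):
        det = diffexp.detection_counts(protein_matrix, design10)
        assert det.loc["P0", "n_detected_case"] == 2   # 3 of 5 cases missing
        assert det.loc["P0", "n_detected_control"] == 5
        assert det.loc["P1", "n_detected_control"] == 0

    def test_transcript_counts_positive_cells(self, transcript_matrix, design10):
        det = diffexp.detection_counts(transcript_matrix, design10)
        assert det.loc["G0", "n_detected_control"] == 0
        assert det.loc["G1", "n_detected_case"] == 5

    def test_undetected_feature_excluded_downstream(self, protein_matrix, design10):
        de = diffexp.protein_de(protein_matrix, design10)
        assert "P1" not in de.index        # zero detections in controls
        assert "P0" in de.index


class TestProteinDE:
    def test_identical_groups_not_significant(self, design10):
        vals = np.tile(np.array([10.0, 20.0, 30.0])[:, None], (1, 10))
        m = ExpressionMatrix(PROTEIN, pd.DataFrame(
            vals, index=list("abc"), columns=list(design10.assignments)))
        de = diffexp.protein_de(m, design10)
        assert (de["p_value"] == 1.0).all()
        assert not de["significant"].any()
        assert (de["direction"] == "none").all()

    def test_fold_change_is_mean_ratio(self, design10):
        vals = np.array([[15.0] * 5 + [10.0] * 5])
        m = ExpressionMatrix(PROTEIN, pd.DataFrame(
            vals, index=["a"], columns=list(design10.assignments)))
        de = diffexp.protein_de(m, design10)
        assert de.loc["a", "fold_change"] == pytest.approx(1.5)

    def test_planted_shift_detected(self):
        """A 2-fold planted protein shift at n=20/20 with low noise comes out
        significant and up."""
        rng = np.random.default_rng(3)
        n = 20
        base = rng.normal(20, 0.2, (50, 2 * n))
        base[0, :n] += np.log(2.0)
        cols = [f"case_{i}" for i in range(n)] + [f"ctrl_{i}" for i in range(n)]
        m = ExpressionMatrix(PROTEIN, pd.DataFrame(
            np.exp(base), index=[f"P{i}" for i in range(50)], columns=cols))
        design = CohortDesign({c: "case" if c.startswith("case") else "control"
                               for c in cols})
        de = diffexp.protein_de(m, design)
        assert de.loc["P0", "significant"]
        assert de.loc["P0", "direction"] == "up"
        assert de.loc["P0", "fold_change"] > 1.5

    def test_underdetected_feature_reported_with_unit_p(self, design10):
        vals = np.full((1, 10), np.nan)
        vals[0, 0] = 100.0
        vals[0, 5:] = [10.0, 12.0, 9.0, 11.0, 10.0]
        m = ExpressionMatrix(PROTEIN, pd.DataFrame(
            vals, index=["a"], columns=list(design10.assignments)))
        de = diffexp.protein_de(m, design10)
        assert de.loc["a", "p_value"] == 1.0
        assert de.loc["a", "q_value"] == 1.0
        assert not de.loc["a", "significant"]

    def test_q_dominates_p(self, protein_matrix, design10):
        de = diffexp.protein_de(protein_matrix, design10)
        assert (de["q_value"] >= de["p_value"] - 1e-15).all()


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame(np.tile([[10], [20], [5]], (1, 4)).astype(float),
                          columns=list("abcd"))
        np.testing.assert_allclose(diffexp.tmm_factors(df), 1.0)

    def test_scaled_library_compensated(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(100, size=(200, 3)).astype(float)
        df = pd.DataFrame(np.column_stack([base, 2 * base[:, 0]]),
                          columns=list("abcd"))
        f = diffexp.tmm_factors(df)
        # a pure depth change is absorbed by the library size, not the factor
        assert f["d"] == pytest.approx(f["a"], rel=2e-3)
        eff = diffexp.effective_library_sizes(df)
        assert eff["d"] / eff["a"] == pytest.approx(2.0, rel=2e-3)

    def test_factors_product_is_one(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.negative_binomial(5, 0.05, (300, 6)).astype(float))
        f = diffexp.tmm_factors(df)
        assert np.prod(f) == pytest.approx(1.0, rel=1e-12)

    def test_matches_edgeR(self, tmp_path):
        """Cross-check against Bioconductor edgeR's calcNormFactors."""
        import subprocess
        rng = np.random.default_rng(42)
        X = rng.negative_binomial(5, 0.1, size=(200, 6)).astype(float)
        X[rng.random(X.shape) < 0.1] = 0
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(200)],
                          columns=[f"s{j}" for j in range(6)])
        csv = tmp_path / "counts.csv"
        df.to_csv(csv)
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.csv("{csv}", row.names=1));'
            'cat(sprintf("%.12f", calcNormFactors(x, method="TMM")), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(diffexp.tmm_factors(df).to_numpy(), ref,
                                   atol=1e-9)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame([[1.0, 0.0], [2.0, 0.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            diffexp.tmm_factors(df)


class TestFPKM:
    def _matrix(self, counts, lengths, columns):
        df = pd.DataFrame(counts, columns=columns, dtype=float)
        return ExpressionMatrix(TRANSCRIPT, df,
                                pd.Series(lengths, index=df.index, dtype=float))

    def test_formula(self):
        # identical columns -> unit factors -> library size is the raw sum
        m = self._matrix(np.tile([[10], [999_990]], (1, 2)),
                         [2000, 1000], ["a", "b"])
        out = diffexp.fpkm(m)
        assert out.iloc[0, 0] == pytest.approx(10 / (2.0 * 1.0))

    def test_doubling_length_halves_fpkm(self):
        m1 = self._matrix(np.tile([[10], [990]], (1, 2)), [1000, 500], ["a", "b"])
        m2 = self._matrix(np.tile([[10], [990]], (1, 2)), [2000, 500], ["a", "b"])
        assert diffexp.fpkm(m2).iloc[0, 0] == \
            pytest.approx(diffexp.fpkm(m1).iloc[0, 0] / 2)

    def test_zero_count_zero_fpkm(self):
        m = self._matrix(np.tile([[0], [100]], (1, 2)), [1000, 500], ["a", "b"])
        assert diffexp.fpkm(m).iloc[0, 0] == 0.0

    def test_missing_length_rejected(self, design10):
        df = pd.DataFrame(np.ones((2, 10)), columns=list(design10.assignments))
        m = ExpressionMatrix(TRANSCRIPT, df)
        with pytest.raises(ValueError, match="length"):
            diffexp.fpkm(m)


class TestTranscriptDE:
    def _design(self, n):
        cols = [f"case_{i}" for i in range(n)] + [f"ctrl_{i}" for i in range(n)]
        return cols, CohortDesign({c: "case" if c.startswith("case") else "control"
                                   for c in cols})

    def test_symmetric_null_gives_unit_p(self):
        cols, design = self._design(3)
        rng = np.random.default_rng(0)
        base = rng.poisson(60, size=(40, 3)).astype(float)
        df = pd.DataFrame(np.column_stack([base, base]),
                          index=[f"G{i}" for i in range(40)], columns=cols)
        de = diffexp.transcript_de(ExpressionMatrix(TRANSCRIPT, df), design)
        np.testing.assert_allclose(de["p_value"], 1.0, rtol=1e-6)

    def test_fold_change_threshold_gates_significance(self):
        """A consistent 1.5-fold shift can be arbitrarily well supported yet
        is never called significant under the 2-fold rule."""
        cols, design = self._design(10)
        rng = np.random.default_rng(1)
        base = rng.poisson(4000, size=(30, 20)).astype(float)
        base[:5, :10] = np.round(base[:5, :10] * 1.5)
        df = pd.DataFrame(base, index=[f"G{i}" for i in range(30)], columns=cols)
        de = diffexp.transcript_de(ExpressionMatrix(TRANSCRIPT, df), design,
                                   dispersion=0.0)
        shifted = de.loc[[f"G{i}" for i in range(5)]]
        assert (shifted["q_value"] < 0.01).all()
        assert (shifted["fold_change"] < 2.0).all()
        assert not shifted["significant"].any()
        de2 = diffexp.transcript_de(ExpressionMatrix(TRANSCRIPT, df), design,
                                    dispersion=0.0, fc_min=1.2)
        assert de2.loc[shifted.index, "significant"].all()

    def test_zero_dispersion_matches_binomial_split(self):
        """With equal library sizes and dispersion 0, the conditional exact
        test is the binomial split test on each gene's total."""
        n1 = n2 = 4
        pi = n1 / (n1 + n2)
        for y1 in range(0, 30, 3):
            for y2 in range(0, 30, 5):
                t = y1 + y2
                if t == 0:
                    continue
                pm = binom.pmf(np.arange(t + 1), t, pi)
                expect = pm[pm <= pm[y1] * (1 + 1e-9)].sum()
                got = diffexp.nb_exact_pvalues([y1], [y2], n1, n2, 0.0)[0]
                assert got == pytest.approx(min(expect, 1.0), rel=1e-9)

    def test_depth_change_invariance(self):
        """Multiplying one sample's counts by a constant is absorbed by the
        effective library size, up to TMM re-estimation error."""
        cols, design = self._design(5)
        rng = np.random.default_rng(9)
        base = rng.poisson(rng.lognormal(3.5, 1, 300)[:, None] + 1,
                           size=(300, 10)).astype(float)
        df = pd.DataFrame(base, index=[f"G{i}" for i in range(300)], columns=cols)
        df2 = df.copy()
        df2[cols[0]] = df2[cols[0]] * 3
        de1 = diffexp.transcript_de(ExpressionMatrix(TRANSCRIPT, df), design)
        de2 = diffexp.transcript_de(ExpressionMatrix(TRANSCRIPT, df2), design)
        common = de1.index.intersection(de2.index)
        fc1 = de1.loc[common, "fold_change"]
        fc2 = de2.loc[common, "fold_change"]
        np.testing.assert_allclose(fc1, fc2, rtol=0.10)
        assert np.corrcoef(np.log(de1.loc[common, "p_value"] + 1e-300),
                           np.log(de2.loc[common, "p_value"] + 1e-300))[0, 1] > 0.97

    def test_undetected_in_one_cohort_excluded(self, transcript_matrix, design10):
        de = diffexp.transcript_de(transcript_matrix, design10)
        assert "G0" not in de.index


class TestNullCalibration:
    def test_raw_p_fraction_near_alpha(self):
        """Smoke-scale calibration: under a no-effect scenario the raw
        p < 0.05 fraction sits near 0.05 for both omes (full 50-seed check
        lives in the acceptance suite)."""
        fr_t, fr_p = [], []
        for seed in range(5):
            t, p, d, _ = generate_cohort(null_scenario(seed=seed))
            fr_t.append((diffexp.transcript_de(t, d)["p_value"] < 0.05).mean())
            fr_p.append((diffexp.protein_de(p, d)["p_value"] < 0.05).mean())
        assert 0.02 < np.mean(fr_t) < 0.08
        assert 0.02 < np.mean(fr_p) < 0.08
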