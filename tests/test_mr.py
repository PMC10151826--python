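import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genosleep import mr
from genosleep import synthetic_data as synth
from genosleep.mr import (
    WeakInstrumentError,
    harmonize,
    ivw,
    mr_analysis,
    wald_ratio,
    weighted_median,
)
from genosleep.synthetic_data import GroundTruth


def _ss(variants, e1, e2, beta, se, eaf=None):
    df = pd.DataFrame(
        {
            "variant_id": variants,
            "effect_allele": e1,
            "other_allele": e2,
            "beta": beta,
            "se": se,
        }
    )
    if eaf is not None:
        df.insert(3, "eaf", eaf)
    return df


class TestHarmonize:
    def test_identity_on_shared_variants(self):
        expo = _ss(["rs1", "rs2"], ["A", "C"], ["G", "T"], [0.2, 0.3], [0.01, 0.02], [0.3, 0.4])
        outc = _ss(["rs2", "rs1"], ["C", "A"], ["T", "G"], [0.05, 0.04], [0.01, 0.01], [0.4, 0.3])
        h, dropped = harmonize(expo, outc)
        assert dropped.empty
        assert set(h["variant_id"]) == {"rs1", "rs2"}
        r1 = h[h["variant_id"] == "rs1"].iloc[0]
        assert r1["beta_outcome"] == 0.04 and r1["beta_exposure"] == 0.2

    def test_swapped_alleles_flip_sign_and_eaf(self):
        expo = _ss(["rs1"], ["A"], ["G"], [0.2], [0.01], [0.3])
        outc = _ss(["rs1"], ["G"], ["A"], [0.05], [0.01], [0.7])
        h, _ = harmonize(expo, outc)
        row = h.iloc[0]
        assert row["beta_outcome"] == -0.05
        assert row["eaf_outcome"] == pytest.approx(0.3)

    def test_strand_flip_resolved(self):
        expo = _ss(["rs1"], ["A"], ["G"], [0.2], [0.01], [0.3])
        outc = _ss(["rs1"], ["T"], ["C"], [0.05], [0.01], [0.3])
        h, dropped = harmonize(expo, outc)
        assert dropped.empty
        assert h.iloc[0]["beta_outcome"] == 0.05

    def test_strand_flip_swapped_resolved(self):
        expo = _ss(["rs1"], ["A"], ["G"], [0.2], [0.01], [0.3])
        outc = _ss(["rs1"], ["C"], ["T"], [0.05], [0.01], [0.7])
        h, dropped = harmonize(expo, outc)
        assert dropped.empty
        assert h.iloc[0]["beta_outcome"] == -0.05

    def test_palindromic_near_half_dropped(self):
        expo = _ss(["rs1"], ["A"], ["T"], [0.2], [0.01], [0.5])
        outc = _ss(["rs1"], ["A"], ["T"], [0.05], [0.01], [0.5])
        h, dropped = harmonize(expo, outc)
        assert h.empty
        assert dropped.iloc[0]["reason"] == "palindromic_ambiguous"

    def test_palindromic_clear_maf_kept(self):
        expo = _ss(["rs1"], ["A"], ["T"], [0.2], [0.01], [0.1])
        outc = _ss(["rs1"], ["A"], ["T"], [0.05], [0.01], [0.1])
        h, dropped = harmonize(expo, outc)
        assert len(h) == 1 and dropped.empty

    def test_incompatible_alleles_dropped(self):
        expo = _ss(["rs1"], ["A"], ["G"], [0.2], [0.01], [0.3])
        outc = _ss(["rs1"], ["A"], ["C"], [0.05], [0.01], [0.3])
        h, dropped = harmonize(expo, outc)
        assert h.empty
        assert dropped.iloc[0]["reason"] == "incompatible_alleles"

    def test_empty_intersection_errors(self):
        expo = _ss(["rs1"], ["A"], ["G"], [0.2], [0.01])
        outc = _ss(["rs2"], ["A"], ["G"], [0.05], [0.01])
        with pytest.raises(ValueError, match="no shared variants"):
            harmonize(expo, outc)

    def test_missing_allele_columns_error(self):
        with pytest.raises(ValueError, match="lacks columns"):
            harmonize(
                pd.DataFrame({"variant_id": ["rs1"], "beta": [0.1], "se": [0.1]}),
                _ss(["rs1"], ["A"], ["G"], [0.05], [0.01]),
            )

    def test_idempotent(self):
        expo = _ss(
            ["rs1", "rs2", "rs3"], ["A", "C", "A"], ["G", "T", "T"],
            [0.2, 0.3, 0.1], [0.01, 0.02, 0.01], [0.3, 0.4, 0.1],
        )
        outc = _ss(
            ["rs1", "rs2", "rs3"], ["G", "C", "A"], ["A", "T", "T"],
            [0.05, 0.04, 0.02], [0.01, 0.01, 0.01], [0.7, 0.4, 0.1],
        )
        h1, _ = harmonize(expo, outc)
        expo2 = h1[["variant_id", "effect_allele", "other_allele"]].assign(
            eaf=h1["eaf_exposure"], beta=h1["beta_exposure"], se=h1["se_exposure"]
        )
        outc2 = h1[["variant_id", "effect_allele", "other_allele"]].assign(
            eaf=h1["eaf_outcome"], beta=h1["beta_outcome"], se=h1["se_outcome"]
        )
        h2, dropped2 = harmonize(expo2, outc2)
        assert dropped2.empty
        pd.testing.assert_frame_equal(
            h1.reset_index(drop=True), h2.reset_index(drop=True), check_like=True
        )


class TestWaldRatio:
    def test_quoted_definition(self):
        est = wald_ratio(0.5, 0.05, 0.25, 0.02)
        assert est.beta == pytest.approx(0.5)

    def test_beta_out_zero_limit(self):
        est = wald_ratio(0.5, 0.0, 0.0, 0.02)
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.02 / 0.5)

    def test_se_exp_zero_delta_limit(self):
        est = wald_ratio(-0.4, 0.0, 0.12, 0.03)
        assert est.se == pytest.approx(0.03 / 0.4)

    def test_weak_instrument_error(self):
        with pytest.raises(WeakInstrumentError):
            wald_ratio(0.0, 0.05, 0.25, 0.02)

    def test_first_order_delta_formula(self):
        be, se_e, bo, se_o = 0.3, 0.04, 0.12, 0.03
        est = wald_ratio(be, se_e, bo, se_o)
        hand = math.sqrt(se_o**2 / be**2 + bo**2 * se_e**2 / be**4)
        assert est.se == pytest.approx(hand, rel=1e-12)

    def test_ci_brackets_beta(self):
        est = wald_ratio(0.3, 0.04, 0.12, 0.03)
        assert est.ci_low <= est.beta <= est.ci_high
        assert 0.0 <= est.pval <= 1.0


class TestIvw:
    def test_single_instrument_collapse(self, toy_harmonized):
        single = toy_harmonized.iloc[[0]]
        est_ivw = ivw(single)
        est_wald = wald_ratio(0.5, 0.05, 0.15, 0.03)
        assert abs(est_ivw.beta - est_wald.beta) < 1e-12
        assert abs(est_ivw.se - est_wald.se) < 1e-12

    def test_equal_weights_unweighted_mean(self):
        # identical (|ratio|, se structure) => equal delta SEs => plain mean
        df = pd.DataFrame(
            {
                "beta_exposure": [1.0, 1.0, 1.0],
                "se_exposure": [0.0, 0.0, 0.0],
                "beta_outcome": [0.1, 0.2, 0.6],
                "se_outcome": [0.05, 0.05, 0.05],
            }
        )
        est = ivw(df)
        assert est.beta == pytest.approx((0.1 + 0.2 + 0.6) / 3)

    def test_three_instrument_hand_weighted_average(self, toy_harmonized):
        be = toy_harmonized["beta_exposure"].to_numpy()
        se_e = toy_harmonized["se_exposure"].to_numpy()
        bo = toy_harmonized["beta_outcome"].to_numpy()
        se_o = toy_harmonized["se_outcome"].to_numpy()
        r = bo / be
        w0 = be**2 / se_o**2
        pilot = (w0 * r).sum() / w0.sum()
        s2 = se_o**2 / be**2 + pilot**2 * se_e**2 / be**2
        w = 1 / s2
        hand_beta = (w * r).sum() / w.sum()
        hand_se = 1 / math.sqrt(w.sum())
        est = ivw(toy_harmonized)
        assert est.beta == pytest.approx(hand_beta, abs=1e-12)
        assert est.se == pytest.approx(hand_se, abs=1e-12)

    def test_random_effects_never_below_fixed(self, toy_harmonized):
        fixed = ivw(toy_harmonized, mode="fixed")
        random = ivw(toy_harmonized, mode="random")
        assert random.se >= fixed.se
        assert random.beta == pytest.approx(fixed.beta)

    def test_zero_instruments_error(self):
        with pytest.raises(ValueError):
            ivw(pd.DataFrame(columns=["beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]))


class TestWeightedMedian:
    def test_degenerate_all_equal_ratios(self):
        df = pd.DataFrame(
            {
                "beta_exposure": [0.2, 0.4, 0.5],
                "se_exposure": [0.01, 0.01, 0.01],
                "beta_outcome": [0.1, 0.2, 0.25],
                "se_outcome": [0.01, 0.01, 0.01],
            }
        )
        est = weighted_median(df, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)
        assert est.se > 0

    def test_median_identity_equal_weights(self):
        # odd J, equal weights, symmetric spacing -> middle ratio
        df = pd.DataFrame(
            {
                "beta_exposure": [1.0, 1.0, 1.0],
                "se_exposure": [0.0, 0.0, 0.0],
                "beta_outcome": [0.2, 0.5, 0.8],
                "se_outcome": [0.05, 0.05, 0.05],
            }
        )
        est = weighted_median(df, n_boot=200, seed=2)
        # hand evaluation: se_exp=0 so every delta SE is 0.05 -> equal weights;
        # midpoints (1/6, 3/6, 5/6); interpolation at 0.5 -> middle ratio 0.5
        assert est.beta == pytest.approx(0.5)

    def test_outlier_resistance_hand_percentile(self):
        # 7 concordant instruments at ratio 0.5 with high weight, 3 outliers
        # at ratio 3 with low total weight (< 50%) -> estimate stays near 0.5
        be = np.array([1.0] * 7 + [1.0] * 3)
        bo = np.array([0.5] * 7 + [3.0] * 3)
        se_o = np.array([0.05] * 7 + [0.5] * 3)
        df = pd.DataFrame(
            {
                "beta_exposure": be,
                "se_exposure": np.zeros(10),
                "beta_outcome": bo,
                "se_outcome": se_o,
            }
        )
        est = weighted_median(df, n_boot=200, seed=3)
        assert abs(est.beta - 0.5) < 0.05

    def test_too_few_instruments(self):
        df = pd.DataFrame(
            {
                "beta_exposure": [0.2, 0.4],
                "se_exposure": [0.01, 0.01],
                "beta_outcome": [0.1, 0.2],
                "se_outcome": [0.01, 0.01],
            }
        )
        with pytest.raises(ValueError, match=">= 3 instruments"):
            weighted_median(df)

    def test_bootstrap_determinism(self, toy_harmonized):
        e1 = weighted_median(toy_harmonized, n_boot=300, seed=99)
        e2 = weighted_median(toy_harmonized, n_boot=300, seed=99)
        assert e1.se == e2.se
        e3 = weighted_median(toy_harmonized, n_boot=300, seed=100)
        assert e3.se != e1.se


class TestSignEquivariance:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_allele_relabeling_leaves_estimates(self, seed):
        rng = np.random.default_rng(seed)
        j = 5
        expo = _ss(
            [f"rs{i}" for i in range(j)], ["A"] * j, ["G"] * j,
            rng.normal(0.2, 0.05, j), rng.uniform(0.01, 0.05, j),
            rng.uniform(0.1, 0.45, j),
        )
        outc = _ss(
            [f"rs{i}" for i in range(j)], ["A"] * j, ["G"] * j,
            rng.normal(0.06, 0.02, j), rng.uniform(0.01, 0.05, j),
            expo["eaf"].to_numpy(),
        )
        # relabel: outcome reported on the other allele
        outc_flip = outc.copy()
        outc_flip["effect_allele"], outc_flip["other_allele"] = (
            outc["other_allele"],
            outc["effect_allele"],
        )
        outc_flip["beta"] = -outc["beta"]
        outc_flip["eaf"] = 1 - outc["eaf"]
        h1, _ = harmonize(expo, outc)
        h2, _ = harmonize(expo, outc_flip)
        est1, est2 = ivw(h1), ivw(h2)
        assert est1.beta == pytest.approx(est2.beta, abs=1e-12)
        assert est1.se == pytest.approx(est2.se, abs=1e-12)


class TestMrAnalysis:
    def _two_sample(self, theta, seed, n_pleio=0, beta_direct=0.0, n=2000, j=8):
        snps = synth.random_snp_panel(
            j, seed=seed, n_pleiotropic=n_pleio, beta_direct=beta_direct
        )
        truth = GroundTruth(theta=theta, seed=seed)
        return synth.simulate_summary_stats(snps, truth, n, n, seed=seed)

    def test_single_instrument_ivw_equals_wald(self):
        expo, outc = self._two_sample(0.3, seed=21, j=5)
        expo, outc = expo.iloc[[0]], outc.iloc[[0]]
        report = mr_analysis(expo, outc, methods=("ivw", "wald"))
        assert len(report.estimates) == 2
        b = [e.beta for e in report.estimates]
        s = [e.se for e in report.estimates]
        assert abs(b[0] - b[1]) < 1e-12 and abs(s[0] - s[1]) < 1e-12

    def test_wald_with_many_instruments_is_error_not_abort(self):
        expo, outc = self._two_sample(0.3, seed=22)
        report = mr_analysis(expo, outc, methods=("wald", "ivw_fixed"))
        assert "wald" in report.errors
        assert [e.method for e in report.estimates] == ["ivw_fixed"]

    def test_estimate_near_theta(self):
        expo, outc = self._two_sample(0.3, seed=23, n=5000, j=12)
        report = mr_analysis(expo, outc, methods=("ivw_fixed",))
        est = report.estimates[0]
        assert abs(est.beta - 0.3) < 4 * est.se

    def test_instrument_table_and_dropped(self):
        expo, outc = self._two_sample(0.0, seed=24)
        report = mr_analysis(expo, outc, methods=("ivw_fixed",))
        assert {"ratio", "ratio_se", "weight"} <= set(report.instruments.columns)
        assert report.dropped.empty
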