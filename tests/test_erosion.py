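import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import episcape as ep
from conftest import toy_table
from helpers import exact_binom_log10_sf


def _rec(site, direction, tissue="A"):
    return ep.UniqueSiteRecord(site, tissue, direction, 0.1, 0.7, 0.9, 4, 8)


def _two_group_table(site_values, tissue_of, group_of):
    samples = [f"s{i:02d}" for i in range(len(tissue_of))]
    df = pd.DataFrame.from_dict(site_values, orient="index", columns=samples)
    df.index.name = "site_id"
    meta = pd.DataFrame({"sample_id": samples, "tissue": tissue_of,
                         "group": group_of}).set_index("sample_id")
    return ep.MethylationMatrix(df), meta


class TestBinomialTail:
    def test_empty_tail_is_certain(self):
        assert ep.binom_log10_sf(0, 50) == 0.0

    def test_full_tail_closed_form(self):
        # P(X = n) = p0^n exactly
        n = 3673
        assert ep.binom_log10_sf(n, n) == pytest.approx(n * math.log10(0.5), abs=1e-9)
        assert ep.binom_log10_sf(7, 7, p0=0.3) == pytest.approx(7 * math.log10(0.3), rel=1e-12)

    @pytest.mark.parametrize("k,n,num,den_exp", [
        (26, 28, 407, 28),              # sum C(28,i), i=26..28 = 378+28+1
        (16, 17, 18, 17),               # 17 + 1
    ])
    def test_printed_count_examples_vs_hand_sum(self, k, n, num, den_exp):
        expected = math.log10(num) - den_exp * math.log10(2)
        assert ep.binom_log10_sf(k, n) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_integer_oracle_on_grid(self):
        for n in (10, 100, 1000, 5000):
            for frac in (0.5, 0.6, 0.8, 0.95, 1.0):
                k = int(round(frac * n))
                got = ep.binom_log10_sf(k, n)
                want = exact_binom_log10_sf(k, n)
                assert got == pytest.approx(want, rel=1e-9), (k, n)

    def test_asymmetric_null_vs_oracle(self):
        got = ep.binom_log10_sf(90, 100, p0=0.3)
        want = exact_binom_log10_sf(90, 100, Fraction(3, 10))
        assert got == pytest.approx(want, rel=1e-9)

    def test_deep_tail_does_not_underflow(self):
        lp = ep.binom_log10_sf(21556, 21556 + 731)  # far below float tiny
        assert np.isfinite(lp) and lp < -1000

    def test_complementary_tails_sum_to_one(self):
        for n in (10, 100, 1000, 10_000):
            k = n // 3
            upper = 10.0 ** ep.binom_log10_sf(k, n)
            lower = 10.0 ** ep.binom_log10_sf(n - k + 1, n)  # = P(X <= k-1) by symmetry
            assert upper + lower == pytest.approx(1.0, rel=1e-12)

    def test_two_sided_doubles_the_tail(self):
        one = ep.binom_log10_sf(26, 28)
        two = ep.binom_log10_sf(26, 28, two_sided=True)
        assert two == pytest.approx(one + math.log10(2), rel=1e-12)

    @pytest.mark.parametrize("k,n", [(-1, 5), (6, 5)])
    def test_invalid_counts_rejected(self, k, n):
        with pytest.raises(ValueError):
            ep.binom_log10_sf(k, n)


class TestGroupCalls:
    def _fixture(self):
        # one tissue, 2 controls + 2 cases; three sites covering the rules
        tissue_of = ["A"] * 4
        group_of = ["healthy", "healthy", "sick", "sick"]
        values = {
            "low_reg": [0.20, 0.20, 0.35, 0.35],   # low site gains -> regression
            "low_div": [0.20, 0.20, 0.05, 0.05],   # low site loses -> divergence
            "high_tie": [0.90, 0.90, 0.90, 0.90],  # no change -> tie
            "high_reg": [0.90, 0.90, 0.70, 0.70],  # high site loses -> regression
        }
        m, meta = _two_group_table(values, tissue_of, group_of)
        recs = [_rec("low_reg", "low"), _rec("low_div", "low"),
                _rec("high_tie", "high"), _rec("high_reg", "high")]
        return m, meta, recs

    def test_sign_rules_and_summary_counts(self):
        m, meta, recs = self._fixture()
        calls, summary = ep.call_direction_group(m, meta, recs, "healthy", "sick")
        by_id = {c.site_id: c for c in calls}
        assert by_id["low_reg"].call == "regression"
        assert by_id["low_reg"].delta == pytest.approx(0.15)
        assert by_id["low_div"].call == "divergence"
        assert by_id["high_tie"].call == "tie"
        assert by_id["high_reg"].call == "regression"
        assert (summary.n_regression, summary.n_divergence, summary.n_tie) == (2, 1, 1)
        assert summary.n_informative == 3  # ties never enter the binomial n
        assert summary.fraction_regression == pytest.approx(100 * 2 / 3)
        assert summary.log10_p == pytest.approx(exact_binom_log10_sf(2, 3), rel=1e-9)
        assert set(summary.by_direction) == {"low", "high"}
        assert summary.by_direction["high"].n_tie == 1

    def test_swapping_labels_flips_every_call(self):
        m, meta, recs = self._fixture()
        fwd, _ = ep.call_direction_group(m, meta, recs, "healthy", "sick")
        rev, _ = ep.call_direction_group(m, meta, recs, "sick", "healthy")
        flip = {"regression": "divergence", "divergence": "regression",
                "tie": "tie", "undefined": "undefined"}
        for a, b in zip(fwd, rev):
            assert b.call == flip[a.call]

    def test_missing_site_gives_undefined_call(self):
        m, meta, recs = self._fixture()
        recs = recs + [_rec("cg_absent", "low")]
        calls, summary = ep.call_direction_group(m, meta, recs, "healthy", "sick")
        assert calls[-1].call == "undefined"
        assert summary.n_undefined == 1

    def test_unknown_label_rejected(self):
        m, meta, recs = self._fixture()
        with pytest.raises(ValueError, match="label"):
            ep.call_direction_group(m, meta, recs, "healthy", "zombie")

    def test_fraction_invariant_to_order_and_sample_duplication(self):
        m, meta, recs = self._fixture()
        _, s1 = ep.call_direction_group(m, meta, recs, "healthy", "sick")
        _, s2 = ep.call_direction_group(m, meta, list(reversed(recs)),
                                        "healthy", "sick")
        dup_vals = pd.concat([m.values, m.values.add_suffix("_dup", axis=1)], axis=1)
        m2 = ep.MethylationMatrix(dup_vals)
        meta2 = pd.concat([meta, meta.rename(index=lambda s: s + "_dup")])
        _, s3 = ep.call_direction_group(m2, meta2, recs, "healthy", "sick")
        assert s1.fraction_regression == s2.fraction_regression == s3.fraction_regression

    def test_erosion_majority_follows_planted_lambda(self, eroded_cohort):
        _, matrix, meta, truth = eroded_cohort
        recs = [ep.UniqueSiteRecord(p.site_id, p.tissue, p.direction,
                                    p.clean_tissue_mean, 0, 0, 0, 0)
                for p in truth.unique_sites]
        calls, summary = ep.call_direction_group(matrix, meta, recs,
                                                 "control", "case")
        assert summary.majority == "regression"
        assert summary.fraction_regression >= 99.0

    def test_negative_lambda_gives_majority_divergence(self):
        cfg = ep.SyntheticConfig(n_tissues=3, samples_per_tissue_per_group=20,
                                 n_sites=800, n_unique_per_tissue=17,
                                 concentration=50, erosion_lambda=-0.5,
                                 missing_rate=0.0, seed=21)
        matrix, meta, truth = ep.generate_multitissue(cfg)
        recs = [ep.UniqueSiteRecord(p.site_id, p.tissue, p.direction,
                                    0, 0, 0, 0, 0) for p in truth.unique_sites]
        _, summary = ep.call_direction_group(matrix, meta, recs, "control", "case")
        assert summary.majority == "divergence"
        assert summary.fraction_regression < 50.0


class TestCorrelationCalls:
    def test_monotone_age_increase_at_low_site_is_regression(self):
        tissue_of = ["A"] * 6
        group_of = ["g"] * 6
        m, meta = _two_group_table(
            {"cg1": [0.10, 0.15, 0.20, 0.25, 0.30, 0.35]}, tissue_of, group_of)
        meta["age"] = [30, 40, 50, 60, 70, 80]
        calls, summary = ep.call_direction_correlation(m, meta, [_rec("cg1", "low")])
        assert calls[0].r == pytest.approx(1.0)
        assert calls[0].call == "regression"

    def test_threshold_excludes_weak_correlations_from_n(self):
        rng = np.random.default_rng(0)
        noise = list(rng.uniform(0.4, 0.6, size=6))
        m, meta = _two_group_table(
            {"strong": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6], "weak": noise},
            ["A"] * 6, ["g"] * 6)
        meta["age"] = [30, 40, 50, 60, 70, 80]
        calls, summary = ep.call_direction_correlation(
            m, meta, [_rec("strong", "low"), _rec("weak", "low")], min_abs_r=0.9)
        by_id = {c.site_id: c for c in calls}
        assert by_id["strong"].included and not by_id["weak"].included
        assert summary.n_informative == 1

    def test_constant_methylation_is_undefined(self):
        m, meta = _two_group_table({"cg1": [0.5] * 6}, ["A"] * 6, ["g"] * 6)
        meta["age"] = [30, 40, 50, 60, 70, 80]
        calls, _ = ep.call_direction_correlation(m, meta, [_rec("cg1", "low")])
        assert calls[0].call == "undefined"

    def test_age_drift_recovery(self):
        """Planted drift of 0.12 beta over 60 years is recovered at |r| > 0.3."""
        cfg = ep.SyntheticConfig(n_tissues=2, samples_per_tissue_per_group=40,
                                 n_sites=400, n_unique_per_tissue=25,
                                 concentration=100, age_slope=0.12 / 60,
                                 missing_rate=0.0, seed=31)
        matrix, meta, truth = ep.generate_multitissue(cfg)
        recs = [ep.UniqueSiteRecord(p.site_id, p.tissue, p.direction,
                                    0, 0, 0, 0, 0) for p in truth.unique_sites]
        calls, summary = ep.call_direction_correlation(matrix, meta, recs,
                                                       covariate="age",
                                                       min_abs_r=0.3)
        included = [c for c in calls if c.included]
        assert len(included) / len(calls) >= 0.9
        assert summary.fraction_regression >= 90.0


class TestGlobalTrend:
    def test_uniform_shift_gives_full_fraction(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.2, 0.7, size=(30, 1)) + rng.normal(0, 1e-3, (30, 4))
        shifted = base + 0.01
        values = {f"cg{i}": list(base[i]) + list(shifted[i]) for i in range(30)}
        m, meta = _two_group_table(values, ["A"] * 8,
                                   ["healthy"] * 4 + ["sick"] * 4)
        gt = ep.global_trend(m, meta, "healthy", "sick")
        assert gt.frac_increased_all == 100.0
        assert gt.frac_increased_robust == 100.0
        assert gt.n_ties == 0

    def test_identical_groups_all_ties(self):
        base = np.full((5, 4), 0.4)
        values = {f"cg{i}": list(base[i]) + list(base[i]) for i in range(5)}
        m, meta = _two_group_table(values, ["A"] * 8,
                                   ["healthy"] * 4 + ["sick"] * 4)
        gt = ep.global_trend(m, meta, "healthy", "sick")
        assert gt.n_ties == 5
        assert np.isnan(gt.frac_increased_all)

    def test_planted_global_shift_recovered(self):
        """A case shift planted at ~84% of sites is recovered within 2 points."""
        rng = np.random.default_rng(17)
        n_sites, n_per = 3000, 25
        base = rng.uniform(0.25, 0.75, size=n_sites)
        up = rng.random(n_sites) < 0.84
        shift = np.where(up, 0.04, -0.04)
        noise = 0.02
        ctrl = np.clip(base[:, None] + rng.normal(0, noise, (n_sites, n_per)), 0, 1)
        case = np.clip((base + shift)[:, None] + rng.normal(0, noise, (n_sites, n_per)), 0, 1)
        values = {f"cg{i}": list(ctrl[i]) + list(case[i]) for i in range(n_sites)}
        m, meta = _two_group_table(values, ["A"] * (2 * n_per),
                                   ["healthy"] * n_per + ["sick"] * n_per)
        gt = ep.global_trend(m, meta, "healthy", "sick")
        assert gt.frac_increased_all == pytest.approx(100 * up.mean(), abs=2.0)

    def test_empty_group_rejected(self):
        m, meta = _two_group_table({"cg1": [0.1, 0.2]}, ["A", "A"], ["healthy"] * 2)
        with pytest.raises(ValueError, match="group"):
            ep.global_trend(m, meta, "healthy", "sick")


class TestDeltaVsPanMean:
    def _cohort(self):
        # tissue A: 2 healthy + 2 sick; tissue B provides the pan mean (0.8)
        tissue_of = ["A"] * 4 + ["B"] * 4
        group_of = ["healthy", "healthy", "sick", "sick"] + ["healthy"] * 4
        values = {
            # control 0.2, case 0.35, pan 0.8: both rules say regression
            "agree_reg": [0.2, 0.2, 0.35, 0.35] + [0.8] * 4,
            # moderate overshoot: control 0.2, case 0.9, pan 0.8: still closer
            "overshoot_ok": [0.2, 0.2, 0.9, 0.9] + [0.8] * 4,
            # far overshoot: control 0.7, case 0.95, pan 0.8: rules disagree
            "overshoot_far": [0.7, 0.7, 0.95, 0.95] + [0.8] * 4,
            # divergence on both rules
            "agree_div": [0.2, 0.2, 0.1, 0.1] + [0.8] * 4,
        }
        m, meta = _two_group_table(values, tissue_of, group_of)
        recs = [_rec(s, "low") for s in values]
        return m, meta, recs

    def test_enumerated_sign_magnitude_combinations(self):
        m, meta, recs = self._cohort()
        table = ep.delta_vs_pan_mean(m, meta, recs, "healthy", "sick").set_index("site_id")
        row = table.loc["agree_reg"]
        assert row["control_delta"] == pytest.approx(-0.6)
        assert row["case_delta"] == pytest.approx(-0.45)
        assert row["sign_call"] == row["magnitude_call"] == "regression"
        assert table.loc["overshoot_ok", "sign_call"] == "regression"
        assert table.loc["overshoot_ok", "magnitude_call"] == "regression"
        far = table.loc["overshoot_far"]
        assert far["sign_call"] == "regression"
        assert far["magnitude_call"] == "divergence"
        assert not far["agree"]
        assert table.loc["agree_div", "magnitude_call"] == "divergence"
        assert table["agree"].sum() == 3
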