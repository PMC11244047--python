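"""Cohort generator, normality test, mixed ANOVA and contrasts."""

import dataclasses
import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest

from bafawubu import intervention as iv


def _balanced_records(pre1, post1, pre2, post2):
    records = []
    for g, pre, post in (("precision", pre1, post1), ("standard", pre2, post2)):
        for i, (a, b) in enumerate(zip(pre, post)):
            records.append(iv.OutcomeRecord(f"{g}{i}", g, "balance_s",
                                            float(a), float(b)))
    return records


class TestSynthCohort:
    def test_group_sizes_match_completers(self):
        records = iv.synth_cohort(iv.CohortSpec(seed=0))
        frame = iv.records_to_frame(records)
        balance = frame[frame.measure == "balance_s"]
        assert (balance.group == "precision").sum() == 21
        assert (balance.group == "standard").sum() == 29

    def test_seeded_determinism(self):
        a = iv.synth_cohort(iv.CohortSpec(seed=3))
        b = iv.synth_cohort(iv.CohortSpec(seed=3))
        assert a == b

    def test_sample_means_within_clt_bound(self):
        """Pre-means fall within 3 sd/sqrt(n) of the spec mean in >= 99%
        of seeds (CLT bound, simulated)."""
        m1, s1 = iv.PUBLISHED_SUMMARY[("precision", "balance_s")][:2]
        n, hits, total = 21, 0, 200
        for seed in range(total):
            spec = iv.CohortSpec(seed=seed, measures=("balance_s",))
            frame = iv.records_to_frame(iv.synth_cohort(spec))
            pre = frame[frame.group == "precision"].pre.to_numpy()
            if abs(pre.mean() - m1) < 3 * s1 / np.sqrt(n):
                hits += 1
        assert hits / total >= 0.99

    def test_prepost_correlation_near_rho(self):
        spec = iv.CohortSpec(seed=1, n_precision=2000, n_standard=2,
                             measures=("grip_kg",))
        frame = iv.records_to_frame(iv.synth_cohort(spec))
        g = frame[frame.group == "precision"]
        r = np.corrcoef(g.pre, g.post)[0, 1]
        assert r == pytest.approx(0.7, abs=0.05)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            iv.CohortSpec(rho=1.5)
        bad = dict(iv.PUBLISHED_SUMMARY)
        bad[("precision", "balance_s")] = (8.0, -1.0, 9.0, 1.0)
        with pytest.raises(ValueError):
            iv.CohortSpec(summary=bad)


class TestNormality:
    def test_w_statistic_range_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        w, p = iv.normality_test(x)
        assert 0 < w <= 1
        w2, _ = iv.normality_test(5.0 + 3.0 * x)
        assert w2 == pytest.approx(w, abs=1e-10)

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            iv.normality_test([1.0, 2.0])

    def test_against_r_reference_implementation(self):
        """Shapiro–Wilk W agrees with R's shapiro.test to 1e-3."""
        x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
        w, p = iv.normality_test(x)
        script = ("x <- c(148,154,158,160,161,162,166,170,182,195,236);"
                  "r <- shapiro.test(x);"
                  "cat(sprintf('%.6f %.6f', r$statistic, r$p.value))")
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        w_ref, p_ref = float(out[0]), float(out[1])
        assert w == pytest.approx(w_ref, abs=1e-3)
        assert p == pytest.approx(p_ref, abs=1e-3)


class TestMixedAnova:
    def test_no_change_gives_zero_time_effects(self):
        rng = np.random.default_rng(0)
        pre1, pre2 = rng.normal(10, 2, 8), rng.normal(9, 2, 8)
        result = iv.mixed_anova_2x2(
            _balanced_records(pre1, pre1, pre2, pre2), "balance_s")
        assert result.effects["time"].F == 0.0
        assert result.effects["group_x_time"].F == 0.0

    def test_balanced_toy_matches_brute_force_sums_of_squares(self):
        """F values equal an independent brute-force cell-means SS
        computation on a hand-enumerable balanced design."""
        pre1, post1 = np.array([3.0, 5.0, 4.0]), np.array([6.0, 8.0, 7.0])
        pre2, post2 = np.array([4.0, 4.0, 6.0]), np.array([5.0, 3.0, 7.0])
        records = _balanced_records(pre1, post1, pre2, post2)
        result = iv.mixed_anova_2x2(records, "balance_s")

        # brute force: classical balanced mixed-design decomposition
        y = np.stack([np.stack([pre1, post1]), np.stack([pre2, post2])])
        # y[g, t, i]; g groups, t times, i subjects
        n = y.shape[2]
        grand = y.mean()
        ss_group_bf = 2 * n * ((y.mean(axis=(1, 2)) - grand) ** 2).sum()
        subj_means = y.mean(axis=1)  # (g, i)
        ss_subj_bf = 2 * ((subj_means - y.mean(axis=(1, 2))[:, None]) ** 2).sum()
        ss_time_bf = 2 * n * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
        cell = y.mean(axis=2)
        ss_cells = n * ((cell - grand) ** 2).sum()
        ss_inter_bf = ss_cells - ss_group_bf - ss_time_bf
        ss_total = ((y - grand) ** 2).sum()
        ss_err_bf = ss_total - ss_cells - ss_subj_bf
        df_den = 2 * (n - 1)
        f_group_bf = ss_group_bf / (ss_subj_bf / df_den)
        f_time_bf = ss_time_bf / (ss_err_bf / df_den)
        f_inter_bf = ss_inter_bf / (ss_err_bf / df_den)

        assert result.effects["group"].F == pytest.approx(f_group_bf)
        assert result.effects["time"].F == pytest.approx(f_time_bf)
        assert result.effects["group_x_time"].F == pytest.approx(f_inter_bf)

    def test_matches_pingouin_balanced(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        records = _balanced_records(rng.normal(10, 3, 12),
                                    rng.normal(12, 3, 12),
                                    rng.normal(10, 3, 12),
                                    rng.normal(10.5, 3, 12))
        mine = iv.mixed_anova_2x2(records, "balance_s")
        rows = []
        for r in records:
            rows.append({"s": r.subject_id, "g": r.group, "t": "pre", "y": r.pre})
            rows.append({"s": r.subject_id, "g": r.group, "t": "post", "y": r.post})
        ref = pingouin.mixed_anova(data=pd.DataFrame(rows), dv="y",
                                   within="t", subject="s", between="g")
        for name, source in (("group", "g"), ("time", "t"),
                             ("group_x_time", "Interaction")):
            row = ref[ref["Source"] == source].iloc[0]
            assert mine.effects[name].F == pytest.approx(row["F"])
            assert mine.effects[name].eta2p == pytest.approx(row["np2"])

    def test_unbalanced_interaction_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        records = _balanced_records(rng.normal(10, 3, 21),
                                    rng.normal(12, 3, 21),
                                    rng.normal(10, 3, 29),
                                    rng.normal(10.5, 3, 29))
        mine = iv.mixed_anova_2x2(records, "balance_s")
        rows = []
        for r in records:
            rows.append({"s": r.subject_id, "g": r.group, "t": "pre", "y": r.pre})
            rows.append({"s": r.subject_id, "g": r.group, "t": "post", "y": r.post})
        ref = pingouin.mixed_anova(data=pd.DataFrame(rows), dv="y",
                                   within="t", subject="s", between="g")
        inter = ref[ref["Source"] == "Interaction"].iloc[0]
        assert mine.effects["group_x_time"].F == pytest.approx(inter["F"])
        group = ref[ref["Source"] == "g"].iloc[0]
        assert mine.effects["group"].F == pytest.approx(group["F"])

    def test_ss_decomposition_partitions_total_on_balanced_data(self):
        rng = np.random.default_rng(9)
        records = _balanced_records(rng.normal(8, 4, 10),
                                    rng.normal(10, 3, 10),
                                    rng.normal(7, 3, 10),
                                    rng.normal(7, 2, 10))
        result = iv.mixed_anova_2x2(records, "balance_s")
        e = result.effects
        ss_sum = (e["group"].ss_effect + e["group"].ss_error
                  + e["time"].ss_effect + e["group_x_time"].ss_effect
                  + e["time"].ss_error)
        y = np.asarray([[r.pre, r.post] for r in records])
        ss_total = ((y - y.mean()) ** 2).sum()
        assert ss_sum == pytest.approx(ss_total, rel=1e-9)

    def test_eta2p_bounded_over_random_data(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            records = _balanced_records(rng.normal(0, 1, 5),
                                        rng.normal(0, 1, 5),
                                        rng.normal(0, 1, 5),
                                        rng.normal(0, 1, 5))
            for effect in iv.mixed_anova_2x2(records,
                                             "balance_s").effects.values():
                assert 0.0 <= effect.eta2p <= 1.0

    def test_tiny_group_rejected(self):
        records = _balanced_records([1.0], [2.0], [1.0, 2.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            iv.mixed_anova_2x2(records, "balance_s")


class TestContrasts:
    def test_identical_prepost_gives_null_paired_tests(self):
        rng = np.random.default_rng(0)
        pre1, pre2 = rng.normal(10, 2, 6), rng.normal(9, 2, 6)
        result = iv.contrasts(_balanced_records(pre1, pre1, pre2, pre2),
                              "balance_s")
        for group in ("precision", "standard"):
            assert result.paired[group].t == 0.0
            assert result.paired[group].p == 1.0

    def test_paired_t_matches_hand_arithmetic(self):
        pre, post = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 3.0])
        other = np.array([5.0, 6.0, 7.0])
        other_post = np.array([5.5, 7.0, 7.2])
        result = iv.contrasts(_balanced_records(pre, post, other, other_post),
                              "balance_s")
        d = post - pre
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert result.paired["precision"].t == pytest.approx(t_manual)

    def test_group_swap_flips_between_group_sign(self):
        rng = np.random.default_rng(2)
        pre1, post1 = rng.normal(10, 2, 8), rng.normal(12, 2, 8)
        pre2, post2 = rng.normal(9, 2, 8), rng.normal(9, 2, 8)
        a = iv.contrasts(_balanced_records(pre1, post1, pre2, post2),
                         "balance_s")
        b = iv.contrasts(_balanced_records(pre2, post2, pre1, post1),
                         "balance_s")
        assert a.post_between.t == pytest.approx(-b.post_between.t)
        assert a.change_between.t == pytest.approx(-b.change_between.t)


class TestSimulationHelpers:
    def test_rejection_rate_bounded_and_deterministic(self):
        spec = iv.CohortSpec(measures=("balance_s",))
        a = iv.interaction_rejection_rate(spec, n_reps=20, seed=1)
        b = iv.interaction_rejection_rate(spec, n_reps=20, seed=1)
        assert a == b
        assert 0.0 <= a <= 1.0

    def test_summary_table_shape(self):
        records = iv.synth_cohort(iv.CohortSpec(seed=2))
        table = iv.summary_table(records)
        assert list(table.measure) == list(iv.MEASURES)
        assert {"interaction_p", "eta2p"} <= set(table.columns)
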