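"""Statistics layer: published worked examples, permutation and SS oracles,
calibration under the null, and cohort-report behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from musclemorph.core import DesignError, ParameterError
from musclemorph.stats import (
    GroupSummary,
    cohens_d,
    cohort_report,
    effect_label,
    mixed_anova_2x2,
    MORPHOLOGY_OUTCOMES,
    ttest_independent,
    ttest_paired,
)


class TestWorkedExamples:
    """Effect sizes and CIs recomputed from published summary statistics
    of the bilateral semitendinosus study (n = 18 per group)."""

    def test_hausdorff_effect_size(self):
        d = cohens_d(GroupSummary(9.60, 2.47, 18), GroupSummary(23.1, 8.68, 18))
        assert round(d, 2) == -2.12

    def test_rmse_effect_size(self):
        d = cohens_d(GroupSummary(3.34, 1.03, 18), GroupSummary(7.57, 2.44, 18))
        assert round(d, 2) == -2.26

    def test_normalized_length_effect_size(self):
        d = cohens_d(GroupSummary(26.44, 6.32, 18), GroupSummary(36.64, 3.01, 18))
        assert round(d, 2) == -2.06

    def test_hausdorff_confidence_interval(self):
        res = ttest_independent(GroupSummary(9.60, 2.47, 18),
                                GroupSummary(23.1, 8.68, 18))
        assert res.mean_difference == pytest.approx(-13.5)
        assert res.ci95_low == pytest.approx(-17.83, abs=0.01)
        assert res.ci95_high == pytest.approx(-9.18, abs=0.01)
        assert res.df == 34


class TestTTest:
    def test_identical_groups(self):
        x = np.array([2.1, 1.9, 2.2, 1.8, 2.0])
        res = ttest_independent(x, x.copy())
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert res.ci95_low == pytest.approx(-res.ci95_high)

    def test_summary_path_equals_sample_path(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 18), rng.normal(0.7, 1.2, 18)
        r1 = ttest_independent(a, b)
        r2 = ttest_independent(GroupSummary.from_samples(a),
                               GroupSummary.from_samples(b))
        for f in ("t_statistic", "p_value", "cohens_d", "ci95_low", "ci95_high"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f), abs=1e-12)

    def test_zero_variance_unequal_means(self):
        res = ttest_independent(np.full(3, 1.0), np.full(3, 2.0))
        assert np.isinf(res.t_statistic)
        assert res.p_value == 0.0

    def test_matches_permutation_oracle(self):
        """Student-t p agrees within 0.01 with a 1e5-resample permutation
        test on normal samples of the study's size."""
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 18), rng.normal(0.6, 1, 18)
        res = ttest_independent(a, b)
        pooled = np.concatenate([a, b])
        n = len(pooled)
        perms = rng.permuted(np.tile(pooled, (100_000, 1)), axis=1)
        pa, pb = perms[:, :18], perms[:, 18:]
        va = pa.var(axis=1, ddof=1)
        vb = pb.var(axis=1, ddof=1)
        sp = np.sqrt((17 * va + 17 * vb) / 34)
        t = (pa.mean(axis=1) - pb.mean(axis=1)) / (sp * np.sqrt(2 / 18))
        p_perm = np.mean(np.abs(t) >= abs(res.t_statistic))
        assert res.p_value == pytest.approx(p_perm, abs=0.01)

    def test_type_one_error_nominal(self):
        """Rejection rate under the null stays near alpha (quick check;
        the full 1e4-replicate calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(2)
        rejections = sum(
            ttest_independent(rng.normal(0, 1, 18),
                              rng.normal(0, 1, 18)).p_value < 0.05
            for _ in range(1500))
        assert 0.02 < rejections / 1500 < 0.08


class TestCohensD:
    @given(st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0.1, 20), st.floats(0.1, 20))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_antisymmetry(self, m1, m2, s1, s2):
        a, b = GroupSummary(m1, s1, 18), GroupSummary(m2, s2, 18)
        assert cohens_d(a, b) == -cohens_d(b, a)

    @pytest.mark.parametrize("d,label", [
        (0.0, "negligible"), (0.19, "negligible"), (0.20, "small"),
        (0.49, "small"), (0.50, "medium"), (0.79, "medium"),
        (0.80, "large"), (2.5, "large"), (-2.12, "large"), (-0.3, "small"),
    ])
    def test_effect_labels(self, d, label):
        assert effect_label(d) == label

    def test_paired_mode_uses_difference_sd(self):
        a, b = GroupSummary(10.0, 3.0, 12), GroupSummary(8.0, 3.0, 12)
        assert cohens_d(a, b, mode="paired", diff_sd=0.5) == pytest.approx(4.0)

    def test_zero_spread_rejected(self):
        with pytest.raises(ParameterError):
            cohens_d(GroupSummary(1.0, 0.0, 5), GroupSummary(2.0, 0.0, 5))


def _toy_design(value_fn, n=4):
    rows = []
    for i in range(n):
        for gi, g in enumerate(("control", "aclr")):
            for li, limb in enumerate(("reference", "moving")):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "limb_role": limb, "value": value_fn(i, gi, li)})
    return pd.DataFrame(rows)


def _oracle_interaction_F(df):
    """Brute-force balanced split-plot sum-of-squares decomposition."""
    grand = df.value.mean()
    n = df.subject_id.nunique() // 2
    ss_int = 0.0
    for g in df.group.unique():
        for l in df.limb_role.unique():
            cell = df[(df.group == g) & (df.limb_role == l)].value.mean()
            gm = df[df.group == g].value.mean()
            lm = df[df.limb_role == l].value.mean()
            ss_int += n * (cell - gm - lm + grand) ** 2
    ss_err = 0.0
    for _, sub in df.groupby("subject_id"):
        g = sub.group.iloc[0]
        smean = sub.value.mean()
        gmean = df[df.group == g].value.mean()
        for _, r in sub.iterrows():
            cell = df[(df.group == g) & (df.limb_role == r.limb_role)].value.mean()
            ss_err += (r.value - cell - smean + gmean) ** 2
    return (ss_int / 1.0) / (ss_err / (2 * n - 2))


class TestMixedAnova:
    def test_additive_data_zero_interaction(self):
        """Pure group + limb + subject effects: interaction F = 0."""
        df = _toy_design(lambda i, g, l: 2.0 * g + 3.0 * l + 0.1 * i)
        an = mixed_anova_2x2(df, dv="value", within="limb_role")
        assert abs(an["F"]) < 1e-9

    def test_matches_ss_oracle(self):
        rng = np.random.default_rng(3)
        df = _toy_design(lambda i, g, l: 2.0 * g + 3.0 * l + 0.1 * i)
        df["value"] += rng.normal(0, 1, len(df))
        an = mixed_anova_2x2(df, dv="value", within="limb_role")
        assert an["F"] == pytest.approx(_oracle_interaction_F(df), abs=1e-9)
        assert an["df1"] == 1 and an["df2"] == df.subject_id.nunique() - 2

    def test_matches_pingouin_on_noisy_data(self):
        import pingouin as pg
        rng = np.random.default_rng(4)
        df = _toy_design(lambda i, g, l: 0.0, n=9)
        df["value"] = rng.normal(0, 1, len(df))
        an = mixed_anova_2x2(df, dv="value", within="limb_role")
        aov = pg.mixed_anova(data=df, dv="value", within="limb_role",
                             subject="subject_id", between="group")
        F_pg = float(aov.loc[aov.Source == "Interaction", "F"].iloc[0])
        assert an["F"] == pytest.approx(F_pg, rel=1e-9)

    def test_null_p_values_uniform(self):
        """Interaction p under the null is uniform (KS on 400 replicates)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(400):
            df = _toy_design(lambda i, g, l: 0.0, n=8)
            df["value"] = rng.normal(0, 1, len(df))
            ps.append(mixed_anova_2x2(df, dv="value", within="limb_role")["p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_unbalanced_groups_still_valid(self):
        """Unequal group sizes (post-quarantine cohorts) keep N-2 error df."""
        rng = np.random.default_rng(10)
        df = _toy_design(lambda i, g, l: 0.0, n=5)
        df["value"] = rng.normal(0, 1, len(df))
        df = df[df.subject_id != "aclr0"]
        an = mixed_anova_2x2(df, dv="value", within="limb_role")
        assert np.isfinite(an["F"]) and an["df2"] == 7

    def test_incomplete_designs_rejected(self):
        df = _toy_design(lambda i, g, l: 0.0)
        with pytest.raises(DesignError):  # one subject missing a limb
            mixed_anova_2x2(df.drop(index=[0]), dv="value", within="limb_role")
        few = df[df.subject_id.isin(["control0", "aclr0", "aclr1"])]
        with pytest.raises(DesignError):  # a group with one subject
            mixed_anova_2x2(few, dv="value", within="limb_role")


def _numeric_cohort(rng, n=10, injured_volume_scale=1.0, bilateral_null=True):
    """Subject-level outcome tables without any mesh work."""
    sim_rows, morph_rows, meta_rows = [], [], []
    for g in ("control", "aclr"):
        for i in range(n):
            sid = f"{g}{i}"
            meta_rows.append({"subject_id": sid, "group": g,
                              "mass_kg": rng.normal(75, 12),
                              "limb_length_m": rng.normal(0.82, 0.05),
                              "regenerated": bool(i % 2) if g == "aclr" else False})
            sim_rows.append({"subject_id": sid,
                             "jaccard": rng.normal(0.7, 0.05),
                             "rmse_mm": rng.normal(3.5, 0.8),
                             "hausdorff_mm": rng.normal(10, 2)})
            for role in ("reference", "moving"):
                base = {"subject_id": sid, "limb_role": role}
                scale = (injured_volume_scale
                         if (g == "aclr" and role == "moving") else 1.0)
                for out in MORPHOLOGY_OUTCOMES:
                    mu = 3.0 if "volume" in out else (0.18 if "csa" in out else 36.0)
                    sd = mu * 0.1
                    base[out] = rng.normal(mu, sd) * (
                        scale if ("volume" in out or "csa" in out) else 1.0)
                morph_rows.append(base)
    return (pd.DataFrame(sim_rows), pd.DataFrame(morph_rows),
            pd.DataFrame(meta_rows))


class TestCohortReport:
    def test_control_bilateral_type_one_rate(self):
        """Under the null, each outcome's control bilateral test rejects
        in <= 10% of 100 replicates (nominal 5% level, no correction)."""
        rng = np.random.default_rng(6)
        rejected = {out: 0 for out in MORPHOLOGY_OUTCOMES}
        reps = 100
        for _ in range(reps):
            sim, morph, meta = _numeric_cohort(rng, n=8)
            ctrl = morph.merge(meta)
            ctrl = ctrl[ctrl.group == "control"]
            wide = ctrl.pivot_table(index="subject_id", columns="limb_role",
                                    values=list(MORPHOLOGY_OUTCOMES))
            for out in MORPHOLOGY_OUTCOMES:
                res = ttest_paired(wide[(out, "moving")].to_numpy(),
                                   wide[(out, "reference")].to_numpy())
                rejected[out] += res.p_value < 0.05
        for out, k in rejected.items():
            assert k / reps <= 0.10, out

    def test_halved_injured_volume_gives_large_effect(self):
        """Injured volume at 50%: the paired within-arm d is large in
        every replicate."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            sim, morph, meta = _numeric_cohort(rng, n=9,
                                               injured_volume_scale=0.5)
            rep = cohort_report(sim, morph, meta)
            comp = rep["comparisons"]
            row = comp[(comp.outcome == "volume_cm3_per_kg_m")
                       & (comp.contrast == "injured_vs_uninjured")]
            assert len(row) == 1
            assert abs(row.cohens_d.iloc[0]) > 0.8

    def test_report_structure_and_subgroup_skip(self):
        rng = np.random.default_rng(8)
        sim, morph, meta = _numeric_cohort(rng, n=6)
        rep = cohort_report(sim, morph, meta)
        assert len(rep["similarity_groups"]) == 3
        assert len(rep["anova"]) == len(MORPHOLOGY_OUTCOMES)
        assert len(rep["regeneration"]) > 0  # both subgroups have n >= 2

        meta2 = meta.copy()
        meta2.loc[meta2.group == "aclr", "regenerated"] = False
        meta2.loc[meta2[meta2.group == "aclr"].index[0], "regenerated"] = True
        with pytest.warns(UserWarning, match="subgroup"):
            rep2 = cohort_report(sim, morph, meta2)
        assert len(rep2["regeneration"]) == 0

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(9)
        sim, morph, meta = _numeric_cohort(rng, n=2)
        keep = meta.subject_id != "control1"
        with pytest.raises(DesignError):
            cohort_report(sim[keep.values], morph, meta[keep.values])
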