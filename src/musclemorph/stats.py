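"""Group statistics for the bilateral shape/morphometry study.

Between-group comparisons use Student's pooled-variance independent t-test
(the convention that reproduces the published worked examples, df = n1+n2-2)
with a 95% CI on the mean difference. Effect size is Cohen's d — pooled-SD
for independent groups, mean difference over the SD of paired differences
for within-subject contrasts — labelled small (0.20-0.49), medium
(0.50-0.79) or large (>= 0.80). Each discrete morphology outcome is tested
with a mixed-design ANOVA (group between, limb within); a significant
group-by-limb interaction triggers the post-hoc set: paired injured vs
uninjured within the surgical arm, and each surgical limb against the
healthy bilateral average (averaging is used only when the healthy limbs do
not differ). No multiple-testing correction is applied by default; a Holm
option exists behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DesignError, ParameterError

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "effect_label",
    "cohens_d",
    "ttest_independent",
    "ttest_paired",
    "mixed_anova_2x2",
    "cohort_report",
    "MORPHOLOGY_OUTCOMES",
    "SIMILARITY_OUTCOMES",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean +- SD of one outcome in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("group summary needs n >= 2")
        if self.sd < 0:
            raise ParameterError("sd must be non-negative")

    @classmethod
    def from_samples(cls, x) -> "GroupSummary":
        x = np.asarray(x, float)
        if len(x) < 2:
            raise ParameterError("need at least 2 observations")
        return cls(float(x.mean()), float(x.std(ddof=1)), int(len(x)))


@dataclass
class ComparisonResult:
    """One contrast: mean difference, CI, t, p and Cohen's d."""

    outcome: str
    contrast: str
    mean_difference: float
    ci95_low: float
    ci95_high: float
    t_statistic: float
    df: float
    p_value: float
    cohens_d: float
    effect_label: str
    n_a: int
    n_b: int

    def to_row(self) -> dict:
        return asdict(self)


def effect_label(d: float) -> str:
    a = abs(d)
    if a < 0.20:
        return "negligible"
    if a < 0.50:
        return "small"
    if a < 0.80:
        return "medium"
    return "large"


def _as_summary(x) -> GroupSummary:
    return x if isinstance(x, GroupSummary) else GroupSummary.from_samples(x)


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    return float(np.sqrt(((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2)
                         / (a.n + b.n - 2)))


def cohens_d(a: GroupSummary, b: GroupSummary, mode: str = "pooled",
             diff_sd: float | None = None) -> float:
    """Standardized mean difference, sign following (a - b).

    pooled: (mean_a - mean_b) / s_p, s_p the pooled SD.
    paired: (mean_a - mean_b) / diff_sd, the SD of the paired differences.
    """
    a, b = _as_summary(a), _as_summary(b)
    if mode == "pooled":
        sp = _pooled_sd(a, b)
    elif mode == "paired":
        if diff_sd is None:
            raise ParameterError("paired mode requires diff_sd")
        sp = float(diff_sd)
    else:
        raise ParameterError("mode must be 'pooled' or 'paired'")
    if sp <= 0:
        raise ParameterError("undefined effect size: zero spread")
    return float((a.mean - b.mean) / sp)


def ttest_independent(a, b, outcome: str = "", contrast: str = "a_vs_b"
                      ) -> ComparisonResult:
    """Student pooled-variance two-sided t-test from summaries or samples.

    Works from (mean, sd, n) alone — required to reproduce published
    results from printed tables — with an identical code path for raw
    samples (summaries are computed first).
    """
    a, b = _as_summary(a), _as_summary(b)
    diff = a.mean - b.mean
    df = a.n + b.n - 2
    sp = _pooled_sd(a, b)
    se = sp * np.sqrt(1 / a.n + 1 / b.n)
    if se == 0:
        if diff == 0:
            t, p = 0.0, 1.0
        else:  # zero pooled variance, unequal means: infinite-t contract
            t, p = float(np.sign(diff) * np.inf), 0.0
        ci_low = ci_high = diff
        d = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    else:
        t = float(diff / se)
        p = float(2 * sps.t.sf(abs(t), df))
        tcrit = float(sps.t.ppf(0.975, df))
        ci_low, ci_high = diff - tcrit * se, diff + tcrit * se
        d = cohens_d(a, b)
    return ComparisonResult(outcome, contrast, float(diff), float(ci_low),
                            float(ci_high), t, float(df), p, d,
                            effect_label(d) if np.isfinite(d) else "large",
                            a.n, b.n)


def ttest_paired(x, y, outcome: str = "", contrast: str = "paired"
                 ) -> ComparisonResult:
    """Paired two-sided t-test; d = mean difference / SD of differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or len(x) < 2:
        raise ParameterError("paired test needs two equal-length samples, n >= 2")
    dvals = x - y
    n = len(dvals)
    md = float(dvals.mean())
    sd = float(dvals.std(ddof=1))
    df = n - 1
    if sd == 0:
        t, p = (0.0, 1.0) if md == 0 else (float(np.sign(md) * np.inf), 0.0)
        ci_low = ci_high = md
        d = 0.0 if md == 0 else float(np.sign(md) * np.inf)
    else:
        se = sd / np.sqrt(n)
        t = float(md / se)
        p = float(2 * sps.t.sf(abs(t), df))
        tcrit = float(sps.t.ppf(0.975, df))
        ci_low, ci_high = md - tcrit * se, md + tcrit * se
        d = md / sd
    return ComparisonResult(outcome, contrast, md, float(ci_low), float(ci_high),
                            t, float(df), float(p), float(d),
                            effect_label(d) if np.isfinite(d) else "large", n, n)


def mixed_anova_2x2(data: pd.DataFrame, dv: str, subject: str = "subject_id",
                    between: str = "group", within: str = "limb") -> dict:
    """Group-by-limb interaction of a 2x2 mixed (split-plot) design.

    Every subject must contribute both limb levels. The interaction F with
    (1, N - 2) df is computed through the exact split-plot identity
    F = t^2, with t the pooled-variance independent t-test comparing the
    per-subject within-limb differences between groups — identical to the
    classical sum-of-squares decomposition when the design is balanced,
    and well defined (with N - 2 error df) when group sizes differ, e.g.
    after failed cases are quarantined. Returns {"F", "df1", "df2", "p"}.
    """
    if data[between].nunique() != 2 or data[within].nunique() != 2:
        raise DesignError("mixed_anova_2x2 needs exactly two levels per factor")
    counts = data.groupby([subject])[within].nunique()
    if not (counts == 2).all():
        raise DesignError("every subject needs both within-factor levels")
    sizes = data.groupby(between)[subject].nunique()
    if sizes.min() < 2:
        raise DesignError("each between group needs >= 2 subjects")

    levels = sorted(data[within].unique())
    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv).reset_index()
    diff = wide[levels[1]] - wide[levels[0]]
    groups = sorted(wide[between].unique())
    d1 = diff[wide[between] == groups[0]].to_numpy(float)
    d2 = diff[wide[between] == groups[1]].to_numpy(float)
    res = ttest_independent(d1, d2)
    F = res.t_statistic ** 2 if np.isfinite(res.t_statistic) else float("inf")
    return {"F": float(F), "df1": 1.0, "df2": float(len(d1) + len(d2) - 2),
            "p": res.p_value}


# --------------------------------------------------------------------------- #
# cohort-level reporting
# --------------------------------------------------------------------------- #

SIMILARITY_OUTCOMES = ("jaccard", "rmse_mm", "hausdorff_mm")

#: normalized morphology outcomes, whole muscle then per region
MORPHOLOGY_OUTCOMES = (
    "length_cm_per_m",
    "peak_csa_cm2_per_kg_m",
    "volume_cm3_per_kg_m",
    "proximal_peak_csa_cm2_per_kg_m",
    "middle_peak_csa_cm2_per_kg_m",
    "distal_peak_csa_cm2_per_kg_m",
    "proximal_volume_cm3_per_kg_m",
    "middle_volume_cm3_per_kg_m",
    "distal_volume_cm3_per_kg_m",
)


def _msd(x) -> str:
    x = np.asarray(x, float)
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def cohort_report(similarity: pd.DataFrame, morphology: pd.DataFrame,
                  meta: pd.DataFrame, alpha: float = 0.05,
                  holm_correct: bool = False) -> dict:
    """Full study report from tidy per-subject tables.

    similarity: one row per subject (subject_id, jaccard, rmse_mm,
    hausdorff_mm). morphology: one row per limb (subject_id, limb_role in
    {reference, moving}, outcome columns). meta: subject_id, group
    (control/aclr), mass_kg, limb_length_m, regenerated.

    Emits group summary tables, the between-group similarity t-tests, the
    per-outcome mixed-ANOVA interactions with their post-hoc set, and the
    regeneration-subgroup t-tests (skipped with a warning when a subgroup
    has n < 2). The healthy bilateral average is used wherever the healthy
    limbs do not differ (paired test at ``alpha``), following the
    averaging rule of the study design.
    """
    meta = meta.copy()
    meta["group"] = meta["group"].str.lower()
    if meta.groupby("group")["subject_id"].count().min() < 2:
        raise DesignError("need >= 2 subjects per group")
    sim = similarity.merge(meta, on="subject_id")
    morph = morphology.merge(meta, on="subject_id")

    # ---- demographics (Table 1 shape) ----
    demo_rows = []
    for grp, g in meta.groupby("group"):
        demo_rows.append({
            "group": grp, "n": len(g),
            "mass_kg": _msd(g["mass_kg"]),
            "limb_length_m": _msd(g["limb_length_m"]),
            "regenerated_n": int(g["regenerated"].sum()),
        })
    demographics = pd.DataFrame(demo_rows)

    # ---- similarity: group summaries + independent t-tests (Table 2 shape) ----
    comparisons: list[ComparisonResult] = []
    sim_rows = []
    for out in SIMILARITY_OUTCOMES:
        h = sim.loc[sim.group == "control", out].to_numpy()
        a = sim.loc[sim.group == "aclr", out].to_numpy()
        res = ttest_independent(h, a, outcome=out, contrast="healthy_vs_aclr")
        comparisons.append(res)
        sim_rows.append({"outcome": out, "healthy": _msd(h), "aclr": _msd(a),
                         "mean_difference": res.mean_difference,
                         "ci95_low": res.ci95_low, "ci95_high": res.ci95_high,
                         "cohens_d": res.cohens_d, "p_value": res.p_value})
    similarity_table = pd.DataFrame(sim_rows)

    # ---- morphology: wide per-limb frame ----
    wide = morph.pivot_table(index=["subject_id", "group", "regenerated"],
                             columns="limb_role",
                             values=list(MORPHOLOGY_OUTCOMES)).reset_index()
    ctrl = wide[wide.group == "control"]
    aclr = wide[wide.group == "aclr"]

    anova_rows, morph_rows = [], []
    for out in MORPHOLOGY_OUTCOMES:
        long = morph[["subject_id", "group", "limb_role", out]].rename(
            columns={out: "value"})
        an = mixed_anova_2x2(long, dv="value", within="limb_role")
        anova_rows.append({"outcome": out, **an})

        c_ref = ctrl[(out, "reference")].to_numpy()
        c_mov = ctrl[(out, "moving")].to_numpy()
        bilateral = ttest_paired(c_mov, c_ref, outcome=out,
                                 contrast="control_left_vs_right")
        healthy = (0.5 * (c_ref + c_mov) if bilateral.p_value >= alpha
                   else c_ref)
        inj = aclr[(out, "moving")].to_numpy()
        uninj = aclr[(out, "reference")].to_numpy()
        morph_rows.append({"outcome": out,
                           "average_healthy": _msd(healthy),
                           "uninjured_aclr": _msd(uninj),
                           "injured_aclr": _msd(inj)})

        if an["p"] < alpha:
            comparisons.append(ttest_paired(
                inj, uninj, outcome=out, contrast="injured_vs_uninjured"))
            comparisons.append(ttest_independent(
                inj, healthy, outcome=out, contrast="injured_vs_healthy"))
            comparisons.append(ttest_independent(
                uninj, healthy, outcome=out, contrast="uninjured_vs_healthy"))

    # ---- regeneration subgroups (injured-limb + similarity outcomes) ----
    regen_ids = set(meta.loc[(meta.group == "aclr") & meta.regenerated,
                             "subject_id"])
    non_ids = set(meta.loc[(meta.group == "aclr") & ~meta.regenerated,
                           "subject_id"])
    regen_rows = []
    if len(regen_ids) >= 2 and len(non_ids) >= 2:
        for out in SIMILARITY_OUTCOMES:
            r = sim.loc[sim.subject_id.isin(regen_ids), out].to_numpy()
            nr = sim.loc[sim.subject_id.isin(non_ids), out].to_numpy()
            res = ttest_independent(r, nr, outcome=out,
                                    contrast="regenerated_vs_nonregenerated")
            comparisons.append(res)
            regen_rows.append(res.to_row())
        for out in MORPHOLOGY_OUTCOMES:
            r = aclr.loc[aclr.subject_id.isin(regen_ids), (out, "moving")].to_numpy()
            nr = aclr.loc[aclr.subject_id.isin(non_ids), (out, "moving")].to_numpy()
            res = ttest_independent(r, nr, outcome=out,
                                    contrast="regenerated_vs_nonregenerated")
            comparisons.append(res)
            regen_rows.append(res.to_row())
    else:
        warnings.warn("a regeneration subgroup has n < 2: subgroup tests skipped")

    comp_df = pd.DataFrame([c.to_row() for c in comparisons])
    if holm_correct and len(comp_df):
        comp_df["p_holm"] = holm(comp_df["p_value"].to_numpy())

    return {
        "demographics": demographics,
        "similarity_groups": similarity_table,
        "morphology_groups": pd.DataFrame(morph_rows),
        "anova": pd.DataFrame(anova_rows),
        "comparisons": comp_df,
        "regeneration": pd.DataFrame(regen_rows),
    }
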