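"""Clinical outcome and ERD statistics for the two-arm rehabilitation study.

Covers the reporting conventions of the trial: group summaries as mean ± SD,
the percentage of FMA-UE improvement (mean gain over the 66-point scale
maximum), responder counts (> 5-point gain), paired and independent t-tests,
a 2x2 fully-within repeated-measures ANOVA (time x channel on ERD) and a
mixed ANOVA (time within, group between, on FMA-UE). A reference clinical
dataset (two groups of seven subacute stroke patients with pre/post FMA-UE
and T1/T12 ERD values) ships with the package for worked examples and
regression checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

FMA_UE_MAX = 66
RESPONDER_THRESHOLD = 5.0


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float


@dataclass
class AnovaEffect:
    F: float
    df1: float
    df2: float
    p: float


@dataclass
class ANOVAResult:
    """Per-effect F tests, keyed by effect name."""

    effects: dict[str, AnovaEffect]

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def group_summary(values, decimals: int | None = 1) -> tuple[float, float]:
    """(mean, sample SD), rounded for report parity (n−1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 for a standard deviation")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if decimals is not None:
        mean, sd = round(mean, decimals), round(sd, decimals)
    return mean, sd


def improvement_percent(pre, post, scale_max: float = FMA_UE_MAX) -> float:
    """Mean (post − pre) gain as a percentage of the scale maximum."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0 or pre.shape != post.shape:
        raise ValueError("pre/post must be equal-length and non-empty")
    return float((post - pre).mean() / scale_max * 100.0)


def responders(pre, post, threshold: float = RESPONDER_THRESHOLD) -> tuple[int, float]:
    """Count and proportion of patients improving strictly more than threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    gain = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    if gain.size == 0:
        raise ValueError("empty group")
    count = int((gain > threshold).sum())
    return count, count / gain.size


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def paired_ttest(x, y) -> TTestResult:
    """Classical paired t-test on x − y, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must be equal-length, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t undefined (p -> 0 limit)")
    res = sps.ttest_rel(x, y)
    return TTestResult(float(res.statistic), float(x.size - 1),
                       float(res.pvalue), float(d.mean()))


def independent_ttest(x, y, equal_var: bool = True) -> TTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = x.size + y.size - 2 if equal_var else float(res.df)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue),
                       float(x.mean() - y.mean()))


def rm_anova_2x2_within(data: np.ndarray,
                        factor_names: tuple[str, str] = ("time", "channel")) -> ANOVAResult:
    """Two-way fully-within-subject ANOVA on a (subjects, 2, 2) array.

    Classical sums of squares with subject-by-effect error terms; each
    effect has (1, n−1) degrees of freedom. For 2-level factors every F
    equals the squared paired t on the corresponding subject-wise contrast.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 3 or Y.shape[1:] != (2, 2):
        raise ValueError("expect data shaped (subjects, 2, 2)")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells in the within-subject design")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    a_means = Y.mean(axis=2)          # subjects x A
    b_means = Y.mean(axis=1)          # subjects x B
    subj_means = Y.mean(axis=(1, 2))
    grand = Y.mean()

    def _effect(cell_means: np.ndarray) -> AnovaEffect:
        # 2-level main effect; the other factor contributes the factor 2
        lvl_means = cell_means.mean(axis=0)
        ss_eff = 2 * n * ((lvl_means - grand) ** 2).sum()
        # error term: subject x level residual after subject and level means
        resid = cell_means - subj_means[:, None] - lvl_means[None, :] + grand
        ss_err = 2 * (resid**2).sum()
        df1, df2 = 1, n - 1
        F = (ss_eff / df1) / (ss_err / df2)
        return AnovaEffect(float(F), df1, df2, float(sps.f.sf(F, df1, df2)))

    eff_a = _effect(a_means)
    eff_b = _effect(b_means)

    # interaction: contrast (a1b1 - a1b2) - (a2b1 - a2b2) per subject
    inter = Y - a_means[:, :, None] - b_means[:, None, :] + subj_means[:, None, None]
    cell_eff = Y.mean(axis=0) - a_means.mean(axis=0)[:, None] \
        - b_means.mean(axis=0)[None, :] + grand
    ss_int = n * (cell_eff**2).sum()
    ss_int_err = ((inter - cell_eff[None]) ** 2).sum()
    df1, df2 = 1, n - 1
    F_int = (ss_int / df1) / (ss_int_err / df2)
    eff_ab = AnovaEffect(float(F_int), df1, df2, float(sps.f.sf(F_int, df1, df2)))

    a, b = factor_names
    return ANOVAResult({a: eff_a, b: eff_b, f"{a} * {b}": eff_ab})


def mixed_anova(data: np.ndarray, groups) -> ANOVAResult:
    """Mixed-design ANOVA: time (2 levels, within) x group (between).

    ``data`` is (subjects, 2) with the two timepoints; ``groups`` labels each
    subject. Balanced split-plot sums of squares (Type II == Type III here):
    F_group tests against subjects-within-groups, F_time and the interaction
    against the time x subject(group) residual.
    """
    Y = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    if Y.ndim != 2 or Y.shape[1] != 2 or len(groups) != Y.shape[0]:
        raise ValueError("expect (subjects, 2) data with one group label per subject")
    levels = np.unique(groups)
    counts = {g: int((groups == g).sum()) for g in levels}
    if any(c < 2 for c in counts.values()):
        raise ValueError("each group needs >= 2 subjects")
    n, t = Y.shape
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    time_means = Y.mean(axis=0)
    group_means = np.array([Y[groups == g].mean() for g in levels])
    gt_means = np.array([Y[groups == g].mean(axis=0) for g in levels])  # g x t

    ss_group = t * sum(counts[g] * (gm - grand) ** 2
                       for g, gm in zip(levels, group_means))
    ss_subj_within = t * sum(
        ((subj_means[groups == g] - gm) ** 2).sum()
        for g, gm in zip(levels, group_means))
    ss_time = n * ((time_means - grand) ** 2).sum()
    ss_int = sum(counts[g] * ((gt_means[i] - time_means - group_means[i] + grand) ** 2).sum()
                 for i, g in enumerate(levels))
    ss_total = ((Y - grand) ** 2).sum()
    ss_resid = ss_total - ss_group - ss_subj_within - ss_time - ss_int

    k = len(levels)
    df_group, df_subj = k - 1, n - k
    df_time, df_resid = t - 1, (t - 1) * (n - k)
    effects = {}
    F = (ss_group / df_group) / (ss_subj_within / df_subj)
    effects["group"] = AnovaEffect(float(F), df_group, df_subj,
                                   float(sps.f.sf(F, df_group, df_subj)))
    F = (ss_time / df_time) / (ss_resid / df_resid)
    effects["time"] = AnovaEffect(float(F), df_time, df_resid,
                                  float(sps.f.sf(F, df_time, df_resid)))
    F = (ss_int / (df_group * df_time)) / (ss_resid / df_resid)
    effects["time * group"] = AnovaEffect(float(F), df_group * df_time, df_resid,
                                          float(sps.f.sf(F, df_group * df_time, df_resid)))
    return ANOVAResult(effects)


# ---------------------------------------------------------------------------
# Reference clinical dataset and report
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("smrbci").joinpath("data", name)))


def load_reference_fma() -> pd.DataFrame:
    """Per-patient pre/post FMA-UE scores for both study arms."""
    return pd.read_csv(_data_path("clinical_fma.csv"))


def load_reference_erd() -> pd.DataFrame:
    """Per-patient ERD fractions at T1/T12, ipsi-/contralesional hemisphere."""
    return pd.read_csv(_data_path("erd_t1_t12.csv"))


def load_reference_baseline() -> pd.DataFrame:
    """Baseline demographics: sex, age, months since injury, baseline FMA-UE."""
    return pd.read_csv(_data_path("baseline_characteristics.csv"))


def erd_wide(erd: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long ERD table to (patient x [T1/T12 x hemisphere]) columns."""
    wide = erd.pivot_table(index="patient_id", columns=["timepoint", "hemisphere"],
                           values="value", sort=False)
    wide.columns = [f"{t}_{h}" for t, h in wide.columns]
    return wide


def clinical_report(fma: pd.DataFrame, erd: pd.DataFrame | None = None) -> dict:
    """Full statistics bundle: summaries, improvement, responders, tests.

    ``fma`` columns: patient_id, group, pre, post. ``erd`` columns:
    patient_id, timepoint (T1/T12), hemisphere (ipsilesional/contralesional),
    value (fraction).
    """
    report: dict = {"groups": {}}
    for g, sub in fma.groupby("group", sort=False):
        pre, post = sub["pre"].to_numpy(), sub["post"].to_numpy()
        count, prop = responders(pre, post)
        t_pp = paired_ttest(post, pre)
        report["groups"][g] = {
            "n": int(len(sub)),
            "fma_pre_mean_sd": group_summary(pre),
            "fma_post_mean_sd": group_summary(post),
            "improvement_percent": round(improvement_percent(pre, post), 2),
            "responders": count,
            "responder_percent": round(prop * 100, 1),
            "paired_p_pre_post": t_pp.p,
        }
    Y = fma[["pre", "post"]].to_numpy(float)
    res = mixed_anova(Y, fma["group"].to_numpy())
    report["fma_mixed_anova"] = {
        name: {"F": e.F, "df": [e.df1, e.df2], "p": e.p}
        for name, e in res.effects.items()
    }

    if erd is not None:
        wide = erd_wide(erd)
        cols = ["T1_ipsilesional", "T1_contralesional",
                "T12_ipsilesional", "T12_contralesional"]
        means = {c: round(float(wide[c].mean()), 3) for c in cols}
        data = np.stack([
            wide[["T1_ipsilesional", "T1_contralesional"]].to_numpy(float),
            wide[["T12_ipsilesional", "T12_contralesional"]].to_numpy(float),
        ], axis=1)  # subjects x time x hemisphere
        anova = rm_anova_2x2_within(data, ("time", "channel"))
        t_ipsi = paired_ttest(wide["T1_ipsilesional"], wide["T12_ipsilesional"])
        t_contra = paired_ttest(wide["T1_contralesional"], wide["T12_contralesional"])
        report["erd"] = {
            "means": means,
            "rm_anova": {name: {"F": e.F, "df": [e.df1, e.df2], "p": e.p}
                         for name, e in anova.effects.items()},
            "paired_p_ipsilesional": t_ipsi.p,
            "paired_p_contralesional": t_contra.p,
        }
    return report
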