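"""The study's statistical battery over MMN feature tables.

Between groups: one-way fixed-effects ANOVA per feature x deviant class
with Tukey HSD post-hocs.  Within groups: one-factor repeated-measures
ANOVA over the four deviant classes with Bonferroni-adjusted paired t
post-hocs.  Demographics use pooled-variance two-sample t tests and
Mann-Whitney U.  Summary-statistic forms (``anova_from_summary``,
``t_from_summary``) recompute the same tests from printed group means/SDs/n
alone, which is how the published worked-example tables are verified.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats", "AnovaResult", "RMAnovaResult", "PairwiseResult",
    "anova_oneway", "anova_from_summary", "t_from_summary", "tukey_hsd",
    "rm_anova", "bonferroni_pairwise", "mann_whitney", "run_study",
    "StudyResults",
]

FEATURES = ("amplitude_uV", "latency_ms", "auc_uVms")


@dataclass(frozen=True)
class SummaryStats:
    """Per-group first and second moments: (label, mean, sd, n)."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("each group needs n >= 2")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_effect: float
    df_error: float
    p: float
    epsilon: float = 1.0  # Greenhouse-Geisser epsilon if correction applied


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_adjusted: float
    method: str


def anova_oneway(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA on raw per-subject values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    F, p = stats.f_oneway(*arrays)
    k = len(arrays)
    N = sum(len(a) for a in arrays)
    return AnovaResult(F=float(F), df_between=k - 1, df_within=N - k,
                       p=float(p))


def anova_from_summary(summaries: list[SummaryStats]) -> AnovaResult:
    """One-way ANOVA recomputed from group means, SDs and sizes only.

    SSB = sum n_i (mean_i - grand mean)^2 over k-1 df; MSW pools the
    (n_i - 1) s_i^2.  Identical to :func:`anova_oneway` fed the same moments.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    n = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    N = n.sum()
    k = len(summaries)
    grand = float((n * means).sum() / N)
    ssb = float((n * (means - grand) ** 2).sum())
    ssw = float(((n - 1) * sds ** 2).sum())
    if ssw == 0:
        raise ValueError("zero pooled within-group variance")
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    F = msb / msw
    p = float(stats.f.sf(F, k - 1, N - k))
    return AnovaResult(F=F, df_between=k - 1, df_within=int(N - k), p=p)


def t_from_summary(a: SummaryStats, b: SummaryStats,
                   pooled: bool = True) -> dict:
    """Two-sample t test from group moments (pooled/Student by default)."""
    if pooled:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:  # Welch
        va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        se = np.sqrt(va + vb)
        if se == 0:
            raise ValueError("zero variance in both groups")
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    p = 2 * float(stats.t.sf(abs(t), df))
    return {"t": float(t), "df": float(df), "p": p}


def tukey_hsd(groups: dict[str, np.ndarray]) -> list[PairwiseResult]:
    """Tukey HSD pairwise comparisons (studentized-range family-wise p)."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 for Tukey HSD")
    res = stats.tukey_hsd(*arrays)
    out = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        out.append(PairwiseResult(
            pair=(labels[i], labels[j]),
            statistic=float(res.statistic[i, j]),
            p_adjusted=float(res.pvalue[i, j]),
            method="tukey",
        ))
    return out


def rm_anova(matrix: np.ndarray, gg_correction: bool = False) -> RMAnovaResult:
    """One-factor repeated-measures ANOVA on a subjects x conditions matrix.

    Decomposes total SS into subject, condition and residual
    (condition x subject) parts; F = MS_condition / MS_residual with
    df = (c-1), (c-1)(n-1).  ``gg_correction`` applies the
    Greenhouse-Geisser sphericity adjustment to the dfs and p.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n>=2 subjects by c>=2 conditions matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells in the repeated-measures matrix")
    n, c = x.shape
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = c * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_eff = float(c - 1)
    df_err = float((c - 1) * (n - 1))
    ms_cond = ss_cond / df_eff
    ms_err = ss_err / df_err
    F = 0.0 if ms_cond == 0 else ms_cond / ms_err

    eps = 1.0
    if gg_correction:
        # Greenhouse-Geisser epsilon from the double-centered covariance
        s = np.cov(x, rowvar=False, bias=True)
        dc = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
        eps = float(np.trace(dc) ** 2 / ((c - 1) * (dc ** 2).sum()))
        eps = min(max(eps, 1.0 / (c - 1)), 1.0)
    p = float(stats.f.sf(F, df_eff * eps, df_err * eps)) if ms_err > 0 else (
        1.0 if F == 0 else 0.0)
    return RMAnovaResult(F=float(F), df_effect=df_eff * eps,
                         df_error=df_err * eps, p=p, epsilon=eps)


def bonferroni_pairwise(matrix: np.ndarray,
                        condition_labels: list[str] | None = None
                        ) -> list[PairwiseResult]:
    """Paired t tests between all condition pairs, Bonferroni adjusted.

    Adjusted p = min(1, n_pairs x raw p).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n>=2 subjects by c>=2 conditions matrix")
    c = x.shape[1]
    labels = condition_labels or [f"c{i + 1}" for i in range(c)]
    pairs = list(itertools.combinations(range(c), 2))
    out = []
    for i, j in pairs:
        d = x[:, i] - x[:, j]
        if np.allclose(d.std(ddof=1), 0):
            t, p = (0.0, 1.0) if np.allclose(d.mean(), 0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(x[:, i], x[:, j])
        out.append(PairwiseResult(
            pair=(labels[i], labels[j]), statistic=float(t),
            p_adjusted=min(1.0, float(p) * len(pairs)), method="bonferroni",
        ))
    return out


def mann_whitney(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided Mann-Whitney U (exact for small untied samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {"U": float(res.statistic), "p": float(res.pvalue)}


@dataclass
class StudyResults:
    """Serializable bundle of every test the study battery runs."""

    oneway: dict[str, dict] = field(default_factory=dict)
    tukey: dict[str, list[dict]] = field(default_factory=dict)
    rm: dict[str, dict] = field(default_factory=dict)
    bonferroni: dict[str, list[dict]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "oneway": self.oneway, "tukey": self.tukey, "rm": self.rm,
            "bonferroni": self.bonferroni, "warnings": self.warnings,
        }, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_flat_frame(self) -> pd.DataFrame:
        rows = []
        for key, r in sorted(self.oneway.items()):
            rows.append({"test": "oneway_anova", "context": key,
                         "statistic": r["F"], "df1": r["df_between"],
                         "df2": r["df_within"], "p": r["p"]})
        for key, r in sorted(self.rm.items()):
            rows.append({"test": "rm_anova", "context": key,
                         "statistic": r["F"], "df1": r["df_effect"],
                         "df2": r["df_error"], "p": r["p"]})
        for key, lst in sorted(self.tukey.items()):
            for r in lst:
                rows.append({"test": "tukey", "context": f"{key}|{r['pair'][0]} vs {r['pair'][1]}",
                             "statistic": r["statistic"], "df1": np.nan,
                             "df2": np.nan, "p": r["p_adjusted"]})
        for key, lst in sorted(self.bonferroni.items()):
            for r in lst:
                rows.append({"test": "bonferroni_t", "context": f"{key}|{r['pair'][0]} vs {r['pair'][1]}",
                             "statistic": r["statistic"], "df1": np.nan,
                             "df2": np.nan, "p": r["p_adjusted"]})
        return pd.DataFrame(rows)


def run_study(feature_table: pd.DataFrame) -> StudyResults:
    """Run the full battery on a long-format feature table.

    Expects columns subject_id, group, deviant_kind and the three feature
    columns.  Produces one one-way ANOVA + Tukey per feature x deviant class
    (skipped with a warning when fewer than two groups are present) and one
    RM-ANOVA + Bonferroni pairwise set per group x feature.
    """
    required = {"subject_id", "group", "deviant_kind", *FEATURES}
    missing = required - set(feature_table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    kinds = sorted(feature_table["deviant_kind"].unique())
    groups = sorted(feature_table["group"].unique())
    res = StudyResults()

    for feat in FEATURES:
        for kind in kinds:
            sub = feature_table[feature_table["deviant_kind"] == kind]
            by_group = {g: sub.loc[sub["group"] == g, feat].to_numpy()
                        for g in groups}
            key = f"{feat}|{kind}"
            if len(groups) < 2:
                msg = f"only one group present; skipping one-way ANOVA for {key}"
                warnings.warn(msg)
                res.warnings.append(msg)
                continue
            res.oneway[key] = asdict(anova_oneway(by_group))
            res.tukey[key] = [asdict(r) for r in tukey_hsd(by_group)]

    for g in groups:
        sub = feature_table[feature_table["group"] == g]
        for feat in FEATURES:
            wide = sub.pivot(index="subject_id", columns="deviant_kind",
                             values=feat).reindex(columns=kinds)
            if wide.isna().any().any():
                raise ValueError(
                    f"incomplete design for group {g!r}, feature {feat!r}")
            key = f"{g}|{feat}"
            mat = wide.to_numpy()
            res.rm[key] = asdict(rm_anova(mat))
            res.bonferroni[key] = [asdict(r) for r in
                                   bonferroni_pairwise(mat, list(wide.columns))]
    return res
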