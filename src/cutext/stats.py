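"""Group/modality comparison harness.

Implements the parametric toolkit used for picture-description cohort
comparisons: one-way ANOVA with Tukey HSD post hoc contrasts and Cohen's d,
a one-between (group) / one-within (written vs spoken modality) split-plot
ANOVA, Pearson correlations, and a one-covariate common-slope ANCOVA.

Everything is computed from explicit sums of squares with exact reference
distributions (F, t, studentized range) from scipy; this keeps the
decomposition auditable and lets independent general-linear-model
implementations serve as cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


class DesignError(ValueError):
    pass


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_tukey: float
    ci95: tuple[float, float]
    cohens_d: float


@dataclass
class GroupComparisonResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False
    group_names: list[str] = field(default_factory=list)
    pairwise: list[PairwiseComparison] = field(default_factory=list)


@dataclass
class EffectTest:
    name: str
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class MixedAnovaResult:
    between: EffectTest       # group main effect
    within: EffectTest        # modality main effect
    interaction: EffectTest   # group x modality
    modality_contrasts: list[PairwiseComparison] = field(default_factory=list)


def _as_arrays(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise DesignError("need at least 2 groups")
    for i, a in enumerate(arrs):
        if a.ndim != 1 or a.size < 2:
            raise DesignError(f"group {i} needs n >= 2 observations")
        if not np.all(np.isfinite(a)):
            raise DesignError(f"group {i} contains non-finite values")
    return arrs


def one_way_anova(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> GroupComparisonResult:
    """Classic between/within sums-of-squares one-way ANOVA.

    If every observation is identical the F statistic is 0/0; the result is
    flagged degenerate with F and p reported as NaN.
    """
    arrs = _as_arrays(groups)
    g = len(arrs)
    ns = [a.size for a in arrs]
    N = sum(ns)
    grand = sum(a.sum() for a in arrs) / N
    ss_between = sum(n * (a.mean() - grand) ** 2 for n, a in zip(ns, arrs))
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = g - 1, N - g
    if ss_within == 0.0 and ss_between == 0.0:
        return GroupComparisonResult(
            F=math.nan, df_between=df_b, df_within=df_w, p=math.nan,
            degenerate=True, group_names=list(names or map(str, range(g))),
        )
    if ss_within == 0.0:
        F, p = math.inf, 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    return GroupComparisonResult(
        F=float(F), df_between=df_b, df_within=df_w, p=p,
        group_names=list(names or map(str, range(g))),
    )


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """(mean_a - mean_b) / pooled SD with (n-1)-weighted pooling.

    NaN when the pooled SD is zero (effect size undefined).
    """
    x, y = np.asarray(a, float), np.asarray(b, float)
    if x.size < 2 or y.size < 2:
        raise DesignError("cohens_d needs n >= 2 per group")
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0.0:
        return math.nan
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD (Tukey-Kramer under unequal n).

    p-values and simultaneous CIs come from the studentized range
    distribution with k groups and N-k error degrees of freedom, with the
    pooled within-group mean square as the error variance.
    """
    arrs = _as_arrays(groups)
    k = len(arrs)
    labels = list(names or map(str, range(k)))
    N = sum(a.size for a in arrs)
    df_err = N - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_err
    out: list[PairwiseComparison] = []
    qcrit = float(sps.studentized_range.ppf(1 - alpha, k, df_err))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[i], arrs[j]
            diff = float(a.mean() - b.mean())
            se = math.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            if se == 0.0:
                p = math.nan if diff == 0 else 0.0
                ci = (diff, diff)
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_err))
                half = qcrit * se
                ci = (diff - half, diff + half)
            out.append(
                PairwiseComparison(
                    group_a=labels[i], group_b=labels[j], mean_diff=diff,
                    p_tukey=min(1.0, p) if not math.isnan(p) else p,
                    ci95=ci, cohens_d=cohens_d(a, b),
                )
            )
    return out


def compare_groups(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
) -> GroupComparisonResult:
    """Omnibus one-way ANOVA plus Tukey pairwise records in one result."""
    res = one_way_anova(groups, names)
    if not res.degenerate:
        res.pairwise = tukey_hsd(groups, names)
    return res


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value (n-2 df).

    Returns (nan, nan) when either vector has zero variance.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size != ya.size or xa.size < 3:
        raise DesignError("pearson_corr needs paired vectors with n >= 3")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise DesignError("pearson_corr requires finite values")
    if xa.std() == 0.0 or ya.std() == 0.0:
        return (math.nan, math.nan)
    res = sps.pearsonr(xa, ya)
    return (float(res.statistic), float(res.pvalue))


def mixed_anova(
    values: Sequence[tuple[str, float, float]],
    modality_names: tuple[str, str] = ("written", "spoken"),
    alpha: float = 0.05,
) -> MixedAnovaResult:
    """One-between (group) / one-within (two-level modality) split-plot ANOVA.

    ``values`` holds one ``(group_label, value_modality1, value_modality2)``
    triple per subject; subjects missing a modality must be excluded by the
    caller (the pipeline drops them with a warning).  The group effect is
    tested against the subject-within-group mean square, the modality and
    interaction effects against the modality-by-subject residual.  Tukey
    contrasts of modality within each group use the within error term with
    the studentized range over all 2g cell means.
    """
    rows = list(values)
    if not rows:
        raise DesignError("mixed_anova needs at least one subject")
    groups = sorted({r[0] for r in rows})
    data: dict[str, np.ndarray] = {}
    for gname in groups:
        mat = np.array([[r[1], r[2]] for r in rows if r[0] == gname], float)
        if mat.shape[0] < 2:
            raise DesignError(f"group {gname!r} needs >= 2 subjects")
        if not np.all(np.isfinite(mat)):
            raise DesignError(f"group {gname!r} has non-finite values")
        data[gname] = mat
    g = len(groups)
    ns = {k: v.shape[0] for k, v in data.items()}
    N = sum(ns.values())
    m = 2
    all_vals = np.vstack([data[k] for k in groups])
    grand = all_vals.mean()

    subj_means = all_vals.mean(axis=1)
    ss_between_subj = m * ((subj_means - grand) ** 2).sum()
    ss_group = m * sum(
        ns[k] * (data[k].mean() - grand) ** 2 for k in groups
    )
    ss_subj_within = ss_between_subj - ss_group

    ss_within_total = ((all_vals - subj_means[:, None]) ** 2).sum()
    mod_means = all_vals.mean(axis=0)
    ss_modality = N * ((mod_means - grand) ** 2).sum()
    ss_cells = sum(
        ns[k] * ((data[k].mean(axis=0) - grand) ** 2).sum() for k in groups
    )
    ss_interaction = ss_cells - ss_group - ss_modality
    ss_err_within = ss_within_total - ss_modality - ss_interaction

    df_group, df_subj = g - 1, N - g
    df_mod, df_int, df_err = m - 1, g - 1, N - g

    def _test(name: str, ss: float, df1: int, ss_err: float, df2: int) -> EffectTest:
        if ss_err <= 0 or df1 == 0:
            return EffectTest(name, math.nan, df1, df2, math.nan)
        F = (ss / df1) / (ss_err / df2)
        return EffectTest(name, float(F), df1, df2, float(sps.f.sf(F, df1, df2)))

    between = _test("group", ss_group, df_group, ss_subj_within, df_subj)
    within = _test("modality", ss_modality, df_mod, ss_err_within, df_err)
    interaction = _test("group x modality", ss_interaction, df_int, ss_err_within, df_err)
    if g == 1:
        between = EffectTest("group", math.nan, 0, df_subj, math.nan)
        interaction = EffectTest("group x modality", math.nan, 0, df_err, math.nan)
    if ss_err_within <= 0:
        # identical modality columns: zero within-subject variability
        within = EffectTest("modality", 0.0 if ss_modality == 0 else math.inf,
                            df_mod, df_err, 1.0 if ss_modality == 0 else 0.0)

    contrasts: list[PairwiseComparison] = []
    ms_err = ss_err_within / df_err if df_err > 0 else math.nan
    n_cells = g * m
    if math.isfinite(ms_err) and ms_err > 0:
        qcrit = float(sps.studentized_range.ppf(1 - alpha, n_cells, df_err))
        for k in groups:
            diff = float(data[k][:, 0].mean() - data[k][:, 1].mean())
            se = math.sqrt(ms_err * 2.0 / ns[k])
            q = abs(diff) / (se / math.sqrt(2.0)) if se > 0 else math.inf
            p = float(sps.studentized_range.sf(q, n_cells, df_err))
            half = qcrit * se / math.sqrt(2.0)
            contrasts.append(
                PairwiseComparison(
                    group_a=f"{k}:{modality_names[0]}",
                    group_b=f"{k}:{modality_names[1]}",
                    mean_diff=diff, p_tukey=p,
                    ci95=(diff - half, diff + half),
                    cohens_d=cohens_d(data[k][:, 0], data[k][:, 1]),
                )
            )
    return MixedAnovaResult(
        between=between, within=within, interaction=interaction,
        modality_contrasts=contrasts,
    )


def ancova_one_covariate(
    values: Sequence[float],
    group_labels: Sequence[str],
    covariate: Sequence[float],
) -> tuple[float, float, float]:
    """Common-slope one-covariate ANCOVA.

    Returns (adjusted group F, group p, covariate p).  With a constant
    covariate the model reduces exactly to the one-way ANOVA.
    """
    y = np.asarray(values, float)
    x = np.asarray(covariate, float)
    labels = list(group_labels)
    if not (y.size == x.size == len(labels)):
        raise DesignError("values, group_labels and covariate must align")
    groups = sorted(set(labels))
    g = len(groups)
    if g < 2:
        raise DesignError("need at least 2 groups")
    N = y.size
    idx = {k: np.array([i for i, l in enumerate(labels) if l == k]) for k in groups}
    for k, ii in idx.items():
        if ii.size < 2:
            raise DesignError(f"group {k!r} needs n >= 2")

    exx = sum(((x[ii] - x[ii].mean()) ** 2).sum() for ii in idx.values())
    if exx == 0.0:
        res = one_way_anova([y[ii] for ii in idx.values()])
        return (res.F, res.p, math.nan)
    eyy = sum(((y[ii] - y[ii].mean()) ** 2).sum() for ii in idx.values())
    exy = sum(
        ((x[ii] - x[ii].mean()) * (y[ii] - y[ii].mean())).sum()
        for ii in idx.values()
    )
    txx = ((x - x.mean()) ** 2).sum()
    tyy = ((y - y.mean()) ** 2).sum()
    txy = ((x - x.mean()) * (y - y.mean())).sum()

    sse_full = eyy - exy**2 / exx          # covariate + group
    df_full = N - g - 1
    sse_reduced = tyy - txy**2 / txx       # covariate only
    if sse_full <= 1e-12 * max(1.0, tyy):
        # saturated fit: if the covariate alone already explains the outcome,
        # the group effect adds nothing (p = 1); otherwise it is decisive
        if sse_reduced <= 1e-12 * max(1.0, tyy):
            return (0.0, 1.0, 0.0)
        return (math.inf, 0.0, 0.0)
    ms_full = sse_full / df_full
    F_group = ((sse_reduced - sse_full) / (g - 1)) / ms_full
    p_group = float(sps.f.sf(F_group, g - 1, df_full))
    F_cov = (exy**2 / exx) / ms_full
    p_cov = float(sps.f.sf(F_cov, 1, df_full))
    return (float(F_group), p_group, p_cov)
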