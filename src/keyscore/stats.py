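"""Behavioural statistics applied to the performance scores.

Repeated-measures ANOVA (one- and two-way, fully within-subject, classical
sums-of-squares decomposition), Welch's two-sample t-test, Bonferroni
correction, and the ≥3 SD outlier rule.  Sphericity correction is NOT
applied by default (a Greenhouse–Geisser option exists): the design here
reports uncorrected degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectStats",
    "AnovaResult",
    "TTestResult",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "ttest_two_sample",
    "remove_outliers_3sd",
    "bonferroni",
]


@dataclass(frozen=True)
class EffectStats:
    """One F-test: degrees of freedom, F, p and partial eta squared."""

    df1: float
    df2: float
    F: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, EffectStats]

    def __getitem__(self, name: str) -> EffectStats:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": name,
                    "df1": e.df1,
                    "df2": e.df2,
                    "F": e.F,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                }
                for name, e in self.effects.items()
            ]
        )


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t: statistic, fractional df, p, Cohen's d, 95% CI."""

    t: float
    df: float
    p: float
    cohen_d: float
    ci_low: float
    ci_high: float


def _pivot_complete(
    data: pd.DataFrame, dv: str, index: str, columns: Sequence[str]
) -> pd.DataFrame:
    counts = data.pivot_table(
        index=index, columns=list(columns), values=dv, aggfunc="size", fill_value=0
    )
    if (counts.to_numpy() != 1).any():
        raise ValueError(
            "design must be complete and balanced: every subject needs exactly "
            "one observation per cell (no imputation is performed)"
        )
    return data.pivot_table(index=index, columns=list(columns), values=dv)


def _effect(ss_eff: float, df1: float, ss_err: float, df2: float) -> EffectStats:
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    F = 0.0 if ms_err == 0 and ms_eff == 0 else ms_eff / ms_err
    p = float(sps.f.sf(F, df1, df2))
    denom = ss_eff + ss_err
    np2 = 0.0 if denom == 0 else ss_eff / denom
    return EffectStats(df1=df1, df2=df2, F=float(F), p=p, partial_eta_sq=float(np2))


def _gg_epsilon(wide: np.ndarray) -> float:
    # Greenhouse–Geisser epsilon from the double-centered condition covariance
    S = np.cov(wide, rowvar=False, ddof=1)
    k = S.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    S_dc = J @ S @ J
    lam = np.linalg.eigvalsh(S_dc)
    num = lam.sum() ** 2
    den = (k - 1) * (lam**2).sum()
    return float(num / den) if den > 0 else 1.0


def rm_anova_oneway(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    correction: Literal["none", "gg"] = "none",
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a long table.

    For two conditions F equals the square of the paired t statistic.
    Missing cells raise; no imputation.
    """
    wide = _pivot_complete(data, dv, subject, [within]).to_numpy(dtype=float)
    n, k = wide.shape
    if k < 2:
        raise ValueError("need at least 2 within-subject conditions")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    gm = wide.mean()
    ss_cond = n * float(((wide.mean(axis=0) - gm) ** 2).sum())
    ss_subj = k * float(((wide.mean(axis=1) - gm) ** 2).sum())
    ss_tot = float(((wide - gm) ** 2).sum())
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = float(k - 1), float((n - 1) * (k - 1))
    eff = _effect(ss_cond, df1, ss_err, df2)
    if correction == "gg":
        eps = _gg_epsilon(wide)
        p = float(sps.f.sf(eff.F, df1 * eps, df2 * eps))
        eff = EffectStats(df1 * eps, df2 * eps, eff.F, p, eff.partial_eta_sq)
    return AnovaResult({within: eff})


def rm_anova_twoway(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str,
) -> AnovaResult:
    """Two-way fully within-subject ANOVA with effect-specific error terms.

    Each effect is tested against its interaction with subjects (A against
    A×S, B against B×S, A×B against A×B×S); partial eta squared is
    SS_effect / (SS_effect + SS_error).  Degrees of freedom are uncorrected.
    """
    fa, fb = within
    table = _pivot_complete(data, dv, subject, [fa, fb])
    a_levels = table.columns.get_level_values(0).unique()
    b_levels = table.columns.get_level_values(1).unique()
    n, a, b = table.shape[0], len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("both within factors need at least 2 levels")
    X = table.to_numpy(dtype=float).reshape(n, a, b)

    gm = X.mean()
    m_s = X.mean(axis=(1, 2))
    m_a = X.mean(axis=(0, 2))
    m_b = X.mean(axis=(0, 1))
    m_sa = X.mean(axis=2)
    m_sb = X.mean(axis=1)
    m_ab = X.mean(axis=0)

    ss_a = n * b * float(((m_a - gm) ** 2).sum())
    ss_b = n * a * float(((m_b - gm) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum())
    ss_as = b * float(((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2).sum())
    ss_bs = a * float(((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2).sum())
    resid = (
        X
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - gm
    )
    ss_abs = float((resid**2).sum())

    return AnovaResult(
        {
            fa: _effect(ss_a, float(a - 1), ss_as, float((a - 1) * (n - 1))),
            fb: _effect(ss_b, float(b - 1), ss_bs, float((b - 1) * (n - 1))),
            f"{fa} * {fb}": _effect(
                ss_ab, float((a - 1) * (b - 1)), ss_abs, float((a - 1) * (b - 1) * (n - 1))
            ),
        }
    )


def ttest_two_sample(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Welch's two-sample t-test with fractional df, Cohen's d and 95% CI.

    Welch (unequal variances) is the default two-sample comparison here;
    Cohen's d uses the pooled standard deviation.  Two zero-variance samples
    with equal means return t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        diff = float(x.mean() - y.mean())
        if diff == 0:
            df = float(x.size + y.size - 2)
            return TTestResult(t=0.0, df=df, p=1.0, cohen_d=0.0, ci_low=0.0, ci_high=0.0)
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(0.95)
    s_pooled = np.sqrt(
        ((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2)
    )
    d = float(abs(x.mean() - y.mean()) / s_pooled)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        cohen_d=d,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def remove_outliers_3sd(
    values: Sequence[float],
    groups: Sequence | None = None,
    n_sd: float = 3.0,
) -> tuple[np.ndarray, int]:
    """Single-pass removal of values ≥ ``n_sd`` standard deviations from
    their group mean.

    Group statistics are estimated once on the full data (no iterative
    re-trimming), so the operation is idempotent.  With ``groups`` given,
    mean and SD are computed per group.
    """
    v = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(v.size)
    g = np.asarray(groups)
    if g.shape != v.shape:
        raise ValueError("groups must align with values")
    keep = np.ones(v.size, dtype=bool)
    for label in pd.unique(g):
        idx = g == label
        if idx.sum() < 2:
            continue
        mu, sd = v[idx].mean(), v[idx].std(ddof=1)
        if sd > 0:
            keep[idx] &= np.abs(v[idx] - mu) < n_sd * sd
    return v[keep], int((~keep).sum())


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, m * p)``; m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)
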