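"""Shared statistical machinery for group-level inference.

Paired and one-sample t-tests with Cohen's d, exact/approximate Wilcoxon
signed-rank tests, balanced repeated-measures ANOVA with partial eta squared,
Benjamini-Hochberg FDR and Bonferroni corrections.  All group results are
returned as :class:`StatResult` records so downstream writers can serialize
them uniformly.

Conventions
-----------
* Degrees of freedom are reported as ``(df_effect, df_error)``.
* Effect sizes: Cohen's d for t statistics (``d = t / sqrt(n)`` for paired and
  one-sample designs), partial eta squared for F statistics.
* No sphericity correction is applied by default; repeated-measures F tests
  use the uncorrected degrees of freedom ``(a-1, (a-1)(n-1))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "paired_t",
    "one_sample_t",
    "wilcoxon_signed_rank",
    "rm_anova",
    "pairwise_posthoc",
    "partial_eta_sq_from_F",
    "cohens_d_from_t",
    "fdr_bh",
    "bonferroni",
    "attach_fdr",
]


@dataclass
class StatResult:
    """A single inferential statistic with its effect size and correction."""

    name: str                       # "t", "F" or "W"
    statistic: float
    df: tuple[float, float] | float | None
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    p_corrected: float | None = None
    correction: str | None = None
    family: str | None = None
    label: str = ""                 # what was tested (e.g. "post-post vs pre-pre")
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")

    def to_dict(self) -> dict:
        df = self.df
        if isinstance(df, tuple):
            df_effect, df_error = df
        else:
            df_effect, df_error = df, None
        nan = float("nan")
        return {
            "label": self.label,
            "statistic_name": self.name,
            "statistic": self.statistic,
            "df_effect": nan if df_effect is None else float(df_effect),
            "df_error": nan if df_error is None else float(df_error),
            "p_raw": self.p,
            "effect_size": nan if self.effect_size is None else self.effect_size,
            "effect_size_name": self.effect_size_name or "",
            "p_corrected": nan if self.p_corrected is None else self.p_corrected,
            "correction": self.correction or "",
            "family": self.family or "",
            "n": nan if self.n is None else float(self.n),
        }


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def cohens_d_from_t(t: float, n: int) -> float:
    """Cohen's d for a paired/one-sample t statistic: ``d = t / sqrt(n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(t) / math.sqrt(n)


def partial_eta_sq_from_F(F: float, df_effect: float, df_error: float) -> float:
    """Partial eta squared from an F statistic and its degrees of freedom.

    eta_p^2 = F * df_effect / (F * df_effect + df_error); for balanced
    repeated-measures designs this equals SS_effect / (SS_effect + SS_error).
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    if df_effect < 1 or df_error < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return (F * df_effect) / (F * df_effect + df_error)


def paired_t(a, b, label: str = "") -> StatResult:
    """Paired t-test across subjects with Cohen's d = mean(diff)/sd(diff)."""
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    return one_sample_t(diff, label=label)


def one_sample_t(x, popmean: float = 0.0, label: str = "") -> StatResult:
    x = _as_1d(x, "x")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    t, p = stats.ttest_1samp(x, popmean)
    d = (x.mean() - popmean) / sd
    return StatResult(
        name="t", statistic=float(t), df=(1, n - 1), p=float(p),
        effect_size=float(d), effect_size_name="cohen_d", label=label, n=n,
    )


def wilcoxon_signed_rank(x, y=None, label: str = "") -> StatResult:
    """Two-sided Wilcoxon signed-rank test (paired if ``y`` given, else vs 0).

    Zero differences are dropped (classic Wilcoxon treatment).  The exact null
    distribution is used for n <= 25 when the absolute differences are free of
    ties; otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    x = _as_1d(x, "x")
    if y is not None:
        y = _as_1d(y, "y")
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        diff = x - y
    else:
        diff = x
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        raise ValueError("all differences are zero: test undefined")
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        diff, zero_method="wilcox", alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    return StatResult(
        name="W", statistic=float(res.statistic), df=None, p=float(res.pvalue),
        label=label, n=int(nonzero.size),
    )


def _check_balanced(data: pd.DataFrame, dv: str, within: list[str], subject: str) -> None:
    counts = data.groupby([subject, *within], sort=False)[dv].count()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:5]
        raise ValueError(f"unbalanced design; cells with count != 1: {bad}")
    levels = [data[w].nunique() for w in within]
    n_sub = data[subject].nunique()
    expected = n_sub * int(np.prod(levels))
    if len(data) != expected:
        raise ValueError(
            f"incomplete design: {len(data)} rows, expected {expected} "
            f"({n_sub} subjects x {levels} levels)"
        )


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | Sequence[str],
    subject: str,
    family: str | None = None,
) -> list[StatResult]:
    """Repeated-measures ANOVA with one or two within-subject factors.

    Returns one :class:`StatResult` per effect (main effects, and the
    interaction for two-factor designs), with uncorrected-sphericity F tests
    and partial eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    if len(within) not in (1, 2):
        raise ValueError("rm_anova supports 1 or 2 within factors")
    _check_balanced(data, dv, within, subject)
    vals = data[dv].to_numpy(dtype=float)
    if np.ptp(vals) <= 1e-12 * max(1.0, np.abs(vals).max()):
        # degenerate constant input: every effect SS is 0
        n = data[subject].nunique()
        out = []
        for i, w in enumerate(within):
            a = data[w].nunique()
            out.append(StatResult(
                name="F", statistic=0.0, df=(a - 1, (a - 1) * (n - 1)), p=1.0,
                effect_size=0.0, effect_size_name="partial_eta_sq",
                label=w, family=family, n=n,
            ))
        if len(within) == 2:
            a, b = (data[w].nunique() for w in within)
            dfe = (a - 1) * (b - 1)
            out.append(StatResult(
                name="F", statistic=0.0, df=(dfe, dfe * (n - 1)), p=1.0,
                effect_size=0.0, effect_size_name="partial_eta_sq",
                label=f"{within[0]} * {within[1]}", family=family, n=n,
            ))
        return out
    table = pg.rm_anova(
        data=data, dv=dv, within=within if len(within) > 1 else within[0],
        subject=subject, detailed=True, effsize="np2",
    )
    table.columns = [c.replace("-", "_") for c in table.columns]
    n = data[subject].nunique()
    results = []
    for _, row in table.iterrows():
        if row["Source"] == "Error":
            continue
        if "ddof1" in table.columns:
            df_eff, df_err = float(row["ddof1"]), float(row["ddof2"])
        else:
            a = data[within[0]].nunique()
            df_eff = float(row["DF"])
            df_err = df_eff * (n - 1) if a - 1 == df_eff else float("nan")
        F = float(row["F"])
        results.append(StatResult(
            name="F", statistic=F, df=(df_eff, df_err), p=float(row["p_unc"]),
            effect_size=float(row["np2"]), effect_size_name="partial_eta_sq",
            label=str(row["Source"]), family=family, n=n,
        ))
    return results


def pairwise_posthoc(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    restrict: dict[str, object] | None = None,
    family: str | None = None,
) -> list[StatResult]:
    """Bonferroni-corrected paired-t post-hoc comparisons across factor levels.

    ``restrict`` optionally filters the table first (e.g. within one stage of
    a two-factor design).  The correction multiplies each p by the number of
    pairwise comparisons performed.
    """
    sub = data
    if restrict:
        for col, val in restrict.items():
            sub = sub[sub[col] == val]
    levels = list(pd.unique(sub[within]))
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    wide = sub.pivot_table(index=subject, columns=within, values=dv)
    results = []
    for la, lb in pairs:
        diffs = wide[la].to_numpy() - wide[lb].to_numpy()
        if (diffs == diffs[0]).all() and diffs[0] == 0:
            # identical levels: no difference anywhere, nothing to test
            res = StatResult(name="t", statistic=0.0, df=(1, len(diffs) - 1),
                             p=1.0, effect_size=0.0, effect_size_name="cohen_d",
                             label=f"{within}: {la} vs {lb}", n=len(diffs))
        else:
            res = paired_t(wide[la].to_numpy(), wide[lb].to_numpy(),
                           label=f"{within}: {la} vs {lb}")
        res.p_corrected = bonferroni(res.p, m)
        res.correction = "bonferroni"
        res.family = family
        results.append(res)
    return results


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: ``min(1, p * m)``."""
    if not 0 <= p <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def attach_fdr(results: list[StatResult], family: str) -> list[StatResult]:
    """Apply BH-FDR across a family of results, returning corrected copies."""
    if not results:
        return []
    adjusted = fdr_bh([r.p for r in results])
    return [
        replace(r, p_corrected=float(q), correction="fdr_bh", family=family)
        for r, q in zip(results, adjusted)
    ]
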