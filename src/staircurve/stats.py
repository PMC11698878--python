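"""Cohort statistics: Pearson correlation matrix with significance
flags, paired and two-sample t-tests (raw-data and summary-statistic
paths), and 2x2 chi-square tests without continuity correction.

These are the group-comparison tools used to adjudicate compensation
("poorer baseline gains more") against magnification ("richer baseline
gains more"): the sign of the baseline-gain correlation and the
between-arm gain contrasts carry the substance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationMatrix",
    "TTestResult",
    "ChiSquareResult",
    "pearson_matrix",
    "paired_t",
    "paired_t_from_summary",
    "two_sample_t",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "format_p",
]


def format_p(p: float) -> str:
    """Render a p value; very small ones print as '< 0.001'."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson r with two-sided p and two-tier significance flags."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    alpha_levels: tuple[float, float] = (0.05, 0.01)

    @property
    def flags(self) -> pd.DataFrame:
        """'**' below the stricter level, '*' below the looser, '' otherwise."""
        loose, strict = self.alpha_levels
        out = self.p.map(lambda v: "" if not np.isfinite(v) else
                         "**" if v < strict else "*" if v < loose else "")
        np.fill_diagonal(out.values, "")
        return out


@dataclass(frozen=True)
class TTestResult:
    kind: str  # "paired" | "two_sample_welch" | "two_sample_pooled"
    t: float
    df: float
    p: float
    group_summaries: tuple  # ((mean, sd, n), ...) — one per group, or the diff for paired

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError(f"degrees of freedom must be > 0, got {self.df}")


@dataclass(frozen=True)
class ChiSquareResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


def pearson_matrix(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    alpha_levels: tuple[float, float] = (0.05, 0.01),
) -> CorrelationMatrix:
    """Product-moment correlation matrix with t-transform p values (n-2 df).

    Zero-variance columns yield undefined correlations for their pairs,
    reported as NaN with a warning.  Requires >= 3 complete rows.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    data = table[variables].dropna()
    n = len(data)
    if n < 3:
        raise ValueError(f"need >= 3 complete rows, got {n}")

    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    degenerate = [v for v, s in zip(variables, sd) if s == 0.0]
    if degenerate:
        warnings.warn(
            f"zero-variance column(s) {degenerate}: correlations undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        for v in degenerate:
            i = variables.index(v)
            r[i, :] = r[:, i] = np.nan
        np.fill_diagonal(r, [np.nan if v in degenerate else 1.0 for v in variables])
        # two-sided p from t = r * sqrt((n-2) / (1-r^2))
        rr = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
        t = rr * np.sqrt((n - 2) / (1.0 - rr * rr))
        p = 2.0 * sps.t.sf(t, df=n - 2)
    np.fill_diagonal(p, np.nan)
    rdf = pd.DataFrame(r, index=variables, columns=variables)
    pdf = pd.DataFrame(p, index=variables, columns=variables)
    return CorrelationMatrix(r=rdf, p=pdf, n=n, alpha_levels=alpha_levels)


def paired_t(pre, post) -> TTestResult:
    """Two-sided paired t-test on the per-subject differences (post - pre)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"pre/post lengths differ: {pre.shape} vs {post.shape}")
    diff = post - pre
    n = len(diff)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero-variance differences: paired t undefined")
    return paired_t_from_summary(float(diff.mean()), sd, n)


def paired_t_from_summary(mean_gain: float, sd_gain: float, n: int) -> TTestResult:
    """Paired t from the gain summary: t = mean / (sd / sqrt(n)), df = n - 1."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_gain <= 0:
        raise ValueError("sd_gain must be > 0")
    t = mean_gain / (sd_gain / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TTestResult(
        kind="paired",
        t=float(t),
        df=float(n - 1),
        p=float(p),
        group_summaries=((mean_gain, sd_gain, n),),
    )


def two_sample_t(x, y, welch: bool = True) -> TTestResult:
    """Two-sided two-sample t-test on raw samples (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    return two_sample_t_from_summary(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
        welch=welch,
    )


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    welch: bool = True,
) -> TTestResult:
    """Two-sample t from group summaries; Welch-Satterthwaite df by default.

    A fully degenerate comparison (both SDs zero, equal means) reports
    t = 0 with a warning rather than failing.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            warnings.warn("degenerate comparison (no variance, equal means): t = 0",
                          RuntimeWarning, stacklevel=2)
            kind = "two_sample_welch" if welch else "two_sample_pooled"
            return TTestResult(kind=kind, t=0.0, df=float(n1 + n2 - 2), p=1.0,
                               group_summaries=((mean1, sd1, n1), (mean2, sd2, n2)))
        raise ValueError("both SDs are zero with unequal means: t undefined")
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        kind = "two_sample_welch"
    else:
        df = n1 + n2 - 2
        kind = "two_sample_pooled"
    return TTestResult(
        kind=kind, t=float(t), df=float(df), p=float(p),
        group_summaries=((mean1, sd1, n1), (mean2, sd2, n2)),
    )


def chi_square_2x2(observed) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Expected counts come from the row/column margins; a zero margin is
    rejected (expected counts would be zero).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"observed must be 2x2, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin: chi-square undefined")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(
        observed=obs, expected=expected, chi2=float(chi2), df=int(df), p=float(p)
    )
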