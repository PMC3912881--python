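"""Inferential procedures for the within-subjects study design.

* normality screening (Shapiro-Wilk);
* one-sample Wilcoxon signed-rank test against a hypothesized median, with
  an exact null distribution at small n and a tie-corrected normal
  approximation with continuity correction otherwise;
* paired-samples t-test;
* two-factor within-subjects (repeated-measures) ANOVA with the classical
  partitioned error strata, e.g. a 3 (time: baseline, pre-performance,
  performance) x 2 (audition: simulated, real) design.

The Wilcoxon exact path evaluates the full null distribution of the
positive-rank sum over all 2^n sign assignments (computed by convolution,
which enumerates the same distribution without materialising the 2^n
patterns).  Zeros are removed before ranking (Wilcoxon's convention) by
default; Pratt's method is available via ``zero_method="pratt"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WilcoxonResult",
    "TTestResult",
    "AnovaResult",
    "shapiro_wilk",
    "wilcoxon_one_sample",
    "paired_t",
    "rm_anova",
    "rm_anova_3x2",
]


@dataclass(frozen=True)
class WilcoxonResult:
    """One-sample Wilcoxon signed-rank test result."""

    n_effective: int
    w_statistic: float
    p_value: float
    method: str          # "exact" or "normal_approx"
    alternative: str     # "two_sided", "greater" or "less"


@dataclass(frozen=True)
class TTestResult:
    """Paired-samples t-test result."""

    t: float
    df: int
    p_value: float
    mean_diff: float


@dataclass(frozen=True)
class AnovaResult:
    """Within-subjects ANOVA table with partitioned error strata.

    ``table`` rows: one per effect and per matched error stratum, columns
    ``effect``, ``df``, ``ss``, ``ms``, ``f``, ``p`` (f and p are NaN for
    error strata and for degenerate zero-variance data).
    """

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}")
        return rows.iloc[0]

    def f(self, name: str) -> float:
        return float(self.effect(name)["f"])

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def df_pair(self, name: str) -> tuple[int, int]:
        """(effect df, matched error df) for a tested effect."""
        eff = self.effect(name)
        err = self.effect(f"error({name})")
        return int(eff["df"]), int(err["df"])


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality screen.

    Thin, validated surface over the Royston-algorithm implementation in
    scipy.  Constant input raises (zero variance carries no distributional
    information).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires a 1-D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input: zero variance")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def _signed_rank_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per value of 2W under the null.

    ``doubled_ranks`` are the (average) ranks times two, hence integers even
    in the presence of ties.  Element s of the returned array counts the
    assignments with positive-rank sum W = s/2; the counts total 2^n.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_one_sample(
    values,
    mu0: float = 3.0,
    alternative: str = "two_sided",
    zero_method: str = "wilcox",
    method: str = "auto",
    exact_threshold: int = 25,
) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test against a hypothesized median.

    Differences ``d_i = values_i - mu0`` are formed; zero differences are
    removed (``zero_method="wilcox"``, default) or retained for ranking and
    then dropped from the statistic (``"pratt"``).  Absolute differences are
    ranked with average ranks for ties and W is the sum of ranks of positive
    differences.

    The exact null distribution (full enumeration of sign assignments) is
    used when ``n_effective <= 12``, or up to ``exact_threshold`` when the
    ranks are untied; otherwise a normal approximation with tie-corrected
    variance and continuity correction.  ``method`` forces a path
    ("exact" / "normal_approx").
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("need a 1-D sample with n >= 1")
    d = x - mu0
    nonzero = d != 0
    if not np.any(nonzero):
        raise ValueError("all values equal mu0: no information against mu0")

    if zero_method == "wilcox":
        d_used = d[nonzero]
        ranks = stats.rankdata(np.abs(d_used))
    else:  # pratt: rank with zeros included, then drop zero ranks
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    n_eff = int(d_used.size)
    w = float(np.sum(ranks[d_used > 0]))

    doubled = np.rint(2.0 * ranks).astype(int)
    has_ties = bool(np.any(doubled % 2)) or np.unique(np.abs(d_used)).size < n_eff

    if method == "auto":
        use_exact = n_eff <= 12 or (n_eff <= exact_threshold and not has_ties)
    elif method == "exact":
        use_exact = True
    elif method == "normal_approx":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if use_exact:
        counts = _signed_rank_null_counts(doubled)
        total = 2.0**n_eff
        w2 = int(np.rint(2.0 * w))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(n_eff, w, float(p), "exact", alternative)

    mu_w = n_eff * (n_eff + 1) / 4.0
    var_w = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var_w <= 0:
        raise ValueError("degenerate variance in normal approximation")
    sd_w = np.sqrt(var_w)
    if alternative == "greater":
        z = (w - mu_w - 0.5) / sd_w
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (w - mu_w + 0.5) / sd_w
        p = stats.norm.cdf(z)
    else:
        z = (w - mu_w - 0.5 * np.sign(w - mu_w)) / sd_w
        p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(n_eff, w, float(min(p, 1.0)), "normal_approx", alternative)


def paired_t(a, b) -> TTestResult:
    """Paired-samples t-test: t = mean(d) / (sd(d) / sqrt(n)), d = a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D sequences of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p_value=p, mean_diff=float(np.mean(d)))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A k x (k-1) orthonormal basis of the space orthogonal to the mean."""
    from scipy.linalg import null_space

    return null_space(np.ones((1, k)))


def _gg_epsilon(scores: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one effect's contrast space."""
    s = np.cov(scores, rowvar=False)
    m = contrasts.T @ np.atleast_2d(s) @ contrasts
    df = m.shape[0]
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / df, tr**2 / (df * tr2))))


def rm_anova(
    data,
    factor_a: str = "time",
    factor_b: str = "audition",
    sphericity_correction: str = "none",
) -> AnovaResult:
    """Two-factor within-subjects ANOVA with partitioned error strata.

    ``data`` is either an ndarray of cell scores with shape
    ``(n_participants, a_levels, b_levels)`` or a long DataFrame with columns
    ``participant``, ``<factor_a>``, ``<factor_b>``, ``value`` forming a
    complete balanced design (no missing cells, no imputation).

    Sums of squares follow the classical decomposition: each within-subjects
    effect is tested against its own participant-by-effect interaction
    stratum, so for a 3 x 2 design with n participants the df are
    (a-1, (a-1)(n-1)), (b-1, (b-1)(n-1)) and ((a-1)(b-1), (a-1)(b-1)(n-1)).
    F uses uncorrected df by default; ``sphericity_correction="gg"`` adjusts
    the p-values with the Greenhouse-Geisser epsilon.
    """
    if sphericity_correction not in ("none", "gg"):
        raise ValueError(f"unknown sphericity correction {sphericity_correction!r}")
    if isinstance(data, pd.DataFrame):
        y = _long_to_cells(data, factor_a, factor_b)
    else:
        y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected data with shape (participants, a_levels, b_levels)")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 1:
        raise ValueError("need >= 2 participants and >= 2 levels of the first factor")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite cells: design must be complete")

    gm = y.mean()
    m_i = y.mean(axis=(1, 2))
    m_j = y.mean(axis=(0, 2))
    m_k = y.mean(axis=(0, 1))
    m_ij = y.mean(axis=2)
    m_ik = y.mean(axis=1)
    m_jk = y.mean(axis=0)

    ss_total = float(((y - gm) ** 2).sum())
    ss_subj = float(a * b * ((m_i - gm) ** 2).sum())
    ss_a = float(n * b * ((m_j - gm) ** 2).sum())
    ss_err_a = float(b * ((m_ij - m_i[:, None] - m_j[None, :] + gm) ** 2).sum())
    rows = [
        ("participants", n - 1, ss_subj),
        (factor_a, a - 1, ss_a),
        (f"error({factor_a})", (a - 1) * (n - 1), ss_err_a),
    ]
    if b >= 2:
        ss_b = float(n * a * ((m_k - gm) ** 2).sum())
        ss_ab = float(
            n * ((m_jk - m_j[:, None] - m_k[None, :] + gm) ** 2).sum()
        )
        ss_err_b = float(a * ((m_ik - m_i[:, None] - m_k[None, :] + gm) ** 2).sum())
        ss_err_ab = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_err_a - ss_err_b
        inter = f"{factor_a}:{factor_b}"
        rows += [
            (factor_b, b - 1, ss_b),
            (f"error({factor_b})", (b - 1) * (n - 1), ss_err_b),
            (inter, (a - 1) * (b - 1), ss_ab),
            (f"error({inter})", (a - 1) * (b - 1) * (n - 1), ss_err_ab),
        ]

    table = pd.DataFrame(rows, columns=["effect", "df", "ss"])
    table["ms"] = table["ss"] / table["df"]
    table["f"] = np.nan
    table["p"] = np.nan

    tested = [factor_a] + ([factor_b, f"{factor_a}:{factor_b}"] if b >= 2 else [])
    for name in tested:
        eff = table.index[table["effect"] == name][0]
        err = table.index[table["effect"] == f"error({name})"][0]
        ms_eff = table.at[eff, "ms"]
        ms_err = table.at[err, "ms"]
        df1 = table.at[eff, "df"]
        df2 = table.at[err, "df"]
        if ms_err <= 0:
            warnings.warn(
                f"zero error variance for effect {name!r}: F undefined", stacklevel=2
            )
            continue
        f = ms_eff / ms_err
        eps = 1.0
        if sphericity_correction == "gg":
            c_a = _orthonormal_contrasts(a)
            if name == factor_a:
                eps = _gg_epsilon(m_ij, c_a)
            elif name == factor_b:
                eps = _gg_epsilon(m_ik, _orthonormal_contrasts(b))
            else:
                c = np.kron(c_a, _orthonormal_contrasts(b))
                eps = _gg_epsilon(y.reshape(n, a * b), c)
        table.at[eff, "f"] = f
        table.at[eff, "p"] = stats.f.sf(f, eps * df1, eps * df2)
    return AnovaResult(table=table)


def rm_anova_3x2(data, **kwargs) -> AnovaResult:
    """The study's 3 (time) x 2 (audition) within-subjects ANOVA."""
    result = rm_anova(data, **kwargs)
    a_levels = result.df_pair(kwargs.get("factor_a", "time"))[0] + 1
    if a_levels != 3:
        raise ValueError(f"expected 3 levels of time, got {a_levels}")
    return result


def _long_to_cells(df: pd.DataFrame, factor_a: str, factor_b: str) -> np.ndarray:
    required = {"participant", factor_a, factor_b, "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    pivot = df.pivot_table(
        index="participant", columns=[factor_a, factor_b], values="value",
        aggfunc="mean", sort=True,
    )
    if pivot.isna().any().any():
        raise ValueError("unbalanced design: missing cells (no imputation)")
    counts = df.groupby(["participant", factor_a, factor_b]).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal cell counts")
    a_levels = df[factor_a].nunique()
    b_levels = df[factor_b].nunique()
    return pivot.to_numpy().reshape(len(pivot), a_levels, b_levels)
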