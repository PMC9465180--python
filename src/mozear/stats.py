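"""Statistical tests used across the analysis chain.

Implements the aligned rank transform (ART) for 1- and 2-factor
designs, exact/approximate Wilcoxon tests, Bonferroni adjustment and a
one-way repeated-measures ANOVA with reference-tissue contrasts.

The ART procedure makes factorial ANOVA applicable to non-normal
responses: for each effect, the response is "aligned" by subtracting
the cell-mean estimates of every *other* effect, the aligned values are
ranked (mid-ranks for ties) and an ordinary factorial ANOVA is run on
the ranks — only the effect of interest is then read off. With response
y_ijk, cell means m_ij, marginal means m_i., m_.j and grand mean m:

    align(A)   = y_ijk - m_ij + m_i. - m
    align(B)   = y_ijk - m_ij + m_.j - m
    align(AxB) = y_ijk - m_i. - m_.j + m
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "FactorialData",
    "TestResult",
    "art_anova",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bonferroni",
    "repeat_anova",
]


@dataclass(frozen=True)
class TestResult:
    """One test outcome: effect name, statistic, df (or n), p, optional p_adj."""

    effect: str
    statistic: float
    p_value: float
    df: tuple[float, float] | None = None
    n: int | None = None
    p_adjusted: float | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FactorialData:
    """Response vector with one or two crossed categorical factors."""

    response: np.ndarray
    factors: dict[str, np.ndarray]
    subject: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", y)
        if not np.all(np.isfinite(y)):
            raise InvalidInputError("response must be finite")
        if not 1 <= len(self.factors) <= 2:
            raise InvalidInputError("FactorialData supports 1 or 2 factors")
        facs = {k: np.asarray(v) for k, v in self.factors.items()}
        object.__setattr__(self, "factors", facs)
        for name, v in facs.items():
            if v.shape != y.shape:
                raise InvalidInputError(f"factor {name!r} length mismatch")
            if len(np.unique(v)) < 2:
                raise InvalidInputError(f"factor {name!r} needs >= 2 levels")


def _rank(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _anova_on_ranks(
    ranks: np.ndarray, factors: dict[str, np.ndarray]
) -> dict[str, tuple[float, float, float, float]]:
    """Full factorial ANOVA of ``ranks``; returns effect -> (F, df1, df2, p).

    Balanced designs use the classical sums-of-squares decomposition;
    unbalanced two-factor designs fall back to a type-II linear-model
    ANOVA (statsmodels).
    """
    names = list(factors)
    if len(names) == 1:
        f_res = _oneway_anova(ranks, factors[names[0]])
        return {names[0]: f_res}

    a, b = (factors[n] for n in names)
    cells = pd.Series(ranks).groupby([pd.Series(a), pd.Series(b)])
    counts = cells.size()
    if counts.nunique() == 1:
        return _balanced_twoway(ranks, a, b, names)
    return _typeII_twoway(ranks, a, b, names)


def _oneway_anova(y: np.ndarray, g: np.ndarray) -> tuple[float, float, float, float]:
    levels = np.unique(g)
    grand = y.mean()
    ss_between = sum(
        (g == lv).sum() * (y[g == lv].mean() - grand) ** 2 for lv in levels
    )
    ss_within = sum(((y[g == lv] - y[g == lv].mean()) ** 2).sum() for lv in levels)
    df1 = len(levels) - 1
    df2 = y.size - len(levels)
    if ss_within <= 1e-12 * max(ss_between, 1.0):
        if ss_between <= 1e-12:
            return (0.0, df1, df2, 1.0)
        return (np.inf, df1, df2, 0.0)
    f = (ss_between / df1) / (ss_within / df2)
    return (f, df1, df2, float(sps.f.sf(f, df1, df2)))


def _balanced_twoway(
    y: np.ndarray, a: np.ndarray, b: np.ndarray, names: list[str]
) -> dict[str, tuple[float, float, float, float]]:
    la, lb = np.unique(a), np.unique(b)
    grand = y.mean()
    ma = {lv: y[a == lv].mean() for lv in la}
    mb = {lv: y[b == lv].mean() for lv in lb}
    mab = {(i, j): y[(a == i) & (b == j)].mean() for i in la for j in lb}
    nab = {(i, j): ((a == i) & (b == j)).sum() for i in la for j in lb}
    ss_a = sum((a == lv).sum() * (ma[lv] - grand) ** 2 for lv in la)
    ss_b = sum((b == lv).sum() * (mb[lv] - grand) ** 2 for lv in lb)
    ss_ab = sum(
        nab[(i, j)] * (mab[(i, j)] - ma[i] - mb[j] + grand) ** 2 for i in la for j in lb
    )
    ss_err = sum(
        ((y[(a == i) & (b == j)] - mab[(i, j)]) ** 2).sum() for i in la for j in lb
    )
    df_err = y.size - len(la) * len(lb)
    out = {}
    for eff, ss, df1 in (
        (names[0], ss_a, len(la) - 1),
        (names[1], ss_b, len(lb) - 1),
        (f"{names[0]}:{names[1]}", ss_ab, (len(la) - 1) * (len(lb) - 1)),
    ):
        if ss_err <= 1e-12 * max(ss, 1.0):
            out[eff] = (0.0, df1, df_err, 1.0) if ss <= 1e-12 else (np.inf, df1, df_err, 0.0)
        else:
            f = (ss / df1) / (ss_err / df_err)
            out[eff] = (f, df1, df_err, float(sps.f.sf(f, df1, df_err)))
    return out


def _typeII_twoway(
    y: np.ndarray, a: np.ndarray, b: np.ndarray, names: list[str]
) -> dict[str, tuple[float, float, float, float]]:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "A": a.astype(str), "B": b.astype(str)})
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    mapping = {"C(A)": names[0], "C(B)": names[1], "C(A):C(B)": f"{names[0]}:{names[1]}"}
    df2 = float(tab.loc["Residual", "df"])
    return {
        mapping[k]: (
            float(tab.loc[k, "F"]),
            float(tab.loc[k, "df"]),
            df2,
            float(tab.loc[k, "PR(>F)"]),
        )
        for k in mapping
    }


def art_anova(data: FactorialData) -> list[TestResult]:
    """Aligned rank transform factorial ANOVA, one result per effect."""
    y = data.response
    names = list(data.factors)
    if np.ptp(y) == 0:
        return [
            TestResult(effect=n, statistic=float("nan"), p_value=float("nan"),
                       flags=("degenerate",))
            for n in names + ([f"{names[0]}:{names[1]}"] if len(names) == 2 else [])
        ]

    if len(names) == 1:
        # alignment subtracts only the grand mean, which leaves ranks unchanged
        ranks = _rank(y)
        f, df1, df2, p = _anova_on_ranks(ranks, data.factors)[names[0]]
        return [TestResult(effect=names[0], statistic=f, p_value=p, df=(df1, df2))]

    a, b = (data.factors[n] for n in names)
    la, lb = np.unique(a), np.unique(b)
    for i in la:
        for j in lb:
            if not np.any((a == i) & (b == j)):
                raise InvalidInputError(f"empty cell ({i}, {j}) in factorial design")
    grand = y.mean()
    ma = np.zeros_like(y)
    mb = np.zeros_like(y)
    mab = np.zeros_like(y)
    for lv in la:
        ma[a == lv] = y[a == lv].mean()
    for lv in lb:
        mb[b == lv] = y[b == lv].mean()
    for i in la:
        for j in lb:
            cell = (a == i) & (b == j)
            mab[cell] = y[cell].mean()

    aligned = {
        names[0]: y - mab + ma - grand,
        names[1]: y - mab + mb - grand,
        f"{names[0]}:{names[1]}": y - ma - mb + grand,
    }
    results = []
    for eff, av in aligned.items():
        table = _anova_on_ranks(_rank(av), data.factors)
        f, df1, df2, p = table[eff]
        results.append(TestResult(effect=eff, statistic=f, p_value=p, df=(df1, df2)))
    return results


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for the signed-rank statistic by sign-flip enumeration.

    The null distribution of T+ over all 2^n sign assignments is built
    by dynamic programming on doubled ranks (mid-ranks for tied |d| are
    half-integers), so tied magnitudes are handled exactly.
    """
    ranks = sps.rankdata(np.abs(d))
    r2 = np.round(2 * ranks).astype(int)
    t_plus = float(ranks[d > 0].sum())
    t2 = int(round(2 * t_plus))
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_low = counts[: t2 + 1].sum()
    p_high = counts[t2:].sum()
    return t_plus, float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray | None = None, zero_policy: str = "wilcox"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    Exact null distribution (sign-flip enumeration, tie-safe) for
    n <= 25 under the default drop-zeros policy; normal approximation
    with continuity correction otherwise. ``"pratt"`` keeps zero
    differences in the ranking (always approximate here).
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size < 2:
        raise InsufficientDataError("signed-rank test needs >= 2 pairs")
    if zero_policy not in ("wilcox", "pratt"):
        raise InvalidInputError(f"unknown zero_policy {zero_policy!r}")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return TestResult(effect="signed_rank", statistic=0.0, p_value=1.0,
                          n=int(d.size), flags=("zero_variance",))
    n_eff = nonzero.size if zero_policy == "wilcox" else d.size
    if zero_policy == "wilcox" and n_eff <= 25:
        stat, p = _exact_signed_rank_p(nonzero)
        return TestResult(effect="signed_rank", statistic=stat, p_value=p,
                          n=int(n_eff))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, zero_method=zero_policy, correction=True,
                           alternative="two-sided", method="approx")
    return TestResult(effect="signed_rank", statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)), n=int(n_eff))


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact for combined n <= 20 without ties, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("rank-sum test needs >= 2 observations per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(effect="rank_sum", statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)), n=int(pooled.size))


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p), order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m_eff = p.size if m is None else int(m)
    return np.minimum(1.0, m_eff * p)


def repeat_anova(
    table: pd.DataFrame,
    value_col: str = "delta_ct",
    subject_col: str = "repeat",
    within_col: str = "tissue",
    gene_col: str = "gene",
    reference_level: str = "head",
) -> dict[str, list[TestResult]]:
    """One-way repeated-measures ANOVA per gene, tissue within subject.

    Incomplete subjects (a repeat missing any tissue) are dropped
    listwise with a warning. The omnibus test is followed by paired
    contrasts of each tissue against the reference, Bonferroni-adjusted.
    Sphericity is assumed (no correction).
    """
    results: dict[str, list[TestResult]] = {}
    for gene, sub in table.groupby(gene_col, sort=True):
        wide = sub.pivot_table(index=subject_col, columns=within_col,
                               values=value_col, aggfunc="mean")
        complete = wide.dropna()
        if len(complete) < len(wide):
            warnings.warn(
                f"gene {gene!r}: dropped {len(wide) - len(complete)} incomplete repeat(s)",
                stacklevel=2,
            )
        n_subj, k = complete.shape
        if n_subj < 2:
            raise InsufficientDataError(
                f"gene {gene!r}: repeated-measures ANOVA needs >= 2 complete repeats"
            )
        y = complete.to_numpy(dtype=float)
        grand = y.mean()
        m_t = y.mean(axis=0)
        m_s = y.mean(axis=1)
        ss_within_factor = n_subj * ((m_t - grand) ** 2).sum()
        resid = y - m_t[None, :] - m_s[:, None] + grand
        ss_err = (resid**2).sum()
        df1, df2 = k - 1, (k - 1) * (n_subj - 1)
        if ss_err <= 1e-12 * max(ss_within_factor, 1.0):
            f_stat, p = (0.0, 1.0) if ss_within_factor <= 1e-12 else (np.inf, 0.0)
        else:
            f_stat = (ss_within_factor / df1) / (ss_err / df2)
            p = float(sps.f.sf(f_stat, df1, df2))
        out = [TestResult(effect=within_col, statistic=f_stat, p_value=p,
                          df=(df1, df2), n=n_subj)]

        others = [c for c in complete.columns if c != reference_level]
        if reference_level in complete.columns and others:
            raw = []
            for tissue in others:
                diff = complete[tissue] - complete[reference_level]
                if np.allclose(diff, 0):
                    raw.append((tissue, 0.0, 1.0))
                else:
                    t_res = sps.ttest_rel(complete[tissue], complete[reference_level])
                    raw.append((tissue, float(t_res.statistic), float(t_res.pvalue)))
            adj = bonferroni(np.array([p for _, _, p in raw]))
            for (tissue, t_stat, p_raw), p_adj in zip(raw, adj):
                out.append(TestResult(
                    effect=f"{tissue} vs {reference_level}", statistic=t_stat,
                    p_value=p_raw, df=(1.0, float(n_subj - 1)), n=n_subj,
                    p_adjusted=float(p_adj),
                ))
        results[str(gene)] = out
    return results
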