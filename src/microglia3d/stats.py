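"""Group-comparison statistics with a normality gate.

Each two-sample comparison first applies the Shapiro-Wilk test to both
samples; if both pass at ``normality_alpha`` (default 0.05) a classical
(equal-variance) two-sided Student's t-test is used, otherwise a two-sided
Mann-Whitney U test -- exact when the sample sizes allow full enumeration
(n*m <= 2000 and no ties), normal approximation with tie correction
otherwise.  The branch taken is always recorded in the result.

Datasets with two factors (group x CD68 status) use a two-way ANOVA with
Type-II sums of squares on the unbalanced 2x2 design, followed by the four
scientifically relevant pairwise contrasts with Bonferroni correction
(pooled-variance t statistics on the residual mean square).

Reporting follows the mean +/- SEM convention with significance stars
* p<=0.05, ** p<=0.01, *** p<=0.001, **** p<=0.0001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p <= level:
            return stars
    return "ns"


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    alternative: str = "two-sided"
    normality_p: tuple[float, ...] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        d = {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "stars": self.stars,
            "alternative": self.alternative,
        }
        for i, n in enumerate(self.n_per_group):
            d[f"n{i + 1}"] = n
        if self.normality_p is not None:
            for i, p in enumerate(self.normality_p):
                d[f"shapiro_p{i + 1}"] = p
        d.update(self.extra)
        return d


@dataclass
class GroupTable:
    """Observations tagged with group, optional second factor and unit id.

    The unit of analysis (per-cell vs per-subject) is the caller's explicit
    declaration: pass per-subject averages for count/proportion comparisons
    and per-cell values for size and shape metrics.
    """

    data: pd.DataFrame  # columns: value, group, optional factor2, optional unit

    def __post_init__(self) -> None:
        required = {"value", "group"}
        if not required <= set(self.data.columns):
            raise ValueError("GroupTable needs columns 'value' and 'group'")
        if not np.isfinite(self.data["value"].to_numpy(float)).all():
            raise ValueError("values must be finite")

    def samples(self) -> dict[str, np.ndarray]:
        return {
            g: sub["value"].to_numpy(float) for g, sub in self.data.groupby("group", sort=True)
        }


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation); requires 3 <= n <= 5000."""
    x = np.asarray(sample, float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if len(x) > 5000:
        raise ValueError("Shapiro-Wilk p-value approximation is unreliable for n > 5000")
    if not np.isfinite(x).all():
        raise ValueError("sample contains non-finite values")
    if len(np.unique(x)) < len(x):
        warnings.warn("ties present in Shapiro-Wilk sample", stacklevel=2)
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality statistic")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = (len(a) * len(b) <= 2000) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def two_sample_test(
    a,
    b,
    normality_alpha: float = 0.05,
    welch: bool = False,
) -> TestResult:
    """Normality-gated two-sided comparison of two independent samples.

    Both samples passing Shapiro-Wilk at ``normality_alpha`` selects
    Student's t (classical equal-variance form unless ``welch``); otherwise
    Mann-Whitney U.  The result records which branch fired and both
    normality p-values.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("normality gate requires n >= 3 per sample")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical across both samples; test degenerate")
    norm_p = []
    for s in (a, b):
        try:
            _, p = shapiro_wilk(s)
        except ValueError:  # constant within one sample
            p = 0.0
        norm_p.append(p)
    both_normal = all(p > normality_alpha for p in norm_p)
    if both_normal:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        name = "welch_t" if welch else "student_t"
        stat, p, method = float(res.statistic), float(res.pvalue), "parametric"
    else:
        stat, p, method = _mann_whitney(a, b)
        name = "mann_whitney_u"
    return TestResult(
        test_name=name,
        statistic=stat,
        p_value=min(p, 1.0),
        n_per_group=(len(a), len(b)),
        normality_p=tuple(norm_p),
        extra={"branch": name, "mw_method": method if name == "mann_whitney_u" else ""},
    )


@dataclass
class AnovaResult:
    table: pd.DataFrame  # Type-II ANOVA table (F and p for each effect)
    contrasts: list[TestResult]  # Bonferroni-corrected pairwise comparisons
    cell_means: pd.DataFrame

    def effect_p(self, effect: str) -> float:
        return float(self.table.loc[effect, "PR(>F)"])


def two_way_anova_bonferroni(
    table: GroupTable,
    factor2: str = "factor2",
    n_comparisons: int | None = None,
) -> AnovaResult:
    """Two-way ANOVA (Type-II SS) with Bonferroni pairwise comparisons.

    The four reported contrasts are the scientifically relevant ones on a
    group x status design: between groups within each status level, and
    between status levels within each group.  Raw pooled-variance t
    p-values are multiplied by the number of comparisons and capped at 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.data.rename(columns={factor2: "factor2"}).copy()
    if "factor2" not in df.columns:
        raise ValueError("two-way ANOVA needs a second factor column")
    groups = sorted(df["group"].unique())
    levels = sorted(df["factor2"].unique())
    if len(groups) != 2 or len(levels) != 2:
        raise ValueError("expected a 2x2 design (two groups x two factor levels)")
    for g in groups:
        for l in levels:
            n = ((df["group"] == g) & (df["factor2"] == l)).sum()
            if n < 2:
                raise ValueError(f"cell ({g}, {l}) has {n} observations; >= 2 required")

    model = smf.ols("value ~ C(group) * C(factor2)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(group)": "group",
            "C(factor2)": "factor2",
            "C(group):C(factor2)": "interaction",
            "Residual": "residual",
        }
    )
    mse = float(anova.loc["residual", "sum_sq"] / anova.loc["residual", "df"])
    df_resid = float(anova.loc["residual", "df"])

    cells = {
        (g, l): df.loc[(df["group"] == g) & (df["factor2"] == l), "value"].to_numpy(float)
        for g in groups
        for l in levels
    }
    pairs = [
        ((groups[0], levels[0]), (groups[1], levels[0])),
        ((groups[0], levels[1]), (groups[1], levels[1])),
        ((groups[0], levels[0]), (groups[0], levels[1])),
        ((groups[1], levels[0]), (groups[1], levels[1])),
    ]
    k = n_comparisons if n_comparisons is not None else len(pairs)
    contrasts = []
    for (c1, c2) in pairs:
        x1, x2 = cells[c1], cells[c2]
        se = np.sqrt(mse * (1.0 / len(x1) + 1.0 / len(x2)))
        t = (x1.mean() - x2.mean()) / se
        p_raw = 2.0 * sps.t.sf(abs(t), df_resid)
        contrasts.append(
            TestResult(
                test_name="bonferroni_t",
                statistic=float(t),
                p_value=float(min(1.0, k * p_raw)),
                n_per_group=(len(x1), len(x2)),
                extra={
                    "comparison": f"{c1[0]}/{c1[1]} vs {c2[0]}/{c2[1]}",
                    "p_raw": float(p_raw),
                    "k": k,
                },
            )
        )
    cell_means = (
        df.groupby(["group", "factor2"])["value"].agg(["mean", "sem", "count"]).reset_index()
    )
    return AnovaResult(table=anova, contrasts=contrasts, cell_means=cell_means)


def summarize(sample, label: str = "") -> dict:
    """Mean +/- SEM summary row (SEM = sample sd / sqrt(n), n-1 denominator)."""
    x = np.asarray(sample, float)
    if len(x) == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return {
        "label": label,
        "n": len(x),
        "mean": mean,
        "sem": sem,
        "text": f"{mean:.4g} ± {sem:.4g}",
    }
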