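"""Group statistics: screening, ANOVA with Tukey-Kramer post hoc, Grubbs.

The battery applied to per-animal summary metrics:

* Shapiro-Wilk normality and pairwise two-sided variance-ratio (F)
  screening, reported alongside the ANOVA but never used to switch the
  model (no silent fallback to nonparametric tests);
* one-way or two-way ANOVA (with interaction by default for two factors),
  followed by the Tukey-Kramer post hoc test, which uses the studentized
  range distribution with the unequal-n adjustment;
* Grubbs' test for a single outlier per group (no iterative stripping).

One-way ANOVA uses scipy and two-way ANOVA statsmodels OLS (Type II sums
of squares). Tukey-Kramer, Grubbs and the two-sided variance F test are
implemented directly against scipy's distributions (the statsmodels
Tukey route re-inverts the studentized-range distribution numerically on
every call, far too slow for simulation-based calibration; it remains
the independent cross-check in the test suite).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "GrubbsResult",
    "GroupDesign",
    "StatsReport",
    "grubbs_test",
    "grubbs_critical",
    "variance_f_test",
    "tukey_kramer",
    "anova_with_posthoc",
]


@dataclass
class GrubbsResult:
    """Outcome of a two-sided single-outlier Grubbs test."""

    g: float
    critical: float
    flagged: bool
    index: int | None
    value: float | None
    n: int
    alpha: float


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value at significance ``alpha``.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided Grubbs test for a single outlier.

    G = max_i |x_i - mean| / s with the sample standard deviation
    (n-1 denominator); the most extreme value is flagged iff G exceeds the
    two-sided critical value. A zero-variance sample has no outlier by
    definition. NaNs are dropped first.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        raise ValueError(f"Grubbs test requires n >= 3 (got n={n})")
    s = x.std(ddof=1)
    crit = grubbs_critical(n, alpha)
    if s == 0:
        return GrubbsResult(0.0, crit, False, None, None, n, alpha)
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / s)
    flagged = g > crit
    return GrubbsResult(
        g=g,
        critical=float(crit),
        flagged=bool(flagged),
        index=i if flagged else None,
        value=float(x[i]) if flagged else None,
        n=n,
        alpha=alpha,
    )


def variance_f_test(x, y) -> tuple[float, float]:
    """Two-sided variance-ratio F test for homogeneity of two samples.

    Returns (F, p) with F = s_x^2 / s_y^2 on (n_x-1, n_y-1) degrees of
    freedom and a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("variance F test requires n >= 2 per group")
    f = x.var(ddof=1) / y.var(ddof=1)
    dfx, dfy = x.size - 1, y.size - 1
    p_one = sps.f.sf(f, dfx, dfy) if f >= 1 else sps.f.cdf(f, dfx, dfy)
    return float(f), float(min(1.0, 2.0 * p_one))


@dataclass
class GroupDesign:
    """A response column and 1-2 crossed factors in a tidy per-animal table.

    Each animal contributes one value per response stratum; group sizes may
    be unequal (hence Tukey-Kramer rather than plain Tukey). Rows with a
    missing response are dropped listwise (the a priori exclusion policy:
    animals lost before study end simply have no value).
    """

    data: pd.DataFrame
    response: str
    factors: list[str]

    def __post_init__(self) -> None:
        if not 1 <= len(self.factors) <= 2:
            raise ValueError("design requires 1 or 2 factors")
        missing = [c for c in [self.response, *self.factors] if c not in self.data.columns]
        if missing:
            raise ValueError(f"design columns absent from data: {missing}")
        d = self.data[[self.response, *self.factors]].copy()
        self.n_excluded = int(d[self.response].isna().sum())
        self.data = d.dropna(subset=[self.response]).reset_index(drop=True)

    def group_labels(self) -> pd.Series:
        if len(self.factors) == 1:
            return self.data[self.factors[0]].astype(str)
        return (
            self.data[self.factors[0]].astype(str)
            + ":"
            + self.data[self.factors[1]].astype(str)
        )

    def groups(self) -> dict[str, np.ndarray]:
        labels = self.group_labels()
        return {
            str(g): self.data.loc[labels == g, self.response].to_numpy(dtype=float)
            for g in labels.unique()
        }


@dataclass
class StatsReport:
    """Assembled output of the statistical battery."""

    anova: pd.DataFrame  # effect, F, df_num, df_den, p
    posthoc: pd.DataFrame  # group1, group2, meandiff, p_adj, significant
    shapiro: pd.DataFrame  # group, W, p, n
    variance_f: pd.DataFrame  # group1, group2, F, p
    outliers: pd.DataFrame  # group, flagged, value, g, critical
    alpha: float
    n_excluded: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "n_excluded": self.n_excluded,
                "anova": self.anova.to_dict(orient="records"),
                "posthoc": self.posthoc.to_dict(orient="records"),
                "shapiro": self.shapiro.to_dict(orient="records"),
                "variance_f": self.variance_f.to_dict(orient="records"),
                "outliers": self.outliers.to_dict(orient="records"),
            },
            default=lambda o: None if (isinstance(o, float) and np.isnan(o)) else str(o),
            indent=2,
        )


@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_kramer(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer all-pairs comparison with unequal group sizes.

    For each pair, q = |mean_i - mean_j| / sqrt(MSE/2 (1/n_i + 1/n_j))
    is referred to the studentized range distribution with k groups and
    N - k error degrees of freedom; the harmonic 1/n adjustment makes the
    procedure valid for unequal n. Confidence bounds use the upper-alpha
    critical value of the same distribution.
    """
    names = sorted(groups)
    vals = [np.asarray(groups[g], dtype=float) for g in names]
    k = len(vals)
    n_tot = sum(v.size for v in vals)
    df = n_tot - k
    if df <= 0:
        raise ValueError("no error degrees of freedom for Tukey-Kramer")
    mse = sum(((v - v.mean()) ** 2).sum() for v in vals) / df
    crit = _q_crit(alpha, k, df)
    rows = []
    for (g1, v1), (g2, v2) in itertools.combinations(zip(names, vals), 2):
        diff = v2.mean() - v1.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / v1.size + 1.0 / v2.size))
        if se > 0:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df))
        else:
            q, p = 0.0, 1.0
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "meandiff": diff,
                "p_adj": min(max(p, 0.0), 1.0),
                "lower": diff - crit * se,
                "upper": diff + crit * se,
            }
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_adj"] < alpha
    return out


def _one_way_anova(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    vals = list(groups.values())
    f, p = sps.f_oneway(*vals)
    k = len(vals)
    n = sum(len(v) for v in vals)
    return pd.DataFrame(
        [{"effect": "group", "F": float(f), "df_num": k - 1, "df_den": n - k, "p": float(p)}]
    )


def _two_way_anova(design: GroupDesign, interaction: bool) -> pd.DataFrame:
    f1, f2 = design.factors
    d = design.data.rename(columns={design.response: "_y", f1: "_f1", f2: "_f2"})
    cells = d.groupby(["_f1", "_f2"]).size()
    full = pd.MultiIndex.from_product([d["_f1"].unique(), d["_f2"].unique()])
    empty = [c for c in full if c not in cells.index]
    if empty:
        raise ValueError(
            f"empty cell(s) in two-way design: {[f'{f1}={a}, {f2}={b}' for a, b in empty]}"
        )
    op = "*" if interaction else "+"
    model = ols(f"_y ~ C(_f1) {op} C(_f2)", data=d).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    names = {
        "C(_f1)": f1,
        "C(_f2)": f2,
        "C(_f1):C(_f2)": f"{f1}:{f2}",
    }
    rows = []
    df_den = float(tab.loc["Residual", "df"])
    for key, label in names.items():
        if key in tab.index:
            rows.append(
                {
                    "effect": label,
                    "F": float(tab.loc[key, "F"]),
                    "df_num": float(tab.loc[key, "df"]),
                    "df_den": df_den,
                    "p": float(tab.loc[key, "PR(>F)"]),
                }
            )
    return pd.DataFrame(rows)


def anova_with_posthoc(
    design: GroupDesign, alpha: float = 0.05, interaction: bool = True
) -> StatsReport:
    """Run the full battery on a group design.

    One factor -> one-way ANOVA; two factors -> two-way ANOVA (Type II,
    with interaction unless disabled). The Tukey-Kramer post hoc compares
    all factor-level (or cell) pairs using the studentized range
    distribution; screening tests and per-group Grubbs results are
    reported but never gate the analysis.
    """
    groups = design.groups()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    if len(design.factors) == 1:
        anova = _one_way_anova(groups)
    else:
        anova = _two_way_anova(design, interaction)

    posthoc = tukey_kramer(groups, alpha=alpha)

    shapiro_rows = []
    for g, v in sorted(groups.items()):
        if v.size >= 3 and np.ptp(v) > 0:
            w, p = sps.shapiro(v)
        else:
            w, p = np.nan, np.nan
        shapiro_rows.append({"group": g, "W": w, "p": p, "n": v.size})

    var_rows = []
    for (g1, v1), (g2, v2) in itertools.combinations(sorted(groups.items()), 2):
        if v1.var(ddof=1) > 0 or v2.var(ddof=1) > 0:
            f, p = variance_f_test(v1, v2)
        else:
            f, p = np.nan, np.nan
        var_rows.append({"group1": g1, "group2": g2, "F": f, "p": p})

    out_rows = []
    for g, v in sorted(groups.items()):
        if v.size >= 3:
            res = grubbs_test(v, alpha)
            out_rows.append(
                {
                    "group": g,
                    "flagged": res.flagged,
                    "value": res.value,
                    "g": res.g,
                    "critical": res.critical,
                }
            )
        else:
            out_rows.append(
                {"group": g, "flagged": False, "value": None, "g": np.nan, "critical": np.nan}
            )

    return StatsReport(
        anova=anova,
        posthoc=posthoc,
        shapiro=pd.DataFrame(shapiro_rows),
        variance_f=pd.DataFrame(var_rows),
        outliers=pd.DataFrame(out_rows),
        alpha=alpha,
        n_excluded=design.n_excluded,
    )
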