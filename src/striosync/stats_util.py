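"""Thin, explicitly-contracted wrappers for the standard group comparisons.

Omnibus ANOVA gating nonparametric post-hocs: pairs are only tested when
the omnibus test is significant, and no further multiple-testing correction
is applied beyond that gate.  All tests are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestReport:
    test: str
    statistic: float
    p: float
    n: tuple
    direction: str = ""  # e.g. "late > early"

    def as_row(self) -> dict:
        return {"test": self.test, "statistic": self.statistic, "p": self.p,
                "n": "/".join(str(v) for v in self.n),
                "direction": self.direction}


def _direction(name_a, a, name_b, b) -> str:
    ma, mb = float(np.median(a)), float(np.median(b))
    if ma == mb:
        return f"{name_a} = {name_b}"
    return f"{name_a} > {name_b}" if ma > mb else f"{name_b} > {name_a}"


def _pairs(names):
    return [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]


def stage_comparison(groups: dict, design: str = "one_way",
                     alpha: float = 0.05) -> list[TestReport]:
    """Omnibus ANOVA followed by gated Wilcoxon post-hocs.

    ``groups`` maps group name -> 1-D samples.  Designs:

    * ``one_way``: independent groups; post-hoc rank-sum tests.
    * ``paired``: repeated measures on the same subjects (equal lengths);
      omnibus is a one-way repeated-measures F; post-hoc signed-rank tests.

    Two-way designs are fitted on a long-format frame via
    :func:`two_way_anova` (type-II sums of squares).
    """
    names = list(groups)
    samples = [np.asarray(groups[name], float) for name in names]
    if len(names) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    sizes = tuple(s.size for s in samples)
    reports = []
    if design == "one_way":
        f, p = stats.f_oneway(*samples)
        reports.append(TestReport("one-way ANOVA", float(f), float(p), sizes))
        post = "rank-sum"
    elif design == "paired":
        if len(set(sizes)) != 1:
            raise ValueError("paired design requires equal group sizes")
        X = np.column_stack(samples)  # subjects x conditions
        n, k = X.shape
        grand = X.mean()
        ss_cond = n * np.sum((X.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((X - grand) ** 2)
        ss_err = ss_tot - ss_cond - ss_subj
        df_cond, df_err = k - 1, (n - 1) * (k - 1)
        f = (ss_cond / df_cond) / (ss_err / df_err) if ss_err > 0 else np.inf
        p = float(stats.f.sf(f, df_cond, df_err))
        reports.append(TestReport("repeated-measures ANOVA", float(f), p,
                                  sizes))
        post = "signed-rank"
    else:
        raise ValueError(f"unknown design '{design}'")
    if reports[0].p < alpha:
        for name_a, name_b in _pairs(names):
            a = np.asarray(groups[name_a], float)
            b = np.asarray(groups[name_b], float)
            if post == "rank-sum":
                stat, pv = stats.ranksums(a, b)
                label = f"Wilcoxon rank-sum {name_a} vs {name_b}"
            else:
                stat, pv = stats.wilcoxon(a, b)
                label = f"Wilcoxon signed-rank {name_a} vs {name_b}"
            reports.append(TestReport(label, float(stat), float(pv),
                                      (a.size, b.size),
                                      _direction(name_a, a, name_b, b)))
    return reports


def two_way_anova(frame: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> list[TestReport]:
    """Two-way ANOVA, type-II sums of squares (robust to mild imbalance).

    Main effects and interaction on a long-format table, via statsmodels.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = frame[[value, factor_a, factor_b]].rename(
        columns={value: "y", factor_a: "fa", factor_b: "fb"}
    )
    model = smf.ols("y ~ C(fa) * C(fb)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    label = {"C(fa)": f"{factor_a} (type II)",
             "C(fb)": f"{factor_b} (type II)",
             "C(fa):C(fb)": f"{factor_a} x {factor_b}"}
    return [
        TestReport(label[row], float(table.loc[row, "F"]),
                   float(table.loc[row, "PR(>F)"]), (len(frame),))
        for row in label
    ]
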