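"""Statistical comparison of design factors.

An n-way main-effects linear model explains the per-session TP-FP score
from categorical factors (patient, electrode set, band, spatial filter,
classifier); factor influence is tested with an ANOVA on that model
(type-II sums of squares — identical to type I/III on balanced grids).
Pairwise level comparisons use Wilcoxon's rank-sum test with Bonferroni
correction.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf


def anova_factors(results: pd.DataFrame, factors: list[str],
                  response: str = "score") -> pd.DataFrame:
    """Main-effects n-way ANOVA of ``response`` on categorical ``factors``.

    Returns one row per factor with sum of squares, degrees of freedom,
    F statistic and p-value.
    """
    if not factors:
        raise ValueError("at least one factor required")
    df = results.copy()
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor {f!r} not in results table")
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
        df[f] = df[f].astype(str)
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = table.rename(
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"}
    ).reset_index(names="factor")
    out["factor"] = (out["factor"].str.replace(r"^C\((.*)\)$", r"\1", regex=True))
    return out


def pairwise_wilcoxon(results: pd.DataFrame, factor: str,
                      response: str = "score") -> pd.DataFrame:
    """Wilcoxon rank-sum test for every level pair, Bonferroni-adjusted.

    The adjusted p-value is ``min(1, p * n_pairs)``.
    """
    if factor not in results.columns:
        raise ValueError(f"factor {factor!r} not in results table")
    levels = sorted(results[factor].dropna().unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        xa = results.loc[results[factor] == a, response].to_numpy(float)
        xb = results.loc[results[factor] == b, response].to_numpy(float)
        if min(xa.size, xb.size) < 2:
            raise ValueError(f"level {a if xa.size < 2 else b!r} has < 2 observations")
        stat, p = sstats.ranksums(xa, xb)
        rows.append({
            "level_a": a, "level_b": b,
            "mean_a": xa.mean(), "mean_b": xb.mean(),
            "statistic": float(stat), "p_raw": float(p),
            "p_adj": float(min(1.0, p * len(pairs))),
        })
    return pd.DataFrame(rows)


def factor_report(results: pd.DataFrame, factors: list[str],
                  response: str = "score") -> dict:
    """ANOVA plus per-factor pairwise comparisons, as a JSON-friendly dict."""
    anova = anova_factors(results, factors, response)
    report = {
        "anova": anova.to_dict(orient="records"),
        "pairwise": {},
        "n_observations": int(len(results)),
    }
    for f in factors:
        if results[f].nunique() >= 2:
            report["pairwise"][f] = pairwise_wilcoxon(
                results, f, response).to_dict(orient="records")
    return report
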