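"""Group-level inferential statistics for DNAmAGE and phenotype readouts.

Two-way ANOVA with interaction (Type-I sums of squares for balanced
designs, Type-II otherwise), Tukey HSD post hoc comparisons, Welch and
pooled unpaired t-tests, and Pearson correlation. Thin, validated
wrappers over statsmodels/scipy with the conventions fixed (limbs are
treated as independent observations, matching the study design's
original analysis of the contralateral-limb comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

log = logging.getLogger("methregen.studystats")

__all__ = ["two_way_anova", "tukey_hsd", "unpaired_t", "pearson_correlation", "AnovaTable"]


@dataclass
class AnovaTable:
    """Two-way ANOVA effects table; ``ss_type`` records the SS convention."""

    table: pd.DataFrame  # index: factor_a, factor_b, interaction, residual
    ss_type: int

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def summary(self) -> str:
        lines = [f"Two-way ANOVA (Type-{'I' if self.ss_type == 1 else 'II'} SS)"]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.6g}"))
        return "\n".join(lines)


def two_way_anova(values, factor_a, factor_b, names: tuple[str, str] = ("a", "b")) -> AnovaTable:
    """Two-way factorial ANOVA with interaction.

    Balanced designs use Type-I SS (orderings coincide); unbalanced ones
    Type-II. Requires >=2 levels per factor and no empty cells.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "fa": pd.Categorical(factor_a),
            "fb": pd.Categorical(factor_b),
        }
    )
    if df["fa"].nunique() < 2 or df["fb"].nunique() < 2:
        raise ValidationError("each factor needs >=2 levels")
    cells = df.groupby(["fa", "fb"], observed=False).size()
    empty = cells[cells == 0]
    if len(empty):
        raise ValidationError(f"empty design cell(s): {list(empty.index)}")
    balanced = cells.nunique() == 1
    ss_type = 1 if balanced else 2

    name_a, name_b = names
    if np.ptp(df["y"].to_numpy()) == 0.0:
        # zero total variance: every F is 0/0; report no-effect outcome
        idx = [name_a, name_b, "interaction", "residual"]
        tab = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "df": [
                    df["fa"].nunique() - 1,
                    df["fb"].nunique() - 1,
                    (df["fa"].nunique() - 1) * (df["fb"].nunique() - 1),
                    len(df) - df["fa"].nunique() * df["fb"].nunique(),
                ],
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=idx,
        )
        return AnovaTable(table=tab, ss_type=ss_type)

    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    raw = sm.stats.anova_lm(model, typ=ss_type)
    rename = {
        "C(fa)": name_a,
        "C(fb)": name_b,
        "C(fa):C(fb)": "interaction",
        "Residual": "residual",
    }
    raw = raw.rename(index=rename)
    tab = pd.DataFrame(
        {
            "sum_sq": raw["sum_sq"],
            "df": raw["df"],
            "F": raw.get("F"),
            "p": raw.get("PR(>F)"),
        }
    )
    return AnovaTable(table=tab.loc[[name_a, name_b, "interaction", "residual"]], ss_type=ss_type)


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized range, pooled MS_residual)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise ValidationError("need >=2 groups")
    small = sizes[sizes < 2]
    if len(small):
        raise ValidationError(f"group(s) with n < 2: {list(small.index)}")
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    uniq = list(res.groupsunique)
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    return pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "mean_diff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "lower": res.confint[:, 0].astype(float),
            "upper": res.confint[:, 1].astype(float),
            "significant": np.asarray(res.reject, dtype=bool),
        }
    )


def unpaired_t(values_a, values_b, pooled: bool = False) -> dict:
    """Two-tailed unpaired t-test (Welch df by default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need n >= 2 per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        log.warning("zero variance in both groups with equal means; p = 1")
        df = a.size + b.size - 2 if pooled else a.size + b.size - 2
        return {"t": 0.0, "df": float(df), "p": 1.0}
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def pearson_correlation(x, y) -> dict:
    """Sample Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": int(x.size)}
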