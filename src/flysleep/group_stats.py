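"""Group-comparison decision procedures for per-fly summary metrics.

The decision chain mirrors common practice in the fly-sleep literature:
D'Agostino-Pearson normality on each group; non-normal data go to
Mann-Whitney; normal data with unequal variances (Brown-Forsythe gate) go
to Welch's t; otherwise Student's t.  Two-factor designs are tested with a
two-way ANOVA for the interaction followed by a selectable post-hoc family
(Sidak for planned pairs, Tukey for all pairs, Dunnett against a control).
A thermogenetic screen calls a line a hit only when its experimental group
differs from BOTH of its controls at alpha with the same direction of
effect.

The ANOVA / post-hoc numerics delegate to statsmodels and scipy; this
module owns the selector logic and the report schema.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupData",
    "TestDecision",
    "choose_two_group_test",
    "compare_two_groups",
    "interaction_anova",
    "screen_hits",
    "write_report_json",
]

NORMALITY_MIN_N = 8


@dataclass
class GroupData:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("each group needs >= 2 values")


@dataclass(frozen=True)
class TestDecision:
    chosen_test: str  # t | welch_t | mann_whitney
    normality_p: tuple[float | None, float | None]
    variance_p: float | None
    alpha: float


def choose_two_group_test(
    a: GroupData, b: GroupData, alpha: float = 0.05, min_n: int = NORMALITY_MIN_N
) -> TestDecision:
    """Pick t / Welch t / Mann-Whitney by the normality-then-variance gates.

    Groups below ``min_n`` (the validity floor of the normality test) fall
    through to Mann-Whitney with a warning.
    """
    if min(len(a.values), len(b.values)) < min_n:
        warnings.warn(
            f"group below n={min_n}: normality untestable, using Mann-Whitney"
        )
        return TestDecision("mann_whitney", (None, None), None, alpha)
    p_a = float(stats.normaltest(a.values).pvalue)
    p_b = float(stats.normaltest(b.values).pvalue)
    if p_a < alpha or p_b < alpha:
        return TestDecision("mann_whitney", (p_a, p_b), None, alpha)
    # Brown-Forsythe: Levene's test on deviations from the median
    p_var = float(stats.levene(a.values, b.values, center="median").pvalue)
    chosen = "welch_t" if p_var < alpha else "t"
    return TestDecision(chosen, (p_a, p_b), p_var, alpha)


def compare_two_groups(
    a: GroupData, b: GroupData, alpha: float = 0.05
) -> dict:
    """Run the decision chain and the selected test; JSON-ready report."""
    decision = choose_two_group_test(a, b, alpha)
    if decision.chosen_test == "mann_whitney":
        res = stats.mannwhitneyu(a.values, b.values, alternative="two-sided")
        effect = float(np.median(a.values) - np.median(b.values))
        ci = None
        df = None
    else:
        equal_var = decision.chosen_test == "t"
        res = stats.ttest_ind(a.values, b.values, equal_var=equal_var)
        effect = float(a.values.mean() - b.values.mean())
        df = float(res.df)
        lo, hi = res.confidence_interval(1 - alpha)
        ci = (float(lo), float(hi))
    return {
        "groups": [a.label, b.label],
        "test": decision.chosen_test,
        "statistic": float(res.statistic),
        "df": df,
        "p": float(res.pvalue),
        "effect": effect,
        "ci": ci,
        "normality_p": decision.normality_p,
        "variance_p": decision.variance_p,
        "alpha": alpha,
    }


def interaction_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
    posthoc: str = "tukey",
    control_cell: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Two-way ANOVA interaction p plus a post-hoc contrast family.

    ``posthoc``: ``"sidak"`` compares factor-A levels within each level of
    factor B (planned pairs, Sidak-adjusted Welch t); ``"tukey"`` compares
    all cells (Tukey HSD); ``"dunnett"`` compares every cell against
    ``control_cell``.  Returns (interaction p, contrasts table).
    """
    df = data.rename(
        columns={value: "y", factor_a: "A", factor_b: "B"}
    )[["y", "A", "B"]].copy()
    counts = df.groupby(["A", "B"], observed=True).size()
    levels_a = df["A"].unique()
    levels_b = df["B"].unique()
    if len(counts) < len(levels_a) * len(levels_b) or (counts < 2).any():
        raise ValueError("every factor cell needs >= 2 observations")

    model = ols("y ~ C(A) * C(B)", data=df).fit()
    table = anova_lm(model, typ=2)
    p_interaction = float(table.loc["C(A):C(B)", "PR(>F)"])

    cell = df["A"].astype(str) + "/" + df["B"].astype(str)
    if posthoc == "tukey":
        res = pairwise_tukeyhsd(df["y"].to_numpy(), cell.to_numpy(), alpha=alpha)
        contrasts = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        ).rename(columns={"p-adj": "p_adj"})
    elif posthoc == "sidak":
        rows = []
        m = len(levels_b) * (len(levels_a) * (len(levels_a) - 1) // 2)
        for lb in levels_b:
            sub = df[df["B"] == lb]
            for i, a1 in enumerate(levels_a):
                for a2 in levels_a[i + 1 :]:
                    x = sub.loc[sub["A"] == a1, "y"].to_numpy()
                    z = sub.loc[sub["A"] == a2, "y"].to_numpy()
                    t = stats.ttest_ind(x, z, equal_var=False)
                    rows.append(
                        {
                            "group1": f"{a1}/{lb}",
                            "group2": f"{a2}/{lb}",
                            "meandiff": float(x.mean() - z.mean()),
                            "p_raw": float(t.pvalue),
                            "p_adj": float(1 - (1 - t.pvalue) ** m),
                        }
                    )
        contrasts = pd.DataFrame(rows)
    elif posthoc == "dunnett":
        if control_cell is None:
            raise ValueError("dunnett post-hoc needs control_cell")
        ctrl_key = f"{control_cell[0]}/{control_cell[1]}"
        groups = {k: g["y"].to_numpy() for k, g in df.groupby(cell)}
        if ctrl_key not in groups:
            raise ValueError(f"control cell {ctrl_key} absent")
        others = [k for k in groups if k != ctrl_key]
        res = stats.dunnett(*(groups[k] for k in others), control=groups[ctrl_key])
        contrasts = pd.DataFrame(
            {
                "group1": others,
                "group2": ctrl_key,
                "meandiff": [
                    float(groups[k].mean() - groups[ctrl_key].mean()) for k in others
                ],
                "p_adj": res.pvalue,
            }
        )
    else:
        raise ValueError(f"unknown posthoc family {posthoc!r}")
    return p_interaction, contrasts


def screen_hits(
    lines: Mapping[str, Mapping[str, Sequence[float]]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dual-control hit calling for a thermogenetic screen.

    ``lines`` maps line name -> {"experimental": values,
    "gal4_control": values, "uas_control": values} (the UAS control is
    typically shared across lines).  A line is a hit iff the experimental
    group differs from BOTH controls (Welch's t, p < alpha) with the same
    sign of effect.  Lines missing a control are skipped with a warning.
    Reported ``delta_vs_uas`` is the experimental minus UAS-control mean —
    the quantity a screen summary plot shows.
    """
    rows = []
    for name, groups in lines.items():
        missing = {"experimental", "gal4_control", "uas_control"} - set(groups)
        if missing:
            warnings.warn(f"line {name}: missing {sorted(missing)}; skipped")
            continue
        exp = np.asarray(groups["experimental"], dtype=float)
        gal4 = np.asarray(groups["gal4_control"], dtype=float)
        uas = np.asarray(groups["uas_control"], dtype=float)
        t_gal4 = stats.ttest_ind(exp, gal4, equal_var=False)
        t_uas = stats.ttest_ind(exp, uas, equal_var=False)
        d_gal4 = exp.mean() - gal4.mean()
        d_uas = exp.mean() - uas.mean()
        hit = (
            t_gal4.pvalue < alpha
            and t_uas.pvalue < alpha
            and np.sign(d_gal4) == np.sign(d_uas)
            and d_uas != 0
        )
        rows.append(
            {
                "line": name,
                "delta_vs_uas": float(d_uas),
                "delta_vs_gal4": float(d_gal4),
                "p_vs_uas": float(t_uas.pvalue),
                "p_vs_gal4": float(t_gal4.pvalue),
                "hit": bool(hit),
            }
        )
    return pd.DataFrame(rows)


def write_report_json(report: dict | list, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
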