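"""Univariate testing and the three-criterion discriminating-variable call.

Each variable is tested case vs control with a pooled-variance two-sample
Student t test (Welch available behind a flag), corrected across variables by
Benjamini–Hochberg.  A variable is called a discriminator when all three
criteria hold: (1) BH-adjusted p below α, (2) |p(corr)| above 0.6 on the
fitted OPLS-DA model, (3) VIP above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SelectionCriteria",
    "ttest_raw",
    "ttest_summary",
    "bh_adjust",
    "percent_change",
    "univariate_table",
    "select_discriminators",
]


@dataclass(frozen=True)
class SelectionCriteria:
    alpha_adj: float = 0.05
    pcorr_min: float = 0.6
    vip_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha_adj", "pcorr_min", "vip_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def ttest_raw(x_case: np.ndarray, x_control: np.ndarray, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t test; returns (t, df, two-sided p)."""
    x1 = np.asarray(x_case, dtype=float)
    x2 = np.asarray(x_control, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch and x1.var(ddof=1) + x2.var(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x1, x2, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ttest_summary(
    mean_case: float, sd_case: float, n_case: int,
    mean_control: float, sd_control: float, n_control: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Same test computed from group summary statistics (means, SDs, n)."""
    if sd_case <= 0 and sd_control <= 0:
        raise ValueError("zero pooled variance")
    if n_case < 2 or n_control < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind_from_stats(
        mean_case, sd_case, n_case, mean_control, sd_control, n_control,
        equal_var=not welch,
    )
    df = n_case + n_control - 2 if not welch else float(res.df) if hasattr(res, "df") else np.nan
    if welch:
        num = (sd_case**2 / n_case + sd_control**2 / n_control) ** 2
        den = (sd_case**2 / n_case) ** 2 / (n_case - 1) + (sd_control**2 / n_control) ** 2 / (n_control - 1)
        df = num / den
    return float(res.statistic), float(df), float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent_change(mean_case: float, mean_control: float, ndigits: int | None = 1) -> float:
    """Signed %-change of the case mean relative to the control mean."""
    if mean_control == 0:
        raise ValueError("control mean is zero; percent change undefined")
    pct = 100.0 * (mean_case - mean_control) / mean_control
    return round(pct, ndigits) if ndigits is not None else pct


def _direction(pct: float) -> str:
    if pct > 0:
        return "↑"
    if pct < 0:
        return "↓"
    return "="


def univariate_table(
    values: pd.DataFrame,
    groups: pd.Series,
    case_label: str,
    control_label: str,
    var_ids=None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-variable t tests with BH correction across all variables.

    ``values`` holds raw (unscaled) integrals, samples × variables; the
    returned frame mirrors a published univariate summary table: group
    means ± SDs, t, df, raw and adjusted p, %-change, direction.
    """
    case = values.loc[groups == case_label]
    ctrl = values.loc[groups == control_label]
    if case.empty or ctrl.empty:
        raise ValueError(f"groups {case_label!r}/{control_label!r} not both present")
    if var_ids is None:
        var_ids = [int(c.split("_", 1)[1]) for c in values.columns]
    rows = []
    for j, col in enumerate(values.columns):
        t, df, p = ttest_raw(case[col], ctrl[col], welch=welch)
        mc, mk = case[col].mean(), ctrl[col].mean()
        rows.append(
            {
                "var_id": var_ids[j],
                "mean_case": mc,
                "sd_case": case[col].std(ddof=1),
                "mean_control": mk,
                "sd_control": ctrl[col].std(ddof=1),
                "t_stat": t,
                "df": df,
                "p_raw": p,
                "pct_change": percent_change(mc, mk),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["direction"] = out["pct_change"].map(_direction)
    return out


def select_discriminators(
    univar: pd.DataFrame,
    sline_vip: pd.DataFrame,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> pd.DataFrame:
    """Apply the three-criterion verdict per variable.

    ``univar`` needs columns var_id and p_adj; ``sline_vip`` needs var_id,
    p_corr and vip.  Inputs must cover identical var_id sets.
    """
    u_ids = set(univar["var_id"])
    s_ids = set(sline_vip["var_id"])
    if u_ids != s_ids:
        raise ValueError(
            f"misaligned inputs: var_ids differ ({sorted(u_ids ^ s_ids)})"
        )
    merged = univar.merge(sline_vip, on="var_id", how="inner").sort_values("var_id")
    merged["selected"] = (
        (merged["p_adj"] < criteria.alpha_adj)
        & (merged["p_corr"].abs() > criteria.pcorr_min)
        & (merged["vip"] > criteria.vip_min)
    )
    return merged.reset_index(drop=True)
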