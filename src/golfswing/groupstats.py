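"""Group-level statistics on the discrete swing parameters.

Inference unit is the per-player mean over trials: the study's printed
correlation p-values are exactly recovered from the printed r values with
n = 6 boys / 8 girls, which identifies player means (not trials) as the
observation unit. Tests: Shapiro-Wilk normality screen (reported, never
used to switch methods), one-way ANOVA with partial eta squared, and
Pearson correlation with exact two-tailed significance from the t
transform r * sqrt(n - 2) / sqrt(1 - r^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PARAMETER_COLUMNS = ("tmax_deg", "pmax_deg", "xfac_deg", "sxfac_deg", "gcv_mps")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    eta_p2: float
    df1: int
    df2: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def player_means(parameters: pd.DataFrame) -> pd.DataFrame:
    """Per-player mean of each parameter over that player's trials.

    ``parameters`` needs a ``participant_id`` column plus the five parameter
    columns (the per-trial table written by the pipeline).
    """
    if parameters.empty:
        raise ValueError("no trials to average")
    cols = [c for c in PARAMETER_COLUMNS if c in parameters.columns]
    if not cols:
        raise ValueError("no parameter columns found")
    return parameters.groupby("participant_id", as_index=False)[cols].mean()


def oneway_anova(values, groups) -> AnovaResult:
    """One-way ANOVA with partial eta squared.

    eta_p2 = SSb / (SSb + SSw), which for the one-way design equals
    F * df1 / (F * df1 + df2) exactly.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two values")
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0 and ssb == 0:
        raise ValueError("zero variance everywhere: F undefined")
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    F, p = stats.f_oneway(*samples)
    return AnovaResult(
        F=float(F),
        p=float(p),
        eta_p2=float(ssb / (ssb + ssw)),
        df1=int(df1),
        df2=int(df2),
    )


def pearson_test(x, y) -> CorrelationResult:
    """Pearson r with exact two-tailed p on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    p = 0.0 if abs(r) >= 1.0 else float(res.pvalue)
    return CorrelationResult(r=r, p=p, n=len(x))


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed significance of a printed correlation coefficient.

    Uses t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees of freedom;
    this is how a reported r/n pair is converted back into its p-value.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def normality_screen(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Shapiro-Wilk W and p per group; reported, never acted on."""
    rows = []
    for group, values in values_by_group.items():
        values = np.asarray(values, dtype=float)
        if not 3 <= len(values) <= 50:
            raise ValueError(
                f"group {group!r}: Shapiro-Wilk needs 3 <= n <= 50, got {len(values)}"
            )
        W, p = stats.shapiro(values)
        rows.append({"group": group, "n": len(values), "W": float(W), "p": float(p)})
    return pd.DataFrame(rows)


def descriptives(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Group mean and sample SD (n - 1); singleton groups get SD = NaN."""
    rows = []
    for group, values in values_by_group.items():
        values = np.asarray(values, dtype=float)
        if len(values) == 0:
            raise ValueError(f"group {group!r} is empty")
        rows.append({
            "group": group,
            "n": len(values),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
        })
    return pd.DataFrame(rows)


def cohort_statistics(means: pd.DataFrame, sex_by_player: dict[str, str]) -> dict:
    """Descriptives, normality, ANOVA and per-sex GCV correlations.

    ``means`` is the per-player mean table from :func:`player_means`.
    Returns a JSON-serializable dict with a descriptive block (group mean
    and SD per parameter), a sex-effect ANOVA per parameter, and a per-sex
    correlation block of each movement parameter against club velocity.
    """
    sexes = np.array([sex_by_player[p] for p in means["participant_id"]])
    out: dict = {"descriptives": {}, "normality": {}, "anova": {},
                 "correlations": {}}
    for col in PARAMETER_COLUMNS:
        if col not in means.columns:
            continue
        by_group = {s: means.loc[sexes == s, col].to_numpy()
                    for s in ("F", "M") if (sexes == s).any()}
        out["descriptives"][col] = descriptives(by_group).to_dict("records")
        try:
            out["normality"][col] = normality_screen(by_group).to_dict("records")
        except ValueError as exc:
            out["normality"][col] = {"error": str(exc)}
        res = oneway_anova(means[col].to_numpy(), sexes)
        out["anova"][col] = {"F": res.F, "p": res.p, "eta_p2": res.eta_p2,
                             "df1": res.df1, "df2": res.df2}
    movement = [c for c in PARAMETER_COLUMNS if c != "gcv_mps"]
    for sex in ("F", "M"):
        mask = sexes == sex
        if mask.sum() < 3:
            continue
        block = {}
        for col in movement:
            res = pearson_test(means.loc[mask, col], means.loc[mask, "gcv_mps"])
            block[col] = {"r": res.r, "p": res.p, "n": res.n}
        out["correlations"][sex] = block
    return out
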