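"""Two-sample statistical parametric mapping (SPM) on 1-D curves.

A pointwise two-sample t field over Q nodes is compared against a single
familywise critical threshold derived from random field theory (RFT): the
threshold u solves

    E[EC(u)] = P(T_df > u) + R * sqrt(4 ln 2) / (2 pi)
                              * (1 + u^2 / df)^(-(df - 1) / 2) = alpha,

the 1-D Euler-characteristic expectation of a t field with R = (Q-1)/fwhm
resels, where the residual smoothness fwhm is estimated from the pointwise-
normalized residual gradients. Two-sided inference on |t| uses alpha/2 per
tail. A seeded permutation threshold (max-|t| distribution over group-label
reassignments) is provided as a nonparametric cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, log

import numpy as np
from scipy import optimize, stats


@dataclass
class SPMResult:
    """Result of a two-sample SPM t test on 1-D curves."""

    t_trajectory: np.ndarray
    df: int
    fwhm: float
    threshold: float
    alpha: float
    clusters: list[tuple[int, int]]
    n1: int
    n2: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "t_trajectory": [float(v) for v in self.t_trajectory],
            "df": int(self.df),
            "fwhm": float(self.fwhm),
            "threshold": float(self.threshold),
            "alpha": float(self.alpha),
            "clusters": [[int(a), int(b)] for a, b in self.clusters],
            "n1": int(self.n1),
            "n2": int(self.n2),
            "metadata": self.metadata,
        }


def _as_groups(group_a, group_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share curve length Q")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 curves")
    return a, b


def t_field(group_a, group_b) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise pooled-variance two-sample t statistic at every node.

    Returns ``(t, residuals)`` where residuals are each curve minus its
    group mean, stacked with group A first. Supports unbalanced groups.
    """
    a, b = _as_groups(group_a, group_b)
    n1, n2 = a.shape[0], b.shape[0]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ss_a = ((a - mean_a) ** 2).sum(axis=0)
    ss_b = ((b - mean_b) ** 2).sum(axis=0)
    df = n1 + n2 - 2
    pooled = (ss_a + ss_b) / df
    if np.any(pooled <= 0):
        node = int(np.argmax(pooled <= 0))
        raise ValueError(f"zero pooled variance at node {node}")
    t = (mean_a - mean_b) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    residuals = np.vstack([a - mean_a, b - mean_b])
    return t, residuals


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Residual smoothness (FWHM, in nodes) from normalized gradients.

    Residual curves are normalized pointwise by the pooled SD; with v the
    mean squared gradient of the normalized residuals at unit node spacing,
    fwhm = sqrt(4 ln 2 / v), clamped to [1, Q].
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    if r.shape[0] < 2 or r.shape[1] < 3:
        raise ValueError("need >= 2 residual curves of length >= 3")
    sd = np.sqrt((r ** 2).mean(axis=0))
    if np.all(sd == 0):
        raise ValueError("all-zero residuals: smoothness undefined")
    sd = np.where(sd == 0, 1.0, sd)
    normalized = r / sd
    grad = np.diff(normalized, axis=1)
    v = float((grad ** 2).mean())
    if v <= 0:
        raise ValueError("degenerate residual gradients")
    fwhm = np.sqrt(4.0 * log(2.0) / v)
    return float(np.clip(fwhm, 1.0, r.shape[1]))


def expected_ec(u: float, df: int, resels: float) -> float:
    """1-D Euler-characteristic expectation of a t field above u."""
    tail = stats.t.sf(u, df)
    density = (np.sqrt(4.0 * log(2.0)) / (2.0 * np.pi)
               * (1.0 + u ** 2 / df) ** (-(df - 1) / 2.0))
    return float(tail + resels * density)


def rft_threshold(df: int, fwhm: float, Q: int, alpha: float) -> float:
    """Critical t* solving E[EC(u)] = alpha for a one-sided t field.

    In the smooth limit (fwhm -> inf, resels -> 0) this converges to the
    uncorrected one-sided t quantile; two-sided use passes alpha/2.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    resels = (Q - 1) / fwhm
    f = lambda u: expected_ec(u, df, resels) - alpha
    lo, hi = 1e-6, 100.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("no RFT threshold in (0, 100) for these inputs")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of |t| > threshold as inclusive (start, end) node pairs."""
    above = np.abs(t) > threshold
    clusters = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start, i - 1))
            start = None
    if start is not None:
        clusters.append((start, len(t) - 1))
    return clusters


def spm_ttest2(
    group_a,
    group_b,
    alpha: float = 0.05,
    balance_seed: int | None = None,
    *,
    two_sided: bool = True,
) -> SPMResult:
    """Two-sample SPM: t field, RFT threshold, suprathreshold clusters.

    When ``balance_seed`` is given and the groups are unbalanced, the larger
    group is randomly subsampled (seeded) to the smaller size before
    testing — the balanced-design option some SPM implementations require.
    """
    a, b = _as_groups(group_a, group_b)
    balanced = False
    if balance_seed is not None and a.shape[0] != b.shape[0]:
        rng = np.random.default_rng(balance_seed)
        n = min(a.shape[0], b.shape[0])
        if a.shape[0] > n:
            a = a[np.sort(rng.choice(a.shape[0], size=n, replace=False))]
        else:
            b = b[np.sort(rng.choice(b.shape[0], size=n, replace=False))]
        balanced = True
    t, residuals = t_field(a, b)
    df = a.shape[0] + b.shape[0] - 2
    fwhm = estimate_fwhm(residuals)
    level = alpha / 2 if two_sided else alpha
    threshold = rft_threshold(df, fwhm, len(t), level)
    return SPMResult(
        t_trajectory=t,
        df=df,
        fwhm=fwhm,
        threshold=threshold,
        alpha=alpha,
        clusters=_clusters(t, threshold),
        n1=a.shape[0],
        n2=b.shape[0],
        metadata={
            "sidedness": "two-sided" if two_sided else "one-sided",
            "balance_seed": balance_seed,
            "balanced_subsample": balanced,
        },
    )


def permutation_threshold(
    group_a,
    group_b,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | None = None,
) -> float:
    """Nonparametric familywise threshold from the max-|t| permutation law.

    All group-label reassignments are enumerated when there are at most
    ``n_perm`` of them; otherwise ``n_perm`` seeded random reassignments are
    drawn. Returns the (1 - alpha) quantile of the max-over-nodes |t|.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a, b = _as_groups(group_a, group_b)
    n1, n2 = a.shape[0], b.shape[0]
    n = n1 + n2
    if comb(n, n1) < 1.0 / alpha:
        raise ValueError(
            f"only {comb(n, n1)} distinct permutations; need >= {1.0 / alpha:.0f}"
        )
    X = np.vstack([a, b])
    if comb(n, n1) <= n_perm:
        labelings = np.array([
            [1 if i in idx else 0 for i in range(n)]
            for idx in (set(c) for c in combinations(range(n), n1))
        ], dtype=float)
    else:
        rng = np.random.default_rng(seed)
        labelings = np.zeros((n_perm, n))
        for row in labelings:
            row[rng.choice(n, size=n1, replace=False)] = 1.0
    L = labelings
    M = 1.0 - L
    df = n - 2
    mean_a = (L @ X) / n1
    mean_b = (M @ X) / n2
    sq = X ** 2
    ss = (L @ sq - n1 * mean_a ** 2) + (M @ sq - n2 * mean_b ** 2)
    pooled = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    max_abs_t = np.nanmax(np.abs(t), axis=1)
    return float(np.quantile(max_abs_t, 1.0 - alpha))
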