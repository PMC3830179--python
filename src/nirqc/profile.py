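"""Accuracy profiles: per-level bias, intermediate-precision variance
components and β-expectation tolerance intervals against fixed acceptance
limits.

The validation design is balanced: at each concentration level, p independent
series (day/operator) each contribute n replicate determinations.  Relative
recovery errors e = 100·(recovered − level)/level are decomposed by a one-way
random-effects ANOVA (method of moments) into within-series variance s_W² and
between-series variance s_B²; intermediate precision is s_IP² = s_W² + s_B².
The β-expectation tolerance interval — expected to contain a fraction β of
future individual determinations — is the Mee-type interval

    bias ± t_{ν,(1+β)/2} · s_IP · sqrt(1 + 1/(p·n·B²)),

with B² = (R+1)/(nR+1), R = s_B²/s_W², and Satterthwaite degrees of freedom

    ν = (R+1)² / [ (R+1/n)²/(p−1) + (1−1/n)/(p·n) ].

The procedure passes if at every level the tolerance interval lies within the
acceptance limits ±λ (λ = 5% for this pharmaceutical assay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_results",
    "variance_components",
    "tolerance_interval",
    "LevelProfile",
    "AccuracyProfile",
    "accuracy_profile",
    "content_summary",
    "plot_profile",
]

DEFAULT_BETA = 0.95
DEFAULT_LAMBDA = 5.0


class UnbalancedDesignError(ValueError):
    pass


def relative_results(level: float, recovered: np.ndarray) -> np.ndarray:
    """Relative recovery errors in %: 100 × (recovered − level) / level."""
    if level <= 0:
        raise ValueError("level must be > 0")
    return 100.0 * (np.asarray(recovered, float) - level) / level


def variance_components(errors_by_series: np.ndarray) -> tuple[float, float, float]:
    """One-way random-effects ANOVA by method of moments on a balanced
    p-series × n-replicates table.

    Returns (s_W², s_B², bias).  s_W² = MS_within; s_B² = max(0,
    (MS_between − MS_within)/n); bias = grand mean.
    """
    E = np.asarray(errors_by_series, float)
    if E.ndim != 2:
        raise UnbalancedDesignError(
            "expected a balanced 2-D (series × replicates) table"
        )
    p, n = E.shape
    if p < 2 or n < 2:
        raise UnbalancedDesignError("need >= 2 series and >= 2 replicates each")
    if not np.all(np.isfinite(E)):
        raise ValueError("non-finite recovery errors")
    grand = E.mean()
    series_means = E.mean(axis=1)
    ms_within = float(np.sum((E - series_means[:, None]) ** 2) / (p * (n - 1)))
    ms_between = float(n * np.sum((series_means - grand) ** 2) / (p - 1))
    s2_w = ms_within
    s2_b = max(0.0, (ms_between - ms_within) / n)
    return s2_w, s2_b, float(grand)


def tolerance_interval(
    bias: float,
    s2_w: float,
    s2_b: float,
    p: int,
    n: int,
    beta: float = DEFAULT_BETA,
) -> tuple[float, float]:
    """β-expectation tolerance limits for future individual determinations.

    Degenerate cases: both variances zero gives the point interval
    (bias, bias); s_W² = 0 with s_B² > 0 (R → ∞) reduces to B² = 1/n and
    ν = p − 1, i.e. limits driven by the between-series spread only.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    if s2_w < 0 or s2_b < 0:
        raise ValueError("variance components must be >= 0")
    s_ip = np.sqrt(s2_w + s2_b)
    if s_ip == 0.0:
        return bias, bias
    if s2_w == 0.0:  # R -> infinity
        b2 = 1.0 / n
        nu = p - 1
    else:
        R = s2_b / s2_w
        b2 = (R + 1.0) / (n * R + 1.0)
        nu = (R + 1.0) ** 2 / (
            (R + 1.0 / n) ** 2 / (p - 1) + (1.0 - 1.0 / n) / (p * n)
        )
    t = stats.t.ppf((1.0 + beta) / 2.0, df=nu)
    half = t * s_ip * np.sqrt(1.0 + 1.0 / (p * n * b2))
    return float(bias - half), float(bias + half)


@dataclass(frozen=True)
class LevelProfile:
    level: float
    bias: float  # mean relative error, %
    s_w: float  # within-series SD, %
    s_b: float  # between-series SD, %
    s_ip: float  # intermediate-precision SD, %
    df: float  # Satterthwaite degrees of freedom
    low: float  # lower tolerance limit, %
    high: float  # upper tolerance limit, %


@dataclass(frozen=True)
class AccuracyProfile:
    levels: tuple[LevelProfile, ...]
    beta: float
    acceptance_limit: float  # λ, %

    @property
    def passed(self) -> bool:
        lam = self.acceptance_limit
        return all(-lam < lp.low and lp.high < lam for lp in self.levels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "level_percent": lp.level,
                    "bias_percent": lp.bias,
                    "s_within": lp.s_w,
                    "s_between": lp.s_b,
                    "s_ip": lp.s_ip,
                    "df": lp.df,
                    "tolerance_low": lp.low,
                    "tolerance_high": lp.high,
                    "acceptance_limit": self.acceptance_limit,
                    "within_limits": -self.acceptance_limit < lp.low
                    and lp.high < self.acceptance_limit,
                }
                for lp in self.levels
            ]
        )


def _satterthwaite_df(s2_w: float, s2_b: float, p: int, n: int) -> float:
    if s2_w == 0.0:
        return float(p - 1)
    R = s2_b / s2_w
    return (R + 1.0) ** 2 / ((R + 1.0 / n) ** 2 / (p - 1) + (1.0 - 1.0 / n) / (p * n))


def accuracy_profile(
    data: pd.DataFrame,
    beta: float = DEFAULT_BETA,
    acceptance_limit: float = DEFAULT_LAMBDA,
) -> AccuracyProfile:
    """Build the profile from long-format validation results.

    ``data`` needs columns ``level_percent``, ``series_id``, ``replicate_id``
    and ``recovered_percent``.  Each level must form a balanced series ×
    replicate table (unbalanced data are rejected).  The verdict is invariant
    to level ordering and series relabeling.
    """
    required = {"level_percent", "series_id", "replicate_id", "recovered_percent"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if acceptance_limit <= 0:
        raise ValueError("acceptance limit must be > 0")
    levels = []
    for level, grp in data.groupby("level_percent", sort=True):
        counts = grp.groupby("series_id").size()
        if counts.nunique() != 1:
            raise UnbalancedDesignError(
                f"level {level:g}: unequal replicates across series {dict(counts)}"
            )
        p, n = len(counts), int(counts.iloc[0])
        table = (
            grp.sort_values(["series_id", "replicate_id"])["recovered_percent"]
            .to_numpy()
            .reshape(p, n)
        )
        errors = relative_results(float(level), table)
        s2_w, s2_b, bias = variance_components(errors)
        low, high = tolerance_interval(bias, s2_w, s2_b, p, n, beta)
        levels.append(
            LevelProfile(
                level=float(level),
                bias=bias,
                s_w=float(np.sqrt(s2_w)),
                s_b=float(np.sqrt(s2_b)),
                s_ip=float(np.sqrt(s2_w + s2_b)),
                df=_satterthwaite_df(s2_w, s2_b, p, n),
                low=low,
                high=high,
            )
        )
    if not levels:
        raise ValueError("no levels in validation data")
    return AccuracyProfile(
        levels=tuple(levels), beta=beta, acceptance_limit=acceptance_limit
    )


def content_summary(determinations: np.ndarray) -> tuple[float, float]:
    """(mean %, RSD %) of replicate content determinations."""
    x = np.asarray(determinations, float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 determinations")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean content")
    return float(mean), float(100.0 * x.std(ddof=1) / mean)


def plot_profile(profile: AccuracyProfile, title: str = "", ax=None):
    """Bias line, β-expectation tolerance band and ±λ acceptance rails."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    lv = [lp.level for lp in profile.levels]
    ax.plot(lv, [lp.bias for lp in profile.levels], "o-", color="k", label="bias")
    ax.fill_between(
        lv,
        [lp.low for lp in profile.levels],
        [lp.high for lp in profile.levels],
        alpha=0.25,
        color="tab:blue",
        label=f"{profile.beta:.0%}-expectation limits",
    )
    lam = profile.acceptance_limit
    ax.axhline(lam, ls="--", color="tab:red", label=f"±{lam:g}% acceptance")
    ax.axhline(-lam, ls="--", color="tab:red")
    ax.axhline(0.0, lw=0.5, color="gray")
    ax.set_xlabel("level (% of label)")
    ax.set_ylabel("relative error (%)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
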