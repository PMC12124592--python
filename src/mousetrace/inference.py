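"""Statistical layer: choice tests, 2x2 rmANOVA, paired t with dz CIs, power.

Everything here is within-subject.  Effect sizes are Cohen's dz
(mean difference over SD of differences; dz = t / sqrt(n) for a paired t),
with 95% confidence intervals from the noncentral-t pivot: the interval
bounds are the noncentrality parameters whose noncentral-t distributions
place 2.5% of probability beyond the observed t, divided by sqrt(n).

Power for the two-tailed paired/one-sample t-test is exact noncentral-t
power, matching R's ``power.t.test``:

    power(n, dz) = P(|T'| > t_crit),  T' ~ t(df = n-1, ncp = dz * sqrt(n))

The sample-size solver inverts this over a continuous n (as ``power.t.test``
does) and rounds to the nearest integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TTestResult",
    "AnovaResult",
    "DegenerateDataError",
    "summarize_cells",
    "choice_frequency_test",
    "rm_anova_2x2",
    "paired_t",
    "paired_t_from_arrays",
    "dz_confidence_interval",
    "power_paired_t",
    "required_n",
    "minimal_detectable_dz",
]

MEASURE_COLUMNS = {"it": "it_ms", "mt": "mt_ms", "auc": "auc_xu2"}
ANOVA_EFFECTS = ("comparison", "innovativeness", "interaction")


class DegenerateDataError(ValueError):
    """Zero-variance differences make the t statistic undefined."""


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    dz: float
    ci_low: float
    ci_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "dz": self.dz,
            "ci95": [self.ci_low, self.ci_high],
            "n": self.n,
        }


@dataclass
class AnovaResult:
    effect: str  # comparison | innovativeness | interaction
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "eta_p2": self.eta_p2,
        }


# ---------------------------------------------------------------------------
# noncentral-t machinery


def _nct_cdf(x: float, df: float, ncp: float) -> float:
    """Noncentral-t CDF with far-tail underflow mapped to its limit."""
    val = stats.nct.cdf(x, df, ncp)
    if np.isnan(val):
        # scipy underflows deep in the tails; the limit is 0 for ncp >> x
        # and 1 for ncp << x
        return 0.0 if ncp > x else 1.0
    return float(val)


def power_paired_t(n: float, dz: float, alpha: float = 0.05) -> float:
    """Exact two-tailed power of a paired/one-sample t-test.

    ``n`` is the number of pairs (may be non-integer during root finding);
    ``dz`` the true standardized mean difference.
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    ncp = dz * np.sqrt(n)
    return (1.0 - _nct_cdf(t_crit, df, ncp)) + _nct_cdf(-t_crit, df, ncp)


def required_n(dz: float, power: float = 0.80, alpha: float = 0.05) -> int:
    """Sample size for a paired t-test at the given power.

    Solves the continuous-n power equation by root finding — the same
    arithmetic as R's ``power.t.test`` — and rounds to the nearest integer,
    treating a continuous solution within half a participant of an integer
    as that integer.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    lo, hi = 2.0, 4.0
    while power_paired_t(hi, dz, alpha) < power:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("sample size search did not converge")
    n_cont = optimize.brentq(
        lambda n: power_paired_t(n, dz, alpha) - power, lo, hi, xtol=1e-8
    )
    return int(np.floor(n_cont + 0.5))


def minimal_detectable_dz(n: int, power: float = 0.80, alpha: float = 0.05) -> float:
    """Effect size dz detectable at the given power with n pairs."""
    if n < 2:
        raise ValueError("n must be at least 2")
    hi = 0.1
    while power_paired_t(n, hi, alpha) < power:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("effect size search did not converge")
    return float(
        optimize.brentq(
            lambda d: power_paired_t(n, d, alpha) - power, 1e-12, hi, xtol=1e-8
        )
    )


def dz_confidence_interval(
    t: float, df: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Noncentral-t pivot CI for Cohen's dz.

    Finds noncentrality parameters ncp_L < ncp_U such that a noncentral
    t(df, ncp_U) leaves probability (1-level)/2 below the observed t and a
    t(df, ncp_L) leaves the same probability above it; bounds are ncp/sqrt(n).
    """
    if not np.isfinite(t):
        raise ValueError("t statistic must be finite")
    if df < 1:
        raise ValueError("df must be at least 1")
    tail = (1.0 - level) / 2.0

    # cdf(t; ncp) is strictly decreasing in ncp; expand the bracket until it
    # straddles the requested tail probability
    def _invert(target: float) -> float:
        span = abs(t) + 10.0
        while _nct_cdf(t, df, t + span) > target or _nct_cdf(t, df, t - span) < target:
            span *= 2.0
            if span > 1e8:
                raise RuntimeError("noncentrality bracket did not converge")
        return optimize.brentq(
            lambda ncp: _nct_cdf(t, df, ncp) - target, t - span, t + span, xtol=1e-10
        )

    ncp_hi = _invert(tail)
    ncp_lo = _invert(1.0 - tail)
    root_n = np.sqrt(n)
    return float(ncp_lo / root_n), float(ncp_hi / root_n)


# ---------------------------------------------------------------------------
# t-tests


def paired_t_from_arrays(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Two-tailed paired t-test of ``a`` vs ``b`` with dz and its 95% CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences; t is undefined")
    t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    dz = t / np.sqrt(n)
    ci_low, ci_high = dz_confidence_interval(t, df, n)
    return TTestResult(
        t=float(t), df=df, p=float(p), dz=float(dz), ci_low=ci_low, ci_high=ci_high, n=n
    )


def summarize_cells(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-participant cell means of IT/MT/AUC over valid, included trials.

    One row per participant x comparison-type x innovativeness cell, with
    columns ``mean_it``, ``mean_mt``, ``mean_auc`` and ``n_valid``.  Expects
    the exclusion cascade to have run (``excluded`` and
    ``participant_included`` columns).
    """
    valid = measures[~measures["excluded"] & measures["participant_included"]]
    cells = (
        valid.groupby(
            ["participant_id", "comparison_type", "chosen_innovativeness"], sort=False
        )
        .agg(
            mean_it=("it_ms", "mean"),
            mean_mt=("mt_ms", "mean"),
            mean_auc=("auc_xu2", "mean"),
            n_valid=("it_ms", "size"),
        )
        .reset_index()
        .rename(columns={"chosen_innovativeness": "innovativeness"})
    )
    return cells


def choice_frequency_test(measures: pd.DataFrame, comparison_type: str) -> TTestResult:
    """Paired t-test of more- vs less-innovative choice counts.

    Uses *all* trials of the given comparison type (performance exclusions
    do not apply to choice frequencies).  Per participant the number of
    more-innovative minus less-innovative clicks is formed; a one-sample t
    against zero across participants — equivalent to the paired t on the two
    counts — is returned with dz and its CI.
    """
    sub = measures[measures["comparison_type"] == comparison_type]
    if len(sub) == 0:
        raise ValueError(f"no trials of comparison type {comparison_type!r}")
    zero_trial = set(measures["participant_id"].unique()) - set(
        sub["participant_id"].unique()
    )
    if zero_trial:
        warnings.warn(
            f"{len(zero_trial)} participant(s) with zero {comparison_type!r} "
            "trials dropped from the choice test",
            stacklevel=2,
        )
    counts = (
        sub.assign(high=lambda d: d["chosen_innovativeness"] == "high")
        .groupby("participant_id", sort=False)["high"]
        .agg(n_high="sum", n_total="size")
    )
    n_high = counts["n_high"].to_numpy(dtype=float)
    n_low = counts["n_total"].to_numpy(dtype=float) - n_high
    return paired_t_from_arrays(n_high, n_low)


def paired_t(cells: pd.DataFrame, comparison_type: str, measure: str) -> TTestResult:
    """Follow-up paired t: high vs low innovativeness within a comparison type.

    ``measure`` is one of ``"it"``, ``"mt"``, ``"auc"``.  Only participants
    with both innovativeness cells for the given comparison type enter.
    """
    col = f"mean_{measure}"
    if col not in cells.columns:
        raise KeyError(f"unknown measure {measure!r}")
    sub = cells[cells["comparison_type"] == comparison_type]
    wide = sub.pivot(index="participant_id", columns="innovativeness", values=col)
    wide = wide.dropna(subset=["high", "low"])
    return paired_t_from_arrays(wide["high"].to_numpy(), wide["low"].to_numpy())


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA


def rm_anova_2x2(cells: pd.DataFrame, measure: str) -> list[AnovaResult]:
    """Within-subject 2x2 ANOVA on per-participant cell means.

    Factors are comparison type (past/future) and chosen-target
    innovativeness (high/low).  Returns the two main effects and the
    interaction, each with F(1, n-1), p, and partial eta squared
    (= F / (F + df2) for single-df effects).  Participants missing any cell
    are dropped with a warning before fitting.
    """
    import pingouin as pg

    col = f"mean_{measure}"
    if col not in cells.columns:
        raise KeyError(f"unknown measure {measure!r}")
    complete = cells.groupby("participant_id", sort=False)[col].transform("size") == 4
    n_dropped = cells.loc[~complete, "participant_id"].nunique()
    if n_dropped:
        warnings.warn(
            f"{n_dropped} participant(s) missing a design cell dropped from ANOVA",
            stacklevel=2,
        )
    data = cells[complete]
    n = data["participant_id"].nunique()
    if n < 2:
        raise ValueError("ANOVA needs at least 2 complete participants")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pingouin's pandas-compat chatter
        aov = pg.rm_anova(
            data=data,
            dv=col,
            within=["comparison_type", "innovativeness"],
            subject="participant_id",
        )
    by_source = {row.Source: row for row in aov.itertuples()}
    mapping = {
        "comparison": "comparison_type",
        "innovativeness": "innovativeness",
        "interaction": "comparison_type * innovativeness",
    }
    out = []
    for effect, source in mapping.items():
        row = by_source[source]
        F = float(row.F)
        df2 = n - 1
        out.append(
            AnovaResult(
                effect=effect,
                F=F,
                df1=1,
                df2=df2,
                p=float(row.p_unc),
                eta_p2=F / (F + df2),
            )
        )
    return out
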