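"""Nonparametric survival description and comparison of methylation tiers.

Kaplan-Meier product-limit curves (delegated to lifelines), fixed-horizon
survival rates, two-group log-rank tests with the full observed/expected
decomposition, and the per-tier survival report for a three-tier
classification rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import chi2

from .cohort import Cohort
from .errors import DegenerateTestError, NoEventsError
from .threshold import TIERS, ThreeTierRule


@dataclass
class KMCurve:
    """A Kaplan-Meier step function with its risk table.

    ``survival_prob[k]`` is S at ``event_times[k]`` (right-continuous);
    S = 1 before the first event.  Median is the smallest event time with
    S <= 0.5, None when S never reaches 0.5.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray
    group: str = ""
    n: int = 0

    @property
    def median(self) -> float | None:
        hit = self.survival_prob <= 0.5
        if not hit.any():
            return None
        return float(self.event_times[np.argmax(hit)])

    def survival_at(self, t: float) -> float:
        k = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if k == 0 else float(self.survival_prob[k - 1])

    @property
    def max_observed_time(self) -> float:
        times = np.concatenate([self.event_times, self.censor_times])
        return float(times.max()) if len(times) else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Curve as a table for external plotting."""
        return pd.DataFrame({
            "time": self.event_times, "survival": self.survival_prob,
            "n_at_risk": self.n_at_risk, "n_events": self.n_events,
            "group": self.group,
        })


def km_estimate(times, events, group: str = "") -> KMCurve:
    """Product-limit survival estimate with standard tie handling
    (events precede censoring in the risk set at tied times)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) < 1:
        raise ValueError("need at least one observation")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e, label=group or "KM")
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    surv = kmf.survival_function_.iloc[:, 0]
    return KMCurve(
        event_times=ev.index.to_numpy(dtype=float),
        survival_prob=surv.loc[ev.index].to_numpy(dtype=float),
        n_at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        censor_times=np.sort(t[e == 0]),
        group=group, n=len(t))


def survival_rates(curve: KMCurve, horizons) -> list[dict]:
    """S(t) at fixed horizons (months).

    Horizons beyond the last observed time carry the last estimate with an
    ``extrapolated`` flag.
    """
    out = []
    last = curve.max_observed_time
    for h in horizons:
        if h < 0:
            raise ValueError("horizons must be non-negative")
        out.append({"horizon": float(h), "survival": curve.survival_at(h),
                    "extrapolated": bool(h > last)})
    return out


@dataclass
class LogRankResult:
    """Two-group log-rank test with its O/E decomposition."""

    chi_square: float
    p_value: float
    df: int
    observed: tuple  # (O_a, O_b)
    expected: tuple  # (E_a, E_b)
    variance: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Standard two-group log-rank test.

    At each distinct event time the expected events per group come from the
    hypergeometric mean given the risk sets; the statistic is
    (O_a - E_a)^2 / V with V the summed hypergeometric variances, referred
    to chi-square with 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise NoEventsError("no events in either group")

    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O_a = E_a = V = 0.0
    for tj in all_event_times:
        n1 = int((ta >= tj).sum())
        n2 = int((tb >= tj).sum())
        d1 = int(((ta == tj) & (ea == 1)).sum())
        d2 = int(((tb == tj) & (eb == 1)).sum())
        n_j, d_j = n1 + n2, d1 + d2
        if n_j == 0 or d_j == 0:
            continue
        O_a += d1
        E_a += d_j * n1 / n_j
        if n_j > 1:
            V += d_j * (n1 / n_j) * (n2 / n_j) * (n_j - d_j) / (n_j - 1)
    if V <= 0:
        raise DegenerateTestError(
            "zero log-rank variance; groups share no comparable event "
            "structure")
    O_total = float(ea.sum() + eb.sum())
    stat = (O_a - E_a) ** 2 / V
    return LogRankResult(
        chi_square=float(stat), p_value=float(chi2.sf(stat, 1)), df=1,
        observed=(float(O_a), O_total - float(O_a)),
        expected=(float(E_a), O_total - float(E_a)), variance=float(V))


@dataclass
class TierSurvival:
    """Survival description of one methylation tier."""

    tier: str
    n: int
    n_events: int
    curve: KMCurve | None
    median_os: float | None
    rates: list = field(default_factory=list)


@dataclass
class ThreeTierSurvivalReport:
    """Per-tier Kaplan-Meier summaries plus all pairwise log-rank tests."""

    tiers: dict  # tier name -> TierSurvival
    pairwise: dict  # (tier_a, tier_b) -> LogRankResult
    warnings: list = field(default_factory=list)

    def km_frame(self) -> pd.DataFrame:
        frames = [ts.curve.to_frame() for ts in self.tiers.values()
                  if ts.curve is not None]
        return (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame())


def three_tier_survival_report(cohort: Cohort | pd.DataFrame,
                               rule: ThreeTierRule,
                               horizons=(12.0, 24.0, 60.0),
                               bonferroni: bool = False
                               ) -> ThreeTierSurvivalReport:
    """Kaplan-Meier curves, medians, fixed-horizon rates and pairwise
    log-rank tests for the three methylation tiers.

    P-values are unadjusted by default; ``bonferroni`` multiplies them by
    the number of pairwise tests (capped at 1).
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    labels = rule.classify(df["mean_meth"].to_numpy(dtype=float))
    tiers, warnings = {}, []
    for tier in TIERS:
        sub = df[labels == tier]
        if len(sub) == 0:
            tiers[tier] = TierSurvival(tier, 0, 0, None, None, [])
            warnings.append(f"tier {tier!r} is empty")
            continue
        curve = km_estimate(sub["os_months"], sub["event"], group=tier)
        tiers[tier] = TierSurvival(
            tier=tier, n=len(sub), n_events=int(sub["event"].sum()),
            curve=curve, median_os=curve.median,
            rates=survival_rates(curve, horizons))
    nonempty = [t for t in TIERS if tiers[t].n > 0]
    pairwise = {}
    if len(nonempty) < 2:
        warnings.append("fewer than two non-empty tiers; no comparisons")
    else:
        pairs = [(a, b) for i, a in enumerate(nonempty)
                 for b in nonempty[i + 1:]]
        for a, b in pairs:
            sa = df[labels == a]
            sb = df[labels == b]
            try:
                res = logrank_test(sa["os_months"], sa["event"],
                                   sb["os_months"], sb["event"])
                if bonferroni:
                    res.p_value = min(1.0, res.p_value * len(pairs))
                pairwise[(a, b)] = res
            except (DegenerateTestError, NoEventsError) as exc:
                warnings.append(f"log-rank {a} vs {b} degenerate: {exc}")
    return ThreeTierSurvivalReport(tiers=tiers, pairwise=pairwise,
                                   warnings=warnings)
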