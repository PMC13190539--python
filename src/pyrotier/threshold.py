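"""Survival-informed cut-off search and the three-tier classification rule.

The supervised cut-off is found by scanning candidate thresholds (integer
percent, 1-25 by default), dichotomizing methylation at each candidate,
refitting the adjusted log-logistic AFT model under 5-fold cross-validation,
scoring each candidate by the out-of-fold concordance index, and selecting
the maximum.  The interval between this supervised cut-off (lower bound of
unmethylated, "at or below") and the unsupervised mixture-intersection
cut-off (lower bound of methylated, "at or above") is the gray zone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aft import LogLogisticAFT, build_design, concordance_index
from .cohort import CPG_COLUMNS, Cohort
from .errors import (InsufficientEventsError, MissingPerCpGError,
                     NoValidThresholdError)
from .mixture import CutoffEstimate

DEFAULT_CANDIDATES = tuple(range(1, 26))


def make_folds(events, n_folds: int, seed: int) -> np.ndarray:
    """Randomized fold assignment stratified by event indicator.

    Within each stratum (dead / censored) indices are shuffled and dealt
    round-robin, so every fold gets its share of events.  Deterministic
    given ``seed``.
    """
    events = np.asarray(events, dtype=int)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(events), dtype=int)
    for value in (1, 0):
        idx = np.flatnonzero(events == value)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def fold_hash(folds: np.ndarray) -> str:
    """Short digest of a fold assignment, for sharing audits."""
    return hashlib.sha256(np.asarray(folds, dtype=np.int64)
                          .tobytes()).hexdigest()[:12]


@dataclass
class CandidateResult:
    """Cross-validated score of one candidate cut-off."""

    cutoff: int
    valid: bool
    mean_c: float | None
    fold_c: list
    n_methylated: int
    note: str = ""


@dataclass
class ThresholdScanResults:
    """Full cross-validated threshold scan and the selected cut-off."""

    marker: str
    candidates: list  # of CandidateResult, one per candidate
    selected_cutoff: int
    cv_seed: int
    n_folds: int
    fold_assignment: np.ndarray
    score: str = "fold_mean"

    @property
    def fold_hash(self) -> str:
        return fold_hash(self.fold_assignment)

    @property
    def best_c(self) -> float:
        return next(c.mean_c for c in self.candidates
                    if c.cutoff == self.selected_cutoff)

    def cutoff_estimate(self) -> CutoffEstimate:
        return CutoffEstimate(value_pct=float(self.selected_cutoff),
                              method="supervised", diagnostics=self)

    def to_frame(self) -> pd.DataFrame:
        """Scan curve as a table (candidate, validity, mean and per-fold C)."""
        return pd.DataFrame([{
            "cutoff": c.cutoff, "valid": c.valid, "mean_c": c.mean_c,
            "n_methylated": c.n_methylated,
            **{f"fold{j}_c": (c.fold_c[j] if c.valid else None)
               for j in range(self.n_folds)},
        } for c in self.candidates])

    def summary(self) -> str:
        lines = [
            f"Cross-validated threshold scan on {self.marker!r} "
            f"({self.n_folds} folds, cv_seed={self.cv_seed})",
            f"  selected cut-off: <= {self.selected_cutoff}% unmethylated "
            f"(mean out-of-fold C = {self.best_c:.4f})",
        ]
        return "\n".join(lines)


def scan_thresholds(cohort: Cohort | pd.DataFrame, marker: str = "mean_meth",
                    candidates=DEFAULT_CANDIDATES, n_folds: int = 5,
                    cv_seed: int = 0, score: str = "fold_mean",
                    folds: np.ndarray | None = None,
                    **design_kwargs) -> ThresholdScanResults:
    """Scan candidate cut-offs by cross-validated out-of-fold concordance.

    For each integer candidate c the marker is dichotomized as methylated =
    value > c (unmethylated means at-or-below c).  Folds are formed once,
    stratified by event status, and shared across all candidates.  Per fold,
    the adjusted AFT model (dichotomy + age + performance status + extent of
    resection) is fitted on the training four fifths and the held-out fifth
    is scored by Harrell's C on its linear predictor.  Candidates whose
    dichotomy is degenerate (a single class) in any training fold are
    recorded invalid and excluded from selection.  Ties in the score break
    toward the lowest candidate.

    ``score``: ``"fold_mean"`` (mean of per-fold C, default) or ``"pooled"``
    (single C over the pooled out-of-fold predictions).
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if marker not in df.columns:
        raise MissingPerCpGError(f"marker column {marker!r} not in cohort")
    events = df["event"].to_numpy(dtype=int)
    if events.sum() < n_folds:
        raise InsufficientEventsError(
            f"{events.sum()} events < {n_folds} folds")
    if folds is None:
        folds = make_folds(events, n_folds, cv_seed)
    values = df[marker].to_numpy(dtype=float)
    times = df["os_months"].to_numpy(dtype=float)

    results = []
    for c in candidates:
        meth = values > float(c)
        fold_c, pooled_eta = [], np.empty(len(df))
        note = ""
        valid = True
        for j in range(n_folds):
            train, test = folds != j, folds == j
            if meth[train].all() or (~meth[train]).all():
                valid, note = False, f"degenerate dichotomy in fold {j}"
                break
            X_train = build_design(df.loc[train], cutoff=c, marker=marker,
                                   **design_kwargs)
            model = LogLogisticAFT(times[train], events[train], X_train)
            fit = model.fit()
            X_test = build_design(df.loc[test], cutoff=c, marker=marker,
                                  **design_kwargs)
            eta = fit.predict(X_test)
            pooled_eta[test] = eta
            fold_c.append(concordance_index(times[test], events[test],
                                            eta).c_index)
        if not valid:
            results.append(CandidateResult(int(c), False, None, [],
                                           int(meth.sum()), note))
            continue
        if score == "pooled":
            mean_c = concordance_index(times, events, pooled_eta).c_index
        else:
            mean_c = float(np.mean(fold_c))
        results.append(CandidateResult(int(c), True, mean_c, fold_c,
                                       int(meth.sum())))

    valid_results = [r for r in results if r.valid]
    if not valid_results:
        raise NoValidThresholdError(
            "every candidate cut-off produced a degenerate dichotomy")
    best = max(valid_results, key=lambda r: (r.mean_c, -r.cutoff))
    return ThresholdScanResults(
        marker=marker, candidates=results, selected_cutoff=best.cutoff,
        cv_seed=cv_seed, n_folds=n_folds, fold_assignment=folds, score=score)


@dataclass
class MarkerComparison:
    """One marker's best cross-validated performance vs the CpG mean."""

    marker: str
    selected_cutoff: int
    best_c: float
    diff_vs_mean_pct_points: float


@dataclass
class CpGComparison:
    """Mean-of-CpGs vs individual-CpG predictive performance.

    Differences are in concordance percentage points relative to the mean
    marker (0 for the mean itself by definition).
    """

    markers: list  # of MarkerComparison, mean first
    fold_hash: str
    scans: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.markers])


def compare_markers(cohort: Cohort | pd.DataFrame,
                    candidates=DEFAULT_CANDIDATES, n_folds: int = 5,
                    cv_seed: int = 0, **scan_kwargs) -> CpGComparison:
    """Run the threshold scan for the mean and each individual CpG.

    All five scans share one fold assignment (audited by ``fold_hash``) so
    concordance differences reflect the marker, not fold noise.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    missing = [c for c in CPG_COLUMNS if c not in df.columns
               or df[c].isna().any()]
    if missing:
        raise MissingPerCpGError(
            f"per-CpG columns missing or incomplete: {missing}")
    folds = make_folds(df["event"].to_numpy(dtype=int), n_folds, cv_seed)
    markers, scans = [], {}
    mean_best = None
    for marker in ["mean_meth", *CPG_COLUMNS]:
        scan = scan_thresholds(df, marker=marker, candidates=candidates,
                               n_folds=n_folds, cv_seed=cv_seed, folds=folds,
                               **scan_kwargs)
        scans[marker] = scan
        if marker == "mean_meth":
            mean_best = scan.best_c
        markers.append(MarkerComparison(
            marker=marker, selected_cutoff=scan.selected_cutoff,
            best_c=scan.best_c,
            diff_vs_mean_pct_points=100.0 * (scan.best_c - mean_best)))
    return CpGComparison(markers=markers, fold_hash=fold_hash(folds),
                         scans=scans)


TIER_UNMETH = "unmethylated"
TIER_GRAY = "gray_zone"
TIER_METH = "methylated"
TIERS = (TIER_UNMETH, TIER_GRAY, TIER_METH)


@dataclass(frozen=True)
class ThreeTierRule:
    """Three-tier classification from a (lower, upper) cut-off pair.

    unmethylated: value <= lower; methylated: value >= upper; gray zone:
    strictly between.  When lower >= upper the gray zone is empty and the
    rule collapses to the single threshold at ``upper`` (value >= upper is
    methylated, below is unmethylated).
    """

    lower: float
    upper: float

    @property
    def collapsed(self) -> bool:
        return self.lower >= self.upper

    def classify(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.collapsed:
            return np.where(v >= self.upper, TIER_METH, TIER_UNMETH)
        out = np.full(v.shape, TIER_GRAY, dtype=object)
        out[v <= self.lower] = TIER_UNMETH
        out[v >= self.upper] = TIER_METH
        return out.astype(str)

    def describe(self) -> str:
        if self.collapsed:
            return (f"single cut-off: methylated >= {self.upper:g}% "
                    "(gray zone empty)")
        return (f"unmethylated <= {self.lower:g}%, gray zone "
                f"> {self.lower:g} to < {self.upper:g}%, "
                f"methylated >= {self.upper:g}%")


def derive_three_tier(unsupervised: CutoffEstimate | float,
                      supervised: CutoffEstimate | float) -> ThreeTierRule:
    """Gray-zone rule: lower = supervised cut-off, upper = unsupervised.

    The unsupervised (mixture-intersection) estimate is used at its rounded
    integer value, matching how such thresholds are reported clinically;
    the supervised estimate is already an integer candidate.
    """
    upper = (unsupervised.value_int
             if isinstance(unsupervised, CutoffEstimate)
             else float(unsupervised))
    lower = (supervised.value_pct if isinstance(supervised, CutoffEstimate)
             else float(supervised))
    return ThreeTierRule(lower=float(lower), upper=float(upper))
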