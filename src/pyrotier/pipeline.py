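"""End-to-end three-tier MGMT methylation analysis.

Orchestrates: cohort load or simulation -> mixture fit and unsupervised
intersection cut-off -> cross-validated supervised threshold search ->
three-tier rule and classification counts -> cut-off overlap statistic ->
per-CpG marker comparison (when per-CpG data are present) -> per-tier
survival report.  The result is a versioned, schema-validated
:class:`AnalysisReport`; identical configuration (including the master
seed) yields an identical report.
"""

from __future__ import annotations

import importlib.metadata
import json

import numpy as np
from pydantic import BaseModel

from . import km as km_mod
from .cohort import Cohort, read_cohort, summarize_cohort
from .errors import MissingPerCpGError, PyrotierError, UndefinedStatisticError
from .mixture import MethylationMixture, MixtureResults, NoIntersectionError
from .simulate import SimulationConfig, simulate_cohort
from .threshold import (DEFAULT_CANDIDATES, ThreeTierRule, compare_markers,
                        derive_three_tier, scan_thresholds)

REPORT_SCHEMA_VERSION = "1"


# --------------------------------------------------------------------------
# report schema (pydantic models; the shipped report_schema.json is the
# emitted JSON schema of AnalysisReport)
# --------------------------------------------------------------------------

class MixtureSection(BaseModel):
    weights: list[float]
    means_log: list[float]
    sds_log: list[float]
    loglik: float
    n_iter: int
    converged: bool
    cutoff_raw_pct: float | None
    cutoff_int_pct: int | None
    no_intersection: bool = False


class CandidateRow(BaseModel):
    cutoff: int
    valid: bool
    mean_c: float | None
    fold_c: list[float]
    n_methylated: int
    note: str = ""


class ScanSection(BaseModel):
    marker: str
    selected_cutoff: int
    best_c: float
    cv_seed: int
    n_folds: int
    fold_hash: str
    candidates: list[CandidateRow]


class RuleSection(BaseModel):
    lower_pct: float
    upper_pct: float
    collapsed: bool
    description: str


class TierCounts(BaseModel):
    counts: dict[str, int]
    fractions_pct: dict[str, float]
    n: int


class OverlapSection(BaseModel):
    frac_mixture_methylated_above_supervised: float
    frac_above_supervised_in_mixture_methylated: float
    n_mixture_methylated: int
    n_above_supervised: int


class MarkerRow(BaseModel):
    marker: str
    selected_cutoff: int
    best_c: float
    diff_vs_mean_pct_points: float


class CpGSection(BaseModel):
    markers: list[MarkerRow]
    fold_hash: str


class RateRow(BaseModel):
    horizon: float
    survival: float
    extrapolated: bool


class TierSurvivalSection(BaseModel):
    n: int
    n_events: int
    median_os: float | None
    rates: list[RateRow]


class PairwiseTest(BaseModel):
    groups: list[str]
    chi_square: float
    p_value: float


class SurvivalSection(BaseModel):
    tiers: dict[str, TierSurvivalSection]
    pairwise: list[PairwiseTest]


class AnalysisReport(BaseModel):
    """Versioned end-to-end analysis report (JSON-serializable)."""

    schema_version: str
    software_version: str
    seeds: dict[str, int]
    provenance: str
    config: dict | None
    cohort_summary: dict
    mixture: MixtureSection
    scan: ScanSection
    rule: RuleSection
    tiers: TierCounts
    overlap: OverlapSection | None
    cpg_comparison: CpGSection | None
    cpg_comparison_notice: str | None
    survival: SurvivalSection
    warnings: list[str]
    incomplete: bool = False

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(indent=2, **kwargs)


def report_json_schema() -> dict:
    return AnalysisReport.model_json_schema()


# --------------------------------------------------------------------------
# overlap statistic
# --------------------------------------------------------------------------

def overlap_statistic(cohort: Cohort, mixture: MixtureResults,
                      rule: ThreeTierRule) -> OverlapSection:
    """Agreement between the mixture labeling and the supervised cut-off.

    Primary direction: among patients assigned to the methylated mixture
    component (posterior probability > 0.5), the fraction whose mean
    methylation exceeds the supervised lower cut-off, i.e. is *not* labeled
    truly unmethylated.  The complementary direction (among patients above
    the supervised cut-off, the fraction mixture-methylated) is reported
    alongside because either reading is clinically meaningful.
    """
    values = cohort.df["mean_meth"].to_numpy(dtype=float)
    post = mixture.posterior(values)
    mix_meth = post[:, 1] > 0.5
    above = values > rule.lower
    n_mix = int(mix_meth.sum())
    n_above = int(above.sum())
    if n_mix == 0:
        raise UndefinedStatisticError("empty methylated mixture component")
    frac_primary = float((mix_meth & above).sum() / n_mix)
    frac_complement = (float((mix_meth & above).sum() / n_above)
                       if n_above else 0.0)
    return OverlapSection(
        frac_mixture_methylated_above_supervised=frac_primary,
        frac_above_supervised_in_mixture_methylated=frac_complement,
        n_mixture_methylated=n_mix, n_above_supervised=n_above)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def _software_version() -> str:
    try:
        return importlib.metadata.version("pyrotier")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def run_pipeline(cohort_source, seed: int = 0, floor_pct: float = 0.5,
                 candidates=DEFAULT_CANDIDATES, n_folds: int = 5,
                 n_starts: int = 10, horizons=(12.0, 24.0, 60.0),
                 compare_cpgs: bool = True) -> AnalysisReport:
    """Run the full three-tier analysis.

    Parameters
    ----------
    cohort_source : Cohort, SimulationConfig or path
        An in-memory cohort, a simulation configuration (a cohort is drawn
        from it), or a path to a cohort CSV file.
    seed : int
        Master seed; the mixture EM multi-start seed and the
        cross-validation fold seed are derived from it (``seed + 1`` and
        ``seed + 2``).  A simulation uses the seed inside its own config.
    """
    warnings: list[str] = []
    seeds = {"master": int(seed), "em": int(seed) + 1, "cv": int(seed) + 2}
    sim_config_dict = None

    if isinstance(cohort_source, SimulationConfig):
        cohort, _ = simulate_cohort(cohort_source)
        sim_config_dict = cohort_source.to_dict()
        seeds["simulation"] = int(cohort_source.seed)
    elif isinstance(cohort_source, Cohort):
        cohort = cohort_source
    else:
        cohort = read_cohort(cohort_source)
        if cohort.rejections.n_rejected:
            warnings.append(
                f"{cohort.rejections.n_rejected} record(s) rejected on "
                f"validation: {cohort.rejections.reasons}")
    cohort.require_nonempty("pipeline")
    values = cohort.df["mean_meth"].to_numpy(dtype=float)

    # -- unsupervised cut-off --------------------------------------------
    mix = MethylationMixture(values, floor_pct=floor_pct).fit(
        n_starts=n_starts, seed=seeds["em"])
    if not mix.converged:
        warnings.append("mixture EM did not converge within max_iter")
    try:
        unsup = mix.intersection_cutoff()
        mixture_section = MixtureSection(
            weights=list(mix.weights), means_log=list(mix.means),
            sds_log=list(mix.sds), loglik=mix.loglik, n_iter=mix.n_iter,
            converged=mix.converged, cutoff_raw_pct=unsup.value_pct,
            cutoff_int_pct=unsup.value_int)
    except NoIntersectionError as exc:
        warnings.append(f"no mixture-density intersection: {exc}")
        mixture_section = MixtureSection(
            weights=list(mix.weights), means_log=list(mix.means),
            sds_log=list(mix.sds), loglik=mix.loglik, n_iter=mix.n_iter,
            converged=mix.converged, cutoff_raw_pct=None,
            cutoff_int_pct=None, no_intersection=True)
        unsup = None

    # -- supervised cut-off ----------------------------------------------
    scan = scan_thresholds(cohort, marker="mean_meth", candidates=candidates,
                           n_folds=n_folds, cv_seed=seeds["cv"])
    n_invalid = sum(not c.valid for c in scan.candidates)
    if n_invalid:
        warnings.append(f"{n_invalid} candidate cut-off(s) degenerate and "
                        "excluded from selection")
    sup = scan.cutoff_estimate()
    scan_section = ScanSection(
        marker=scan.marker, selected_cutoff=scan.selected_cutoff,
        best_c=scan.best_c, cv_seed=scan.cv_seed, n_folds=scan.n_folds,
        fold_hash=scan.fold_hash,
        candidates=[CandidateRow(**vars(c)) for c in scan.candidates])

    # -- three-tier rule and classification ------------------------------
    if unsup is not None:
        rule = derive_three_tier(unsup, sup)
    else:
        rule = ThreeTierRule(lower=float(sup.value_pct),
                             upper=float(sup.value_pct))
        warnings.append("rule collapsed to the supervised cut-off only")
    if rule.collapsed:
        warnings.append("gray zone empty: lower cut-off >= upper cut-off")
    labels = rule.classify(values)
    n = len(cohort)
    counts = {tier: int((labels == tier).sum())
              for tier in ("unmethylated", "gray_zone", "methylated")}
    tiers_section = TierCounts(
        counts=counts,
        fractions_pct={k: round(100.0 * v / n, 1) for k, v in counts.items()},
        n=n)

    # -- overlap ----------------------------------------------------------
    try:
        overlap = overlap_statistic(cohort, mix, rule)
    except UndefinedStatisticError as exc:
        warnings.append(f"overlap statistic undefined: {exc}")
        overlap = None

    # -- per-CpG comparison ------------------------------------------------
    cpg_section, cpg_notice = None, None
    if compare_cpgs:
        try:
            comp = compare_markers(cohort, candidates=candidates,
                                   n_folds=n_folds, cv_seed=seeds["cv"])
            cpg_section = CpGSection(
                markers=[MarkerRow(**vars(m)) for m in comp.markers],
                fold_hash=comp.fold_hash)
        except MissingPerCpGError as exc:
            cpg_notice = f"per-CpG comparison skipped: {exc}"
    else:
        cpg_notice = "per-CpG comparison disabled by configuration"

    # -- survival ----------------------------------------------------------
    incomplete = False
    try:
        surv = km_mod.three_tier_survival_report(cohort, rule,
                                                 horizons=horizons)
        warnings.extend(surv.warnings)
        survival_section = SurvivalSection(
            tiers={name: TierSurvivalSection(
                n=ts.n, n_events=ts.n_events, median_os=ts.median_os,
                rates=[RateRow(**r) for r in ts.rates])
                for name, ts in surv.tiers.items()},
            pairwise=[PairwiseTest(groups=list(pair),
                                   chi_square=res.chi_square,
                                   p_value=res.p_value)
                      for pair, res in surv.pairwise.items()])
    except PyrotierError as exc:  # emit a partial report
        warnings.append(f"survival stage failed: {exc}")
        incomplete = True
        survival_section = SurvivalSection(tiers={}, pairwise=[])

    return AnalysisReport(
        schema_version=REPORT_SCHEMA_VERSION,
        software_version=_software_version(),
        seeds=seeds, provenance=cohort.provenance, config=sim_config_dict,
        cohort_summary=_jsonable(summarize_cohort(cohort)),
        mixture=mixture_section, scan=scan_section,
        rule=RuleSection(lower_pct=rule.lower, upper_pct=rule.upper,
                         collapsed=rule.collapsed,
                         description=rule.describe()),
        tiers=tiers_section, overlap=overlap,
        cpg_comparison=cpg_section, cpg_comparison_notice=cpg_notice,
        survival=survival_section, warnings=warnings, incomplete=incomplete)


def _jsonable(obj):
    """Recursively convert numpy scalars / tuples for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report: AnalysisReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(report.to_json())


def load_report(path) -> AnalysisReport:
    """Parse (and thereby schema-validate) a report JSON file."""
    with open(path) as fh:
        return AnalysisReport.model_validate(json.load(fh))
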