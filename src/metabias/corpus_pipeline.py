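"""Corpus-level orchestration: run the audit, apply sensitivity filters, and
tabulate results by research area, plus ROBIS judgment tallies.

For every meta-analysis with at least two studies the pipeline re-pools the
effect with a random-effects model and, where at least ``min_k_tests`` (=3)
studies are available, runs the Egger small-study-effect test and the
excess-significance test.  Research-area summaries report, per area and
overall, how many meta-analyses are nominally significant (pooled p < 0.05),
how many of the test-eligible ones are flagged by each bias test, and how
many show more observed than expected significant studies (O > E).

Two sensitivity filters mirror common robustness checks: restricting to
meta-analyses with at least 10 primary studies, and dropping small primary
studies (fewer than 200 deaths) before re-auditing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .bias_tests import egger_test, excess_significance_test
from .errors import DegenerateDesignError, InsufficientStudiesError, InvalidInputError
from .meta_engine import pool_random_effects
from .study_data import Corpus, MetaAnalysisRecord, ResearchArea, RobisAssessment

__all__ = [
    "AuditConfig",
    "AuditResult",
    "RobisSummary",
    "run_audit",
    "sensitivity_min_k",
    "sensitivity_exclude_small",
    "tabulate_by_area",
    "robis_tabulate",
    "write_report",
    "PER_META_COLUMNS",
]

# significance threshold for the pooled random-effects estimate
POOLED_ALPHA = 0.05

PER_META_COLUMNS = [
    "meta_id", "research_area", "k",
    "pooled_effect_ratio", "ci_lower", "ci_upper", "p_value", "q", "tau2", "i2", "significant",
    "egger_eligible", "egger_reason", "egger_intercept", "egger_intercept_se",
    "egger_t", "egger_p", "egger_flag",
    "excess_eligible", "excess_reason", "O", "E", "theta_star_ratio",
    "chi2", "excess_p", "o_gt_e", "excess_flag",
]

_AREA_ORDER = [a.value for a in ResearchArea]


@dataclass(frozen=True)
class AuditConfig:
    """Thresholds of the audit; defaults follow the standard conventions
    (Egger p < 0.10, excess two-sided p < 0.10 with O > E, per-study α = 0.05,
    sensitivity cutoffs of 10 studies and 200 deaths)."""

    min_k_tests: int = 3
    egger_alpha: float = 0.10
    excess_alpha: float = 0.10
    study_alpha: float = 0.05
    sensitivity_min_k: int = 10
    min_deaths: int = 200
    direction_restricted: bool = False

    def __post_init__(self) -> None:
        for name in ("egger_alpha", "excess_alpha", "study_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidInputError(f"{name} must be in (0,1), got {v}")
        if self.min_k_tests < 3:
            raise InvalidInputError(f"min_k_tests must be >= 3, got {self.min_k_tests}")
        if self.sensitivity_min_k < 1 or self.min_deaths < 0:
            raise InvalidInputError("sensitivity thresholds must be nonnegative")


@dataclass
class AuditResult:
    per_meta: pd.DataFrame
    area_summary: pd.DataFrame
    config: AuditConfig
    log: list[dict] = field(default_factory=list)


@dataclass
class RobisSummary:
    """Tidy judgment tallies: one row per (research_area, domain, judgment),
    with an ``overall`` aggregate area and an ``overall`` phase-3 domain."""

    table: pd.DataFrame

    def count(self, domain: str, judgment: str, area: str = "overall") -> int:
        t = self.table
        row = t[(t.research_area == area) & (t.domain == domain) & (t.judgment == judgment)]
        return int(row["count"].iloc[0]) if len(row) else 0

    def percent(self, domain: str, judgment: str, area: str = "overall") -> float:
        t = self.table
        row = t[(t.research_area == area) & (t.domain == domain) & (t.judgment == judgment)]
        return float(row["percent"].iloc[0]) if len(row) else float("nan")


def _pct(n: int, d: int) -> float:
    """Integer-rounded percentage (half away from zero); NaN for d = 0."""
    if d == 0:
        return float("nan")
    return float(math.floor(100.0 * n / d + 0.5))


def run_audit(corpus: Corpus, config: Optional[AuditConfig] = None) -> AuditResult:
    """Audit every meta-analysis in the corpus; deterministic.

    Meta-analyses with fewer than two studies are skipped, logged with a
    machine-readable reason, and excluded from every denominator.
    """
    if config is None:
        config = AuditConfig()
    if len(corpus) == 0:
        raise InvalidInputError("cannot audit an empty corpus")
    rows: list[dict] = []
    log: list[dict] = []
    for meta in corpus:
        if meta.k < 2:
            log.append({"event": "meta_excluded", "meta_id": meta.meta_id, "reason": "k_lt_2"})
            continue
        stats = meta.log_stats()
        pooled = pool_random_effects(stats)
        row = {
            "meta_id": meta.meta_id,
            "research_area": meta.research_area.value,
            "k": meta.k,
            "pooled_effect_ratio": math.exp(pooled.y_pooled),
            "ci_lower": math.exp(pooled.ci_lower),
            "ci_upper": math.exp(pooled.ci_upper),
            "p_value": pooled.p_value,
            "q": pooled.q_stat,
            "tau2": pooled.tau2,
            "i2": pooled.i2,
            "significant": pooled.p_value < POOLED_ALPHA,
        }
        # Egger small-study-effect test
        if meta.k < config.min_k_tests:
            row.update(egger_eligible=False, egger_reason="k_lt_min",
                       egger_intercept=math.nan, egger_intercept_se=math.nan,
                       egger_t=math.nan, egger_p=math.nan, egger_flag=False)
            log.append({"event": "egger_ineligible", "meta_id": meta.meta_id, "reason": "k_lt_min"})
        else:
            try:
                egger = egger_test(stats, config.egger_alpha)
                row.update(egger_eligible=True, egger_reason="",
                           egger_intercept=egger.intercept, egger_intercept_se=egger.intercept_se,
                           egger_t=egger.t_stat, egger_p=egger.p_two_sided, egger_flag=egger.flagged)
            except DegenerateDesignError:
                row.update(egger_eligible=False, egger_reason="degenerate_design",
                           egger_intercept=math.nan, egger_intercept_se=math.nan,
                           egger_t=math.nan, egger_p=math.nan, egger_flag=False)
                log.append({"event": "egger_ineligible", "meta_id": meta.meta_id,
                            "reason": "degenerate_design"})
        # excess-significance test
        if meta.k < config.min_k_tests:
            row.update(excess_eligible=False, excess_reason="k_lt_min",
                       O=pd.NA, E=math.nan, theta_star_ratio=math.nan,
                       chi2=math.nan, excess_p=math.nan, o_gt_e=False, excess_flag=False)
            log.append({"event": "excess_ineligible", "meta_id": meta.meta_id, "reason": "k_lt_min"})
        else:
            excess = excess_significance_test(
                stats, config.study_alpha, config.excess_alpha,
                direction_restricted=config.direction_restricted,
            )
            row.update(excess_eligible=True, excess_reason="",
                       O=excess.observed, E=excess.expected,
                       theta_star_ratio=math.exp(excess.theta_star),
                       chi2=excess.chi2, excess_p=excess.p_value,
                       o_gt_e=excess.o_gt_e, excess_flag=excess.flagged)
            if excess.expected_clamped:
                log.append({"event": "excess_expected_clamped", "meta_id": meta.meta_id,
                            "reason": "E_at_boundary"})
        rows.append(row)
    per_meta = pd.DataFrame(rows, columns=PER_META_COLUMNS)
    area_summary = tabulate_by_area(per_meta)
    return AuditResult(per_meta=per_meta, area_summary=area_summary, config=config, log=log)


def sensitivity_min_k(corpus: Corpus, min_k: int, log: Optional[list] = None) -> Corpus:
    """Retain meta-analyses with at least ``min_k`` studies; non-mutating."""
    if min_k < 1:
        raise InvalidInputError(f"min_k must be >= 1, got {min_k}")
    kept, dropped = [], []
    for meta in corpus:
        (kept if meta.k >= min_k else dropped).append(meta)
    if log is not None:
        for meta in dropped:
            log.append({"event": "meta_excluded", "meta_id": meta.meta_id,
                        "reason": f"k_lt_{min_k}", "filter": "sensitivity_min_k"})
    if not kept:
        warnings.warn(f"sensitivity filter min_k={min_k} removed every meta-analysis")
    return Corpus(metas=kept)


def sensitivity_exclude_small(corpus: Corpus, min_deaths: int, log: Optional[list] = None) -> Corpus:
    """Drop primary studies with a known death count below ``min_deaths``.

    Studies with a missing death count are retained (with a warning);
    meta-analyses left with fewer than two studies are dropped and logged.
    """
    if min_deaths < 0:
        raise InvalidInputError(f"min_deaths must be >= 0, got {min_deaths}")
    kept_metas = []
    for meta in corpus:
        kept_studies = []
        for s in meta.studies:
            if s.n_deaths is None:
                warnings.warn(
                    f"meta {meta.meta_id!r} study {s.study_id!r}: missing death count, "
                    f"retained despite the <{min_deaths}-deaths filter"
                )
                if log is not None:
                    log.append({"event": "study_kept_missing_deaths", "meta_id": meta.meta_id,
                                "study_id": s.study_id, "filter": "exclude_small"})
                kept_studies.append(s)
            elif s.n_deaths >= min_deaths:
                kept_studies.append(s)
            elif log is not None:
                log.append({"event": "study_excluded", "meta_id": meta.meta_id,
                            "study_id": s.study_id, "reason": f"deaths_lt_{min_deaths}",
                            "filter": "exclude_small"})
        if len(kept_studies) >= 2:
            kept_metas.append(
                MetaAnalysisRecord(
                    meta_id=meta.meta_id, research_area=meta.research_area,
                    exposure=meta.exposure, outcome=meta.outcome, studies=kept_studies,
                    metadata=dict(meta.metadata),
                )
            )
        else:
            if log is not None:
                log.append({"event": "meta_excluded", "meta_id": meta.meta_id,
                            "reason": "k_lt_2_after_exclude_small", "filter": "exclude_small"})
    if not kept_metas:
        warnings.warn(f"exclude-small filter (min_deaths={min_deaths}) removed every meta-analysis")
    return Corpus(metas=kept_metas)


def _summary_row(area: str, df: pd.DataFrame) -> dict:
    n_total = len(df)
    n_sig = int(df["significant"].sum())
    egger = df[df["egger_eligible"]]
    excess = df[df["excess_eligible"]]
    n_egger_eligible = len(egger)
    n_egger_flag = int(egger["egger_flag"].sum())
    n_excess_eligible = len(excess)
    n_o_gt_e = int(excess["o_gt_e"].sum())
    n_excess_flag = int(excess["excess_flag"].sum())
    return {
        "research_area": area,
        "n_total": n_total,
        "n_sig": n_sig,
        "pct_sig": _pct(n_sig, n_total),
        "n_egger_eligible": n_egger_eligible,
        "n_egger_flag": n_egger_flag,
        "pct_egger": _pct(n_egger_flag, n_egger_eligible),
        "n_excess_eligible": n_excess_eligible,
        "n_o_gt_e": n_o_gt_e,
        "pct_o_gt_e": _pct(n_o_gt_e, n_excess_eligible),
        "n_excess_flag": n_excess_flag,
        "pct_excess": _pct(n_excess_flag, n_excess_eligible),
        # the same flag count over the area total, the other base used in prose
        "pct_excess_total": _pct(n_excess_flag, n_total),
        "prop_sig": n_sig / n_total if n_total else math.nan,
        "prop_egger": n_egger_flag / n_egger_eligible if n_egger_eligible else math.nan,
        "prop_o_gt_e": n_o_gt_e / n_excess_eligible if n_excess_eligible else math.nan,
        "prop_excess": n_excess_flag / n_excess_eligible if n_excess_eligible else math.nan,
    }


def tabulate_by_area(per_meta: pd.DataFrame) -> pd.DataFrame:
    """One summary row per research area plus an ``overall`` row.

    Percent columns are integer-rounded; test percentages use the eligible
    count as denominator, the significance percentage uses the area total.
    Raw proportions are emitted alongside.
    """
    if len(per_meta) == 0:
        raise InvalidInputError("cannot tabulate empty per-meta results")
    unknown = set(per_meta["research_area"]) - set(_AREA_ORDER)
    if unknown:
        raise InvalidInputError(f"unknown research area label(s): {sorted(unknown)}")
    rows = [
        _summary_row(area, per_meta[per_meta["research_area"] == area])
        for area in _AREA_ORDER
        if (per_meta["research_area"] == area).any()
    ]
    rows.append(_summary_row("overall", per_meta))
    return pd.DataFrame(rows)


def robis_tabulate(assessments: Sequence[RobisAssessment]) -> RobisSummary:
    """Tally {low, high, unclear} per ROBIS domain, overall and per area.

    The phase-3 ``overall`` judgment is tallied only over reviews where it is
    recorded.  Percentages use the number of contributing reviews in the
    (area, domain) cell's area as denominator.
    """
    if len(assessments) == 0:
        raise InvalidInputError("no ROBIS assessments to tabulate")
    judgments = ["low", "high", "unclear"]
    domains = ["d1", "d2", "d3", "d4", "overall"]
    areas = ["overall"] + [
        a for a in _AREA_ORDER if any(x.research_area.value == a for x in assessments)
    ]
    rows = []
    for area in areas:
        subset = [
            x for x in assessments if area == "overall" or x.research_area.value == area
        ]
        for domain in domains:
            values = [
                getattr(x, domain) for x in subset
                if not (domain == "overall" and x.overall is None)
            ]
            denom = len(values)
            for j in judgments:
                n = sum(1 for v in values if v is not None and v.value == j)
                rows.append({
                    "research_area": area,
                    "domain": domain,
                    "judgment": j,
                    "count": n,
                    "n_reviews": denom,
                    "percent": _pct(n, denom),
                })
    return RobisSummary(table=pd.DataFrame(rows))


def write_report(
    result: AuditResult,
    out_dir: str | Path,
    robis_summary: Optional[RobisSummary] = None,
    seed: Optional[int] = None,
    extra_log: Optional[list] = None,
) -> dict[str, Path]:
    """Write per_meta.csv, area_summary.csv, robis_summary.csv and run_log.json.

    Output is deterministic: re-running on identical inputs produces
    byte-identical files (no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "per_meta": out / "per_meta.csv",
        "area_summary": out / "area_summary.csv",
        "robis_summary": out / "robis_summary.csv",
        "run_log": out / "run_log.json",
    }
    result.per_meta.to_csv(paths["per_meta"], index=False)
    result.area_summary.to_csv(paths["area_summary"], index=False)
    if robis_summary is not None:
        robis_summary.table.to_csv(paths["robis_summary"], index=False)
    else:
        pd.DataFrame(
            columns=["research_area", "domain", "judgment", "count", "n_reviews", "percent"]
        ).to_csv(paths["robis_summary"], index=False)
    run_log = {
        "package_version": _pkg_version,
        "config": asdict(result.config),
        "seed": seed,
        "pooling_model": "random-effects (DerSimonian-Laird), applied to every meta-analysis",
        "n_metas_audited": int(len(result.per_meta)),
        "events": list(result.log) + list(extra_log or []),
    }
    paths["run_log"].write_text(json.dumps(run_log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return paths
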