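"""Domain types and file I/O for meta-analytic corpora and ROBIS judgments.

A *corpus* is a collection of meta-analyses, each a list of primary studies
reporting a ratio-scale effect estimate (RR/OR/HR) with a 95% confidence
interval, participant and death counts.  All statistics downstream operate on
the natural-log scale: each study contributes a log effect ``y = ln(effect)``
and a standard error ``s`` back-calculated from its CI width.  Ratio measures
are treated identically on the log scale; no OR-to-RR conversion is attempted
because the source reviews pool whatever measure the primary studies report.

ROBIS judgments (four review-process domains plus an overall call, each
low/high/unclear risk of bias) are consumed as data produced by human
assessors; they are tallied, never computed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional

from scipy.stats import norm

from .errors import InvalidInputError, SchemaError

__all__ = [
    "ResearchArea",
    "Measure",
    "Judgment",
    "PrimaryStudy",
    "LogStats",
    "MetaAnalysisRecord",
    "Corpus",
    "RobisAssessment",
    "se_from_ci",
    "study_log_stats",
    "parse_corpus_csv",
    "write_corpus_csv",
    "parse_robis_csv",
    "write_robis_csv",
    "bundled_robis_path",
    "CORPUS_COLUMNS",
    "ROBIS_COLUMNS",
]

# Exact column names of the two CSV interfaces.
CORPUS_COLUMNS = [
    "meta_id", "research_area", "exposure", "outcome", "study_id",
    "effect", "ci_lower", "ci_upper", "measure", "n_participants", "n_deaths",
]
ROBIS_COLUMNS = ["review_id", "research_area", "d1", "d2", "d3", "d4", "overall"]

# Relative slack allowed when checking that the point estimate lies inside its
# published CI: tolerates rounding of effects/bounds to 2 decimals in print.
_CI_ROUNDING_SLACK = 0.01


class ResearchArea(str, Enum):
    physical_activity = "physical_activity"
    sedentary_behavior = "sedentary_behavior"
    alcohol = "alcohol"
    smoking = "smoking"
    diet = "diet"
    statin = "statin"


class Measure(str, Enum):
    RR = "RR"
    OR = "OR"
    HR = "HR"
    other = "other"


class Judgment(str, Enum):
    low = "low"
    high = "high"
    unclear = "unclear"


@lru_cache(maxsize=None)
def _z_quantile(level: float) -> float:
    # two-sided critical value; z = 1.959964 at the default 95% level
    return float(norm.ppf((1.0 + level) / 2.0))


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Back-calculate the log-scale standard error from a ratio-scale CI.

    ``s = (ln U - ln L) / (2 z)`` with ``z`` the standard-normal quantile at
    ``(1+level)/2``.  Symmetric on the log scale: ``se_from_ci(1/U, 1/L)``
    gives the same value.
    """
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"ci level must be in (0,1), got {level}")
    if lower <= 0.0 or upper <= 0.0:
        raise InvalidInputError(f"CI bounds must be positive, got ({lower}, {upper})")
    if lower >= upper:
        raise InvalidInputError(f"ci_lower must be < ci_upper, got ({lower}, {upper})")
    s = (math.log(upper) - math.log(lower)) / (2.0 * _z_quantile(level))
    if not math.isfinite(s) or s <= 0.0:
        raise InvalidInputError(f"degenerate standard error from CI ({lower}, {upper})")
    return s


@dataclass(frozen=True)
class LogStats:
    """A study's contribution on the analysis scale: log effect and its SE."""

    y: float
    s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.y) and math.isfinite(self.s)):
            raise InvalidInputError(f"log stats must be finite, got y={self.y}, s={self.s}")
        if self.s <= 0.0:
            raise InvalidInputError(f"standard error must be positive, got {self.s}")


@dataclass(frozen=True)
class PrimaryStudy:
    """One primary study's published ratio-scale result.

    ``n_participants``/``n_deaths`` may be ``None`` (missing); such studies are
    retained everywhere except the small-study sensitivity filter, where a
    missing death count keeps the study with a warning.
    """

    study_id: str
    effect_point: float
    ci_lower: float
    ci_upper: float
    ci_level: float = 0.95
    n_participants: Optional[int] = None
    n_deaths: Optional[int] = None
    measure: Measure = Measure.RR

    def __post_init__(self) -> None:
        if self.effect_point <= 0.0:
            raise InvalidInputError(
                f"study {self.study_id!r}: ratio-scale effect must be > 0, got {self.effect_point}"
            )
        if self.ci_lower <= 0.0 or self.ci_upper <= 0.0:
            raise InvalidInputError(
                f"study {self.study_id!r}: CI bounds must be > 0, got "
                f"({self.ci_lower}, {self.ci_upper})"
            )
        if self.ci_lower >= self.ci_upper:
            raise InvalidInputError(
                f"study {self.study_id!r}: ci_lower must be strictly < ci_upper, got "
                f"({self.ci_lower}, {self.ci_upper})"
            )
        if not (0.0 < self.ci_level < 1.0):
            raise InvalidInputError(
                f"study {self.study_id!r}: ci_level must be in (0,1), got {self.ci_level}"
            )
        # published rounding tolerance: widen bounds by 1% before containment check
        lo = self.ci_lower * (1.0 - _CI_ROUNDING_SLACK)
        hi = self.ci_upper * (1.0 + _CI_ROUNDING_SLACK)
        if not (lo <= self.effect_point <= hi):
            raise InvalidInputError(
                f"study {self.study_id!r}: effect {self.effect_point} outside CI "
                f"({self.ci_lower}, {self.ci_upper}) beyond rounding tolerance"
            )
        for name in ("n_participants", "n_deaths"):
            val = getattr(self, name)
            if val is not None and (not isinstance(val, int) or val < 0):
                raise InvalidInputError(
                    f"study {self.study_id!r}: {name} must be a nonnegative integer or missing, got {val!r}"
                )
        if not isinstance(self.measure, Measure):
            object.__setattr__(self, "measure", Measure(self.measure))


def study_log_stats(study: PrimaryStudy) -> LogStats:
    """Convert a published ratio-scale result to ``(y, s)`` on the log scale."""
    return LogStats(
        y=math.log(study.effect_point),
        s=se_from_ci(study.ci_lower, study.ci_upper, study.ci_level),
    )


@dataclass
class MetaAnalysisRecord:
    """A named exposure-outcome meta-analysis within a research area."""

    meta_id: str
    research_area: ResearchArea
    exposure: str
    outcome: str
    studies: list[PrimaryStudy]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.research_area, ResearchArea):
            self.research_area = ResearchArea(self.research_area)
        if len(self.studies) < 1:
            raise InvalidInputError(f"meta {self.meta_id!r}: at least one study required")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"meta {self.meta_id!r}: duplicate study_id(s) {dup}")

    @property
    def k(self) -> int:
        return len(self.studies)

    def log_stats(self) -> list[LogStats]:
        return [study_log_stats(s) for s in self.studies]


@dataclass
class Corpus:
    """An ordered collection of meta-analyses with unique identifiers."""

    metas: list[MetaAnalysisRecord]

    def __post_init__(self) -> None:
        ids = [m.meta_id for m in self.metas]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate meta_id(s) in corpus: {dup}")

    def __len__(self) -> int:
        return len(self.metas)

    def __iter__(self):
        return iter(self.metas)


@dataclass(frozen=True)
class RobisAssessment:
    """ROBIS phase-2 domain judgments plus the phase-3 overall call for one review.

    Domains: (1) study eligibility criteria, (2) identification and selection
    of studies, (3) data collection and study appraisal, (4) synthesis and
    findings.  ``overall`` may be missing when a source table prints only the
    four domain judgments.
    """

    review_id: str
    research_area: ResearchArea
    d1: Judgment
    d2: Judgment
    d3: Judgment
    d4: Judgment
    overall: Optional[Judgment] = None


# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_columns(fieldnames: Optional[Iterable[str]], required: list[str], path: Path) -> None:
    have = set(fieldnames or [])
    for col in required:
        if col not in have:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _opt_int(raw: str, *, where: str, name: str) -> Optional[int]:
    raw = (raw or "").strip()
    if raw == "" or raw.upper() in {"NA", "NAN", "NONE"}:
        return None
    try:
        val = int(float(raw))
    except ValueError as exc:
        raise InvalidInputError(f"{where}: {name} must be an integer, got {raw!r}") from exc
    return val


def parse_corpus_csv(path: str | Path) -> Corpus:
    """Read a per-study corpus CSV into a validated :class:`Corpus`.

    One :class:`MetaAnalysisRecord` per distinct ``meta_id``, studies kept in
    file order.  Raises :class:`SchemaError` for missing columns and a
    row-level :class:`InvalidInputError` (naming meta_id/study_id) for
    invariant violations.
    """
    path = Path(path)
    groups: dict[str, dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, CORPUS_COLUMNS, path)
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            meta_id = row["meta_id"].strip()
            study_id = row["study_id"].strip()
            where = f"{path} line {lineno} (meta {meta_id!r}, study {study_id!r})"
            try:
                study = PrimaryStudy(
                    study_id=study_id,
                    effect_point=float(row["effect"]),
                    ci_lower=float(row["ci_lower"]),
                    ci_upper=float(row["ci_upper"]),
                    n_participants=_opt_int(row["n_participants"], where=where, name="n_participants"),
                    n_deaths=_opt_int(row["n_deaths"], where=where, name="n_deaths"),
                    measure=Measure(row["measure"].strip() or "other"),
                )
            except (InvalidInputError, ValueError) as exc:
                raise InvalidInputError(f"{where}: {exc}") from exc
            grp = groups.setdefault(
                meta_id,
                {
                    "research_area": row["research_area"].strip(),
                    "exposure": row["exposure"].strip(),
                    "outcome": row["outcome"].strip(),
                    "studies": [],
                },
            )
            if any(s.study_id == study.study_id for s in grp["studies"]):
                raise InvalidInputError(f"{where}: duplicate study_id within meta_id")
            grp["studies"].append(study)
    if n_rows == 0:
        raise InvalidInputError(f"{path}: empty corpus (no data rows)")
    metas = []
    for meta_id, grp in groups.items():
        try:
            area = ResearchArea(grp["research_area"])
        except ValueError as exc:
            raise InvalidInputError(
                f"{path} meta {meta_id!r}: unknown research_area {grp['research_area']!r}"
            ) from exc
        metas.append(
            MetaAnalysisRecord(
                meta_id=meta_id,
                research_area=area,
                exposure=grp["exposure"],
                outcome=grp["outcome"],
                studies=grp["studies"],
            )
        )
    return Corpus(metas=metas)


def write_corpus_csv(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to the documented CSV schema (UTF-8, header row)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CORPUS_COLUMNS)
        for meta in corpus:
            for s in meta.studies:
                writer.writerow(
                    [
                        meta.meta_id,
                        meta.research_area.value,
                        meta.exposure,
                        meta.outcome,
                        s.study_id,
                        repr(s.effect_point),
                        repr(s.ci_lower),
                        repr(s.ci_upper),
                        s.measure.value,
                        "" if s.n_participants is None else s.n_participants,
                        "" if s.n_deaths is None else s.n_deaths,
                    ]
                )


def _normalize_judgment(token: str, *, where: str) -> Judgment:
    cleaned = token.strip().lower()
    for suffix in (" risk of bias", " risk"):
        if cleaned.endswith(suffix):
            cleaned = cleaned[: -len(suffix)].strip()
    try:
        return Judgment(cleaned)
    except ValueError as exc:
        raise InvalidInputError(f"{where}: unknown ROBIS judgment {token!r}") from exc


def parse_robis_csv(path: str | Path) -> list[RobisAssessment]:
    """Read ROBIS judgments; tokens are normalized case-insensitively and a
    trailing " risk"/" risk of bias" is tolerated.  ``overall`` may be blank."""
    path = Path(path)
    out: list[RobisAssessment] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ROBIS_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            review_id = row["review_id"].strip()
            where = f"{path} line {lineno} (review {review_id!r})"
            if review_id in seen:
                raise InvalidInputError(f"{where}: duplicate review_id")
            seen.add(review_id)
            try:
                area = ResearchArea(row["research_area"].strip())
            except ValueError as exc:
                raise InvalidInputError(
                    f"{where}: unknown research_area {row['research_area']!r}"
                ) from exc
            overall_raw = (row["overall"] or "").strip()
            out.append(
                RobisAssessment(
                    review_id=review_id,
                    research_area=area,
                    d1=_normalize_judgment(row["d1"], where=where),
                    d2=_normalize_judgment(row["d2"], where=where),
                    d3=_normalize_judgment(row["d3"], where=where),
                    d4=_normalize_judgment(row["d4"], where=where),
                    overall=_normalize_judgment(overall_raw, where=where) if overall_raw else None,
                )
            )
    return out


def write_robis_csv(assessments: list[RobisAssessment], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROBIS_COLUMNS)
        for a in assessments:
            writer.writerow(
                [
                    a.review_id,
                    a.research_area.value,
                    a.d1.value,
                    a.d2.value,
                    a.d3.value,
                    a.d4.value,
                    "" if a.overall is None else a.overall.value,
                ]
            )


def bundled_robis_path() -> Path:
    """Path to the packaged ROBIS judgments for the 49 systematic reviews of
    the behavior- and statin-mortality literatures (four domain judgments per
    review; no per-review overall judgment was published)."""
    return Path(__file__).parent / "data" / "robis_cvd_mortality_reviews.csv"
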