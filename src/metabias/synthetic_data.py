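"""Synthetic meta-analytic corpora with known truth and optional selective
publication, for exercising the audit pipeline and estimating the operating
characteristics of the two bias tests.

Generative model (normal-normal, matching the assumptions of the tests):

* study standard error ``s`` drawn log-uniform on ``(se_min, se_max)`` — a
  long-tailed study-size mix of the kind seen in funnel plots;
* study-level true effect ``θᵢ = θ + Normal(0, τ²)`` on the log scale;
* observed log effect ``y ~ Normal(θᵢ, s²)``, published as ``exp(y)`` with a
  95% CI ``exp(y ± z·s)``;
* file-drawer selection: a study with two-sided p < 0.05 is always published,
  otherwise it is published with probability ``p_publish_nonsig``;
* death counts are tied to precision by ``deaths = round(c/s²)`` so the
  small-study sensitivity filter is exercisable.

Defaults emulate a behavior-mortality literature: nine published studies per
meta-analysis, a modest protective effect (RR 0.8), moderate heterogeneity,
and no selection unless requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .bias_tests import egger_test, excess_significance_test
from .errors import InvalidInputError, SimulationExhaustedError
from .meta_engine import wald_p
from .study_data import (
    Corpus,
    Measure,
    MetaAnalysisRecord,
    PrimaryStudy,
    ResearchArea,
)

__all__ = ["SyntheticConfig", "OperatingCharacteristics", "simulate_study",
           "apply_selection", "generate_meta", "generate_corpus",
           "operating_characteristics"]

_CANDIDATE_CAP = 10**6
_Z95 = 1.959963984540054  # norm.ppf(0.975)


@dataclass(frozen=True)
class SyntheticConfig:
    """Truth and selection mechanism of a synthetic corpus.

    ``theta`` is the true common log effect, ``tau`` the between-study SD on
    the log scale, ``deaths_coef`` the constant c in deaths = round(c/se²),
    and ``p_publish_nonsig = 1`` means no selection.
    """

    theta: float = math.log(0.8)
    tau: float = 0.15
    k_published: int = 9
    se_range: tuple[float, float] = (0.05, 0.5)
    p_publish_nonsig: float = 1.0
    deaths_coef: float = 1.0
    participants_per_death: int = 25
    n_metas: int = 10
    research_area: ResearchArea = ResearchArea.diet
    seed: int = 0

    def __post_init__(self) -> None:
        se_min, se_max = self.se_range
        if not (0.0 < se_min < se_max):
            raise InvalidInputError(f"need 0 < se_min < se_max, got {self.se_range}")
        if self.tau < 0.0:
            raise InvalidInputError(f"tau must be >= 0, got {self.tau}")
        if self.k_published < 3:
            raise InvalidInputError(f"k_published must be >= 3, got {self.k_published}")
        if not (0.0 <= self.p_publish_nonsig <= 1.0):
            raise InvalidInputError(
                f"p_publish_nonsig must be in [0,1], got {self.p_publish_nonsig}"
            )
        if self.deaths_coef <= 0.0:
            raise InvalidInputError(f"deaths_coef must be > 0, got {self.deaths_coef}")
        if self.n_metas < 0:
            raise InvalidInputError(f"n_metas must be >= 0, got {self.n_metas}")
        if not isinstance(self.research_area, ResearchArea):
            object.__setattr__(self, "research_area", ResearchArea(self.research_area))


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo estimates of the bias tests' behavior under a config."""

    reps: int
    egger_flag_rate: float
    excess_flag_rate: float
    mean_O: float
    mean_E: float
    mc_se: dict = field(default_factory=dict)


def simulate_study(config: SyntheticConfig, stream: np.random.Generator,
                   study_id: str = "s1") -> PrimaryStudy:
    """Draw one published-scale primary study from the generative model."""
    se_min, se_max = config.se_range
    s = float(np.exp(stream.uniform(np.log(se_min), np.log(se_max))))
    theta_i = config.theta + (config.tau * float(stream.standard_normal()) if config.tau > 0 else 0.0)
    y = theta_i + s * float(stream.standard_normal())
    deaths = int(round(config.deaths_coef / s**2))
    return PrimaryStudy(
        study_id=study_id,
        effect_point=math.exp(y),
        ci_lower=math.exp(y - _Z95 * s),
        ci_upper=math.exp(y + _Z95 * s),
        n_participants=deaths * config.participants_per_death,
        n_deaths=deaths,
        measure=Measure.RR,
    )


def apply_selection(p_two_sided: float, config: SyntheticConfig,
                    stream: np.random.Generator) -> bool:
    """File-drawer rule: significant results always publish; others with
    probability ``p_publish_nonsig``."""
    if not (0.0 <= p_two_sided <= 1.0):
        raise InvalidInputError(f"p-value must be in [0,1], got {p_two_sided}")
    if p_two_sided < 0.05:
        return True
    if config.p_publish_nonsig >= 1.0:
        return True
    return bool(stream.random() < config.p_publish_nonsig)


def generate_meta(config: SyntheticConfig, stream: np.random.Generator,
                  meta_id: str = "meta1") -> MetaAnalysisRecord:
    """Draw candidate studies until ``k_published`` survive selection.

    The number of suppressed candidates is recorded in the record's
    ``metadata``; generation aborts after one million candidates when
    selection is too severe.
    """
    published: list[PrimaryStudy] = []
    suppressed = 0
    candidates = 0
    while len(published) < config.k_published:
        candidates += 1
        if candidates > _CANDIDATE_CAP:
            raise SimulationExhaustedError(
                f"selection too severe: {_CANDIDATE_CAP} candidates produced only "
                f"{len(published)}/{config.k_published} published studies"
            )
        study = simulate_study(config, stream, study_id=f"{meta_id}_s{candidates}")
        y = math.log(study.effect_point)
        s = (math.log(study.ci_upper) - math.log(study.ci_lower)) / (2.0 * _Z95)
        if apply_selection(wald_p(y, s), config, stream):
            published.append(study)
        else:
            suppressed += 1
    return MetaAnalysisRecord(
        meta_id=meta_id,
        research_area=config.research_area,
        exposure="synthetic exposure",
        outcome="all-cause mortality",
        studies=published,
        metadata={"suppressed_candidates": suppressed},
    )


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(ss)) for ss in np.random.SeedSequence(seed).spawn(n)]


def generate_corpus(config: SyntheticConfig) -> Corpus:
    """``n_metas`` independent meta-analyses from per-meta substreams of the
    config seed; reproducible and order-independent."""
    if config.n_metas == 0:
        raise InvalidInputError("cannot generate an empty corpus (n_metas = 0)")
    streams = _substreams(config.seed, config.n_metas)
    metas = [
        generate_meta(config, stream, meta_id=f"{config.research_area.value}_m{i + 1:03d}")
        for i, stream in enumerate(streams)
    ]
    return Corpus(metas=metas)


def operating_characteristics(config: SyntheticConfig, reps: int,
                              seed: Optional[int] = None) -> OperatingCharacteristics:
    """Estimate flag rates and O/E calibration over ``reps`` simulated metas.

    Uses the config's seed unless ``seed`` overrides it.  Monte-Carlo standard
    errors: sqrt(r(1-r)/reps) for rates, sd/sqrt(reps) for means.
    """
    if reps < 100:
        raise InvalidInputError(f"reps must be >= 100 for stable estimates, got {reps}")
    base = replace(config, seed=config.seed if seed is None else seed)
    streams = _substreams(base.seed, reps)
    egger_flags = np.zeros(reps, dtype=bool)
    excess_flags = np.zeros(reps, dtype=bool)
    obs = np.zeros(reps)
    exp_ = np.zeros(reps)
    for i, stream in enumerate(streams):
        meta = generate_meta(base, stream, meta_id=f"oc_m{i + 1}")
        stats = meta.log_stats()
        egger_flags[i] = egger_test(stats).flagged
        res = excess_significance_test(stats)
        excess_flags[i] = res.flagged
        obs[i] = res.observed
        exp_[i] = res.expected
    r_egger = float(egger_flags.mean())
    r_excess = float(excess_flags.mean())
    return OperatingCharacteristics(
        reps=reps,
        egger_flag_rate=r_egger,
        excess_flag_rate=r_excess,
        mean_O=float(obs.mean()),
        mean_E=float(exp_.mean()),
        mc_se={
            "egger_flag_rate": math.sqrt(r_egger * (1.0 - r_egger) / reps),
            "excess_flag_rate": math.sqrt(r_excess * (1.0 - r_excess) / reps),
            "mean_O": float(obs.std(ddof=1) / math.sqrt(reps)),
            "mean_E": float(exp_.std(ddof=1) / math.sqrt(reps)),
        },
    )
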