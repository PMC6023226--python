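import numpy as np
import pytest

from metabias import LogStats, MetaAnalysisRecord, PrimaryStudy, ResearchArea


def make_study(study_id="s1", effect=1.5, lo=1.1, hi=2.05, deaths=300, participants=5000):
    return PrimaryStudy(
        study_id=study_id,
        effect_point=effect,
        ci_lower=lo,
        ci_upper=hi,
        n_participants=participants,
        n_deaths=deaths,
    )


def random_log_stats(rng: np.random.Generator, k: int, theta_sd: float = 0.3):
    """A random meta-analysis on the log scale: heterogeneous effects,
    log-uniform standard errors."""
    s = np.exp(rng.uniform(np.log(0.05), np.log(0.5), k))
    theta = rng.normal(0.0, theta_sd)
    y = rng.normal(theta, s)
    return [LogStats(float(yy), float(ss)) for yy, ss in zip(y, s)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def five_study_meta():
    studies = [
        make_study("s1", 0.80, 0.70, 0.92, deaths=800),
        make_study("s2", 0.75, 0.60, 0.94, deaths=250),
        make_study("s3", 0.90, 0.70, 1.15, deaths=150),
        make_study("s4", 0.60, 0.40, 0.90, deaths=60),
        make_study("s5", 0.85, 0.74, 0.98, deaths=1200),
    ]
    return MetaAnalysisRecord(
        meta_id="pa_walking_acm",
        research_area=ResearchArea.physical_activity,
        exposure="walking",
        outcome="all-cause mortality",
        studies=studies,
    )
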