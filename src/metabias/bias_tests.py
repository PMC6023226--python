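"""Reporting-bias statistics: Egger small-study-effect regression and the
excess-significance test.

The Egger test regresses each study's standardized effect ``tᵢ = yᵢ/sᵢ`` on
its precision ``1/sᵢ`` by ordinary least squares and asks whether the
intercept differs from zero (t reference with k−2 degrees of freedom);
p < 0.10 two-sided flags a small-study effect.

The excess-significance test compares the observed number of nominally
significant primary studies O against the expected number E = Σ powerᵢ, where
each study's power is computed for a two-sided α = 0.05 Wald test under a
plausible true effect θ* — taken as the effect of the most precise study in
the meta-analysis.  O vs E is referred to a chi-square with 1 df; bias is
flagged only when O > E with one-sided p < 0.05 (two-sided p < 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .errors import DegenerateDesignError, InsufficientStudiesError, InvalidInputError
from .meta_engine import wald_p
from .study_data import LogStats

__all__ = [
    "EggerResult",
    "ExcessResult",
    "egger_test",
    "plausible_effect",
    "study_power",
    "observed_significant",
    "excess_significance_test",
]

EGGER_ALPHA = 0.10
EXCESS_ALPHA_TWO_SIDED = 0.10
STUDY_ALPHA = 0.05
MIN_K = 3
# relative clamp keeping the chi-square finite when E hits 0 or k exactly
_E_CLAMP = 1e-9


@dataclass(frozen=True)
class EggerResult:
    k: int
    intercept: float
    intercept_se: float
    t_stat: float
    df: int
    p_two_sided: float
    flagged: bool


@dataclass(frozen=True)
class ExcessResult:
    k: int
    observed: int
    expected: float
    theta_star: float
    powers: tuple[float, ...]
    chi2: float
    p_value: float
    o_gt_e: bool
    flagged: bool
    expected_clamped: bool = False


def egger_test(log_stats: Sequence[LogStats], alpha: float = EGGER_ALPHA) -> EggerResult:
    """Egger regression asymmetry test.

    Raises :class:`InsufficientStudiesError` for k < 3 (the caller records the
    meta-analysis as ineligible) and :class:`DegenerateDesignError` when all
    standard errors coincide, which makes the precision regressor constant.
    """
    k = len(log_stats)
    if k < MIN_K:
        raise InsufficientStudiesError(f"Egger test requires k >= {MIN_K} studies, got {k}")
    y = np.array([ls.y for ls in log_stats], dtype=float)
    s = np.array([ls.s for ls in log_stats], dtype=float)
    t = y / s
    x = 1.0 / s
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("all standard errors identical: precision regressor is constant")
    design = np.column_stack([np.ones(k), x])
    fit = sm.OLS(t, design).fit()
    intercept = float(fit.params[0])
    intercept_se = float(fit.bse[0])
    t_stat = float(fit.tvalues[0])
    p = float(fit.pvalues[0])  # two-sided t with k-2 df
    return EggerResult(
        k=k,
        intercept=intercept,
        intercept_se=intercept_se,
        t_stat=t_stat,
        df=k - 2,
        p_two_sided=p,
        flagged=bool(p < alpha),
    )


def plausible_effect(log_stats: Sequence[LogStats]) -> float:
    """θ*: the log effect of the most precise study (smallest sᵢ).

    Ties on sᵢ break toward the effect closest to the null (smallest |yᵢ|),
    then toward input order — the conservative choice for power.
    """
    if len(log_stats) == 0:
        raise InvalidInputError("plausible effect undefined for an empty meta-analysis")
    best = min(enumerate(log_stats), key=lambda item: (item[1].s, abs(item[1].y), item[0]))
    return best[1].y


def study_power(s: float, theta_star: float, alpha: float = STUDY_ALPHA) -> float:
    """Power of the two-sided level-α Wald test for one study under θ*.

    1 − Φ(z_{1−α/2} − |θ*|/s) + Φ(−z_{1−α/2} − |θ*|/s); equals α at θ* = 0 and
    increases monotonically in |θ*|/s toward 1.
    """
    if s <= 0.0:
        raise InvalidInputError(f"standard error must be positive, got {s}")
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must be in (0,1), got {alpha}")
    z = norm.ppf(1.0 - alpha / 2.0)
    lam = abs(theta_star) / s
    return float(norm.sf(z - lam) + norm.cdf(-z - lam))


def observed_significant(
    log_stats: Sequence[LogStats],
    alpha: float = STUDY_ALPHA,
    *,
    theta_star: float | None = None,
    direction_restricted: bool = False,
) -> int:
    """Count studies with two-sided Wald p strictly below ``alpha``.

    With ``direction_restricted`` a study only counts when its effect lies in
    the direction of ``theta_star`` (either direction when θ* = 0).
    """
    if len(log_stats) == 0:
        raise InvalidInputError("observed count undefined for an empty meta-analysis")
    count = 0
    for ls in log_stats:
        if wald_p(ls.y, ls.s) >= alpha:
            continue
        if direction_restricted and theta_star is not None and theta_star != 0.0:
            if ls.y * theta_star <= 0.0:
                continue
        count += 1
    return count


def excess_significance_test(
    log_stats: Sequence[LogStats],
    alpha_study: float = STUDY_ALPHA,
    alpha_test: float = EXCESS_ALPHA_TWO_SIDED,
    *,
    direction_restricted: bool = False,
) -> ExcessResult:
    """Excess-significance test: does O exceed E = Σ powers under θ*?

    χ² = (O−E)²/E + (O−E)²/(k−E) on 1 df gives the two-sided p; the flag
    requires both O > E and two-sided p < ``alpha_test`` (equivalently a
    one-sided p < ``alpha_test``/2).  Degenerate E (0 or k) is clamped just
    inside (0, k) so the statistic stays finite; the result records the clamp.
    """
    k = len(log_stats)
    if k < MIN_K:
        raise InsufficientStudiesError(
            f"excess-significance test requires k >= {MIN_K} studies, got {k}"
        )
    theta_star = plausible_effect(log_stats)
    powers = tuple(study_power(ls.s, theta_star, alpha_study) for ls in log_stats)
    expected = float(sum(powers))
    observed = observed_significant(
        log_stats, alpha_study, theta_star=theta_star, direction_restricted=direction_restricted
    )
    clamped = False
    e_for_chi2 = expected
    lo, hi = k * _E_CLAMP, k * (1.0 - _E_CLAMP)
    if not (lo <= e_for_chi2 <= hi):
        e_for_chi2 = min(max(e_for_chi2, lo), hi)
        clamped = True
    diff = observed - e_for_chi2
    chi2 = diff**2 / e_for_chi2 + diff**2 / (k - e_for_chi2)
    p_two = float(chi2_dist.sf(chi2, df=1))
    o_gt_e = observed > expected
    return ExcessResult(
        k=k,
        observed=observed,
        expected=expected,
        theta_star=theta_star,
        powers=powers,
        chi2=float(chi2),
        p_value=p_two,
        o_gt_e=o_gt_e,
        flagged=bool(o_gt_e and p_two < alpha_test),
        expected_clamped=clamped,
    )
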