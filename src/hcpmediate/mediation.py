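"""2-1-1 multilevel mediation and the two healthy-context-paradox tests.

Three model specifications on a cluster-randomised trial with a
cluster-level binary treatment T, an individual-level mediator m and an
individual-level outcome y:

* **Baseline** — mediator equation: random-intercept model of m on T
  (treatment effect ``a``); outcome equation: random-intercept model of y
  on the uncentred m (within/individual path ``b_w``), the observed
  cluster mean of m (contextual path ``b_b``) and T (direct path ``c'``).
  The total indirect effect is ``a * (b_w + b_b)``, splitting into an
  individual component ``a * b_w`` and a contextual component ``a * b_b``.
* **Test 1 (contextual moderation)** — the outcome equation gains a
  T x cluster-mean-mediator interaction.  A significant interaction whose
  sign strengthens the adverse mediator-outcome link under treatment is
  evidence of a healthy context paradox operating between clusters.
* **Test 2 (individual moderation)** — the mediator is cluster-mean
  centred; the within-cluster deviation gets a cluster random slope, and
  the slope is regressed on treatment (implemented as a fixed
  T x deviation product ``d`` plus random-slope variance and
  slope-intercept covariance).  The deviation's main coefficient is the
  control-arm within-cluster slope, and the cluster-mean coefficient now
  approximates the SUM of the individual and contextual paths.

The mediator and outcome equations are fitted as two separate mixed models
and combined; the a-path and the b-paths are treated as independent in the
delta method (asymptotically justified for correctly specified Gaussian
models, and documented as an approximation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace as dataclasses_replace

import numpy as np
from scipy import stats

from .data import TrialDataset, center_within_cluster, add_cluster_means
from .lmm import (
    COV_INT_SLOPE,
    VAR_SLOPE,
    FitResult,
    MixedModelSpec,
    WaldResult,
    fit_lmm,
    wald_test,
)

TERM_T = "treatment"
TERM_M = "mediator"
TERM_MBAR = "mediator_cluster_mean"
TERM_DEV = "mediator_dev"
TERM_T_X_MBAR = f"{TERM_T}:{TERM_MBAR}"
TERM_T_X_DEV = f"{TERM_T}:{TERM_DEV}"

PARADOX_SUPPORTED = "paradox_supported"
OPPOSITE_DIRECTION = "opposite_direction"
NOT_SUPPORTED = "not_supported"


@dataclass(frozen=True)
class AnalysisSettings:
    """Knobs shared by the mediation fits.

    alpha : two-sided significance level for all tests.
    mc_draws : draws for the Monte-Carlo indirect-effect intervals.
    seed : seed for those draws (None leaves them out).
    """

    alpha: float = 0.05
    mc_draws: int = 10_000
    seed: int | None = 0


@dataclass(frozen=True)
class PathEstimate:
    estimate: float
    se: float
    p_value: float

    def to_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class IndirectEffect:
    estimate: float
    se: float  # delta method
    ci_delta: tuple[float, float]
    ci_monte_carlo: tuple[float, float] | None

    def to_dict(self):
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_delta": list(self.ci_delta),
            "ci_monte_carlo": (
                None if self.ci_monte_carlo is None else list(self.ci_monte_carlo)
            ),
        }


@dataclass(frozen=True)
class MediationResult:
    """Decomposed 2-1-1 mediation fit."""

    a_path: PathEstimate
    b_within: PathEstimate
    b_between: PathEstimate
    c_prime: PathEstimate
    indirect_within: IndirectEffect
    indirect_contextual: IndirectEffect
    indirect_total: IndirectEffect
    mediator_screen_pass: bool
    mediator_fit: FitResult
    outcome_fit: FitResult
    settings: AnalysisSettings

    @property
    def screen_note(self) -> str:
        if self.mediator_screen_pass:
            return (
                "treatment-mediator path is significant: the candidate "
                "mediator warrants consideration"
            )
        return (
            "treatment-mediator path is NOT significant "
            f"(p={self.a_path.p_value:.3f}): the candidate mediator should "
            "not be considered further; Tests 1 and 2 are still reported"
        )

    def to_dict(self) -> dict:
        return {
            "a_path": self.a_path.to_dict(),
            "b_within": self.b_within.to_dict(),
            "b_between": self.b_between.to_dict(),
            "c_prime": self.c_prime.to_dict(),
            "indirect_within": self.indirect_within.to_dict(),
            "indirect_contextual": self.indirect_contextual.to_dict(),
            "indirect_total": self.indirect_total.to_dict(),
            "mediator_screen": {
                "pass": self.mediator_screen_pass,
                "p_value": self.a_path.p_value,
                "note": self.screen_note,
            },
        }


@dataclass(frozen=True)
class HcpTestResult:
    """Outcome of Test 1 (contextual) or Test 2 (individual)."""

    level: str  # "contextual" | "individual"
    moderation: PathEstimate
    moderation_term: str
    wald_vs_baseline: WaldResult
    classification: str
    direction_note: str
    fit: FitResult
    wald_vs_reduced: WaldResult | None = None
    control_arm_slope: PathEstimate | None = None
    between_coefficient: PathEstimate | None = None
    caveats: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        out = {
            "level": self.level,
            "moderation_term": self.moderation_term,
            "moderation": self.moderation.to_dict(),
            "wald_vs_baseline": self.wald_vs_baseline.to_dict(),
            "classification": self.classification,
            "direction_note": self.direction_note,
            "caveats": list(self.caveats),
        }
        if self.wald_vs_reduced is not None:
            out["wald_vs_reduced"] = self.wald_vs_reduced.to_dict()
        if self.control_arm_slope is not None:
            out["control_arm_slope"] = self.control_arm_slope.to_dict()
        if self.between_coefficient is not None:
            out["between_coefficient"] = self.between_coefficient.to_dict()
        return out


# -- classification ---------------------------------------------------------


def paradox_sign(mediator_higher_is_worse: bool, outcome_higher_is_better: bool) -> int:
    """Sign of a moderation estimate consistent with the paradox.

    The paradox requires the treatment to STRENGTHEN the adverse
    mediator-outcome association.  With a higher-is-worse mediator and a
    higher-is-better outcome the adverse association is negative, so a
    paradox-consistent moderation is negative; flipping exactly one
    direction flag flips the sign.
    """
    return -1 if mediator_higher_is_worse == outcome_higher_is_better else 1


def classify_hcp(
    estimate: float,
    p_value: float,
    *,
    mediator_higher_is_worse: bool = True,
    outcome_higher_is_better: bool = True,
    alpha: float = 0.05,
) -> tuple[str, str]:
    """Directional classification of a moderation estimate.

    Returns ``(classification, direction_note)`` where classification is
    ``paradox_supported`` (significant, paradox-consistent sign),
    ``opposite_direction`` (significant, protective sign) or
    ``not_supported``.
    """
    sign = paradox_sign(mediator_higher_is_worse, outcome_higher_is_better)
    adverse = "negative" if sign < 0 else "positive"
    if p_value < alpha and estimate != 0 and np.sign(estimate) == sign:
        return (
            PARADOX_SUPPORTED,
            f"significant moderation with the paradox-consistent ({adverse}) "
            "sign: the treatment strengthens the adverse mediator-outcome "
            "association",
        )
    if p_value < alpha and estimate != 0:
        return (
            OPPOSITE_DIRECTION,
            "significant moderation with the opposite sign: the treatment "
            "WEAKENS the adverse mediator-outcome association (an enhanced "
            "benefit, not a paradox)",
        )
    if estimate != 0 and np.sign(estimate) == sign:
        note = (
            "not significant; the point estimate has the paradox-consistent "
            f"({adverse}) sign but the data do not support the paradox"
        )
    else:
        note = (
            "not significant; the point estimate's sign would, if anything, "
            "indicate an enhanced benefit where the mediator remains high"
        )
    return NOT_SUPPORTED, note


# -- indirect-effect assembly ------------------------------------------------


def _indirect(a, var_a, b, var_b, alpha, rng, draws_a, draws_b):
    """Delta-method and Monte-Carlo interval for the product a*b."""
    est = a * b
    var = b * b * var_a + a * a * var_b
    se = float(np.sqrt(max(var, 0.0)))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    ci_delta = (est - zcrit * se, est + zcrit * se)
    ci_mc = None
    if rng is not None:
        prod = draws_a * draws_b
        lo, hi = np.quantile(prod, [alpha / 2, 1 - alpha / 2])
        ci_mc = (float(lo), float(hi))
    return IndirectEffect(float(est), se, ci_delta, ci_mc)


def _path(fit: FitResult, term: str) -> PathEstimate:
    return PathEstimate(fit.estimate(term), fit.se(term), fit.z_p_value(term))


# -- model fits --------------------------------------------------------------


def fit_baseline_mediation(
    data: TrialDataset, settings: AnalysisSettings | None = None
) -> MediationResult:
    """Fit the baseline 2-1-1 mediation model.

    Mediator equation: ``m ~ T`` with a cluster random intercept.  Outcome
    equation: ``y ~ T + m + mean_j(m)`` with a cluster random intercept;
    the cluster-mean coefficient is the contextual effect in this
    uncentred formulation.
    """
    settings = settings or AnalysisSettings()
    if float(np.var(data.df[TERM_M])) == 0.0:
        raise ValueError("mediator is degenerate (zero variance)")
    work = add_cluster_means(data, TERM_M)

    med_fit = fit_lmm(MixedModelSpec("mediator", (TERM_T,)), work)
    out_fit = fit_lmm(
        MixedModelSpec("outcome", (TERM_T, TERM_M, TERM_MBAR)), work
    )

    a = _path(med_fit, TERM_T)
    b_w = _path(out_fit, TERM_M)
    b_b = _path(out_fit, TERM_MBAR)
    c_prime = _path(out_fit, TERM_T)

    # joint covariance of (b_w, b_b) from the outcome fit; a independent
    bcov = out_fit.cov_block([TERM_M, TERM_MBAR])
    rng = (
        np.random.default_rng(settings.seed) if settings.seed is not None else None
    )
    if rng is not None:
        draws_a = rng.normal(a.estimate, a.se, settings.mc_draws)
        draws_b = rng.multivariate_normal(
            [b_w.estimate, b_b.estimate], bcov, settings.mc_draws
        )
    else:
        draws_a = draws_b = None

    def col(i):
        return None if draws_b is None else draws_b[:, i]

    ind_w = _indirect(
        a.estimate, a.se**2, b_w.estimate, bcov[0, 0], settings.alpha,
        rng, draws_a, col(0),
    )
    ind_c = _indirect(
        a.estimate, a.se**2, b_b.estimate, bcov[1, 1], settings.alpha,
        rng, draws_a, col(1),
    )
    b_sum_var = float(bcov.sum())
    ind_t = _indirect(
        a.estimate, a.se**2, b_w.estimate + b_b.estimate, b_sum_var,
        settings.alpha, rng, draws_a,
        None if draws_b is None else draws_b.sum(axis=1),
    )
    # the decomposition is additive by definition; enforce it exactly
    ind_t = dataclasses_replace(
        ind_t, estimate=ind_w.estimate + ind_c.estimate
    )

    return MediationResult(
        a_path=a,
        b_within=b_w,
        b_between=b_b,
        c_prime=c_prime,
        indirect_within=ind_w,
        indirect_contextual=ind_c,
        indirect_total=ind_t,
        mediator_screen_pass=bool(a.p_value < settings.alpha),
        mediator_fit=med_fit,
        outcome_fit=out_fit,
        settings=settings,
    )


def fit_test1(
    data: TrialDataset, settings: AnalysisSettings | None = None
) -> HcpTestResult:
    """Contextual-moderation test (Test 1).

    Augments the baseline outcome equation with the product of treatment
    and the cluster-mean mediator; the Wald comparison against the
    baseline constrains that single parameter (df = 1).
    """
    settings = settings or AnalysisSettings()
    work = add_cluster_means(data, TERM_M)
    fit = fit_lmm(
        MixedModelSpec(
            "outcome", (TERM_T, TERM_M, TERM_MBAR, TERM_T_X_MBAR)
        ),
        work,
    )
    moderation = _path(fit, TERM_T_X_MBAR)
    wald = wald_test(fit, [TERM_T_X_MBAR])
    classification, note = classify_hcp(
        moderation.estimate,
        moderation.p_value,
        mediator_higher_is_worse=data.mediator_higher_is_worse,
        outcome_higher_is_better=data.outcome_higher_is_better,
        alpha=settings.alpha,
    )
    return HcpTestResult(
        level="contextual",
        moderation=moderation,
        moderation_term=TERM_T_X_MBAR,
        wald_vs_baseline=wald,
        classification=classification,
        direction_note=note,
        fit=fit,
        between_coefficient=_path(fit, TERM_MBAR),
        caveats=fit.caveats,
    )


def fit_test2(
    data: TrialDataset, settings: AnalysisSettings | None = None
) -> HcpTestResult:
    """Individual-moderation test (Test 2).

    Cluster-mean centres the mediator, gives the within-cluster deviation a
    cluster random slope (covarying with the random intercept) and
    regresses that slope on treatment — i.e. adds a fixed
    treatment x deviation product ``d``.  Wald comparisons: against the
    baseline (constraining d, the slope variance and the slope-intercept
    covariance; df = 3) and against the reduced model that keeps only the
    slope variance (constraining d and the covariance; df = 2).
    """
    settings = settings or AnalysisSettings()
    work = center_within_cluster(data, TERM_M)
    fit = fit_lmm(
        MixedModelSpec(
            "outcome",
            (TERM_T, TERM_DEV, TERM_MBAR, TERM_T_X_DEV),
            random_slope=TERM_DEV,
            slope_cov=True,
        ),
        work,
    )
    moderation = _path(fit, TERM_T_X_DEV)
    wald_baseline = wald_test(fit, [TERM_T_X_DEV, VAR_SLOPE, COV_INT_SLOPE])
    wald_reduced = wald_test(fit, [TERM_T_X_DEV, COV_INT_SLOPE])
    classification, note = classify_hcp(
        moderation.estimate,
        moderation.p_value,
        mediator_higher_is_worse=data.mediator_higher_is_worse,
        outcome_higher_is_better=data.outcome_higher_is_better,
        alpha=settings.alpha,
    )
    return HcpTestResult(
        level="individual",
        moderation=moderation,
        moderation_term=TERM_T_X_DEV,
        wald_vs_baseline=wald_baseline,
        wald_vs_reduced=wald_reduced,
        classification=classification,
        direction_note=note,
        fit=fit,
        control_arm_slope=_path(fit, TERM_DEV),
        between_coefficient=_path(fit, TERM_MBAR),
        caveats=fit.caveats,
    )


# -- reporting ---------------------------------------------------------------


def analysis_report(
    baseline: MediationResult, test1: HcpTestResult, test2: HcpTestResult
) -> dict:
    """Combined JSON-ready report for one dataset."""
    return {
        "baseline": baseline.to_dict(),
        "test1_contextual": test1.to_dict(),
        "test2_individual": test2.to_dict(),
    }


def format_text_summary(
    baseline: MediationResult, test1: HcpTestResult, test2: HcpTestResult
) -> str:
    """Human-readable summary mirroring the JSON report."""

    def pe(p: PathEstimate) -> str:
        return f"{p.estimate:+.3f} (SE {p.se:.3f}, p={p.p_value:.3f})"

    def wald(w: WaldResult) -> str:
        s = f"chi2={w.statistic:.2f}, df={w.df}, p={w.p_value:.3f}"
        if w.caveats:
            s += "  [caveat: " + "; ".join(w.caveats) + "]"
        return s

    lines = [
        "Healthy context paradox analysis",
        "================================",
        "",
        "Baseline 2-1-1 mediation",
        f"  a (treatment -> mediator):        {pe(baseline.a_path)}",
        f"  b_w (individual mediator path):   {pe(baseline.b_within)}",
        f"  b_b (contextual mediator path):   {pe(baseline.b_between)}",
        f"  c' (direct treatment path):       {pe(baseline.c_prime)}",
        f"  indirect (individual):  {baseline.indirect_within.estimate:+.4f}",
        f"  indirect (contextual):  {baseline.indirect_contextual.estimate:+.4f}",
        f"  indirect (total):       {baseline.indirect_total.estimate:+.4f}"
        + (
            "  MC {:.0%} CI ({:+.4f}, {:+.4f})".format(
                1 - baseline.settings.alpha, *baseline.indirect_total.ci_monte_carlo
            )
            if baseline.indirect_total.ci_monte_carlo is not None
            else ""
        ),
        f"  Mediator screen: {'PASS' if baseline.mediator_screen_pass else 'WARN'}"
        f" - {baseline.screen_note}",
        "",
        "Test 1 - contextual moderation (treatment x cluster-mean mediator)",
        f"  moderation: {pe(test1.moderation)}",
        f"  Wald vs baseline: {wald(test1.wald_vs_baseline)}",
        f"  classification: {test1.classification}",
        f"  note: {test1.direction_note}",
        "",
        "Test 2 - individual moderation (random slope regressed on treatment)",
        f"  moderation d: {pe(test2.moderation)}",
        f"  control-arm within slope: {pe(test2.control_arm_slope)}",
        f"  between coefficient (~ b_w + b_b): {pe(test2.between_coefficient)}",
        f"  Wald vs baseline: {wald(test2.wald_vs_baseline)}",
        f"  Wald vs reduced (slope variance kept): {wald(test2.wald_vs_reduced)}",
        f"  classification: {test2.classification}",
        f"  note: {test2.direction_note}",
    ]
    return "\n".join(lines)
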