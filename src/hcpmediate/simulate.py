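"""Synthetic two-level cluster-randomised trial generator.

The generative model mirrors the analysis models, with a clean
within/between separation built on the LATENT cluster mediator mean:

    T_j        ~ balanced allocation over J clusters
    mu_Mj      = alpha0 + a * T_j + u^M_j,        u^M_j ~ N(0, tau2_M)
    m_ij       = mu_Mj + e^M_ij,                  e^M_ij ~ N(0, sigma2_M)
    y_ij       = beta0 + c' T_j
                 + (b_b + b_w + gamma_B * T_j) * mu_Mj
                 + (b_w + d * T_j + s_j) * (m_ij - mu_Mj)
                 + u^Y_j + e^Y_ij

with (u^Y_j, s_j) jointly normal (variances tau2_0, tau2_1, covariance
tau_01) and e^Y_ij ~ N(0, sigma2).  ``gamma_B`` plants a contextual
(between-level) healthy-context-paradox effect; ``d`` plants an
individual-level one.

Generation uses the latent mean mu_Mj while estimation uses the observed
cluster mean, so between-level coefficient estimates are mildly attenuated
at finite cluster size (reliability tau2_M / (tau2_M + sigma2_M/n_j)).

Default parameter values emulate a school trial of ~40 schools x ~150
students with a bullying-victimisation mediator (higher = worse) and a
mental-wellbeing outcome (higher = better).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import TrialDataset
from .mediation import (
    AnalysisSettings,
    PARADOX_SUPPORTED,
    fit_test1,
    fit_test2,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationScenario:
    """Generative parameters for a two-level trial.

    Cluster sizes are constant (``n_per_cluster``) unless ``n_range`` is
    given, in which case sizes are drawn uniformly from the inclusive
    integer range.
    """

    # design
    J: int = 40
    n_per_cluster: int = 150
    n_range: tuple[int, int] | None = None
    allocation: float = 0.5
    # mediator model (victimisation-like scale)
    alpha0: float = 1.0
    a: float = -0.30
    tau2_M: float = 0.05
    sigma2_M: float = 0.8
    # outcome model (wellbeing-like scale)
    beta0: float = 23.0
    c_prime: float = 0.25
    b_w: float = -0.687
    b_b: float = 0.34
    gamma_B: float = 0.0
    d: float = 0.0
    tau2_0: float = 0.5
    tau2_1: float = 0.0
    tau_01: float = 0.0
    sigma2: float = 12.0

    def __post_init__(self):
        if self.J < 4:
            raise ValueError("need at least J=4 clusters (2 per arm)")
        if not 0 < self.allocation < 1:
            raise ValueError("allocation fraction must be in (0, 1)")
        for name in ("tau2_M", "sigma2_M", "tau2_0", "tau2_1", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_01**2 > self.tau2_0 * self.tau2_1 + 1e-12:
            raise ValueError(
                "random-effects covariance not positive semi-definite: "
                "tau_01^2 must not exceed tau2_0 * tau2_1"
            )
        if self.n_range is not None:
            lo, hi = self.n_range
            if not (1 <= lo <= hi):
                raise ValueError("n_range must satisfy 1 <= lo <= hi")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out["n_range"] is not None:
            out["n_range"] = list(out["n_range"])
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationScenario":
        payload = dict(payload)
        if payload.get("n_range") is not None:
            payload["n_range"] = tuple(payload["n_range"])
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown scenario field(s): {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- derived quantities ----------------------------------------------

    def outcome_icc_null(self, arm: int = 0) -> float:
        """Closed-form outcome intraclass correlation within one arm.

        Valid under null moderation (gamma_B = d = 0) and no random slope
        (tau2_1 = 0).  Within an arm the cluster-level outcome variance is
        ``(b_w + b_b)^2 tau2_M + tau2_0`` (mediator-induced plus intrinsic)
        and the individual-level variance is ``b_w^2 sigma2_M + sigma2``.
        """
        if self.gamma_B != 0 or self.d != 0 or self.tau2_1 != 0:
            raise ValueError("closed-form ICC requires null moderation/slope")
        between = (self.b_w + self.b_b) ** 2 * self.tau2_M + self.tau2_0
        within = self.b_w**2 * self.sigma2_M + self.sigma2
        return between / (between + within)


# -- named scenarios ---------------------------------------------------------


def scenario_s0() -> SimulationScenario:
    """Null-moderation defaults emulating the motivating school trial."""
    return SimulationScenario()


def scenario_null_a() -> SimulationScenario:
    """No treatment effect on the mediator (screen should fail)."""
    return dataclasses.replace(scenario_s0(), a=0.0)


def scenario_contextual_paradox() -> SimulationScenario:
    """Strong planted between-level (contextual) paradox."""
    return dataclasses.replace(scenario_s0(), gamma_B=-3.0)


def scenario_individual_paradox() -> SimulationScenario:
    """Planted individual-level paradox sized for roughly 80% power."""
    return dataclasses.replace(
        scenario_s0(), d=-0.35, tau2_1=0.02, tau_01=-0.03
    )


NAMED_SCENARIOS = {
    "s0": scenario_s0,
    "null-a": scenario_null_a,
    "contextual-paradox": scenario_contextual_paradox,
    "individual-paradox": scenario_individual_paradox,
}


# -- generation --------------------------------------------------------------


def generate_trial(scenario: SimulationScenario, seed: int) -> TrialDataset:
    """Draw one trial dataset.  Deterministic given (scenario, seed)."""
    rng = np.random.default_rng(seed)
    J = scenario.J
    n_treat = int(round(J * scenario.allocation))
    n_treat = min(max(n_treat, 2), J - 2)
    T = np.zeros(J, dtype=int)
    T[rng.permutation(J)[:n_treat]] = 1

    if scenario.n_range is None:
        nj = np.full(J, scenario.n_per_cluster)
    else:
        lo, hi = scenario.n_range
        nj = rng.integers(lo, hi + 1, size=J)
    N = int(nj.sum())
    cluster = np.repeat(np.arange(J), nj)
    Ti = T[cluster]

    u_M = rng.normal(0.0, np.sqrt(scenario.tau2_M), J)
    mu_M = scenario.alpha0 + scenario.a * T + u_M
    e_M = rng.normal(0.0, np.sqrt(scenario.sigma2_M), N)
    m = mu_M[cluster] + e_M

    cov = np.array(
        [[scenario.tau2_0, scenario.tau_01], [scenario.tau_01, scenario.tau2_1]]
    )
    # PSD guaranteed by scenario validation; Cholesky of the 2x2 by hand
    # to keep the draw order stable even when tau2_1 = 0
    l11 = np.sqrt(cov[0, 0])
    l21 = cov[1, 0] / l11 if l11 > 0 else 0.0
    l22 = np.sqrt(max(cov[1, 1] - l21**2, 0.0))
    z = rng.standard_normal((J, 2))
    u_Y = l11 * z[:, 0]
    s = l21 * z[:, 0] + l22 * z[:, 1]

    e_Y = rng.normal(0.0, np.sqrt(scenario.sigma2), N)
    dev = m - mu_M[cluster]
    between_slope = scenario.b_b + scenario.b_w + scenario.gamma_B * T
    within_slope = scenario.b_w + scenario.d * Ti + s[cluster]
    y = (
        scenario.beta0
        + scenario.c_prime * Ti
        + between_slope[cluster] * mu_M[cluster]
        + within_slope * dev
        + u_Y[cluster]
        + e_Y
    )

    df = pd.DataFrame(
        {
            "cluster": np.char.add("c", (cluster + 1).astype(str)),
            "treatment": Ti,
            "mediator": m,
            "outcome": y,
        }
    )
    return TrialDataset.from_frame(df)


# -- operating characteristics -----------------------------------------------


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo rejection and classification rates of the two tests."""

    scenario: SimulationScenario
    n_reps: int
    alpha: float
    base_seed: int
    test1_rejection_rate: float
    test1_mc_se: float
    test2_rejection_rate: float
    test2_mc_se: float
    test1_paradox_rate: float
    test2_paradox_rate: float
    n_converged: int
    n_failed: int
    flagged: bool = False

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["scenario"] = self.scenario.to_dict()
        return out

    def to_frame(self) -> pd.DataFrame:
        row = self.to_dict()
        row.pop("scenario")
        return pd.DataFrame([row])


def operating_characteristics(
    scenario: SimulationScenario,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    progress=None,
) -> OperatingCharacteristics:
    """Monte-Carlo type-I error / power study of Tests 1 and 2.

    Replicate ``r`` uses seed ``seed + r`` so any single replicate can be
    reproduced in isolation.  Replicates whose fits fail to converge are
    excluded from the denominators and counted; more than 20% failures
    flags the output.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_reps < 100:
        logger.warning("n_reps=%d < 100: rates will be very noisy", n_reps)
    settings = AnalysisSettings(alpha=alpha, seed=None)
    rej1 = rej2 = par1 = par2 = 0
    n_ok = n_fail = 0
    for r in range(n_reps):
        rep_seed = seed + r
        try:
            data = generate_trial(scenario, rep_seed)
            t1 = fit_test1(data, settings)
            t2 = fit_test2(data, settings)
            if not (t1.fit.converged and t2.fit.converged):
                raise RuntimeError("non-converged fit")
        except Exception as exc:  # noqa: BLE001 - per-replicate isolation
            n_fail += 1
            logger.debug("replicate %d (seed %d) failed: %s", r, rep_seed, exc)
            continue
        n_ok += 1
        if t1.moderation.p_value < alpha:
            rej1 += 1
            if t1.classification == PARADOX_SUPPORTED:
                par1 += 1
        if t2.moderation.p_value < alpha:
            rej2 += 1
            if t2.classification == PARADOX_SUPPORTED:
                par2 += 1
        if progress is not None:
            progress(r + 1, n_reps)

    if n_ok == 0:
        raise RuntimeError("every replicate failed; check the scenario")
    flagged = n_fail > 0.2 * n_reps
    if flagged:
        warnings.warn(
            f"{n_fail}/{n_reps} replicates failed to converge; rates are "
            "computed on the converged subset only",
            stacklevel=2,
        )

    def rate_se(k):
        p = k / n_ok
        return p, float(np.sqrt(p * (1 - p) / n_ok))

    p1, se1 = rate_se(rej1)
    p2, se2 = rate_se(rej2)
    return OperatingCharacteristics(
        scenario=scenario,
        n_reps=n_reps,
        alpha=alpha,
        base_seed=seed,
        test1_rejection_rate=p1,
        test1_mc_se=se1,
        test2_rejection_rate=p2,
        test2_mc_se=se2,
        test1_paradox_rate=par1 / n_ok,
        test2_paradox_rate=par2 / n_ok,
        n_converged=n_ok,
        n_failed=n_fail,
        flagged=flagged,
    )
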