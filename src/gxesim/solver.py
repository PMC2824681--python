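"""Knowledge-aided parametrization: epidemiological inputs -> model coefficients.

The simulator is parametrised with standard epidemiological measures — overall
disease frequency ``m``, genotype frequencies, relative risk ``RR31`` of the
high-risk homozygote, inheritance weight ``W`` and the environmental odds
ratio — rather than raw logistic coefficients.  This module converts those
inputs into the per-genotype ``(alpha_i, beta_i)`` pairs of the multi-logistic
model, under the constraint pattern of the requested interaction archetype:

========  =====================================  ==========================
model     intercepts                             slopes
========  =====================================  ==========================
GM        alpha_1 <= alpha_2 <= alpha_3          beta_1 = beta_2 = beta_3 = 0
EM        alpha_1 = alpha_2 = alpha_3            beta_1 = beta_2 = beta_3 != 0
GEM       alpha_1 = alpha_2 = alpha_3            beta_1 <= beta_2 <= beta_3
AM        alpha_1 <= alpha_2 <= alpha_3          beta_1 = beta_2 = beta_3 != 0
========  =====================================  ==========================

The marginal anchor is the conservation identity

    m = sum_i P(i) * TR_i

which, combined with RR21 = TR_2/TR_1 and RR31 = TR_3/TR_1, fixes the three
per-genotype total risks in closed form; the coefficients are then obtained by
deterministic bracketed root finding on the total-risk quadrature.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .mlm import (
    EnvironmentDistribution,
    MLMCoefficients,
    heterozygote_rr,
    logit,
    total_risk,
)

__all__ = [
    "InteractionModel",
    "PopulationSpec",
    "SolverResult",
    "InfeasibleParametersError",
    "InconsistentSpecError",
    "ConstraintViolationError",
    "target_total_risks",
    "solve_gm",
    "solve_em",
    "solve_am",
    "solve_gem",
    "solve_coefficients",
    "validate_constraints",
    "random_valid_spec",
]

# Bracket for intercept searches, in log-odds units; logistic(+-50) pins the
# total risk within ~2e-22 of 0/1, so any attainable target lies inside.
_ALPHA_BRACKET = (-50.0, 50.0)
# Slopes can need to be tiny when exposures are large, or sizeable when the
# exposure scale is small; a wide symmetric bracket keeps the search generic.
_BETA_BRACKET = (-500.0, 500.0)
_ROOT_TOL = 1e-10  # |TR - target| residual tolerance
_EQ_TOL = 1e-9  # equality tolerance when validating constraint patterns


class InfeasibleParametersError(ValueError):
    """m, relative risks and environment jointly demand an unreachable risk."""


class InconsistentSpecError(ValueError):
    """Inputs contradict the requested interaction model's constraints."""


class ConstraintViolationError(RuntimeError):
    """A solved coefficient set violates its interaction-model pattern."""


class InteractionModel(str, enum.Enum):
    GM = "GM"  # genetic only: flat exposure response, genotype shifts
    EM = "EM"  # environmental only: one shared logistic curve
    GEM = "GEM"  # genotype modulates the exposure slope
    AM = "AM"  # additive: shared slope, genotype-shifted intercepts
    CUSTOM = "CUSTOM"  # user-provided coefficient table, no solving


@dataclass(frozen=True)
class PopulationSpec:
    """Complete description of one simulated population.

    ``genotype_freqs`` holds one ``(P(AA), P(Aa), P(aa))`` triple per genetic
    factor and ``env_dists`` one exposure distribution per environmental
    factor.  Exactly one gene and one environment (``causal_gene_index`` /
    ``causal_env_index``) drive the disease risk; every other factor is noisy
    background that never enters the risk function.
    """

    n_individuals: int
    genotype_freqs: tuple[tuple[float, float, float], ...]
    env_dists: tuple[EnvironmentDistribution, ...]
    disease_freq: float
    model: InteractionModel
    rr31: float = 1.0
    w: float = 0.0
    env_or: float = 1.0
    causal_gene_index: int = 0
    causal_env_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", InteractionModel(self.model))
        object.__setattr__(
            self,
            "genotype_freqs",
            tuple(tuple(float(p) for p in t) for t in self.genotype_freqs),
        )
        object.__setattr__(self, "env_dists", tuple(self.env_dists))
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if not self.genotype_freqs:
            raise ValueError("at least one genetic factor is required")
        if not self.env_dists:
            raise ValueError("at least one environmental factor is required")
        for t in self.genotype_freqs:
            if len(t) != 3 or any(p < 0 for p in t):
                raise ValueError(f"invalid genotype-frequency triple {t}")
            if abs(sum(t) - 1.0) > 1e-9:
                raise ValueError(f"genotype frequencies must sum to 1, got {t}")
        if not 0.0 < self.disease_freq < 1.0:
            raise ValueError("disease_freq must lie in (0,1)")
        if not self.rr31 >= 1.0:
            raise ValueError("rr31 must be >= 1")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if not self.env_or > 0.0:
            raise ValueError("env_or must be positive")
        if not 0 <= self.causal_gene_index < self.n_genes:
            raise ValueError("causal_gene_index out of range")
        if not 0 <= self.causal_env_index < self.n_envs:
            raise ValueError("causal_env_index out of range")

    @property
    def n_genes(self) -> int:
        return len(self.genotype_freqs)

    @property
    def n_envs(self) -> int:
        return len(self.env_dists)

    @property
    def causal_genotype_freqs(self) -> tuple[float, float, float]:
        return self.genotype_freqs[self.causal_gene_index]

    @property
    def causal_env(self) -> EnvironmentDistribution:
        return self.env_dists[self.causal_env_index]

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "genotype_freqs": [list(t) for t in self.genotype_freqs],
            "env_dists": [e.to_dict() for e in self.env_dists],
            "disease_freq": self.disease_freq,
            "model": self.model.value,
            "rr31": self.rr31,
            "w": self.w,
            "env_or": self.env_or,
            "causal_gene_index": self.causal_gene_index,
            "causal_env_index": self.causal_env_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(
            n_individuals=int(d["n_individuals"]),
            genotype_freqs=tuple(tuple(t) for t in d["genotype_freqs"]),
            env_dists=tuple(
                EnvironmentDistribution.from_dict(e) for e in d["env_dists"]
            ),
            disease_freq=float(d["disease_freq"]),
            model=InteractionModel(d["model"]),
            rr31=float(d.get("rr31", 1.0)),
            w=float(d.get("w", 0.0)),
            env_or=float(d.get("env_or", 1.0)),
            causal_gene_index=int(d.get("causal_gene_index", 0)),
            causal_env_index=int(d.get("causal_env_index", 0)),
        )


@dataclass(frozen=True)
class SolverResult:
    """Solved coefficients plus the marginal risks they were asked to match."""

    coefficients: MLMCoefficients
    target_trs: tuple[float, float, float]
    achieved_trs: tuple[float, float, float]
    max_residual: float
    model: InteractionModel

    def to_dict(self) -> dict:
        return {
            "model": self.model.value,
            "coefficients": self.coefficients.to_dict(),
            "target_total_risks": list(self.target_trs),
            "achieved_total_risks": list(self.achieved_trs),
            "max_residual": self.max_residual,
        }


def target_total_risks(
    m: float,
    genotype_freqs: Sequence[float],
    rr31: float,
    w: float,
) -> tuple[float, float, float]:
    """Per-genotype total risks implied by (m, genotype freqs, RR31, W).

    Solving m = sum_i P(i) TR_i together with TR_2 = RR21 TR_1 and
    TR_3 = RR31 TR_1 gives

        TR_1 = m / (P_1 + P_2 RR21 + P_3 RR31)

    with RR21 = 1 + W (RR31 - 1).
    """
    p1, p2, p3 = genotype_freqs
    if not 0.0 < m < 1.0:
        raise ValueError("m must lie in (0,1)")
    rr21 = heterozygote_rr(rr31, w)
    tr1 = m / (p1 + p2 * rr21 + p3 * rr31)
    trs = (tr1, tr1 * rr21, tr1 * rr31)
    if max(trs) >= 1.0:
        raise InfeasibleParametersError(
            f"requested m={m} with RR21={rr21:.4g}, RR31={rr31:.4g} implies a "
            f"per-genotype total risk of {max(trs):.4g} >= 1; reduce m or the "
            "relative risks"
        )
    return trs


def _solve_root(f, bracket: tuple[float, float], what: str) -> float:
    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise InfeasibleParametersError(
            f"no bracketed root for {what}: f({lo})={flo:.3g}, f({hi})={fhi:.3g}"
        )
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))


def _solve_alpha(beta: float, env: EnvironmentDistribution, target: float) -> float:
    """Intercept with total_risk(alpha, beta, env) = target (monotone in alpha)."""
    return _solve_root(
        lambda a: total_risk(a, beta, env) - target,
        _ALPHA_BRACKET,
        f"intercept matching TR={target:.4g}",
    )


def _result(
    spec: PopulationSpec,
    coeffs: MLMCoefficients,
    targets: tuple[float, float, float],
) -> SolverResult:
    env = spec.causal_env
    achieved = tuple(
        total_risk(coeffs.alpha[i], coeffs.beta[i], env) for i in range(3)
    )
    resid = max(abs(a - t) for a, t in zip(achieved, targets))
    if resid > _ROOT_TOL:
        raise ArithmeticError(
            f"solver residual {resid:.3g} exceeds tolerance {_ROOT_TOL:g}"
        )
    violations = validate_constraints(coeffs, spec.model)
    if violations:
        raise ConstraintViolationError(
            f"{spec.model.value} constraints violated: " + "; ".join(violations)
        )
    return SolverResult(
        coefficients=coeffs,
        target_trs=targets,
        achieved_trs=achieved,
        max_residual=resid,
        model=spec.model,
    )


def _spec_targets(spec: PopulationSpec) -> tuple[float, float, float]:
    return target_total_risks(
        spec.disease_freq, spec.causal_genotype_freqs, spec.rr31, spec.w
    )


def solve_gm(spec: PopulationSpec) -> SolverResult:
    """Genetic model: zero slopes, intercepts in closed form.

    With beta_i = 0 the total risk of genotype i is logistic(alpha_i)
    independently of the environment, so alpha_i = logit(TR_i).
    """
    targets = _spec_targets(spec)
    coeffs = MLMCoefficients(
        alpha=tuple(logit(t) for t in targets), beta=(0.0, 0.0, 0.0)
    )
    return _result(spec, coeffs, targets)


def solve_em(spec: PopulationSpec) -> SolverResult:
    """Environmental model: one shared curve; requires rr31 = 1 and env_or != 1."""
    if spec.rr31 != 1.0:
        raise InconsistentSpecError(
            "EM makes all genotype risks equal; rr31 must be 1 "
            f"(got {spec.rr31})"
        )
    if spec.env_or == 1.0:
        raise InconsistentSpecError("EM requires a non-null slope: env_or must differ from 1")
    targets = _spec_targets(spec)  # all equal to m here
    beta = math.log(spec.env_or)
    alpha = _solve_alpha(beta, spec.causal_env, spec.disease_freq)
    coeffs = MLMCoefficients(alpha=(alpha,) * 3, beta=(beta,) * 3)
    return _result(spec, coeffs, targets)


def solve_am(spec: PopulationSpec) -> SolverResult:
    """Additive model: shared slope from env_or, per-genotype intercepts."""
    if spec.env_or == 1.0:
        raise InconsistentSpecError("AM requires a non-null slope: env_or must differ from 1")
    targets = _spec_targets(spec)
    beta = math.log(spec.env_or)
    env = spec.causal_env
    alphas = tuple(_solve_alpha(beta, env, t) for t in targets)
    coeffs = MLMCoefficients(alpha=alphas, beta=(beta,) * 3)
    return _result(spec, coeffs, targets)


def solve_gem(spec: PopulationSpec) -> SolverResult:
    """Gene-modulated environmental response: shared intercept, solved slopes.

    The user's odds ratio anchors the reference-homozygote slope,
    beta_1 = ln(env_or); the shared intercept is solved so that genotype 1
    matches TR_1, then beta_2 and beta_3 are solved one equation at a time.
    Total risk is monotone in beta only when exposures are nonnegative, so
    environments whose (numerical) support extends below zero are rejected.
    """
    env = spec.causal_env
    if env.support_min < 0.0:
        raise InconsistentSpecError(
            "GEM slope solving needs a nonnegative exposure support (total "
            f"risk must be monotone in beta); support reaches {env.support_min:.4g}. "
            "Shift the exposure scale so its support starts at 0 or above."
        )
    targets = _spec_targets(spec)
    beta1 = math.log(spec.env_or)
    alpha = _solve_alpha(beta1, env, targets[0])
    betas = [beta1]
    for i in (1, 2):
        # equal target risks force the slope already in hand (also covers a
        # degenerate exposure the slope cannot act on)
        if abs(total_risk(alpha, betas[-1], env) - targets[i]) < _ROOT_TOL:
            betas.append(betas[-1])
            continue
        betas.append(
            _solve_root(
                lambda b: total_risk(alpha, b, env) - targets[i],
                _BETA_BRACKET,
                f"slope matching TR_{i + 1}={targets[i]:.4g}",
            )
        )
    coeffs = MLMCoefficients(alpha=(alpha,) * 3, beta=tuple(betas))
    return _result(spec, coeffs, targets)


_DISPATCH = {
    InteractionModel.GM: solve_gm,
    InteractionModel.EM: solve_em,
    InteractionModel.GEM: solve_gem,
    InteractionModel.AM: solve_am,
}


def solve_coefficients(spec: PopulationSpec) -> SolverResult:
    """Dispatch to the interaction-model-specific solver and validate."""
    if spec.model is InteractionModel.CUSTOM:
        raise InconsistentSpecError(
            "CUSTOM model is not solved: supply a GeneralCoefficientTable "
            "with the coefficients instead"
        )
    return _DISPATCH[spec.model](spec)


def validate_constraints(
    coeffs: MLMCoefficients, model: InteractionModel
) -> list[str]:
    """All Table-pattern violations of ``coeffs`` under ``model`` (empty = pass).

    Equalities are checked with absolute tolerance 1e-9; inequalities allow
    the same slack.
    """
    a1, a2, a3 = coeffs.alpha
    b1, b2, b3 = coeffs.beta
    out: list[str] = []

    def eq(x, y):  # noqa: ANN001 - tiny local predicate
        return abs(x - y) <= _EQ_TOL

    def le(x, y):
        return x <= y + _EQ_TOL

    if model is InteractionModel.GM:
        if not (le(a1, a2) and le(a2, a3)):
            out.append(f"alpha not nondecreasing: {coeffs.alpha}")
        if not (eq(b1, 0) and eq(b2, 0) and eq(b3, 0)):
            out.append(f"beta not all zero: {coeffs.beta}")
    elif model is InteractionModel.EM:
        if not (eq(a1, a2) and eq(a2, a3)):
            out.append(f"alpha not all equal: {coeffs.alpha}")
        if not (eq(b1, b2) and eq(b2, b3)):
            out.append(f"beta not all equal: {coeffs.beta}")
        if eq(b1, 0):
            out.append("beta must be non-null under EM")
    elif model is InteractionModel.GEM:
        if not (eq(a1, a2) and eq(a2, a3)):
            out.append(f"alpha not all equal: {coeffs.alpha}")
        if not (le(b1, b2) and le(b2, b3)):
            out.append(f"beta not nondecreasing: {coeffs.beta}")
    elif model is InteractionModel.AM:
        if not (le(a1, a2) and le(a2, a3)):
            out.append(f"alpha not nondecreasing: {coeffs.alpha}")
        if not (eq(b1, b2) and eq(b2, b3)):
            out.append(f"beta not all equal: {coeffs.beta}")
        if eq(b1, 0):
            out.append("beta must be non-null under AM")
    else:
        out.append(f"no constraint pattern defined for model {model}")
    return out


def random_valid_spec(
    rng: np.random.Generator,
    model: InteractionModel | str | None = None,
    n_individuals: int = 1000,
    max_tries: int = 200,
) -> PopulationSpec:
    """Draw a random feasible one-gene/one-environment specification.

    Sampling ranges: RR31 uniform in [1, 5], W uniform in [0, 1], m uniform in
    [0.02, 0.3], allele frequency uniform in [0.1, 0.9] (genotype triple by
    Hardy-Weinberg), environmental OR log-uniform in [1/3, 3] (bounded away
    from 1 where the model requires a non-null slope).  Environments are drawn
    among discrete, uniform and normal kinds, restricted to nonnegative
    support for GEM.  Draws that are infeasible (an implied total risk >= 1 or
    an unreachable slope) are rejected and resampled.
    """
    want = None if model is None else InteractionModel(model)
    for _ in range(max_tries):
        solvable = (
            InteractionModel.GM,
            InteractionModel.EM,
            InteractionModel.GEM,
            InteractionModel.AM,
        )
        mdl = want or solvable[int(rng.integers(len(solvable)))]
        rr31 = 1.0 if mdl is InteractionModel.EM else float(rng.uniform(1.0, 5.0))
        w = float(rng.uniform(0.0, 1.0))
        m = float(rng.uniform(0.02, 0.3))
        p = float(rng.uniform(0.1, 0.9))
        freqs = (p * p, 2 * p * (1 - p), (1 - p) * (1 - p))
        env_or = float(np.exp(rng.uniform(np.log(1 / 3), np.log(3.0))))
        if mdl in (InteractionModel.EM, InteractionModel.AM) and abs(env_or - 1) < 0.05:
            env_or = 1.2
        kind = rng.choice(["discrete", "uniform", "normal"])
        if kind == "discrete":
            k = int(rng.integers(2, 5))
            probs = rng.dirichlet(np.ones(k))
            env = EnvironmentDistribution.discrete_dist(np.arange(k, dtype=float), probs)
        elif kind == "uniform":
            env = EnvironmentDistribution.uniform_dist(0.0, float(rng.uniform(1.0, 4.0)))
        elif mdl is InteractionModel.GEM:
            # normal support crosses zero: use a nonnegative uniform instead
            env = EnvironmentDistribution.uniform_dist(0.0, float(rng.uniform(1.0, 4.0)))
        else:
            env = EnvironmentDistribution.normal_dist(
                float(rng.uniform(-1.0, 1.0)), float(rng.uniform(0.5, 2.0))
            )
        try:
            spec = PopulationSpec(
                n_individuals=n_individuals,
                genotype_freqs=(freqs,),
                env_dists=(env,),
                disease_freq=m,
                model=mdl,
                rr31=rr31,
                w=w,
                env_or=env_or,
            )
            solve_coefficients(spec)  # feasibility probe
        except (InfeasibleParametersError, InconsistentSpecError, ConstraintViolationError):
            continue
        return spec
    raise RuntimeError(f"no feasible specification found in {max_tries} draws")
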