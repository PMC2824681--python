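"""Empirical validation of a simulated sample against its specification.

Recomputes the epidemiological quantities a user asked for — prevalence,
per-genotype risks and their ratios, per-genotype exposure slopes — directly
from the generated data, and reports each discrepancy in standard-error units
so a run can be sanity-checked at a glance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mlm import EnvironmentDistribution, logistic, heterozygote_rr
from .population import Dataset
from .solver import InteractionModel, PopulationSpec, target_total_risks

__all__ = ["SummaryReport", "summarize", "mc_total_risk", "logit_fit"]

_NEWTON_TOL = 1e-8
_NEWTON_MAXIT = 100


def logit_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Maximum-likelihood simple logistic regression of y on x with intercept.

    Newton-Raphson on the two-parameter log-likelihood, converged when the
    update norm drops below 1e-8; returns (intercept, slope, se_intercept,
    se_slope) with standard errors from the inverse observed information.
    Raises ``ArithmeticError`` when the fit cannot converge (e.g. complete
    separation or a one-class stratum).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must be equal-length, nonempty vectors")
    if y.min() == y.max():
        raise ArithmeticError("degenerate outcome: all responses identical")
    X = np.column_stack([np.ones_like(x), x])
    theta = np.zeros(2)
    for _ in range(_NEWTON_MAXIT):
        eta = X @ theta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wvar = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * wvar[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ArithmeticError("singular information matrix in logit fit") from exc
        # dampen huge steps (quasi-separation) to keep the iteration stable
        norm = float(np.max(np.abs(step)))
        if norm > 10.0:
            step *= 10.0 / norm
        theta = theta + step
        if norm < _NEWTON_TOL:
            cov = np.linalg.inv(info)
            return (
                float(theta[0]),
                float(theta[1]),
                float(math.sqrt(cov[0, 0])),
                float(math.sqrt(cov[1, 1])),
            )
    raise ArithmeticError("logit fit did not converge")


@dataclass(frozen=True)
class SummaryReport:
    """Empirical measures of one dataset next to the values its spec requested."""

    n: int
    empirical_prevalence: float
    per_genotype_n: tuple[int, int, int]
    per_genotype_risk: tuple[float, float, float]
    empirical_rr21: float
    empirical_rr31: float
    per_genotype_logit_slope: tuple[float | None, float | None, float | None]
    per_genotype_slope_se: tuple[float | None, float | None, float | None]
    spec_targets: dict
    z_scores: dict

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "empirical_prevalence": self.empirical_prevalence,
            "per_genotype_n": list(self.per_genotype_n),
            "per_genotype_risk": list(self.per_genotype_risk),
            "empirical_rr21": self.empirical_rr21,
            "empirical_rr31": self.empirical_rr31,
            "per_genotype_logit_slope": list(self.per_genotype_logit_slope),
            "per_genotype_slope_se": list(self.per_genotype_slope_se),
            "spec_targets": self.spec_targets,
            "z_scores": self.z_scores,
        }

    def render(self) -> str:
        """Human-readable block for the run log."""
        t = self.spec_targets
        z = self.z_scores
        lines = [
            f"n = {self.n}",
            f"prevalence: {self.empirical_prevalence:.5f} "
            f"(requested {t['m']:.5f}, z = {z['prevalence']:+.2f})",
        ]
        for i in range(3):
            slope = self.per_genotype_logit_slope[i]
            slope_s = "undefined" if slope is None else f"{slope:+.4f}"
            lines.append(
                f"genotype {i + 1}: n={self.per_genotype_n[i]}, "
                f"affected fraction {self.per_genotype_risk[i]:.5f} "
                f"(target TR {t['total_risks'][i]:.5f}), slope {slope_s}"
            )
        lines.append(
            f"RR21 = {self.empirical_rr21:.4f} (target {t['rr21']:.4f}); "
            f"RR31 = {self.empirical_rr31:.4f} (target {t['rr31']:.4f})"
        )
        return "\n".join(lines)


def summarize(dataset: Dataset, spec: PopulationSpec) -> SummaryReport:
    """Recompute the requested epidemiological measures from the sample.

    Per-genotype affected fractions and exposure slopes are computed in the
    causal gene's strata against the causal exposure.  An empty or degenerate
    stratum yields an undefined (None) slope rather than an error.  The
    function is deterministic: the only iterative piece is the Newton logistic
    fit.
    """
    if dataset.status is None:
        raise RuntimeError("summarize requires a dataset with assigned status")
    status = dataset.status.astype(float)
    n = dataset.n
    prev = float(status.mean())
    g = dataset.genotypes[:, spec.causal_gene_index]
    x = dataset.exposures[:, spec.causal_env_index]

    counts: list[int] = []
    fracs: list[float] = []
    slopes: list[float | None] = []
    slope_ses: list[float | None] = []
    for i in (1, 2, 3):
        mask = g == i
        ni = int(mask.sum())
        counts.append(ni)
        fracs.append(float(status[mask].mean()) if ni else float("nan"))
        try:
            _, slope, _, se = logit_fit(x[mask], status[mask])
            slopes.append(slope)
            slope_ses.append(se)
        except (ArithmeticError, ValueError):
            slopes.append(None)
            slope_ses.append(None)

    rr21 = fracs[1] / fracs[0] if fracs[0] > 0 else float("nan")
    rr31 = fracs[2] / fracs[0] if fracs[0] > 0 else float("nan")

    m = spec.disease_freq
    if spec.model is InteractionModel.CUSTOM:
        targets = {"m": m, "rr21": float("nan"), "rr31": float("nan"),
                   "total_risks": [float("nan")] * 3}
    else:
        trs = target_total_risks(m, spec.causal_genotype_freqs, spec.rr31, spec.w)
        targets = {
            "m": m,
            "rr21": heterozygote_rr(spec.rr31, spec.w),
            "rr31": spec.rr31,
            "total_risks": list(trs),
        }

    z: dict[str, float] = {}
    se_prev = math.sqrt(m * (1 - m) / n)
    z["prevalence"] = (prev - m) / se_prev if se_prev > 0 else float("nan")
    z["per_genotype_risk"] = []
    for i in range(3):
        tr = targets["total_risks"][i]
        ni = counts[i]
        if ni > 0 and 0 < tr < 1:
            se = math.sqrt(tr * (1 - tr) / ni)
            z["per_genotype_risk"].append((fracs[i] - tr) / se)
        else:
            z["per_genotype_risk"].append(float("nan"))

    return SummaryReport(
        n=n,
        empirical_prevalence=prev,
        per_genotype_n=tuple(counts),
        per_genotype_risk=tuple(fracs),
        empirical_rr21=rr21,
        empirical_rr31=rr31,
        per_genotype_logit_slope=tuple(slopes),
        per_genotype_slope_se=tuple(slope_ses),
        spec_targets=targets,
        z_scores=z,
    )


def mc_total_risk(
    alpha: float,
    beta: float,
    env: EnvironmentDistribution,
    n: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte Carlo estimate of the total risk, with its standard error.

    Sampling-based counterpart of :func:`gxesim.mlm.total_risk`: the mean of
    ``logistic(alpha + beta x)`` over ``n`` draws from the exposure law.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = logistic(alpha + beta * env.sample(n, rng))
    r = np.atleast_1d(r)
    est = float(r.mean())
    se = float(r.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return est, se
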